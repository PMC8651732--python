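"""Cleaning of raw trait tables and derivation of the model covariates.

Mirrors the study's pre-analysis: particles of the two large ciliates with a
bio-area below 1000 µm² are discarded as non-living debris, per-sample density
is derived from the tracked count and the effective sampled video volume
(34.4 µl), and bio-fraction — the share of a sample's total bio-area
contributed by competitor species — is computed per focal species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import EmptySampleError

#: Bio-area filter threshold, µm². Strictly smaller particles are removed.
DEFAULT_MIN_BIOAREA = 1000.0

#: Effective video sample volume, µl.
DEFAULT_VOLUME_UL = 34.4

#: Species the bio-area filter applies to (debris is only mistakable for the
#: two large ciliates).
FILTERED_SPECIES = ("PA", "ST")


@dataclass(frozen=True)
class FilterResult:
    records: pd.DataFrame
    n_retained: int
    n_removed: int


def filter_min_bioarea(
    records: pd.DataFrame,
    threshold: float = DEFAULT_MIN_BIOAREA,
    species: Sequence[str] = FILTERED_SPECIES,
) -> FilterResult:
    """Remove records with ``bio_area`` strictly below ``threshold``.

    Applies only to the species in ``species``; the boundary value itself is
    retained.  Row order is preserved.  Idempotent.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    applies = records["species"].isin(species)
    keep = ~applies | (records["bio_area"] >= threshold)
    kept = records.loc[keep]
    return FilterResult(kept, int(keep.sum()), int((~keep).sum()))


def compute_density(n_individuals: int, sampled_volume_ul: float = DEFAULT_VOLUME_UL) -> float:
    """Individuals per ml from a tracked count and sampled volume in µl."""
    if sampled_volume_ul <= 0:
        raise ValueError("sampled_volume_ul must be > 0")
    if n_individuals < 0:
        raise ValueError("n_individuals must be >= 0")
    return n_individuals / (sampled_volume_ul / 1000.0)


def compute_biofraction(sample_records: pd.DataFrame, focal_species: str) -> float:
    """Share of the sample's total bio-area contributed by non-focal species.

    0 when only the focal species is present, 1 when the focal species is
    absent.  Raises :class:`EmptySampleError` on an empty sample.
    """
    if len(sample_records) == 0:
        raise EmptySampleError("bio-fraction is undefined for an empty sample")
    total = float(sample_records["bio_area"].sum())
    focal = float(
        sample_records.loc[sample_records["species"] == focal_species, "bio_area"].sum()
    )
    return (total - focal) / total


@dataclass(frozen=True)
class SampleContext:
    """Per-sample covariates for one focal species in one sampled video."""

    sample_id: str
    focal_species: str
    counts: Mapping[str, int]
    density: float
    biofraction: float
    sampled_volume_ul: float = DEFAULT_VOLUME_UL

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if not 0.0 <= self.biofraction <= 1.0:
            raise ValueError("biofraction must lie in [0, 1]")


def derive_sample_contexts(
    records: pd.DataFrame, sampled_volume_ul: float = DEFAULT_VOLUME_UL
) -> dict[tuple[str, str], SampleContext]:
    """Compute one :class:`SampleContext` per (sample, focal species) pair
    from the records themselves.

    Density is the focal species' count scaled to individuals/ml; bio-fraction
    is the competitors' bio-area share within the sample.
    """
    contexts: dict[tuple[str, str], SampleContext] = {}
    for sample_id, grp in records.groupby("sample_id", sort=True):
        counts = grp["species"].value_counts().to_dict()
        for sp in counts:
            contexts[(sample_id, sp)] = SampleContext(
                sample_id=sample_id,
                focal_species=sp,
                counts=counts,
                density=compute_density(counts[sp], sampled_volume_ul),
                biofraction=compute_biofraction(grp, sp),
                sampled_volume_ul=sampled_volume_ul,
            )
    return contexts


def build_analysis_table(
    records: pd.DataFrame,
    contexts: Mapping[tuple[str, str], SampleContext],
) -> pd.DataFrame:
    """Join per-sample covariates onto individual records.

    Returns one row per individual with ``density`` and ``biofraction``
    columns added.  Records whose (sample, species) pair has no context are
    rejected with the offending identifiers.
    """
    keys = list(zip(records["sample_id"], records["species"]))
    orphans = sorted({k for k in keys if k not in contexts})
    if orphans:
        raise ValueError(
            "records without a sample context: "
            + ", ".join(f"{s}/{sp}" for s, sp in orphans[:10])
            + ("..." if len(orphans) > 10 else "")
        )
    out = records.copy()
    out["density"] = [contexts[k].density for k in keys]
    out["biofraction"] = [contexts[k].biofraction for k in keys]
    return out


def prepare_analysis_table(
    records: pd.DataFrame,
    min_bioarea: float = DEFAULT_MIN_BIOAREA,
    sampled_volume_ul: float = DEFAULT_VOLUME_UL,
    filtered_species: Sequence[str] = FILTERED_SPECIES,
) -> pd.DataFrame:
    """Filter debris, derive covariates and return the model-ready table.

    Counts (hence density and bio-fraction) are computed after filtering,
    since the removed particles are non-living.
    """
    filt = filter_min_bioarea(records, min_bioarea, filtered_species)
    if len(filt.records) == 0:
        return filt.records.assign(density=pd.Series(dtype=float),
                                   biofraction=pd.Series(dtype=float))
    contexts = derive_sample_contexts(filt.records, sampled_volume_ul)
    return build_analysis_table(filt.records, contexts)
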