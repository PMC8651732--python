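"""Enumeration of the selection-phase and common-garden experimental designs.

The selection phase crosses salinity levels with species treatments (each
species alone, or the full community) and replicates each combination.  The
common garden re-exposes every surviving selection line to the salinity
gradient: lines selected at zero salinity are inoculated into all common-garden
salinities, while lines selected at non-zero salinity can only be inoculated
into the non-zero salinities (carry-over of medium makes a strict zero
impossible).  *T. thermophila* lines are excluded from the common garden.

Identifiers are deterministic composites so that re-running the enumeration
with identical inputs yields byte-identical designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .exceptions import DesignError

#: Salinity levels used in the study, g/l NaCl.
SALINITY_LEVELS: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)

#: Species treatments: each ciliate alone, or the three-species community.
SPECIES_TREATMENTS: tuple[str, ...] = ("PA_alone", "ST_alone", "TT_alone", "community")

#: Treatments excluded from the common garden by default (T. thermophila went
#: extinct in almost all microcosms during the selection phase).
DEFAULT_CG_EXCLUDED: frozenset[str] = frozenset({"TT_alone"})


def _fmt_salinity(s: float) -> str:
    """Compact label for a salinity level: 0.0 -> '0', 0.5 -> '0.5'."""
    return f"{s:g}"


@dataclass(frozen=True)
class SelectionMicrocosm:
    """One selection-phase microcosm (a 50 ml tube evolved for 78 days)."""

    microcosm_id: str
    salinity: float
    species_treatment: str
    replicate: int
    alias: Optional[str] = field(default=None, compare=False)

    @property
    def competition(self) -> bool:
        """True when interspecific competitors are present."""
        return self.species_treatment == "community"


@dataclass(frozen=True)
class CommonGardenMicrocosm:
    """One common-garden microcosm, inoculated from a selection line on day 78."""

    cg_id: str
    source_microcosm_id: str
    historical_salinity: float
    cg_salinity: float
    cg_replicate: int
    species_treatment: str
    replicate: int
    alias: Optional[str] = field(default=None, compare=False)


def enumerate_selection_design(
    salinities: Sequence[float] = SALINITY_LEVELS,
    species_treatments: Sequence[str] = SPECIES_TREATMENTS,
    n_replicates: int = 3,
) -> list[SelectionMicrocosm]:
    """Enumerate the full-factorial selection design.

    Returns ``len(salinities) * len(species_treatments) * n_replicates``
    microcosms in deterministic (salinity, treatment, replicate) order.
    With the study's levels (5 salinities x 4 treatments x 3 replicates)
    this yields 60 microcosms over 20 unique treatment combinations.

    Raises
    ------
    DesignError
        If any input list is empty, salinity levels repeat, or
        ``n_replicates < 1``.
    """
    salinities = list(salinities)
    species_treatments = list(species_treatments)
    if not salinities or not species_treatments:
        raise DesignError("salinities and species_treatments must be non-empty")
    if len(set(salinities)) != len(salinities):
        raise DesignError(f"duplicate salinity levels in {salinities}")
    if len(set(species_treatments)) != len(species_treatments):
        raise DesignError(f"duplicate species treatments in {species_treatments}")
    if n_replicates < 1:
        raise DesignError("n_replicates must be >= 1")

    out = []
    for sal in salinities:
        for treat in species_treatments:
            for rep in range(1, n_replicates + 1):
                mid = f"S{_fmt_salinity(sal)}_{treat}_r{rep}"
                out.append(SelectionMicrocosm(mid, float(sal), treat, rep))
    return out


def enumerate_common_garden_design(
    selection: Sequence[SelectionMicrocosm],
    cg_salinities: Sequence[float] = SALINITY_LEVELS,
    n_cg_replicates: int = 2,
    excluded_treatments: Iterable[str] = DEFAULT_CG_EXCLUDED,
) -> list[CommonGardenMicrocosm]:
    """Enumerate the common-garden design from a selection design.

    For every selection microcosm whose treatment is not excluded, one
    common-garden microcosm is created per admissible salinity per
    common-garden replicate.  Zero-salinity selection lines admit every
    common-garden salinity; non-zero lines admit only the non-zero
    salinities.  With the study's design (45 non-excluded lines, 5 levels,
    2 replicates) this yields 378 microcosms.

    Raises
    ------
    DesignError
        If a selection microcosm carries an unknown treatment label, the
        salinity lists are inconsistent, or ``n_cg_replicates < 1``.
    """
    cg_salinities = list(cg_salinities)
    excluded = frozenset(excluded_treatments)
    if not cg_salinities:
        raise DesignError("cg_salinities must be non-empty")
    if len(set(cg_salinities)) != len(cg_salinities):
        raise DesignError(f"duplicate common-garden salinity levels in {cg_salinities}")
    if n_cg_replicates < 1:
        raise DesignError("n_cg_replicates must be >= 1")

    known = set(SPECIES_TREATMENTS) | excluded
    unknown = {m.species_treatment for m in selection} - known
    if unknown:
        raise DesignError(f"unknown species treatments in selection design: {sorted(unknown)}")
    missing = {m.salinity for m in selection} - set(cg_salinities)
    if missing:
        raise DesignError(
            f"selection salinities {sorted(missing)} absent from common-garden levels"
        )

    out = []
    for src in selection:
        if src.species_treatment in excluded:
            continue
        if src.salinity == 0:
            admissible = cg_salinities
        else:
            admissible = [s for s in cg_salinities if s != 0]
        for cg_sal in admissible:
            for cg_rep in range(1, n_cg_replicates + 1):
                cg_id = f"{src.microcosm_id}_CG{_fmt_salinity(cg_sal)}_r{cg_rep}"
                out.append(
                    CommonGardenMicrocosm(
                        cg_id=cg_id,
                        source_microcosm_id=src.microcosm_id,
                        historical_salinity=src.salinity,
                        cg_salinity=float(cg_sal),
                        cg_replicate=cg_rep,
                        species_treatment=src.species_treatment,
                        replicate=src.replicate,
                    )
                )
    return out


def selection_design_frame(design: Sequence[SelectionMicrocosm]) -> pd.DataFrame:
    """Selection design as a table (TSV-ready)."""
    return pd.DataFrame(
        {
            "microcosm_id": [m.microcosm_id for m in design],
            "salinity_g_per_l": [m.salinity for m in design],
            "species_treatment": [m.species_treatment for m in design],
            "replicate": [m.replicate for m in design],
        }
    )


def common_garden_design_frame(design: Sequence[CommonGardenMicrocosm]) -> pd.DataFrame:
    """Common-garden design as a table (TSV-ready)."""
    return pd.DataFrame(
        {
            "cg_id": [m.cg_id for m in design],
            "source_microcosm_id": [m.source_microcosm_id for m in design],
            "historical_salinity_g_per_l": [m.historical_salinity for m in design],
            "cg_salinity_g_per_l": [m.cg_salinity for m in design],
            "cg_replicate": [m.cg_replicate for m in design],
            "species_treatment": [m.species_treatment for m in design],
            "replicate": [m.replicate for m in design],
        }
    )
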