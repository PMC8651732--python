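"""Selection-phase temporal trait-shift analysis.

For each species x trait, fits the mixed model

    trait ~ salinity + time + competition + density + biofraction
            + salinity:time + salinity:competition + time:competition
            + salinity:time:competition + (1 | microcosm)

on the two selection-phase samplings (day 4 = start, day 78 = end).  A
significant ``time`` effect is a trait shift over the selection phase; a
significant ``time:competition`` interaction means the shift differed
between the absence and presence of competitors.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .mixedmodel import (
    InsufficientData,
    ModelFit,
    ModelSpec,
    fit_lmm,
    significance_code,
)
from .simulate import PHASE_CG, TRAITS

#: Fixed terms of the temporal model; "historical_salinity" is the salinity
#: of the microcosm during the selection phase.
TEMPORAL_FIXED = ("historical_salinity", "time", "competition", "density", "biofraction")
TEMPORAL_INTERACTIONS = (
    ("historical_salinity", "time"),
    ("historical_salinity", "competition"),
    ("time", "competition"),
    ("historical_salinity", "time", "competition"),
)


def temporal_model_spec(trait: str, df_method: str = "satterthwaite") -> ModelSpec:
    return ModelSpec(
        response=trait,
        fixed_terms=TEMPORAL_FIXED,
        interactions=TEMPORAL_INTERACTIONS,
        random_intercepts=("microcosm_id",),
        df_method=df_method,
    )


def fit_temporal_model(
    table: pd.DataFrame,
    species: str,
    trait: str,
    df_method: str = "satterthwaite",
) -> Union[ModelFit, InsufficientData]:
    """Fit the temporal trait-shift model for one species.

    Returns :class:`InsufficientData` (not an exception) when the species has
    no records at one of the two time points — e.g. populations extinct by
    day 78.
    """
    sub = table[(table["species"] == species) & (table["phase"] != PHASE_CG)]
    if len(sub) == 0:
        return InsufficientData(f"no selection-phase records for species {species!r}")
    times = set(pd.unique(sub["time"].astype(int)))
    if times != {0, 1}:
        missing = {0, 1} - times
        day = "day 4" if 0 in missing else "day 78"
        return InsufficientData(
            f"species {species!r} lacks {day} records; temporal shift not estimable"
        )
    sub = sub.copy()
    sub["time"] = sub["time"].astype(int)
    sub["competition"] = sub["competition"].astype(int)
    return fit_lmm(sub, temporal_model_spec(trait, df_method))


def summarize_temporal(
    fits: Mapping[tuple[str, str], Union[ModelFit, InsufficientData]],
) -> pd.DataFrame:
    """Long-format effect table over (species, trait) fits with significance
    codes; deterministic row order (species, trait, model term order)."""
    rows = []
    for (species, trait) in sorted(fits):
        fit = fits[(species, trait)]
        if isinstance(fit, InsufficientData):
            rows.append(
                dict(species=species, trait=trait, term="(insufficient data)",
                     estimate=np.nan, se=np.nan, p=np.nan, signif="",
                     note=fit.reason)
            )
            continue
        for term in fit.terms:
            p = fit.p_values[term]
            rows.append(
                dict(species=species, trait=trait, term=term,
                     estimate=fit.coefficients[term],
                     se=fit.standard_errors[term], p=p,
                     signif=significance_code(p), note="")
            )
    return pd.DataFrame(rows)


def pairwise_temporal_differences(
    table: pd.DataFrame, species: str, trait: str, max_pairs_per_cell: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Descriptive start-vs-end trait differences of all pairwise individual
    combinations within each microcosm (not used for inference).

    Each row is one (day-78 individual, day-4 individual) pair from the same
    microcosm with their trait difference end - start.  ``max_pairs_per_cell``
    caps the combinatorial blow-up per microcosm by uniform subsampling.
    """
    sub = table[(table["species"] == species) & (table["phase"] != PHASE_CG)]
    rng = np.random.default_rng(seed)
    rows = []
    for mid, grp in sub.groupby("microcosm_id", sort=True):
        start = grp.loc[grp["time"] == 0, trait].to_numpy()
        end = grp.loc[grp["time"] == 1, trait].to_numpy()
        if len(start) == 0 or len(end) == 0:
            continue
        pairs = [(i, j) for i in range(len(end)) for j in range(len(start))]
        if len(pairs) > max_pairs_per_cell:
            idx = rng.choice(len(pairs), size=max_pairs_per_cell, replace=False)
            pairs = [pairs[k] for k in sorted(idx)]
        for i, j in pairs:
            rows.append(dict(microcosm_id=mid, species=species, trait=trait,
                             difference=end[i] - start[j]))
    return pd.DataFrame(rows, columns=["microcosm_id", "species", "trait", "difference"])
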