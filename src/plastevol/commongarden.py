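"""Common-garden analyses.

Three operations on day-82 common-garden records:

* the full common-garden model: historical salinity x common-garden salinity
  x competition history (plus density and bio-fraction covariates), with
  random intercepts for the source selection microcosm and for replicate
  nested within historical x common-garden salinity (encoded as a composite
  grouping label);
* per-population plasticity regressions: the trait's slope on common-garden
  salinity between one pair of environments for one selected population;
* genetic contrasts: the trait difference between populations selected in
  the same salinity but opposite competition treatments, valid only where
  competitor species are absent from the compared samples (extinction is
  verified from the data, with an explicit override to acknowledge
  confounding, mirroring the judgement call on contaminated samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ConfoundedSamplesError, NotComputableError
from .mixedmodel import InsufficientData, ModelFit, ModelSpec, fit_lmm
from .simulate import PHASE_CG

CG_FIXED = ("historical_salinity", "cg_salinity", "competition", "density", "biofraction")
CG_INTERACTIONS = (
    ("historical_salinity", "cg_salinity"),
    ("historical_salinity", "competition"),
    ("cg_salinity", "competition"),
    ("historical_salinity", "cg_salinity", "competition"),
)


def commongarden_model_spec(trait: str, df_method: str = "satterthwaite") -> ModelSpec:
    return ModelSpec(
        response=trait,
        fixed_terms=CG_FIXED,
        interactions=CG_INTERACTIONS,
        random_intercepts=(
            "microcosm_id",
            ("historical_salinity", "cg_salinity", "replicate"),
        ),
        df_method=df_method,
    )


def fit_commongarden_model(
    table: pd.DataFrame,
    species: str,
    trait: str,
    df_method: str = "satterthwaite",
) -> ModelFit:
    """Fit the full common-garden model for one species.

    Requires at least two historical salinities and two common-garden
    salinities; missing treatment cells surface as rank-deficiency errors
    naming the aliased terms, never as silently dropped effects.
    """
    sub = table[(table["species"] == species) & (table["phase"] == PHASE_CG)].copy()
    if len(sub) == 0:
        raise NotComputableError(f"no common-garden records for species {species!r}")
    if sub["historical_salinity"].nunique() < 2:
        raise NotComputableError(
            "common-garden model needs >= 2 historical salinities, got "
            f"{sorted(sub['historical_salinity'].unique())}"
        )
    if sub["cg_salinity"].nunique() < 2:
        raise NotComputableError(
            "common-garden model needs >= 2 common-garden salinities, got "
            f"{sorted(sub['cg_salinity'].unique())}"
        )
    sub["competition"] = sub["competition"].astype(int)
    return fit_lmm(sub, commongarden_model_spec(trait, df_method))


@dataclass(frozen=True)
class PlasticityEstimate:
    """Reaction-norm slope of one selected population over one environment pair."""

    historical_salinity: float
    competition: bool
    env_pair: tuple[float, float]
    trait: str
    slope: float
    se: float
    p: float
    n_obs: int


def fit_selected_plasticity(
    table: pd.DataFrame,
    species: str,
    trait: str,
    historical_salinity: float,
    competition: bool,
    env_pair: tuple[float, float],
    df_method: str = "satterthwaite",
) -> Union[PlasticityEstimate, InsufficientData]:
    """Plasticity of one selected population: the trait's slope on
    common-garden salinity across ``env_pair``, with density as covariate and
    the common-garden tube as random intercept.
    """
    e_ref, e_test = env_pair
    if e_ref == e_test:
        raise ValueError("env_pair environments must differ")
    sub = table[
        (table["species"] == species)
        & (table["phase"] == PHASE_CG)
        & (table["historical_salinity"] == historical_salinity)
        & (table["competition"].astype(bool) == competition)
        & (table["cg_salinity"].isin(env_pair))
    ].copy()
    present = set(sub["cg_salinity"].unique())
    if present != set(env_pair):
        missing = sorted(set(env_pair) - present)
        return InsufficientData(
            f"population (hist={historical_salinity} g/l, competition={competition}) "
            f"has no records at common-garden salinity {missing}"
        )
    fit = fit_lmm(
        sub,
        ModelSpec(response=trait, fixed_terms=("cg_salinity", "density"),
                  random_intercepts=("cg_id",), df_method=df_method),
    )
    return PlasticityEstimate(
        historical_salinity=historical_salinity, competition=competition,
        env_pair=env_pair, trait=trait,
        slope=fit.coefficients["cg_salinity"],
        se=fit.standard_errors["cg_salinity"],
        p=fit.p_values["cg_salinity"], n_obs=fit.n_obs,
    )


@dataclass(frozen=True)
class GeneticContrast:
    """Competition-history difference in trait mean at one (historical,
    common-garden) salinity, estimable only without live competitors."""

    historical_salinity: float
    cg_salinity: float
    trait: str
    effect: float
    se: float
    p: float
    n_obs: int
    confounded: bool


def fit_genetic_contrast(
    table: pd.DataFrame,
    species: str,
    trait: str,
    historical_salinity: float,
    cg_salinity: float,
    df_method: str = "satterthwaite",
    allow_confounded: bool = False,
    exclude_units: Sequence[str] = (),
) -> GeneticContrast:
    """Contrast populations from the same historical salinity but opposite
    competition treatments, measured in one common-garden salinity.

    Model: trait ~ competition + density with replicate and the source
    microcosm as random intercepts.  Refuses (naming the contaminating
    samples) when competitor species records are present in the compared
    common gardens, unless ``allow_confounded`` acknowledges the confounding.
    ``exclude_units`` drops named common-garden tubes first — the handle for
    borderline contaminated microcosms, so both included/excluded results are
    reportable.
    """
    cg = table[
        (table["phase"] == PHASE_CG)
        & (table["historical_salinity"] == historical_salinity)
        & (table["cg_salinity"] == cg_salinity)
        & (~table["cg_id"].isin(set(exclude_units)))
    ]
    # only tubes containing the focal species enter the comparison
    focal_units = set(cg.loc[cg["species"] == species, "cg_id"])
    cg = cg[cg["cg_id"].isin(focal_units)]
    competitor_ids = sorted(cg.loc[cg["species"] != species, "cg_id"].unique())
    if competitor_ids and not allow_confounded:
        raise ConfoundedSamplesError(competitor_ids)
    sub = cg[cg["species"] == species].copy()
    histories = set(sub["competition"].astype(bool).unique())
    if histories != {False, True}:
        raise NotComputableError(
            "genetic contrast needs both competition histories at "
            f"hist={historical_salinity}, cg={cg_salinity}; found {sorted(histories)}"
        )
    sub["competition"] = sub["competition"].astype(int)
    fit = fit_lmm(
        sub,
        ModelSpec(response=trait, fixed_terms=("competition", "density"),
                  random_intercepts=("replicate", "microcosm_id"),
                  df_method=df_method),
    )
    return GeneticContrast(
        historical_salinity=historical_salinity, cg_salinity=cg_salinity,
        trait=trait, effect=fit.coefficients["competition"],
        se=fit.standard_errors["competition"], p=fit.p_values["competition"],
        n_obs=fit.n_obs, confounded=bool(competitor_ids),
    )
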