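"""Reaction-norm partition of trait change into ancestral plasticity, mean
trait evolution, and evolution of plasticity.

The partition contrasts four cells — the ancestral population and one
selected population, each measured at a reference environment (0.5 g/l NaCl)
and a test environment (1 or 2 g/l) — via a regression with two 0/1
indicator variables and their interaction:

    trait ~ population + environment + population:environment
            + density + (1 | microcosm)

With treatment (0/1) coding the coefficients are exactly the components:

* ``environment``             -> ancestral plasticity (ancestral response to
                                 the environment step),
* ``population``              -> mean trait evolution (ancestral -> selected
                                 change at the reference environment),
* ``population:environment``  -> evolution of plasticity (change in the
                                 environmental response).

Ancestral records are the day-4, competition-free selection-phase
measurements at the matching salinities (the only pre-evolution exposure
data the design contains); selected records are common-garden measurements.
The conservation identity  selected@test − ancestral@reference =
plasticity + mean trait evolution + evolution of plasticity  holds exactly
at the cell-mean level and is exposed as :func:`partition_oracle`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import NotComputableError
from .mixedmodel import InsufficientData, ModelFit, ModelSpec, fit_lmm
from .simulate import PHASE_CG, PHASE_DAY4

#: Reference environment of the partition, g/l NaCl.
REFERENCE_ENV = 0.5

#: Common-garden test environments with ancestral (day-4, competition-free)
#: counterparts. No ancestral trait values exist for 4 g/l, so the partition
#: is not computable there.
ADMISSIBLE_TEST_ENVS = (1.0, 2.0)


@dataclass(frozen=True)
class PartitionInput:
    """Records for the four cells of one partition.

    ``ancestral_ref``/``ancestral_test`` are competition-free day-4 records
    at the reference and test salinity; ``selected_ref``/``selected_test``
    are the selected population's common-garden records at the same pair.
    """

    ancestral_ref: pd.DataFrame
    ancestral_test: pd.DataFrame
    selected_ref: pd.DataFrame
    selected_test: pd.DataFrame
    env_ref: float
    env_test: float
    selected_has_competitors: bool = False

    def __post_init__(self):
        if self.env_ref == self.env_test:
            raise ValueError("reference and test environments must differ")
        for name in ("ancestral_ref", "ancestral_test", "selected_ref", "selected_test"):
            if len(getattr(self, name)) == 0:
                raise NotComputableError(f"partition cell {name!r} is empty")
        for name in ("ancestral_ref", "ancestral_test"):
            if getattr(self, name)["competition"].astype(bool).any():
                raise ValueError(f"{name} must contain competition-free records only")


def build_partition_table(inp: PartitionInput) -> pd.DataFrame:
    """Stack the four cells into one coded table.

    Adds indicator ``population`` (0 = ancestral, 1 = selected), indicator
    ``environment`` (0 = reference, 1 = test) and keeps density and the
    physical-tube identifier ``unit_id`` for the random intercept.
    """
    pieces = []
    for df, pop, env in (
        (inp.ancestral_ref, 0, 0),
        (inp.ancestral_test, 0, 1),
        (inp.selected_ref, 1, 0),
        (inp.selected_test, 1, 1),
    ):
        part = df.copy()
        part["population"] = pop
        part["environment"] = env
        pieces.append(part)
    return pd.concat(pieces, ignore_index=True)


@dataclass(frozen=True)
class ComponentEstimate:
    estimate: float
    se: float
    p: float
    dof: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PartitionResult:
    """The three reaction-norm components with uncertainty, in raw trait units."""

    trait: str
    env_pair: tuple[float, float]
    plasticity: ComponentEstimate
    mean_trait_evolution: ComponentEstimate
    evolution_of_plasticity: ComponentEstimate
    confounded: bool
    historical_salinity: Optional[float] = None
    competition_history: Optional[bool] = None
    fit: ModelFit = None

    def components(self) -> dict[str, ComponentEstimate]:
        return {
            "plasticity": self.plasticity,
            "mean_trait_evolution": self.mean_trait_evolution,
            "evolution_of_plasticity": self.evolution_of_plasticity,
        }


def _component(fit: ModelFit, term: str) -> ComponentEstimate:
    from scipy import stats

    est = fit.coefficients[term]
    se = fit.standard_errors[term]
    df = fit.dof[term]
    if se > 0 and np.isfinite(df):
        tcrit = stats.t.ppf(0.975, df)
    elif se > 0:
        tcrit = stats.norm.ppf(0.975)
    else:
        tcrit = 0.0
    return ComponentEstimate(
        estimate=est, se=se, p=fit.p_values[term], dof=df,
        ci_low=est - tcrit * se, ci_high=est + tcrit * se,
    )


def partition_trait_change(
    inp: PartitionInput,
    trait: str,
    df_method: str = "satterthwaite",
    include_density: bool = True,
    reference_population: str = "ancestral",
) -> PartitionResult:
    """Fit the indicator-variable partition model and return the components.

    ``reference_population`` may be set to ``"selected"`` to swap the
    population indicator's reference level (negates the evolution components
    but leaves plasticity unchanged — useful as a consistency check).
    """
    table = build_partition_table(inp)
    if reference_population == "selected":
        table["population"] = 1 - table["population"]
    elif reference_population != "ancestral":
        raise ValueError("reference_population must be 'ancestral' or 'selected'")
    fixed = ("population", "environment") + (("density",) if include_density else ())
    spec = ModelSpec(
        response=trait,
        fixed_terms=fixed,
        interactions=(("population", "environment"),),
        random_intercepts=("unit_id",),
        df_method=df_method,
    )
    fit = fit_lmm(table, spec)
    return PartitionResult(
        trait=trait,
        env_pair=(inp.env_ref, inp.env_test),
        plasticity=_component(fit, "environment"),
        mean_trait_evolution=_component(fit, "population"),
        evolution_of_plasticity=_component(fit, "population:environment"),
        confounded=inp.selected_has_competitors,
        fit=fit,
    )


def partition_oracle(
    anc_ref: float, anc_test: float, sel_ref: float, sel_test: float
) -> tuple[float, float, float]:
    """Closed-form components from the four cell means.

    plasticity = anc_test − anc_ref; mean trait evolution = sel_ref −
    anc_ref; evolution of plasticity = (sel_test − sel_ref) − (anc_test −
    anc_ref).  Satisfies sel_test − anc_ref = sum of the three exactly.
    """
    plasticity = anc_test - anc_ref
    mte = sel_ref - anc_ref
    eop = (sel_test - sel_ref) - (anc_test - anc_ref)
    return plasticity, mte, eop


@dataclass(frozen=True)
class PartitionBatch:
    results: tuple[PartitionResult, ...]
    skipped: tuple[tuple[float, str], ...]  # (historical salinity, reason)


def partition_all(
    records: pd.DataFrame,
    species: str,
    trait: str,
    cg_env: float,
    competition_history: bool,
    df_method: str = "satterthwaite",
) -> PartitionBatch:
    """Partition ancestral -> selected trait change for every selected
    population (one per historical salinity) of one competition history,
    measured at common-garden test environment ``cg_env``.

    ``cg_env`` must be 1 or 2 g/l: no ancestral trait values exist for the
    4 g/l environment, so the partition is refused there.  Populations whose
    selected cells contain competitor records are flagged ``confounded``
    (their mean-trait-evolution component mixes genetic change with a plastic
    response to competitors); populations with no surviving records are
    reported in ``skipped``.
    """
    if cg_env not in ADMISSIBLE_TEST_ENVS:
        raise NotComputableError(
            f"partition not computable at common-garden salinity {cg_env:g} g/l: "
            "no ancestral (day-4, competition-free) trait values exist there; "
            f"admissible test environments are {ADMISSIBLE_TEST_ENVS}"
        )
    sp = records[records["species"] == species]
    anc = sp[
        (sp["phase"] == PHASE_DAY4) & (~sp["competition"].astype(bool))
    ]
    anc_ref = anc[anc["historical_salinity"] == REFERENCE_ENV]
    anc_test = anc[anc["historical_salinity"] == cg_env]
    for cell, env in ((anc_ref, REFERENCE_ENV), (anc_test, cg_env)):
        if len(cell) == 0:
            raise NotComputableError(
                f"no ancestral day-4 records at {env:g} g/l for species {species!r}"
            )

    cg = sp[(sp["phase"] == PHASE_CG) & (sp["competition"].astype(bool) == competition_history)]
    results = []
    skipped = []
    # intended populations: every salinity the species was selected at,
    # so extinct populations are reported as skipped rather than omitted
    for hist in sorted(sp["historical_salinity"].unique()):
        pop = cg[cg["historical_salinity"] == hist]
        sel_ref = pop[pop["cg_salinity"] == REFERENCE_ENV]
        sel_test = pop[pop["cg_salinity"] == cg_env]
        if len(sel_ref) == 0 or len(sel_test) == 0:
            missing = REFERENCE_ENV if len(sel_ref) == 0 else cg_env
            skipped.append((float(hist), f"no selected records at {missing:g} g/l"))
            continue
        if competition_history:
            units = set(sel_ref["cg_id"]) | set(sel_test["cg_id"])
            competitors = records[
                (records["cg_id"].isin(units)) & (records["species"] != species)
            ]
            has_competitors = len(competitors) > 0
        else:
            has_competitors = False
        inp = PartitionInput(
            ancestral_ref=anc_ref, ancestral_test=anc_test,
            selected_ref=sel_ref, selected_test=sel_test,
            env_ref=REFERENCE_ENV, env_test=float(cg_env),
            selected_has_competitors=has_competitors,
        )
        res = partition_trait_change(inp, trait, df_method=df_method)
        results.append(
            PartitionResult(
                trait=res.trait, env_pair=res.env_pair,
                plasticity=res.plasticity,
                mean_trait_evolution=res.mean_trait_evolution,
                evolution_of_plasticity=res.evolution_of_plasticity,
                confounded=res.confounded,
                historical_salinity=float(hist),
                competition_history=competition_history,
                fit=res.fit,
            )
        )
    return PartitionBatch(tuple(results), tuple(skipped))


def partition_results_frame(batch: PartitionBatch) -> pd.DataFrame:
    """One row per (population, component), TSV-ready."""
    rows = []
    for res in batch.results:
        for comp, est in res.components().items():
            rows.append(
                dict(
                    trait=res.trait,
                    historical_salinity=res.historical_salinity,
                    competition_history=res.competition_history,
                    env_ref=res.env_pair[0], env_test=res.env_pair[1],
                    component=comp, estimate=est.estimate, se=est.se,
                    p=est.p, ci_low=est.ci_low, ci_high=est.ci_high,
                    confounded=res.confounded,
                )
            )
    return pd.DataFrame(rows)
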