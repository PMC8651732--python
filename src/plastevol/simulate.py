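"""Synthetic individual-level trait records for the microcosm experiment.

Generates video-style trait records (bio-area, aspect ratio, gross speed per
tracked individual) with the statistical structure the downstream analyses
assume: ancestral plastic slopes along the salinity gradient, evolutionary
mean-trait shifts, evolution-of-plasticity interactions, competition-history
shifts, density and bio-fraction covariate effects, microcosm-level random
intercepts, Gaussian individual residuals, and deterministic extinction of
populations that fell below the detection threshold in the study.

Every generative coefficient is stored in :class:`SimulationParams`, so tests
can compare fitted model coefficients against known truth via
:func:`ground_truth_components`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import CommonGardenMicrocosm, SelectionMicrocosm

SPECIES = ("PA", "ST", "TT")
TRAITS = ("bio_area", "aspect_ratio", "gross_speed")

#: Phase labels for the two selection-phase samplings and the common garden.
PHASE_DAY4 = "selection_day4"
PHASE_DAY78 = "selection_day78"
PHASE_CG = "common_garden_day82"

_TRAIT_FLOORS = {"bio_area": 1.0, "aspect_ratio": 1.0, "gross_speed": 0.0}

_TREATMENT_SPECIES = {
    "PA_alone": ("PA",),
    "ST_alone": ("ST",),
    "TT_alone": ("TT",),
    "community": ("PA", "ST", "TT"),
}


@dataclass(frozen=True)
class TraitParams:
    """Generative parameters for one species x trait combination.

    The linear predictor for an individual is::

        intercept
        + plastic_slope * env_salinity
        + evolved * ( evolution_shift
                      + evolution_shift_per_salinity * historical_salinity
                      + plasticity_evolution_delta * env_salinity
                      + competition * competition_shift )
        + density_coef * density + biofraction_coef * biofraction
        + microcosm_effect + residual

    where ``env_salinity`` is the salinity the individual currently
    experiences (historical salinity during the selection phase, common-garden
    salinity afterwards) and ``evolved`` is 0 at day 4 and 1 thereafter.
    """

    intercept: float
    plastic_slope: float = 0.0
    evolution_shift: float = 0.0
    evolution_shift_per_salinity: float = 0.0
    plasticity_evolution_delta: float = 0.0
    competition_shift: float = 0.0
    density_coef: float = 0.0
    biofraction_coef: float = 0.0
    sigma_microcosm: float = 0.0
    sigma_cg_microcosm: float = 0.0
    sigma_residual: float = 0.0

    def __post_init__(self):
        for name in ("sigma_microcosm", "sigma_cg_microcosm", "sigma_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ExtinctionRule:
    """Deterministic extinction: matching populations emit no records after day 4.

    ``salinities=None`` matches every salinity level.
    """

    species: str
    requires_competition: bool = True
    salinities: Optional[tuple[float, ...]] = None

    def matches(self, species: str, competition: bool, salinity: float) -> bool:
        if species != self.species:
            return False
        if self.requires_competition and not competition:
            return False
        return self.salinities is None or salinity in self.salinities


@dataclass
class SimulationParams:
    """Ground-truth generative parameters for a synthetic experiment."""

    traits: dict[str, dict[str, TraitParams]]
    extinction_rules: tuple[ExtinctionRule, ...] = ()
    mean_count: float = 40.0
    mean_count_by_species: dict[str, float] = field(default_factory=dict)
    sampled_volume_ul: float = 34.4
    detection_threshold_per_ml: float = 29.07
    seed: int = 0

    def __post_init__(self):
        if self.detection_threshold_per_ml < 0:
            raise ValueError("detection_threshold_per_ml must be >= 0")
        if self.sampled_volume_ul <= 0:
            raise ValueError("sampled_volume_ul must be > 0")
        valid = set(SPECIES)
        for rule in self.extinction_rules:
            if rule.species not in valid:
                raise ValueError(f"extinction rule references unknown species {rule.species!r}")

    def trait_params(self, species: str, trait: str) -> TraitParams:
        return self.traits[species][trait]

    def expected_count(self, species: str) -> float:
        return self.mean_count_by_species.get(species, self.mean_count)

    def is_extinct(self, species: str, competition: bool, salinity: float) -> bool:
        return any(r.matches(species, competition, salinity) for r in self.extinction_rules)


def default_params(seed: int = 0) -> SimulationParams:
    """Study-like default parameters.

    Directions mimic the observed trait responses (P. aurelia: biomass and
    speed decrease, cell elongation increases; S. teres: all three increase);
    the magnitudes are invented but scaled to plausible ciliate phenotypes.
    The extinction rules mirror the study's outcome: T. thermophila extinct
    under competition at every salinity, S. teres extinct under competition
    at the two highest salinities.
    """
    pa = {
        "bio_area": TraitParams(
            intercept=2800.0, plastic_slope=-60.0, evolution_shift=-250.0,
            plasticity_evolution_delta=25.0, competition_shift=-120.0,
            sigma_microcosm=80.0, sigma_cg_microcosm=60.0, sigma_residual=350.0,
        ),
        "aspect_ratio": TraitParams(
            intercept=1.8, plastic_slope=0.03, evolution_shift=0.12,
            plasticity_evolution_delta=-0.01, competition_shift=0.05,
            sigma_microcosm=0.05, sigma_cg_microcosm=0.04, sigma_residual=0.25,
        ),
        "gross_speed": TraitParams(
            intercept=550.0, plastic_slope=-15.0, evolution_shift=-60.0,
            plasticity_evolution_delta=5.0, competition_shift=-25.0,
            sigma_microcosm=20.0, sigma_cg_microcosm=15.0, sigma_residual=90.0,
        ),
    }
    st = {
        "bio_area": TraitParams(
            intercept=9000.0, plastic_slope=120.0, evolution_shift=500.0,
            plasticity_evolution_delta=40.0, competition_shift=200.0,
            sigma_microcosm=250.0, sigma_cg_microcosm=180.0, sigma_residual=1100.0,
        ),
        "aspect_ratio": TraitParams(
            intercept=6.0, plastic_slope=0.05, evolution_shift=0.3,
            plasticity_evolution_delta=0.02, competition_shift=0.1,
            sigma_microcosm=0.15, sigma_cg_microcosm=0.1, sigma_residual=0.7,
        ),
        "gross_speed": TraitParams(
            intercept=150.0, plastic_slope=4.0, evolution_shift=20.0,
            plasticity_evolution_delta=1.5, competition_shift=8.0,
            sigma_microcosm=8.0, sigma_cg_microcosm=6.0, sigma_residual=35.0,
        ),
    }
    tt = {
        "bio_area": TraitParams(intercept=900.0, sigma_microcosm=40.0, sigma_residual=150.0),
        "aspect_ratio": TraitParams(intercept=1.3, sigma_microcosm=0.03, sigma_residual=0.12),
        "gross_speed": TraitParams(intercept=300.0, sigma_microcosm=15.0, sigma_residual=60.0),
    }
    rules = (
        ExtinctionRule("TT", requires_competition=True, salinities=None),
        ExtinctionRule("ST", requires_competition=True, salinities=(2.0, 4.0)),
    )
    return SimulationParams(traits={"PA": pa, "ST": st, "TT": tt},
                            extinction_rules=rules, seed=seed)


def noise_free_params(base: Optional[SimulationParams] = None) -> SimulationParams:
    """Copy of ``base`` (default preset) with every variance set to zero."""
    base = base if base is not None else default_params()
    out = copy.deepcopy(base)
    for sp, traits in out.traits.items():
        for tr, tp in traits.items():
            traits[tr] = replace(tp, sigma_microcosm=0.0, sigma_cg_microcosm=0.0,
                                 sigma_residual=0.0)
    return out


@dataclass(frozen=True)
class TraitRecord:
    """One tracked individual's phenotype with full treatment provenance."""

    microcosm_id: str
    species: str
    phase: str
    historical_salinity: float
    competition: bool
    bio_area: float
    aspect_ratio: float
    gross_speed: float
    cg_id: Optional[str] = None
    cg_salinity: Optional[float] = None
    time: Optional[int] = None
    replicate: Optional[int] = None
    cg_replicate: Optional[int] = None
    species_treatment: Optional[str] = None

    def __post_init__(self):
        if self.bio_area <= 0:
            raise ValueError("bio_area must be > 0")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")
        if self.gross_speed < 0:
            raise ValueError("gross_speed must be >= 0")
        is_cg = self.phase == PHASE_CG
        if is_cg != (self.cg_id is not None) or is_cg != (self.cg_salinity is not None):
            raise ValueError("cg fields must be present exactly for common-garden records")


@dataclass(frozen=True)
class SimulationContext:
    """Treatment context for one sampled video (one tube at one phase)."""

    species: str
    phase: str
    microcosm_id: str
    historical_salinity: float
    competition: bool
    density: float = 0.0
    biofraction: float = 0.0
    cg_id: Optional[str] = None
    cg_salinity: Optional[float] = None
    replicate: Optional[int] = None
    cg_replicate: Optional[int] = None
    species_treatment: Optional[str] = None
    microcosm_effects: Optional[dict[str, float]] = None


def _linear_predictor(tp: TraitParams, ctx: SimulationContext) -> float:
    env = ctx.cg_salinity if ctx.phase == PHASE_CG else ctx.historical_salinity
    evolved = 0.0 if ctx.phase == PHASE_DAY4 else 1.0
    mu = tp.intercept + tp.plastic_slope * env
    mu += evolved * (
        tp.evolution_shift
        + tp.evolution_shift_per_salinity * ctx.historical_salinity
        + tp.plasticity_evolution_delta * env
        + (tp.competition_shift if ctx.competition else 0.0)
    )
    mu += tp.density_coef * ctx.density + tp.biofraction_coef * ctx.biofraction
    return mu


def simulate_sample(
    params: SimulationParams,
    context: SimulationContext,
    n_individuals: int,
    rng: np.random.Generator,
) -> list[TraitRecord]:
    """Draw ``n_individuals`` trait records for one sampled video.

    Each trait is linear predictor + shared microcosm intercept + Gaussian
    residual, floored to respect the physical trait ranges (bio-area > 0,
    aspect ratio >= 1, speed >= 0).
    """
    if n_individuals < 0:
        raise ValueError("n_individuals must be >= 0")
    effects = context.microcosm_effects or {}
    records = []
    mus = {}
    for trait in TRAITS:
        tp = params.trait_params(context.species, trait)
        mus[trait] = _linear_predictor(tp, context) + effects.get(trait, 0.0)
    for _ in range(n_individuals):
        vals = {}
        for trait in TRAITS:
            tp = params.trait_params(context.species, trait)
            eps = rng.normal(0.0, tp.sigma_residual) if tp.sigma_residual > 0 else 0.0
            vals[trait] = max(mus[trait] + eps, _TRAIT_FLOORS[trait])
        records.append(
            TraitRecord(
                microcosm_id=context.microcosm_id,
                species=context.species,
                phase=context.phase,
                historical_salinity=context.historical_salinity,
                competition=context.competition,
                bio_area=vals["bio_area"],
                aspect_ratio=vals["aspect_ratio"],
                gross_speed=vals["gross_speed"],
                cg_id=context.cg_id,
                cg_salinity=context.cg_salinity,
                time=(None if context.phase == PHASE_CG
                      else (0 if context.phase == PHASE_DAY4 else 1)),
                replicate=context.replicate,
                cg_replicate=context.cg_replicate,
                species_treatment=context.species_treatment,
            )
        )
    return records


def records_to_frame(records: Sequence[TraitRecord]) -> pd.DataFrame:
    """Stack trait records into the canonical analysis DataFrame."""
    cols = [
        "microcosm_id", "cg_id", "species", "species_treatment", "phase", "time",
        "historical_salinity", "competition", "cg_salinity", "replicate",
        "cg_replicate", "bio_area", "aspect_ratio", "gross_speed",
    ]
    if not records:
        return pd.DataFrame(columns=cols + ["unit_id", "sample_id"])
    df = pd.DataFrame([vars(r) if not hasattr(r, "__dataclass_fields__")
                       else {f: getattr(r, f) for f in r.__dataclass_fields__}
                       for r in records])[cols]
    for col in ("time", "cg_salinity", "replicate", "cg_replicate"):
        df[col] = pd.to_numeric(df[col])
    df["cg_id"] = df["cg_id"].astype("string")
    df["unit_id"] = df["cg_id"].where(df["cg_id"].notna(), df["microcosm_id"])
    df["sample_id"] = df["unit_id"].astype(str) + "@" + df["phase"].astype(str)
    return df


def _expected_biofractions(params, species_present, counts, phase_ctx):
    """Generative bio-fraction per focal species, from expected bio-areas.

    Uses the noise-free expected bio-area per species (times realized counts),
    not the realized record values: covariates must be known before records
    are drawn.  Downstream preprocessing recomputes the observed bio-fraction.
    """
    totals = {}
    for sp in species_present:
        tp = params.trait_params(sp, "bio_area")
        ctx = replace(phase_ctx, species=sp)
        totals[sp] = counts[sp] * max(_linear_predictor(tp, ctx), _TRAIT_FLOORS["bio_area"])
    grand = sum(totals.values())
    if grand <= 0:
        return {sp: 0.0 for sp in species_present}
    return {sp: (grand - totals[sp]) / grand for sp in species_present}


def simulate_experiment(
    params: SimulationParams,
    selection_design: Sequence[SelectionMicrocosm],
    cg_design: Sequence[CommonGardenMicrocosm] = (),
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate the full experiment: day-4 and day-78 selection samples plus
    common-garden samples for every non-extinct population.

    Returns the canonical trait-record table (one row per tracked individual).
    Reproducible given ``seed`` (falls back to ``params.seed``).
    """
    sel_ids = {m.microcosm_id for m in selection_design}
    for cg in cg_design:
        if cg.source_microcosm_id not in sel_ids:
            raise ValueError(f"common-garden microcosm {cg.cg_id} references unknown "
                             f"source {cg.source_microcosm_id}")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    # one microcosm intercept per (selection tube, species, trait), shared
    # across day 4, day 78 and all descendant common gardens
    sel_effects: dict[tuple[str, str], dict[str, float]] = {}
    for m in sorted(selection_design, key=lambda m: m.microcosm_id):
        for sp in _TREATMENT_SPECIES[m.species_treatment]:
            sel_effects[(m.microcosm_id, sp)] = {
                tr: rng.normal(0.0, params.trait_params(sp, tr).sigma_microcosm)
                if params.trait_params(sp, tr).sigma_microcosm > 0 else 0.0
                for tr in TRAITS
            }

    records: list[TraitRecord] = []

    def sample_tube(ctx_base, species_present, extra_effects=None):
        counts = {sp: int(rng.poisson(params.expected_count(sp))) for sp in species_present}
        bfs = _expected_biofractions(params, species_present, counts, ctx_base)
        vol_ml = params.sampled_volume_ul / 1000.0
        for sp in species_present:
            if counts[sp] == 0:
                continue
            eff = dict(sel_effects[(ctx_base.microcosm_id, sp)])
            if extra_effects is not None:
                for tr in TRAITS:
                    eff[tr] = eff.get(tr, 0.0) + extra_effects[sp][tr]
            ctx = replace(
                ctx_base, species=sp, density=counts[sp] / vol_ml,
                biofraction=bfs[sp], microcosm_effects=eff,
            )
            records.extend(simulate_sample(params, ctx, counts[sp], rng))

    # selection phase
    for m in sorted(selection_design, key=lambda m: m.microcosm_id):
        base = SimulationContext(
            species="", phase=PHASE_DAY4, microcosm_id=m.microcosm_id,
            historical_salinity=m.salinity, competition=m.competition,
            replicate=m.replicate, species_treatment=m.species_treatment,
        )
        sample_tube(base, _TREATMENT_SPECIES[m.species_treatment])
        survivors = tuple(
            sp for sp in _TREATMENT_SPECIES[m.species_treatment]
            if not params.is_extinct(sp, m.competition, m.salinity)
        )
        if survivors:
            sample_tube(replace(base, phase=PHASE_DAY78), survivors)

    # common garden
    sel_by_id = {m.microcosm_id: m for m in selection_design}
    for cg in sorted(cg_design, key=lambda c: c.cg_id):
        src = sel_by_id[cg.source_microcosm_id]
        survivors = tuple(
            sp for sp in _TREATMENT_SPECIES[src.species_treatment]
            if not params.is_extinct(sp, src.competition, src.salinity)
        )
        if not survivors:
            continue
        cg_effects = {
            sp: {tr: rng.normal(0.0, params.trait_params(sp, tr).sigma_cg_microcosm)
                 if params.trait_params(sp, tr).sigma_cg_microcosm > 0 else 0.0
                 for tr in TRAITS}
            for sp in survivors
        }
        base = SimulationContext(
            species="", phase=PHASE_CG, microcosm_id=src.microcosm_id,
            historical_salinity=src.salinity, competition=src.competition,
            cg_id=cg.cg_id, cg_salinity=cg.cg_salinity,
            replicate=src.replicate, cg_replicate=cg.cg_replicate,
            species_treatment=src.species_treatment,
        )
        sample_tube(base, survivors, extra_effects=cg_effects)

    return records_to_frame(records)


@dataclass(frozen=True)
class GroundTruthComponents:
    """Analytic reaction-norm components implied by the generative parameters."""

    plasticity: float
    mean_trait_evolution: float
    evolution_of_plasticity: float


def ground_truth_components(
    params: SimulationParams,
    species: str,
    trait: str,
    historical_salinity: float,
    env_pair: tuple[float, float],
    competition: bool = False,
) -> GroundTruthComponents:
    """Expected (plasticity, mean trait evolution, evolution of plasticity)
    for a partition of ancestral -> selected trait change over ``env_pair``.

    ``plasticity`` is the ancestral response to the environment step,
    ``mean_trait_evolution`` the ancestral->selected change at the reference
    environment, and ``evolution_of_plasticity`` the change in the response
    slope, each in raw trait units.
    """
    e0, e1 = env_pair
    tp = params.trait_params(species, trait)
    plasticity = tp.plastic_slope * (e1 - e0)
    mte = (
        tp.evolution_shift
        + tp.evolution_shift_per_salinity * historical_salinity
        + tp.plasticity_evolution_delta * e0
        + (tp.competition_shift if competition else 0.0)
    )
    eop = tp.plasticity_evolution_delta * (e1 - e0)
    return GroundTruthComponents(plasticity, mte, eop)
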