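# Methods

`plastevol` implements the statistical analysis of a salinity × competition
experimental-evolution study on freshwater ciliates (*Paramecium aurelia*,
*Spirostomum teres*, *Tetrahymena thermophila*): populations evolve for 78
days along a salinity gradient (0, 0.5, 1, 2, 4 g/l NaCl) in the absence or
presence of the other species, are then assayed in a common garden across the
same gradient, and individual-level video-derived trait records (bio-area in
µm², aspect ratio, gross speed in µm/s) are analysed with linear mixed
models. This note documents the models, the synthetic data that drives the
test suite, and the numerical choices.

## Experimental design

The selection phase is a full factorial of 5 salinities × 4 species
treatments (each species alone, or the community) × 3 replicates = 60
microcosms, with 20 unique salinity × treatment combinations. The common
garden takes every surviving selection line except the *T. thermophila*
lines (45 lines), inoculates each into the salinity gradient twice, and bars
non-zero-salinity lines from the 0 g/l garden (a strict zero cannot be
reached when transferring live cultures): 2 × (9 lines × 5 + 36 lines × 4)
= 378 microcosms. Identifiers are deterministic composites
(`S<salinity>_<treatment>_r<rep>`, suffixed with `_CG<salinity>_r<rep>` for
garden tubes) so re-enumeration is byte-identical; an `alias` field maps to
external opaque IDs.

## Mixed models

All analyses share one fitting contract (`mixedmodel.ModelSpec` /
`fit_lmm`): numeric/binary fixed terms, product interactions, and
independent random intercepts, possibly on composite labels — the standard
encoding of "replicate nested within historical × garden salinity". Salinity
and density enter as numeric covariates; competition and time are 0/1
indicators.

Variance parameters are estimated by maximizing the profiled REML
log-likelihood directly. The marginal covariance is
V = σ²ₑI + Σₖ σ²ₖ ZₖZₖᵀ; the Woodbury identity reduces every likelihood and
GLS evaluation to q × q solves (q = total random levels), and Nelder–Mead on
log-variances (one restart on stall) handles one, several or crossed
intercepts through a single code path. This engine replaced an initial
delegation to an off-the-shelf Python mixed-model fitter, which proved
unreliable here: it mis-converged on the crossed common-garden structure
(variance component off by two orders of magnitude against lme4), raised
linear-algebra errors on occasional bootstrap subsamples, and stalled in
line searches; the in-package optimizer found an equal or strictly higher
REML log-likelihood in every comparison and matches lme4 to ~4 decimals in
coefficients, standard errors and variance components (enforced by a
subprocess test against `lmerTest`).

**Degrees of freedom.** p-values default to a Satterthwaite approximation
built from first principles: for each coefficient,
df = 2·Var(β̂ᵢ)² / gᵀA g, where g is the numerical gradient of the GLS
variance with respect to the variance parameters and A is the inverse
negative Hessian of the profiled REML log-likelihood. Variance components
estimated at the zero boundary are held fixed (the surface is one-sided
there). Agreement with `lmerTest` is ~1% in df and closer in p. `residual`
(t with n − p df) and `normal` (Wald z) methods are selectable; the
bootstrap loop uses `normal` for speed since only mean p-values are
summarised there.

**Degenerate data.** Noise-free inputs (zero residual after OLS) cannot be
REML-fit; they short-circuit to an exact least-squares solution flagged
`degenerate` (SE 0, p undefined, variance components 0). This path is what
makes exact-oracle comparisons well-defined.

**R².** σ²_f is the variance (n − 1 denominator) of the fixed-effect linear
predictor across observations; R²_m = σ²_f/(σ²_f + σ²_r + σ²_e) and
R²_c = (σ²_f + σ²_r)/(σ²_f + σ²_r + σ²_e), with σ²_r summed over intercepts.
The ordering 0 ≤ R²_m ≤ R²_c ≤ 1 is structural.

**Diagnostics.** Residual-vs-fitted values (conditional fitted, i.e.
including BLUPs), normal q–q pairs, and a Cook's-distance analogue computed
exactly via the Henderson augmented least-squares formulation: deleting a
data row of the augmented system is the leave-one-out GLS refit at fixed
variance parameters, so influence is (Δβ)ᵀ Cov(β̂)⁻¹ (Δβ)/p per observation
in O(np²).

## Analysis stages

- **Preprocessing.** Records of the two large ciliates with bio-area
  < 1000 µm² are removed (debris; the boundary value is retained — the rule
  is strictly-smaller). Density = count / (34.4 µl / 1000) individuals per
  ml, computed per sample after filtering; it is the *focal* species'
  density (the motivating evidence concerns intraspecific density effects —
  the alternative total-density reading is noted as an open choice).
  Bio-fraction = competitors' share of the sample's total bio-area (bio-area
  is the biomass proxy, so biomass share = bio-area share); 0 without
  competitors, 1 when the focal species is absent.
- **Temporal model** (selection phase): trait ~ salinity + time +
  competition + density + biofraction + all 2-/3-way interactions of
  (salinity, time, competition) + (1 | microcosm), with time 0 = day 4,
  1 = day 78. Extinct populations yield an explicit `InsufficientData`
  result. The descriptive all-pairwise start/end trait differences are
  available (`pairwise_temporal_differences`) but carry no inference.
- **Common-garden model:** trait ~ historical salinity × garden salinity ×
  competition + density + biofraction + (1 | source microcosm) +
  (1 | historical × garden salinity × replicate). Garden salinity enters
  numerically (consistent with a single-slope formulation). Per-population
  plasticity slopes are separate regressions on one environment pair with
  density and a garden-tube intercept. Genetic contrasts (same historical
  salinity, opposite competition history) refuse to run when competitor
  records remain in the compared gardens — extinction is verified from the
  data — unless explicitly overridden; named tubes can be excluded first, so
  a borderline contaminated microcosm can be reported both ways.
- **Reaction-norm partition:** trait ~ P + E + P·E + density +
  (1 | microcosm tube) with treatment-coded indicators
  P (0 ancestral / 1 selected) and E (0 = 0.5 g/l reference / 1 = test
  environment). The coefficients *are* the components: E → ancestral
  plasticity, P → mean trait evolution, P·E → evolution of plasticity, in
  raw trait units. Ancestral cells are day-4 competition-free records at the
  matching salinities — the only pre-evolution exposure data the design
  contains, which is the operational meaning of "ancestral plasticity" here.
  Test environments are 1 and 2 g/l; 4 g/l is refused (no ancestral data).
  Components from competition-history populations with surviving
  competitors are flagged confounded. The cell-mean oracle satisfies the
  conservation identity sel@E1 − anc@E0 = plasticity + MTE + EoP exactly.
  Note that swapping the population reference level negates MTE and EoP but
  turns the E coefficient into the *selected* population's slope
  (plasticity + EoP) — an exact reparameterization, verified as such.
- **Robustness:** subsampling without replacement at fractions 0.9…0.1,
  refitting per subsample (1000 replicates by default), and per-fraction
  per-coefficient means and 95% empirical percentile CIs of estimates and
  p-values; failed fits are counted, never imputed. Subsampling is stratified
  on the first random factor by default (each group keeps ≥ 1 row where
  possible) so the random structure stays estimable at low fractions; the
  resampling unit in the original analysis is unstated, so an unstratified
  mode ships too. Subsamples keep original row order, making fraction 1.0
  reproduce the full table — and hence the full fit with zero CI width —
  exactly. One master seed spawns an independent stream per replicate.

## Synthetic data

The generator emulates the study's video-derived records: per species ×
trait, an individual's value is intercept + plastic slope × current salinity
+ (evolved ? mean-evolution shift + plasticity-evolution delta × current
salinity + competition shift : 0) + density and bio-fraction terms + a
microcosm intercept (drawn once per selection tube and inherited by its
gardens, plus a garden-tube term) + Gaussian residual, floored to physical
ranges (bio-area ≥ 1 µm², aspect ratio ≥ 1, speed ≥ 0). Gaussian noise on
the natural scale matches the linearity of the fitted models; the floor
matters only in stress tests. Per-sample counts are Poisson (default mean
40 per video); the density covariate is recomputed from realized counts.
Extinction is a deterministic rule (no population-dynamic model exists to
calibrate): *T. thermophila* vanishes after day 4 under competition at all
salinities, *S. teres* at 2 and 4 g/l — matching the study's outcome except
its single surviving *S. teres* replicate, which is not emulated (the
associated contamination judgement call is instead exercised by injecting a
stray competitor record in tests). The generative bio-fraction uses expected
bio-areas × realized counts (covariates must exist before records are
drawn); preprocessing recomputes the observed value.

Default magnitudes are invented but plausible for these ciliates
(*P. aurelia* ≈ 2800 µm², aspect ≈ 1.8, speed ≈ 550 µm/s, biomass and speed
declining and elongation rising; *S. teres* larger, slower, all traits
rising), and are never used as acceptance truth — recovery tests compare
fits against `ground_truth_components`, the analytic component values
implied by whatever parameters generated the data.

What passing tests do **not** show about real data: the generator is linear
and Gaussian with deterministic extinction, so the suite validates the
estimators under the models' own assumptions, not against skewed trait
distributions, density-dependent dynamics, misclassified trajectories or
other field realities.

## Problem sizes and tolerances

Simulation-based checks use scaled-down sizes chosen as this package's
study conditions: parameter recovery runs 200 replicates of 4 cells × 3
microcosms × 10 individuals (30 per cell); the type-I calibration runs 500
null replicates of a 12-microcosm two-phase design (~190 records) and
checks the time × competition rejection rate against binomial 99% bounds at
α = 0.05; the robustness sweep uses 200 bootstrap replicates per fraction on
a 300-row, 20-group dataset. Effect-stability of the bootstrap is judged on
the mean effect across the fraction sweep: a per-fraction mean at fraction
0.1 carries ≈ √((1/f − 1)/n_boot) ≈ 0.2 full-fit SE of pure resampling
noise at n_boot = 200, so only the sweep-level mean (noise ≈ 0.03 SE) is a
stable stability measure; both are reported. Exact checks (design counts,
cell-mean oracle, R² formulas, filter boundaries) use tolerances 1e-6/1e-8.
Nelder–Mead runs on log-variances with xatol 1e-7; variances below 1e-8 ×
σ²_e are treated as boundary zeros.

## Known limitations

- Random slopes, correlated random effects and generalized LMMs are out of
  scope; intercept-only structures mirror the original analyses.
- Satterthwaite df relies on numerical derivatives; for variance components
  at or near zero the method falls back to normal-approximation p-values
  (df = ∞) rather than guessing.
- The common-garden model treats garden salinity numerically; factor-coded
  environment contrasts would capture non-linear reaction norms but change
  the meaning of every interaction coefficient.
- `partition_all` reports populations with missing cells as skipped rather
  than imputing; extinct populations are therefore visible but absent from
  estimates.
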