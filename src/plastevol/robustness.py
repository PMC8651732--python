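"""Subsampling bootstrap robustness of mixed-model effect sizes.

The data are repeatedly subsampled *without replacement* at decreasing
fractions (90% down to 10% in the study), the model is refit on each
subsample, and per-coefficient mean effect sizes and mean p-values with
95% empirical percentile confidence intervals are summarised per fraction.
A robust effect keeps a stable mean and a CI bounded away from zero as the
fraction shrinks.

By default subsampling is stratified on the model's first random factor so
that every group keeps at least one record where possible — otherwise low
fractions routinely lose whole groups and the random structure collapses.
An unstratified mode is available.  Subsamples are returned in original row
order, so fraction 1.0 reproduces the input table (and hence the full fit)
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mixedmodel import ModelFit, ModelSpec, factor_name, fit_lmm

#: The study's fraction grid, 90% down to 10%.
DEFAULT_FRACTIONS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)

#: The study's number of bootstrap samples per fraction.
DEFAULT_N_BOOT = 1000


def subsample_without_replacement(
    table: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator,
    stratify_by: Optional[str] = None,
) -> pd.DataFrame:
    """Draw ``floor(fraction * n)`` rows uniformly without replacement.

    With ``stratify_by``, one row per stratum is guaranteed first (as long as
    the subsample size allows), the remainder drawn uniformly from the rest.
    Rows are returned in their original order; ``fraction=1.0`` therefore
    returns the table unchanged.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    n = len(table)
    k = int(np.floor(fraction * n))
    if k == 0:
        raise ValueError(f"fraction {fraction} yields an empty subsample (n={n})")
    if k == n:
        return table
    if stratify_by is None:
        pos = rng.choice(n, size=k, replace=False)
    else:
        codes, _ = pd.factorize(table[stratify_by])
        strata = {}
        for i, c in enumerate(codes):
            strata.setdefault(c, []).append(i)
        guaranteed = []
        if len(strata) <= k:
            for c in sorted(strata):
                guaranteed.append(strata[c][rng.integers(len(strata[c]))])
        rest = np.setdiff1d(np.arange(n), np.asarray(guaranteed, dtype=int))
        extra = rng.choice(rest, size=k - len(guaranteed), replace=False)
        pos = np.concatenate([np.asarray(guaranteed, dtype=int), extra])
    return table.iloc[np.sort(pos)]


@dataclass(frozen=True)
class BootstrapSummary:
    """Per (fraction, coefficient) bootstrap aggregates."""

    table: pd.DataFrame  # fraction, term, mean_effect, effect_ci_low/high,
    #                      mean_p, p_ci_low/high, n_successful_fits, n_failed_fits
    fractions: tuple[float, ...]
    n_boot: int
    seed: int
    full_fit: ModelFit = None


def _aggregate(fraction, terms, estimates, pvalues, n_failed):
    rows = []
    est = np.asarray(estimates)  # (n_ok, p)
    pv = np.asarray(pvalues)
    for j, term in enumerate(terms):
        e = est[:, j]
        p = pv[:, j]
        rows.append(
            dict(
                fraction=fraction, term=term,
                mean_effect=float(np.mean(e)),
                effect_ci_low=float(np.percentile(e, 2.5)),
                effect_ci_high=float(np.percentile(e, 97.5)),
                mean_p=float(np.nanmean(p)) if np.isfinite(p).any() else float("nan"),
                p_ci_low=float(np.nanpercentile(p, 2.5)) if np.isfinite(p).any() else float("nan"),
                p_ci_high=float(np.nanpercentile(p, 97.5)) if np.isfinite(p).any() else float("nan"),
                n_successful_fits=len(e),
                n_failed_fits=n_failed,
            )
        )
    return rows


def bootstrap_robustness(
    table: pd.DataFrame,
    spec: ModelSpec,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    stratified: bool = True,
) -> BootstrapSummary:
    """Run the subsample-and-refit robustness analysis.

    For each fraction (processed in decreasing order), ``n_boot`` independent
    subsample -> refit cycles; failed fits are counted, never imputed.  One
    master seed spawns an independent random stream per replicate.  Aborts
    before subsampling if the model is inestimable on the full data.
    """
    fractions = sorted(set(fractions), reverse=True)
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("all fractions must lie in (0, 1]")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    full_fit = fit_lmm(table, spec)  # raises if the spec is inestimable
    stratify_col = None
    if stratified and spec.random_intercepts:
        first = spec.random_intercepts[0]
        if isinstance(first, str):
            stratify_col = first
        else:
            name = "__stratum__"
            table = table.copy()
            table[name] = table[list(first)].astype(str).agg(":".join, axis=1)
            stratify_col = name

    streams = np.random.SeedSequence(seed).spawn(len(fractions) * n_boot)
    rows = []
    idx = 0
    for frac in fractions:
        estimates, pvalues = [], []
        n_failed = 0
        for _ in range(n_boot):
            rng = np.random.default_rng(streams[idx])
            idx += 1
            sub = subsample_without_replacement(table, frac, rng, stratify_col)
            try:
                fit = fit_lmm(sub, spec)
            except Exception:
                n_failed += 1
                continue
            if not fit.converged:
                n_failed += 1
                continue
            estimates.append([fit.coefficients[t] for t in fit.terms])
            pvalues.append([fit.p_values[t] for t in fit.terms])
        if estimates:
            rows.extend(_aggregate(frac, full_fit.terms, estimates, pvalues, n_failed))
        else:
            for term in full_fit.terms:
                rows.append(dict(fraction=frac, term=term, mean_effect=float("nan"),
                                 effect_ci_low=float("nan"), effect_ci_high=float("nan"),
                                 mean_p=float("nan"), p_ci_low=float("nan"),
                                 p_ci_high=float("nan"), n_successful_fits=0,
                                 n_failed_fits=n_failed))
    return BootstrapSummary(
        table=pd.DataFrame(rows), fractions=tuple(fractions),
        n_boot=n_boot, seed=seed, full_fit=full_fit,
    )
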