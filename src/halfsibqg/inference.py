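"""Hypothesis tests and uncertainty for variance components and fixed effects.

* Likelihood-ratio tests of random effects between nested REML fits that
  share the same fixed part (1 df for an intercept variance, 2 df for a
  correlated slope variance + covariance).  Because variances are bounded
  at zero, the chi-square reference is conservative at the boundary —
  p-values can be up to twice their correct size.  Unmodified p-values are
  reported (matching common practice), with the 50:50 chi-square-mixture
  p-value alongside.
* Nonparametric case bootstrap for fixed effects: individuals are
  resampled with replacement (whole-individual blocks for repeated
  measures), the model is refit per resample, and percentile 95% CIs and
  sign-flip p-values are collected.
* The three-way random-structure comparison for repeated per-minute
  activity (individual intercepts vs. individual time slopes vs. sire
  time slopes).
* The reaction-norm genotype-by-environment test: random density slopes
  within sire, high density as the intercept level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lmm import (
    DesignMatrices,
    FittedModel,
    ModelError,
    ModelSpec,
    RandomTerm,
    _fit,
    build_design,
    fit_reml,
    information_criteria,
)

__all__ = [
    "LRTResult",
    "BootstrapResult",
    "GxEResult",
    "ActivityModelComparison",
    "lrt_random",
    "bootstrap_fixed",
    "compare_activity_models",
    "gxe_test",
]

BOUNDARY_NOTE = (
    "variance components are tested on the boundary of the parameter "
    "space; the chi-square p-value is conservative (up to 2x too large)"
)


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float
    p_mixture: float
    note: str = BOUNDARY_NOTE

    def __post_init__(self):
        assert self.chi2 >= 0 and 0 <= self.p <= 1


def _mixture_p(chi2: float, df: int) -> float:
    """Upper-tail p under the 50:50 boundary mixture.

    df=1 (one variance): mixture of a point mass at 0 and chi2(1).
    df=2 (variance + covariance): mixture of chi2(1) and chi2(2).
    """
    if chi2 <= 0:
        return 1.0
    if df == 1:
        return 0.5 * stats.chi2.sf(chi2, 1)
    return 0.5 * stats.chi2.sf(chi2, df - 1) + 0.5 * stats.chi2.sf(chi2, df)


def lrt_random(full_fit: FittedModel, reduced_fit: FittedModel, df: int) -> LRTResult:
    """LRT of a random effect between two REML fits of nested structures.

    Both fits must be on the same rows with identical fixed parts; the
    statistic is clamped at zero against optimizer jitter.
    """
    if full_fit.reml != reduced_fit.reml:
        raise ModelError("both fits must use the same likelihood (REML or ML)")
    if full_fit.n_obs != reduced_fit.n_obs:
        raise ModelError("fits use different numbers of rows")
    if list(full_fit.fixed_estimates.index) != list(reduced_fit.fixed_estimates.index):
        raise ModelError("fixed parts differ; the restricted likelihoods are not comparable")
    full_labels = {t.label for t in full_fit.spec.random}
    red_labels = {t.label for t in reduced_fit.spec.random}
    if not red_labels <= full_labels:
        raise ModelError("reduced random structure is not nested in the full structure")
    if df not in (1, 2):
        raise ModelError("df must be 1 (intercept) or 2 (slope + covariance)")
    chi2 = max(0.0, 2.0 * (full_fit.loglik - reduced_fit.loglik))
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return LRTResult(chi2=float(chi2), df=df, p=p, p_mixture=_mixture_p(chi2, df))


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    lower: float
    upper: float
    p: float
    n_replicates: int
    n_failed: int = 0


def _resample_design(dm: DesignMatrices, spec: ModelSpec, table, cluster, rng):
    """Case-bootstrap one resample and return arrays ready for fitting."""
    n = dm.y.shape[0]
    if cluster is None:
        idx = rng.integers(0, n, n)
        draw_of_row = None
    else:
        codes, _ = pd.factorize(table[cluster].iloc[dm.index], sort=True)
        m = codes.max() + 1
        members = [np.flatnonzero(codes == c) for c in range(m)]
        draws = rng.integers(0, m, m)
        idx = np.concatenate([members[d] for d in draws])
        draw_of_row = np.concatenate(
            [np.full(len(members[d]), j) for j, d in enumerate(draws)]
        )
        cluster_codes = codes
    # group levels absent from a resample are harmless: an empty level's
    # Gamma^{-1} and M contributions cancel exactly in the likelihood, so
    # codes are reused without relabeling
    terms = []
    for rt, codes_t, g, slope in dm.terms:
        if cluster is not None and rt.group == cluster:
            # a cluster drawn twice is two distinct realized clusters
            new_codes = draw_of_row.astype(np.int64)
            g_new = int(draw_of_row.max()) + 1
        else:
            new_codes, g_new = codes_t[idx], g
        terms.append((rt, new_codes, g_new,
                      None if slope is None else slope[idx]))
    return DesignMatrices(
        y=dm.y[idx], X=dm.X[idx], x_names=dm.x_names, terms=terms,
        n_dropped=dm.n_dropped, index=dm.index[idx] if cluster is None else np.arange(len(idx)),
    )


def _quick_refit_beta(bdm: DesignMatrices, theta_hat, reml: bool):
    """Warm-started refit of one bootstrap resample; returns beta or None.

    Coefficient estimates are smooth in the variance ratios, so a short
    Nelder-Mead budget from the full-data optimum is sufficient; the
    resulting GLS coefficients are what the bootstrap distribution needs.
    """
    from .lmm import _Precomputed, _neg2ll

    try:
        pre = _Precomputed(bdm)
    except (ValueError, np.linalg.LinAlgError):
        return None
    theta = np.asarray(theta_hat, dtype=float)
    if theta.size:
        res = optimize.minimize(
            _neg2ll, theta, args=(pre, reml), method="Nelder-Mead",
            options=dict(xatol=2e-3, fatol=1e-5, maxfev=18),
        )
        theta = res.x
    cache: dict = {}
    val = _neg2ll(theta, pre, reml, out=cache)
    if not np.isfinite(val):
        return None
    return np.asarray(cache["beta"], dtype=float)


def bootstrap_fixed(
    table: pd.DataFrame,
    spec: ModelSpec,
    n_replicates: int = 10_000,
    seed: int = 0,
    cluster: str | None = None,
    drop_warn_frac: float = 0.05,
    **fit_kw,
) -> dict:
    """Case bootstrap of the fixed effects.

    Resamples rows (or whole clusters named by ``cluster``, for repeated
    measures) with replacement, refits by the model's likelihood, and
    returns per-coefficient :class:`BootstrapResult` with percentile 95%
    CIs and the two-sided sign p-value
    ``max(2 * min(P(b <= 0), P(b >= 0)), 1/(R+1))``.
    """
    if n_replicates < 100:
        raise ModelError("n_replicates must be >= 100")
    rng = np.random.default_rng(seed)
    full = _fit(spec, table, reml=spec.reml, **fit_kw)
    dm = full._design
    draws = np.empty((n_replicates, dm.X.shape[1]))
    failed = 0
    kept = 0
    for _ in range(n_replicates):
        bdm = _resample_design(dm, spec, table, cluster, rng)
        beta = _quick_refit_beta(bdm, full.theta, spec.reml)
        if beta is None:
            failed += 1
        else:
            draws[kept] = beta
            kept += 1
    draws = draws[:kept]
    if kept == 0:
        raise ModelError("all bootstrap replicates failed")
    if failed > drop_warn_frac * n_replicates:
        import warnings

        warnings.warn(
            f"{failed}/{n_replicates} bootstrap replicates failed to fit",
            RuntimeWarning,
        )
    out = {}
    floor = 1.0 / (n_replicates + 1)
    for j, name in enumerate(full.fixed_estimates.index):
        b = draws[:, j]
        lo, hi = np.percentile(b, [2.5, 97.5])
        p = 2.0 * min(np.mean(b <= 0.0), np.mean(b >= 0.0))
        p = float(min(1.0, max(p, floor)))
        out[name] = BootstrapResult(
            estimate=float(full.fixed_estimates["estimate"].iloc[j]),
            lower=float(lo), upper=float(hi), p=p,
            n_replicates=kept, n_failed=failed,
        )
    return out


# ---------------------------------------------------------------------------
# reaction-norm G x E


@dataclass
class GxEResult:
    full: FittedModel
    reduced: FittedModel
    lrt: LRTResult
    slope_variance: float
    intercept_slope_corr: float
    slope_factor: str


def _slope_indicator(table: pd.DataFrame, treatment_col: str, reference: str) -> pd.Series:
    levels = sorted(pd.unique(table[treatment_col].astype(str)))
    if len(levels) < 2:
        raise ModelError("both treatment levels must be present")
    other = [l for l in levels if l != reference]
    if len(levels) != 2:
        raise ModelError(f"treatment must be binary, found levels {levels}")
    return (table[treatment_col].astype(str) == other[0]).astype(float)


def gxe_test(
    table: pd.DataFrame,
    trait: str,
    slope_factor: str = "sire",
    *,
    fixed: tuple = ("treatment", "sex", "treatment:sex"),
    extra_random: tuple = ("dam:sire", "block"),
    treatment_col: str = "treatment",
    reference: str = "high",
    **fit_kw,
) -> GxEResult:
    """Reaction-norm test for genotype-by-environment interaction.

    Fits random (intercept, density-slope) pairs within ``slope_factor``
    (sire by default; pass ``dam`` for the maternal-by-environment
    analogue) with the reference treatment as the intercept level, against
    a reduced model with an intercept-only term for that factor, via a
    2-df REML likelihood-ratio test.
    """
    if trait not in table.columns:
        raise ModelError(f"trait column {trait!r} not in table")
    tab = table.copy()
    ind_col = f"_{treatment_col}_nonref"
    tab[ind_col] = _slope_indicator(tab, treatment_col, reference)
    counts = tab.groupby(slope_factor)[treatment_col].nunique()
    if (counts >= 2).sum() < 2:
        raise ModelError("need both treatments within at least 2 groups of the slope factor")

    group = {"sire": "sire:block", "dam": "dam:sire"}.get(slope_factor, slope_factor)
    slope_term = RandomTerm(group, slope=ind_col, name=slope_factor)
    int_term = RandomTerm(group, name=slope_factor)
    extras = tuple(
        RandomTerm(g, name=g.split(":")[0]) for g in extra_random
    )
    full_spec = ModelSpec(trait, fixed, (slope_term,) + extras)
    red_spec = ModelSpec(trait, fixed, (int_term,) + extras)
    full = fit_reml(full_spec, tab, **fit_kw)
    reduced = fit_reml(red_spec, tab, **fit_kw)
    lrt = lrt_random(full, reduced, df=2)
    v_slope, r = full.components.slopes[slope_factor]
    return GxEResult(full=full, reduced=reduced, lrt=lrt,
                     slope_variance=v_slope, intercept_slope_corr=r,
                     slope_factor=slope_factor)


# ---------------------------------------------------------------------------
# three-way random-structure comparison for per-minute activity


@dataclass
class ActivityModelComparison:
    selected: int
    fits: dict
    lrts: dict
    aic: dict


def activity_model_specs(
    response: str = "activity",
    *,
    fixed: tuple = ("treatment", "sex", "treatment:sex", "time_std", "time_std2"),
    time_col: str = "time_std",
) -> dict:
    """The three candidate random structures for per-minute activity.

    1. random intercepts for individual, sire, dam, block, test day
       (no individual-by-time or genotype-by-time structure);
    2. correlated random time slopes within individual, plus sire, dam,
       block, test-day intercepts (individuals differ in their activity
       trajectory);
    3. correlated random time slopes within sire, plus individual, dam,
       block, test-day intercepts (families differ in trajectory).
    """
    base = (
        RandomTerm("sire:block", name="sire"),
        RandomTerm("dam:sire", name="dam"),
        RandomTerm("block"),
        RandomTerm("test_day"),
    )
    ind_int = RandomTerm("individual")
    m1 = ModelSpec(response, fixed, (ind_int,) + base)
    m2 = ModelSpec(
        response, fixed,
        (RandomTerm("individual", slope=time_col, name="individual"),) + base,
    )
    m3 = ModelSpec(
        response, fixed,
        (RandomTerm("sire:block", slope=time_col, name="sire"),
         ind_int,
         RandomTerm("dam:sire", name="dam"),
         RandomTerm("block"),
         RandomTerm("test_day")),
    )
    return {1: m1, 2: m2, 3: m3}


def compare_activity_models(
    table: pd.DataFrame,
    response: str = "activity",
    alpha: float = 0.05,
    *,
    fixed: tuple = ("treatment", "sex", "treatment:sex", "time_std", "time_std2"),
    **fit_kw,
) -> ActivityModelComparison:
    """Fit the three candidate structures and select one.

    Models 2 and 3 are each tested against model 1 with a 2-df LRT; model
    1 is retained unless at least one larger model rejects at ``alpha``,
    in which case the significant model with the greater log-likelihood
    (equivalently, with identical fixed parts, the lower AIC) wins.
    """
    tab = table
    if "time_std2" in fixed and "time_std2" not in tab.columns:
        tab = tab.copy()
        tab["time_std2"] = tab["time_std"] ** 2
    specs = activity_model_specs(response, fixed=fixed)
    fits = {k: fit_reml(s, tab, **fit_kw) for k, s in specs.items()}
    lrts = {k: lrt_random(fits[k], fits[1], df=2) for k in (2, 3)}
    aic = {k: information_criteria(f)["aic"] for k, f in fits.items()}
    candidates = [k for k in (2, 3) if lrts[k].p < alpha]
    if not candidates:
        selected = 1
    else:
        selected = max(candidates, key=lambda k: (fits[k].loglik, -aic[k], -k))
    return ActivityModelComparison(selected=selected, fits=fits, lrts=lrts, aic=aic)
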