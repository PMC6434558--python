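r"""Gaussian linear mixed models by (restricted) maximum likelihood.

The model is

.. math::

    y = X\beta + \sum_k Z_k u_k + e, \qquad
    u_k \sim N(0, G_k), \quad e \sim N(0, \sigma^2 I),

where each random term is either a set of independent group intercepts
(:math:`G_k = \sigma_k^2 I`) or a correlated (intercept, slope) pair per
group over a covariate, :math:`G_k = \Sigma_k \otimes I` with a 2x2
:math:`\Sigma_k`.  Nesting is encoded by composite group labels
(``dam`` within ``sire``, ``sire`` within ``block``); crossed intercepts
(e.g. test day) are just additional terms.

Estimation profiles out :math:`\beta` and :math:`\sigma^2` and optimizes
the restricted (or full) log-likelihood over variance *ratios*
:math:`\gamma_k = \sigma_k^2/\sigma^2` on the log scale, with correlations
mapped through :math:`\tanh`.  This enforces the nonnegativity/|r|<=1
bounds and lets a component run cleanly to the zero boundary, where it is
reported as exactly 0 with a boundary flag.  All linear algebra goes
through the Woodbury identity, so one evaluation costs a Cholesky of the
q x q matrix :math:`\Gamma^{-1} + Z'Z` (q = total random-effect columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.linalg.lapack import dposv as _posv

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "VarianceComponents",
    "FittedModel",
    "ModelError",
    "build_design",
    "fit_reml",
    "fit_ml",
    "information_criteria",
]

_LOG_GAMMA_FLOOR = -30.0  # log variance ratio treated as the 0 boundary
_BOUNDARY_RATIO = 1e-8    # gamma below this is reported as variance 0


class ModelError(ValueError):
    """Raised for malformed model specifications or degenerate designs."""


@dataclass(frozen=True)
class RandomTerm:
    """One random term.

    ``group`` is a column name or a ``"inner:outer"`` composite encoding
    nesting.  With ``slope`` set, the term is a correlated
    (intercept, slope-on-``slope``) pair per group; ``slope`` must name a
    numeric column.
    """

    group: str
    slope: str | None = None
    name: str | None = None

    @property
    def label(self) -> str:
        return self.name or (self.group if self.slope is None
                             else f"{self.group}|{self.slope}")

    @property
    def n_params(self) -> int:
        return 1 if self.slope is None else 3


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``fixed`` lists term strings over table columns: a bare column name
    (categoricals are dummy-coded against the reference level in
    ``references``), or ``"a:b"`` for an interaction.  An intercept is
    always included.  ``random`` lists :class:`RandomTerm`s; at most one
    slope term per grouping factor.
    """

    response: str
    fixed: tuple = ()
    random: tuple = ()
    reml: bool = True
    references: dict = field(default_factory=lambda: {"treatment": "high", "sex": "F"})

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        rnd = tuple(
            t if isinstance(t, RandomTerm) else RandomTerm(t) for t in self.random
        )
        object.__setattr__(self, "random", rnd)
        slope_groups = [t.group for t in rnd if t.slope is not None]
        if len(slope_groups) != len(set(slope_groups)):
            raise ModelError("at most one intercept+slope term per grouping factor")

    def drop_random(self, label: str) -> "ModelSpec":
        """Spec with the named random term removed."""
        kept = tuple(t for t in self.random if t.label != label)
        if len(kept) == len(self.random):
            raise ModelError(f"no random term labelled {label!r}")
        return ModelSpec(self.response, self.fixed, kept, self.reml, dict(self.references))

    def replace_random(self, random: Sequence[RandomTerm]) -> "ModelSpec":
        return ModelSpec(self.response, self.fixed, tuple(random), self.reml,
                         dict(self.references))


@dataclass
class VarianceComponents:
    """Named variance estimates on the response scale.

    ``variances`` maps term label -> variance (intercept variance for
    slope terms) and always contains ``"residual"``.  For each slope term,
    ``slopes[label]`` holds ``(slope_variance, intercept_slope_corr)``.
    ``boundary`` lists labels whose estimate hit the zero boundary.
    """

    variances: dict
    slopes: dict = field(default_factory=dict)
    boundary: list = field(default_factory=list)

    def __getitem__(self, key):
        return self.variances[key]

    def total(self, include: Iterable[str] | None = None) -> float:
        keys = list(self.variances) if include is None else list(include)
        return float(sum(self.variances[k] for k in keys))

    def as_series(self) -> pd.Series:
        return pd.Series(self.variances, dtype=float)


@dataclass
class FittedModel:
    spec: ModelSpec
    components: VarianceComponents
    fixed_estimates: pd.DataFrame
    loglik: float
    converged: bool
    n_obs: int
    n_dropped: int
    n_groups: dict
    sigma2: float
    theta: np.ndarray
    reml: bool
    _design: "DesignMatrices" = None

    @property
    def k_varpar(self) -> int:
        """Number of estimated covariance parameters (incl. residual)."""
        return 1 + sum(t.n_params for t in self.spec.random)


@dataclass
class DesignMatrices:
    """Numeric design prepared from a table: fixed matrix, per-term group
    codes, and optional slope covariates."""

    y: np.ndarray
    X: np.ndarray
    x_names: list
    terms: list            # (RandomTerm, codes, n_levels, slope_values|None)
    n_dropped: int
    index: np.ndarray      # surviving row positions in the original table


def _composite_codes(table: pd.DataFrame, group: str) -> pd.Series:
    cols = group.split(":")
    for c in cols:
        if c not in table.columns:
            raise ModelError(f"grouping column {c!r} not in table")
    if len(cols) == 1:
        return table[cols[0]].astype(str)
    out = table[cols[0]].astype(str)
    for c in cols[1:]:
        out = out + ":" + table[c].astype(str)
    return out


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def _encode_column(table, col, references):
    """Return list of (name, values) for one main-effect column."""
    if col not in table.columns:
        raise ModelError(f"fixed-effect column {col!r} not in table")
    s = table[col]
    if _is_categorical(s):
        levels = sorted(pd.unique(s.astype(str)))
        ref = references.get(col, levels[0])
        if ref not in levels:
            ref = levels[0]
        out = []
        for lev in levels:
            if lev == ref:
                continue
            out.append((f"{col}[{lev}]", (s.astype(str) == lev).to_numpy(float)))
        return out
    return [(col, s.to_numpy(float))]


def build_design(spec: ModelSpec, table: pd.DataFrame) -> DesignMatrices:
    """Build numeric design structures, dropping rows with missing values
    in any referenced column."""
    needed = {spec.response}
    for term in spec.fixed:
        needed.update(term.split(":"))
    for rt in spec.random:
        needed.update(rt.group.split(":"))
        if rt.slope is not None:
            needed.add(rt.slope)
    missing = sorted(c for c in needed if c not in table.columns)
    if missing:
        raise ModelError(f"missing columns: {missing}")

    sub = table[sorted(needed)]
    keep = ~sub.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    t = table.loc[keep]
    n = len(t)
    if n == 0:
        raise ModelError("no complete rows")

    cols = [("Intercept", np.ones(n))]
    for term in spec.fixed:
        parts = term.split(":")
        encoded = [_encode_column(t, p, spec.references) for p in parts]
        combo = encoded[0]
        for nxt in encoded[1:]:
            combo = [(f"{na}:{nb}", va * vb) for na, va in combo for nb, vb in nxt]
        cols.extend(combo)
    X = np.column_stack([v for _, v in cols])
    x_names = [nm for nm, _ in cols]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("rank-deficient fixed-effect design")

    y = t[spec.response].to_numpy(float)

    terms = []
    for rt in spec.random:
        codes, levels = pd.factorize(_composite_codes(t, rt.group), sort=True)
        if len(levels) < 2:
            raise ModelError(f"random factor {rt.label!r} has < 2 levels")
        slope_vals = None
        if rt.slope is not None:
            sv = t[rt.slope]
            if _is_categorical(sv):
                raise ModelError(f"slope covariate {rt.slope!r} must be numeric")
            slope_vals = sv.to_numpy(float)
        terms.append((rt, codes.astype(np.int64), len(levels), slope_vals))

    if X.shape[0] <= X.shape[1]:
        raise ModelError("more fixed coefficients than observations")
    return DesignMatrices(
        y=y, X=X, x_names=x_names, terms=terms, n_dropped=n_dropped,
        index=np.flatnonzero(keep.to_numpy()),
    )


# ---------------------------------------------------------------------------
# likelihood machinery


class _Precomputed:
    """Per-dataset cross-products; evaluation cost is then O(q^3).

    Also precomputes, per random-effect block, the flat indices of the
    matrix entries that receive the Gamma^{-1} contributions, so one
    likelihood evaluation is a handful of vectorized operations plus one
    Cholesky factorization.
    """

    def __init__(self, dm: DesignMatrices):
        self.n, self.p = dm.X.shape
        blocks = []
        q = 0
        rows = []
        cols = []
        vals = []
        for rt, codes, g, slope in dm.terms:
            r = np.arange(self.n)
            rows.append(r)
            cols.append(q + codes)
            vals.append(np.ones(self.n))
            if rt.slope is None:
                blocks.append(("i", q, g))
                q += g
            else:
                rows.append(r)
                cols.append(q + g + codes)
                vals.append(slope)
                blocks.append(("s", q, g))
                q += 2 * g
        self.q = q
        self.blocks = blocks
        W = np.column_stack([dm.y, dm.X])
        if q:
            from scipy import sparse

            Z = sparse.csc_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.n, q),
            )
            self.ZtZ = np.asarray((Z.T @ Z).todense())
            self.ZtW = np.asarray(Z.T @ W)
        else:
            self.ZtZ = np.zeros((0, 0))
            self.ZtW = np.zeros((0, 1 + self.p))
        self.WtW = W.T @ W
        self.dm = dm
        # flat index arrays into the q*q matrix for in-place Gamma^{-1} adds
        self.flat = []
        for kind, off, g in blocks:
            i = np.arange(off, off + g)
            if kind == "i":
                self.flat.append((i * q + i,))
            else:
                j = i + g
                self.flat.append((i * q + i, j * q + j, i * q + j, j * q + i))


def _unpack_theta(theta, blocks):
    """theta -> (Gamma^{-1} filler, log|Gamma|) pieces per block."""
    out = []
    logdet_gamma = 0.0
    i = 0
    for kind, off, g in blocks:
        if kind == "i":
            lg = float(np.clip(theta[i], _LOG_GAMMA_FLOOR, 30.0))
            gamma = np.exp(lg)
            out.append(("i", off, g, gamma))
            logdet_gamma += g * lg
            i += 1
        else:
            lg0 = float(np.clip(theta[i], _LOG_GAMMA_FLOOR, 30.0))
            lg1 = float(np.clip(theta[i + 1], _LOG_GAMMA_FLOOR, 30.0))
            r = float(np.tanh(theta[i + 2]))
            r = float(np.clip(r, -1 + 1e-12, 1 - 1e-12))
            g0, g1 = np.exp(lg0), np.exp(lg1)
            det = g0 * g1 * (1.0 - r * r)
            out.append(("s", off, g, (g0, g1, r, det)))
            logdet_gamma += g * np.log(det)
            i += 3
    return out, logdet_gamma


def _neg2ll(theta, pre: _Precomputed, reml: bool, out: dict | None = None):
    n, p, q = pre.n, pre.p, pre.q
    parts, logdet_gamma = _unpack_theta(theta, pre.blocks)

    if q:
        M = pre.ZtZ.copy()
        mf = M.reshape(-1)
        for (kind, off, g, par), flat in zip(parts, pre.flat):
            if kind == "i":
                mf[flat[0]] += 1.0 / par
            else:
                g0, g1, r, det = par
                b = -r * np.sqrt(g0 * g1) / det
                mf[flat[0]] += g1 / det
                mf[flat[1]] += g0 / det
                mf[flat[2]] += b
                mf[flat[3]] += b
        cM, A, info = _posv(M, pre.ZtW, lower=1, overwrite_a=1)
        if info != 0:
            return np.inf
        d = np.einsum("ii->i", cM)
        logdet_M = 2.0 * float(np.sum(np.log(d)))
        WtVW = pre.WtW - pre.ZtW.T @ A
        logdet_V0 = logdet_gamma + logdet_M
    else:
        WtVW = pre.WtW
        logdet_V0 = 0.0

    yVy = WtVW[0, 0]
    XtVX = WtVW[1:, 1:]
    XtVy = WtVW[1:, 0]
    try:
        cX = cho_factor(XtVX, lower=True, check_finite=False)
    except LinAlgError:
        return np.inf
    beta = cho_solve(cX, XtVy, check_finite=False)
    rss = float(yVy - XtVy @ beta)
    if not np.isfinite(rss):
        return np.inf
    # floor guards exactly-collinear/constant responses (rss -> 0)
    rss = max(rss, 1e-12 * (abs(yVy) + 1.0))
    logdet_XtVX = 2.0 * np.sum(np.log(np.diag(cX[0])))

    if reml:
        dof = n - p
        s2 = rss / dof
        val = dof * (np.log(2 * np.pi * s2) + 1.0) + logdet_V0 + logdet_XtVX
    else:
        s2 = rss / n
        val = n * (np.log(2 * np.pi * s2) + 1.0) + logdet_V0
    if out is not None:
        out["beta"] = beta
        out["sigma2"] = s2
        out["XtVX"] = XtVX
        out["cX"] = cX
    return float(val)


def _initial_theta(dm: DesignMatrices) -> np.ndarray:
    """Method-of-moments starting values on the log-ratio scale.

    Uses OLS residuals: for each grouping factor, the variance of group
    means (less its own sampling noise) over the residual variance gives a
    rough variance ratio; crude, but it starts the simplex at the right
    order of magnitude.
    """
    beta, *_ = np.linalg.lstsq(dm.X, dm.y, rcond=None)
    r = dm.y - dm.X @ beta
    s2 = max(float(r @ r) / max(len(r) - dm.X.shape[1], 1), 1e-300)
    init = []
    for rt, codes, g, _slope in dm.terms:
        cnt = np.bincount(codes, minlength=g).astype(float)
        cnt[cnt == 0] = 1.0
        means = np.bincount(codes, weights=r, minlength=g) / cnt
        v_between = float(np.var(means, ddof=1)) - s2 * float(np.mean(1.0 / cnt))
        gamma = np.clip(v_between / s2, 0.02, 20.0)
        if rt.slope is None:
            init.append(np.log(gamma))
        else:
            init.extend([np.log(gamma), np.log(max(gamma / 2.0, 0.02)), 0.0])
    return np.array(init)


#: Nelder-Mead settings per accuracy profile.  "full" adds a simplex
#: restart and a quasi-Newton polish; "medium" trades the last decimals of
#: the optimum for speed in large simulation loops; "fast" is reserved for
#: warm starts (bootstrap refits).
_NM_PROFILES = {
    "full": dict(xatol=1e-8, fatol=1e-11, scale=600),
    "medium": dict(xatol=1e-5, fatol=1e-9, scale=300),
    "fast": dict(xatol=2e-3, fatol=1e-5, scale=30),
}


def _optimize(pre, reml, theta0, n_starts, accuracy):
    k = len(theta0)
    if k == 0:
        return theta0, _neg2ll(theta0, pre, reml), True

    prof = _NM_PROFILES[accuracy]
    opts = dict(xatol=prof["xatol"], fatol=prof["fatol"],
                maxiter=prof["scale"] * k, maxfev=prof["scale"] * k)

    starts = [theta0]
    if n_starts >= 2:
        starts.append(theta0 + 1.5)
    if n_starts >= 3:
        starts.append(theta0 - 2.0)
    for extra in range(3, n_starts):
        starts.append(theta0 + ((-1) ** extra) * (0.5 + extra))

    best = None
    for th0 in starts:
        res = optimize.minimize(
            _neg2ll, th0, args=(pre, reml), method="Nelder-Mead", options=opts
        )
        if best is None or res.fun < best.fun:
            best = res
    if accuracy == "full":
        # polish: restart the simplex at the optimum, then quasi-Newton
        res = optimize.minimize(
            _neg2ll, best.x, args=(pre, reml), method="Nelder-Mead", options=opts
        )
        if res.fun <= best.fun:
            best = res
        res = optimize.minimize(
            _neg2ll, best.x, args=(pre, reml), method="L-BFGS-B",
            bounds=[(_LOG_GAMMA_FLOOR, 30.0)] * k,
        )
        if np.isfinite(res.fun) and res.fun <= best.fun:
            best = res
    converged = bool(np.isfinite(best.fun))
    return np.asarray(best.x, dtype=float), float(best.fun), converged


def _fit(spec: ModelSpec, table: pd.DataFrame, reml: bool, *,
         n_starts: int = 3, warm_start=None, accuracy: str = "full",
         fast: bool = False, design: DesignMatrices | None = None) -> FittedModel:
    if fast:
        accuracy = "fast"
    if accuracy not in _NM_PROFILES:
        raise ModelError(f"unknown accuracy profile {accuracy!r}")
    dm = design if design is not None else build_design(spec, table)
    pre = _Precomputed(dm)
    theta0 = np.asarray(warm_start, float) if warm_start is not None else _initial_theta(dm)
    if warm_start is not None:
        n_starts = 1
    theta, fun, converged = _optimize(pre, reml, theta0, n_starts, accuracy)

    cache: dict = {}
    fun = _neg2ll(theta, pre, reml, out=cache)
    if not np.isfinite(fun):
        raise ModelError("likelihood evaluation failed at the reported optimum")
    sigma2 = cache["sigma2"]
    beta = cache["beta"]
    cov_beta = sigma2 * cho_solve(cache["cX"], np.eye(pre.p), check_finite=False)
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))

    variances = {}
    slopes = {}
    boundary = []
    n_groups = {}
    i = 0
    for (rt, codes, g, slope_vals) in dm.terms:
        n_groups[rt.label] = g
        if rt.slope is None:
            gamma = float(np.exp(np.clip(theta[i], _LOG_GAMMA_FLOOR, 30.0)))
            if gamma < _BOUNDARY_RATIO:
                variances[rt.label] = 0.0
                boundary.append(rt.label)
            else:
                variances[rt.label] = gamma * sigma2
            i += 1
        else:
            g0 = float(np.exp(np.clip(theta[i], _LOG_GAMMA_FLOOR, 30.0)))
            g1 = float(np.exp(np.clip(theta[i + 1], _LOG_GAMMA_FLOOR, 30.0)))
            r = float(np.tanh(theta[i + 2]))
            v_int = 0.0 if g0 < _BOUNDARY_RATIO else g0 * sigma2
            v_slo = 0.0 if g1 < _BOUNDARY_RATIO else g1 * sigma2
            if g0 < _BOUNDARY_RATIO or g1 < _BOUNDARY_RATIO:
                boundary.append(rt.label)
                if g1 < _BOUNDARY_RATIO:
                    r = 0.0
            variances[rt.label] = v_int
            slopes[rt.label] = (v_slo, r)
            i += 3
    variances["residual"] = float(sigma2)

    fixed = pd.DataFrame(
        {"term": dm.x_names, "estimate": beta, "se": se}
    ).set_index("term")

    return FittedModel(
        spec=spec,
        components=VarianceComponents(variances, slopes, boundary),
        fixed_estimates=fixed,
        loglik=-0.5 * fun,
        converged=converged,
        n_obs=pre.n,
        n_dropped=dm.n_dropped,
        n_groups=n_groups,
        sigma2=float(sigma2),
        theta=theta,
        reml=reml,
        _design=dm,
    )


def fit_reml(spec: ModelSpec, table: pd.DataFrame, **kw) -> FittedModel:
    """Fit by restricted maximum likelihood (the reporting default)."""
    return _fit(spec, table, reml=True, **kw)


def fit_ml(spec: ModelSpec, table: pd.DataFrame, **kw) -> FittedModel:
    """Fit by unrestricted maximum likelihood (for comparisons across
    models with different fixed parts)."""
    return _fit(spec, table, reml=False, **kw)


def information_criteria(fit: FittedModel) -> dict:
    """AIC/BIC at the optimum.

    Parameter count ``k`` is the number of covariance parameters
    (variances, correlations, residual); under ML the fixed coefficients
    are added as well.  Under REML these criteria are comparable only
    across models sharing the same fixed part.
    """
    if not fit.converged:
        raise ModelError("cannot compute information criteria for an unconverged fit")
    k = fit.k_varpar + (0 if fit.reml else fit.fixed_estimates.shape[0])
    n = fit.n_obs - (fit.fixed_estimates.shape[0] if fit.reml else 0)
    aic = -2.0 * fit.loglik + 2.0 * k
    bic = -2.0 * fit.loglik + np.log(n) * k
    return {"aic": float(aic), "bic": float(bic), "k": int(k)}
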