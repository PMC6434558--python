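"""Gaussian phenotype simulation over a nested half-sib breeding design.

Phenotypes are built additively from independent Gaussian random effects
(block, sire, dam, test day, residual) plus fixed effects of density
treatment, sex, and their interaction.  Two extensions mirror the
structures the analysis targets:

* a sire-level *reaction norm*: each sire carries a bivariate-normal
  (intercept, slope) pair where the slope is the sire's deviation in the
  low-density environment (high density is the reference level), with
  intercept-slope correlation ``r_is``;
* individual-level intercept/slope pairs over standardized time for
  repeated per-minute activity scores.

Every simulation returns both the phenotype table and a "truth" record of
the latent effect draws, so variance-component recovery can be checked
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BreedingDesign


class TraitConfigError(ValueError):
    """Raised for invalid trait-model configurations."""


def _check_var(name, v):
    if v < 0:
        raise TraitConfigError(f"{name} must be >= 0, got {v}")


def _check_corr(name, r):
    if not -1.0 <= r <= 1.0:
        raise TraitConfigError(f"{name} must be in [-1, 1], got {r}")


@dataclass(frozen=True)
class TraitModel:
    """Generating model for a single-measurement Gaussian trait.

    Variances are on the (possibly transformed) trait scale, squared
    units.  ``V_slope``/``r_is`` parameterize the sire reaction norm over
    density; with ``V_slope = 0`` the trait has no genotype-by-environment
    structure and ``r_is`` is ignored.
    """

    mu: float = 0.0
    beta_density: float = 0.0
    beta_sex: float = 0.0
    beta_density_sex: float = 0.0
    V_S: float = 1.0
    V_M: float = 1.0
    V_block: float = 0.0
    V_testday: float = 0.0
    V_R: float = 1.0
    V_slope: float = 0.0
    r_is: float = 0.0
    n_testdays: int = 10

    def __post_init__(self):
        for nm in ("V_S", "V_M", "V_block", "V_testday", "V_R", "V_slope"):
            _check_var(nm, getattr(self, nm))
        _check_corr("r_is", self.r_is)
        if self.n_testdays < 1:
            raise TraitConfigError("n_testdays must be >= 1")


@dataclass(frozen=True)
class RepeatedModel(TraitModel):
    """Generating model for repeated per-minute activity.

    Adds individual (intercept, slope-over-standardized-time) pairs with
    variances ``V_I_int``/``V_I_slope`` and correlation ``r_I``, plus
    fixed linear and quadratic time effects.
    """

    V_I_int: float = 1.0
    V_I_slope: float = 0.0
    r_I: float = 0.0
    beta_time: float = 0.0
    beta_time2: float = 0.0
    n_minutes: int = 5

    def __post_init__(self):
        super().__post_init__()
        for nm in ("V_I_int", "V_I_slope"):
            _check_var(nm, getattr(self, nm))
        _check_corr("r_I", self.r_I)
        if self.n_minutes < 2:
            raise TraitConfigError("n_minutes must be >= 2")


@dataclass(frozen=True)
class SimulatedTrait:
    """Phenotype table plus the latent draws that generated it."""

    data: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _bivariate_pairs(rng, n, v_int, v_slope, r):
    """Draw n (intercept, slope) pairs from the implied bivariate normal."""
    cov = r * np.sqrt(v_int * v_slope)
    sigma = np.array([[v_int, cov], [cov, v_slope]])
    # sqrt via eigendecomposition: robust to singular corner cases
    w, q = np.linalg.eigh(sigma)
    root = q @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ q.T
    z = rng.standard_normal((n, 2))
    return z @ root.T


def _assign_test_days(df, n_testdays, rng):
    """Round-robin test days within each dam family, with a shuffled
    starting offset, so siblings spread over multiple days and every day
    mixes families."""
    day = np.empty(len(df), dtype=int)
    for _, idx in df.groupby("dam", sort=False).indices.items():
        order = rng.permutation(len(idx))
        start = rng.integers(n_testdays)
        day[idx] = (start + order) % n_testdays
    return np.array([f"day{d + 1}" for d in day])


def _base_components(design: BreedingDesign, model: TraitModel, rng):
    """Draw all family-level effects and assemble the offspring table."""
    df = design.to_frame()
    n = len(df)

    blocks = list(design.blocks)
    sire_ids = [s for s, _ in design.sires]
    dam_ids = [d for d, _ in design.dams]

    b_eff = rng.standard_normal(len(blocks)) * np.sqrt(model.V_block)
    pairs = _bivariate_pairs(
        rng, len(sire_ids), model.V_S, model.V_slope, model.r_is if model.V_slope > 0 else 0.0
    )
    s_int, s_slope = pairs[:, 0], pairs[:, 1]
    if model.V_slope == 0:
        s_slope = np.zeros(len(sire_ids))
    d_eff = rng.standard_normal(len(dam_ids)) * np.sqrt(model.V_M)
    t_eff = rng.standard_normal(model.n_testdays) * np.sqrt(model.V_testday)

    df["test_day"] = _assign_test_days(df, model.n_testdays, rng)
    df["days_after_eclosion"] = rng.integers(7, 15, size=n)

    low = (df["treatment"] == "low").to_numpy(float)
    male = (df["sex"] == "M").to_numpy(float)
    fixed = (
        model.mu
        + model.beta_density * low
        + model.beta_sex * male
        + model.beta_density_sex * low * male
    )

    bmap = dict(zip(blocks, b_eff))
    smap_i = dict(zip(sire_ids, s_int))
    smap_s = dict(zip(sire_ids, s_slope))
    dmap = dict(zip(dam_ids, d_eff))
    tmap = {f"day{i + 1}": t_eff[i] for i in range(model.n_testdays)}

    latent = (
        fixed
        + df["block"].map(bmap).to_numpy()
        + df["sire"].map(smap_i).to_numpy()
        + df["sire"].map(smap_s).to_numpy() * low
        + df["dam"].map(dmap).to_numpy()
        + df["test_day"].map(tmap).to_numpy()
    )
    truth = {
        "block_effects": pd.Series(b_eff, index=blocks, name="effect"),
        "sire_intercepts": pd.Series(s_int, index=sire_ids, name="intercept"),
        "sire_slopes": pd.Series(s_slope, index=sire_ids, name="slope"),
        "dam_effects": pd.Series(d_eff, index=dam_ids, name="effect"),
        "testday_effects": pd.Series(t_eff, index=[f"day{i+1}" for i in range(model.n_testdays)]),
        "fixed_part": fixed,
    }
    return df, latent, truth


def simulate_trait(
    design: BreedingDesign,
    model: TraitModel,
    seed: int = 0,
    trait_name: str = "y",
) -> SimulatedTrait:
    """Simulate one Gaussian observation per offspring.

    The phenotype is ``mu + fixed + block + sire + sire_slope * low +
    dam + test_day + residual``; the residual draw per row is stored in
    the truth record so the additive bookkeeping is exactly checkable.
    """
    rng = np.random.default_rng(seed)
    df, latent, truth = _base_components(design, model, rng)
    resid = rng.standard_normal(len(df)) * np.sqrt(model.V_R)
    df[trait_name] = latent + resid
    truth["residuals"] = resid
    truth["model"] = model
    return SimulatedTrait(data=df, truth=truth)


def simulate_latency(
    design: BreedingDesign,
    model: TraitModel,
    cap_s: float = 1800.0,
    seed: int = 0,
) -> SimulatedTrait:
    """Simulate refuge-emergence latencies with right censoring.

    The latent trait is generated on the ``log(latency + 1)`` scale (the
    scale on which latency is analyzed), back-transformed to seconds, and
    censored at ``cap_s``: any animal whose latent latency reaches the cap
    is recorded at exactly ``cap_s`` with ``censored = True``.
    """
    if cap_s <= 0:
        raise TraitConfigError("cap_s must be > 0")
    rng = np.random.default_rng(seed)
    df, latent, truth = _base_components(design, model, rng)
    resid = rng.standard_normal(len(df)) * np.sqrt(model.V_R)
    log_latency = latent + resid
    latency = np.expm1(log_latency)
    latency = np.clip(latency, 0.0, None)
    censored = latency >= cap_s
    latency = np.where(censored, cap_s, latency)
    df["latency_s"] = latency
    df["censored"] = censored
    truth["residuals"] = resid
    truth["log_latency"] = log_latency
    truth["model"] = model
    return SimulatedTrait(data=df, truth=truth)


def simulate_repeated_activity(
    design: BreedingDesign,
    model: RepeatedModel,
    seed: int = 0,
    trait_name: str = "activity",
) -> SimulatedTrait:
    """Simulate per-minute activity: a long table with ``n_minutes`` rows
    per individual.

    Each row is ``mu + fixed(density, sex, time, time^2) + block + sire +
    sire_slope * low + dam + test_day + ind_intercept + ind_slope * time +
    residual`` where ``time`` is the minute index standardized to mean 0,
    SD 1.
    """
    if not isinstance(model, RepeatedModel):
        raise TraitConfigError("simulate_repeated_activity requires a RepeatedModel")
    rng = np.random.default_rng(seed)
    df, latent, truth = _base_components(design, model, rng)
    n_ind = len(df)

    ind_pairs = _bivariate_pairs(rng, n_ind, model.V_I_int, model.V_I_slope,
                                 model.r_I if model.V_I_slope > 0 else 0.0)
    ind_int = ind_pairs[:, 0]
    ind_slope = ind_pairs[:, 1] if model.V_I_slope > 0 else np.zeros(n_ind)

    minutes = np.arange(1, model.n_minutes + 1, dtype=float)
    t_std = (minutes - minutes.mean()) / minutes.std(ddof=1)

    long = df.loc[df.index.repeat(model.n_minutes)].reset_index(drop=True)
    long["minute"] = np.tile(minutes.astype(int), n_ind)
    long["time_std"] = np.tile(t_std, n_ind)

    base = np.repeat(latent, model.n_minutes)
    ii = np.repeat(ind_int, model.n_minutes)
    isl = np.repeat(ind_slope, model.n_minutes)
    tt = long["time_std"].to_numpy()
    resid = rng.standard_normal(len(long)) * np.sqrt(model.V_R)
    long[trait_name] = (
        base
        + model.beta_time * tt
        + model.beta_time2 * tt**2
        + ii
        + isl * tt
        + resid
    )
    truth["individual_intercepts"] = pd.Series(ind_int, index=df["individual"])
    truth["individual_slopes"] = pd.Series(ind_slope, index=df["individual"])
    truth["residuals"] = resid
    truth["model"] = model
    return SimulatedTrait(data=long, truth=truth)

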