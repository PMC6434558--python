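"""Construction of analysis-scale trait variables from raw measurements.

Raw measurements enter the mixed models after fixed transforms: mass in
grams is analyzed untransformed, development time as the natural log of
days to eclosion, total open-field distance square-root transformed, and
per-minute distance as ``log(cm + 1)``.  Emergence latency is censored at
30 min (1800 s) and reverse-scored into a boldness value so that larger
means bolder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class TraitDataError(ValueError):
    """Raised when raw values fall outside a transform's domain."""


#: registered transforms; log transforms of quantities whose range includes
#: zero (latency, per-minute distance) use a +1 offset so they are defined
#: everywhere and order-preserving.
TRANSFORMS = ("identity", "log", "log1p", "sqrt")


@dataclass(frozen=True)
class TraitDefinition:
    """How a raw column becomes an analysis trait.

    ``censor_cap`` (seconds) applies only to latency-type traits;
    ``direction`` is a free-text note on the sign convention.
    """

    name: str
    raw_column: str
    transform: str = "identity"
    censor_cap: float | None = None
    direction: str = ""

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise TraitDataError(
                f"unknown transform {self.transform!r}; expected one of {TRANSFORMS}"
            )


def transform_trait(values, definition: TraitDefinition) -> np.ndarray:
    """Apply the definition's transform to raw values (NaN passes through)."""
    x = np.asarray(values, dtype=float)
    t = definition.transform
    finite = np.isfinite(x)
    if t == "identity":
        return x.copy()
    if t == "sqrt":
        if np.any(x[finite] < 0):
            raise TraitDataError(f"{definition.name}: sqrt of negative value")
        return np.sqrt(x)
    if t == "log":
        if np.any(x[finite] <= 0):
            raise TraitDataError(f"{definition.name}: log of non-positive value")
        return np.log(x)
    if t == "log1p":
        if np.any(x[finite] < 0):
            raise TraitDataError(f"{definition.name}: log1p of negative value")
        return np.log1p(x)
    raise AssertionError("unreachable")


def inverse_transform(values, definition: TraitDefinition) -> np.ndarray:
    """Back-transform analysis-scale values to the raw scale."""
    x = np.asarray(values, dtype=float)
    t = definition.transform
    if t == "identity":
        return x.copy()
    if t == "sqrt":
        return x**2
    if t == "log":
        return np.exp(x)
    if t == "log1p":
        return np.expm1(x)
    raise AssertionError("unreachable")


def boldness_score(latency_s, cap_s: float = 1800.0) -> np.ndarray:
    """Reverse-scored log latency to emerge from a refuge.

    Latencies are censored at ``cap_s`` and scored as
    ``log(cap_s + 1) - log(latency + 1)``: a strictly decreasing map of
    censored latency onto ``[0, log(cap_s + 1)]``.  An animal that never
    emerged (latency at the cap) scores exactly 0; an instant emerger
    scores ``log(cap_s + 1)``.  The +1 offset keeps the log defined at a
    raw latency of 0 s.
    """
    x = np.asarray(latency_s, dtype=float)
    if np.any(np.isfinite(x) & (x < 0)):
        raise TraitDataError("negative latency")
    if cap_s <= 0:
        raise TraitDataError("cap_s must be > 0")
    capped = np.minimum(x, cap_s)
    return np.log1p(cap_s) - np.log1p(capped)


def standardize_covariate(values) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (NaN ignored in moments)."""
    x = np.asarray(values, dtype=float)
    m = np.nanmean(x)
    s = np.nanstd(x, ddof=1)
    if not np.isfinite(s) or s == 0:
        raise TraitDataError("cannot standardize a constant covariate")
    return (x - m) / s


def add_standard_columns(
    table: pd.DataFrame,
    definitions: list[TraitDefinition] | None = None,
) -> pd.DataFrame:
    """Return a copy of ``table`` with derived analysis columns appended.

    Adds, where the source columns are present: ``boldness`` (from
    ``latency_s``), standardized ``days_std`` (from ``days_after_eclosion``),
    and the transformed column for each definition (written under the
    definition's ``name``).
    """
    out = table.copy()
    if "latency_s" in out.columns:
        cap = 1800.0
        if definitions:
            for d in definitions:
                if d.raw_column == "latency_s" and d.censor_cap:
                    cap = d.censor_cap
        out["boldness"] = boldness_score(out["latency_s"], cap_s=cap)
    if "days_after_eclosion" in out.columns:
        out["days_std"] = standardize_covariate(out["days_after_eclosion"])
    for d in definitions or []:
        if d.raw_column in out.columns and d.name not in out.columns:
            out[d.name] = transform_trait(out[d.raw_column], d)
    if "time_std" in out.columns and "time_std2" not in out.columns:
        out["time_std2"] = out["time_std"] ** 2
    return out
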