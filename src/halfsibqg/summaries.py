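"""Quantitative-genetic summaries from fitted variance components.

In a nested paternal half-sib design the among-sire variance estimates a
quarter of the additive genetic variance, so :math:`V_A = 4 V_S`.
Narrow-sense heritability and the maternal-effect ratio are

.. math::

    h^2 = \\frac{4 V_S}{4 V_S + V_M + V_{block} + V_R}, \\qquad
    m^2 = \\frac{V_M}{4 V_S + V_M + V_{block} + V_R},

with the block term simply omitted in the "without block" model variant.
Test-day variance (and, for repeated measures, individual-level
variances) is excluded from these denominators but *included* in the
percent-of-phenotypic-variance breakdown, where each fitted component —
V_S counted once, not multiplied by 4 — is expressed against the sum of
all fitted random components.

The with/without-block model pair probes confounding between temporal
block and family: when families cannot be randomized over blocks, block
variance may absorb genetic (sire) or maternal (dam) variance, and the
direction of component shifts when block is dropped diagnoses which.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .lmm import FittedModel, ModelError, ModelSpec, RandomTerm, fit_reml

__all__ = [
    "QGSummary",
    "heritability",
    "maternal_effect",
    "percent_vp",
    "percent_vp_table",
    "summary_from_components",
    "summarize_fit",
    "treatment_specific_components",
    "block_sensitivity",
    "BlockSensitivity",
]

#: component labels never counted in the h2/m2 denominator
_NON_QG_LABELS = ("test_day", "individual")


def _check_components(*vals):
    for v in vals:
        if v < 0:
            raise ModelError(f"variance components must be >= 0, got {v}")


def heritability(V_S: float, V_M: float, V_block: float, V_R: float) -> float:
    """Narrow-sense heritability ``4*V_S / (4*V_S + V_M + V_block + V_R)``.

    Pass ``V_block = 0`` for the model variant without the temporal-block
    intercept (whose denominator simply omits the block term).
    """
    _check_components(V_S, V_M, V_block, V_R)
    va = 4.0 * V_S
    denom = va + V_M + V_block + V_R
    if denom <= 0:
        raise ModelError("all variance components are zero; h2 undefined")
    return va / denom


def maternal_effect(V_S: float, V_M: float, V_block: float, V_R: float) -> float:
    """Maternal-effect ratio ``V_M / (4*V_S + V_M + V_block + V_R)``."""
    _check_components(V_S, V_M, V_block, V_R)
    denom = 4.0 * V_S + V_M + V_block + V_R
    if denom <= 0:
        raise ModelError("all variance components are zero; m2 undefined")
    return V_M / denom


def percent_vp(component: str, all_components: Mapping[str, float]) -> float:
    """Percent of phenotypic variance: ``100 * V_c / sum(all components)``.

    The total includes every fitted random component (test-day and
    individual-level terms included; the sire component enters once, not
    multiplied by 4).
    """
    if component not in all_components:
        raise ModelError(f"unknown component {component!r}")
    total = float(sum(all_components.values()))
    if total <= 0:
        raise ModelError("zero total variance")
    return 100.0 * all_components[component] / total


def percent_vp_table(all_components: Mapping[str, float]) -> pd.Series:
    """Percent of V_P for every component (sums to 100)."""
    return pd.Series(
        {k: percent_vp(k, all_components) for k in all_components}, dtype=float
    )


@dataclass
class QGSummary:
    """h2, m2 and the %V_P breakdown for one trait/model variant."""

    trait: str
    variant: str                    # "with_block" | "without_block"
    subset: str                     # "all" | "high" | "low"
    h2: float
    m2: float
    pct_VP: dict
    components: dict
    slopes: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": f"V_{k}", "value": v, "pct_VP": self.pct_VP.get(k, np.nan)}
            for k, v in self.components.items()
        ]
        rows.append({"quantity": "h2", "value": self.h2, "pct_VP": np.nan})
        rows.append({"quantity": "m2", "value": self.m2, "pct_VP": np.nan})
        df = pd.DataFrame(rows)
        df.insert(0, "subset", self.subset)
        df.insert(0, "variant", self.variant)
        df.insert(0, "trait", self.trait)
        return df


def summary_from_components(
    components: Mapping[str, float],
    trait: str = "",
    variant: str = "with_block",
    subset: str = "all",
    slopes: Mapping | None = None,
) -> QGSummary:
    """Build a :class:`QGSummary` from named components.

    Expects keys ``sire``, ``dam``, ``residual`` and optionally ``block``,
    ``test_day``, ``individual``.  ``block`` enters the h2/m2 denominator
    only for the ``with_block`` variant; ``test_day`` and ``individual``
    never do, but both count in %V_P.
    """
    comp = dict(components)
    vs = comp.get("sire", 0.0)
    vm = comp.get("dam", 0.0)
    vb = comp.get("block", 0.0) if variant == "with_block" else 0.0
    vr = comp["residual"]
    return QGSummary(
        trait=trait,
        variant=variant,
        subset=subset,
        h2=heritability(vs, vm, vb, vr),
        m2=maternal_effect(vs, vm, vb, vr),
        pct_VP=dict(percent_vp_table(comp)),
        components=comp,
        slopes=dict(slopes or {}),
    )


def summarize_fit(fit: FittedModel, trait: str = "", variant: str = "with_block",
                  subset: str = "all") -> QGSummary:
    return summary_from_components(
        fit.components.variances, trait=trait, variant=variant, subset=subset,
        slopes=fit.components.slopes,
    )


def _strip_density(spec: ModelSpec, treatment_col: str) -> ModelSpec:
    """Remove density from the fixed part and any density slope terms."""
    fixed = tuple(
        t for t in spec.fixed if treatment_col not in t.split(":")
    )
    random = []
    for rt in spec.random:
        if rt.slope is not None and treatment_col in rt.slope:
            random.append(RandomTerm(rt.group, name=rt.name or rt.group.split(":")[0]))
        else:
            random.append(rt)
    return ModelSpec(spec.response, fixed, tuple(random), spec.reml,
                     dict(spec.references))


def treatment_specific_components(
    table: pd.DataFrame,
    trait: str,
    spec: ModelSpec,
    treatment_col: str = "treatment",
    variant: str = "with_block",
    **fit_kw,
) -> dict:
    """Refit the intercept-only random structure within each treatment.

    Intended after a significant reaction-norm (G x E) test: density
    fixed terms and density slope terms are removed, and the model is fit
    to the high- and low-density subsets separately.  Returns
    ``{level: (QGSummary, FittedModel)}``.
    """
    sub_spec = _strip_density(spec, treatment_col)
    levels = sorted(pd.unique(table[treatment_col].astype(str)))
    if len(levels) < 2:
        raise ModelError(
            f"treatment-specific refit needs both density subsets; found {levels}"
        )
    out = {}
    for level in levels:
        sub = table[table[treatment_col].astype(str) == level]
        if sub.empty:
            raise ModelError(f"no rows for treatment level {level!r}")
        fit = fit_reml(sub_spec, sub, **fit_kw)
        out[level] = (
            summarize_fit(fit, trait=trait, variant=variant, subset=level),
            fit,
        )
    return out


@dataclass
class BlockSensitivity:
    """Paired with/without-block fits and the confounding diagnosis."""

    with_block: QGSummary
    without_block: QGSummary
    fit_with: FittedModel
    fit_without: FittedModel
    delta_VA: float
    delta_VM: float
    flag: str


def block_sensitivity(
    table: pd.DataFrame,
    trait: str,
    spec: ModelSpec,
    rel_threshold: float = 0.02,
    **fit_kw,
) -> BlockSensitivity:
    """Fit the model with and without the temporal-block intercept and
    diagnose block/family confounding.

    A component is said to *rise* when dropping block increases it by
    more than ``rel_threshold`` of the with-block phenotypic variance.
    Both V_A (= 4 V_S) and V_M rising means block variance was independent
    of family structure ("block_independent"); a rise in only one flags
    the component block was absorbing ("sire_confounded" /
    "dam_confounded"); neither rising means block carried little variance
    ("block_negligible").
    """
    if not any(rt.label == "block" for rt in spec.random):
        raise ModelError("spec has no 'block' random term to drop")
    fit_with = fit_reml(spec, table, **fit_kw)
    fit_without = fit_reml(spec.drop_random("block"), table, **fit_kw)
    s_with = summarize_fit(fit_with, trait=trait, variant="with_block")
    s_without = summarize_fit(fit_without, trait=trait, variant="without_block")

    vp = sum(s_with.components.values())
    d_va = 4.0 * (s_without.components.get("sire", 0.0) - s_with.components.get("sire", 0.0))
    d_vm = s_without.components.get("dam", 0.0) - s_with.components.get("dam", 0.0)
    thr = rel_threshold * vp
    rise_a, rise_m = d_va > thr, d_vm > thr
    if rise_a and rise_m:
        flag = "block_independent"
    elif rise_a:
        flag = "sire_confounded"
    elif rise_m:
        flag = "dam_confounded"
    else:
        flag = "block_negligible"
    return BlockSensitivity(
        with_block=s_with, without_block=s_without,
        fit_with=fit_with, fit_without=fit_without,
        delta_VA=float(d_va), delta_VM=float(d_vm), flag=flag,
    )
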