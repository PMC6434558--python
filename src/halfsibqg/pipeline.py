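"""End-to-end analysis orchestration and the simulation/recovery harness.

`run_full_analysis` drives the whole per-trait workflow on a phenotype
table (loaded from CSV or freshly simulated): with/without-block fits and
their confounding diagnosis, the reaction-norm G x E test with
treatment-specific components when it rejects, h2/m2/%V_P summaries, a
case bootstrap of the fixed effects, and — for repeated per-minute data —
the three-way random-structure comparison.  All artifacts are delimited
text plus a JSON manifest embedding the seed and settings, so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as _design
from . import simulate as _simulate
from .inference import bootstrap_fixed, compare_activity_models, gxe_test
from .lmm import ModelError, ModelSpec, RandomTerm, fit_reml
from .summaries import (
    block_sensitivity,
    summarize_fit,
    treatment_specific_components,
)
from .traits import add_standard_columns

log = logging.getLogger("halfsibqg")

REQUIRED_COLUMNS = ("individual", "sire", "dam", "block", "treatment", "sex")


class SchemaError(ValueError):
    """Aggregated input-table schema violations."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def validate_schema(table: pd.DataFrame, traits=(), repeated: bool = False) -> None:
    """Check the long-format phenotype table; list every problem at once."""
    problems = []
    for c in REQUIRED_COLUMNS:
        if c not in table.columns:
            problems.append(f"missing required column {c!r}")
    for t in traits:
        if t not in table.columns:
            problems.append(f"missing trait column {t!r}")
    if repeated and "minute" not in table.columns:
        problems.append("repeated-measures table needs a 'minute' column")
    if "treatment" in table.columns:
        bad = set(map(str, pd.unique(table["treatment"].dropna()))) - {"high", "low"}
        if bad:
            problems.append(f"unknown treatment levels {sorted(bad)}")
    if problems:
        raise SchemaError(problems)


@dataclass
class TraitAnalysisSpec:
    """Per-trait analysis settings."""

    name: str
    fixed: tuple = ("treatment", "sex", "treatment:sex")
    include_test_day: bool = False
    repeated: bool = False


@dataclass
class AnalysisConfig:
    seed: int
    output_dir: str
    input_csv: str | None = None
    simulate: dict = field(default_factory=dict)
    traits: list = field(default_factory=list)
    bootstrap_replicates: int = 10_000
    alpha: float = 0.05
    fit_options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.seed is None:
            raise ModelError("a seed is mandatory for any stochastic step")
        if not 0.0 < self.alpha < 1.0:
            raise ModelError("alpha must be in (0, 1)")
        self.traits = [
            t if isinstance(t, TraitAnalysisSpec) else TraitAnalysisSpec(**t)
            for t in self.traits
        ]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _model_from_dict(cls, d):
    return cls(**d)


def simulate_from_config(cfg: dict, seed: int):
    """Build the design and phenotype tables described by a config block.

    Keys: ``design`` (build_pedigree kwargs or ``paper_scale: true``),
    ``traits`` (name -> TraitModel kwargs), ``latency`` (TraitModel kwargs
    + ``cap_s``), ``repeated`` (RepeatedModel kwargs).
    """
    dcfg = dict(cfg.get("design", {"paper_scale": True}))
    if dcfg.pop("paper_scale", False):
        des = _design.paper_scale_design(seed=seed, **dcfg)
    else:
        for k in ("sires_per_block", "dams_per_sire"):
            if isinstance(dcfg.get(k), list) and len(dcfg[k]) == 2:
                dcfg[k] = tuple(dcfg[k])
        des = _design.build_pedigree(seed=seed, **dcfg)

    table = des.to_frame()
    truth = {}
    sub = seed
    for name, mk in cfg.get("traits", {}).items():
        sub += 1
        sim = _simulate.simulate_trait(des, _model_from_dict(_simulate.TraitModel, mk),
                                       seed=sub, trait_name=name)
        table = table.merge(
            sim.data[["individual", "test_day", "days_after_eclosion", name]]
            if "test_day" not in table.columns
            else sim.data[["individual", name]],
            on="individual",
        )
        truth[name] = sim.truth
    if "latency" in cfg:
        sub += 1
        lk = dict(cfg["latency"])
        cap = lk.pop("cap_s", 1800.0)
        sim = _simulate.simulate_latency(des, _model_from_dict(_simulate.TraitModel, lk),
                                         cap_s=cap, seed=sub)
        cols = ["individual", "latency_s", "censored"]
        if "test_day" not in table.columns:
            cols = ["individual", "test_day", "days_after_eclosion", "latency_s", "censored"]
        table = table.merge(sim.data[cols], on="individual")
        truth["latency"] = sim.truth
    repeated = None
    if "repeated" in cfg:
        sub += 1
        sim = _simulate.simulate_repeated_activity(
            des, _model_from_dict(_simulate.RepeatedModel, cfg["repeated"]), seed=sub
        )
        repeated = sim.data
        truth["repeated"] = sim.truth
    return des, table, repeated, truth


def _base_spec(tspec: TraitAnalysisSpec) -> ModelSpec:
    random = [
        RandomTerm("sire:block", name="sire"),
        RandomTerm("dam:sire", name="dam"),
        RandomTerm("block"),
    ]
    if tspec.include_test_day:
        random.append(RandomTerm("test_day"))
    return ModelSpec(tspec.name, tspec.fixed, tuple(random))


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the complete per-trait workflow; returns the manifest dict."""
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fit_kw = dict(config.fit_options)

    if config.input_csv:
        table = pd.read_csv(config.input_csv)
        repeated = None
    else:
        _, table, repeated, _ = simulate_from_config(config.simulate, config.seed)
    validate_schema(table, traits=[t.name for t in config.traits if not t.repeated])
    table = add_standard_columns(table)

    manifest = {
        "seed": config.seed,
        "alpha": config.alpha,
        "bootstrap_replicates": config.bootstrap_replicates,
        "n_rows": int(len(table)),
        "traits": {},
        "files": [],
    }

    def _write(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=True, float_format="%.10g")
        manifest["files"].append(name)

    summaries = []
    for tspec in config.traits:
        t0 = time.time()
        tname = tspec.name
        log.info("analyzing trait %s", tname)
        entry = {}
        if tspec.repeated:
            if repeated is None:
                raise ModelError("repeated-measures trait requested but no long table")
            long = add_standard_columns(repeated)
            validate_schema(long, traits=[tname], repeated=True)
            cmp_res = compare_activity_models(long, tname, alpha=config.alpha, **fit_kw)
            entry["selected_model"] = cmp_res.selected
            entry["aic"] = cmp_res.aic
            entry["lrt_p"] = {k: v.p for k, v in cmp_res.lrts.items()}
            best = cmp_res.fits[cmp_res.selected]
            qg = summarize_fit(best, trait=tname)
            summaries.append(qg.as_frame())
            _write(best.fixed_estimates, f"{tname}_fixed_effects.csv")
        else:
            spec = _base_spec(tspec)
            sens = block_sensitivity(table, tname, spec, **fit_kw)
            entry["block_flag"] = sens.flag
            summaries.append(sens.with_block.as_frame())
            summaries.append(sens.without_block.as_frame())

            gxe = gxe_test(
                table, tname, fixed=tspec.fixed,
                extra_random=("dam:sire", "block") + (("test_day",) if tspec.include_test_day else ()),
                **fit_kw,
            )
            entry["gxe"] = {
                "chi2": gxe.lrt.chi2, "df": gxe.lrt.df, "p": gxe.lrt.p,
                "slope_variance": gxe.slope_variance,
                "intercept_slope_corr": gxe.intercept_slope_corr,
            }
            if gxe.lrt.p < config.alpha:
                per_trt = treatment_specific_components(table, tname, spec, **fit_kw)
                for level, (qg, _) in per_trt.items():
                    summaries.append(qg.as_frame())

            if config.bootstrap_replicates:
                boots = bootstrap_fixed(
                    table, spec, n_replicates=config.bootstrap_replicates,
                    seed=config.seed + 1000,
                )
                bdf = pd.DataFrame(
                    {k: dataclasses.asdict(v) for k, v in boots.items()}
                ).T
                _write(bdf, f"{tname}_fixed_effects.csv")
            else:
                _write(sens.fit_with.fixed_estimates, f"{tname}_fixed_effects.csv")
        entry["seconds"] = round(time.time() - t0, 3)
        manifest["traits"][tname] = entry

    if summaries:
        _write(pd.concat(summaries, ignore_index=True), "variance_components.csv")

    manifest["seconds_total"] = round(time.time() - t_start, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    manifest["files"].append("manifest.json")
    return manifest


def recovery_harness(
    truth: _simulate.TraitModel,
    n_replicates: int = 50,
    seed: int = 0,
    design_kwargs: dict | None = None,
    fixed: tuple = ("treatment", "sex", "treatment:sex"),
    **fit_kw,
) -> pd.DataFrame:
    """Simulate -> fit -> summarize loop for parameter recovery.

    Each replicate draws a fresh paper-scale design (or one from
    ``design_kwargs``) and phenotypes from ``truth``, fits the standard
    with-block model, and records variance components and fixed effects.
    Returns one row per parameter with truth, mean estimate, bias, RMSE,
    and (for fixed effects) Wald 95% coverage.
    """
    if n_replicates < 2:
        raise ModelError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    random = (
        RandomTerm("sire:block", name="sire"),
        RandomTerm("dam:sire", name="dam"),
        RandomTerm("block"),
    )
    if truth.V_testday > 0:
        random = random + (RandomTerm("test_day"),)
    spec = ModelSpec("y", fixed, random)

    truth_map = {
        "sire": truth.V_S, "dam": truth.V_M, "block": truth.V_block,
        "test_day": truth.V_testday, "residual": truth.V_R,
        "Intercept": truth.mu, "treatment[low]": truth.beta_density,
        "sex[M]": truth.beta_sex, "treatment[low]:sex[M]": truth.beta_density_sex,
    }
    rows = []
    n_failed = 0
    for _ in range(n_replicates):
        s = int(rng.integers(0, 2**31 - 1))
        des = (_design.paper_scale_design(seed=s)
               if not design_kwargs else _design.build_pedigree(seed=s, **design_kwargs))
        sim = _simulate.simulate_trait(des, truth, seed=s + 1)
        try:
            fit = fit_reml(spec, sim.data, **fit_kw)
        except ModelError:
            n_failed += 1
            continue
        rec = dict(fit.components.variances)
        for term, r in fit.fixed_estimates.iterrows():
            rec[term] = r["estimate"]
            lo = r["estimate"] - 1.96 * r["se"]
            hi = r["estimate"] + 1.96 * r["se"]
            rec[f"_cover_{term}"] = float(lo <= truth_map.get(term, np.nan) <= hi)
        rows.append(rec)
    if not rows:
        raise ModelError("all recovery replicates failed")
    est = pd.DataFrame(rows)

    out = []
    for name, tv in truth_map.items():
        if name not in est.columns:
            continue
        e = est[name].to_numpy()
        row = {
            "parameter": name, "truth": tv, "mean": e.mean(),
            "bias": e.mean() - tv, "rmse": float(np.sqrt(np.mean((e - tv) ** 2))),
            "mc_se": e.std(ddof=1) / np.sqrt(len(e)),
        }
        cov = f"_cover_{name}"
        row["coverage"] = est[cov].mean() if cov in est.columns else np.nan
        out.append(row)
    res = pd.DataFrame(out).set_index("parameter")
    res.attrs["n_replicates"] = n_replicates
    res.attrs["n_failed"] = n_failed
    res.attrs["seed"] = seed
    return res
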