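import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize as sopt

from halfsibqg import (
    FittedModel,
    ModelError,
    ModelSpec,
    RandomTerm,
    TraitModel,
    VarianceComponents,
    build_design,
    fit_ml,
    fit_reml,
    information_criteria,
    simulate_trait,
)
from conftest import STANDARD_RANDOM, balanced_nested, balanced_oneway, nested_anova_ems


# ---------------------------------------------------------------------------
# design-matrix construction


class TestBuildDesign:
    def test_intercept_only_plus_grouping(self, mass_table):
        spec = ModelSpec("y", (), (RandomTerm("sire"),))
        dm = build_design(spec, mass_table)
        assert dm.X.shape[1] == 1 and dm.x_names == ["Intercept"]
        (rt, codes, g, slope) = dm.terms[0]
        assert g == mass_table["sire"].nunique()
        assert slope is None

    def test_binary_interaction_gives_four_columns(self, mass_table):
        spec = ModelSpec("y", ("treatment", "sex", "treatment:sex"), (RandomTerm("sire"),))
        dm = build_design(spec, mass_table)
        assert dm.x_names == ["Intercept", "treatment[low]", "sex[M]",
                              "treatment[low]:sex[M]"]

    def test_reference_levels_are_high_density_and_female(self, mass_table):
        spec = ModelSpec("y", ("treatment", "sex"), (RandomTerm("sire"),))
        dm = build_design(spec, mass_table)
        # reference rows (high, F) have all-zero dummies
        assert "treatment[low]" in dm.x_names and "sex[M]" in dm.x_names

    def test_slope_term_structure(self, mass_table):
        tab = mass_table.copy()
        tab["low"] = (tab.treatment == "low").astype(float)
        spec = ModelSpec("y", (), (RandomTerm("sire", slope="low"),))
        dm = build_design(spec, mass_table.assign(low=tab["low"]))
        (rt, codes, g, slope) = dm.terms[0]
        assert slope is not None and len(slope) == len(dm.y)

    def test_nesting_by_composite_labels(self, mass_table):
        spec = ModelSpec("y", (), (RandomTerm("dam:sire"),))
        dm = build_design(spec, mass_table)
        assert dm.terms[0][2] == mass_table["dam"].nunique()

    def test_missing_column_and_rank_deficiency(self, mass_table):
        with pytest.raises(ModelError, match="missing columns"):
            build_design(ModelSpec("y", ("nope",), (RandomTerm("sire"),)), mass_table)
        bad = mass_table.assign(dup=lambda t: (t.treatment == "low").astype(float))
        with pytest.raises(ModelError, match="rank-deficient"):
            build_design(ModelSpec("y", ("treatment", "dup"), (RandomTerm("sire"),)), bad)

    def test_rows_with_missing_values_dropped(self, mass_table):
        tab = mass_table.copy()
        tab.loc[tab.index[:5], "y"] = np.nan
        dm = build_design(ModelSpec("y", ("treatment",), (RandomTerm("sire"),)), tab)
        assert dm.n_dropped == 5
        assert len(dm.y) == len(tab) - 5


# ---------------------------------------------------------------------------
# REML/ML against independent oracles


def _dense_neg2ll(v, Zs, X, y, reml):
    """Brute-force likelihood via the dense n x n covariance matrix."""
    n, p = X.shape
    V = v[-1] * np.eye(n)
    for vk, Z in zip(v[:-1], Zs):
        V += vk * (Z @ Z.T)
    sign, logdetV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = r @ Vi @ r
    val = n * np.log(2 * np.pi) + logdetV + quad
    if reml:
        s2, logdetX = np.linalg.slogdet(XtViX)
        val += logdetX - p * np.log(2 * np.pi)
    return val


def _dense_oracle_fit(df, reml):
    groups = pd.get_dummies(df["grp"]).to_numpy(float)
    X = np.ones((len(df), 1))
    y = df["y"].to_numpy()
    res = sopt.minimize(
        lambda lv: _dense_neg2ll(np.exp(lv), [groups], X, y, reml),
        np.log([1.0, 1.0]), method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-12, maxiter=2000),
    )
    return np.exp(res.x), -0.5 * res.fun


class TestAgainstOracles:
    def test_oneway_reml_equals_ems(self):
        """Balanced one-way REML equals (MSB - MSW)/n for the between
        component when interior."""
        df = balanced_oneway()
        g, nper = 12, 8
        fit = fit_reml(ModelSpec("y", (), (RandomTerm("grp"),)), df)
        gm = df.groupby("grp")["y"].mean()
        msb = nper * gm.var(ddof=1)
        msw = ((df.y - df.grp.map(gm)) ** 2).sum() / (g * (nper - 1))
        ems_between = (msb - msw) / nper
        assert fit.components["grp"] == pytest.approx(ems_between, rel=1e-6)
        assert fit.components["residual"] == pytest.approx(msw, rel=1e-6)

    def test_oneway_reml_matches_dense_brute_force(self):
        df = balanced_oneway(g=6, n_per=4, seed=3)
        fit = fit_reml(ModelSpec("y", (), (RandomTerm("grp"),)), df)
        v_oracle, ll_oracle = _dense_oracle_fit(df, reml=True)
        assert fit.components["grp"] == pytest.approx(v_oracle[0], rel=1e-5)
        assert fit.components["residual"] == pytest.approx(v_oracle[1], rel=1e-5)
        assert fit.loglik == pytest.approx(ll_oracle, abs=1e-6)

    def test_oneway_ml_matches_closed_form_and_dense(self):
        """Balanced one-way ML between-group component equals
        ((1 - 1/g) MSB - MSW)/n, the REML estimator shrunk by the known
        ML bias factor on the between mean square."""
        df = balanced_oneway(g=10, n_per=6, seed=5)
        g, nper = 10, 6
        fit = fit_ml(ModelSpec("y", (), (RandomTerm("grp"),)), df)
        gm = df.groupby("grp")["y"].mean()
        msb = nper * gm.var(ddof=1)
        msw = ((df.y - df.grp.map(gm)) ** 2).sum() / (g * (nper - 1))
        ml_between = ((1 - 1 / g) * msb - msw) / nper
        assert fit.components["grp"] == pytest.approx(ml_between, rel=1e-5)
        v_oracle, ll_oracle = _dense_oracle_fit(df, reml=False)
        assert fit.components["grp"] == pytest.approx(v_oracle[0], rel=1e-5)
        assert fit.loglik == pytest.approx(ll_oracle, abs=1e-6)

    def test_nested_sire_dam_matches_henderson_ems(self):
        """Balanced nested sire/dam REML equals the Henderson/EMS
        estimators when all components are interior."""
        df = balanced_nested(s=10, d_per=2, k=5)
        spec = ModelSpec("y", (), (RandomTerm("sire"), RandomTerm("dam:sire", name="dam")))
        fit = fit_reml(spec, df)
        ems_s, ems_d, ems_r = nested_anova_ems(df)
        assert min(ems_s, ems_d) > 0  # interior case required for equality
        assert fit.components["sire"] == pytest.approx(ems_s, rel=1e-6)
        assert fit.components["dam"] == pytest.approx(ems_d, rel=1e-6)
        assert fit.components["residual"] == pytest.approx(ems_r, rel=1e-6)

    def test_zero_sire_variance_goes_to_boundary(self):
        """With no true sire variance the sire component estimate is
        consistent for the zero boundary at large n."""
        from halfsibqg import build_pedigree

        d = build_pedigree(n_blocks=2, sires_per_block=30, dams_per_sire=2,
                           offspring_per_dam_per_treatment=10, seed=1)
        m = TraitModel(mu=1.0, V_S=0.0, V_M=0.0, V_block=0.0, V_R=1.0)
        big = simulate_trait(d, m, seed=30).data
        fit = fit_reml(ModelSpec("y", (), (RandomTerm("sire"),)), big)
        assert fit.components["sire"] <= 0.02
        # exact zero report carries a boundary flag
        if fit.components["sire"] == 0.0:
            assert "sire" in fit.components.boundary


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
class TestLme4CrossCheck:
    """One structured dataset cross-checked against lme4 as an
    independent REML implementation."""

    def test_full_reaction_norm_model_matches_lme4(self, tmp_path, paper_design):
        m = TraitModel(mu=5, beta_density=0.4, beta_sex=-0.3, beta_density_sex=0.1,
                       V_S=1.0, V_M=0.8, V_block=1.5, V_testday=0.3, V_R=4.0,
                       V_slope=0.8, r_is=-0.4)
        tab = simulate_trait(paper_design, m, seed=11).data
        csv = tmp_path / "dat.csv"
        tab.to_csv(csv, index=False)
        rfile = tmp_path / "fit.R"
        rfile.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
d$low <- as.numeric(d$treatment=="low")
d$sireb <- interaction(d$sire, d$block)
d$damsire <- interaction(d$dam, d$sire)
fit <- lmer(y ~ treatment + sex + treatment:sex + (1+low|sireb) + (1|damsire)
            + (1|block) + (1|test_day), data=d, REML=TRUE,
            control=lmerControl(optimizer="bobyqa"))
vc <- as.data.frame(VarCorr(fit))
write.csv(vc, "{tmp_path}/vc.csv", row.names=FALSE)
write.csv(data.frame(term=names(fixef(fit)), est=fixef(fit)),
          "{tmp_path}/fe.csv", row.names=FALSE)
cat(sprintf("%.6f", as.numeric(logLik(fit))), file="{tmp_path}/ll.txt")
""")
        subprocess.run(["Rscript", str(rfile)], check=True, capture_output=True)
        vc = pd.read_csv(tmp_path / "vc.csv")
        fe = pd.read_csv(tmp_path / "fe.csv")
        ll = float((tmp_path / "ll.txt").read_text())

        spec = ModelSpec(
            "y", ("treatment", "sex", "treatment:sex"),
            (RandomTerm("sire:block", slope="_low", name="sire"),
             RandomTerm("dam:sire", name="dam"),
             RandomTerm("block"), RandomTerm("test_day")),
        )
        tab["_low"] = (tab.treatment == "low").astype(float)
        fit = fit_reml(spec, tab)

        def r_var(grp, var1=None):
            sel = vc[(vc.grp == grp) & (vc.var2.isna())]
            if var1 is not None:
                sel = sel[sel.var1 == var1]
            return float(sel.vcov.iloc[0])

        assert fit.components["dam"] == pytest.approx(r_var("damsire"), rel=1e-3)
        assert fit.components["block"] == pytest.approx(r_var("block"), rel=1e-3)
        assert fit.components["test_day"] == pytest.approx(r_var("test_day"), rel=1e-3)
        assert fit.components["sire"] == pytest.approx(r_var("sireb", "(Intercept)"), rel=1e-3)
        v_slope, r_is = fit.components.slopes["sire"]
        assert v_slope == pytest.approx(r_var("sireb", "low"), rel=1e-3)
        r_lme4 = float(vc[(vc.grp == "sireb") & (vc.var2 == "low")].sdcor.iloc[0])
        assert r_is == pytest.approx(r_lme4, abs=1e-3)
        assert fit.components["residual"] == pytest.approx(
            float(vc[vc.grp == "Residual"].vcov.iloc[0]), rel=1e-3
        )
        ours = fit.fixed_estimates["estimate"]
        assert ours["Intercept"] == pytest.approx(
            float(fe.set_index("term").loc["(Intercept)", "est"]), abs=1e-4)
        assert ours["treatment[low]"] == pytest.approx(
            float(fe.set_index("term").loc["treatmentlow", "est"]), abs=1e-4)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)


# ---------------------------------------------------------------------------
# structural invariants


class TestInvariances:
    def test_row_order_and_relabeling_invariance(self, mass_table, standard_spec):
        base = fit_reml(standard_spec, mass_table, accuracy="medium", n_starts=1)
        rng = np.random.default_rng(0)
        shuffled = mass_table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.assign(
            sire=shuffled.sire.map(lambda s: f"S_{hash(s) % 997}_{s}"),
            block=shuffled.block.map(lambda b: b.upper()),
        )
        for tab in (shuffled, relabeled):
            fit = fit_reml(standard_spec, tab, accuracy="medium", n_starts=1)
            for k, v in base.components.variances.items():
                assert fit.components[k] == pytest.approx(v, rel=1e-4, abs=1e-10)
            assert fit.loglik == pytest.approx(base.loglik, abs=1e-6)

    def test_nesting_monotonicity_of_restricted_loglik(self, mass_table, standard_spec):
        """Adding a random term can only increase the restricted
        log-likelihood at the optimum."""
        full = fit_reml(standard_spec, mass_table)
        reduced = fit_reml(standard_spec.drop_random("block"), mass_table)
        assert full.loglik >= reduced.loglik - 1e-6
        smaller = fit_reml(
            ModelSpec("y", standard_spec.fixed, (RandomTerm("dam:sire", name="dam"),)),
            mass_table,
        )
        assert reduced.loglik >= smaller.loglik - 1e-6

    def test_identical_refit_reproduces_loglik(self, mass_table, standard_spec):
        a = fit_reml(standard_spec, mass_table)
        b = fit_reml(standard_spec, mass_table)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.theta, b.theta)


# ---------------------------------------------------------------------------
# information criteria


class TestInformationCriteria:
    def test_formula(self):
        stub = FittedModel(
            spec=ModelSpec("y", (), (RandomTerm("g"),)),
            components=VarianceComponents({"g": 1.0, "residual": 1.0}),
            fixed_estimates=pd.DataFrame({"estimate": [0.0], "se": [1.0]},
                                         index=["Intercept"]),
            loglik=-10.0, converged=True, n_obs=50, n_dropped=0,
            n_groups={"g": 5}, sigma2=1.0, theta=np.zeros(1), reml=True,
        )
        ic = information_criteria(stub)
        assert ic["k"] == 2
        assert ic["aic"] == pytest.approx(24.0)

    def test_extra_parameter_with_same_loglik_costs_two(self, mass_table, standard_spec):
        full = fit_reml(standard_spec, mass_table)
        ic_full = information_criteria(full)
        assert ic_full["aic"] == pytest.approx(-2 * full.loglik + 2 * ic_full["k"])

    def test_unconverged_fit_rejected(self, mass_table, standard_spec):
        fit = fit_reml(standard_spec, mass_table, accuracy="medium", n_starts=1)
        fit.converged = False
        with pytest.raises(ModelError):
            information_criteria(fit)


def test_too_few_groups_rejected(mass_table):
    tab = mass_table.assign(onegrp="all")
    with pytest.raises(ModelError, match="< 2 levels"):
        fit_reml(ModelSpec("y", (), (RandomTerm("onegrp"),)), tab)
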