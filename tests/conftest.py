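import numpy as np
import pandas as pd
import pytest

from halfsibqg import (
    ModelSpec,
    RandomTerm,
    TraitModel,
    build_pedigree,
    paper_scale_design,
    simulate_trait,
)

# default random structure of the with-block analysis model
STANDARD_RANDOM = (
    RandomTerm("sire:block", name="sire"),
    RandomTerm("dam:sire", name="dam"),
    RandomTerm("block"),
)

SIM_FIT = dict(accuracy="medium", n_starts=1)  # profile for simulation loops


@pytest.fixture(scope="session")
def small_design():
    return build_pedigree(
        n_blocks=3, sires_per_block=2, dams_per_sire=2,
        offspring_per_dam_per_treatment=4, seed=10,
    )


@pytest.fixture(scope="session")
def paper_design():
    return paper_scale_design(seed=1)


@pytest.fixture(scope="session")
def mass_like_model():
    """Generating model shaped like adult mass in mg: moderate sire and
    block variance, small dam variance."""
    return TraitModel(
        mu=727.0, beta_density=50.0, beta_sex=-90.0, beta_density_sex=-20.0,
        V_S=529.0, V_M=689.0, V_block=2298.0, V_R=14422.0,
    )


@pytest.fixture(scope="session")
def mass_table(paper_design, mass_like_model):
    return simulate_trait(paper_design, mass_like_model, seed=21).data


@pytest.fixture(scope="session")
def standard_spec():
    return ModelSpec("y", ("treatment", "sex", "treatment:sex"), STANDARD_RANDOM)


def balanced_oneway(g=12, n_per=8, v_between=2.0, v_within=1.5, seed=42):
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"g{i}" for i in range(g)], n_per)
    u = rng.normal(0, np.sqrt(v_between), g)
    y = np.repeat(u, n_per) + rng.normal(0, np.sqrt(v_within), g * n_per)
    return pd.DataFrame({"grp": groups, "y": y})


def balanced_nested(s=10, d_per=2, k=5, v_s=1.0, v_d=0.8, v_r=2.0, seed=7):
    """Balanced sire/dam nested layout with known generating variances."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(s):
        us = rng.normal(0, np.sqrt(v_s))
        for j in range(d_per):
            ud = rng.normal(0, np.sqrt(v_d))
            for _ in range(k):
                rows.append((f"s{i}", f"s{i}d{j}", us + ud + rng.normal(0, np.sqrt(v_r))))
    return pd.DataFrame(rows, columns=["sire", "dam", "y"])


def nested_anova_ems(df):
    """Henderson/EMS estimators for the balanced sire/dam nested design.

    Returns (sigma2_sire, sigma2_dam, sigma2_resid) from the standard
    expected-mean-squares identities; valid when all estimates interior.
    """
    s = df["sire"].nunique()
    d_per = df.groupby("sire")["dam"].nunique().iloc[0]
    k = len(df) // (s * d_per)
    grand = df["y"].mean()
    sire_means = df.groupby("sire")["y"].mean()
    dam_means = df.groupby(["sire", "dam"])["y"].mean()

    ss_sire = d_per * k * ((sire_means - grand) ** 2).sum()
    ms_sire = ss_sire / (s - 1)
    ss_dam = k * sum(
        (dam_means[sire] - sire_means[sire]).pow(2).sum() for sire in sire_means.index
    )
    ms_dam = ss_dam / (s * (d_per - 1))
    resid = df["y"] - df.set_index(["sire", "dam"]).index.map(dam_means)
    ms_within = (resid**2).sum() / (s * d_per * (k - 1))

    sigma_d = (ms_dam - ms_within) / k
    sigma_s = (ms_sire - ms_dam) / (d_per * k)
    return float(sigma_s), float(sigma_d), float(ms_within)
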