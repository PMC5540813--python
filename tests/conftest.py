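import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160913)


@pytest.fixture(scope="session")
def small_sites():
    """Ten modest synthetic sites, shared across read-only tests."""
    from subasym import SimConfig, generate_multisite

    return generate_multisite(SimConfig(n_sites=10, n_per_site=(80, 250), seed=11))


@pytest.fixture(scope="session")
def small_pedigree():
    """A compact pedigree set with a heritable trait."""
    from subasym import PedigreeSimConfig, generate_pedigrees, kinship_from_pedigree

    cfg = PedigreeSimConfig(n_pedigrees=12, h2=(0.5,), seed=4)
    ped, phen = generate_pedigrees(cfg)
    K = kinship_from_pedigree(ped)
    X = np.column_stack([
        phen["age_years"].to_numpy(),
        (phen["sex"] == "M").to_numpy(float),
        phen["icv_mm3"].to_numpy() / 1e5,
    ])
    return ped, phen, K, X


def toy_summary(**overrides):
    """One summary row with valid defaults, for filter tests."""
    row = dict(
        site_id="s", structure="putamen", contrast="sex",
        freesurfer_version="5.3", n_total=100, n_excluded=0,
        n_male=40, n_female=40, n_left=10, n_right=70,
        median_age=30.0, age_iqr=10.0, n_group1=40, n_group2=40,
        effect=0.0, se=0.01, t=0.0, df=50.0, p=1.0,
        ci_low=-0.02, ci_high=0.02,
    )
    row.update(overrides)
    return row


@pytest.fixture
def make_summary():
    def _make(rows):
        return pd.DataFrame([toy_summary(**r) for r in rows])

    return _make
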