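import numpy as np
import pandas as pd
import pytest

from harmodp import CovariateTable, FeatureMatrix, SyntheticSpec


def make_cov(sites, diagnosis=None, sex=None, age=None, ids=None) -> CovariateTable:
    """Covariate table from per-subject lists, site levels in appearance order."""
    n = len(sites)
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        {
            "subject_id": ids if ids is not None else [f"S{i:03d}" for i in range(n)],
            "site": pd.Categorical(sites, categories=list(pd.unique(pd.Series(sites)))),
            "diagnosis": diagnosis if diagnosis is not None else rng.integers(0, 2, n),
            "sex": sex if sex is not None else rng.integers(0, 2, n),
            "age": age if age is not None else rng.uniform(8, 40, n),
        }
    )
    return CovariateTable(frame=df)


def small_spec(
    seed=0,
    n_sites=4,
    per_site=30,
    n_features=80,
    site_additive_sd=1.0,
    noise_sd=1.0,
    age_effect=0.0,
    delta=None,
):
    """A small hand-rolled multi-site spec for unit tests (no cohort calibration)."""
    rng = np.random.default_rng(seed)
    L, V = n_sites, n_features
    gamma = rng.normal(0, site_additive_sd, (L, V)) if site_additive_sd > 0 else np.zeros((L, V))
    effects = {"age": np.full(V, age_effect), "sex": np.zeros(V), "diagnosis": np.zeros(V)}
    params = pd.DataFrame(
        {
            "age_mean": np.full(L, 20.0),
            "age_sd": np.full(L, 6.0),
            "p_male": np.full(L, 0.5),
            "p_asd": np.full(L, 0.4),
        }
    )
    return SyntheticSpec(
        site_names=[f"site{l}" for l in range(L)],
        subjects_per_site=[per_site] * L,
        n_features=V,
        alpha=np.zeros(V),
        signal_effects=effects,
        site_additive=gamma,
        site_multiplicative=np.ones((L, V)) if delta is None else delta,
        noise_sd=noise_sd,
        site_covariate_params=params,
        pooled_covariate_params={"age_mean": 20.0, "age_sd": 6.0, "p_male": 0.5, "p_asd": 0.4},
        confound_strength=0.0,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_site_cov():
    return make_cov(["A"] * 6 + ["B"] * 6)


def make_fm(values, ids=None, **kw) -> FeatureMatrix:
    values = np.asarray(values, float)
    ids = ids if ids is not None else [f"S{i:03d}" for i in range(values.shape[0])]
    return FeatureMatrix(values=values, subject_ids=ids, **kw)
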