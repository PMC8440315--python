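import numpy as np
import pandas as pd
import pytest

from gsel.genotypes import GRM, GenotypeMatrix, compute_grm, impute_mean
from gsel.gblup import ModelDesign, build_design
from gsel.simulate import SimConfig, simulate_genotypes, simulate_phenotypes


def random_psd_grm(n, rng, n_markers=None):
    """A GRM-like PSD matrix built from random HWE dosages."""
    m = n_markers or 4 * n
    p = rng.uniform(0.1, 0.5, size=m)
    d = rng.binomial(2, p, size=(n, m)).astype(float)
    # drop monomorphic columns
    keep = (d.std(axis=0) > 0) & (d.mean(axis=0) > 0) & (d.mean(axis=0) < 2)
    d = d[:, keep]
    acc = np.array([f"A{i:03d}" for i in range(n)], dtype=object)
    mid = np.array([f"M{j:04d}" for j in range(d.shape[1])], dtype=object)
    return compute_grm(GenotypeMatrix(acc, mid, d))


def random_design(n_all, n_obs_acc, rng, reps=1, h2=0.5, grm=None):
    """Small random single-env design with phenotypes drawn from the model."""
    grm = grm or random_psd_grm(n_all, rng)
    s2u, s2e = h2, 1.0 - h2
    L = np.linalg.cholesky(grm.values + 1e-6 * np.eye(n_all))
    u = np.sqrt(s2u) * (L @ rng.standard_normal(n_all))
    obs = rng.choice(n_all, size=n_obs_acc, replace=False)
    rows = np.repeat(obs, reps)
    y = u[rows] + np.sqrt(s2e) * rng.standard_normal(len(rows))
    X = np.ones((len(rows), 1))
    Z = np.zeros((len(rows), n_all))
    Z[np.arange(len(rows)), rows] = 1.0
    return ModelDesign(y=y, X=X, Z=Z, grm=grm), u


def simulated_dataset(n_pool=300, n_train=200, n_markers=600, h2=0.5, seed=0,
                      n_envs=1, genetic_corr=0.5, n_reps=1, n_qtl=None):
    envs = {f"env{i+1}": h2 for i in range(n_envs)}
    cfg = SimConfig(
        n_pool=n_pool, n_train=n_train, n_markers=n_markers,
        n_qtl=n_qtl if n_qtl is not None else n_markers,
        h2_per_env=envs, genetic_corr=genetic_corr, n_reps=n_reps, seed=seed,
    )
    geno = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(geno, cfg)
    grm = compute_grm(impute_mean(geno))
    return cfg, geno, pheno, truth, grm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_genotypes():
    """4 accessions x 5 markers with one missing call."""
    d = np.array([
        [0, 1, 2, 0, 1],
        [1, 1, 0, 0, 2],
        [2, 0, 1, 1, 0],
        [np.nan, 2, 1, 0, 1],
    ], dtype=float)
    return GenotypeMatrix(
        np.array(["a1", "a2", "a3", "a4"], dtype=object),
        np.array([f"m{j}" for j in range(5)], dtype=object),
        d,
    )


@pytest.fixture
def small_pheno():
    rows = []
    for i, acc in enumerate(["a1", "a2", "a3"]):
        for rep in (1, 2):
            rows.append((acc, "E1", rep, "yield", float(i) + 0.1 * rep))
    return pd.DataFrame(rows, columns=["accession_id", "env_id", "rep",
                                       "trait", "value"])
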