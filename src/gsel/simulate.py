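"""Synthetic genotype pools and multi-environment phenotypes with known truth.

The generator mimics the statistical structure of a gene-bank screening study:
a large genotyped pool, a phenotyped training subset, a handful of site-year
environments with distinct intercepts, configurable per-environment
heritability and cross-environment genetic correlation.

Architecture choices (Gaussian effects at a random QTL subset, independent
markers, equicorrelated effects across environments) are stand-ins: they are
not estimated from any real panel and exist only to give downstream
estimators a ground truth with known properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotypes import GenotypeMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_phenotypes",
           "write_truth_tsv"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic data set. See module docstring."""

    n_pool: int = 500
    n_train: int = 300
    n_markers: int = 1000
    maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 200
    h2_per_env: dict = field(default_factory=lambda: {"env1": 0.5})
    env_intercepts: dict | None = None
    genetic_corr: float = 0.5
    n_reps: int = 1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pool, self.n_train, self.n_markers, self.n_qtl) <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_train > self.n_pool:
            raise ConfigurationError("n_train exceeds n_pool")
        if self.n_qtl > self.n_markers:
            raise ConfigurationError("n_qtl exceeds n_markers")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not self.h2_per_env:
            raise ConfigurationError("h2_per_env must name >=1 environment")
        for env, h2 in self.h2_per_env.items():
            if not (0.0 < h2 < 1.0):
                raise ConfigurationError(f"h2 for {env!r} must be in (0,1)")
        n_env = len(self.h2_per_env)
        if n_env > 1 and not (-1.0 / (n_env - 1) <= self.genetic_corr <= 1.0):
            raise ConfigurationError(
                "genetic_corr outside the PSD range for this many environments")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.env_intercepts is not None:
            if set(self.env_intercepts) != set(self.h2_per_env):
                raise ConfigurationError(
                    "env_intercepts keys must match h2_per_env keys")

    @property
    def envs(self) -> list:
        return list(self.h2_per_env)

    def intercept(self, env) -> float:
        if self.env_intercepts is None:
            return 0.0
        return float(self.env_intercepts[env])


@dataclass
class SimTruth:
    """Ground truth of one simulated phenotype set."""

    marker_effects: dict        # env -> length-m effect vector (zeros off-QTL)
    true_genotypic_values: dict  # env -> length-n_pool centered u_true
    realized_h2: dict           # env -> heritability realized in the draw
    qtl_indices: np.ndarray
    train_accessions: np.ndarray


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw a Hardy–Weinberg genotype pool.

    Each marker's alternate-allele frequency is uniform on ``maf_range``;
    dosages are Binomial(2, p); missingness is uniform at ``missing_rate``.
    """
    rng = _rng(config, 0)
    n, m = config.n_pool, config.n_markers
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(np.float64)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan
    acc = np.array([f"ACC{i:05d}" for i in range(n)], dtype=object)
    mid = np.array([f"M{j:06d}" for j in range(m)], dtype=object)
    return GenotypeMatrix(acc, mid, dosages)


def _effect_matrix(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """QTL-by-environment effects with the configured equicorrelation."""
    n_env = len(config.envs)
    cov = np.full((n_env, n_env), config.genetic_corr, dtype=float)
    np.fill_diagonal(cov, 1.0)
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    z = rng.standard_normal((config.n_qtl, n_env))
    return z @ root


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    truth: SimTruth | None = None,
    accessions=None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw replicated multi-environment phenotypes for a training subset.

    For each environment the record is ``intercept + u_true + e`` with the
    residual variance set from the empirical variance of ``u_true`` over the
    phenotyped subset so that the accession-mean variance ratio equals the
    configured heritability:  ``var_e = n_reps * var_u * (1 - h2) / h2``.

    Pass an existing ``truth`` to phenotype further accessions (e.g. a second
    selection cycle) under the same genetic architecture; ``accessions``
    overrides the random training subset.
    """
    rng = _rng(config, 1)
    d = genotypes.dosages
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), col_mean, d)

    acc_ids = genotypes.accession_ids
    if truth is None:
        qtl = np.sort(rng.choice(genotypes.n_markers, size=config.n_qtl,
                                 replace=False))
        B = _effect_matrix(config, rng)
        marker_effects, u_true = {}, {}
        for e_idx, env in enumerate(config.envs):
            beta = np.zeros(genotypes.n_markers)
            beta[qtl] = B[:, e_idx]
            u = d @ beta
            marker_effects[env] = beta
            u_true[env] = u - u.mean()
    else:
        qtl = truth.qtl_indices
        marker_effects = truth.marker_effects
        u_true = truth.true_genotypic_values

    if accessions is None:
        train = rng.choice(acc_ids, size=config.n_train, replace=False)
    else:
        train = np.asarray(list(accessions), dtype=object)
        unknown = set(train) - set(acc_ids)
        if unknown:
            raise ConfigurationError(
                f"accessions not in genotype pool: {sorted(unknown)[:3]}")
    pos = {a: i for i, a in enumerate(acc_ids)}
    tidx = np.array([pos[a] for a in train], dtype=np.intp)

    records = []
    realized_h2 = {}
    for env in config.envs:
        h2 = config.h2_per_env[env]
        mu = config.intercept(env)
        u_tr = u_true[env][tidx]
        var_u = float(np.var(u_tr, ddof=1))
        var_e = config.n_reps * var_u * (1.0 - h2) / h2
        e = rng.normal(0.0, np.sqrt(var_e), size=(len(train), config.n_reps))
        for r in range(config.n_reps):
            for a_i, acc in enumerate(train):
                records.append((acc, env, r + 1, "trait",
                                mu + u_tr[a_i] + e[a_i, r]))
        resid_mean = e.mean(axis=1)
        realized_h2[env] = var_u / (var_u + float(np.var(resid_mean, ddof=1)))

    pt = pd.DataFrame(records,
                      columns=["accession_id", "env_id", "rep", "trait",
                               "value"])
    out_truth = SimTruth(
        marker_effects=marker_effects,
        true_genotypic_values=u_true,
        realized_h2=realized_h2,
        qtl_indices=qtl,
        train_accessions=train,
    )
    return pt, out_truth


def write_truth_tsv(truth: SimTruth, genotypes: GenotypeMatrix, path) -> None:
    """Persist per-accession true genotypic values, one column per environment."""
    df = pd.DataFrame({"accession_id": genotypes.accession_ids})
    for env, u in truth.true_genotypic_values.items():
        df[f"u_true_{env}"] = u
    df.to_csv(path, sep="\t", index=False)
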