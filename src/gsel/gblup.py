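"""Single-variance-component GBLUP: REML fitting, prediction, scaling, heritability.

Model: ``y = X b + Z u + e`` with ``u ~ N(0, G s2u)`` and ``e ~ N(0, I s2e)``.
The restricted likelihood is profiled down to a one-dimensional search over the
variance ratio ``delta = s2e / s2u`` after a single spectral decomposition of
the projected kernel (EMMA-style), which makes the fit exact and deterministic.

Predicted genotypic values (PGVs) are returned for *every* accession in the
supplied relationship matrix: accessions without phenotype records ("untested")
enter only through G and receive the BLUP conditional mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    DesignError,
    InsufficientDataError,
)
from .genotypes import GRM

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("accession_id", "env_id", "rep", "trait", "value")

_LOG_DELTA_BOUNDS = (np.log(1e-6), np.log(1e6))
_GRID_POINTS = 200


def check_phenotypes(pt: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table.

    Required columns: accession_id, env_id, rep, trait, value. Duplicate
    (accession, env, rep, trait) keys or non-finite values are rejected;
    records with missing value are dropped.
    """
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in pt.columns]
    if missing_cols:
        raise ConfigurationError(f"phenotype table missing columns {missing_cols}")
    pt = pt.dropna(subset=["value"]).copy()
    if not np.isfinite(pt["value"].to_numpy(dtype=float)).all():
        raise ConfigurationError("non-finite phenotype values")
    keys = ["accession_id", "env_id", "rep", "trait"]
    if pt.duplicated(subset=keys).any():
        raise ConfigurationError("duplicate (accession, env, rep, trait) records")
    return pt


def scale_phenotypes(pt: pd.DataFrame, only_multi_env: bool = True) -> pd.DataFrame:
    """Standardise values to mean 0 / variance 1 within each (trait, env) group.

    By default the transformation is applied only to traits observed in more
    than one environment; a trait seen in a single environment is returned on
    its raw scale (single-environment fits use raw values).
    """
    pt = check_phenotypes(pt)
    out = pt.copy()
    for trait, sub in pt.groupby("trait"):
        envs = sub["env_id"].unique()
        if only_multi_env and len(envs) < 2:
            continue
        for env in envs:
            idx = sub.index[sub["env_id"] == env]
            v = out.loc[idx, "value"].to_numpy(dtype=float)
            if len(v) < 2 or np.isclose(v.std(ddof=1), 0.0):
                raise DegenerateInputError(
                    f"zero variance for trait {trait!r} in env {env!r}")
            out.loc[idx, "value"] = (v - v.mean()) / v.std(ddof=1)
    return out


@dataclass
class ModelDesign:
    """Assembled regression design for one GBLUP fit.

    ``grm`` spans every accession to be predicted (tested and untested);
    ``Z`` maps the observation rows onto the GRM accession order.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    grm: GRM
    env_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        self.Z = np.asarray(self.Z, dtype=np.float64)
        n = len(self.y)
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise DesignError("row counts of y, X, Z disagree")
        if self.Z.shape[1] != self.grm.n:
            raise DesignError("Z column count does not match GRM dimension")
        if not np.all(self.Z.sum(axis=1) == 1.0):
            raise DesignError("each record must map to exactly one accession")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise DesignError("fixed-effect design X is rank deficient")

    @property
    def tested(self) -> np.ndarray:
        """Boolean mask over GRM accessions with at least one record."""
        return self.Z.sum(axis=0) > 0


def build_design(
    pt: pd.DataFrame,
    grm: GRM,
    trait: str,
    envs=None,
    scale: str | bool = "auto",
) -> ModelDesign:
    """Build a GBLUP design for one trait from a long phenotype table.

    The fixed-effect design carries one intercept column per environment
    (a single all-ones column when one environment is modelled).
    ``scale="auto"`` standardises per environment iff >1 environment enters
    the fit; pass True/False to force either behaviour.
    """
    pt = check_phenotypes(pt)
    sub = pt[pt["trait"] == trait]
    if envs is not None:
        envs = list(envs)
        sub = sub[sub["env_id"].isin(envs)]
    if sub.empty:
        raise ConfigurationError(f"no records for trait {trait!r}")
    env_labels = sorted(sub["env_id"].unique())

    do_scale = scale if isinstance(scale, bool) else len(env_labels) > 1
    if do_scale:
        sub = scale_phenotypes(sub, only_multi_env=False)

    y = sub["value"].to_numpy(dtype=float)
    X = np.column_stack(
        [(sub["env_id"] == env).to_numpy(dtype=float) for env in env_labels])

    pos = {a: i for i, a in enumerate(grm.accession_ids)}
    unknown = set(sub["accession_id"]) - pos.keys()
    if unknown:
        raise DesignError(
            f"{len(unknown)} phenotyped accession(s) absent from GRM, "
            f"e.g. {sorted(unknown)[:3]}")
    Z = np.zeros((len(sub), grm.n))
    for r, acc in enumerate(sub["accession_id"]):
        Z[r, pos[acc]] = 1.0
    return ModelDesign(y=y, X=X, Z=Z, grm=grm, env_labels=env_labels)


@dataclass
class GBLUPFit:
    """REML estimates and BLUPs from one GBLUP fit."""

    beta: np.ndarray
    sigma2_u: float
    sigma2_e: float
    u_hat: np.ndarray
    reml_loglik: float
    accession_ids: np.ndarray
    tested: np.ndarray

    @property
    def h2_model(self) -> float:
        """Variance-ratio heritability on the record level."""
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "accession_id": self.accession_ids,
            "u_hat": self.u_hat,
            "tested": self.tested,
        })


def _restricted_loglik_terms(y, X, K):
    """Spectral pieces of the restricted likelihood profiled over the scale.

    Returns (df, xi, eta2): kernel eigenvalues of the fixed-effect complement
    and squared rotated responses, so that for delta = s2e/s2u

        lR(delta) = 0.5 * [df*log(df/2pi) - df - df*log(sum eta2/(xi+delta))
                           - sum log(xi+delta)]
    """
    n, p = X.shape
    q, _ = np.linalg.qr(X, mode="complete")
    A = q[:, p:]  # orthonormal basis of the complement of col(X)
    KA = A.T @ K @ A
    KA = 0.5 * (KA + KA.T)
    xi, U = np.linalg.eigh(KA)
    xi = np.clip(xi, 0.0, None)
    eta = U.T @ (A.T @ y)
    return n - p, xi, eta ** 2


def fit_gblup_reml(design: ModelDesign) -> GBLUPFit:
    """Fit GBLUP by REML and return BLUPs for all GRM accessions.

    The variance ratio is found by a coarse log-grid scan followed by bounded
    Brent refinement of the restricted log-likelihood; variance components are
    recovered from the profiled scale.
    """
    y, X, Z, G = design.y, design.X, design.Z, design.grm.values
    ZG = Z @ G
    K = ZG @ Z.T
    K = 0.5 * (K + K.T)

    df, xi, eta2 = _restricted_loglik_terms(y, X, K)
    if df < 1:
        raise DesignError("no residual degrees of freedom")

    def negrl(log_delta: float) -> float:
        denom = xi + np.exp(log_delta)
        s = np.sum(eta2 / denom)
        return -0.5 * (df * np.log(df / (2 * np.pi)) - df
                       - df * np.log(s) - np.sum(np.log(denom)))

    grid = np.linspace(*_LOG_DELTA_BOUNDS, _GRID_POINTS)
    vals = np.array([negrl(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(negrl, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    log_delta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    delta = np.exp(log_delta)

    sigma2_u = float(np.sum(eta2 / (xi + delta)) / df)
    sigma2_e = float(delta * sigma2_u)
    reml_loglik = -negrl(log_delta)

    # GLS fixed effects and BLUPs at the optimum
    V = sigma2_u * K + sigma2_e * np.eye(len(y))
    cf = cho_factor(V, lower=True)
    ViX = cho_solve(cf, X)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    resid = y - X @ beta
    u_hat = sigma2_u * (ZG.T @ cho_solve(cf, resid))

    return GBLUPFit(
        beta=beta,
        sigma2_u=sigma2_u,
        sigma2_e=sigma2_e,
        u_hat=u_hat,
        reml_loglik=float(reml_loglik),
        accession_ids=design.grm.accession_ids.copy(),
        tested=design.tested,
    )


def predict_genotypic_values(fit: GBLUPFit, subset: str = "all") -> dict:
    """Return PGVs keyed by accession for 'tested', 'untested' or 'all'."""
    if subset == "all":
        mask = np.ones(len(fit.u_hat), dtype=bool)
    elif subset == "tested":
        mask = fit.tested
    elif subset == "untested":
        mask = ~fit.tested
    else:
        raise ConfigurationError(
            f"subset must be 'tested', 'untested' or 'all', got {subset!r}")
    return {a: float(v)
            for a, v in zip(fit.accession_ids[mask], fit.u_hat[mask])}


@dataclass
class HeritabilityEstimate:
    """Broad-sense heritability from a replicated single-environment trial."""

    V_g: float
    V_e: float
    R: int
    H2: float


def estimate_heritability(pt: pd.DataFrame, env, trait) -> HeritabilityEstimate:
    """Estimate H2 = Vg / (Vg + Ve/R) from a replicated trial.

    Fits ``y_ij = g_i + r_j + e_ij`` by REML with independent
    (identity-covariance) genotype effects and fixed replicate effects —
    this is the broad-sense model and deliberately involves no marker data.
    """
    pt = check_phenotypes(pt)
    sub = pt[(pt["env_id"] == env) & (pt["trait"] == trait)]
    if sub.empty:
        raise ConfigurationError(f"no records for env {env!r}, trait {trait!r}")
    reps = sorted(sub["rep"].unique())
    R = len(reps)
    if R < 2:
        raise InsufficientDataError(
            f"heritability needs >=2 replicates, found {R}")
    accs = sorted(sub["accession_id"].unique())
    apos = {a: i for i, a in enumerate(accs)}

    y = sub["value"].to_numpy(dtype=float)
    X = np.column_stack([(sub["rep"] == r).to_numpy(dtype=float) for r in reps])
    Z = np.zeros((len(sub), len(accs)))
    for r, acc in enumerate(sub["accession_id"]):
        Z[r, apos[acc]] = 1.0

    identity_grm = GRM(np.array(accs, dtype=object), np.eye(len(accs)))
    design = ModelDesign(y=y, X=X, Z=Z, grm=identity_grm)
    fit = fit_gblup_reml(design)
    V_g, V_e = fit.sigma2_u, fit.sigma2_e
    H2 = V_g / (V_g + V_e / R)
    return HeritabilityEstimate(V_g=float(V_g), V_e=float(V_e), R=R,
                                H2=float(H2))
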