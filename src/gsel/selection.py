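"""Selection criteria and list bookkeeping.

Two criteria are supported: the predicted genotypic value itself (PGV) and the
expected improvement

    EI = (m - M) * Phi(z) + s * phi(z),    z = (m - M) / s,

the expected exceedance of a candidate over the incumbent best *observed*
genotypic value M under the Gaussian predictive distribution. The prediction
SD ``s`` can come from the mixed-model-equation conditional covariance (fast,
frequentist) or from a Gibbs sampler on the Bayesian formulation of the same
model (posterior SD); the two agree closely in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import norm

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    SelectionError,
)
from .gblup import GBLUPFit, ModelDesign
from .genotypes import grm_inverse

__all__ = [
    "expected_improvement", "incumbent_best", "genotypic_sd_mme",
    "gibbs_gblup", "genotypic_sd_mcmc", "PosteriorSamples", "EICandidate",
    "ei_table", "SelectionResult", "rank_and_select", "merge_selections",
    "select_controls_equally_spaced",
]


def expected_improvement(m, s, incumbent):
    """Expected improvement of N(m, s^2) candidates over `incumbent`.

    Vectorised over `m` and `s`; at ``s == 0`` the continuous limit
    ``max(m - incumbent, 0)`` is returned.
    """
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ConfigurationError("prediction SD must be non-negative")
    gap = m - incumbent
    with np.errstate(divide="ignore", invalid="ignore", over="ignore",
                     under="ignore"):
        z = np.where(s > 0, gap / np.where(s > 0, s, 1.0), 0.0)
        ei = np.where(s > 0,
                      gap * norm.cdf(z) + s * norm.pdf(z),
                      np.maximum(gap, 0.0))
    return ei if ei.ndim else float(ei)


def incumbent_best(fit: GBLUPFit) -> float:
    """Maximum estimated genotypic value among tested (observed) accessions."""
    if not fit.tested.any():
        raise SelectionError("no tested accessions to define the incumbent")
    return float(fit.u_hat[fit.tested].max())


def genotypic_sd_mme(fit: GBLUPFit, design: ModelDesign) -> dict:
    """Approximate SDs of the genotypic values from the mixed-model equations.

    ``s = sqrt(diag((Z'Z / s2e + G^-1 / s2u)^-1))`` over the full GRM
    (tested and untested accessions), ignoring fixed-effect uncertainty.
    A 1e-6 ridge is applied to G before inversion if it is near-singular.
    """
    if fit.sigma2_u <= 0 or fit.sigma2_e <= 0:
        raise ConfigurationError("variance components must be positive")
    Ginv = grm_inverse(design.grm)
    ztz = design.Z.T @ design.Z
    C = ztz / fit.sigma2_e + Ginv / fit.sigma2_u
    cf = cho_factor(0.5 * (C + C.T), lower=True)
    Cinv = cho_solve(cf, np.eye(C.shape[0]))
    s = np.sqrt(np.clip(np.diag(Cinv), 0.0, None))
    return {a: float(v) for a, v in zip(design.grm.accession_ids, s)}


@dataclass
class PosteriorSamples:
    """Retained Gibbs draws of the genotypic values (draws x accessions)."""

    u: np.ndarray
    accession_ids: np.ndarray
    sigma2_u: np.ndarray
    sigma2_e: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.u.shape[0]


def gibbs_gblup(
    design: ModelDesign,
    n_iter: int = 6000,
    burn_in: int = 1200,
    thin: int = 5,
    seed: int = 0,
    prior_df: float = 5.0,
) -> PosteriorSamples:
    """Gibbs sampler for the Bayesian GBLUP.

    Flat prior on the fixed effects; ``u | s2u ~ N(0, G s2u)``; scaled
    inverse-chi-square priors (df ``prior_df``) on both variances with scales
    set so each prior mode equals half the sample variance of ``y``. Draws of
    ``u`` are retained every ``thin`` iterations after ``burn_in``; the default
    schedule keeps (6000 - 1200) / 5 = 960 draws.
    """
    if n_iter <= 0 or burn_in < 0 or thin <= 0 or burn_in >= n_iter:
        raise ConfigurationError("invalid iteration schedule")
    rng = np.random.default_rng(seed)
    y, X, Z = design.y, design.X, design.Z
    n_obs, n_all = Z.shape
    p = X.shape[1]

    # rotate u into the eigenbasis of G so the prior precision is diagonal
    w, Q = np.linalg.eigh(design.grm.values)
    if w[0] < 1e-8:
        w = w + 1e-6
    ZQ = Z @ Q
    ZQtZQ = ZQ.T @ ZQ
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    LX = np.linalg.cholesky(XtX_inv)

    vy = float(np.var(y, ddof=1))
    # prior mode nu*S/(nu+2) = vy/2  =>  S = vy*(nu+2)/(2*nu)
    S0 = vy * (prior_df + 2.0) / (2.0 * prior_df)

    def sample_scaled_inv_chi2(df, scale):
        return df * scale / rng.chisquare(df)

    beta = np.linalg.solve(XtX, X.T @ y)
    v = np.zeros(n_all)
    sigma2_u = vy / 2.0
    sigma2_e = vy / 2.0

    keep = []
    keep_s2u, keep_s2e = [], []
    for it in range(1, n_iter + 1):
        # fixed effects
        mean_b = np.linalg.solve(XtX, X.T @ (y - ZQ @ v))
        beta = mean_b + np.sqrt(sigma2_e) * (LX @ rng.standard_normal(p))
        # rotated genotypic values
        r = y - X @ beta
        P = ZQtZQ / sigma2_e + np.diag(1.0 / (w * sigma2_u))
        L = np.linalg.cholesky(P)
        rhs = ZQ.T @ r / sigma2_e
        mean_v = cho_solve((L, True), rhs)
        z = rng.standard_normal(n_all)
        v = mean_v + solve_triangular(L, z, trans="T", lower=True)
        # variances
        ss_u = float(np.sum(v * v / w))
        df_u = prior_df + n_all
        sigma2_u = sample_scaled_inv_chi2(df_u, (prior_df * S0 + ss_u) / df_u)
        e = r - ZQ @ v
        ss_e = float(e @ e)
        df_e = prior_df + n_obs
        sigma2_e = sample_scaled_inv_chi2(df_e, (prior_df * S0 + ss_e) / df_e)

        if it > burn_in and (it - burn_in) % thin == 0:
            keep.append(Q @ v)
            keep_s2u.append(sigma2_u)
            keep_s2e.append(sigma2_e)

    return PosteriorSamples(
        u=np.array(keep),
        accession_ids=design.grm.accession_ids.copy(),
        sigma2_u=np.array(keep_s2u),
        sigma2_e=np.array(keep_s2e),
    )


def genotypic_sd_mcmc(samples: PosteriorSamples) -> dict:
    """Posterior SD of the genotypic value per accession (n-1 denominator)."""
    if samples.n_draws < 2:
        raise InsufficientDataError("need >=2 retained draws for an SD")
    s = samples.u.std(axis=0, ddof=1)
    return {a: float(v) for a, v in zip(samples.accession_ids, s)}


@dataclass
class EICandidate:
    accession_id: str
    m: float
    s: float
    z: float
    ei: float


def ei_table(
    fit: GBLUPFit,
    sd: dict,
    untested_only: bool = True,
) -> pd.DataFrame:
    """Tabulate PGV, SD, z and EI per candidate accession.

    The incumbent M is the maximum estimated genotypic value among tested
    accessions; by default EI rows are produced for untested accessions only.
    """
    M = incumbent_best(fit)
    mask = ~fit.tested if untested_only else np.ones(len(fit.u_hat), bool)
    ids = fit.accession_ids[mask]
    m = fit.u_hat[mask]
    s = np.array([sd[a] for a in ids], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, (m - M) / np.where(s > 0, s, 1.0), 0.0)
    ei = expected_improvement(m, s, M)
    return pd.DataFrame(
        {"accession_id": ids, "pgv": m, "sd": s, "z": z, "ei": ei})


@dataclass
class SelectionResult:
    """Top-k list for one criterion / trait / training-site combination."""

    criterion: str
    source: str
    ranked: list  # [(accession_id, score)] ordered (score desc, id asc)
    k: int

    @property
    def accessions(self) -> list:
        return [a for a, _ in self.ranked]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "accession_id": [a for a, _ in self.ranked],
            "score": [s for _, s in self.ranked],
            "rank": np.arange(1, len(self.ranked) + 1),
            "criterion": self.criterion,
            "source": self.source,
        })


def rank_and_select(
    scores: dict,
    k: int = 20,
    exclude=(),
    criterion: str = "PGV",
    source: str = "",
) -> SelectionResult:
    """Deterministic top-k: descending score, ties broken by ascending id."""
    exclude = set(exclude)
    eligible = [(a, float(v)) for a, v in scores.items() if a not in exclude]
    if k > len(eligible):
        raise SelectionError(
            f"k={k} exceeds {len(eligible)} eligible accessions")
    eligible.sort(key=lambda t: (-t[1], t[0]))
    return SelectionResult(criterion=criterion, source=source,
                           ranked=eligible[:k], k=k)


@dataclass
class MergedSelection:
    """Union of several top-k lists with pairwise overlap accounting."""

    labels: list
    union: list            # sorted accession ids
    overlap: pd.DataFrame  # |L_i ∩ L_j|, labelled square matrix

    @property
    def union_size(self) -> int:
        return len(self.union)


def merge_selections(results) -> MergedSelection:
    results = list(results)
    if len(results) < 2:
        raise SelectionError("merge needs >=2 selection lists")
    labels, sets = [], []
    for r in results:
        label = f"{r.criterion}:{r.source}" if r.source else r.criterion
        if label in labels:  # keep labels unique for the overlap matrix
            label = f"{label}#{labels.count(label) + 1}"
        labels.append(label)
        sets.append(set(r.accessions))
    n = len(sets)
    ov = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            ov[i, j] = len(sets[i] & sets[j])
    union = sorted(set().union(*sets))
    return MergedSelection(
        labels=labels,
        union=union,
        overlap=pd.DataFrame(ov, index=labels, columns=labels),
    )


def select_controls_equally_spaced(estimated_values: dict, n_controls: int) -> list:
    """Pick controls at equal rank spacing across the value distribution.

    Candidates are sorted by estimated genotypic value (ties by id); picked
    ranks are equally spaced and include both the first and the last rank, so
    the selected set spans the full range of values.
    """
    if n_controls < 2:
        raise ConfigurationError("need at least 2 controls to span the range")
    items = sorted(estimated_values.items(), key=lambda t: (t[1], t[0]))
    n = len(items)
    if n_controls > n:
        raise SelectionError(f"n_controls={n_controls} exceeds {n} candidates")
    ranks = np.floor(np.linspace(0, n - 1, n_controls) + 0.5).astype(int)
    return [items[r][0] for r in ranks]
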