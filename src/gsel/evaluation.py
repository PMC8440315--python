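"""Accuracy protocols: repeated k-fold CV, forward validation, correlations.

Accuracy throughout is the Pearson correlation between predicted genotypic
values and observed accession means (replicate means within an environment).
Folds always partition *accessions*, never records, so replicates of one
accession can never straddle the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError
from .gblup import build_design, check_phenotypes, fit_gblup_reml
from .genotypes import GRM

__all__ = [
    "CVResult", "kfold_cv", "ForwardValidationResult", "forward_validation",
    "phenotypic_correlation", "genetic_correlation",
]


def _accession_means(pt: pd.DataFrame, trait, env) -> pd.Series:
    sub = pt[(pt["trait"] == trait) & (pt["env_id"] == env)]
    return sub.groupby("accession_id")["value"].mean()


@dataclass
class CVResult:
    """Mean and SD of repeated k-fold cross-validation accuracy."""

    trait: str
    envs: tuple
    mean_accuracy: float
    sd_accuracy: float
    n_folds: int
    n_repeats: int
    seed: int
    per_repeat: np.ndarray


def kfold_cv(
    pt: pd.DataFrame,
    grm: GRM,
    trait,
    env,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    per_fold: bool = False,
) -> CVResult:
    """Repeated k-fold cross-validation of GBLUP accuracy within one environment.

    Accessions are partitioned at random into k folds; each fold's accessions
    are masked from the fit and their PGVs correlated with the observed
    accession means. By default predictions are pooled over folds and one
    Pearson r computed per repeat (``per_fold=True`` averages fold-level r
    instead); the result is the mean and SD over repeats.
    """
    pt = check_phenotypes(pt)
    sub = pt[(pt["trait"] == trait) & (pt["env_id"] == env)]
    if sub.empty:
        raise ConfigurationError(f"no records for trait {trait!r} in {env!r}")
    observed = _accession_means(sub, trait, env)
    accs = np.array(sorted(observed.index), dtype=object)
    if len(accs) < 2 * k:
        raise InsufficientDataError(
            f"{len(accs)} phenotyped accessions is too few for {k}-fold CV")

    ss = np.random.SeedSequence(seed)
    repeat_rngs = [np.random.default_rng(s) for s in ss.spawn(repeats)]
    per_repeat = []
    for rng in repeat_rngs:
        perm = rng.permutation(len(accs))
        folds = np.array_split(perm, k)
        preds = pd.Series(index=observed.index, dtype=float)
        fold_rs = []
        for fold in folds:
            test_accs = set(accs[fold])
            if len(test_accs) < 3:
                raise InsufficientDataError("fold with fewer than 3 accessions")
            train_records = sub[~sub["accession_id"].isin(test_accs)]
            design = build_design(train_records, grm, trait, envs=[env],
                                  scale=False)
            fit = fit_gblup_reml(design)
            pos = {a: i for i, a in enumerate(fit.accession_ids)}
            for a in test_accs:
                preds[a] = fit.u_hat[pos[a]]
            if per_fold:
                ta = sorted(test_accs)
                fold_rs.append(np.corrcoef(preds[ta], observed[ta])[0, 1])
        if per_fold:
            per_repeat.append(float(np.mean(fold_rs)))
        else:
            per_repeat.append(
                float(np.corrcoef(preds[observed.index],
                                  observed[observed.index])[0, 1]))
    per_repeat = np.array(per_repeat)
    return CVResult(
        trait=trait, envs=(env,),
        mean_accuracy=float(per_repeat.mean()),
        sd_accuracy=float(per_repeat.std(ddof=1)) if repeats > 1 else 0.0,
        n_folds=k, n_repeats=repeats, seed=seed, per_repeat=per_repeat,
    )


@dataclass
class ForwardValidationResult:
    """Accuracy of predicting a later trial from an earlier training set."""

    train_envs: tuple
    test_env: str
    subset: str  # 'repeated' or 'new'
    accuracy: float
    n: int


def forward_validation(
    train_pt: pd.DataFrame,
    test_pt: pd.DataFrame,
    grm: GRM,
    trait,
    repeated_set,
    new_set,
) -> tuple[ForwardValidationResult, ForwardValidationResult]:
    """Train on one period, evaluate correlation with the next, split by novelty.

    ``repeated_set`` are test accessions also present in training;
    ``new_set`` must be disjoint from the training accessions.
    """
    train_pt = check_phenotypes(train_pt)
    test_pt = check_phenotypes(test_pt)
    repeated_set, new_set = set(repeated_set), set(new_set)
    train_accs = set(train_pt.loc[train_pt["trait"] == trait, "accession_id"])
    if new_set & train_accs:
        raise ConfigurationError("new_set overlaps the training accessions")
    if not (repeated_set <= train_accs):
        raise ConfigurationError("repeated_set must be inside training accessions")

    design = build_design(train_pt, grm, trait, scale="auto")
    fit = fit_gblup_reml(design)
    pos = {a: i for i, a in enumerate(fit.accession_ids)}

    test_envs = sorted(test_pt.loc[test_pt["trait"] == trait, "env_id"].unique())
    test_means = (test_pt[test_pt["trait"] == trait]
                  .groupby("accession_id")["value"].mean())

    results = []
    for name, subset in (("repeated", repeated_set), ("new", new_set)):
        accs = sorted(subset & set(test_means.index))
        if len(accs) < 3:
            raise InsufficientDataError(
                f"{name} evaluation subset has {len(accs)} accessions (<3)")
        u = np.array([fit.u_hat[pos[a]] for a in accs])
        r = float(np.corrcoef(u, test_means[accs])[0, 1])
        results.append(ForwardValidationResult(
            train_envs=tuple(design.env_labels),
            test_env=",".join(test_envs),
            subset=name, accuracy=r, n=len(accs)))
    return tuple(results)


def phenotypic_correlation(pt: pd.DataFrame, trait,
                           min_shared: int = 3) -> pd.DataFrame:
    """Pearson r of accession-mean phenotypes for every environment pair.

    Each pair uses only accessions observed in both environments; pairs with
    fewer than `min_shared` shared accessions are reported as NaN.
    """
    pt = check_phenotypes(pt)
    envs = sorted(pt.loc[pt["trait"] == trait, "env_id"].unique())
    means = {e: _accession_means(pt, trait, e) for e in envs}
    out = pd.DataFrame(np.eye(len(envs)), index=envs, columns=envs)
    for i, a in enumerate(envs):
        for b in envs[i + 1:]:
            shared = means[a].index.intersection(means[b].index)
            if len(shared) < min_shared:
                out.loc[a, b] = out.loc[b, a] = np.nan
                continue
            r = float(np.corrcoef(means[a][shared], means[b][shared])[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def genetic_correlation(pt: pd.DataFrame, grm: GRM, trait,
                        min_shared: int = 3) -> pd.DataFrame:
    """Pearson r of per-environment GBLUP genotypic values for env pairs.

    A single-environment intercept-only GBLUP is fitted in each environment
    (raw scale); the correlation is taken over accessions tested in both.
    """
    pt = check_phenotypes(pt)
    envs = sorted(pt.loc[pt["trait"] == trait, "env_id"].unique())
    fits, tested = {}, {}
    for e in envs:
        design = build_design(pt, grm, trait, envs=[e], scale=False)
        fit = fit_gblup_reml(design)
        fits[e] = pd.Series(fit.u_hat, index=fit.accession_ids)
        tested[e] = set(fit.accession_ids[fit.tested])
    out = pd.DataFrame(np.eye(len(envs)), index=envs, columns=envs)
    for i, a in enumerate(envs):
        for b in envs[i + 1:]:
            shared = sorted(tested[a] & tested[b])
            if len(shared) < min_shared:
                out.loc[a, b] = out.loc[b, a] = np.nan
                continue
            r = float(np.corrcoef(fits[a][shared], fits[b][shared])[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out
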