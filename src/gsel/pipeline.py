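"""Configuration-driven orchestration of the full selection workflow, plus CLI.

Stages: genotypes (simulate or read) -> marker filtering -> mean imputation ->
GRM -> per-trait GBLUP fits -> selection criteria (PGV / EI) -> top-k lists,
overlap accounting and equally-spaced controls -> evaluation (CV, correlation
matrices). Every artifact is written to the run directory and recorded in a
manifest with a config hash and per-file checksums; a rerun with the same
config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import evaluation, gblup, genotypes, selection, simulate
from .errors import ConfigurationError, GselError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Declarative description of one run. Exactly one of ``genotypes_path``
    (with ``phenotypes_path``) or ``simulation`` must be given."""

    genotypes_path: str | None = None
    genotypes_format: str = "vcf"
    phenotypes_path: str | None = None
    simulation: dict | None = None
    max_missing: float = 0.05
    min_maf: float = 0.025
    traits: list = field(default_factory=list)
    envs: list | None = None
    criteria: list = field(default_factory=lambda: ["PGV", "EI"])
    k: int = 20
    exclude_tested: bool = True
    n_controls: int = 0
    sd_method: str = "mme"  # or "mcmc"
    cv_folds: int = 10
    cv_repeats: int = 10
    run_cv: bool = False
    cycles: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.genotypes_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ConfigurationError(
                "exactly one of input paths or a simulation block is required")
        if has_paths and self.phenotypes_path is None:
            raise ConfigurationError("phenotypes_path required with genotypes_path")
        if any(c not in ("PGV", "EI") for c in self.criteria):
            raise ConfigurationError("criteria must be a subset of {PGV, EI}")
        if self.sd_method not in ("mme", "mcmc"):
            raise ConfigurationError("sd_method must be 'mme' or 'mcmc'")
        if self.cycles < 1:
            raise ConfigurationError("cycles must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

class _Run:
    """Collects artifacts and manifest entries for one pipeline run."""

    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.config = config
        self.manifest = {
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "seed": config.seed,
            "stages": [],
            "files": {},
        }

    def record(self, stage: str, *paths: Path) -> None:
        if stage not in self.manifest["stages"]:
            self.manifest["stages"].append(stage)
        for p in paths:
            self.manifest["files"][str(p.relative_to(self.out))] = _sha256(p)

    def finish(self) -> Path:
        path = self.out / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, default=str))
        return path


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute all configured stages; returns the run directory."""
    run = _Run(Path(out_dir), config)
    try:
        return _run_stages(run, config)
    except GselError:
        raise
    except Exception as exc:  # pragma: no cover - defensive context wrap
        raise GselError(f"pipeline failed: {exc}") from exc


def _load_inputs(run: _Run, config: PipelineConfig):
    """Stage 1: genotypes + phenotypes, simulated or read from disk."""
    if config.simulation is not None:
        sim_cfg = simulate.SimConfig(**{**config.simulation,
                                        "seed": config.seed})
        geno = simulate.simulate_genotypes(sim_cfg)
        pheno, truth = simulate.simulate_phenotypes(geno, sim_cfg)
        tpath = run.out / "truth.tsv"
        simulate.write_truth_tsv(truth, geno, tpath)
        ppath = run.out / "phenotypes.csv"
        pheno.to_csv(ppath, index=False)
        run.record("simulate", tpath, ppath)
        return geno, pheno, truth, sim_cfg
    geno = genotypes.read_genotypes(config.genotypes_path,
                                    format=config.genotypes_format)
    pheno = gblup.check_phenotypes(pd.read_csv(config.phenotypes_path))
    run.record("load")
    return geno, pheno, None, None


def _run_stages(run: _Run, config: PipelineConfig) -> Path:
    geno, pheno, truth, sim_cfg = _load_inputs(run, config)

    filtered = genotypes.filter_markers(geno, config.max_missing, config.min_maf)
    gpath = run.out / "genotypes_filtered.tsv"
    genotypes.write_dosage_tsv(filtered, gpath)
    run.record("filter", gpath)

    imputed = genotypes.impute_mean(filtered)
    grm = genotypes.compute_grm(imputed)
    grm_path = run.out / "grm.tsv"
    genotypes.write_grm_tsv(grm, grm_path)
    run.record("grm", grm_path)

    traits = config.traits or sorted(pheno["trait"].unique())
    for cycle in range(1, config.cycles + 1):
        tag = f"cycle{cycle}" if config.cycles > 1 else ""
        selected_all = _fit_and_select(run, config, pheno, grm, traits, tag)
        if cycle < config.cycles:
            if truth is None:
                raise ConfigurationError(
                    "multi-cycle runs need simulation mode to phenotype "
                    "newly selected accessions")
            new_pheno, _ = simulate.simulate_phenotypes(
                geno, sim_cfg, truth=truth, accessions=sorted(selected_all))
            pheno = pd.concat([pheno, new_pheno], ignore_index=True)
            sizes = pheno.groupby("trait")["accession_id"].nunique()
            logger.info("cycle %d -> training sizes %s", cycle + 1,
                        sizes.to_dict())

    if config.run_cv:
        _evaluate(run, config, pheno, grm, traits)

    manifest = run.finish()
    return manifest.parent


def _fit_and_select(run, config, pheno, grm, traits, tag=""):
    """Fit per trait, compute criteria, write selection tables; return union."""
    suffix = f"_{tag}" if tag else ""
    selected_union: set = set()
    for trait in traits:
        design = gblup.build_design(pheno, grm, trait, envs=config.envs,
                                    scale="auto")
        fit = gblup.fit_gblup_reml(design)
        fit_path = run.out / f"fit_{trait}{suffix}.json"
        fit_path.write_text(json.dumps({
            "beta": fit.beta.tolist(),
            "sigma2_u": fit.sigma2_u,
            "sigma2_e": fit.sigma2_e,
            "reml_loglik": fit.reml_loglik,
            "envs": design.env_labels,
        }, indent=2))
        u_path = run.out / f"u_hat_{trait}{suffix}.tsv"
        fit.to_frame().to_csv(u_path, sep="\t", index=False)
        run.record(f"fit{suffix}", fit_path, u_path)

        if config.sd_method == "mme":
            sd = selection.genotypic_sd_mme(fit, design)
        else:
            samples = selection.gibbs_gblup(design, seed=config.seed)
            sd = selection.genotypic_sd_mcmc(samples)
        table = selection.ei_table(fit, sd,
                                   untested_only=config.exclude_tested)
        crit_path = run.out / f"criteria_{trait}{suffix}.tsv"
        table.sort_values("accession_id").to_csv(crit_path, sep="\t",
                                                 index=False, float_format="%.10g")
        run.record(f"criteria{suffix}", crit_path)

        exclude = set(fit.accession_ids[fit.tested]) if config.exclude_tested else set()
        results = []
        source = f"{trait}:{'+'.join(design.env_labels)}"
        scores_by_crit = {
            "PGV": dict(zip(table["accession_id"], table["pgv"])),
            "EI": dict(zip(table["accession_id"], table["ei"])),
        }
        for crit in config.criteria:
            res = selection.rank_and_select(
                scores_by_crit[crit], k=config.k, exclude=exclude,
                criterion=crit, source=source)
            results.append(res)
            sel_path = run.out / f"selection_{crit}_{trait}{suffix}.tsv"
            res.to_frame().to_csv(sel_path, sep="\t", index=False,
                                  float_format="%.10g")
            run.record(f"select{suffix}", sel_path)
            selected_union |= set(res.accessions)
        if len(results) >= 2:
            merged = selection.merge_selections(results)
            ov_path = run.out / f"overlap_{trait}{suffix}.tsv"
            merged.overlap.to_csv(ov_path, sep="\t")
            run.record(f"select{suffix}", ov_path)

        if config.n_controls >= 2:
            tested_vals = gblup.predict_genotypic_values(fit, "tested")
            controls = selection.select_controls_equally_spaced(
                tested_vals, config.n_controls)
            c_path = run.out / f"controls_{trait}{suffix}.tsv"
            pd.DataFrame({"accession_id": controls}).to_csv(
                c_path, sep="\t", index=False)
            run.record(f"select{suffix}", c_path)
    return selected_union


def _evaluate(run, config, pheno, grm, traits):
    rows = []
    for trait in traits:
        envs = sorted(pheno.loc[pheno["trait"] == trait, "env_id"].unique())
        for env in envs:
            cv = evaluation.kfold_cv(pheno, grm, trait, env,
                                     k=config.cv_folds,
                                     repeats=config.cv_repeats,
                                     seed=config.seed)
            rows.append({"trait": trait, "env": env, "protocol": "cv",
                         "mean_accuracy": cv.mean_accuracy,
                         "sd_accuracy": cv.sd_accuracy})
        if len(envs) >= 2:
            pc = evaluation.phenotypic_correlation(pheno, trait)
            gc = evaluation.genetic_correlation(pheno, grm, trait)
            pc.to_csv(run.out / f"phenotypic_corr_{trait}.tsv", sep="\t")
            gc.to_csv(run.out / f"genetic_corr_{trait}.tsv", sep="\t")
            run.record("evaluate", run.out / f"phenotypic_corr_{trait}.tsv",
                       run.out / f"genetic_corr_{trait}.tsv")
    ev_path = run.out / "evaluation.tsv"
    pd.DataFrame(rows).to_csv(ev_path, sep="\t", index=False,
                              float_format="%.10g")
    run.record("evaluate", ev_path)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def cli(log_level):
    """Genomic-selection pipeline: simulate, filter, fit, select, evaluate."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")


def _config_opts(f):
    f = click.option("--config", "config_path", required=True,
                     type=click.Path(exists=True))(f)
    f = click.option("--out", "out_dir", required=True, type=click.Path())(f)
    f = click.option("--seed", type=int, default=None,
                     help="override the config seed")(f)
    return f


def _load_config(config_path, seed):
    cfg = PipelineConfig.from_file(config_path)
    if seed is not None:
        cfg.seed = seed
    return cfg


@cli.command("run-all")
@_config_opts
def run_all_cmd(config_path, out_dir, seed):
    """Run every configured stage end to end."""
    out = run_pipeline(_load_config(config_path, seed), out_dir)
    click.echo(f"run complete: {out}")


@cli.command("simulate")
@_config_opts
def simulate_cmd(config_path, out_dir, seed):
    """Write simulated genotypes (VCF + TSV), phenotypes and truth."""
    cfg = _load_config(config_path, seed)
    if cfg.simulation is None:
        raise click.UsageError("config has no simulation block")
    sim_cfg = simulate.SimConfig(**{**cfg.simulation, "seed": cfg.seed})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno = simulate.simulate_genotypes(sim_cfg)
    pheno, truth = simulate.simulate_phenotypes(geno, sim_cfg)
    genotypes.write_vcf(geno, out / "genotypes.vcf")
    genotypes.write_dosage_tsv(geno, out / "genotypes.tsv")
    pheno.to_csv(out / "phenotypes.csv", index=False)
    simulate.write_truth_tsv(truth, geno, out / "truth.tsv")
    click.echo(f"simulated {geno.n_accessions} accessions x "
               f"{geno.n_markers} markers -> {out}")


@cli.command("filter")
@click.option("--genotypes", "geno_path", required=True,
              type=click.Path(exists=True))
@click.option("--format", "geno_format", default="vcf", show_default=True,
              type=click.Choice(["vcf", "dosage-tsv"]))
@click.option("--max-missing", default=0.05, show_default=True)
@click.option("--min-maf", default=0.025, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def filter_cmd(geno_path, geno_format, max_missing, min_maf, out_path):
    """Filter markers on missingness and MAF; write a dosage TSV."""
    g = genotypes.read_genotypes(geno_path, format=geno_format)
    f = genotypes.filter_markers(g, max_missing=max_missing, min_maf=min_maf)
    genotypes.write_dosage_tsv(f, out_path)
    click.echo(f"{f.n_markers} of {g.n_markers} markers retained -> {out_path}")


@cli.command("grm")
@click.option("--genotypes", "geno_path", required=True,
              type=click.Path(exists=True))
@click.option("--format", "geno_format", default="dosage-tsv",
              show_default=True, type=click.Choice(["vcf", "dosage-tsv"]))
@click.option("--out", "out_path", required=True, type=click.Path())
def grm_cmd(geno_path, geno_format, out_path):
    """Mean-impute and compute the VanRaden GRM; write as TSV."""
    g = genotypes.read_genotypes(geno_path, format=geno_format)
    grm = genotypes.compute_grm(genotypes.impute_mean(g))
    genotypes.write_grm_tsv(grm, out_path)
    click.echo(f"GRM for {grm.n} accessions -> {out_path}")


@cli.command("fit")
@click.option("--grm", "grm_path", required=True, type=click.Path(exists=True))
@click.option("--phenotypes", "pheno_path", required=True,
              type=click.Path(exists=True))
@click.option("--trait", required=True)
@click.option("--env", "envs", multiple=True,
              help="restrict to these environments (repeatable)")
@click.option("--out", "out_path", required=True, type=click.Path())
def fit_cmd(grm_path, pheno_path, trait, envs, out_path):
    """Fit GBLUP by REML and write per-accession genotypic values."""
    grm = genotypes.read_grm_tsv(grm_path)
    pheno = pd.read_csv(pheno_path)
    design = gblup.build_design(pheno, grm, trait,
                                envs=list(envs) or None, scale="auto")
    fit = gblup.fit_gblup_reml(design)
    fit.to_frame().to_csv(out_path, sep="\t", index=False)
    click.echo(f"sigma2_u={fit.sigma2_u:.6g} sigma2_e={fit.sigma2_e:.6g} "
               f"logLR={fit.reml_loglik:.6g} -> {out_path}")


@cli.command("criteria")
@_config_opts
def criteria_cmd(config_path, out_dir, seed):
    """Fit and write PGV/EI criteria tables (subset of run-all)."""
    cfg = _load_config(config_path, seed)
    cfg.run_cv = False
    cfg.cycles = 1
    out = run_pipeline(cfg, out_dir)
    click.echo(f"criteria written under {out}")


@cli.command("select")
@click.option("--criteria", "crit_path", required=True,
              type=click.Path(exists=True),
              help="criteria TSV from the criteria/run-all stage")
@click.option("--criterion", default="EI", show_default=True,
              type=click.Choice(["PGV", "EI"]))
@click.option("--k", default=20, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def select_cmd(crit_path, criterion, k, out_path):
    """Top-k selection from a criteria table."""
    table = pd.read_csv(crit_path, sep="\t")
    col = "pgv" if criterion == "PGV" else "ei"
    scores = dict(zip(table["accession_id"], table[col]))
    res = selection.rank_and_select(scores, k=k, criterion=criterion)
    res.to_frame().to_csv(out_path, sep="\t", index=False)
    click.echo(f"top-{k} by {criterion} -> {out_path}")


@cli.command("evaluate")
@_config_opts
def evaluate_cmd(config_path, out_dir, seed):
    """Run the evaluation protocols configured in the pipeline config."""
    cfg = _load_config(config_path, seed)
    cfg.run_cv = True
    out = run_pipeline(cfg, out_dir)
    click.echo(f"evaluation written under {out}")


if __name__ == "__main__":  # pragma: no cover
    cli()
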