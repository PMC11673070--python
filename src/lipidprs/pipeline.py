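"""Experiment orchestration: one config drives QC, PRS-scale construction
across methods/sources/phenotypes/cohorts, evaluation, and the optional
ultrasound screen and split experiment.

A *scale* is one (cohort, source, method, phenotype) combination. Sources
tagged without full summary statistics are eligible for classical scoring
only; C+T and shrinkage require complete summary statistics. With the
reference configuration (3 classical sources, of which 2 carry full summary
statistics, 4 lipid phenotypes) this enumerates 28 scales per cohort.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import io as gio
from . import qc as qcmod
from .containers import GenotypeMatrix, SummaryStats
from .ct import ClumpThresholdPRS, CTGrid, default_p_thresholds, split_4to1
from .scoring import PRSCalculator, compute_prs
from .shrinkage import ShrinkagePRS, build_ld_reference
from .simulate import (
    LDBlockSpec,
    TraitSpec,
    UltrasoundSpec,
    default_lipid_traits,
    draw_effect_sizes,
    simulate_base_gwas,
    simulate_genotypes,
    simulate_lipid_phenotypes,
    simulate_ultrasound,
)
from .splits import run_split_experiment

log = logging.getLogger("lipidprs")

METHODS = ("classical", "ct", "shrinkage")
FULL_STATS_METHODS = ("ct", "shrinkage")


class ConfigError(ValueError):
    """The experiment configuration is invalid."""


def child_seed(master: int, *tags) -> int:
    """Deterministic child seed below 2**31 derived from a master seed and tags."""
    h = zlib.crc32("/".join(str(t) for t in tags).encode())
    return int((master * 1_000_003 + h) % (2**31))


@dataclass
class SourceConfig:
    """One base study providing variant weights and (optionally) full summary stats."""

    name: str
    full_sumstats: bool = True
    n_lead_variants: int = 100
    panel_fraction: float = 1.0  # fraction of panel variants the study reports
    n_gwas: int = 100_000
    methods: tuple[str, ...] | None = None  # explicit eligibility override

    def eligible_methods(self, requested: tuple[str, ...]) -> tuple[str, ...]:
        if self.methods is not None:
            for m in self.methods:
                if m in FULL_STATS_METHODS and not self.full_sumstats:
                    raise ConfigError(
                        f"source {self.name!r} is marked eligible for {m!r} "
                        "but provides no full summary statistics"
                    )
            allowed = self.methods
        else:
            allowed = METHODS if self.full_sumstats else ("classical",)
        return tuple(m for m in requested if m in allowed)


@dataclass
class CohortConfig:
    """A cohort: either synthetic generation settings or paths to real files."""

    name: str
    n_samples: int = 1000
    n_blocks: int = 100
    variants_per_block: int = 10
    within_block_r: float = 0.5
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.0
    genotypes_path: str | None = None
    phenotypes_path: str | None = None

    def block_spec(self) -> LDBlockSpec:
        return LDBlockSpec(
            n_blocks=self.n_blocks,
            variants_per_block=self.variants_per_block,
            within_block_r=self.within_block_r,
            maf_range=(self.maf_low, self.maf_high),
            missing_rate=self.missing_rate,
        )


@dataclass
class ExperimentConfig:
    seed: int
    cohorts: list[CohortConfig]
    sources: list[SourceConfig]
    phenotypes: tuple[str, ...] = ("hdl", "ldl", "tc", "tg")
    methods: tuple[str, ...] = METHODS
    pi_hat_threshold: float = 0.33
    min_variants_for_ibd: int = 500
    pca_components: int = 10
    pca_cut: float = 0.01
    ct_r2_thresholds: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    ct_p_points: int = 49
    gibbs_iterations: int = 300
    gibbs_burn_in: int = 300
    bootstrap_reps: int = 200
    ultrasound: bool = False
    ultrasound_rho: float = 0.1
    ultrasound_liability: str = "ldl"
    split_experiment_repeats: int = 0
    traits: dict[str, TraitSpec] = field(default_factory=default_lipid_traits)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        if "seed" not in raw:
            raise ConfigError("config must set an explicit seed")
        cohorts = [CohortConfig(**c) for c in raw.get("cohorts", [])]
        sources = [
            SourceConfig(**{**s, "methods": tuple(s["methods"]) if "methods" in s else None})
            for s in raw.get("sources", [])
        ]
        if not cohorts or not sources:
            raise ConfigError("config must define at least one cohort and one source")
        kwargs = {
            k: v
            for k, v in raw.items()
            if k not in ("cohorts", "sources", "phenotypes", "methods", "ct_r2_thresholds")
        }
        if "phenotypes" in raw:
            kwargs["phenotypes"] = tuple(raw["phenotypes"])
        if "methods" in raw:
            unknown = set(raw["methods"]) - set(METHODS)
            if unknown:
                raise ConfigError(f"unknown method(s): {sorted(unknown)}")
            kwargs["methods"] = tuple(raw["methods"])
        if "ct_r2_thresholds" in raw:
            kwargs["ct_r2_thresholds"] = tuple(raw["ct_r2_thresholds"])
        try:
            config = cls(cohorts=cohorts, sources=sources, **kwargs)
        except TypeError as exc:
            raise ConfigError(f"unrecognised config key: {exc}") from exc
        if config.ultrasound and config.ultrasound_liability not in config.phenotypes:
            raise ConfigError(
                f"ultrasound_liability {config.ultrasound_liability!r} is not "
                "among the configured phenotypes"
            )
        return config

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def ct_grid(self) -> CTGrid:
        return CTGrid(
            r2_thresholds=self.ct_r2_thresholds,
            p_thresholds=default_p_thresholds(n=self.ct_p_points),
        )


@dataclass
class RunManifest:
    """Deterministic enumeration of every PRS scale the config implies."""

    scales: pd.DataFrame  # columns: scale_id, cohort, source, method, phenotype

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def per_cohort(self) -> pd.Series:
        return self.scales.groupby("cohort").size()


def enumerate_scales(config: ExperimentConfig) -> RunManifest:
    """Enumerate (cohort × source × eligible method × phenotype) scales."""
    rows = []
    for cohort in config.cohorts:
        for source in config.sources:
            for method in source.eligible_methods(config.methods):
                for pheno in config.phenotypes:
                    rows.append(
                        {
                            "scale_id": f"{cohort.name}.{source.name}.{method}.{pheno}",
                            "cohort": cohort.name,
                            "source": source.name,
                            "method": method,
                            "phenotype": pheno,
                        }
                    )
    frame = pd.DataFrame(rows, columns=["scale_id", "cohort", "source", "method", "phenotype"])
    if frame["scale_id"].duplicated().any():
        raise ConfigError("duplicate scale ids; cohort/source names must be unique")
    return RunManifest(frame)


def _simulate_cohort(config: ExperimentConfig, cohort: CohortConfig):
    """Generate (or load) one cohort: genotypes, per-trait phenotype tables."""
    seed = config.seed
    if cohort.genotypes_path:
        genotypes = gio.read_genotypes(cohort.genotypes_path)
        phenos = pd.read_csv(cohort.phenotypes_path, sep="\t", index_col=0)
        tables = {p: phenos for p in config.phenotypes}
        effects = None
        return genotypes, tables, effects
    genotypes = simulate_genotypes(
        cohort.n_samples, cohort.block_spec(), child_seed(seed, cohort.name, "geno")
    )
    effects = {}
    tables = {}
    for pheno in config.phenotypes:
        trait = config.traits.get(pheno, TraitSpec())
        eff = draw_effect_sizes(
            genotypes.n_variants,
            trait.causal_fraction,
            trait.h2,
            child_seed(seed, cohort.name, pheno, "effects"),
        )
        effects[pheno] = eff
        tables[pheno] = simulate_lipid_phenotypes(
            genotypes,
            trait,
            child_seed(seed, cohort.name, pheno, "pheno"),
            effects=eff,
            name=pheno,
        )
    return genotypes, tables, effects


def _run_qc(config: ExperimentConfig, genotypes: GenotypeMatrix, ages: pd.Series):
    # method-of-moments PI_HAT has sampling sd ~ 1/sqrt(m); below a few
    # hundred variants the estimates are too noisy to prune on
    if genotypes.n_variants >= config.min_variants_for_ibd:
        pairs = qcmod.estimate_ibd(genotypes)
        related = qcmod.prune_relatives(pairs, ages, config.pi_hat_threshold)
    else:
        log.info(
            "skipping relatedness pruning: %d variants < %d required for a "
            "stable IBD estimate", genotypes.n_variants, config.min_variants_for_ibd,
        )
        related = []
    keep = [s for s in genotypes.samples if s not in set(related)]
    genotypes = genotypes.subset_samples(keep)
    pca = qcmod.pca_outliers(genotypes, k=config.pca_components, cut=config.pca_cut)
    outliers = pca.outlier_ids()
    keep = [s for s in genotypes.samples if s not in set(outliers)]
    genotypes = genotypes.subset_samples(keep)
    accounting = qcmod.qc_accounting(
        len(ages), {"relatives": len(related), "pca_outliers": len(outliers)}
    )
    return genotypes, accounting


def _source_stats(
    config: ExperimentConfig,
    cohort: CohortConfig,
    source: SourceConfig,
    genotypes: GenotypeMatrix,
    effects: np.ndarray,
    pheno: str,
) -> SummaryStats:
    stats = simulate_base_gwas(
        genotypes,
        effects,
        source.n_gwas,
        child_seed(config.seed, cohort.name, source.name, pheno, "gwas"),
    )
    if source.panel_fraction < 1.0:
        rng = np.random.default_rng(child_seed(config.seed, source.name, "panel"))
        n_keep = max(1, int(round(source.panel_fraction * stats.n_variants)))
        idx = np.sort(rng.choice(stats.n_variants, n_keep, replace=False))
        stats = SummaryStats(stats.table.iloc[idx].reset_index(drop=True))
    return stats


def run_experiment(config: ExperimentConfig, outdir: str) -> dict:
    """Execute the full experiment; returns a bundle of result tables.

    Writes manifest, per-scale association results, QC accounting, and the
    optional ultrasound screen and split-experiment summaries to ``outdir``.
    Re-running with the same config and seed reproduces all numeric outputs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = enumerate_scales(config)
    manifest.scales.to_csv(out / "manifest.tsv", sep="\t", index=False)

    results = []
    screen_frames = []
    split_frames = []
    qc_frames = []
    for cohort in config.cohorts:
        log.info("cohort %s: simulating", cohort.name)
        genotypes, tables, effects = _simulate_cohort(config, cohort)
        ages = tables[config.phenotypes[0]]["age"]
        genotypes, accounting = _run_qc(config, genotypes, ages)
        accounting.insert(0, "cohort", cohort.name)
        qc_frames.append(accounting)
        log.info("cohort %s: %d samples after QC", cohort.name, genotypes.n_samples)
        tables = {p: t.loc[genotypes.samples] for p, t in tables.items()}

        scores: dict[str, np.ndarray] = {}
        for _, scale in manifest.scales[manifest.scales["cohort"] == cohort.name].iterrows():
            source = next(s for s in config.sources if s.name == scale["source"])
            pheno = scale["phenotype"]
            table = tables[pheno]
            pheno_col = f"log_{pheno}" if f"log_{pheno}" in table.columns else pheno
            y = table[pheno_col].to_numpy(dtype=float)
            cov = ev.covariate_design(table)
            stats = _source_stats(config, cohort, source, genotypes, effects[pheno], pheno)

            method = scale["method"]
            extra: dict = {}
            if method == "classical":
                lead = stats.table.nsmallest(source.n_lead_variants, "pval")
                weights, _ = gio.harmonize(
                    SummaryStats(lead.reset_index(drop=True)), genotypes, provenance="classical"
                )
                prs = compute_prs(genotypes, weights)
                z = prs.z
                res = ev.incremental_r2(y, cov, z, pheno, scale["scale_id"])
            elif method == "ct":
                train_ids, valid_ids = split_4to1(
                    list(genotypes.samples), child_seed(config.seed, cohort.name, "split")
                )
                tr = table.index.get_indexer(train_ids)
                va = table.index.get_indexer(valid_ids)
                model = ClumpThresholdPRS(grid=config.ct_grid()).fit(
                    genotypes.subset_samples(train_ids),
                    y[tr],
                    stats,
                    cov.iloc[tr].to_numpy(dtype=float),
                )
                model.validate(
                    genotypes.subset_samples(valid_ids), y[va], cov.iloc[va].to_numpy(dtype=float)
                )
                z = model.predict(genotypes)
                res = ev.incremental_r2(y, cov, z, pheno, scale["scale_id"])
                extra = {
                    "r2_train_pct": 100.0 * model.train_delta_r2_,
                    "r2_valid_pct": 100.0 * model.validation_delta_r2_,
                    "best_r2_threshold": model.best_r2_threshold_,
                    "best_p_threshold": model.best_p_threshold_,
                    "n_variants": model.n_variants_,
                }
            else:  # shrinkage
                ld = build_ld_reference(genotypes)
                model = ShrinkagePRS(
                    iterations=config.gibbs_iterations,
                    burn_in=config.gibbs_burn_in,
                    seed=child_seed(config.seed, scale["scale_id"], "gibbs"),
                ).fit(stats, ld)
                scorer = PRSCalculator(model.weights_).fit(genotypes)
                z = scorer.transform(genotypes)
                res = ev.incremental_r2(y, cov, z, pheno, scale["scale_id"])
                extra = {"h2_posterior": model.h2_estimate_, "p_causal_posterior": model.p_causal_estimate_}

            lo, hi = ev.bootstrap_ci_r2(
                y, cov, z, reps=config.bootstrap_reps,
                seed=child_seed(config.seed, scale["scale_id"], "boot"),
            )
            res.r2_ci_lo, res.r2_ci_hi = lo, hi
            row = {**res.__dict__, "cohort": cohort.name, "method": method, **extra}
            results.append(row)
            scores[scale["scale_id"]] = z
            log.info("scale %s: dR2=%.2f%% p=%.2e", scale["scale_id"], res.delta_r2_pct, res.p_anova)

        if config.ultrasound:
            liab = tables[config.ultrasound_liability]["genetic_liability"].to_numpy()
            ultra = simulate_ultrasound(
                liab,
                UltrasoundSpec(target_rho=config.ultrasound_rho),
                child_seed(config.seed, cohort.name, "ultrasound"),
            )
            cov = ev.covariate_design(tables[config.ultrasound_liability])
            screen = ev.association_screen(
                pd.DataFrame(scores, index=list(genotypes.samples)).reset_index(drop=True),
                ultra,
                cov.reset_index(drop=True),
            )
            screen.insert(0, "cohort", cohort.name)
            screen_frames.append(screen)

        if config.split_experiment_repeats > 0:
            pheno = config.phenotypes[0]
            source = next(s for s in config.sources if s.full_sumstats)
            table = tables[pheno]
            pheno_col = f"log_{pheno}" if f"log_{pheno}" in table.columns else pheno
            stats = _source_stats(config, cohort, source, genotypes, effects[pheno], pheno)
            exp = run_split_experiment(
                genotypes,
                table[pheno_col],
                ev.covariate_design(table),
                stats,
                grid=config.ct_grid(),
                n_repeats=config.split_experiment_repeats,
                seed=child_seed(config.seed, cohort.name, "split-exp"),
            )
            summary = exp.summary()
            summary.insert(0, "cohort", cohort.name)
            split_frames.append(summary)

    results_frame = pd.DataFrame(results)
    results_frame.to_csv(out / "results.tsv", sep="\t", index=False)
    pd.concat(qc_frames).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    bundle = {"manifest": manifest, "results": results_frame}
    if screen_frames:
        screen_all = pd.concat(screen_frames)
        screen_all.to_csv(out / "screen.tsv", sep="\t", index=False)
        bundle["screen"] = screen_all
    if split_frames:
        split_all = pd.concat(split_frames)
        split_all.to_csv(out / "split_experiment.tsv", sep="\t", index=False)
        bundle["split_experiment"] = split_all
    from . import __version__

    config_hash = f"{zlib.crc32(repr(config).encode()):08x}"
    with open(out / "run.json", "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "n_scales": manifest.n_scales,
                "version": __version__,
                "config_hash": config_hash,
            },
            fh,
            indent=2,
        )
    return bundle
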