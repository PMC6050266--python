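"""End-to-end orchestration: config, stage sequence, run report.

The pipeline executes: obtain data (read TSVs or simulate) -> 10-TPM
filter -> small-RNA biotype exclusion -> log transform -> per-gene KS
expression and variability tests -> classification and direction split
-> cross-validation (baseline DE caller overlap + KS robustness) ->
signature PCA -> Spearman clinical correlations -> direction-contingency
chi-square -> risk-gene profile.  Every random stage derives its stream
from the single config seed, so a rerun with the same config reproduces
every output file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import downstream, io, kstest, robustness, simulate

log = logging.getLogger("ksvar")


@dataclass
class SimulateBlock:
    """Generator parameters for fully synthetic runs."""

    n_genes: int = 2000
    n_case: int = 10
    n_control: int = 10
    frac_mean_shift: float = 0.05
    frac_var_shift: float = 0.10
    lfc: float = 2.0
    vif: float = 3.0
    sigma: float = 0.3
    frac_expressed: float = 0.85
    frac_decoy: float = 0.04
    rho_clinical: float = -0.7
    comparator_samples: int = 10
    comparator_delta_sd: float = 1.5


@dataclass
class RunConfig:
    """Run parameters; either the input paths or the simulate block."""

    outdir: Path = Path("ksvar_run")
    seed: int = 0
    matrix: str | None = None
    annotations: str | None = None
    metadata: str | None = None
    microglia_matrix: str | None = None
    bulk_matrix: str | None = None
    risk_genes: str | None = None
    simulate: SimulateBlock | None = None
    filter_tpm: float = 10.0
    filter_min_samples: int = 1
    exclude_biotypes: tuple[str, ...] = ("snoRNA", "miRNA")
    pseudocount: float = 1.0
    alpha: float = 0.01
    fdr: float = 0.05
    fc_cutoff: float = 2.0
    cv_k: int = 5
    cv_n_excl: int = 2
    cv_p_threshold: float = 0.05
    n_risk_genes: int = 40

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            cfg.simulate = SimulateBlock(**sim)
        cfg.outdir = Path(cfg.outdir)
        cfg.exclude_biotypes = tuple(cfg.exclude_biotypes)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if self.simulate is None and (self.matrix is None or self.metadata is None):
            raise io.ValidationError("config needs either input paths or a simulate block")
        if not (0 < self.alpha < 1 and 0 < self.fdr < 1):
            raise io.ValidationError("alpha and fdr must lie in (0, 1)")
        if self.filter_tpm < 0 or self.fc_cutoff < 1:
            raise io.ValidationError("filter_tpm must be >= 0 and fc_cutoff >= 1")


def _derived_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; writes TSVs plus ``summary.json`` to
    ``config.outdir`` and returns the summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _derived_seeds(config.seed, 6)
    stages: dict[str, float] = {}

    def stage(name):
        stages[name] = time.perf_counter()
        log.info("stage %s", name)

    def done(name):
        stages[name] = time.perf_counter() - stages[name]

    # -- data ---------------------------------------------------------------
    stage("data")
    truth = None
    if config.simulate is not None:
        sim = config.simulate
        matrix, meta, truth = simulate.simulate_matrix(
            sim.n_genes,
            sim.n_case,
            sim.n_control,
            frac_mean_shift=sim.frac_mean_shift,
            frac_var_shift=sim.frac_var_shift,
            lfc=sim.lfc,
            vif=sim.vif,
            sigma=sim.sigma,
            frac_expressed=sim.frac_expressed,
            frac_decoy=sim.frac_decoy,
            seed=seeds[0],
        )
        down_true = [
            g
            for g in truth.genes_of_class("mean_shift")
            if truth.table.loc[g, "affected_group"] == "control"
        ] or truth.genes_of_class("mean_shift")
        if down_true:
            meta = simulate.simulate_clinical(
                meta, down_true, matrix, rho_target=sim.rho_clinical, seed=seeds[1]
            )
        microglia = simulate.simulate_comparator(
            truth, sim.comparator_samples, sim.comparator_delta_sd, "mg", seed=seeds[2]
        )
        bulk = simulate.simulate_comparator(
            truth, sim.comparator_samples, sim.comparator_delta_sd, "bulk", seed=seeds[3]
        )
        io.write_matrix(matrix, outdir / "matrix.tsv")
        io.write_annotations(matrix.annotations, outdir / "annotations.tsv")
        io.write_metadata(meta, outdir / "metadata.tsv")
        tt = truth.table.copy()
        tt.index.name = "gene_id"
        tt.to_csv(outdir / "truth.tsv", sep="\t", float_format="%.6g")
        io.write_matrix(microglia, outdir / "microglia_matrix.tsv")
        io.write_matrix(bulk, outdir / "bulk_matrix.tsv")
    else:
        ann = io.read_annotations(config.annotations) if config.annotations else None
        matrix = io.read_matrix(config.matrix, units="TPM", annotations=ann)
        meta = io.read_metadata(config.metadata)
        microglia = (
            io.read_matrix(config.microglia_matrix, units="TPM")
            if config.microglia_matrix
            else None
        )
        bulk = io.read_matrix(config.bulk_matrix, units="TPM") if config.bulk_matrix else None
    meta.check_matches(matrix)
    done("data")

    # -- filter / exclude / log --------------------------------------------
    stage("filter")
    filtered = io.filter_expressed(matrix, config.filter_tpm, config.filter_min_samples)
    if config.exclude_biotypes and filtered.annotations is not None:
        filtered = io.exclude_biotypes(filtered, set(config.exclude_biotypes))
    logm = io.log_transform(filtered, config.pseudocount)
    done("filter")

    # -- KS tests and classification ---------------------------------------
    stage("ks")
    records = kstest.ks_test_genes(logm, meta, alpha=config.alpha, rng=seeds[4])
    records.to_csv(outdir / "ks_results.tsv", sep="\t", float_format="%.6g")
    split = kstest.split_by_direction(records)
    done("ks")

    # -- cross validation ---------------------------------------------------
    stage("cv")
    folds = robustness.make_cv_folds(meta, config.cv_k, config.cv_n_excl, seed=seeds[5])
    de_full, de_folds, overlap = robustness.cross_validate_caller(
        filtered, meta, folds, robustness.de_call, fc_cutoff=config.fc_cutoff, fdr=config.fdr
    )
    overlap.to_csv(outdir / "cv_overlap.tsv", sep="\t")
    ks_de_genes = sorted(split.up_case | split.down_case | split.de_ties)
    robust, max_p = robustness.ks_cv_robustness(
        logm, meta, ks_de_genes, folds, p_threshold=config.cv_p_threshold
    )
    max_p.to_frame("max_fold_p").assign(robust=max_p < config.cv_p_threshold).to_csv(
        outdir / "cv_robustness.tsv", sep="\t", float_format="%.6g"
    )
    done("cv")

    # -- PCA ----------------------------------------------------------------
    stage("pca")
    evr = []
    if len(ks_de_genes) >= 2:
        proj, evr = downstream.pca_signature(logm.subset_genes(ks_de_genes), meta)
        proj.to_csv(outdir / "pca_projections.tsv", sep="\t", float_format="%.6g")
        evr = [float(v) for v in evr]
    done("pca")

    # -- Spearman -----------------------------------------------------------
    stage("spearman")
    signature = sorted(split.down_case) or ks_de_genes
    rho = pd.DataFrame()
    if signature:
        rho, npairs = downstream.spearman_clinical(logm, signature, meta)
        rho.to_csv(outdir / "spearman_rho.tsv", sep="\t", float_format="%.4g")
        npairs.to_csv(outdir / "spearman_n.tsv", sep="\t")
    done("spearman")

    # -- contingency chi-square --------------------------------------------
    stage("chi2")
    chi2_block = None
    if microglia is not None and ks_de_genes:
        pd_dir = kstest.direction_labels(records, "de_low_var")
        ct_dir = _celltype_direction(filtered, meta, microglia, ks_de_genes)
        table = downstream.direction_contingency(
            {g: pd_dir[g] for g in ks_de_genes}, ct_dir
        )
        chi2_block = {"table": table.tolist()}
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            res = downstream.chi_square_2x2(table)
            chi2_block.update(chi2=round(res.chi2, 6), p=round(res.p, 6), df=res.df)
    done("chi2")

    # -- risk profile -------------------------------------------------------
    stage("risk")
    risk_block = None
    if microglia is not None:
        risk_genes = _risk_gene_list(config, filtered, seeds[5])
        if risk_genes:
            mats = {
                "monocyte_control": filtered.subset_samples(meta.control_ids),
                "monocyte_case": filtered.subset_samples(meta.case_ids),
                "microglia": microglia.subset_genes(
                    [g for g in risk_genes if g in microglia.gene_ids]
                ),
            }
            if bulk is not None:
                mats["bulk"] = bulk
            profile = downstream.risk_gene_profile(mats, risk_genes)
            profile.table.to_csv(outdir / "risk_profile.tsv", sep="\t", index=False, float_format="%.6g")
            counts = profile.category.value_counts().to_dict()
            risk_block = {
                "n_genes": len(risk_genes),
                "n_missing": len(profile.missing),
                "categories": {k: int(v) for k, v in sorted(counts.items())},
            }
    done("risk")

    label_counts = records["label"].value_counts().to_dict()
    summary = {
        "seed": config.seed,
        "parameters": {
            "filter_tpm": config.filter_tpm,
            "alpha": config.alpha,
            "fdr": config.fdr,
            "fc_cutoff": config.fc_cutoff,
            "cv_k": config.cv_k,
            "cv_n_excl": config.cv_n_excl,
        },
        "n_genes_input": int(matrix.n_genes),
        "n_genes_tested": int(logm.n_genes),
        "label_counts": {k: int(label_counts.get(k, 0)) for k in kstest.LABELS},
        "direction": {
            "up_case": len(split.up_case),
            "down_case": len(split.down_case),
            "var_up_case": len(split.var_up_case),
            "var_up_control": len(split.var_up_control),
        },
        "de_caller": {
            "full_cohort": len(de_full),
            "per_fold": [len(s) for s in de_folds],
        },
        "ks_robust_genes": len(robust),
        "pca_explained_variance": evr,
        "chi2": chi2_block,
        "risk_profile": risk_block,
    }
    for name, seconds in stages.items():
        log.info("stage %s took %.2fs", name, seconds)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _celltype_direction(matrix, meta, microglia, genes) -> dict[str, str]:
    """up/down labels for control-cohort versus comparator mean log2."""
    out = {}
    ctrl = np.log2(matrix.values.loc[genes, meta.control_ids] + 1.0).mean(axis=1)
    for g in genes:
        if g not in microglia.gene_ids:
            out[g] = "tie"
            continue
        mg = float(np.log2(microglia.values.loc[g] + 1.0).mean())
        diff = float(ctrl.loc[g]) - mg
        out[g] = "tie" if diff == 0 else ("up" if diff > 0 else "down")
    return out


def _risk_gene_list(config: RunConfig, matrix, seed: int) -> list[str]:
    if config.risk_genes:
        genes = [
            line.strip()
            for line in Path(config.risk_genes).read_text().splitlines()
            if line.strip()
        ]
        return genes
    n = min(config.n_risk_genes, matrix.n_genes)
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(matrix.gene_ids.to_numpy(), size=n, replace=False).tolist())
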