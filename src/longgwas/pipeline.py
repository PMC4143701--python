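"""End-to-end pipeline: simulate → diagnose → impute → QC → scan → interact → permute.

Each stage writes its outputs as delimited text plus a JSON manifest
(parameters, seeds, input file hashes, package version), so any stage can
be re-run standalone and two runs with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    InteractionScan,
    SingleMarkerGWAS,
    build_trait,
    select_covariates,
)
from .cohort import CohortConfig, simulate_cohort
from .genotypes import GenotypeMatrix
from .imputation import HotDeckImputer, extract_completers
from .missingness import MissingnessModel
from .permutation import validate_top_hits
from .phenotypes import PhenotypeTable
from .qc import GenotypeQC

log = logging.getLogger("longgwas")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds of the full analysis."""

    out_dir: str = "longgwas_run"
    pheno_path: str | None = None  # None -> simulate
    geno_path: str | None = None
    map_path: str | None = None
    simulate: dict = field(default_factory=dict)  # CohortConfig overrides
    mode: str = "imputed"  # imputed | no_imputation
    ibs_threshold: float = 0.84
    ibs_threshold_mode: str = "absolute"
    max_missing: float = 0.40
    min_callrate: float = 0.99
    hwe_alpha: float = 1e-6
    min_maf: float = 0.01
    interaction_min_maf: float = 0.05
    covariate_alpha: float = 0.05
    run_interaction: bool = True
    interaction_top_k: int = 100
    n_top_permute: int = 5
    n_permutations: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("imputed", "no_imputation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name, v, lo, hi in [
            ("ibs_threshold", self.ibs_threshold, 0, np.inf),
            ("max_missing", self.max_missing, 0, 1),
            ("min_callrate", self.min_callrate, 0, 1),
            ("hwe_alpha", self.hwe_alpha, 0, 1),
            ("min_maf", self.min_maf, 0, 0.5),
            ("interaction_min_maf", self.interaction_min_maf, 0, 0.5),
        ]:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, params: dict, inputs: list[Path]) -> None:
    manifest = {
        "version": __version__,
        "params": params,
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # ---- stage: inputs -----------------------------------------------------
    if config.pheno_path is None:
        sim_cfg = CohortConfig(**{"seed": config.seed, **config.simulate})
        cohort = simulate_cohort(sim_cfg)
        pheno = cohort.phenotypes_observed
        geno = cohort.genotypes
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        pheno.to_file(sim_dir / "phenotypes.tsv")
        cohort.phenotypes_complete.to_file(sim_dir / "phenotypes_complete.tsv")
        geno.to_files(sim_dir / "genotypes.tsv", sim_dir / "snps.map")
        _write_manifest(sim_dir, asdict(sim_cfg), [])
        log.info("simulated cohort: n=%d, snps=%d", len(pheno), geno.n_snps)
    else:
        pheno = PhenotypeTable.from_file(config.pheno_path)
        geno = GenotypeMatrix.from_files(config.geno_path, config.map_path)

    # ---- stage: missingness diagnostics ------------------------------------
    diag_dir = out / "diagnose"
    diag_dir.mkdir(exist_ok=True)
    try:
        report = MissingnessModel(pheno).fit()
        (diag_dir / "mechanism.txt").write_text(report.summary() + "\n")
        pd.Series(report.to_dict()).to_csv(diag_dir / "mechanism.tsv", sep="\t", header=False)
        log.info("missingness verdict: %s", report.verdict)
    except ValueError as e:  # e.g. a dropout-free cohort
        (diag_dir / "mechanism.txt").write_text(f"diagnostic not run: {e}\n")

    # ---- stage: imputation -------------------------------------------------
    completer_mask, _ = extract_completers(pheno)
    completer_ids = list(pheno.ids[completer_mask])
    if config.mode == "imputed":
        imp = HotDeckImputer(pheno).fit()
        imp_dir = out / "impute"
        imp_dir.mkdir(exist_ok=True)
        imp.completed.to_file(imp_dir / "phenotypes_imputed.tsv")
        imp.audit.to_csv(imp_dir / "audit.tsv", sep="\t", index=False)
        (imp_dir / "summary.txt").write_text(imp.summary() + "\n")
        _write_manifest(imp_dir, {"exam_years": imp.exam_years}, [])
        analysis_pheno = imp.completed
    else:
        analysis_pheno = pheno

    # ---- stage: genotype QC ------------------------------------------------
    qc = GenotypeQC(
        geno,
        ibs_threshold=config.ibs_threshold,
        ibs_threshold_mode=config.ibs_threshold_mode,
        max_missing=config.max_missing,
        min_callrate=config.min_callrate,
        hwe_alpha=config.hwe_alpha,
        min_maf=config.min_maf,
    )
    clean_geno, qc_report = qc.run()
    qc_dir = out / "qc"
    qc_dir.mkdir(exist_ok=True)
    qc_report.samples_removed.to_csv(qc_dir / "samples_removed.tsv", sep="\t", index=False)
    qc_report.snps_removed.to_csv(qc_dir / "snps_removed.tsv", sep="\t", index=False)
    (qc_dir / "summary.txt").write_text(qc_report.summary() + "\n")
    log.info("QC kept %d samples, %d SNPs", qc_report.n_samples_kept, qc_report.n_snps_kept)

    # ---- stage: trait + covariates + single-marker scan --------------------
    trait = build_trait(analysis_pheno, mode=config.mode)
    covs = select_covariates(trait, completer_ids, alpha=config.covariate_alpha)
    trait.retained_covariates = covs
    scan = SingleMarkerGWAS(trait, clean_geno, covs).fit()
    scan_dir = out / "scan"
    scan_dir.mkdir(exist_ok=True)
    trait.df.to_csv(scan_dir / "trait.tsv", sep="\t", index=False)
    scan.table.to_csv(scan_dir / "single_marker.tsv", sep="\t", index=False)
    (scan_dir / "summary.txt").write_text(scan.summary() + "\n")
    _write_manifest(scan_dir, {"covariates": covs, "mode": config.mode}, [])

    # ---- stage: interaction scan -------------------------------------------
    if config.run_interaction:
        inter = InteractionScan(trait, clean_geno, config.interaction_min_maf).fit(
            top_k=config.interaction_top_k
        )
        inter_dir = out / "interact"
        inter_dir.mkdir(exist_ok=True)
        inter.table.to_csv(inter_dir / "pairs.tsv", sep="\t", index=False)
        (inter_dir / "summary.txt").write_text(inter.summary() + "\n")

    # ---- stage: permutation validation -------------------------------------
    if config.n_top_permute > 0:
        perms = validate_top_hits(
            scan, trait, clean_geno,
            n_top=config.n_top_permute,
            n_replicates=config.n_permutations,
            seed=config.seed,
        )
        perm_dir = out / "permute"
        perm_dir.mkdir(exist_ok=True)
        pd.DataFrame(
            [
                {
                    "snp": r.snp_id, "k": r.k, "n": r.n_replicates,
                    "p_mc": r.p_mc, "p_mc_conservative": r.p_mc_conservative,
                    "parametric_p": r.parametric_p, "n_ties": r.n_ties,
                }
                for r in perms
            ]
        ).to_csv(perm_dir / "top_hits_mc.tsv", sep="\t", index=False)

    _write_manifest(out, asdict(config), [])
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return out
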