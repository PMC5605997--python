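"""End-to-end orchestration: QC -> PCs -> GWAS -> conditional selection ->
gene mapping -> GSEA, with a run manifest for auditability.

A single seed in the configuration feeds a per-stage seed derivation
(stage name hashed with the master seed), so each stage is individually
reproducible. All intermediates are TSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import assoc as assoc_mod
from . import condsel, genemap, gsea, io, qc
from .core import ValidationError, stage_seed

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    genotypes: str = ""
    phenotypes: str = ""
    genes: str = ""  # BED
    eqtls: str = ""  # TSV, empty if eqtl route unused
    gene_sets: str = ""  # GMT
    outdir: str = "results"
    # QC thresholds
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    hwe_alpha: float = 1e-4
    info_min: float = 0.9
    # association model
    n_pcs: int = 3
    covariates: list[str] = field(default_factory=lambda: ["group"])
    # selection cutoffs
    p_marginal: float = 0.05
    p_entry: float = 1e-3
    # mapping
    routes: list[str] = field(default_factory=lambda: ["intragenic", "eqtl"])
    tissues: list[str] = field(default_factory=lambda: ["caudate"])
    # GSEA
    n_perm: int = 10_000
    weight_exponent: float = 0.0
    fdr_threshold: float = 0.05
    min_set_size: int = 10
    max_set_size: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_alpha", "info_min"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in ("p_marginal", "p_entry", "fdr_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        for route in self.routes:
            if route not in ("intragenic", "eqtl", "proximity"):
                raise ValidationError(f"unknown mapping route {route!r}")
        for path_attr in ("genotypes", "phenotypes", "genes", "gene_sets"):
            p = getattr(self, path_attr)
            if not p or not Path(p).exists():
                raise ValidationError(f"{path_attr} file missing: {p!r}")
        if "eqtl" in self.routes and (not self.eqtls or not Path(self.eqtls).exists()):
            raise ValidationError(
                f"eqtl route requested but eQTL file missing: {self.eqtls!r}"
            )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write TSVs to ``outdir``, return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    outputs: dict[str, Path] = {}

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    geno = run_stage("read", lambda: io.read_genotypes(config.genotypes))
    pheno = run_stage("read", lambda: io.read_phenotypes(config.phenotypes))
    genes = run_stage("read", lambda: io.read_bed(config.genes))
    gene_sets = run_stage("read", lambda: io.read_gmt(config.gene_sets))

    thresholds = qc.QcThresholds(
        maf_min=config.maf_min,
        call_rate_min=config.call_rate_min,
        hwe_alpha=config.hwe_alpha,
        info_min=config.info_min,
    )
    log.info("QC thresholds applied: %s", thresholds)
    geno_qc, report = run_stage("qc", lambda: qc.filter_markers(geno, thresholds))
    outputs["qc_report"] = outdir / "qc_report.tsv"
    io.write_table(report.per_marker, outputs["qc_report"])

    covariates = list(config.covariates)
    if config.n_pcs > 0:
        pcs = run_stage("pcs", lambda: assoc_mod.compute_pcs(geno_qc, config.n_pcs))
        import pandas as pd

        pheno = pheno.copy()
        # PCs computed on QC-passing genotypes, aligned to phenotype rows
        pc_cols = [f"PC{i + 1}" for i in range(config.n_pcs)]
        pc_df = pd.DataFrame(pcs.scores, columns=pc_cols)
        pc_df.insert(0, "sample_id", geno_qc.sample_ids)
        pheno = pheno.merge(pc_df, on="sample_id", how="inner")
        covariates += pc_cols
        outputs["pcs"] = outdir / "pcs.tsv"
        io.write_table(pc_df, outputs["pcs"])

    log.info("association model: dosage + intercept + %s", covariates)
    assoc = run_stage(
        "gwas", lambda: assoc_mod.gwas_linear(geno_qc, pheno, covariates)
    )
    outputs["assoc"] = outdir / "assoc.tsv"
    io.write_table(assoc, outputs["assoc"])

    selected = run_stage(
        "condsel",
        lambda: condsel.stepwise_select(
            geno_qc,
            pheno,
            covariates,
            p_entry=config.p_entry,
            p_marginal=config.p_marginal,
            assoc=assoc,
        ),
    )
    outputs["selected"] = outdir / "selected.tsv"
    io.write_table(selected, outputs["selected"])
    log.info(
        "selection cutoffs: p_marginal<%g, p_entry<%g; %d markers selected",
        config.p_marginal,
        config.p_entry,
        len(selected),
    )

    def _map():
        links = []
        if "intragenic" in config.routes:
            links.append(
                genemap.map_intragenic(
                    selected,
                    genes,
                    geno_qc.markers,
                    p_marginal=config.p_marginal,
                    p_entry=config.p_entry,
                )
            )
        if "eqtl" in config.routes:
            eqtls = io.read_eqtls(config.eqtls)
            links.append(
                genemap.map_eqtl(
                    assoc, eqtls, config.tissues, p_nominal=config.p_marginal
                )
            )
        if "proximity" in config.routes:
            for window in genemap.PROXIMITY_WINDOWS:
                links.append(
                    genemap.map_proximity(
                        selected, genes, geno_qc.markers, window,
                        p_marginal=config.p_marginal, p_entry=config.p_entry,
                    )
                )
        return genemap.combine_links(*links)

    links = run_stage("genemap", _map)
    outputs["links"] = outdir / "links.tsv"
    io.write_table(links, outputs["links"])

    scores = run_stage("genemap", lambda: genemap.score_genes(links, assoc))
    outputs["gene_scores"] = outdir / "gene_scores.rnk"
    io.write_rnk(scores, outputs["gene_scores"])

    def _gsea():
        if len(scores) == 0:
            import pandas as pd

            return pd.DataFrame(columns=["set", "size", "es", "nes", "p_perm", "fdr"])
        return gsea.run_gsea(
            scores,
            gene_sets,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "gsea"),
            weight_exponent=config.weight_exponent,
            min_size=config.min_set_size,
            max_size=config.max_set_size,
        )

    results = run_stage("gsea", _gsea)
    outputs["gsea"] = outdir / "gsea.tsv"
    io.write_table(results, outputs["gsea"])

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stage_seeds": {"gsea": stage_seed(config.seed, "gsea")},
        "inputs": {
            k: _sha256(Path(getattr(config, k)))
            for k in ("genotypes", "phenotypes", "genes", "gene_sets")
        },
        "outputs": {k: _sha256(p) for k, p in outputs.items()},
        "started": t0,
        "finished": time.time(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
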