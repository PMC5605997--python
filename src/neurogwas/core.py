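"""Core data containers shared across the pipeline.

Conventions
-----------
* Genomic positions are 1-based inclusive everywhere in memory (the VCF
  convention); BED input/output is converted at the file boundary.
* Dosages are expected alternate-allele counts in [0, 2]; missing entries
  are ``NaN``.
* Tables (phenotypes, annotations, eQTLs, association results, links,
  scores) are plain :class:`pandas.DataFrame` objects with documented
  column names, so they stay diff-able as TSV on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns of the per-marker metadata table carried by GenotypeMatrix
MARKER_COLUMNS = ["marker", "chrom", "pos", "ref", "alt", "info_score", "call_rate"]

#: columns of a phenotype/covariate table
PHENO_COLUMNS = ["sample_id", "phenotype", "group"]

#: columns of an eQTL link table
EQTL_COLUMNS = ["marker", "gene", "tissue"]

#: columns of a gene annotation table (1-based inclusive intervals)
GENE_COLUMNS = ["gene", "chrom", "start", "end"]


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    Parameters
    ----------
    n_samples, n_markers : int
        Cohort and panel size.
    maf_range : (float, float)
        Minor allele frequencies are drawn uniformly from this interval;
        the lower bound must be positive and the upper bound at most 0.5.
    ld_block_size : int
        Markers per linkage block. Within a block each haplotype allele
        copies the previous marker's allele with probability
        ``within_block_r`` (else it is redrawn from its own frequency),
        giving adjacent-marker genotype correlation close to that value.
    within_block_r : float
        Target adjacent-marker genotype correlation, in [0, 1).
    causal_markers : list of (int, float)
        Marker index and additive phenotype effect per dosage unit.
    group_effect : float
        Phenotype shift applied to group==1 samples (the sated-smoker
        indicator in the study design this generator emulates).
    baseline : float
        Phenotype intercept, i.e. the group==0 mean when no causal
        effects are planted.
    noise_sd : float
        Residual standard deviation of the phenotype.
    group_prevalence : float
        Bernoulli probability of group membership (default 0.4, roughly
        the smoker fraction of the emulated cohort).
    missing_rate : float
        Per-entry dosage missingness rate (default 0).
    continuous_dosages : bool
        If true, jitter hard calls into fractional dosages clipped to
        [0, 2], mimicking imputed dosage data.
    n_chromosomes : int
        Markers are split evenly over this many chromosomes; LD blocks
        never span a chromosome boundary.
    seed : int
        Seed for all randomness in the generator.
    """

    n_samples: int
    n_markers: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    within_block_r: float = 0.0
    causal_markers: list[tuple[int, float]] = field(default_factory=list)
    group_effect: float = 0.0
    baseline: float = 0.0
    noise_sd: float = 1.0
    group_prevalence: float = 0.4
    missing_rate: float = 0.0
    continuous_dosages: bool = False
    n_chromosomes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValidationError("n_samples must be non-negative")
        if self.n_markers < 0:
            raise ValidationError("n_markers must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError(
                "maf_range must satisfy 0 < low <= high <= 0.5, got "
                f"{self.maf_range!r}"
            )
        if self.ld_block_size < 1:
            raise ValidationError("ld_block_size must be >= 1")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValidationError("within_block_r must lie in [0, 1)")
        for idx, _ in self.causal_markers:
            if not (0 <= idx < self.n_markers):
                raise ValidationError(
                    f"causal_markers index {idx} out of range for "
                    f"n_markers={self.n_markers}"
                )
        if not (0.0 <= self.group_prevalence <= 1.0):
            raise ValidationError("group_prevalence must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.n_chromosomes < 1:
            raise ValidationError("n_chromosomes must be >= 1")


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with per-marker metadata.

    Attributes
    ----------
    sample_ids : list of str
    markers : DataFrame
        One row per marker with :data:`MARKER_COLUMNS`.
    dosage : ndarray, shape (n_samples, n_markers)
        Alternate-allele dosages in [0, 2]; NaN marks a missing call.
    """

    sample_ids: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def validate(self) -> None:
        if self.dosage.shape != (self.n_samples, self.n_markers):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{self.n_samples} samples x {self.n_markers} markers"
            )
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValidationError(f"marker table missing columns: {missing}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad & ~np.isnan(self.dosage)):
            raise ValidationError("dosage values outside [0, 2]")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"marker positions not strictly increasing on {chrom}"
                )
        for col in ("info_score", "call_rate"):
            vals = self.markers[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1)):
                raise ValidationError(f"{col} outside [0, 1]")
        if self.markers["marker"].duplicated().any():
            raise ValidationError("duplicate marker ids")

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to a boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            markers=self.markers.iloc[keep].reset_index(drop=True),
            dosage=self.dosage[:, keep].copy(),
        )

    def subset_samples(self, keep: list[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in keep],
            markers=self.markers.copy(),
            dosage=self.dosage[keep, :].copy(),
        )


class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> unique member gene ids."""

    def __init__(
        self,
        sets: dict[str, list[str]],
        descriptions: dict[str, str] | None = None,
    ):
        for name, genes in sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")
        self.sets = dict(sets)
        self.descriptions = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


def validate_phenotypes(pheno: pd.DataFrame) -> None:
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    if pheno["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in phenotype table")


def align_samples(
    geno: GenotypeMatrix, pheno: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Restrict both inputs to shared samples, in genotype order."""
    validate_phenotypes(pheno)
    shared = [s for s in geno.sample_ids if s in set(pheno["sample_id"])]
    if not shared:
        raise ValidationError("no shared samples between genotypes and phenotypes")
    idx = [geno.sample_ids.index(s) for s in shared]
    geno2 = geno.subset_samples(idx)
    pheno2 = (
        pheno.set_index("sample_id").loc[shared].reset_index()
    )
    return geno2, pheno2


def stage_seed(seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed below 2**31 from a master seed."""
    import hashlib

    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
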