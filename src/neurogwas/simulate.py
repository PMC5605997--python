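"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes:
LD-blocked diploid genotypes in Hardy-Weinberg equilibrium, a quantitative
imaging phenotype with planted additive variant effects plus a binary group
covariate, tissue-tagged eQTL links, non-overlapping gene annotations, and
gene set collections with an optional planted set. Every draw is controlled
by a single seed so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    EQTL_COLUMNS,
    GENE_COLUMNS,
    GeneSetCollection,
    GenotypeMatrix,
    SimulationConfig,
    ValidationError,
)

#: group means of caudate activity during reward for the three smoking
#: states (non-smoker, sated, abstinent) used as generator defaults.
CAUDATE_REWARD_MEANS = (0.186, -0.317, 0.002)

#: caudate-amygdala resting-state connectivity group parameters
#: (non-smoker, sated, abstinent): means and the parenthesized spreads.
CAUDATE_AMYGDALA_MEANS = (0.148, -0.539, 0.361)
CAUDATE_AMYGDALA_SPREADS = (0.102, 0.146, 0.149)

GROUP_LABELS = ("non-smoker", "sated", "abstinent")

_MARKER_SPACING = 1_000  # bp between consecutive synthetic markers


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a diploid dosage matrix under HWE with block LD.

    Each marker's alternate-allele frequency is uniform on
    ``config.maf_range``. Haplotypes are generated marker-by-marker within
    an LD block: with probability ``within_block_r`` the allele is copied
    from the previous marker on the same haplotype, otherwise it is
    redrawn Bernoulli(f). The two haplotypes of an individual are
    independent, so genotypes are in HWE at every marker.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_markers

    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    chrom_of = np.repeat(
        np.arange(config.n_chromosomes), -(-m // config.n_chromosomes)
    )[:m]
    # positions restart per chromosome, strictly increasing
    pos = np.empty(m, dtype=int)
    for c in range(config.n_chromosomes):
        idx = np.flatnonzero(chrom_of == c)
        pos[idx] = (np.arange(len(idx)) + 1) * _MARKER_SPACING

    haplos = np.empty((2 * n, m), dtype=np.int8) if m else np.empty((2 * n, 0), np.int8)
    r = config.within_block_r
    for j in range(m):
        fresh = rng.random(2 * n) < freqs[j]
        new_block = (j % config.ld_block_size == 0) or (
            j > 0 and chrom_of[j] != chrom_of[j - 1]
        )
        if new_block or r == 0.0:
            haplos[:, j] = fresh
        else:
            copy = rng.random(2 * n) < r
            haplos[:, j] = np.where(copy, haplos[:, j - 1], fresh)

    dosage = (haplos[:n] + haplos[n:]).astype(float)

    if config.continuous_dosages and m:
        dosage = np.clip(dosage + rng.normal(0.0, 0.05, size=dosage.shape), 0.0, 2.0)

    if config.missing_rate > 0 and m:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    call_rate = (
        1.0 - np.mean(np.isnan(dosage), axis=0) if n else np.ones(m)
    )
    info_score = 1.0 - rng.uniform(0.0, 0.2, size=m)

    markers = pd.DataFrame(
        {
            "marker": [f"m{j:06d}" for j in range(m)],
            "chrom": [str(c + 1) for c in chrom_of],
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "info_score": info_score,
            "call_rate": call_rate,
        }
    )
    geno = GenotypeMatrix(
        sample_ids=[f"s{i:05d}" for i in range(n)],
        markers=markers,
        dosage=dosage,
    )
    geno.validate()
    return geno


def simulate_phenotype(
    geno: GenotypeMatrix,
    config: SimulationConfig,
    group: np.ndarray | None = None,
) -> pd.DataFrame:
    """Additive quantitative phenotype with a binary group covariate.

    phenotype = baseline + sum(effect * dosage) + group_effect * group
    + Normal(0, noise_sd). Missing dosages contribute their marker mean.
    Group is Bernoulli(``group_prevalence``) unless supplied.
    """
    if geno.n_samples == 0:
        raise ValidationError("cannot simulate phenotypes for zero samples")
    rng = np.random.default_rng(config.seed + 1)

    if group is None:
        group = (rng.random(geno.n_samples) < config.group_prevalence).astype(int)
    else:
        group = np.asarray(group, dtype=int)
        if group.shape != (geno.n_samples,):
            raise ValidationError("group vector length mismatch")

    y = np.full(geno.n_samples, config.baseline, dtype=float)
    for idx, effect in config.causal_markers:
        d = geno.dosage[:, idx].copy()
        if np.all(np.isnan(d)):
            raise ValidationError(f"causal marker {idx} is all-missing")
        d[np.isnan(d)] = np.nanmean(d)
        y += effect * d
    y += config.group_effect * group
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=geno.n_samples)

    return pd.DataFrame(
        {"sample_id": list(geno.sample_ids), "phenotype": y, "group": group}
    )


def simulate_annotations(
    n_genes: int,
    genome_length: int,
    eqtl_fraction: float,
    seed: int,
    markers: pd.DataFrame | None = None,
    tissues: tuple[str, ...] = ("caudate", "putamen"),
    max_eqtl_distance: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place non-overlapping gene intervals and draw tissue-tagged eQTLs.

    Genes are placed in disjoint slots of the genome so intervals never
    overlap. Each gene independently becomes an eQTL target with
    probability ``eqtl_fraction``; its linked markers are drawn from the
    supplied marker table restricted to the same chromosome and within
    ``max_eqtl_distance`` bp of the gene body.
    """
    if n_genes < 0:
        raise ValidationError("n_genes must be non-negative")
    rng = np.random.default_rng(seed)

    genes = pd.DataFrame(columns=GENE_COLUMNS)
    if n_genes > 0:
        slot = genome_length // n_genes
        min_len = 200
        if slot < 2 * min_len:
            raise ValidationError(
                f"genome_length {genome_length} too short to place {n_genes} "
                "non-overlapping genes"
            )
        starts, ends = [], []
        for g in range(n_genes):
            lo = g * slot + 1
            length = int(rng.integers(min_len, slot // 2))
            start = int(rng.integers(lo, lo + slot - length - 1))
            starts.append(start)
            ends.append(start + length - 1)
        genes = pd.DataFrame(
            {
                "gene": [f"GENE{g:04d}" for g in range(n_genes)],
                "chrom": "1",
                "start": starts,
                "end": ends,
            }
        )

    rows: list[tuple[str, str, str]] = []
    if eqtl_fraction > 0 and markers is not None and len(markers) and n_genes:
        mk = markers.reset_index(drop=True)
        for _, gene in genes.iterrows():
            if rng.random() >= eqtl_fraction:
                continue
            near = mk[
                (mk["chrom"] == gene["chrom"])
                & (mk["pos"] >= gene["start"] - max_eqtl_distance)
                & (mk["pos"] <= gene["end"] + max_eqtl_distance)
            ]
            if near.empty:
                continue
            k = int(rng.integers(1, min(3, len(near)) + 1))
            chosen = rng.choice(near["marker"].to_numpy(), size=k, replace=False)
            for marker in chosen:
                tissue = tissues[int(rng.integers(len(tissues)))]
                rows.append((marker, gene["gene"], tissue))

    eqtls = pd.DataFrame(rows, columns=EQTL_COLUMNS).drop_duplicates()
    return genes, eqtls.reset_index(drop=True)


def simulate_gene_sets(
    genes: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    planted_set: list[str] | None = None,
    seed: int = 0,
    planted_name: str = "PLANTED",
) -> GeneSetCollection:
    """Random gene sets drawn without replacement, plus an optional planted set."""
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ValidationError("set_size_range must satisfy 1 <= low <= high")
    if hi > len(genes):
        raise ValidationError(
            f"set_size_range upper bound {hi} exceeds gene universe of {len(genes)}"
        )
    rng = np.random.default_rng(seed)
    universe = np.asarray(genes)
    sets: dict[str, list[str]] = {}
    for s in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"SET{s:04d}"] = sorted(members.tolist())
    if planted_set is not None:
        sets[planted_name] = list(planted_set)
    return GeneSetCollection(sets)


def simulate_group_measures(
    group_means: tuple[float, ...] = CAUDATE_AMYGDALA_MEANS,
    group_sds: tuple[float, ...] = CAUDATE_AMYGDALA_SPREADS,
    group_sizes: tuple[int, ...] = (67, 52, 52),
    seed: int = 0,
    group_labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Normal per-subject measures for a multi-group design.

    Defaults mirror the caudate-amygdala connectivity comparison of the
    emulated three-group study (non-smoker, sated smoker, abstinent
    smoker). The spread parameters are taken at face value as the scale
    of the Normal draws; whether a published table's parenthesized values
    are standard deviations or standard errors is the caller's call, so
    both interpretations are expressible through ``group_sds``.
    """
    if not (len(group_means) == len(group_sds) == len(group_sizes)):
        raise ValidationError("group parameter lists must have equal length")
    if any(sd < 0 for sd in group_sds):
        raise ValidationError("group_sds must be non-negative")
    labels = group_labels or GROUP_LABELS[: len(group_means)]
    if len(labels) != len(group_means):
        raise ValidationError("group_labels length mismatch")
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for label, mu, sd, size in zip(labels, group_means, group_sds, group_sizes):
        vals = mu + sd * rng.standard_normal(size)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"sub{offset + i:05d}" for i in range(size)],
                    "group": label,
                    "value": vals,
                }
            )
        )
        offset += size
    return pd.concat(frames, ignore_index=True)
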