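"""Rank-based gene set enrichment with a permutation null.

A ranked gene list (descending -log10 GWAS p) is walked from top to
bottom; encountering a gene in the set increments a running sum by the
gene's normalized weight, a miss decrements it by 1/(N - n_hit). The
enrichment score (ES) is the signed running-sum value of largest
magnitude. With weight exponent 0 (the default, classic
Kolmogorov-Smirnov form) all hits carry equal weight and |ES| <= 1.

The null is generated by permuting gene labels over the fixed rank
positions — equivalently permuting the rank order — and recomputing ES
for every set. Normalized scores (NES) divide each positive observed ES
by the mean of that set's positive permutation ESs (negative ESs mark
sets overrepresented at the bottom of the list and receive no NES). The
permutation p-value uses the add-one convention, and the FDR of a set is
the fraction of the pooled (across sets) null NESs at or above the set's
observed NES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneSetCollection, ValidationError

log = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    """Genes ordered by non-increasing score, unique ids."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.genes.shape != self.scores.shape:
            raise ValidationError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(scores: pd.DataFrame) -> RankedGeneList:
    """Order a gene score table descending by score, ties by gene id."""
    if len(scores) == 0:
        raise ValidationError("empty gene score list")
    if scores["gene"].duplicated().any():
        raise ValidationError("duplicate gene ids in score list")
    df = scores.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    )
    return RankedGeneList(
        genes=df["gene"].to_numpy(dtype=object),
        scores=df["score"].to_numpy(dtype=float),
    )


def _weights(ranked: RankedGeneList, weight_exponent: float) -> np.ndarray:
    if weight_exponent == 0:
        return np.ones(len(ranked))
    return np.abs(ranked.scores) ** weight_exponent


def _es_batch(P: np.ndarray, w: np.ndarray, n_total: int) -> np.ndarray:
    """ES for a batch of hit-position sets.

    P : int array (batch, k) of 0-based hit positions, sorted row-wise.
    w : weight per rank position, length n_total.

    The running sum only attains its extrema immediately before or after
    a hit, so those 2k candidate values per row suffice.
    """
    batch, k = P.shape
    miss = 1.0 / (n_total - k)
    W = w[P]
    cum = np.cumsum(W, axis=1)
    tot = cum[:, -1:]
    j = np.arange(1, k + 1)
    after = cum / tot - (P + 1 - j) * miss
    before = np.concatenate([np.zeros((batch, 1)), cum[:, :-1]], axis=1) / tot - (
        P - (j - 1)
    ) * miss
    best_pos = np.maximum(after.max(axis=1), 0.0)
    best_neg = np.minimum(before.min(axis=1), 0.0)
    return np.where(best_pos >= -best_neg, best_pos, best_neg)


def enrichment_score(
    ranked: RankedGeneList,
    gene_set,
    weight_exponent: float = 0,
) -> tuple[float, np.ndarray]:
    """ES of one gene set, plus the full running-sum trace.

    Raises when the set's overlap with the ranked list is empty or is
    the whole list (the running sum is undefined in either case).
    """
    n = len(ranked)
    members = set(gene_set)
    hits = np.array([g in members for g in ranked.genes])
    k = int(hits.sum())
    if k == 0 or k == n:
        raise ValidationError(
            f"gene set overlap {k} of {n} leaves no ranked contrast"
        )
    w = _weights(ranked, weight_exponent)
    steps = np.where(hits, w / w[hits].sum(), -1.0 / (n - k))
    trace = np.cumsum(steps)
    best_pos = max(float(trace.max()), 0.0)
    best_neg = min(float(trace.min()), 0.0)
    es = best_pos if best_pos >= -best_neg else best_neg
    return es, trace


def permutation_null(
    ranked: RankedGeneList,
    gene_sets: GeneSetCollection | dict,
    n_perm: int = 10_000,
    seed: int = 0,
    weight_exponent: float = 0,
    batch_size: int = 1024,
    identity: bool = False,
) -> dict[str, np.ndarray]:
    """Null ES arrays per set under gene-label permutation.

    Every permutation reassigns all gene labels over the fixed rank
    positions simultaneously, so set nulls within one permutation share
    the relabeling. ``identity=True`` forces the identity relabeling for
    every permutation (a testing hook: the null then equals the observed
    ES).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    n = len(ranked)
    pos_of_gene = {g: i for i, g in enumerate(ranked.genes)}
    sets = gene_sets.items() if hasattr(gene_sets, "items") else gene_sets
    set_idx = {}
    for name, members in dict(sets).items():
        idx = np.array([pos_of_gene[g] for g in members if g in pos_of_gene])
        if 0 < len(idx) < n:
            set_idx[name] = idx
        else:
            log.info("set %s skipped in null: overlap %d of %d", name, len(idx), n)

    w = _weights(ranked, weight_exponent)
    out = {name: np.empty(n_perm) for name in set_idx}
    rng = np.random.default_rng(seed)
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        if identity:
            perms = np.tile(np.arange(n), (b, 1))
        else:
            perms = np.argsort(rng.random((b, n)), axis=1)
        for name, idx in set_idx.items():
            P = np.sort(perms[:, idx], axis=1)
            out[name][done : done + b] = _es_batch(P, w, n)
        done += b
    return out


def normalize_and_fdr(
    observed: dict[str, float],
    nulls: dict[str, np.ndarray],
    sizes: dict[str, int] | None = None,
    pool: bool = True,
) -> pd.DataFrame:
    """Permutation p, NES, and pooled-null FDR for observed ESs.

    p_perm uses the add-one convention (never exactly zero). NES divides
    a positive observed ES by the mean positive null ES of the same set;
    the same mean scales that set's positive null ESs into null NESs,
    which are pooled across sets for the FDR denominator (``pool=False``
    compares each set against its own null NESs only). Sets with
    non-positive ES are reported without NES or FDR.
    """
    rows = []
    null_nes_pool: list[np.ndarray] = []
    null_nes_by_set: dict[str, np.ndarray] = {}
    nes_by_set: dict[str, float] = {}
    for name, es in observed.items():
        null = np.asarray(nulls[name], dtype=float)
        if null.size == 0:
            raise ValidationError(f"empty null array for set {name!r}")
        n_perm = null.size
        # upper-tail add-one p for every set: enrichment at the top of the
        # list is the only direction of interest, so a negative observed ES
        # simply lands deep in the null's upper tail (p near 1)
        p = (1 + int(np.sum(null >= es))) / (1 + n_perm)
        if es > 0:
            pos = null[null > 0]
            if pos.size == 0:
                nes = np.nan
                log.warning("set %s has no positive null ESs; NES undefined", name)
            else:
                mean_pos = pos.mean()
                nes = es / mean_pos
                null_nes_by_set[name] = pos / mean_pos
                null_nes_pool.append(null_nes_by_set[name])
            nes_by_set[name] = nes
        else:
            nes = np.nan
        rows.append(
            {
                "set": name,
                "size": (sizes or {}).get(name, np.nan),
                "es": es,
                "nes": nes,
                "p_perm": p,
                "fdr": np.nan,
            }
        )
    pooled = (
        np.concatenate(null_nes_pool) if null_nes_pool else np.empty(0)
    )
    for row in rows:
        nes = nes_by_set.get(row["set"], np.nan)
        if not np.isfinite(nes):
            continue
        ref = pooled if pool else null_nes_by_set.get(row["set"], np.empty(0))
        if ref.size:
            row["fdr"] = float(np.mean(ref >= nes))
    df = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p_perm", "fdr"])
    return df.sort_values(
        ["fdr", "p_perm", "set"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def run_gsea(
    scores: pd.DataFrame,
    gene_sets: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int = 0,
    weight_exponent: float = 0,
    min_size: int = 10,
    max_size: int = 2000,
    pool_fdr: bool = True,
) -> pd.DataFrame:
    """Full enrichment analysis: rank, score sets, permute, normalize.

    Genes in a set but absent from the score list are dropped before
    scoring; sets whose remaining overlap falls outside
    [min_size, max_size] (or equals the whole list) are skipped with a
    logged reason. Results are sorted by FDR ascending.
    """
    ranked = rank_genes(scores)
    universe = set(ranked.genes)
    usable: dict[str, list[str]] = {}
    sizes: dict[str, int] = {}
    for name, members in gene_sets.items():
        overlap = [g for g in members if g in universe]
        if len(overlap) < len(members):
            log.info(
                "set %s: %d of %d genes absent from ranked list",
                name,
                len(members) - len(overlap),
                len(members),
            )
        if not (min_size <= len(overlap) <= max_size) or len(overlap) >= len(ranked):
            log.info("set %s skipped: overlap %d outside bounds", name, len(overlap))
            continue
        usable[name] = overlap
        sizes[name] = len(overlap)

    observed = {
        name: enrichment_score(ranked, members, weight_exponent)[0]
        for name, members in usable.items()
    }
    if not observed:
        return pd.DataFrame(columns=["set", "size", "es", "nes", "p_perm", "fdr"])
    nulls = permutation_null(
        ranked, usable, n_perm=n_perm, seed=seed, weight_exponent=weight_exponent
    )
    return normalize_and_fdr(observed, nulls, sizes, pool=pool_fdr)
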