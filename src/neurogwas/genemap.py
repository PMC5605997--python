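"""Variant-to-gene mapping and gene scoring.

Three mapping routes are provided:

* intragenic — an independently associated variant (marginal p < 0.05 and
  conditional p < 0.001) links to every gene whose body contains it
  (1-based inclusive on both boundaries; a variant inside overlapping
  genes links to all of them);
* eqtl — a nominally significant variant (marginal p < 0.05) links to a
  gene when a tissue-tagged eQTL row connects them in a requested tissue;
* proximity — sensitivity-analysis route linking an independently
  associated variant to genes within a window of the gene boundary
  (window 0 reduces to the intragenic route).

Genes are then scored with the largest -log10 marginal p over their
linked variants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ValidationError

LINK_COLUMNS = ["marker", "gene", "kind", "window", "p_gwas"]

#: proximity windows (bp) used for the sensitivity analysis
PROXIMITY_WINDOWS = (5_000, 20_000, 50_000, 100_000, 500_000, 1_000_000)


def _check_selected(selected: pd.DataFrame, p_marginal: float, p_entry: float) -> None:
    if len(selected) == 0:
        return
    if (selected["p_gwas"] >= p_marginal).any() or (
        selected["p_conditional"] >= p_entry
    ).any():
        raise ValidationError(
            "selected variants must satisfy p_gwas < "
            f"{p_marginal} and p_conditional < {p_entry}"
        )


def _marker_coords(markers: pd.DataFrame, ids) -> pd.DataFrame:
    mk = markers.set_index("marker")
    missing = [m for m in ids if m not in mk.index]
    if missing:
        raise ValidationError(f"markers absent from marker table: {missing}")
    return mk.loc[list(ids)]


def _check_chroms(marker_chroms, gene_chroms) -> None:
    mset, gset = set(map(str, marker_chroms)), set(map(str, gene_chroms))
    if mset and gset and not (mset & gset):
        raise ValidationError(
            f"chromosome naming mismatch: markers use {sorted(mset)}, "
            f"genes use {sorted(gset)}"
        )


def map_proximity(
    selected: pd.DataFrame,
    genes: pd.DataFrame,
    markers: pd.DataFrame,
    window_bp: int,
    p_marginal: float = 0.05,
    p_entry: float = 1e-3,
) -> pd.DataFrame:
    """Link selected variants to genes within ``window_bp`` of the gene body.

    Distance is base pairs to the nearest interval edge, zero for a
    variant inside the gene, so window 0 is exactly intragenic mapping.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be non-negative")
    _check_selected(selected, p_marginal, p_entry)
    rows = []
    if len(selected) and len(genes):
        coords = _marker_coords(markers, selected["marker"])
        _check_chroms(coords["chrom"], genes["chrom"])
        for (mid, p_gwas), (_, mrow) in zip(
            selected[["marker", "p_gwas"]].itertuples(index=False),
            coords.iterrows(),
        ):
            same = genes[genes["chrom"].astype(str) == str(mrow["chrom"])]
            pos = int(mrow["pos"])
            dist = np.maximum(
                np.maximum(same["start"].to_numpy() - pos, pos - same["end"].to_numpy()),
                0,
            )
            for gene in same.loc[dist <= window_bp, "gene"]:
                kind = "intragenic" if window_bp == 0 else "proximity"
                rows.append((mid, gene, kind, window_bp, p_gwas))
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def map_intragenic(
    selected: pd.DataFrame,
    genes: pd.DataFrame,
    markers: pd.DataFrame,
    p_marginal: float = 0.05,
    p_entry: float = 1e-3,
) -> pd.DataFrame:
    """Link independently associated variants to genes containing them."""
    links = map_proximity(
        selected, genes, markers, window_bp=0, p_marginal=p_marginal, p_entry=p_entry
    )
    links["kind"] = "intragenic"
    return links


def map_eqtl(
    assoc: pd.DataFrame,
    eqtls: pd.DataFrame,
    tissues: list[str],
    p_nominal: float = 0.05,
    selected: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Link nominally significant variants to genes via tissue eQTL rows.

    By design any nominal variant is eligible; passing ``selected``
    enables a strict mode restricting the route to conditionally
    selected variants.
    """
    if not tissues:
        raise ValidationError("tissue list must be non-empty")
    present = set(eqtls["tissue"]) if len(eqtls) else set()
    absent = [t for t in tissues if present and t not in present]
    if absent and len(eqtls):
        raise ValidationError(f"tissues absent from eQTL table: {absent}")
    nominal = assoc.loc[assoc["p"] < p_nominal, ["marker", "p"]]
    if selected is not None:
        nominal = nominal[nominal["marker"].isin(set(selected["marker"]))]
    merged = eqtls[eqtls["tissue"].isin(tissues)].merge(nominal, on="marker")
    out = pd.DataFrame(
        {
            "marker": merged["marker"],
            "gene": merged["gene"],
            "kind": "eqtl",
            "window": np.nan,
            "p_gwas": merged["p"],
        }
    )
    return out.drop_duplicates(subset=["marker", "gene", "kind"]).reset_index(drop=True)


def combine_links(*link_frames: pd.DataFrame) -> pd.DataFrame:
    """Union of link tables (the intragenic + eqtl design), de-duplicated."""
    frames = [f for f in link_frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=LINK_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates(subset=["marker", "gene", "kind"]).reset_index(drop=True)


def score_genes(links: pd.DataFrame, assoc: pd.DataFrame) -> pd.DataFrame:
    """Score each linked gene with its best variant association.

    score(gene) = max over the gene's linked markers of -log10(p_gwas),
    with the supporting marker recorded. The caller must floor p-values
    above zero (the association scan already floors at 1e-300); an exact
    zero is rejected because its logarithm is undefined.
    """
    if len(links) == 0:
        return pd.DataFrame(columns=["gene", "score", "marker"])
    p_by_marker = assoc.set_index("marker")["p"]
    missing = [m for m in links["marker"].unique() if m not in p_by_marker.index]
    if missing:
        raise ValidationError(f"linked markers absent from association table: {missing}")
    p = p_by_marker.loc[links["marker"]].to_numpy(dtype=float)
    if np.any(p <= 0):
        raise ValidationError("p-value of 0 encountered; floor p-values first")
    df = pd.DataFrame(
        {"gene": links["gene"].to_numpy(), "marker": links["marker"].to_numpy(),
         "score": -np.log10(p)}
    )
    df = df.sort_values(["gene", "score", "marker"], ascending=[True, False, True])
    best = df.groupby("gene", sort=True).first().reset_index()
    return best[["gene", "score", "marker"]]
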