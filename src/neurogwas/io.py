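"""File formats: VCF (dosage field), dosage TSV, phenotype TSV, BED, GMT,
eQTL tables, link/score/result TSVs.

Positions are 1-based inclusive in memory; BED's 0-based half-open
intervals are converted at read/write time. Every writer here has a
paired reader that round-trips.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    EQTL_COLUMNS,
    GENE_COLUMNS,
    GeneSetCollection,
    GenotypeMatrix,
    ValidationError,
)

_META_COLS = ["marker", "chrom", "pos", "ref", "alt", "info_score", "call_rate"]


# ---------------------------------------------------------------- genotypes

def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with per-sample dosage in FORMAT/DS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=IS,Number=1,Type=Float,Description="Imputation info score">\n'
        )
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n'
        )
        for chrom in dict.fromkeys(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(geno.sample_ids)) + "\n")
        for j, row in geno.markers.iterrows():
            d = geno.dosage[:, j]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(row["marker"]),
                str(row["ref"]),
                str(row["alt"]),
                ".",
                "PASS",
                f"IS={row['info_score']:.6g}",
                "DS",
            ]
            fields += ["." if np.isnan(v) else f"{v:.6g}" for v in d]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from VCF via cyvcf2, preferring FORMAT/DS dosages."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta_rows, dosage_cols = [], []
    for i, var in enumerate(vcf):
        try:
            alt = var.ALT[0] if var.ALT else "."
            info_score = var.INFO.get("IS")
            if info_score is None:
                info_score = 1.0
            ds = None
            try:
                ds = var.format("DS")
            except KeyError:
                ds = None
            if ds is not None:
                d = np.asarray(ds, dtype=float).reshape(-1)[: len(samples)]
                d = np.where(np.isfinite(d) & (d >= 0) & (d <= 2), d, np.nan)
            else:
                # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
                gt = np.asarray(var.gt_types)
                d = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
            dosage_cols.append(d)
            meta_rows.append(
                {
                    "marker": var.ID or f"{var.CHROM}:{var.POS}",
                    "chrom": str(var.CHROM),
                    "pos": int(var.POS),
                    "ref": var.REF,
                    "alt": alt,
                    "info_score": float(info_score),
                    "call_rate": float(np.mean(~np.isnan(d))) if len(d) else 1.0,
                }
            )
        except Exception as exc:  # noqa: BLE001 - surface the record index
            raise ValidationError(f"malformed VCF record #{i + 1}: {exc}") from exc
    markers = pd.DataFrame(meta_rows, columns=_META_COLS)
    dosage = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.empty((len(samples), 0))
    )
    geno = GenotypeMatrix(sample_ids=samples, markers=markers, dosage=dosage)
    geno.validate()
    return geno


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    dosages = pd.DataFrame(geno.dosage.T, columns=list(geno.sample_ids))
    df = pd.concat([geno.markers[_META_COLS].reset_index(drop=True), dosages], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"dosage TSV missing columns: {missing}")
    sample_ids = [c for c in df.columns if c not in _META_COLS]
    dosage = df[sample_ids].to_numpy(dtype=float).T
    geno = GenotypeMatrix(
        sample_ids=sample_ids,
        markers=df[_META_COLS].reset_index(drop=True),
        dosage=dosage,
    )
    geno.validate()
    return geno


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "dosage-tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "dosage-tsv":
        return read_dosage_tsv(path)
    raise ValidationError(f"unknown genotype format {format!r}")


# --------------------------------------------------------------- phenotypes

def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


# -------------------------------------------------------------- annotations

def write_bed(genes: pd.DataFrame, path) -> None:
    """Write 1-based inclusive gene intervals as 0-based half-open BED."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"].astype(int) - 1,
            "end": genes["end"].astype(int),
            "name": genes["gene"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name"],
        usecols=[0, 1, 2, 3],
        dtype={0: str},
    )
    genes = pd.DataFrame(
        {
            "gene": df["name"],
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(int) + 1,
            "end": df["end"].astype(int),
        }
    )
    if (genes["start"] > genes["end"]).any():
        raise ValidationError("BED interval with start > end after conversion")
    if genes["gene"].duplicated().any():
        raise ValidationError("duplicate gene ids in BED")
    return genes[GENE_COLUMNS]


def write_eqtls(eqtls: pd.DataFrame, path) -> None:
    eqtls[EQTL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_eqtls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"eQTL table missing columns: {missing}")
    if df.duplicated(subset=EQTL_COLUMNS).any():
        raise ValidationError("duplicate (marker, gene, tissue) rows in eQTL table")
    return df[EQTL_COLUMNS]


# --------------------------------------------------------------------- GMT

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then member gene ids.

    Duplicate members within a set are dropped with a warning; duplicate
    set names are an error.
    """
    import warnings

    sets: dict[str, list[str]] = {}
    descs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line {lineno}: need name, description, >=1 gene"
                )
            name, desc, *genes = parts
            genes = [g for g in genes if g]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                warnings.warn(
                    f"GMT set {name!r}: duplicate members de-duplicated",
                    stacklevel=2,
                )
            sets[name] = unique
            descs[name] = desc
    return GeneSetCollection(sets, descs)


# ----------------------------------------------------------- result tables

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_rnk(scores: pd.DataFrame, path) -> None:
    """Two-column ranked gene score file (gene, score), descending."""
    out = scores.sort_values(["score", "gene"], ascending=[False, True])
    out[["gene", "score"]].to_csv(path, sep="\t", index=False, header=False)


def read_rnk(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
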