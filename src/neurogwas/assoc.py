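"""Covariate-adjusted additive GWAS of a quantitative phenotype.

The per-marker model is ordinary least squares of the phenotype on
allelic dosage plus an intercept and covariates (group indicator and
genotype principal components by default). Estimation is vectorized
across markers by Frisch-Waugh-Lovell residualization: phenotype and
dosages are projected off the covariate space once, after which each
marker's beta, SE and t-test are simple-regression quantities with the
degrees of freedom of the full model. This is numerically identical to
fitting the full OLS model marker by marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, ValidationError, align_samples

P_FLOOR = 1e-300  # floor applied before any -log10 downstream


@dataclass
class PcMatrix:
    """Sample scores on the top genotype principal components."""

    scores: np.ndarray  # samples x k
    variance_explained: np.ndarray  # length k, fractions

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def compute_pcs(geno: GenotypeMatrix, k: int = 3) -> PcMatrix:
    """Top-k genotype principal components for stratification adjustment.

    Markers are mean-imputed, centered, and scaled by sqrt(2 f (1-f))
    (the expected binomial standard deviation under HWE); monomorphic
    markers drop out. Component signs are fixed deterministically by
    making the largest-magnitude marker loading positive.
    """
    if k < 0:
        raise ValidationError("k must be non-negative")
    n, m = geno.n_samples, geno.n_markers
    if k == 0:
        return PcMatrix(np.empty((n, 0)), np.empty(0))
    if k > min(n, m):
        raise ValidationError(f"k={k} exceeds min(n_samples, n_markers)={min(n, m)}")

    X = geno.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    if np.isnan(col_mean).any():
        raise ValidationError("all-missing markers present; run QC first")
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    f = col_mean / 2.0
    scale = np.sqrt(2.0 * f * (1.0 - f))
    keep = scale > 0
    X = (X[:, keep] - col_mean[keep]) / scale[keep]

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        raise ValidationError(f"k={k} exceeds achievable rank {rank}")

    # deterministic sign: largest-|loading| entry of each component positive
    signs = np.ones(k)
    for c in range(k):
        lead = np.argmax(np.abs(Vt[c]))
        if Vt[c, lead] < 0:
            signs[c] = -1.0
    scores = U[:, :k] * s[:k] * signs
    var_exp = (s[:k] ** 2) / np.sum(s**2)
    return PcMatrix(scores=scores, variance_explained=var_exp)


def _covariate_matrix(
    pheno: pd.DataFrame, covariates: list[str]
) -> np.ndarray:
    n = len(pheno)
    X0 = [np.ones(n)]
    for c in covariates:
        if c not in pheno.columns:
            raise ValidationError(f"covariate column {c!r} not in phenotype table")
        X0.append(pheno[c].to_numpy(dtype=float))
    X0 = np.column_stack(X0)
    rank = np.linalg.matrix_rank(X0)
    if rank < X0.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        for i in range(1, X0.shape[1]):
            if np.linalg.matrix_rank(X0[:, : i + 1]) == np.linalg.matrix_rank(X0[:, :i]):
                bad.append(covariates[i - 1])
        raise ValidationError(f"collinear covariates: {bad}")
    return X0


def gwas_linear(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-marker additive OLS association scan.

    Returns one row per marker: marker, chrom, pos, ref, alt, maf, beta,
    se, t_stat, p, n_used, monomorphic. Missing dosages are mean-imputed
    per marker; markers with zero dosage variance are flagged monomorphic
    and reported with NaN estimates and p = 1. Rows are sorted by
    chromosome and position.
    """
    covariates = covariates or []
    geno, pheno = align_samples(geno, pheno)
    n = geno.n_samples
    y = pheno["phenotype"].to_numpy(dtype=float)
    X0 = _covariate_matrix(pheno, covariates)
    p0 = X0.shape[1]
    df = n - p0 - 1
    if df <= 0:
        raise ValidationError(f"not enough samples: n={n}, model params={p0 + 1}")

    # project off covariates (FWL); Q spans the covariate column space
    Q, _ = np.linalg.qr(X0)
    y_res = y - Q @ (Q.T @ y)

    D = geno.dosage.copy()
    col_mean = np.nanmean(D, axis=0) if geno.n_markers else np.empty(0)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    D_res = D - Q @ (Q.T @ D)

    dd = np.einsum("ij,ij->j", D_res, D_res)
    dy = D_res.T @ y_res
    mono = dd <= 1e-12 * max(n, 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, np.nan, dy / dd)
        yy = float(y_res @ y_res)
        rss = yy - np.where(mono, 0.0, beta**2 * dd)
        rss = np.clip(rss, 0.0, None)
        se = np.sqrt(rss / df / dd)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(mono, 1.0, np.maximum(p, P_FLOOR))
    beta = np.where(mono, np.nan, beta)
    se = np.where(mono, np.nan, se)
    t = np.where(mono, np.nan, t)

    mafs = np.minimum(col_mean / 2.0, 1.0 - col_mean / 2.0)
    out = geno.markers[["marker", "chrom", "pos", "ref", "alt"]].copy()
    out["maf"] = mafs
    out["beta"] = beta
    out["se"] = se
    out["t_stat"] = t
    out["p"] = p
    out["n_used"] = n
    out["monomorphic"] = mono
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def qq_table(p_values) -> pd.DataFrame:
    """Observed vs expected -log10 p quantiles (QQ scatter data export)."""
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValidationError("empty p-value list")
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(np.maximum(p, P_FLOOR)),
        }
    )


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor lambda for a vector of GWAS p-values.

    Each p is back-transformed to a 1-df chi-square statistic; lambda is
    the median statistic divided by the null median (the 0.4549 quantile
    convention: chi2.ppf(0.5, 1) ~= 0.4549).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, 1))
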