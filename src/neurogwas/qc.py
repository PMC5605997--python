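"""Marker-level quality control for dosage matrices.

Filters markers on folded minor allele frequency, genotyping call rate,
an exact Hardy-Weinberg equilibrium test, and imputation info score.
Boundary semantics are literal: a marker is excluded when MAF < maf_min,
call rate < call_rate_min, HWE p < hwe_alpha, or info score <= info_min
(the info filter keeps only scores strictly greater than the threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, ValidationError


@dataclass
class QcThresholds:
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    hwe_alpha: float = 1e-4
    info_min: float = 0.9

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_alpha", "info_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QcReport:
    """Per-marker QC metrics, pass flags and failure reasons."""

    per_marker: pd.DataFrame  # marker, maf, call_rate, hwe_p, info_score, pass, reasons
    summary: dict[str, int]
    warnings: list[str]


def compute_maf(dosages: np.ndarray) -> float:
    """Folded minor allele frequency of one marker's dosage vector.

    Alt-allele frequency is mean(dosage)/2 over non-missing entries,
    folded to min(f, 1-f). NaN if every entry is missing.
    """
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    if not ok.any():
        return float("nan")
    f = float(np.mean(d[ok]) / 2.0)
    return min(f, 1.0 - f)


def hwe_exact_test(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts whose conditional probability does not
    exceed that of the observed count (the standard exact HWE test used
    for marker QC). Returns a p-value in (0, 1].
    """
    for v in (n_ref_hom, n_het, n_alt_hom):
        if v < 0 or int(v) != v:
            raise ValidationError("genotype counts must be non-negative integers")
    n_ref_hom, n_het, n_alt_hom = int(n_ref_hom), int(n_het), int(n_alt_hom)
    n = n_ref_hom + n_het + n_alt_hom
    if n == 0:
        raise ValidationError("total genotype count must be positive")

    n_rare = 2 * min(n_ref_hom, n_alt_hom) + n_het  # rare allele count
    # heterozygote counts share the parity of the rare allele count
    het_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)

    # unnormalized log-probabilities P(het | allele counts) via lgamma
    from scipy.special import gammaln

    def logprob(h):
        a = (n_rare - h) // 2  # rare homozygotes
        b = n - a - h  # common homozygotes
        return (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(a + 1)
            - gammaln(h + 1)
            - gammaln(b + 1)
        )

    lp = logprob(het_values.astype(float))
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    obs = probs[het_values == n_het]
    if obs.size == 0:  # parity mismatch cannot happen for valid counts
        raise ValidationError("inconsistent genotype counts")
    p = float(probs[probs <= obs[0] * (1 + 1e-12)].sum())
    return min(p, 1.0)


def _hard_calls(d: np.ndarray) -> tuple[np.ndarray, bool]:
    """Round dosages to {0,1,2}; report whether rounding changed anything."""
    ok = ~np.isnan(d)
    calls = np.rint(d[ok]).astype(int)
    was_soft = bool(np.any(np.abs(d[ok] - calls) > 1e-9))
    return calls, was_soft


def filter_samples(
    geno: GenotypeMatrix, call_rate_min: float = 0.95
) -> GenotypeMatrix:
    """Optional sample-level screen: drop samples with low genotyping rate.

    The cohort design applies this as an upstream inclusion criterion;
    it is exposed here for completeness.
    """
    if geno.n_markers == 0:
        return geno
    rate = 1.0 - np.mean(np.isnan(geno.dosage), axis=1)
    keep = np.flatnonzero(rate >= call_rate_min)
    return geno.subset_samples(list(keep))


def filter_markers(
    geno: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply all four marker filters; report every exclusion reason.

    MAF is computed on unrounded dosages; the HWE count table uses
    nearest-hard-call rounding (HWE is defined on genotype counts), with
    a warning recorded when rounding was needed.
    """
    thresholds = thresholds or QcThresholds()
    m = geno.n_markers
    mafs = np.empty(m)
    call_rates = np.empty(m)
    hwe_ps = np.empty(m)
    warns: list[str] = []
    rounded_any = False

    for j in range(m):
        d = geno.dosage[:, j]
        ok = ~np.isnan(d)
        call_rates[j] = ok.mean() if d.size else 0.0
        mafs[j] = compute_maf(d)
        if not ok.any():
            hwe_ps[j] = np.nan
            continue
        calls, was_soft = _hard_calls(d)
        rounded_any = rounded_any or was_soft
        hwe_ps[j] = hwe_exact_test(
            int(np.sum(calls == 0)), int(np.sum(calls == 1)), int(np.sum(calls == 2))
        )
    if rounded_any:
        msg = "continuous dosages rounded to hard calls for the HWE test"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)

    info = geno.markers["info_score"].to_numpy(dtype=float)

    reasons: list[str] = []
    passed = np.ones(m, dtype=bool)
    counts = {"maf": 0, "call_rate": 0, "hwe": 0, "info": 0, "all_missing": 0}
    for j in range(m):
        r = []
        if np.isnan(mafs[j]):
            r.append("all_missing")
            counts["all_missing"] += 1
        elif mafs[j] < thresholds.maf_min:
            r.append("maf")
            counts["maf"] += 1
        if call_rates[j] < thresholds.call_rate_min:
            r.append("call_rate")
            counts["call_rate"] += 1
        if not np.isnan(hwe_ps[j]) and hwe_ps[j] < thresholds.hwe_alpha:
            r.append("hwe")
            counts["hwe"] += 1
        if info[j] <= thresholds.info_min and thresholds.info_min > 0:
            r.append("info")
            counts["info"] += 1
        passed[j] = not r
        reasons.append(",".join(r))

    per_marker = pd.DataFrame(
        {
            "marker": geno.markers["marker"].to_numpy(),
            "maf": mafs,
            "call_rate": call_rates,
            "hwe_p": hwe_ps,
            "info_score": info,
            "pass": passed,
            "reasons": reasons,
        }
    )
    summary = {"n_markers": m, "n_pass": int(passed.sum()), **counts}
    report = QcReport(per_marker=per_marker, summary=summary, warnings=warns)
    return geno.subset_markers(passed), report
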