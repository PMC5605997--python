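"""Group statistics for ROI-pair connectivity and task activity.

Connectivity values are Fisher-transformed Pearson correlations between
region-of-interest (ROI) time courses. Group contrasts use unpaired
(Welch by default) or paired t-tests for continuous measures and Pearson
chi-square for categorical ones. Multiple testing over the family of
ROI-pair comparisons is controlled with the Benjamini-Hochberg-Yekutieli
(BY) procedure, which remains valid under arbitrary dependence between
the connectivity values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

#: the 12-ROI universe of the emulated study design
ROIS = (
    "amygdala",
    "ACC",
    "caudate",
    "GP",
    "habenula",
    "insula",
    "NAcc",
    "iPFC",
    "mPFC",
    "sPFC",
    "putamen",
    "SMA",
)


@dataclass
class GroupTestResult:
    label: str
    statistic: float
    df: float
    p: float
    kind: str  # "unpaired t" | "paired t" | "chi-square"


def fisher_z(r):
    """Fisher z-transform, z = arctanh(r); defined for |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValidationError("correlations must satisfy |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z):
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def unpaired_t(a, b, welch: bool = True, label: str = "") -> GroupTestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValidationError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupTestResult(
        label=label,
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        kind="unpaired t",
    )


def paired_t(before, after, label: str = "") -> GroupTestResult:
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValidationError("paired samples must have equal length")
    if len(before) < 2:
        raise ValidationError("need at least 2 pairs")
    diff = after - before
    if np.var(diff) == 0:
        if np.all(diff == 0):
            # no change at all: test statistic is 0 by convention
            return GroupTestResult(label, 0.0, float(len(diff) - 1), 1.0, "paired t")
        raise ValidationError("constant nonzero differences: zero variance")
    res = stats.ttest_rel(after, before)
    return GroupTestResult(
        label=label,
        statistic=float(res.statistic),
        df=float(len(diff) - 1),
        p=float(res.pvalue),
        kind="paired t",
    )


def chi_square(table, yates: bool = False, label: str = "") -> GroupTestResult:
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("contingency table has a zero margin")
    res = stats.chi2_contingency(table, correction=yates)
    return GroupTestResult(
        label=label,
        statistic=float(res.statistic),
        df=float(res.dof),
        p=float(res.pvalue),
        kind="chi-square",
    )


def by_cutoff(alpha: float, m: int) -> float:
    """Single-number BY significance cutoff: alpha / c(m), c(m) = sum 1/i.

    c(m) is the harmonic correction factor that makes the
    Benjamini-Hochberg step-up valid under arbitrary dependence. For the
    12-ROI design (m = 66 pairwise tests) at alpha = 0.05 this gives
    approximately 0.0104.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    c = np.sum(1.0 / np.arange(1, m + 1))
    return float(alpha / c)


def by_stepup(p_values, alpha: float = 0.05) -> np.ndarray:
    """Companion mode: full BY step-up rejection decisions on a p-vector."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_by")
    return reject


def roi_pair_count(n_rois: int) -> int:
    """Number of unordered ROI pairs: n(n-1)/2 (12 ROIs -> 66)."""
    if n_rois < 0:
        raise ValidationError("n_rois must be non-negative")
    return n_rois * (n_rois - 1) // 2


def roi_pair_names(rois=ROIS) -> list[str]:
    return [f"{a}-{b}" for a, b in itertools.combinations(rois, 2)]


def connectivity_from_timeseries(ts: pd.DataFrame) -> pd.Series:
    """Reference helper: Fisher-z connectivity from ROI time courses.

    ``ts`` has one column per ROI; returns a Series indexed by pair name
    with arctanh of the pairwise Pearson correlations.
    """
    corr = ts.corr(method="pearson")
    out = {}
    for a, b in itertools.combinations(ts.columns, 2):
        out[f"{a}-{b}"] = fisher_z(np.clip(corr.loc[a, b], -0.999999, 0.999999))
    return pd.Series(out)


def compare_groups(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    welch: bool = True,
) -> pd.DataFrame:
    """Per-ROI-pair unpaired t contrast of two groups with the BY cutoff.

    ``table`` is long-format with columns subject_id/group/pair/value.
    Returns one row per pair with the test result and a ``significant``
    flag at the by_cutoff(alpha, n_pairs) threshold.
    """
    for col in ("group", "pair", "value"):
        if col not in table.columns:
            raise ValidationError(f"missing column {col!r} in ROI-pair table")
    pairs = sorted(table["pair"].unique())
    cutoff = by_cutoff(alpha, len(pairs))
    rows = []
    for pair in pairs:
        sub = table[table["pair"] == pair]
        a = sub.loc[sub["group"] == group_a, "value"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "value"].to_numpy()
        res = unpaired_t(a, b, welch=welch, label=pair)
        rows.append(
            {
                "pair": pair,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p,
                "significant": res.p < cutoff,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["cutoff"] = cutoff
    return out
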