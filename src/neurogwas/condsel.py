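"""Forward-stepwise conditional selection of independent association signals.

Candidates are markers with marginal P_GWAS below ``p_marginal``. At each
step the candidate with the smallest p-value conditional on the
already-selected markers (plus covariates) is added if that p-value is
below ``p_entry``; after each addition any selected marker whose
joint-model p-value rises above ``p_entry`` is dropped again. The result
is a set of approximately independent signals, avoiding the selection of
many strongly associated markers in linkage disequilibrium. Selection is
deterministic: ties in conditional p are broken by genomic coordinate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import P_FLOOR, _covariate_matrix, gwas_linear
from .core import GenotypeMatrix, ValidationError, align_samples

log = logging.getLogger(__name__)


def _joint_pvalues(X: np.ndarray, y: np.ndarray, n_lead: int) -> np.ndarray:
    """Two-sided t-test p-values of the trailing columns of an OLS fit.

    X includes intercept/covariates as the first ``n_lead`` columns; the
    returned array covers the remaining (marker) columns.
    """
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValidationError("joint model has non-positive degrees of freedom")
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return np.maximum(pvals[n_lead:], P_FLOOR)


def stepwise_select(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    covariates: list[str] | None = None,
    p_entry: float = 1e-3,
    p_marginal: float = 0.05,
    collinearity_r2: float = 0.95,
    assoc: pd.DataFrame | None = None,
    backward: bool = True,
) -> pd.DataFrame:
    """Select independently associated markers by stepwise conditioning.

    Returns a DataFrame with columns marker, step, p_gwas, p_conditional
    (the final joint-model p-value of each retained marker). Candidates
    whose dosage is nearly collinear with the current joint model
    (R^2 > ``collinearity_r2``) are skipped with a logged reason.
    """
    covariates = covariates or []
    geno, pheno = align_samples(geno, pheno)
    if assoc is None:
        assoc = gwas_linear(geno, pheno, covariates)
    assoc = assoc.set_index("marker")

    marker_ids = geno.markers["marker"].tolist()
    p_marg = assoc.loc[marker_ids, "p"].to_numpy(dtype=float)
    order_key = {
        mid: (str(c), int(p))
        for mid, c, p in zip(
            marker_ids, geno.markers["chrom"], geno.markers["pos"]
        )
    }
    candidates = [
        j for j in range(len(marker_ids)) if p_marg[j] < p_marginal
    ]
    if not candidates:
        return pd.DataFrame(columns=["marker", "step", "p_gwas", "p_conditional"])

    y = pheno["phenotype"].to_numpy(dtype=float)
    X0 = _covariate_matrix(pheno, covariates)
    D = geno.dosage.copy()
    col_mean = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    selected: list[int] = []
    pool = set(candidates)
    while True:
        X = np.column_stack([X0] + [D[:, j] for j in selected])
        Q, _ = np.linalg.qr(X)
        y_res = y - Q @ (Q.T @ y)
        df = len(y) - X.shape[1] - 1
        if df <= 0:
            break

        best_j, best_p = None, np.inf
        cand = sorted(pool - set(selected))
        if cand:
            Dc = D[:, cand]
            Dc_res = Dc - Q @ (Q.T @ Dc)
            dd = np.einsum("ij,ij->j", Dc_res, Dc_res)
            total = np.einsum("ij,ij->j", Dc - Dc.mean(0), Dc - Dc.mean(0))
            with np.errstate(divide="ignore", invalid="ignore"):
                r2_vs_model = np.where(total > 0, 1.0 - dd / total, 1.0)
            for i, j in enumerate(cand):
                if r2_vs_model[i] > collinearity_r2 or dd[i] <= 1e-12 * len(y):
                    log.info(
                        "candidate %s skipped: collinear with current model "
                        "(R^2=%.3f)",
                        marker_ids[j],
                        r2_vs_model[i],
                    )
                    pool.discard(j)
                    continue
                b = (Dc_res[:, i] @ y_res) / dd[i]
                rss = float(y_res @ y_res) - b * b * dd[i]
                se = np.sqrt(max(rss, 0.0) / df / dd[i])
                p_cond = max(
                    2.0 * stats.t.sf(abs(b / se), df) if se > 0 else P_FLOOR,
                    P_FLOOR,
                )
                key = (p_cond, order_key[marker_ids[j]])
                if best_j is None or key < (best_p, order_key[marker_ids[best_j]]):
                    best_j, best_p = j, p_cond

        if best_j is None or best_p >= p_entry:
            break
        selected.append(best_j)

        if backward:
            while len(selected) > 1:
                X = np.column_stack([X0] + [D[:, j] for j in selected])
                p_joint = _joint_pvalues(X, y, X0.shape[1])
                worst = int(np.argmax(p_joint))
                if p_joint[worst] >= p_entry and selected[worst] != best_j:
                    dropped = selected.pop(worst)
                    pool.discard(dropped)
                    log.info(
                        "backward step dropped %s (joint p=%.3g)",
                        marker_ids[dropped],
                        p_joint[worst],
                    )
                else:
                    break

    if not selected:
        return pd.DataFrame(columns=["marker", "step", "p_gwas", "p_conditional"])

    X = np.column_stack([X0] + [D[:, j] for j in selected])
    p_joint = _joint_pvalues(X, y, X0.shape[1])
    rows = [
        {
            "marker": marker_ids[j],
            "step": step,
            "p_gwas": p_marg[j],
            "p_conditional": p_joint[step],
        }
        for step, j in enumerate(selected)
    ]
    return pd.DataFrame(rows, columns=["marker", "step", "p_gwas", "p_conditional"])
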