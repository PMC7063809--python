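"""Expression filtering and the two pre-analysis screening procedures.

``filter_top_expressed`` keeps the most highly expressed fraction of genes
(the analysis set).  ``screen_covariate_associations`` reproduces the
clinical-vs-demographic association screen (simple linear regression for
quantitative predictors, one-way ANOVA for categorical ones, raw p-values).
``pc_confounder_screen`` checks whether any demographic/clinical variable
is associated with the leading principal components of expression, with
joint Benjamini-Hochberg adjustment across all (variable x PC) tests.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .association import benjamini_hochberg
from .io import ExpressionMatrix, TraitTable

__all__ = [
    "ScreenResult",
    "filter_top_expressed",
    "screen_covariate_associations",
    "pc_confounder_screen",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ScreenResult:
    """Rows of (variable, target, test, statistic, p, p_adj)."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def filter_top_expressed(expr: ExpressionMatrix, fraction: float) -> ExpressionMatrix:
    """Retain the ceil(fraction * G) genes with the highest mean expression.

    Input row order is preserved among the retained genes; mean ties are
    broken by gene id so the retained set is deterministic.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    G = expr.n_features
    n_keep = math.ceil(fraction * G)
    means = expr.data.mean(axis=1)
    ranked = sorted(expr.feature_ids, key=lambda g: (-means[g], g))
    keep = set(ranked[:n_keep])
    retained = [g for g in expr.feature_ids if g in keep]
    return ExpressionMatrix(expr.data.loc[retained])


def _linreg_p(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Simple linear regression slope test: returns (F statistic, two-sided p)."""
    res = stats.linregress(x, y)
    # F(1, n-2) = t^2; report F to match the ANOVA column convention
    n = len(y)
    if math.isnan(res.pvalue):
        return float("nan"), float("nan")
    tstat = res.slope / res.stderr if res.stderr > 0 else float("inf")
    return float(tstat**2), float(res.pvalue)


def _anova_p(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("categorical predictor has fewer than 2 levels")
    samples = [y[groups == lv] for lv in levels]
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def screen_covariate_associations(
    traits: TraitTable, outcomes: list[str], predictors: list[str]
) -> ScreenResult:
    """Association screen between clinical outcomes and demographic predictors.

    Quantitative predictors are tested by simple linear regression,
    categorical ones by one-way ANOVA; one raw two-sided p per
    (outcome, predictor), with no multiplicity adjustment (this screen is
    read directly for its raw p-values).
    """
    rows = []
    for outcome in outcomes:
        if traits.meta[outcome].kind != "quantitative":
            raise ValueError(f"outcome {outcome!r} must be quantitative")
        y_full = pd.to_numeric(traits.data[outcome], errors="coerce")
        for pred in predictors:
            kind = traits.meta[pred].kind
            x_full = traits.data[pred]
            obs = y_full.notna() & x_full.notna()
            y = y_full[obs].to_numpy(dtype=float)
            if kind == "quantitative":
                x = pd.to_numeric(x_full[obs]).to_numpy(dtype=float)
                test = "linear_regression"
                statistic, p = _linreg_p(y, x)
            else:
                test = "anova"
                statistic, p = _anova_p(y, x_full[obs].to_numpy())
            rows.append(
                {
                    "variable": pred,
                    "target": outcome,
                    "test": test,
                    "statistic": statistic,
                    "p": p,
                    "p_adj": np.nan,
                }
            )
    return ScreenResult(table=pd.DataFrame(rows))


def _expression_pcs(expr: ExpressionMatrix, n_pcs: int) -> pd.DataFrame:
    """Leading principal-component scores of the sample x gene matrix.

    Genes are standardized (z-scored across samples) first, so every gene
    contributes on the same scale regardless of probe intensity.
    """
    x = expr.data.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not np.all(keep):
        logger.warning("dropping %d zero-variance genes before PCA", (~keep).sum())
        x = x[keep]
        sd = sd[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    # samples x genes; PCA over samples
    u, s, _ = np.linalg.svd(z.T - z.T.mean(axis=0, keepdims=True), full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(
        scores, index=expr.sample_ids, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )


def pc_confounder_screen(
    expr: ExpressionMatrix,
    traits: TraitTable,
    variables: list[str] | None = None,
    n_pcs: int = 3,
) -> ScreenResult:
    """Screen variables against the leading expression principal components.

    Each variable is tested against each PC — one-way ANOVA if categorical,
    simple linear regression if quantitative — and all raw p-values are
    BH-adjusted jointly across the (variable x PC) family.  Zero-variance
    variables are skipped with a warning.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if n_pcs >= expr.n_samples:
        raise ValueError("n_pcs must be smaller than the number of samples")
    if variables is None:
        variables = traits.trait_names
    pcs = _expression_pcs(expr, n_pcs)
    traits = traits.aligned_to(list(expr.sample_ids))
    rows = []
    for var in variables:
        kind = traits.meta[var].kind
        col = traits.data[var].reindex(pcs.index)
        if kind == "quantitative" and var in traits.zero_variance:
            logger.warning("skipping zero-variance variable %s", var)
            continue
        obs = col.notna()
        if kind == "categorical" and col[obs].nunique() < 2:
            logger.warning("skipping single-level variable %s", var)
            continue
        for pc in pcs.columns:
            y = pcs.loc[obs, pc].to_numpy(dtype=float)
            if kind == "quantitative":
                x = pd.to_numeric(col[obs]).to_numpy(dtype=float)
                test = "linear_regression"
                statistic, p = _linreg_p(y, x)
            else:
                test = "anova"
                statistic, p = _anova_p(y, col[obs].to_numpy())
            rows.append(
                {"variable": var, "target": pc, "test": test, "statistic": statistic, "p": p}
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = benjamini_hochberg(table.p.to_numpy())
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return ScreenResult(table=table)
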