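"""Module eigengenes and their association with clinical traits.

The eigengene of a module is the first principal component of the module's
gene-standardized expression across samples; it summarizes the module as a
single per-sample profile.  Module-trait association is the Pearson
correlation between each eigengene and each (covariate-adjusted) trait,
with two-sided p-values from the t transform and Benjamini-Hochberg FDR
control across all module x trait pairs.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, TraitTable

__all__ = [
    "Eigengene",
    "EigengeneSet",
    "ModuleTraitResult",
    "module_eigengene",
    "eigengene_set",
    "module_membership",
    "gene_significance",
    "adjust_trait",
    "module_trait_correlation",
    "benjamini_hochberg",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Eigengene:
    """Per-sample eigengene: unit norm, zero mean, sign-aligned.

    The sign convention makes the mean correlation with member genes
    positive, so the eigengene tracks the module's dominant direction.
    """

    values: np.ndarray
    sample_ids: pd.Index
    variance_explained: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.sample_ids)


@dataclasses.dataclass
class EigengeneSet:
    """Module -> eigengene collection sharing one sample axis."""

    eigengenes: dict[int, Eigengene]
    sample_ids: pd.Index

    def to_frame(self, colors: dict[int, str] | None = None) -> pd.DataFrame:
        rows = {}
        for label, eig in sorted(self.eigengenes.items()):
            name = colors.get(label, str(label)) if colors else str(label)
            rows[name] = eig.values
        return pd.DataFrame(rows, index=self.sample_ids).T

    @property
    def variance_explained(self) -> dict[int, float]:
        return {l: e.variance_explained for l, e in self.eigengenes.items()}


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene in module")
    return (x - mu) / sd


def module_eigengene(expr: ExpressionMatrix, module_genes: list[str]) -> Eigengene:
    """First principal component of the standardized module submatrix.

    Genes are z-scored across samples; the leading right singular vector
    gives the per-sample eigengene, centered and renormalized to unit
    Euclidean norm.  Its sign is flipped, if necessary, so the mean
    correlation with member-gene profiles is positive.
    """
    if len(module_genes) < 2:
        raise ValueError("module eigengene requires at least 2 genes")
    x = _standardize_rows(expr.data.loc[module_genes].to_numpy(dtype=float))
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    v = vt[0]
    v = v - v.mean()
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("degenerate module: eigengene has zero variance")
    v = v / norm
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    cors = _row_correlations(x, v)
    if cors.mean() < 0:
        v = -v
    return Eigengene(values=v, sample_ids=expr.sample_ids, variance_explained=var_explained)


def eigengene_set(expr: ExpressionMatrix, labels: pd.Series) -> EigengeneSet:
    """Eigengenes for every non-grey module in a labeling."""
    eigs = {}
    for label in sorted(l for l in labels.unique() if l != 0):
        genes = list(labels.index[labels == label])
        eigs[int(label)] = module_eigengene(expr, genes)
    return EigengeneSet(eigengenes=eigs, sample_ids=expr.sample_ids)


def _row_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of x with vector y."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(yc)
    with np.errstate(invalid="ignore"):
        r = (xc @ yc) / denom
    return np.clip(r, -1.0, 1.0)


def module_membership(expr: ExpressionMatrix, eigengenes: EigengeneSet) -> pd.DataFrame:
    """kME matrix: correlation of every gene with every module eigengene."""
    x = expr.data.to_numpy(dtype=float)
    out = {}
    for label, eig in sorted(eigengenes.eigengenes.items()):
        out[label] = _row_correlations(x, eig.values)
    return pd.DataFrame(out, index=expr.feature_ids)


def gene_significance(expr: ExpressionMatrix, trait: pd.Series) -> pd.Series:
    """GS_g = |cor(x_g, trait)| on pairwise-complete samples."""
    trait = trait.reindex(expr.sample_ids)
    mask = trait.notna().to_numpy()
    if mask.sum() < 3:
        raise ValueError("gene significance needs >= 3 overlapping samples")
    t = trait.to_numpy(dtype=float)[mask]
    if np.std(t) == 0:
        raise ValueError("trait has zero variance")
    x = expr.data.to_numpy(dtype=float)[:, mask]
    return pd.Series(np.abs(_row_correlations(x, t)), index=expr.feature_ids)


def adjust_trait(trait: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """Residualize a trait on intercept + covariates by ordinary least squares.

    Categorical covariates must already be 0/1 encoded.  Missing trait
    values propagate as missing; samples missing any covariate are dropped
    from the fit and returned missing.
    """
    covariates = covariates.reindex(trait.index)
    obs = trait.notna() & covariates.notna().all(axis=1)
    y = trait[obs].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(obs.sum()), covariates.loc[obs].to_numpy(dtype=float)]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    out = pd.Series(np.nan, index=trait.index, dtype=float)
    out[obs] = y - X @ beta
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    For ascending order statistics p_(1) <= ... <= p_(m),
    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, returned in the
    original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _encode_covariates(traits: TraitTable, names: list[str]) -> pd.DataFrame:
    """0/1-encode categorical covariates (reference level alphabetically first)."""
    cols = {}
    for name in names:
        if name not in traits.data.columns:
            raise KeyError(f"covariate {name!r} not in trait table")
        col = traits.data[name]
        meta = traits.meta.get(name)
        if meta is not None and meta.kind == "categorical":
            levels = sorted(col.dropna().unique(), key=str)
            for level in levels[1:]:
                cols[f"{name}[{level}]"] = (col == level).astype(float).where(col.notna())
        else:
            cols[name] = pd.to_numeric(col, errors="coerce")
    return pd.DataFrame(cols, index=traits.data.index)


@dataclasses.dataclass
class ModuleTraitResult:
    """Per (module, trait) correlation with raw and BH-adjusted p-values."""

    table: pd.DataFrame  # columns: module, color, trait, r, p, p_adj, n_used, covariates_adjusted
    fdr_alpha: float = 0.05
    bh_family: str = "matrix"  # "matrix" (all pairs) or "per_trait"

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table.p_adj < self.fdr_alpha]

    def heatmap_long(self) -> pd.DataFrame:
        """Long-format table ready for a module x trait heatmap."""
        cols = ["module", "color", "trait", "r", "p", "p_adj"]
        return self.table[cols].copy()


def module_trait_correlation(
    eigengenes: EigengeneSet,
    traits: TraitTable,
    colors: dict[int, str] | None = None,
    fdr_alpha: float = 0.05,
    bh_family: str = "matrix",
) -> ModuleTraitResult:
    """Correlate every module eigengene with every quantitative trait.

    Each trait is first residualized on its declared adjustment covariates.
    Pearson r is computed on overlapping (pairwise-complete) samples; the
    two-sided p comes from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2
    degrees of freedom; BH adjustment is applied across all module x trait
    pairs (or per trait with ``bh_family="per_trait"``).
    """
    if bh_family not in ("matrix", "per_trait"):
        raise ValueError("bh_family must be 'matrix' or 'per_trait'")
    sample_ids = eigengenes.sample_ids
    rows = []
    for trait_name in traits.quantitative():
        meta = traits.meta[trait_name]
        if trait_name in traits.zero_variance:
            logger.warning("skipping zero-variance trait %s", trait_name)
            continue
        raw = pd.to_numeric(traits.data[trait_name], errors="coerce")
        if meta.adjustment_covariates:
            cov = _encode_covariates(traits, meta.adjustment_covariates)
            values = adjust_trait(raw, cov)
        else:
            values = raw
        values = values.reindex(sample_ids)
        mask = values.notna().to_numpy()
        n_used = int(mask.sum())
        if n_used < 4:
            logger.warning("skipping %s: fewer than 4 overlapping samples", trait_name)
            continue
        t_arr = values.to_numpy(dtype=float)[mask]
        if np.std(t_arr) == 0:
            logger.warning("skipping %s: zero variance after adjustment", trait_name)
            continue
        for label, eig in sorted(eigengenes.eigengenes.items()):
            e = eig.values[mask]
            r = float(np.clip(np.corrcoef(e, t_arr)[0, 1], -1.0, 1.0))
            if abs(r) == 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt((n_used - 2) / (1.0 - r**2))
                p = float(2.0 * stats.t.sf(abs(tstat), df=n_used - 2))
            rows.append(
                {
                    "module": label,
                    "color": (colors or {}).get(label, str(label)),
                    "trait": trait_name,
                    "r": r,
                    "p": p,
                    "n_used": n_used,
                    "covariates_adjusted": ",".join(meta.adjustment_covariates),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["module", "color", "trait", "r", "p", "n_used", "covariates_adjusted"],
    )
    if len(table):
        if bh_family == "matrix":
            table["p_adj"] = benjamini_hochberg(table.p.to_numpy())
        else:
            table["p_adj"] = np.nan
            for trait_name in table.trait.unique():
                sel = table.trait == trait_name
                table.loc[sel, "p_adj"] = benjamini_hochberg(table.loc[sel, "p"].to_numpy())
    else:
        table["p_adj"] = pd.Series(dtype=float)
    table = table[
        ["module", "color", "trait", "r", "p", "p_adj", "n_used", "covariates_adjusted"]
    ]
    return ModuleTraitResult(table=table, fdr_alpha=fdr_alpha, bh_family=bh_family)
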