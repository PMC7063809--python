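"""Unsigned weighted co-expression network construction.

Pearson correlation -> unsigned power adjacency a_ij = |r_ij|**beta ->
connectivity, scale-free-topology fit for soft-threshold selection, and the
topological overlap matrix (TOM) whose complement is the clustering
dissimilarity.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "TOMMatrix",
    "ScaleFreeFit",
    "pairwise_correlation",
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_soft_threshold",
    "select_power",
    "topological_overlap",
]

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    pass


@dataclasses.dataclass
class CorrelationMatrix:
    """Symmetric gene-gene Pearson correlation matrix, unit diagonal."""

    values: np.ndarray
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        np.fill_diagonal(self.values, 1.0)


@dataclasses.dataclass
class AdjacencyMatrix:
    """Unsigned adjacency |r|**power; the diagonal is excluded from sums."""

    values: np.ndarray
    gene_ids: pd.Index
    power: int


@dataclasses.dataclass
class TOMMatrix:
    """Topological overlap similarity in [0, 1] with unit diagonal."""

    values: np.ndarray
    gene_ids: pd.Index


@dataclasses.dataclass
class ScaleFreeFit:
    """Log-log linearity of the binned connectivity distribution."""

    power: int
    r_squared: float
    slope: float
    mean_connectivity: float


def pairwise_correlation(expr: ExpressionMatrix) -> CorrelationMatrix:
    """Pearson correlation across samples for every gene pair.

    Requires at least 3 samples and no zero-variance gene (a constant gene
    has undefined correlation and would poison the whole matrix).
    """
    if expr.n_samples < 3:
        raise ValueError("pairwise correlation needs at least 3 samples")
    x = expr.data.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = expr.feature_ids[np.flatnonzero(sd == 0)[0]]
        raise ZeroVarianceError(f"gene {bad!r} has zero variance across samples")
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    return CorrelationMatrix(values=r, gene_ids=expr.feature_ids)


def adjacency(
    cor: CorrelationMatrix, power: int, network_type: str = "unsigned"
) -> AdjacencyMatrix:
    """Unsigned soft-threshold adjacency a_ij = |r_ij|**power."""
    if network_type != "unsigned":
        raise NotImplementedError("only unsigned networks are supported")
    if not (isinstance(power, (int, np.integer)) and power >= 1):
        raise ValueError("power must be a positive integer")
    a = np.abs(cor.values) ** power
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(values=a, gene_ids=cor.gene_ids, power=int(power))


def connectivity(adj: AdjacencyMatrix) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def scale_free_fit(k: np.ndarray, n_bins: int = 10, power: int = 0) -> ScaleFreeFit:
    """Fit of log10 p(k) against log10 k over equal-width connectivity bins.

    A scale-free network gives a straight line with negative slope; R**2 of
    that regression is the selection criterion for the soft threshold.
    """
    k = np.asarray(k, dtype=float)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if np.any(k < 0):
        raise ValueError("connectivities must be non-negative")
    if np.unique(k).size < 2:
        raise ValueError("all connectivities identical; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_p, log_k = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        log_p.append(np.log10(members.size / k.size))
        log_k.append(np.log10(members.mean()))
    log_p, log_k = np.asarray(log_p), np.asarray(log_k)
    if log_k.size < 2 or np.ptp(log_k) == 0:
        raise ValueError("too few occupied bins for a scale-free fit")
    slope, intercept = np.polyfit(log_k, log_p, 1)
    fitted = slope * log_k + intercept
    ss_res = float(np.sum((log_p - fitted) ** 2))
    ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ScaleFreeFit(
        power=power,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        slope=float(slope),
        mean_connectivity=float(k.mean()),
    )


def pick_soft_threshold(
    expr: ExpressionMatrix,
    candidate_powers: list[int] | None = None,
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    Returns the smallest candidate whose fit reaches ``r2_target`` with a
    negative slope; if none qualifies, falls back to the candidate with the
    maximal R**2 (with a warning) so a network can still be built.
    """
    if candidate_powers is None:
        candidate_powers = list(range(1, 13))
    if not candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    cor = pairwise_correlation(expr)
    fits = []
    for p in candidate_powers:
        k = connectivity(adjacency(cor, p))
        try:
            fits.append(scale_free_fit(k, n_bins=n_bins, power=p))
        except ValueError:
            fits.append(ScaleFreeFit(p, 0.0, 0.0, float(k.mean())))
    table = pd.DataFrame(
        {
            "power": [f.power for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "slope": [f.slope for f in fits],
            "mean_connectivity": [f.mean_connectivity for f in fits],
        }
    )
    return select_power(table, r2_target), table


def select_power(table: pd.DataFrame, r2_target: float = 0.8) -> int:
    """Selection rule: smallest power with R**2 >= target and negative slope;
    otherwise the power with maximal R**2 (with a warning)."""
    ok = table[(table.r_squared >= r2_target) & (table.slope < 0)]
    if len(ok):
        return int(ok.power.iloc[0])
    chosen = int(table.power.iloc[int(table.r_squared.idxmax())])
    msg = (
        f"no candidate power reached R^2 >= {r2_target}; "
        f"falling back to power {chosen} (max R^2 = {table.r_squared.max():.3f})"
    )
    logger.warning(msg)
    warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return chosen


def topological_overlap(adj: AdjacencyMatrix) -> TOMMatrix:
    """Unsigned topological overlap.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    l_ij = sum_{u != i,j} a_iu a_uj counts shared-neighbor strength, and
    TOM_ii = 1.  For adjacencies in [0, 1] the denominator stays positive;
    a saturated pair (denominator 0) is mapped to its limit TOM = 1.
    """
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # (a@a)_ij sums over all u; diagonal zeros drop u = i, j
    num = l + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    return TOMMatrix(values=tom, gene_ids=adj.gene_ids)
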