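"""Hub-gene identification by thresholded topological overlap.

Two genes are "connected" when their TOM similarity exceeds the matrix-wide
95% quantile (computed over the upper-triangle off-diagonal entries; the
unit diagonal would otherwise bias the quantile upward).  A gene's
intramodular connectivity is the number of same-module genes it is
connected to, and hubs are the top 10% of each module by that count.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .modules import ModulePartition
from .network import TOMMatrix

__all__ = [
    "HubResult",
    "tom_quantile_cutoff",
    "intramodular_connectivity",
    "identify_hubs",
]


@dataclasses.dataclass
class HubResult:
    """Connectivity counts and hub membership per module."""

    counts: pd.DataFrame  # gene_id, module, color, connectivity
    hubs: dict[int, list[str]]
    threshold: float
    quantile: float
    top_fraction: float
    ties: dict[int, bool] = dataclasses.field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        hub_sets = {g for genes in self.hubs.values() for g in genes}
        out = self.counts.copy()
        out["is_hub"] = out.gene_id.isin(hub_sets)
        out["threshold"] = self.threshold
        out["quantile"] = self.quantile
        return out


def tom_quantile_cutoff(tom: TOMMatrix, q: float = 0.95) -> float:
    """Empirical q-quantile (linear interpolation) of the off-diagonal TOM.

    Only upper-triangle entries enter; each unordered pair is counted once.
    """
    if not (0 < q < 1):
        raise ValueError("quantile level must be in (0, 1)")
    iu = np.triu_indices_from(tom.values, k=1)
    vals = tom.values[iu]
    if vals.size == 0:
        raise ValueError("TOM has no off-diagonal entries")
    return float(np.quantile(vals, q, method="linear"))


def intramodular_connectivity(
    tom: TOMMatrix, partition: ModulePartition, threshold: float
) -> pd.DataFrame:
    """Count same-module connections above the threshold for every gene.

    Gene i connects to gene j iff TOM_ij > threshold (strict) and both
    carry the same non-grey module label.  Grey genes are excluded.
    """
    labels = partition.labels.reindex(tom.gene_ids)
    if labels.isna().any():
        raise ValueError("partition does not cover all TOM genes")
    lab = labels.to_numpy(dtype=int)
    connected = tom.values > threshold
    np.fill_diagonal(connected, False)
    rows = []
    for module in partition.module_labels:
        idx = np.flatnonzero(lab == module)
        sub = connected[np.ix_(idx, idx)]
        counts = sub.sum(axis=1)
        for i, g in zip(idx, counts):
            rows.append(
                {
                    "gene_id": tom.gene_ids[i],
                    "module": module,
                    "color": partition.color_of(module),
                    "connectivity": int(g),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "module", "color", "connectivity"])


def identify_hubs(
    counts: pd.DataFrame,
    top_fraction: float = 0.10,
    modules: list[int] | None = None,
    pooled: bool = False,
) -> tuple[dict[int, list[str]], dict[int, bool]]:
    """Select the top-``top_fraction`` most connected genes per module.

    Genes are ranked by connectivity descending, ties broken by gene id;
    each module contributes ceil(top_fraction * module_size) hubs (so
    every module of at least a few genes yields at least one).  With
    ``pooled=True`` the fraction is applied to all candidate-module genes
    jointly instead of per module.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if modules is not None:
        counts = counts[counts.module.isin(modules)]
    hubs: dict[int, list[str]] = {}
    ties: dict[int, bool] = {}
    if pooled:
        ranked = counts.sort_values(
            ["connectivity", "gene_id"], ascending=[False, True]
        )
        n_top = math.ceil(top_fraction * len(ranked))
        chosen = ranked.head(n_top)
        for module, grp in chosen.groupby("module"):
            hubs[int(module)] = list(grp.gene_id)
            ties[int(module)] = False
        return hubs, ties
    for module, grp in counts.groupby("module"):
        if len(grp) == 0:
            continue
        ranked = grp.sort_values(["connectivity", "gene_id"], ascending=[False, True])
        n_top = math.ceil(top_fraction * len(ranked))
        cutoff_count = ranked.connectivity.iloc[n_top - 1]
        tied = (ranked.connectivity == cutoff_count).sum() > (
            (ranked.connectivity.iloc[:n_top] == cutoff_count).sum()
        )
        hubs[int(module)] = list(ranked.gene_id.iloc[:n_top])
        ties[int(module)] = bool(tied)
    return hubs, ties


def hub_analysis(
    tom: TOMMatrix,
    partition: ModulePartition,
    quantile: float = 0.95,
    top_fraction: float = 0.10,
    modules: list[int] | None = None,
    pooled: bool = False,
) -> HubResult:
    """Full hub procedure: quantile cutoff -> connectivity -> top fraction."""
    threshold = tom_quantile_cutoff(tom, quantile)
    counts = intramodular_connectivity(tom, partition, threshold)
    hubs, ties = identify_hubs(counts, top_fraction, modules=modules, pooled=pooled)
    return HubResult(
        counts=counts,
        hubs=hubs,
        threshold=threshold,
        quantile=quantile,
        top_fraction=top_fraction,
        ties=ties,
    )
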