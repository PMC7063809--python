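"""Module detection: TOM dissimilarity, average-linkage clustering,
dynamic tree cut, eigengene-based module merging and color labeling.

The tree cut is a dynamic hybrid variant: an adaptive static cut near the
top of the merge-height range yields branches; branches are then
decomposed further (bounded recursive splitting into sub-branches that
each satisfy the size floor), undersized clusters dissolve to the grey
(unassigned) class, and a PAM-like stage assigns outlying genes to the
nearest module medoid.  Over-splitting is corrected by the eigengene
merge step, which fuses modules whose eigengenes are closer than
``merge_cut_height`` in 1 - correlation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix
from .network import TOMMatrix

__all__ = [
    "Dendrogram",
    "ModulePartition",
    "STANDARD_COLORS",
    "tom_dissimilarity",
    "hierarchical_cluster",
    "cut_tree_dynamic",
    "refine_membership",
    "merge_close_modules",
    "assign_colors",
]


# The conventional module color sequence, assigned to modules in decreasing
# size order; position 0 is the largest module.  Grey is reserved for
# unassigned genes and never appears here.
STANDARD_COLORS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
    "lightsteelblue1",
)


@dataclasses.dataclass
class Dendrogram:
    """Agglomerative tree: scipy linkage matrix plus the leaf identifiers."""

    linkage: np.ndarray
    gene_ids: pd.Index

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        return np.asarray(hierarchy.leaves_list(self.linkage))

    def to_newick(self) -> str:
        """Export the tree in Newick form (branch lengths from merge heights)."""
        tree = hierarchy.to_tree(self.linkage)
        names = list(self.gene_ids)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


@dataclasses.dataclass
class ModulePartition:
    """Gene -> module labeling; label 0 ("grey") is the unassigned class.

    Non-zero labels are 1..K in decreasing size order and carry the
    standard color names.
    """

    labels: pd.Series  # gene id -> int label
    colors: dict[int, str]

    def __post_init__(self) -> None:
        if 0 not in self.colors:
            self.colors[0] = "grey"

    @property
    def module_labels(self) -> list[int]:
        return sorted(l for l in self.labels.unique() if l != 0)

    @property
    def n_modules(self) -> int:
        return len(self.module_labels)

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> dict[int, int]:
        return {l: int((self.labels == l).sum()) for l in self.module_labels}

    def color_of(self, label: int) -> str:
        return self.colors.get(label, f"module_{label}")

    def to_frame(self) -> pd.DataFrame:
        sizes = self.sizes()
        return pd.DataFrame(
            {
                "gene_id": self.labels.index,
                "label": self.labels.to_numpy(),
                "color": [self.color_of(l) for l in self.labels],
                "module_size": [sizes.get(l, 0) for l in self.labels],
            }
        )


def tom_dissimilarity(tom: TOMMatrix) -> np.ndarray:
    """d_ij = 1 - TOM_ij with a zero diagonal."""
    d = 1.0 - tom.values
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, 1.0, out=d)
    return d


def hierarchical_cluster(
    diss: np.ndarray, gene_ids: pd.Index | None = None, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a dissimilarity matrix (average linkage).

    scipy's implementation is deterministic; ties resolve to the smallest
    cluster index.
    """
    diss = np.asarray(diss, dtype=float)
    if diss.ndim != 2 or diss.shape[0] != diss.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    n = diss.shape[0]
    if gene_ids is None:
        gene_ids = pd.Index([f"g{i}" for i in range(n)])
    if n == 1:
        return Dendrogram(linkage=np.empty((0, 4)), gene_ids=pd.Index(gene_ids))
    condensed = squareform((diss + diss.T) / 2.0, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(linkage=Z, gene_ids=pd.Index(gene_ids))


def _forced_split(node, min_module_size: int, depth: int) -> list[list[int]]:
    """Decompose a branch into sub-branches.

    Undersized side-branches ("stragglers" hanging near the branch top) are
    peeled off so they cannot block a genuine split; where both children
    satisfy the size floor the branch splits, up to ``depth`` levels.
    """
    pieces: list[list[int]] = []

    def descend(nd, d: int) -> None:
        while True:
            if nd.is_leaf():
                pieces.append([nd.id])
                return
            left, right = nd.left, nd.right
            # a split or peel is justified only when the join sits strictly
            # above the children's own merges (tied heights = one flat block)
            separated = nd.dist > max(left.dist, right.dist) + 1e-12
            if not separated:
                pieces.append(nd.pre_order(lambda leaf: leaf.id))
                return
            lc, rc = left.get_count(), right.get_count()
            if lc >= min_module_size and rc >= min_module_size:
                if d > 0:
                    descend(left, d - 1)
                    descend(right, d - 1)
                else:
                    pieces.append(nd.pre_order(lambda leaf: leaf.id))
                return
            if lc < min_module_size and rc < min_module_size:
                pieces.append(nd.pre_order(lambda leaf: leaf.id))
                return
            small, big = (left, right) if lc < rc else (right, left)
            pieces.append(small.pre_order(lambda leaf: leaf.id))
            nd = big  # keep peeling inside the dominant sub-branch

    descend(node, depth)
    return pieces


def cut_tree_dynamic(
    dendrogram: Dendrogram,
    diss: np.ndarray,
    min_module_size: int = 10,
    cut_height: float | None = None,
    deep_split: int = 2,
    pam_stage: bool = True,
    method: str = "hybrid",
) -> pd.Series:
    """Cut the dendrogram into initial module labels (0 = unassigned).

    ``hybrid``: cut at ``cut_height`` (default: 99% of the merge-height
    range above the lowest merge), decompose each resulting branch by up to
    ``deep_split`` forced binary splits whose pieces all satisfy the size
    floor, dissolve undersized clusters to 0, then assign unassigned genes
    to the nearest module medoid when within that module's radius.
    ``static``: plain height cut plus size floor.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = dendrogram.gene_ids
    n = len(genes)
    if min_module_size > n:
        warnings.warn(
            "min_module_size exceeds the number of genes; all genes unassigned",
            RuntimeWarning,
            stacklevel=2,
        )
        return pd.Series(np.zeros(n, dtype=int), index=genes)
    heights = dendrogram.heights
    if cut_height is None:
        h_min, h_max = float(heights.min()), float(heights.max())
        cut_height = h_min + 0.99 * (h_max - h_min)

    tree = hierarchy.to_tree(dendrogram.linkage)
    # branches entirely below the cut height
    branches: list[list[int]] = []

    def collect(node) -> None:
        if node.is_leaf() or node.dist <= cut_height:
            if method == "hybrid":
                branches.extend(_forced_split(node, min_module_size, deep_split))
            else:
                branches.append(node.pre_order(lambda leaf: leaf.id))
        else:
            collect(node.left)
            collect(node.right)

    collect(tree)

    labels = np.zeros(n, dtype=int)
    kept = [b for b in branches if len(b) >= min_module_size]
    for lab, branch in enumerate(sorted(kept, key=lambda b: (-len(b), min(b))), start=1):
        labels[branch] = lab

    if method == "hybrid" and pam_stage and kept:
        labels = _pam_assign(labels, np.asarray(diss, dtype=float))
    return pd.Series(labels, index=genes)


def _pam_assign(labels: np.ndarray, diss: np.ndarray) -> np.ndarray:
    """Assign unassigned genes to the nearest module medoid, within radius."""
    labels = labels.copy()
    module_ids = [l for l in np.unique(labels) if l != 0]
    medoids: dict[int, int] = {}
    radii: dict[int, float] = {}
    for l in module_ids:
        idx = np.flatnonzero(labels == l)
        mean_d = diss[np.ix_(idx, idx)].mean(axis=1)
        medoid = idx[int(np.argmin(mean_d))]
        medoids[l] = medoid
        # median member-to-medoid distance: a conservative cluster radius that
        # does not inflate when a branch carries stragglers
        radii[l] = float(np.median(diss[idx, medoid]))
    for g in np.flatnonzero(labels == 0):
        best_l, best_d = 0, np.inf
        for l in module_ids:
            d = diss[g, medoids[l]]
            if d < best_d:
                best_l, best_d = l, d
        if best_l != 0 and best_d <= radii[best_l]:
            labels[g] = best_l
    return labels


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Renumber modules 1..K in decreasing size (ties by old label)."""
    sizes = labels[labels != 0].value_counts()
    order = sorted(sizes.index, key=lambda l: (-sizes[l], l))
    remap = {old: new for new, old in enumerate(order, start=1)}
    remap[0] = 0
    return labels.map(remap)


def assign_colors(labels: pd.Series) -> dict[int, str]:
    """Map size-ranked module labels to the standard color sequence.

    Modules beyond the color list fall back to numbered names.  Label 0 is
    always grey.
    """
    sizes = labels[labels != 0].value_counts()
    order = sorted(sizes.index, key=lambda l: (-sizes[l], l))
    colors: dict[int, str] = {0: "grey"}
    for rank, lab in enumerate(order):
        if rank < len(STANDARD_COLORS):
            colors[int(lab)] = STANDARD_COLORS[rank]
        else:
            colors[int(lab)] = f"module_{lab}"
    return colors


def _critical_correlation(n: int, alpha: float) -> float:
    """|r| needed for two-sided significance at level alpha with n samples."""
    from scipy import stats

    tcrit = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(tcrit / np.sqrt(n - 2 + tcrit**2))


def refine_membership(
    expr: ExpressionMatrix,
    labels: pd.Series,
    min_module_size: int = 10,
    alpha: float = 0.01,
    max_iter: int = 3,
) -> pd.Series:
    """Iteratively re-assign genes by module membership (kME).

    Each gene goes to the module whose eigengene it correlates with most
    strongly, provided that correlation clears the module's admission
    threshold: the larger of (a) the critical |r| for two-sided
    significance at level ``alpha`` given the sample size, and (b) the
    module's median member |kME| minus two Fisher-z standard errors — so a
    tight module (members all near |kME| = 1) does not accept loosely
    attached genes that a diffuse module would, while a module whose
    coherence is within sampling noise of the significance floor admits at
    the floor.  Genes clearing no threshold become grey.  This sharpens
    branch assignments (a gene placed on the wrong branch usually has a
    higher kME to its true module) and strips stragglers that joined a
    branch by chance.  Modules falling under the size floor dissolve.
    Converges in a few iterations; deterministic.
    """
    from .association import eigengene_set, module_membership

    labels = labels.copy()
    n = expr.n_samples
    r_crit = _critical_correlation(n, alpha)
    z_se = 1.0 / np.sqrt(max(n - 3, 1))
    for _ in range(max_iter):
        module_ids = sorted(l for l in labels.unique() if l != 0)
        if not module_ids:
            return labels
        eigs = eigengene_set(expr, labels)
        kme = module_membership(expr, eigs).abs()
        thresholds = {}
        for l in module_ids:
            med = float(kme.loc[labels == l, l].median())
            coherent = np.tanh(np.arctanh(min(med, 1.0 - 1e-12)) - 2.0 * z_se)
            thresholds[l] = max(r_crit, coherent)
        best = kme.idxmax(axis=1)
        best_val = kme.max(axis=1)
        admit = np.array(
            [v >= thresholds[b] for b, v in zip(best, best_val)], dtype=bool
        )
        new = pd.Series(
            np.where(admit, best, 0), index=labels.index, dtype=int
        )
        for l in module_ids:
            if (new == l).sum() < min_module_size:
                new[new == l] = 0
        if new.equals(labels):
            break
        labels = new
    return labels


def merge_close_modules(
    expr: ExpressionMatrix,
    labels: pd.Series,
    merge_cut_height: float = 0.25,
    max_iter: int = 20,
) -> ModulePartition:
    """Fuse modules whose eigengenes are closer than ``merge_cut_height``.

    Eigengenes are recomputed each round; modules joined below the height
    in an average-linkage tree of 1 - cor(eigengene) dissimilarities are
    merged, until no pair remains below the threshold.
    """
    from .association import module_eigengene  # local import avoids cycle at import time

    if not (0 < merge_cut_height < 1):
        raise ValueError("merge_cut_height must be in (0, 1)")
    labels = labels.copy()
    for _ in range(max_iter):
        module_ids = sorted(l for l in labels.unique() if l != 0)
        if len(module_ids) < 2:
            break
        eigs = np.column_stack(
            [
                module_eigengene(expr, list(labels.index[labels == l])).values
                for l in module_ids
            ]
        )
        cor = np.corrcoef(eigs.T)
        d = 1.0 - cor
        np.fill_diagonal(d, 0.0)
        np.clip(d, 0.0, None, out=d)
        Z = hierarchy.linkage(squareform((d + d.T) / 2.0, checks=False), "average")
        groups = hierarchy.fcluster(Z, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(module_ids):
            break
        remap = {}
        for g in np.unique(groups):
            members = [module_ids[i] for i in np.flatnonzero(groups == g)]
            target = min(members)
            for m in members:
                remap[m] = target
        remap[0] = 0
        labels = labels.map(remap)
    labels = _relabel_by_size(labels)
    return ModulePartition(labels=labels, colors=assign_colors(labels))
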