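"""Statsmodels-style front end: the :class:`WGCNA` model and its results.

The model is constructed from a gene x sample expression matrix and an
optional clinical trait table; ``fit()`` runs the full analysis —
top-expression filtering, soft-threshold selection (or the fixed default
power), unsigned adjacency, topological overlap, average-linkage
clustering with a dynamic tree cut, eigengene merging, module-trait
correlation with BH FDR, and hub identification — and returns a
:class:`WGCNAResults` carrying every stage's output plus a ``summary()``
table.  The analysis is fully deterministic: identical inputs and
configuration give identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (
    EigengeneSet,
    ModuleTraitResult,
    eigengene_set,
    module_membership,
    module_trait_correlation,
)
from .hubs import HubResult, hub_analysis
from .io import ExpressionMatrix, TraitTable
from .modules import (
    Dendrogram,
    ModulePartition,
    cut_tree_dynamic,
    hierarchical_cluster,
    merge_close_modules,
    refine_membership,
    tom_dissimilarity,
)
from .network import (
    TOMMatrix,
    adjacency,
    pairwise_correlation,
    pick_soft_threshold,
    topological_overlap,
)
from .preprocess import filter_top_expressed

__all__ = ["WGCNA", "WGCNAResults", "PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Analysis parameterization; the defaults are the reference protocol:

    top 30% of genes by mean expression, unsigned network at power 7
    (or scale-free auto-selection), minModuleSize 10, mergeCutHeight 0.25,
    module reassignment disabled, hub threshold at the TOM 95% quantile,
    hubs = top 10% by intramodular connectivity, FDR alpha 0.05.
    """

    expression_fraction: float = 0.30
    power: int | str = 7  # integer, or "auto" for scale-free selection
    network_type: str = "unsigned"
    min_module_size: int = 10
    merge_cut_height: float = 0.25
    deep_split: int = 2
    pam_stage: bool = True
    membership_alpha: float | None = 0.01  # kME refinement; None disables
    hub_quantile: float = 0.95
    hub_top_fraction: float = 0.10
    fdr_alpha: float = 0.05
    bh_family: str = "matrix"
    r2_target: float = 0.8
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class WGCNA:
    """Weighted gene co-expression network model for one expression study.

    Parameters
    ----------
    expr : ExpressionMatrix
        Gene x sample (log-scale) expression, already collapsed to genes.
    traits : TraitTable, optional
        Clinical traits; quantitative traits are correlated with module
        eigengenes after their declared covariate adjustment.
    config : PipelineConfig, optional
        Analysis parameters; defaults are the reference protocol.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        traits: TraitTable | None = None,
        config: PipelineConfig | None = None,
    ):
        self.expr = expr
        self.traits = traits.aligned_to(list(expr.sample_ids)) if traits else None
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(
        cls,
        expr: pd.DataFrame,
        traits: TraitTable | None = None,
        **config_kwargs,
    ) -> "WGCNA":
        return cls(
            ExpressionMatrix(expr), traits, PipelineConfig(**config_kwargs)
        )

    def fit(self) -> "WGCNAResults":
        cfg = self.config
        timings: dict[str, float] = {}

        def stage(name):
            timings[name] = time.perf_counter()

        def done(name):
            timings[name] = time.perf_counter() - timings[name]
            logger.info("stage %s finished in %.2fs", name, timings[name])

        stage("filter")
        filtered = filter_top_expressed(self.expr, cfg.expression_fraction)
        done("filter")

        stage("soft_threshold")
        if cfg.power == "auto":
            power, sft_table = pick_soft_threshold(
                filtered, r2_target=cfg.r2_target
            )
        else:
            power, sft_table = int(cfg.power), None
        done("soft_threshold")

        stage("network")
        cor = pairwise_correlation(filtered)
        adj = adjacency(cor, power, network_type=cfg.network_type)
        tom = topological_overlap(adj)
        done("network")

        stage("modules")
        diss = tom_dissimilarity(tom)
        dendro = hierarchical_cluster(diss, gene_ids=filtered.feature_ids)
        raw_labels = cut_tree_dynamic(
            dendro,
            diss,
            min_module_size=cfg.min_module_size,
            deep_split=cfg.deep_split,
            pam_stage=cfg.pam_stage,
        )
        partition = merge_close_modules(
            filtered, raw_labels, merge_cut_height=cfg.merge_cut_height
        )
        if cfg.membership_alpha is not None and partition.n_modules:
            refined = refine_membership(
                filtered,
                partition.labels,
                min_module_size=cfg.min_module_size,
                alpha=cfg.membership_alpha,
            )
            partition = merge_close_modules(
                filtered, refined, merge_cut_height=cfg.merge_cut_height
            )
        done("modules")

        stage("eigengenes")
        eigs = eigengene_set(filtered, partition.labels)
        kme = module_membership(filtered, eigs)
        done("eigengenes")

        module_trait = None
        if self.traits is not None:
            stage("trait_association")
            module_trait = module_trait_correlation(
                eigs,
                self.traits,
                colors=partition.colors,
                fdr_alpha=cfg.fdr_alpha,
                bh_family=cfg.bh_family,
            )
            done("trait_association")

        stage("hubs")
        hubs = hub_analysis(
            tom,
            partition,
            quantile=cfg.hub_quantile,
            top_fraction=cfg.hub_top_fraction,
        )
        done("hubs")

        return WGCNAResults(
            model=self,
            filtered=filtered,
            power=power,
            scale_free_table=sft_table,
            tom=tom,
            dendrogram=dendro,
            partition=partition,
            eigengenes=eigs,
            kme=kme,
            module_trait=module_trait,
            hubs=hubs,
            timings=timings,
        )


@dataclasses.dataclass
class WGCNAResults:
    """Everything ``WGCNA.fit()`` estimates, with writers and a summary."""

    model: WGCNA
    filtered: ExpressionMatrix
    power: int
    scale_free_table: pd.DataFrame | None
    tom: TOMMatrix
    dendrogram: Dendrogram
    partition: ModulePartition
    eigengenes: EigengeneSet
    kme: pd.DataFrame
    module_trait: ModuleTraitResult | None
    hubs: HubResult
    timings: dict[str, float]

    @property
    def n_modules(self) -> int:
        return self.partition.n_modules

    def module_sizes(self) -> pd.Series:
        sizes = self.partition.sizes()
        return pd.Series(
            {self.partition.color_of(l): s for l, s in sizes.items()}, dtype=int
        )

    def significant_associations(self) -> pd.DataFrame:
        if self.module_trait is None:
            return pd.DataFrame()
        return self.module_trait.significant

    def summary(self) -> str:
        cfg = self.model.config
        sizes = self.module_sizes()
        lines = [
            "Weighted gene co-expression network analysis",
            "=" * 52,
            f"genes analysed        {self.filtered.n_features} "
            f"(top {cfg.expression_fraction:.0%} of {self.model.expr.n_features})",
            f"samples               {self.filtered.n_samples}",
            f"soft-threshold power  {self.power} ({cfg.network_type})",
            f"modules detected      {self.n_modules} "
            f"(min size {cfg.min_module_size}, merge height {cfg.merge_cut_height})",
        ]
        if len(sizes):
            lines.append(
                f"module sizes          {sizes.min()}-{sizes.max()} "
                f"(median {int(sizes.median())})"
            )
            grey = int((self.partition.labels == 0).sum())
            lines.append(f"unassigned (grey)     {grey}")
        if self.module_trait is not None and len(self.module_trait.table):
            sig = self.module_trait.significant
            lines.append(
                f"module-trait tests    {len(self.module_trait.table)} "
                f"(BH family: {self.module_trait.bh_family})"
            )
            lines.append(
                f"significant at q<{self.module_trait.fdr_alpha:g}   {len(sig)}"
            )
            for _, row in sig.iterrows():
                lines.append(
                    f"  {row.color:<14s} ~ {row.trait:<18s} "
                    f"r={row.r:+.3f}  p_adj={row.p_adj:.3g}"
                )
        lines.append(
            f"hub threshold         TOM > {self.hubs.threshold:.4f} "
            f"({self.hubs.quantile:.0%} quantile), top {self.hubs.top_fraction:.0%}"
        )
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, outdir: str | Path, write_tom: bool = False) -> Path:
        """Write all stage outputs plus a machine-readable run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.partition.to_frame().to_csv(
            outdir / "modules.tsv", sep="\t", index=False
        )
        self.eigengenes.to_frame(self.partition.colors).to_csv(
            outdir / "eigengenes.tsv", sep="\t", index_label="module"
        )
        kme = self.kme.copy()
        kme.columns = [self.partition.color_of(c) for c in kme.columns]
        kme.to_csv(outdir / "kme.tsv", sep="\t", index_label="gene_id")
        if self.module_trait is not None:
            self.module_trait.table.to_csv(
                outdir / "module_trait.tsv", sep="\t", index=False
            )
            self.module_trait.heatmap_long().to_csv(
                outdir / "module_trait_heatmap_long.tsv", sep="\t", index=False
            )
        self.hubs.to_frame().to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        if self.scale_free_table is not None:
            self.scale_free_table.to_csv(
                outdir / "scale_free_fit.tsv", sep="\t", index=False
            )
        (outdir / "dendrogram.nwk").write_text(self.dendrogram.to_newick())
        if write_tom:
            pd.DataFrame(
                self.tom.values, index=self.tom.gene_ids, columns=self.tom.gene_ids
            ).to_csv(outdir / "tom.tsv.gz", sep="\t", compression="gzip")
        manifest = {
            "package_version": __version__,
            "config": self.model.config.to_dict(),
            "n_genes_input": self.model.expr.n_features,
            "n_genes_analysed": self.filtered.n_features,
            "n_samples": self.filtered.n_samples,
            "power": self.power,
            "n_modules": self.n_modules,
            "input_checksums": {
                "expression": _digest_frame(self.model.expr.data),
                "traits": (
                    _digest_frame(self.model.traits.data)
                    if self.model.traits is not None
                    else None
                ),
            },
        }
        # timings vary run to run; kept out of the manifest so identical
        # inputs + config give byte-identical manifests
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (outdir / "timings.json").write_text(
            json.dumps({k: round(v, 3) for k, v in self.timings.items()}, indent=1)
        )
        return outdir


def _digest_frame(df: pd.DataFrame) -> str:
    # hash the text serialization: stable across runs for mixed dtypes
    return hashlib.sha256(df.to_csv().encode()).hexdigest()


def run_pipeline(
    expr: ExpressionMatrix,
    traits: TraitTable | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> WGCNAResults:
    """Fit the full analysis and optionally persist every stage output."""
    results = WGCNA(expr, traits, config).fit()
    if outdir is not None:
        results.save(outdir)
    return results
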