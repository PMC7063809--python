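"""Synthetic expression and trait data with planted co-expression modules.

The generator emulates the structure of a small clinical microarray study:
~26 samples, thousands of genes of which blocks form correlated modules,
and quantitative traits built as linear combinations of the modules'
latent factors plus sex/race covariate effects plus noise.  Every gene in
module m follows the single-factor model

    x_g = lambda_m * f_m + sqrt(1 - lambda_m**2) * eps_g,

with f_m a per-sample standard-normal latent factor, eps_g unit-normal
noise and lambda_m = sqrt(within_module_cor), so the expected pairwise
correlation inside module m is exactly within_module_cor.  Background
genes are pure noise.  The returned :class:`SyntheticTruth` records the
planted labels, trait effects and covariates so downstream stages can be
scored against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, TraitMeta, TraitTable

__all__ = ["SimulationConfig", "TraitSpec", "SyntheticTruth", "generate_dataset"]


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class TraitSpec:
    """A planted quantitative trait.

    ``effects`` maps 1-based module indices to linear effect sizes on the
    module's latent factor; sex/race effects add mean shifts by covariate
    group; ``noise_sd`` is the residual standard deviation (0 allowed for
    noiseless constructions).
    """

    name: str
    effects: list[tuple[int, float]] = dataclasses.field(default_factory=list)
    sex_effect: float = 0.0
    race_effect: float = 0.0
    noise_sd: float = 1.0


@dataclasses.dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror the emulated study: 26 samples, and sex/race drawn
    Bernoulli(15/26) to match the cohort's composition.
    ``flipped_fraction`` of modules get negative loadings on half their
    genes, exercising unsigned-network behavior.
    """

    n_genes: int
    module_sizes: list[int]
    within_module_cor: float | list[float]
    n_samples: int = 26
    trait_specs: list[TraitSpec] = dataclasses.field(default_factory=list)
    background_fraction: float | None = None
    flipped_fraction: float = 0.0
    sex_prob: float = 15 / 26
    race_prob: float = 15 / 26
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_background(self) -> int:
        return self.n_genes - sum(self.module_sizes)

    def loadings(self) -> list[float]:
        cors = (
            [self.within_module_cor] * self.n_modules
            if np.isscalar(self.within_module_cor)
            else list(self.within_module_cor)
        )
        if len(cors) != self.n_modules:
            raise ConfigurationError(
                "within_module_cor: need one value or one per module "
                f"(got {len(cors)} for {self.n_modules} modules)"
            )
        for c in cors:
            if not (0 < c <= 1):
                raise ConfigurationError(
                    f"within_module_cor: values must lie in (0, 1], got {c}"
                )
        return [float(np.sqrt(c)) for c in cors]

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ConfigurationError("n_samples: must be >= 4")
        if any(s < 1 for s in self.module_sizes):
            raise ConfigurationError("module_sizes: every module needs >= 1 gene")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"module_sizes: sum {sum(self.module_sizes)} exceeds n_genes {self.n_genes}"
            )
        if self.background_fraction is not None:
            implied = self.n_background / self.n_genes
            if abs(implied - self.background_fraction) > 1e-9:
                raise ConfigurationError(
                    "background_fraction: inconsistent with n_genes and "
                    f"module_sizes (implied {implied:.4f}, stated {self.background_fraction})"
                )
        if not (0 <= self.flipped_fraction <= 1):
            raise ConfigurationError("flipped_fraction: must be in [0, 1]")
        for spec in self.trait_specs:
            for m, _ in spec.effects:
                if not (1 <= m <= self.n_modules):
                    raise ConfigurationError(
                        f"trait_specs: trait {spec.name!r} references module {m}, "
                        f"but only {self.n_modules} modules exist"
                    )
            if spec.noise_sd < 0:
                raise ConfigurationError("trait_specs: noise_sd must be >= 0")
        self.loadings()


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth for one simulated dataset."""

    planted_labels: pd.Series  # gene id -> module index (0 = background)
    planted_trait_effects: dict[str, list[tuple[int, float]]]
    covariate_assignments: pd.DataFrame  # sample id -> sex, race
    factors: pd.DataFrame  # module index -> per-sample latent factor

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_labels": {g: int(l) for g, l in self.planted_labels.items()},
            "planted_trait_effects": {
                t: [[int(m), float(e)] for m, e in effs]
                for t, effs in self.planted_trait_effects.items()
            },
            "covariate_assignments": {
                s: {"sex": str(row.sex), "race": str(row.race)}
                for s, row in self.covariate_assignments.iterrows()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TraitTable, SyntheticTruth]:
    """Draw one dataset under the planted factor model.

    Identical configuration (including seed) gives bitwise-identical
    output.  Returns the gene x sample expression matrix, the trait table
    (quantitative planted traits plus categorical sex/race), and the
    ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, G = config.n_samples, config.n_genes
    lambdas = config.loadings()

    sample_ids = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id")
    gene_ids = pd.Index([f"g{i + 1:05d}" for i in range(G)], name="gene")

    factors = rng.standard_normal((config.n_modules, n))
    labels = np.zeros(G, dtype=int)
    x = np.empty((G, n))

    n_flipped = int(round(config.flipped_fraction * config.n_modules))
    flipped_modules = set(
        rng.choice(config.n_modules, size=n_flipped, replace=False).tolist()
    ) if n_flipped else set()

    row = 0
    for m, (size, lam) in enumerate(zip(config.module_sizes, lambdas)):
        eps = rng.standard_normal((size, n))
        signs = np.ones(size)
        if m in flipped_modules:
            flip_idx = rng.choice(size, size=size // 2, replace=False)
            signs[flip_idx] = -1.0
        x[row : row + size] = (
            signs[:, None] * lam * factors[m][None, :]
            + np.sqrt(1.0 - lam**2) * eps
        )
        labels[row : row + size] = m + 1
        row += size
    if config.n_background:
        x[row:] = rng.standard_normal((config.n_background, n))

    sex = np.where(rng.random(n) < config.sex_prob, "M", "F")
    race = np.where(rng.random(n) < config.race_prob, "A", "B")
    # guarantee two observed levels so the covariates stay usable at small n
    if len(set(sex)) == 1:
        sex[0] = "M" if sex[0] == "F" else "F"
    if len(set(race)) == 1:
        race[0] = "A" if race[0] == "B" else "B"

    trait_cols: dict[str, np.ndarray] = {}
    meta: dict[str, TraitMeta] = {}
    effects_truth: dict[str, list[tuple[int, float]]] = {}
    for spec in config.trait_specs:
        y = np.zeros(n)
        for m, eff in spec.effects:
            y += eff * factors[m - 1]
        y += spec.sex_effect * (sex == "M").astype(float)
        y += spec.race_effect * (race == "A").astype(float)
        if spec.noise_sd > 0:
            y += spec.noise_sd * rng.standard_normal(n)
        trait_cols[spec.name] = y
        adjust = []
        if spec.sex_effect != 0:
            adjust.append("sex")
        if spec.race_effect != 0:
            adjust.append("race")
        meta[spec.name] = TraitMeta(
            kind="quantitative", timepoint="static", adjustment_covariates=adjust
        )
        effects_truth[spec.name] = list(spec.effects)

    trait_df = pd.DataFrame(trait_cols, index=sample_ids)
    trait_df["sex"] = sex
    trait_df["race"] = race
    meta["sex"] = TraitMeta(kind="categorical")
    meta["race"] = TraitMeta(kind="categorical")

    expr = ExpressionMatrix(pd.DataFrame(x, index=gene_ids, columns=sample_ids))
    traits = TraitTable(trait_df, meta)
    truth = SyntheticTruth(
        planted_labels=pd.Series(labels, index=gene_ids),
        planted_trait_effects=effects_truth,
        covariate_assignments=pd.DataFrame(
            {"sex": sex, "race": race}, index=sample_ids
        ),
        factors=pd.DataFrame(
            factors,
            index=pd.Index(range(1, config.n_modules + 1), name="module"),
            columns=sample_ids,
        ),
    )
    return expr, traits, truth
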