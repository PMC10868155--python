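"""Synthetic sparse expression matrices with planted co-expression modules.

The generator emulates the two properties of single-cell count matrices
that motivate latent-space scoring: extreme sparsity (dropout — technical
zeros where a transcript is expressed but not captured) and redundancy
(many near-identical cells). Genes are organized into modules; each module
is "on" in a random subset of cell clusters and off elsewhere, so genes of
one module share a cluster-level expression pattern. On-state counts are
lognormal around a mean expression level with multiplicative noise,
background genes fluctuate independently of clusters, entrywise Bernoulli
dropout zeroes entries, and every cell is duplicated with fresh dropout to
create redundant near-duplicate conditions.

The module assignment doubles as a membership-mode gold standard (module id
= group), giving planted ground truth for every benchmark and calibration
stage without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .benchmark import GoldStandard
from .io import ExpressionMatrix

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass
class FixtureSpec:
    """Parameters of the planted-module generator.

    Defaults describe a sparse 10x-style dataset: 5 modules of 40 genes plus
    20 unstructured background genes, observed in 10 cell clusters of 50
    cells each, every cell tripled (redundancy) and 80% of entries dropped
    out. mean_expression is the typical on-state count; noise_sd is the
    lognormal sigma (~1.6x multiplicative spread at 0.5).
    """

    n_modules: int = 5
    genes_per_module: int = 40
    n_background_genes: int = 20
    n_cell_clusters: int = 10
    cells_per_cluster: int = 50
    dropout_rate: float = 0.8
    redundancy_factor: int = 3
    mean_expression: float = 10.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_modules, self.genes_per_module, self.n_cell_clusters,
               self.cells_per_cluster, self.redundancy_factor) < 1:
            raise ValueError("counts and redundancy_factor must be positive")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.mean_expression <= 0 or self.noise_sd <= 0:
            raise ValueError("mean_expression and noise_sd must be positive")


def generate_fixture(spec: FixtureSpec) -> tuple[ExpressionMatrix, GoldStandard]:
    """Generate (matrix, gold standard) deterministically from spec.seed.

    Module genes are named ``mod{m}_g{j}`` and belong to group ``module{m}``
    in the gold standard; background genes (``bg_g{j}``) are unmapped, so
    benchmark runs exclude their pairs, as real gold standards do for genes
    they never assayed.
    """
    rng = np.random.default_rng(spec.seed)
    n_mod_genes = spec.n_modules * spec.genes_per_module
    n_genes = n_mod_genes + spec.n_background_genes
    n_base_cells = spec.n_cell_clusters * spec.cells_per_cluster

    genes: list[str] = []
    membership: dict[str, set[str]] = {}
    # which clusters each module is "on" in: uniform subset, never empty,
    # never all clusters (otherwise no contrast between modules)
    on_clusters = []
    for m in range(spec.n_modules):
        size = int(rng.integers(1, max(2, spec.n_cell_clusters)))
        on_clusters.append(
            set(rng.choice(spec.n_cell_clusters, size=size, replace=False))
        )

    cluster_of_cell = np.repeat(np.arange(spec.n_cell_clusters), spec.cells_per_cluster)
    mu_log = np.log(spec.mean_expression)
    base = np.zeros((n_genes, n_base_cells))

    row = 0
    for m in range(spec.n_modules):
        on = np.isin(cluster_of_cell, list(on_clusters[m]))
        for j in range(spec.genes_per_module):
            name = f"mod{m + 1}_g{j + 1}"
            genes.append(name)
            membership[name] = {f"module{m + 1}"}
            counts = rng.lognormal(mean=mu_log, sigma=spec.noise_sd, size=on.sum())
            base[row, on] = counts
            row += 1
    for j in range(spec.n_background_genes):
        genes.append(f"bg_g{j + 1}")
        # cluster-independent noise over all cells
        base[row] = rng.lognormal(mean=mu_log, sigma=spec.noise_sd, size=n_base_cells)
        row += 1

    # duplicate each cell redundancy_factor times, then fresh dropout per copy
    tiled = np.repeat(base, spec.redundancy_factor, axis=1)
    if spec.dropout_rate > 0:
        kept = rng.random(tiled.shape) >= spec.dropout_rate
        tiled = tiled * kept
    conditions = [
        f"c{c + 1}_r{r + 1}"
        for c in range(n_base_cells)
        for r in range(spec.redundancy_factor)
    ]
    matrix = ExpressionMatrix(genes, conditions, tiled)
    return matrix, GoldStandard.from_membership(membership)
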