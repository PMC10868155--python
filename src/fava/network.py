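"""Pairwise scoring of genes in the latent space and ranked-network handling.

A functional association network is a ranked list of unordered gene pairs.
The raw score is the Pearson correlation coefficient (PCC) between the two
genes' latent mean vectors; after calibration each pair additionally carries
a posterior probability of same-pathway membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoredNetwork",
    "pairwise_pcc",
    "filter_network",
    "annotate_categories",
]


def canonical_sort(table: pd.DataFrame, by: str = "score") -> pd.DataFrame:
    """Sort pairs by `by` descending, ties broken by (gene1, gene2) ascending."""
    out = table.sort_values(
        [by, "gene1", "gene2"], ascending=[False, True, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


@dataclass
class ScoredNetwork:
    """Ranked list of unordered gene pairs with a raw similarity score.

    The table has columns ``gene1``, ``gene2``, ``score`` and, once
    calibrated, ``probability``. Invariants: gene1 < gene2 lexicographically,
    no self-pairs, no duplicates, rows sorted by score descending with
    lexicographic tie-break.
    """

    table: pd.DataFrame
    excluded_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"gene1", "gene2", "score"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"network table missing columns: {sorted(missing)}")
        if (self.table["gene1"] >= self.table["gene2"]).any():
            raise ValueError("pairs must satisfy gene1 < gene2 (no self-pairs)")
        if self.table.duplicated(["gene1", "gene2"]).any():
            raise ValueError("duplicate pairs in network")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def is_calibrated(self) -> bool:
        return "probability" in self.table.columns

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene1"]) | set(self.table["gene2"])

    @classmethod
    def from_pairs(cls, pairs, excluded_genes=()) -> "ScoredNetwork":
        """Build from an iterable of (gene_a, gene_b, score[, probability]).

        Pair orientation is canonicalized and rows are ranked.
        """
        rows = []
        for rec in pairs:
            a, b, s = rec[0], rec[1], float(rec[2])
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            g1, g2 = (a, b) if a < b else (b, a)
            row = {"gene1": g1, "gene2": g2, "score": s}
            if len(rec) > 3:
                row["probability"] = float(rec[3])
            rows.append(row)
        table = canonical_sort(pd.DataFrame(rows))
        return cls(table, list(excluded_genes))


def pairwise_pcc(
    mu: np.ndarray,
    genes: list[str],
    score_floor: float = -1.0,
    block_size: int = 2048,
) -> ScoredNetwork:
    """Score all gene pairs by the PCC of their latent vectors.

    Parameters
    ----------
    mu
        genes x latent_dim matrix of latent means (or any per-gene vectors,
        e.g. log-scaled expression rows for the raw-PCC baseline).
    genes
        Row identifiers aligned with `mu`.
    score_floor
        Pairs scoring below this are dropped while streaming; the default -1
        keeps everything. All-against-all on n genes is O(n^2) pairs, so for
        atlas-sized inputs a floor bounds memory.
    block_size
        Number of rows correlated against the rest per block.

    Genes whose vector has zero variance across latent dimensions have an
    undefined PCC; they are excluded from scoring and listed in
    ``excluded_genes``.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.ndim != 2 or mu.shape[0] != len(genes):
        raise ValueError("mu must be a genes x latent_dim matrix aligned with genes")
    if mu.shape[0] < 2 or mu.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 latent dimensions")

    sd = mu.std(axis=1)
    keep = sd > 0
    excluded = [g for g, k in zip(genes, keep) if not k]
    if keep.sum() < 2:
        raise ValueError("degenerate latent space: fewer than 2 genes with variance")

    kept_genes = np.array([g for g, k in zip(genes, keep) if k], dtype=object)
    x = mu[keep]
    d = x.shape[1]
    z = (x - x.mean(axis=1, keepdims=True)) / (sd[keep][:, None] * np.sqrt(d))

    n = z.shape[0]
    frames = []
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        corr = z[start:stop] @ z.T  # (block, n)
        # upper triangle only: column index must exceed the global row index
        rows, cols = np.nonzero(
            np.arange(n)[None, :] > np.arange(start, stop)[:, None]
        )
        scores = np.clip(corr[rows, cols], -1.0, 1.0)
        if score_floor > -1.0:
            m = scores >= score_floor
            rows, cols, scores = rows[m], cols[m], scores[m]
        ga = kept_genes[rows + start]
        gb = kept_genes[cols]
        swap = ga > gb
        ga[swap], gb[swap] = gb[swap], ga[swap].copy()
        frames.append(pd.DataFrame({"gene1": ga, "gene2": gb, "score": scores}))
    table = canonical_sort(pd.concat(frames, ignore_index=True))
    return ScoredNetwork(table, excluded)


def filter_network(
    net: ScoredNetwork,
    top_n: int | None = None,
    min_score: float | None = None,
) -> ScoredNetwork:
    """Keep the top_n highest-ranked pairs and/or those with score >= min_score."""
    if top_n is None and min_score is None:
        raise ValueError("provide top_n and/or min_score")
    table = net.table
    if min_score is not None:
        table = table[table["score"] >= min_score]
    if top_n is not None:
        if top_n <= 0:
            raise ValueError("top_n must be positive")
        table = table.head(top_n)
    return ScoredNetwork(table.reset_index(drop=True), list(net.excluded_genes))


def annotate_categories(
    net: ScoredNetwork, category_genes: set[str]
) -> tuple[pd.DataFrame, dict]:
    """Label each pair by how many of its genes belong to a category.

    Intended for gene classes such as the IDG "Tdark" understudied proteins:
    the annotation shows how much of the network covers genes the literature
    says little about.

    Returns the annotated table (extra column ``n_category``, values 0/1/2)
    and a summary dict with the number of pairs touching the category and the
    distinct category genes covered.
    """
    table = net.table.copy()
    in1 = table["gene1"].isin(category_genes)
    in2 = table["gene2"].isin(category_genes)
    table["n_category"] = in1.astype(int) + in2.astype(int)
    covered = set(table.loc[in1, "gene1"]) | set(table.loc[in2, "gene2"])
    summary = {
        "pairs_with_category_gene": int((table["n_category"] >= 1).sum()),
        "pairs_within_category": int((table["n_category"] == 2).sum()),
        "category_genes_covered": len(covered),
    }
    return table, summary
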