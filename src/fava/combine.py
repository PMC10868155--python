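"""Probabilistic combination of calibrated networks from different data types.

Networks inferred from complementary data (e.g. scRNA-seq and bulk
proteomics) are merged over the union of their pairs using the
prior-corrected noisy-OR rule that the STRING database uses for its
evidence channels: each probability is first corrected for the prior
chance of a random pair being functionally associated, the corrected
evidences are combined as 1 - prod(1 - q_i), and the prior is added back.
With prior = 0 this reduces to plain noisy-OR, under which absent evidence
(p = 0) is neutral and two independent 0.5 evidences give 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ScoredNetwork

__all__ = ["CombinedNetwork", "combine_probs", "combine_networks", "confidence_filter"]


@dataclass
class CombinedNetwork:
    """Union of source pairs with combined and per-source probabilities."""

    table: pd.DataFrame  # gene1, gene2, p_combined, p_source1, p_source2, ...

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene1"]) | set(self.table["gene2"])


def combine_probs(p1, p2, prior: float = 0.0):
    """Prior-corrected noisy-OR of two evidence probabilities (vectorized)."""
    if not 0 <= prior < 1:
        raise ValueError("prior must lie in [0, 1)")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q1 = np.clip((p1 - prior) / (1.0 - prior), 0.0, None)
    q2 = np.clip((p2 - prior) / (1.0 - prior), 0.0, None)
    p = 1.0 - (1.0 - q1) * (1.0 - q2)
    out = prior + p * (1.0 - prior)
    return float(out) if out.ndim == 0 else out


def _prob_frame(net: ScoredNetwork, col: str) -> pd.DataFrame:
    if not net.is_calibrated:
        raise ValueError(
            "source network has no probabilities; run calibration first"
        )
    df = net.table[["gene1", "gene2", "probability"]].copy()
    return df.rename(columns={"probability": col})


def combine_networks(
    n1: ScoredNetwork, n2: ScoredNetwork, prior: float = 0.0
) -> CombinedNetwork:
    """Merge two calibrated networks over the union of their pair sets.

    A pair present in only one source keeps that source's probability
    (the missing evidence enters as the prior, which is neutral after
    correction). Output is sorted by p_combined descending with the
    standard lexicographic tie-break.
    """
    merged = _prob_frame(n1, "p_source1").merge(
        _prob_frame(n2, "p_source2"), on=["gene1", "gene2"], how="outer"
    )
    p1 = merged["p_source1"].fillna(prior).to_numpy()
    p2 = merged["p_source2"].fillna(prior).to_numpy()
    merged["p_combined"] = combine_probs(p1, p2, prior)
    merged = merged[["gene1", "gene2", "p_combined", "p_source1", "p_source2"]]
    merged = merged.sort_values(
        ["p_combined", "gene1", "gene2"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return CombinedNetwork(merged)


def combine_many(nets: list[ScoredNetwork], prior: float = 0.0) -> CombinedNetwork:
    """Fold combine_networks over two or more calibrated networks.

    Noisy-OR is associative, so the result does not depend on the fold
    order (up to float round-off).
    """
    if len(nets) < 2:
        raise ValueError("need at least two networks to combine")
    frames = [_prob_frame(n, f"p_source{i + 1}") for i, n in enumerate(nets)]
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.merge(f, on=["gene1", "gene2"], how="outer")
    cols = [c for c in merged.columns if c.startswith("p_source")]
    q = np.clip((merged[cols].fillna(prior).to_numpy() - prior) / (1 - prior), 0, None)
    merged["p_combined"] = prior + (1 - np.prod(1 - q, axis=1)) * (1 - prior)
    merged = merged[["gene1", "gene2", "p_combined", *cols]]
    merged = merged.sort_values(
        ["p_combined", "gene1", "gene2"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return CombinedNetwork(merged)


def confidence_filter(cn: CombinedNetwork, cutoff: float) -> CombinedNetwork:
    """Keep pairs with p_combined >= cutoff (e.g. 0.15/0.40/0.70 for the
    STRING-style low/medium/high confidence levels)."""
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    table = cn.table[cn.table["p_combined"] >= cutoff].reset_index(drop=True)
    return CombinedNetwork(table)
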