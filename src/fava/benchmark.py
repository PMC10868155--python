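"""Benchmarking ranked networks against pathway / interaction gold standards.

Two gold-standard modes are supported:

* membership — a gene -> pathway/complex map (e.g. KEGG maps). A ranked pair
  is a true positive (TP) if the two genes share a group, a false positive
  (FP) if both are mapped but share none, and excluded if either gene is
  unmapped.
* pairs — an interaction list (e.g. BioGRID). A pair present in the list is
  a TP. By default a pair is an FP only when both genes occur somewhere in
  the gold set and is excluded otherwise, mirroring the membership-mode
  unmappable rule; `strict_fp` counts every absent pair as FP instead.

Performance is summarized by the cumulative TP-vs-FP curve over the ranked
list, the standard was of visualizing such benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ScoredNetwork

__all__ = ["GoldStandard", "BenchmarkCurve", "classify_pair", "cumulative_curve"]

TP, FP, EXCLUDED = "TP", "FP", "EXCLUDED"


@dataclass
class GoldStandard:
    """Reference set used to label predicted pairs TP/FP."""

    mode: str  # "membership" or "pairs"
    membership: dict[str, set[str]] = field(default_factory=dict)
    pair_set: set[frozenset] = field(default_factory=set)
    member_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.mode not in ("membership", "pairs"):
            raise ValueError(f"unknown gold-standard mode {self.mode!r}")
        if self.mode == "membership":
            empty = [g for g, s in self.membership.items() if not s]
            if empty:
                raise ValueError(f"genes with empty group sets: {empty[:5]}")
            self.member_genes = set(self.membership)
        else:
            for p in self.pair_set:
                if len(p) != 2:
                    raise ValueError(f"self-pair in gold standard: {set(p)}")
            if not self.member_genes:
                self.member_genes = {g for p in self.pair_set for g in p}

    @classmethod
    def from_membership(cls, membership: dict[str, set[str]]) -> "GoldStandard":
        return cls("membership", membership={g: set(s) for g, s in membership.items()})

    @classmethod
    def from_pairs(cls, pairs) -> "GoldStandard":
        return cls("pairs", pair_set={frozenset(p) for p in pairs if p[0] != p[1]})


def classify_pair(
    a: str, b: str, gs: GoldStandard, strict_fp: bool = False
) -> str:
    """Label an unordered gene pair TP, FP or EXCLUDED under a gold standard."""
    if a == b:
        raise ValueError("self-pair")
    if gs.mode == "membership":
        ga = gs.membership.get(a)
        gb = gs.membership.get(b)
        if ga is None or gb is None:
            return EXCLUDED
        return TP if ga & gb else FP
    if frozenset((a, b)) in gs.pair_set:
        return TP
    if strict_fp:
        return FP
    if a in gs.member_genes and b in gs.member_genes:
        return FP
    return EXCLUDED


@dataclass
class BenchmarkCurve:
    """Cumulative TP-vs-FP curve over a ranked pair list.

    ``labels`` holds the TP/FP/EXCLUDED label of every network pair in rank
    order; ``cum_fp``/``cum_tp`` give one point per evaluable (non-excluded)
    pair.
    """

    labels: np.ndarray
    cum_fp: np.ndarray
    cum_tp: np.ndarray

    @property
    def n_evaluable(self) -> int:
        return len(self.cum_tp)

    @property
    def n_excluded(self) -> int:
        return int((self.labels == EXCLUDED).sum())

    def tp_fp_at(self, prefix: int) -> tuple[int, int]:
        """(TP, FP) counts within the top `prefix` evaluable pairs."""
        if prefix < 1:
            raise ValueError("prefix must be >= 1")
        i = min(prefix, self.n_evaluable) - 1
        return int(self.cum_tp[i]), int(self.cum_fp[i])

    def tp_fp_at_rank(self, rank: int) -> tuple[int, int]:
        """(TP, FP) counts within the top `rank` pairs counting excluded ones."""
        lab = self.labels[:rank]
        return int((lab == TP).sum()), int((lab == FP).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cum_fp": self.cum_fp, "cum_tp": self.cum_tp})


def cumulative_curve(
    net: ScoredNetwork, gs: GoldStandard, strict_fp: bool = False
) -> BenchmarkCurve:
    """Label the ranked network against `gs` and accumulate TP/FP counts.

    Excluded pairs are skipped; the curve advances by exactly one unit in one
    coordinate per evaluable pair. Raises if no pair is evaluable, reporting
    how many network genes the gold standard covers.
    """
    labels = np.array(
        [
            classify_pair(a, b, gs, strict_fp=strict_fp)
            for a, b in zip(net.table["gene1"], net.table["gene2"])
        ],
        dtype=object,
    )
    evaluable = labels != EXCLUDED
    if not evaluable.any():
        covered = len(net.genes & gs.member_genes)
        raise ValueError(
            "no evaluable pairs: gold standard covers "
            f"{covered}/{len(net.genes)} network genes"
        )
    is_tp = (labels[evaluable] == TP).astype(int)
    cum_tp = np.cumsum(is_tp)
    cum_fp = np.cumsum(1 - is_tp)
    return BenchmarkCurve(labels=labels, cum_fp=cum_fp, cum_tp=cum_tp)
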