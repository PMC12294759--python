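"""Post-processing of attribution results.

Rankings use the mean absolute value of sample-level attributions; the
composite "total" score min–max scales each method's ranking vector to
[0, 1] before summing, since Integrated Gradients and Shapley values live on
different scales.  List agreement is the intersection fraction
``|top_k(A) ∩ top_k(B)| / k``.  Ties break lexicographically by entity name
everywhere, so every ranking is deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .attribution import AttributionResult

DEFAULT_KS = (10, 30, 50, 100)


@dataclass
class RankedGeneList:
    """Genes (or other entities) in non-increasing score order."""

    genes: list[str]
    scores: np.ndarray
    method: str = ""
    class_tag: str = ""
    rule: str = "mean absolute sample-level attribution; lexicographic ties"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ValueError("gene and score lengths differ")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def top(self, k: int) -> list[str]:
        if k > len(self.genes):
            raise ValueError(f"k={k} exceeds list length {len(self.genes)}")
        return self.genes[:k]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "score": self.scores, "rank": np.arange(1, len(self.genes) + 1)}
        )


@dataclass
class OverlapReport:
    """Intersection fractions between two ranked lists at several depths."""

    list_a: str
    list_b: str
    fractions: dict[int, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": list(self.fractions), "intersection_fraction": list(self.fractions.values())}
        )


def _sorted_ranking(scores: pd.Series) -> tuple[list[str], np.ndarray]:
    frame = scores.rename("score").rename_axis("gene").reset_index()
    frame = frame.sort_values(["score", "gene"], ascending=[False, True])
    return frame["gene"].tolist(), frame["score"].to_numpy()


def rank_genes(result: AttributionResult, class_tag: str = "") -> RankedGeneList:
    """Rank entities by mean |attribution| over retained samples."""
    if result.scores.shape[0] < 1:
        raise ValueError("attribution result holds no samples")
    mean_abs = result.scores.abs().mean(axis=0)
    genes, scores = _sorted_ranking(mean_abs)
    return RankedGeneList(
        genes=genes, scores=scores, method=result.method,
        class_tag=class_tag or (result.target_class or ""),
    )


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        return np.zeros_like(values)  # degenerate range carries no information
    return (values - lo) / (hi - lo)


def total_score(ig: RankedGeneList, sv: RankedGeneList) -> RankedGeneList:
    """Composite ranking: per-method scores min–max scaled to [0,1], summed."""
    if set(ig.genes) != set(sv.genes):
        raise ValueError("rankings cover different gene universes")
    a = pd.Series(_minmax(ig.scores), index=ig.genes)
    b = pd.Series(_minmax(sv.scores), index=sv.genes)
    combined = a + b.reindex(a.index)
    genes, scores = _sorted_ranking(combined)
    return RankedGeneList(
        genes=genes, scores=scores,
        method=f"{ig.method}+{sv.method}", class_tag=ig.class_tag,
        rule="sum of min-max scaled per-method mean |attribution|; lexicographic ties",
    )


def topk_overlap(
    a: RankedGeneList,
    b: RankedGeneList,
    ks: tuple[int, ...] = DEFAULT_KS,
    jaccard: bool = False,
) -> OverlapReport:
    """Intersection fraction |top_k(a) ∩ top_k(b)| / k at each depth.

    ``jaccard=True`` divides by the union size instead.
    """
    fractions = {}
    for k in ks:
        ta, tb = set(a.top(k)), set(b.top(k))
        denom = len(ta | tb) if jaccard else k
        fractions[int(k)] = len(ta & tb) / denom
    return OverlapReport(
        list_a=f"{a.method}/{a.class_tag}", list_b=f"{b.method}/{b.class_tag}",
        fractions=fractions,
    )


def select_top_fraction(ranking: RankedGeneList, fraction: float = 0.05) -> list[str]:
    """Head of the ranking: ``ceil(fraction × N)`` genes (default top 5%)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return ranking.genes[: math.ceil(fraction * len(ranking.genes))]


@dataclass
class FilterDecision:
    keep: bool
    reason: str = ""


class KeepListFilter:
    """Deterministic gene filter backed by an explicit keep-list.

    Stands where a semantic-refinement step (e.g. a language-model judgement
    of disease relevance) would plug in: any callable mapping a gene name to
    a :class:`FilterDecision` fits the same slot.
    """

    def __init__(self, keep: set[str] | list[str]):
        self.keep = set(keep)

    def __call__(self, gene: str) -> FilterDecision:
        if gene in self.keep:
            return FilterDecision(True, "on keep-list")
        return FilterDecision(False, "not on keep-list")


def refine_genes(
    ranking: RankedGeneList,
    gene_filter: Callable[[str], FilterDecision],
) -> tuple[list[str], dict[str, str]]:
    """Apply a keep/drop predicate, preserving rank order among kept genes.

    Returns the kept genes and a map of dropped gene → reason.  A filter
    exception is re-raised naming the gene it failed on.
    """
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for gene in ranking.genes:
        try:
            decision = gene_filter(gene)
        except Exception as exc:
            raise RuntimeError(f"gene filter failed on {gene!r}: {exc}") from exc
        if decision.keep:
            kept.append(gene)
        else:
            dropped[gene] = decision.reason
    if not kept:
        warnings.warn("gene filter dropped every gene", stacklevel=2)
    return kept, dropped


def pathway_conductance_ranking(
    result: AttributionResult,
    top_n: int = 5,
) -> RankedGeneList:
    """Top pathways by mean |total conductance| across retained samples."""
    if not result.entity_layer.startswith("hidden"):
        raise ValueError("expected a hidden-layer (pathway) conductance result")
    full = rank_genes(result)
    n = min(top_n, len(full.genes))
    return RankedGeneList(
        genes=full.genes[:n], scores=full.scores[:n],
        method="conductance", class_tag=full.class_tag,
        rule="mean absolute total conductance; lexicographic ties",
    )
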