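"""Structural audit of feature sharing between EP pairs.

Two mechanisms let candidate pairs share features and thereby contaminate
a carelessly constructed test set:

* **Shared promoters** — all pairs attached to one promoter carry the same
  P features.  When such a group is class-imbalanced, a model that merely
  memorizes the promoter predicts the held-out members of the group at the
  group's majority-class rate.  A (7 positive, 2 negative) group, for
  example, is predicted at 7/9 ~ 78% accuracy by that rule alone.
* **Overlapping windows** — pairs whose windows (the interval between
  enhancer and promoter) overlap share part of their W signal; enhancers
  on the same side of a promoter are the extreme case.

The audit is structural: it counts sharing relations from coordinates and
group labels, not from feature values.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ep_data import EPDataset, EPDataError, natural_chrom_key

__all__ = [
    "PromoterGroup",
    "SharingMatrix",
    "promoter_groups",
    "sharing_matrix",
    "contamination_accuracy",
    "imbalance_class",
    "leaky_pair_fraction",
    "window_sharing_components",
]


@dataclass(frozen=True)
class PromoterGroup:
    """All pairs attached to one promoter, with their class counts."""

    promoter_id: str
    n_pos: int
    n_neg: int
    pair_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_pos + self.n_neg != len(self.pair_ids):
            raise EPDataError(
                f"group {self.promoter_id}: counts {self.n_pos}+{self.n_neg} "
                f"disagree with {len(self.pair_ids)} pair ids"
            )
        if not self.pair_ids:
            raise EPDataError(f"group {self.promoter_id} is empty")

    @property
    def size(self) -> int:
        return self.n_pos + self.n_neg


@dataclass
class SharingMatrix:
    """Counts of promoter groups (or their pairs) by (n_pos, n_neg).

    ``weighting='promoter'`` counts groups; ``weighting='pair'`` counts the
    pairs they contain, i.e. multiplies each cell by ``n_pos + n_neg``.
    """

    cells: dict[tuple[int, int], int]
    weighting: str

    def total(self) -> int:
        return sum(self.cells.values())

    def cell(self, n_pos: int, n_neg: int) -> int:
        return self.cells.get((n_pos, n_neg), 0)

    def to_records(self) -> list[tuple[int, int, int]]:
        return sorted((a, b, c) for (a, b), c in self.cells.items())


def promoter_groups(dataset: EPDataset) -> list[PromoterGroup]:
    """Partition a dataset's pairs into per-promoter groups."""
    by_prom: dict[str, list] = defaultdict(list)
    for p in dataset.pairs:
        by_prom[p.promoter_id].append(p)
    groups = []
    for pid, members in by_prom.items():
        n_pos = sum(p.label for p in members)
        groups.append(
            PromoterGroup(pid, n_pos, len(members) - n_pos, tuple(p.pair_id for p in members))
        )
    return groups


def sharing_matrix(
    groups: Sequence[PromoterGroup], weighting: str = "pair"
) -> SharingMatrix:
    """Aggregate groups into a (n_pos, n_neg) count matrix.

    With pair weighting a cell at (7, 2) holding 27 pairs corresponds to
    27 / (7 + 2) = 3 distinct promoters; promoter weighting reports the 3
    directly.
    """
    if weighting not in ("pair", "promoter"):
        raise EPDataError(f"weighting must be 'pair' or 'promoter', got {weighting!r}")
    cells: Counter = Counter()
    for g in groups:
        cells[(g.n_pos, g.n_neg)] += g.size if weighting == "pair" else 1
    return SharingMatrix(dict(cells), weighting)


def contamination_accuracy(n_pos: int, n_neg: int) -> float:
    """Accuracy of the promoter-memorizing majority rule on a group.

    A model that learns a rule specific to one promoter's features
    predicts that group's majority class for every member; on a group
    with ``n_pos`` positives and ``n_neg`` negatives this is right a
    fraction ``max(n_pos, n_neg) / (n_pos + n_neg)`` of the time —
    the accuracy leaked into a test set containing part of the group.
    """
    if n_pos < 0 or n_neg < 0 or n_pos + n_neg < 1:
        raise EPDataError("need non-negative counts with at least one pair")
    return max(n_pos, n_neg) / (n_pos + n_neg)


def imbalance_class(n_pos: int, n_neg: int, fold_threshold: float = 2.0) -> str:
    """Classify a group as ``pos_skew``, ``neg_skew`` or ``balanced``.

    A group is skewed when one class outnumbers the other by at least
    ``fold_threshold``; a zero count on one side counts as skew toward the
    other (infinite ratio), since pure groups are the most contaminating.
    """
    if n_pos < 0 or n_neg < 0 or n_pos + n_neg < 1:
        raise EPDataError("need non-negative counts with at least one pair")
    if fold_threshold < 1:
        raise EPDataError(f"fold_threshold must be >= 1, got {fold_threshold}")
    if n_pos >= fold_threshold * n_neg and n_pos >= 1:
        return "pos_skew"
    if n_neg >= fold_threshold * n_pos and n_neg >= 1:
        return "neg_skew"
    return "balanced"


def leaky_pair_fraction(
    groups: Sequence[PromoterGroup], fold_threshold: float = 2.0
) -> float:
    """Fraction of all pairs exposed to promoter-feature contamination.

    A pair is counted when its promoter group (a) contains at least one
    other pair — singletons cannot leak through P features — and (b) is at
    least ``fold_threshold``-fold class-imbalanced.
    """
    total = sum(g.size for g in groups)
    if total == 0:
        raise EPDataError("no pairs in the supplied groups")
    leaky = sum(
        g.size
        for g in groups
        if g.size >= 2 and imbalance_class(g.n_pos, g.n_neg, fold_threshold) != "balanced"
    )
    return leaky / total


def window_sharing_components(dataset: EPDataset) -> np.ndarray:
    """Label pairs by connected component of the window-overlap graph.

    Two pairs are connected when their windows overlap by at least one
    base on the same chromosome; component labels propagate transitively,
    so a chain of pairwise-overlapping windows forms one component.  Pairs
    with zero-width windows (adjacent elements) are isolated singletons.

    Returns an integer label per pair, in dataset order.
    """
    n = dataset.n_pairs
    labels = np.full(n, -1, dtype=int)
    by_chrom: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for i, p in enumerate(dataset.pairs):
        lo = min(p.enhancer.end, p.promoter.end)
        hi = max(p.enhancer.start, p.promoter.start)
        if hi > lo:
            by_chrom[p.chrom].append((lo, hi, i))
        # zero-width windows overlap nothing; labelled below
    next_label = 0
    for chrom in sorted(by_chrom, key=natural_chrom_key):
        intervals = sorted(by_chrom[chrom])
        reach = -1
        for lo, hi, i in intervals:
            if lo >= reach:  # half-open: touching windows do not overlap
                next_label += 1
            labels[i] = next_label - 1
            reach = max(reach, hi)
    for i in range(n):
        if labels[i] == -1:
            labels[i] = next_label
            next_label += 1
    return labels
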