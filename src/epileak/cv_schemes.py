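"""Cross-validation partitioners aware of EP feature sharing.

Three schemes are compared throughout the package:

``random``
    pairs dealt uniformly at random into k folds — the scheme under which
    shared promoter and window features leak between train and test;
``chromosomal``
    pairs sorted by genomic position and cut into k contiguous blocks,
    with cut points snapped forward so that no promoter group and no
    window-overlap component straddles a fold boundary — certified free of
    both P and W sharing across folds;
``promoter_segregated``
    whole promoter groups dealt into folds (greedy balancing), which
    eliminates cross-fold promoter sharing but can still split
    window-overlapping pairs of different promoters.

`certify` counts the cross-fold sharing relations of any partition, so a
scheme's leakage-freeness is checked rather than assumed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ep_data import EPDataset, EPDataError, natural_chrom_key, window_midpoint
from .leakage_audit import window_sharing_components

__all__ = [
    "CVPartition",
    "ContaminationCertificate",
    "random_folds",
    "chromosomal_folds",
    "promoter_folds",
    "certify",
]


@dataclass
class CVPartition:
    """Fold assignment per pair, in dataset order."""

    fold_of_pair: np.ndarray
    k: int
    scheme: str
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.fold_of_pair = np.asarray(self.fold_of_pair, dtype=int)
        if self.k < 2:
            raise EPDataError(f"need at least 2 folds, got k={self.k}")
        if self.fold_of_pair.min(initial=0) < 0 or (
            self.fold_of_pair.size and self.fold_of_pair.max() >= self.k
        ):
            raise EPDataError("fold indices out of range")
        sizes = np.bincount(self.fold_of_pair, minlength=self.k)
        if (sizes == 0).any():
            raise EPDataError("every fold must be non-empty")

    @property
    def n_pairs(self) -> int:
        return int(self.fold_of_pair.size)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_of_pair, minlength=self.k)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_pair == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_pair != fold)


@dataclass(frozen=True)
class ContaminationCertificate:
    """Cross-fold sharing counts of a partition.

    ``cross_fold_promoter_links`` counts unordered pairs of EP pairs that
    share a promoter but sit in different folds; ``cross_fold_window_links``
    counts those with overlapping windows in different folds.  Both must be
    zero for a partition to be leakage-free.
    """

    cross_fold_promoter_links: int
    cross_fold_window_links: int

    @property
    def clean(self) -> bool:
        return self.cross_fold_promoter_links == 0 and self.cross_fold_window_links == 0


def random_folds(dataset: EPDataset, k: int, seed: int) -> CVPartition:
    """Deal pairs uniformly at random into k folds of near-equal size."""
    n = dataset.n_pairs
    if k > n:
        raise EPDataError(f"k={k} exceeds the {n} available pairs")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    fold[rng.permutation(n)] = np.arange(n) % k
    return CVPartition(fold, k, "random", seed)


def _sorted_order(dataset: EPDataset) -> list[int]:
    return sorted(
        range(dataset.n_pairs),
        key=lambda i: (
            natural_chrom_key(dataset.pairs[i].chrom),
            window_midpoint(dataset.pairs[i]),
            dataset.pairs[i].pair_id,
        ),
    )


def _sharing_units(dataset: EPDataset) -> np.ndarray:
    """Merge promoter groups with window-overlap components (union-find)."""
    n = dataset.n_pairs
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_prom: dict[str, int] = {}
    for i, p in enumerate(dataset.pairs):
        if p.promoter_id in by_prom:
            union(by_prom[p.promoter_id], i)
        else:
            by_prom[p.promoter_id] = i
    comp = window_sharing_components(dataset)
    by_comp: dict[int, int] = {}
    for i, c in enumerate(comp):
        if c in by_comp:
            union(by_comp[c], i)
        else:
            by_comp[c] = i
    return np.array([find(i) for i in range(n)])


def chromosomal_folds(dataset: EPDataset, k: int) -> CVPartition:
    """Contiguous genomic blocks whose boundaries respect sharing units.

    Pairs are sorted by (chromosome, window midpoint, pair_id); fold
    boundaries may only fall at positions that no promoter group and no
    window-overlap component straddles, which guarantees a clean
    contamination certificate.  Among all admissible boundary placements
    the partition minimizing the sum of squared fold sizes is chosen
    (best-effort balance).  Deterministic — no seed is involved.

    Raises an error when the dataset has fewer mergeable sharing units in
    genomic order than folds.
    """
    n = dataset.n_pairs
    if k > n:
        raise EPDataError(f"k={k} exceeds the {n} available pairs")
    order = _sorted_order(dataset)
    unit = _sharing_units(dataset)

    # A cut before sorted position i is valid iff no earlier pair's unit
    # extends to i or beyond (track via running max of unit last-positions).
    unit_last: dict[int, int] = {}
    for pos, i in enumerate(order):
        unit_last[unit[i]] = pos
    run_max = -1
    valid_cuts = []
    for pos, i in enumerate(order[:-1]):
        run_max = max(run_max, unit_last[unit[i]])
        if run_max == pos:
            valid_cuts.append(pos + 1)
    if len(valid_cuts) < k - 1:
        raise EPDataError(
            f"dataset has only {len(valid_cuts) + 1} mergeable sharing units in "
            f"genomic order; cannot build k={k} leakage-free contiguous folds"
        )

    # Segments between consecutive valid cuts are indivisible; partition
    # them into k contiguous blocks minimizing sum of squared block sizes.
    bounds_all = [0] + valid_cuts + [n]
    seg_sizes = np.diff(bounds_all)
    m = len(seg_sizes)
    prefix = np.concatenate([[0], np.cumsum(seg_sizes)])
    INF = float("inf")
    cost = np.full((k + 1, m + 1), INF)
    back = np.zeros((k + 1, m + 1), dtype=int)
    cost[0, 0] = 0.0
    for j in range(1, k + 1):
        for i in range(j, m - (k - j) + 1):
            best, best_t = INF, -1
            for t in range(j - 1, i):
                c = cost[j - 1, t] + float(prefix[i] - prefix[t]) ** 2
                if c < best:
                    best, best_t = c, t
            cost[j, i] = best
            back[j, i] = best_t
    seg_cuts = []
    i = m
    for j in range(k, 0, -1):
        t = back[j, i]
        if j > 1:
            seg_cuts.append(t)
        i = t
    cuts = [bounds_all[t] for t in reversed(seg_cuts)]

    fold = np.empty(n, dtype=int)
    bounds = [0] + cuts + [n]
    for f in range(k):
        for pos in range(bounds[f], bounds[f + 1]):
            fold[order[pos]] = f
    return CVPartition(fold, k, "chromosomal")


def promoter_folds(dataset: EPDataset, k: int, seed: int) -> CVPartition:
    """Assign whole promoter groups to folds, balancing fold pair counts.

    Groups are shuffled by ``seed`` and dealt greedily to the currently
    smallest fold, so all pairs sharing a promoter land in one fold.
    """
    groups: dict[str, list[int]] = defaultdict(list)
    for i, p in enumerate(dataset.pairs):
        groups[p.promoter_id].append(i)
    group_ids = sorted(groups)
    if k > len(group_ids):
        raise EPDataError(
            f"k={k} exceeds the {len(group_ids)} promoter groups"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(group_ids))
    sizes = np.zeros(k, dtype=int)
    fold = np.empty(dataset.n_pairs, dtype=int)
    for gi in order:
        members = groups[group_ids[gi]]
        target = int(np.argmin(sizes))
        fold[members] = target
        sizes[target] += len(members)
    return CVPartition(fold, k, "promoter_segregated", seed)


def certify(partition: CVPartition, dataset: EPDataset) -> ContaminationCertificate:
    """Count the cross-fold feature-sharing relations of a partition.

    Exact counts: every unordered pair of EP pairs sharing a promoter or
    overlapping windows contributes one link when its members sit in
    different folds.
    """
    if partition.n_pairs != dataset.n_pairs:
        raise EPDataError(
            f"partition covers {partition.n_pairs} pairs but dataset has "
            f"{dataset.n_pairs}"
        )
    fold = partition.fold_of_pair

    prom_links = 0
    by_prom: dict[str, list[int]] = defaultdict(list)
    for i, p in enumerate(dataset.pairs):
        by_prom[p.promoter_id].append(i)
    for members in by_prom.values():
        s = len(members)
        counts = np.bincount(fold[members], minlength=partition.k)
        prom_links += (s * s - int((counts**2).sum())) // 2

    win_links = 0
    by_chrom: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for i, p in enumerate(dataset.pairs):
        lo = min(p.enhancer.end, p.promoter.end)
        hi = max(p.enhancer.start, p.promoter.start)
        if hi > lo:
            by_chrom[p.chrom].append((lo, hi, i))
    for intervals in by_chrom.values():
        lo = np.array([t[0] for t in intervals])
        hi = np.array([t[1] for t in intervals])
        f = fold[[t[2] for t in intervals]]
        # all-pairs overlap test within one chromosome (m is modest)
        overlap = (lo[:, None] < hi[None, :]) & (lo[None, :] < hi[:, None])
        differ = f[:, None] != f[None, :]
        win_links += int(np.triu(overlap & differ, k=1).sum())
    return ContaminationCertificate(prom_links, win_links)
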