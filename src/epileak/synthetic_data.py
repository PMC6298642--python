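"""Synthetic EP-pair datasets with controllable feature sharing and leakage.

The generator emulates the structural properties of real enhancer-promoter
candidate tables that make naive cross-validation unreliable:

* every pair attached to a promoter carries *bit-identical* P features
  (one latent vector per promoter);
* pairs whose windows overlap share W signal, because W features are
  averages of a common per-chromosome latent track over the window;
* promoter groups are strongly class-imbalanced (by default every group is
  pure positive or pure negative), with a ~1:20 global positive:negative
  ratio;
* the genuine association between features and labels is a tunable mean
  shift ``signal_strength`` on a few E columns, and is *zero by default* —
  so any above-random performance measured under a random fold assignment
  is attributable to leakage alone.

Geometry: promoters (2 kb) are scattered uniformly over a small multi-
chromosome genome, and each promoter's enhancers (1 kb) are dropped on
either side at gap distances drawn log-uniformly between ``min_distance``
and ``max_distance``.  The log-uniform choice mirrors the heavy-tailed
distance distribution of real candidate pairs and leaves uncovered gaps
between regulatory neighbourhoods, so that chromosome-sorted folds with
group snapping remain constructible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .ep_data import EPDataset, EPPair, FeatureTable, GenomicInterval, window_interval

__all__ = [
    "PROMOTER_WIDTH",
    "ENHANCER_WIDTH",
    "ConfigurationError",
    "CapacityError",
    "GeneratorConfig",
    "sample_group_profile",
    "layout_genome",
    "generate_features",
    "simulate",
]

PROMOTER_WIDTH = 2_000
ENHANCER_WIDTH = 1_000

_MAX_PLACEMENT_TRIES = 500


class ConfigurationError(ValueError):
    """Generator configuration is inconsistent or infeasible."""


class CapacityError(RuntimeError):
    """The genome is too small to host the requested layout."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic EP-pair generator.

    Attributes
    ----------
    n_chromosomes, chrom_length:
        Genome shape; ``chrom_length`` in bp.
    n_promoters:
        Number of promoter groups to simulate.
    marks_per_region:
        Epigenomic marks per block, so the full EPW table has
        ``3 * marks_per_region`` columns (408 at the default 136).
    target_pos_fraction:
        Expected global fraction of positive pairs (default 1/21, i.e. a
        1:20 positive:negative ratio).
    profile_mode:
        ``pure_mixture`` makes every promoter group all-positive or
        all-negative (the most contaminating configuration);
        ``beta`` draws each group's positive fraction from a
        Beta(beta_a, beta_b) and produces mixed groups.
    group_size_mean, group_size_max:
        Pairs per promoter: ``1 + Geometric`` with the given mean, capped.
    track_segment_bp:
        Segment length of the piecewise-constant latent window track; sets
        the genomic scale over which W features decorrelate.
    signal_strength:
        Mean shift added to the first ``n_signal_features`` E columns of
        positive pairs; 0 disables any genuine label signal.
    feature_noise_sd:
        Optional iid per-pair noise added to every feature.
    min_distance, max_distance:
        Bounds (bp) on the enhancer-promoter gap; gaps are log-uniform.
    seed:
        Seed for the generator's private PRNG; fully determines output.
    """

    n_chromosomes: int = 5
    chrom_length: int = 50_000_000
    n_promoters: int = 400
    marks_per_region: int = 136
    target_pos_fraction: float = 1.0 / 21.0
    profile_mode: str = "pure_mixture"
    group_size_mean: float = 8.0
    group_size_max: int = 30
    beta_a: float = 0.2
    beta_b: float = 4.0
    track_segment_bp: int = 50_000
    signal_strength: float = 0.0
    n_signal_features: int = 16
    feature_noise_sd: float = 0.0
    min_distance: int = 10_000
    max_distance: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_pos_fraction < 1.0):
            raise ConfigurationError(
                f"target_pos_fraction must be in [0, 1), got {self.target_pos_fraction}"
            )
        if self.profile_mode not in ("pure_mixture", "beta"):
            raise ConfigurationError(f"unknown profile_mode {self.profile_mode!r}")
        if self.group_size_max < 2:
            raise ConfigurationError("group_size_max must be >= 2")
        if not (2.0 <= self.group_size_mean <= self.group_size_max):
            raise ConfigurationError(
                "group_size_mean must lie in [2, group_size_max]"
            )
        for name in (
            "n_chromosomes",
            "chrom_length",
            "n_promoters",
            "marks_per_region",
            "track_segment_bp",
            "min_distance",
            "max_distance",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.signal_strength < 0:
            raise ConfigurationError("signal_strength must be >= 0")
        if self.feature_noise_sd < 0:
            raise ConfigurationError("feature_noise_sd must be >= 0")
        if not (0 <= self.n_signal_features <= self.marks_per_region):
            raise ConfigurationError(
                "n_signal_features must be between 0 and marks_per_region"
            )
        if self.min_distance >= self.max_distance:
            raise ConfigurationError("min_distance must be < max_distance")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ConfigurationError("beta_a and beta_b must be positive")
        margin = self.max_distance + ENHANCER_WIDTH
        if self.chrom_length <= 2 * margin + PROMOTER_WIDTH:
            raise CapacityError(
                "chrom_length too short to place a promoter with enhancers on "
                "both sides at max_distance"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(GeneratorConfig)}
        bad = sorted(set(d) - known)
        if bad:
            raise ConfigurationError(f"unknown config key(s): {bad}")
        return GeneratorConfig(**d)


def _sample_group_sizes(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    # 1 + Geometric with support >= 2 and the requested mean, capped.
    p = 1.0 / (config.group_size_mean - 1.0) if config.group_size_mean > 2 else 1.0
    sizes = 1 + rng.geometric(p, size=config.n_promoters)
    return np.minimum(sizes, config.group_size_max)


def sample_group_profile(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Draw one (n_pos, n_neg) count pair per promoter group.

    In ``pure_mixture`` mode each group is entirely positive with
    probability ``target_pos_fraction`` and entirely negative otherwise,
    so the expected pair-level positive fraction equals the target.  In
    ``beta`` mode each group's positive count is Binomial(size, q) with
    q ~ Beta(beta_a, beta_b), giving mixed, mostly skewed groups.
    """
    sizes = _sample_group_sizes(config, rng)
    profile: list[tuple[int, int]] = []
    if config.profile_mode == "pure_mixture":
        positive = rng.random(config.n_promoters) < config.target_pos_fraction
        for s, pos in zip(sizes, positive):
            profile.append((int(s), 0) if pos else (0, int(s)))
    else:
        q = rng.beta(config.beta_a, config.beta_b, size=config.n_promoters)
        n_pos = rng.binomial(sizes, q)
        for s, npos in zip(sizes, n_pos):
            profile.append((int(npos), int(s - npos)))
    return profile


def _log_uniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    draw = int(math.exp(rng.uniform(math.log(lo), math.log(hi))))
    return min(max(draw, lo), hi)


def _place(
    tree: IntervalTree, start: int, end: int, chrom_length: int
) -> bool:
    if start < 0 or end > chrom_length:
        return False
    if tree.overlap(start, end):
        return False
    tree.addi(start, end)
    return True


def layout_genome(
    profile: Sequence[tuple[int, int]],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> EPDataset:
    """Place promoters and enhancers for the given group profile.

    Promoters (2 kb) are dropped uniformly at random on random chromosomes;
    each group's enhancers (1 kb) go on a random side of their promoter at
    a log-uniform gap in ``[min_distance, max_distance]``.  No two elements
    overlap.  The returned dataset has labels set and an empty feature
    table.
    """
    if not profile:
        raise ConfigurationError("profile must contain at least one group")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    occupied = {c: IntervalTree() for c in chroms}
    margin = config.max_distance + ENHANCER_WIDTH
    lo = margin
    hi = config.chrom_length - margin - PROMOTER_WIDTH
    pairs: list[EPPair] = []
    pair_counter = 0
    for g, (n_pos, n_neg) in enumerate(profile):
        if n_pos + n_neg < 1:
            raise ConfigurationError(f"group {g} has no pairs")
        promoter_id = f"prom_{g:05d}"
        placed = None
        for _ in range(_MAX_PLACEMENT_TRIES):
            chrom = chroms[int(rng.integers(config.n_chromosomes))]
            start = int(rng.integers(lo, hi + 1))
            if _place(occupied[chrom], start, start + PROMOTER_WIDTH, config.chrom_length):
                placed = GenomicInterval(chrom, start, start + PROMOTER_WIDTH)
                break
        if placed is None:
            raise CapacityError(
                f"could not place promoter {g} after {_MAX_PLACEMENT_TRIES} tries; "
                "genome too crowded"
            )
        labels = [1] * n_pos + [0] * n_neg
        for label in labels:
            enh = None
            for _ in range(_MAX_PLACEMENT_TRIES):
                gap = _log_uniform(rng, config.min_distance, config.max_distance)
                if rng.random() < 0.5:
                    e_start = placed.start - gap - ENHANCER_WIDTH
                else:
                    e_start = placed.end + gap
                e_end = e_start + ENHANCER_WIDTH
                if _place(occupied[placed.chrom], e_start, e_end, config.chrom_length):
                    enh = GenomicInterval(placed.chrom, e_start, e_end)
                    break
            if enh is None:
                raise CapacityError(
                    f"could not place an enhancer for promoter {g}; genome too crowded"
                )
            pairs.append(
                EPPair(f"pair_{pair_counter:06d}", enh, placed, promoter_id, label)
            )
            pair_counter += 1
    return EPDataset(pairs, FeatureTable.empty(len(pairs)))


def _window_track_means(
    dataset: EPDataset, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Mean of a per-chromosome piecewise-constant N(0,1) track per window.

    One independent track per chromosome and mark; the W feature of a pair
    is the average track value over its window, so overlapping windows
    share signal in proportion to their overlap.
    """
    m = config.marks_per_region
    seg = config.track_segment_bp
    n_seg = math.ceil(config.chrom_length / seg)
    chrom_order = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    out = np.zeros((dataset.n_pairs, m))
    windows = [window_interval(p) for p in dataset.pairs]
    for chrom in chrom_order:
        idx = [i for i, w in enumerate(windows) if w.chrom == chrom]
        track = rng.standard_normal((n_seg, m))
        if not idx:
            continue
        prefix = np.vstack([np.zeros((1, m)), np.cumsum(track, axis=0)]) * float(seg)

        def integral(x: np.ndarray) -> np.ndarray:
            j = np.minimum(x // seg, n_seg - 1)
            r = x - j * seg
            return prefix[j] + r[:, None] * track[j]

        a = np.array([windows[i].start for i in idx])
        b = np.array([windows[i].end for i in idx])
        out[idx] = (integral(b) - integral(a)) / (b - a)[:, None]
    return out


def generate_features(
    dataset: EPDataset, config: GeneratorConfig, rng: np.random.Generator
) -> FeatureTable:
    """Draw E, P and W feature blocks for a laid-out dataset.

    * P columns: one standard-normal latent vector per promoter, copied to
      every pair of that promoter (hence bit-identical within a group).
    * E columns: one standard-normal latent vector per enhancer, plus a
      mean shift ``signal_strength`` on the first ``n_signal_features``
      columns of positive pairs.
    * W columns: window averages of per-chromosome latent tracks.
    * Optional iid noise with sd ``feature_noise_sd`` on all blocks.
    """
    m = config.marks_per_region
    n = dataset.n_pairs
    labels = dataset.labels

    e_block = rng.standard_normal((n, m))
    if config.signal_strength > 0 and config.n_signal_features > 0:
        e_block[labels == 1, : config.n_signal_features] += config.signal_strength

    prom_order: list[str] = []
    seen: set[str] = set()
    for p in dataset.pairs:
        if p.promoter_id not in seen:
            seen.add(p.promoter_id)
            prom_order.append(p.promoter_id)
    latents = {pid: rng.standard_normal(m) for pid in prom_order}
    p_block = np.stack([latents[p.promoter_id] for p in dataset.pairs])

    w_block = _window_track_means(dataset, config, rng)

    values = np.hstack([e_block, p_block, w_block])
    if config.feature_noise_sd > 0:
        values = values + rng.normal(0.0, config.feature_noise_sd, size=values.shape)

    names = [f"mark{j + 1:03d}" for j in range(m)] * 3
    blocks = ["E"] * m + ["P"] * m + ["W"] * m
    return FeatureTable(values, names, blocks)


def simulate(config: GeneratorConfig) -> EPDataset:
    """Run the full generator: group profile -> genome layout -> features.

    Deterministic: the same config (including ``seed``) yields a
    bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    profile = sample_group_profile(config, rng)
    dataset = layout_genome(profile, config, rng)
    dataset.features = generate_features(dataset, config, rng)
    return dataset


def write_provenance(path: str | Path, config: GeneratorConfig) -> None:
    """Record the exact generator configuration next to a written dataset."""
    with open(path, "w") as fh:
        json.dump({"generator": "epileak.synthetic_data", "config": config.to_dict()}, fh, indent=2)
        fh.write("\n")
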