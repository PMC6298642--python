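"""Shared fixtures: small generator configs and hand-built datasets."""

from __future__ import annotations

import numpy as np
import pytest

from epileak.ep_data import EPDataset, EPPair, FeatureTable, GenomicInterval
from epileak.synthetic_data import GeneratorConfig, simulate


def small_config(**overrides) -> GeneratorConfig:
    """A fast generator configuration for unit tests."""
    base = dict(
        n_chromosomes=3,
        chrom_length=20_000_000,
        n_promoters=60,
        marks_per_region=12,
        n_signal_features=8,
        max_distance=500_000,
        seed=0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def make_dataset(
    group_counts: list[tuple[int, int]],
    chrom: str = "chr1",
    spacing: int = 5_000_000,
    gap: int = 20_000,
    gap_step: int = 30_000,
    n_features: int = 0,
    seed: int = 0,
) -> EPDataset:
    """Hand-built dataset: one promoter per (n_pos, n_neg) group.

    Promoters are spaced far apart; each group's enhancers sit on the
    right side at increasing gaps, so same-group windows nest but groups
    do not interact (with the default spacing).
    """
    pairs = []
    rng = np.random.default_rng(seed)
    counter = 0
    for g, (n_pos, n_neg) in enumerate(group_counts):
        p_start = 1_000_000 + g * spacing
        prom = GenomicInterval(chrom, p_start, p_start + 2_000)
        for j, label in enumerate([1] * n_pos + [0] * n_neg):
            e_start = prom.end + gap + j * gap_step
            enh = GenomicInterval(chrom, e_start, e_start + 1_000)
            pairs.append(EPPair(f"pair_{counter:04d}", enh, prom, f"prom_{g:03d}", label))
            counter += 1
    if n_features:
        features = FeatureTable(
            rng.standard_normal((len(pairs), n_features)),
            [f"mark{j}" for j in range(n_features)],
            (["E", "P", "W"] * n_features)[:n_features],
        )
    else:
        features = FeatureTable.empty(len(pairs))
    return EPDataset(pairs, features)


@pytest.fixture(scope="session")
def small_dataset() -> EPDataset:
    return simulate(small_config())


@pytest.fixture(scope="session")
def default_dataset() -> EPDataset:
    """Full-size dataset at the generator defaults (408 features)."""
    return simulate(GeneratorConfig(seed=0))


@pytest.fixture
def fig1_fixture() -> EPDataset:
    """Three (7 pos, 2 neg) promoter groups: 27 pairs in cell (7, 2)."""
    return make_dataset([(7, 2)] * 3)
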