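"""Generator: group profiles, genome layout, and feature-sharing structure."""

import numpy as np
import pytest
from scipy import stats

from epileak.ep_data import (
    EPDataset,
    EPPair,
    FeatureTable,
    GenomicInterval,
    window_interval,
)
from epileak.synthetic_data import (
    ConfigurationError,
    GeneratorConfig,
    generate_features,
    layout_genome,
    sample_group_profile,
    simulate,
)

from .conftest import small_config


class TestGroupProfile:
    def test_pure_mixture_hits_the_target_positive_fraction(self):
        """Realized pair-level positive fraction matches 1/21 in expectation.

        Averaged over seeds to keep Monte-Carlo noise well below the
        tolerance; each individual draw concentrates as n_promoters grows.
        """
        fractions = []
        for seed in range(10):
            cfg = GeneratorConfig(n_promoters=400, seed=seed)
            profile = sample_group_profile(cfg, np.random.default_rng(seed))
            pos = sum(a for a, _ in profile)
            tot = sum(a + b for a, b in profile)
            fractions.append(pos / tot)
        assert abs(np.mean(fractions) - 1 / 21) < 0.02

    def test_positive_fraction_concentrates_at_large_n(self):
        cfg = GeneratorConfig(n_promoters=2000)
        fractions = []
        for seed in range(5):
            profile = sample_group_profile(cfg, np.random.default_rng(seed))
            pos = sum(a for a, _ in profile)
            tot = sum(a + b for a, b in profile)
            fractions.append(pos / tot)
        assert abs(np.mean(fractions) - 1 / 21) < 0.01

    def test_pure_mixture_groups_are_pure_and_bounded(self):
        cfg = GeneratorConfig(n_promoters=300, seed=3)
        profile = sample_group_profile(cfg, np.random.default_rng(3))
        for n_pos, n_neg in profile:
            assert n_pos == 0 or n_neg == 0
            assert 2 <= n_pos + n_neg <= cfg.group_size_max

    def test_zero_target_gives_all_negative_groups(self):
        cfg = GeneratorConfig(n_promoters=50, target_pos_fraction=0.0)
        profile = sample_group_profile(cfg, np.random.default_rng(0))
        assert all(n_pos == 0 for n_pos, _ in profile)

    def test_symmetric_beta_mode_centers_on_half(self):
        cfg = GeneratorConfig(
            n_promoters=2000, profile_mode="beta", beta_a=2.0, beta_b=2.0
        )
        profile = sample_group_profile(cfg, np.random.default_rng(0))
        pos = sum(a for a, _ in profile)
        tot = sum(a + b for a, b in profile)
        assert abs(pos / tot - 0.5) < 0.03

    def test_beta_mode_produces_mixed_groups(self):
        cfg = GeneratorConfig(n_promoters=500, profile_mode="beta")
        profile = sample_group_profile(cfg, np.random.default_rng(1))
        assert any(a > 0 and b > 0 for a, b in profile)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(target_pos_fraction=1.5)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(profile_mode="uniform")
        with pytest.raises(ConfigurationError):
            GeneratorConfig(group_size_mean=1.0)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(min_distance=100, max_distance=50)


class TestLayout:
    def test_single_group_shares_promoter(self):
        cfg = small_config(n_promoters=1)
        ds = layout_genome([(1, 1)], cfg, np.random.default_rng(0))
        assert ds.n_pairs == 2
        assert ds.pairs[0].promoter_id == ds.pairs[1].promoter_id
        assert ds.pairs[0].promoter == ds.pairs[1].promoter

    def test_gap_bounds_respected(self, small_dataset):
        cfg = small_config()
        for p in small_dataset.pairs:
            gap = max(p.enhancer.start, p.promoter.start) - min(
                p.enhancer.end, p.promoter.end
            )
            assert cfg.min_distance <= gap <= cfg.max_distance

    def test_no_two_elements_overlap(self, small_dataset):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in small_dataset.pairs:
            by_chrom.setdefault(p.chrom, []).append((p.enhancer.start, p.enhancer.end))
        for p in {pp.promoter_id: pp for pp in small_dataset.pairs}.values():
            by_chrom.setdefault(p.chrom, []).append((p.promoter.start, p.promoter.end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2

    def test_same_side_enhancers_have_overlapping_windows(self):
        cfg = small_config(n_promoters=1, min_distance=10_000, max_distance=50_000)
        # keep drawing until one group lands two enhancers on the same side
        for seed in range(50):
            ds = layout_genome([(2, 0)], cfg, np.random.default_rng(seed))
            a, b = ds.pairs
            same_side = (a.enhancer.start > a.promoter.end) == (
                b.enhancer.start > b.promoter.end
            )
            if same_side:
                assert window_interval(a).overlaps(window_interval(b))
                return
        pytest.fail("no same-side placement in 50 draws")


class TestFeatures:
    def test_promoter_block_identical_within_group(self, small_dataset):
        from epileak.ep_data import feature_subset

        p_block = feature_subset(small_dataset, {"P"}).values
        by_prom: dict[str, int] = {}
        for i, pair in enumerate(small_dataset.pairs):
            if pair.promoter_id in by_prom:
                np.testing.assert_array_equal(p_block[i], p_block[by_prom[pair.promoter_id]])
            else:
                by_prom[pair.promoter_id] = i

    def test_default_dataset_has_epw_408_columns(self, default_dataset):
        counts = default_dataset.features.block_counts()
        assert counts == {"E": 136, "P": 136, "W": 136}
        assert default_dataset.features.n_features == 408

    def test_null_features_carry_no_label_signal(self, default_dataset):
        """With zero signal strength, positives and negatives are
        distributionally identical feature by feature.

        E features are iid per pair and P features iid per promoter, so a
        two-sample KS test applies at the pair and group level
        respectively; none should reject after Bonferroni at alpha=0.01.
        (W features are shared across overlapping windows and have no iid
        sampling unit, but are built from label-blind tracks.)
        """
        from epileak.ep_data import feature_subset

        y = default_dataset.labels
        e_block = feature_subset(default_dataset, {"E"}).values
        p_block = feature_subset(default_dataset, {"P"}).values
        first_of_group: dict[str, int] = {}
        for i, pair in enumerate(default_dataset.pairs):
            first_of_group.setdefault(pair.promoter_id, i)
        gi = np.array(sorted(first_of_group.values()))

        pvals = []
        for j in range(e_block.shape[1]):
            pvals.append(stats.ks_2samp(e_block[y == 1, j], e_block[y == 0, j]).pvalue)
        for j in range(p_block.shape[1]):
            pvals.append(
                stats.ks_2samp(p_block[gi[y[gi] == 1], j], p_block[gi[y[gi] == 0], j]).pvalue
            )
        assert min(pvals) > 0.01 / len(pvals)

    def test_signal_shifts_positive_enhancer_features(self):
        cfg = small_config(signal_strength=2.0, n_signal_features=4, seed=5)
        ds = simulate(cfg)
        from epileak.ep_data import feature_subset

        e_block = feature_subset(ds, {"E"}).values
        y = ds.labels
        shift = e_block[y == 1, :4].mean() - e_block[y == 0, :4].mean()
        assert shift > 1.0
        rest = e_block[y == 1, 4:].mean() - e_block[y == 0, 4:].mean()
        assert abs(rest) < 0.5

    def test_window_correlation_increases_with_overlap(self):
        """W vectors of two pairs correlate according to window overlap.

        Three two-promoter geometries with overlap fractions ~0, 0.5 and
        ~1 between equal-length windows; the across-mark correlation of
        the two W rows must increase and approach 1 at full overlap.
        """
        L = 400_000
        m = 300
        cfg = GeneratorConfig(
            n_chromosomes=1,
            chrom_length=20_000_000,
            n_promoters=2,
            marks_per_region=m,
            seed=11,
        )

        def corr_for(offset: int) -> float:
            a_start = 1_000_000
            b_start = a_start + offset
            prom_a = GenomicInterval("chr1", a_start - 2_000, a_start)
            prom_b = GenomicInterval("chr1", b_start - 4_000, b_start - 2_000)
            pairs = [
                EPPair("a", GenomicInterval("chr1", a_start + L, a_start + L + 1_000),
                       prom_a, "pa", 1),
                EPPair("b", GenomicInterval("chr1", b_start + L, b_start + L + 1_000),
                       prom_b, "pb", 0),
            ]
            ds = EPDataset(pairs, FeatureTable.empty(2))
            ft = generate_features(ds, cfg, np.random.default_rng(11))
            w = ft.values[:, 2 * m:]
            return float(np.corrcoef(w[0], w[1])[0, 1])

        c_full = corr_for(6_000)      # ~98.5% overlap
        c_half = corr_for(L // 2)     # ~50% overlap
        c_none = corr_for(2 * L)      # disjoint windows
        assert c_none < c_half < c_full
        assert c_full > 0.9
        assert abs(c_half - 0.5) < 0.25
        assert abs(c_none) < 0.25


class TestSimulate:
    def test_same_seed_is_bit_identical(self):
        cfg = small_config(seed=42)
        d1, d2 = simulate(cfg), simulate(cfg)
        assert d1.pairs == d2.pairs
        np.testing.assert_array_equal(d1.features.values, d2.features.values)

    def test_different_seeds_differ(self):
        d1 = simulate(small_config(seed=1))
        d2 = simulate(small_config(seed=2))
        assert [p.enhancer for p in d1.pairs] != [p.enhancer for p in d2.pairs]
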