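"""Ground-truth cohort generation: graphs, signals, behavioral table."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, pearsonr

from bandclust.connectivity import BETA, DELTA, epoch, wpli
from bandclust.synthetic import (
    EffectConfig,
    NoiseConfig,
    SubgroupSpec,
    check_density_match,
    expected_density,
    generate_cohort,
    make_behavioral_table,
    make_coupling_graph,
    synthesize_recording,
)


class TestCouplingGraph:
    def test_forced_block_structure(self):
        spec = SubgroupSpec("segregated", community_count=2, p_within=1.0, p_between=0.0)
        g = make_coupling_graph(spec, DELTA, n_channels=4, seed=0)
        assert set(g.edges) == {(0, 1), (2, 3)}

    def test_determinism(self):
        spec = SubgroupSpec("segregated")
        a = make_coupling_graph(spec, BETA, n_channels=19, seed=11)
        b = make_coupling_graph(spec, BETA, n_channels=19, seed=11)
        assert a == b

    def test_edge_counts_match_binomial_expectation(self):
        """Within/between edge counts agree with the binomial model to 3 SD,
        pooled over seeds."""
        spec = SubgroupSpec("segregated", community_count=4, p_within=0.6, p_between=0.05)
        n_ch, n_rep = 19, 40
        from bandclust.synthetic import _pair_masks

        within_mask, between_mask = _pair_masks(n_ch, 4)
        W, B = int(within_mask.sum()), int(between_mask.sum())
        w_count = b_count = 0
        for seed in range(n_rep):
            g = make_coupling_graph(spec, DELTA, n_channels=n_ch, seed=seed)
            comm = np.zeros(n_ch, dtype=int)
            for c, members in enumerate(np.array_split(np.arange(n_ch), 4)):
                comm[members] = c
            for i, j in g.edges:
                if comm[i] == comm[j]:
                    w_count += 1
                else:
                    b_count += 1
        for count, m, p in ((w_count, W, 0.6), (b_count, B, 0.05)):
            mean = n_rep * m * p
            sd = np.sqrt(n_rep * m * p * (1 - p))
            assert abs(count - mean) <= 3 * sd

    def test_lags_in_declared_range(self):
        g = make_coupling_graph(SubgroupSpec("integrated"), BETA, 19, seed=3)
        assert all(np.pi / 8 <= lag <= 3 * np.pi / 8 for lag in g.lag_per_edge)

    def test_density_matched_templates(self):
        seg = SubgroupSpec("segregated")
        integ = SubgroupSpec("integrated")
        assert expected_density(seg, 19) == pytest.approx(expected_density(integ, 19))

    def test_density_mismatch_detected(self):
        a = make_coupling_graph(
            SubgroupSpec("segregated", p_within=1.0, p_between=0.5), DELTA, 12, seed=0
        )
        b = make_coupling_graph(
            SubgroupSpec("integrated", p_within=0.1, p_between=0.1), DELTA, 12, seed=0
        )
        with pytest.raises(ValueError, match="density mismatch"):
            check_density_match(a, b)


class TestSynthesizeRecording:
    def _graphs(self, seed=0, n_ch=10):
        seg = SubgroupSpec("segregated")
        rng = np.random.default_rng(seed)
        return (
            make_coupling_graph(seg, DELTA, n_ch, rng),
            make_coupling_graph(seg, BETA, n_ch, rng),
        )

    def test_sample_count(self):
        gd, gb = self._graphs()
        rec = synthesize_recording(gd, gb, duration_s=120.0, rate_hz=256.0, seed=1)
        assert rec.data.shape == (10, 30720)

    def test_determinism(self):
        gd, gb = self._graphs()
        r1 = synthesize_recording(gd, gb, duration_s=8.0, seed=5)
        r2 = synthesize_recording(gd, gb, duration_s=8.0, seed=5)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_nyquist_violation_rejected(self):
        gd, gb = self._graphs()
        with pytest.raises(ValueError, match="Nyquist"):
            synthesize_recording(gd, gb, duration_s=8.0, rate_hz=50.0, seed=0)

    def _planted_vs_nonplanted(self, coupling_gain, noise, seed=0):
        gd, gb = self._graphs(seed=seed)
        rec = synthesize_recording(
            gd, gb, duration_s=60.0, noise=noise, seed=seed,
            coupling_gain=coupling_gain,
        )
        w = wpli(epoch(rec), BETA).weights
        iu, ju = np.triu_indices(rec.n_channels, k=1)
        edge_set = set(gb.edges)
        planted = [w[i, j] for i, j in zip(iu, ju) if (i, j) in edge_set]
        other = [w[i, j] for i, j in zip(iu, ju) if (i, j) not in edge_set]
        return np.array(planted), np.array(other)

    def test_zero_gain_removes_all_signal(self):
        """With no coupling, planted and non-planted pairs are statistically
        indistinguishable."""
        planted, other = [], []
        for seed in range(8):  # pool pairs across seeds
            p, o = self._planted_vs_nonplanted(
                0.0, NoiseConfig(pink_gain=1.0, zero_lag_mix_gain=0.0), seed=seed
            )
            planted.extend(p)
            other.extend(o)
        assert len(planted) + len(other) >= 100
        _, pval = mannwhitneyu(planted, other, alternative="two-sided")
        assert pval > 0.01

    def test_zero_lag_confound_suppressed(self):
        """A strong shared instantaneous source alone leaves mean wPLI < 0.1."""
        p, o = self._planted_vs_nonplanted(
            0.0, NoiseConfig(pink_gain=0.3, zero_lag_mix_gain=3.0)
        )
        assert np.concatenate([p, o]).mean() < 0.1

    def test_planted_edges_recoverable(self):
        """Strong lagged coupling without the zero-lag confound separates
        planted from non-planted pairs by >= 0.15 mean wPLI."""
        p, o = self._planted_vs_nonplanted(
            1.5, NoiseConfig(pink_gain=0.5, zero_lag_mix_gain=0.0)
        )
        assert p.mean() - o.mean() >= 0.15


class TestBehavioral:
    def test_subgroup_sizes(self):
        cohort = generate_cohort(
            n_participants=31, subgroup_fraction=11 / 31, seed=0,
            n_channels=4, duration_s=8.0,
        )
        assert int((cohort.ground_truth == 2).sum()) == 11

    def test_null_effects_uncorrelated_with_subgroup(self):
        """Zero effect_config: |point-biserial r(label, wm2)| <= 0.4 averaged
        over seeds at n = 31."""
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = np.ones(31, dtype=int)
            labels[:11] = 2
            df = make_behavioral_table(labels, EffectConfig.null(), rng)
            rs.append(pearsonr(labels, df["wm2"])[0])
        assert abs(np.mean(rs)) <= 0.4

    def test_wm2_shift_orders_cluster_means(self):
        rng = np.random.default_rng(1)
        labels = np.ones(62, dtype=int)
        labels[:22] = 2
        df = make_behavioral_table(labels, EffectConfig(wm2_shift=6.0), rng)
        assert df.loc[labels == 2, "wm2"].mean() > df.loc[labels == 1, "wm2"].mean()

    def test_device_use_independent_of_subgroup(self):
        """Ordinal device-use draws come from subgroup-independent
        distributions; pooled over seeds the group means agree closely."""
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = np.ones(40, dtype=int)
            labels[:20] = 2
            df = make_behavioral_table(labels, EffectConfig(), rng)
            diffs.append(
                df.loc[labels == 2, "child_weekend_use"].mean()
                - df.loc[labels == 1, "child_weekend_use"].mean()
            )
        assert abs(np.mean(diffs)) < 0.15

    def test_schema_and_ranges(self):
        rng = np.random.default_rng(0)
        labels = np.ones(20, dtype=int)
        labels[:7] = 2
        df = make_behavioral_table(labels, EffectConfig(), rng)
        ordinals = [
            "child_weekday_use",
            "child_weekend_use",
            "parent_weekday_use",
            "parent_weekend_use",
        ]
        assert df[ordinals].isin([0, 1, 2, 3]).all().all()
        assert (df[["wm1", "wm2", "wm3", "errors"]] >= 0).all().all()
        assert set(df["sex"]) <= {"girl", "boy"}
        assert set(df["parent_education"]) <= {"higher", "secondary"}


class TestCohort:
    def test_determinism_bit_identical(self):
        a = generate_cohort(n_participants=4, seed=9, n_channels=4, duration_s=8.0)
        b = generate_cohort(n_participants=4, seed=9, n_channels=4, duration_s=8.0)
        for (p1, q1), (p2, q2) in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(p1.data, p2.data)
            np.testing.assert_array_equal(q1.data, q2.data)
        assert a.behavioral.equals(b.behavioral)
        np.testing.assert_array_equal(a.ground_truth, b.ground_truth)

    def test_pre_and_post_share_template_not_noise(self):
        cohort = generate_cohort(
            n_participants=4, seed=2, n_channels=4, duration_s=8.0
        )
        pre, post = cohort.recordings[0]
        assert pre.participant_id == post.participant_id
        assert not np.array_equal(pre.data, post.data)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError, match="at least 4"):
            generate_cohort(n_participants=3, seed=0)
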