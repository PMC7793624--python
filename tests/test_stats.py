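"""Repertoire statistics: MMD, rank tests, shuffle test, information, UMAP."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.stats import rankdata

from usvkit import synth, segment
from usvkit.stats import (
    rbf_mmd2, half_split_baseline_mmd, paired_repertoire_comparison,
    wilcoxon_signed_rank, mann_whitney_u, mean_latent_shift, cosine_similarity,
    shift_consistency_shuffle_test, condition_information, umap_embed,
    syllable_acoustic_features, median_heuristic_bandwidth,
)


def _labels(mouse, cond, n, onset0=0.0):
    return pd.DataFrame({
        "mouse_id": [mouse] * n, "condition": [cond] * n,
        "onset_s": onset0 + np.arange(n) * 0.5,
    })


class TestMMD:
    def test_identical_multisets_zero(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        res = rbf_mmd2(X, X.copy(), estimator="biased_v")
        assert res.value == pytest.approx(0.0, abs=1e-12)
        assert res.value >= 0

    def test_hand_computed_two_point_example(self):
        res = rbf_mmd2(np.array([[0.0]]), np.array([[1.0]]), bandwidth=1.0,
                       estimator="biased_v")
        assert res.value == pytest.approx(2 - 2 * np.exp(-0.5), abs=1e-9)

    def test_biased_nonnegative_unbiased_near_zero_under_null(self):
        rng = np.random.default_rng(1)
        vals_b, vals_u = [], []
        for _ in range(60):
            X, Y = rng.normal(size=(2, 60, 4))
            vals_b.append(rbf_mmd2(X, Y, bandwidth=1.5, estimator="biased_v").value)
            vals_u.append(rbf_mmd2(X, Y, bandwidth=1.5, estimator="unbiased_u").value)
        assert min(vals_b) >= 0
        se = np.std(vals_u) / np.sqrt(len(vals_u))
        assert abs(np.mean(vals_u)) <= 3 * se

    def test_increases_with_mean_shift(self):
        rng = np.random.default_rng(2)
        means = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            vals = []
            for _ in range(20):
                X = rng.normal(size=(300, 5))
                Y = rng.normal(size=(300, 5)) + delta
                vals.append(rbf_mmd2(X, Y, bandwidth=2.0).value)
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            rbf_mmd2(np.zeros((3, 2)), np.zeros((3, 3)))


class TestHalfSplitBaseline:
    def test_split_rule_at_minimum_size(self):
        res = half_split_baseline_mmd(np.arange(4.0).reshape(-1, 1))
        assert (res.n1, res.n2) == (2, 2)

    def test_iid_session_baseline_near_zero(self):
        rng = np.random.default_rng(3)
        vals = [half_split_baseline_mmd(rng.normal(size=(1000, 4))).value
                for _ in range(50)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) <= 3 * se

    def test_mid_session_drift_inflates_baseline(self):
        rng = np.random.default_rng(4)
        iid = rng.normal(size=(400, 4))
        drift = np.vstack([rng.normal(size=(200, 4)), rng.normal(size=(200, 4)) + 1.0])
        sigma = median_heuristic_bandwidth(drift)
        assert (half_split_baseline_mmd(drift, bandwidth=sigma).value
                > half_split_baseline_mmd(iid, bandwidth=sigma).value)

    def test_too_few_syllables_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            half_split_baseline_mmd(np.zeros((3, 2)))


def _brute_force_signed_rank_p(d):
    """Independent oracle: enumerate all sign assignments of the ranks."""
    ranks = rankdata(np.abs(d))
    n = len(d)
    w_obs = min(ranks[np.asarray(d) > 0].sum(), ranks[np.asarray(d) < 0].sum())
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        s_pos = sum(r for r, s in zip(ranks, signs) if s)
        if min(s_pos, ranks.sum() - s_pos) <= w_obs:
            count += 1
    return count / 2**n


class TestWilcoxonSignedRank:
    def test_all_positive_n5(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], mode="exact")
        assert res["W"] == 0
        assert res["p"] == pytest.approx(2 / 32)

    def test_reported_w9_n15_normal_cc(self):
        d = np.arange(1, 16.0)
        d[8] *= -1  # one negative difference of rank 9 -> W = 9
        cc = wilcoxon_signed_rank(d, mode="normal_cc")
        assert cc["W"] == 9
        assert cc["p"] == pytest.approx(2 * sps.norm.cdf((9 - 60 + 0.5) / np.sqrt(310)))
        assert wilcoxon_signed_rank(d, mode="exact")["p"] == pytest.approx(0.00201416015625)

    @pytest.mark.parametrize("n", [5, 7, 9, 11])
    def test_exact_matches_sign_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(0.4, 1.0, n)
        res = wilcoxon_signed_rank(d, mode="exact")
        assert res["p"] == pytest.approx(_brute_force_signed_rank_p(d), abs=1e-12)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, 12)
            assert wilcoxon_signed_rank(d, "exact")["p"] == pytest.approx(
                sps.wilcoxon(d, method="exact").pvalue, abs=1e-12
            )

    def test_normal_cc_close_to_exact_for_n20(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            d = rng.normal(0.2, 1.0, 20)
            p_cc = wilcoxon_signed_rank(d, "normal_cc")["p"]
            p_ex = wilcoxon_signed_rank(d, "exact")["p"]
            assert abs(p_cc - p_ex) < 0.01

    def test_auto_selects_exact_then_normal(self):
        d = np.random.default_rng(7).normal(0.3, 1, 10)
        assert wilcoxon_signed_rank(d, "auto")["mode"] == "exact"
        assert wilcoxon_signed_rank(np.r_[d, d, d], "auto")["mode"] == "normal_cc"

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0] * 10)


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0

    def test_identical_samples(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p"] >= 0.99

    def test_exact_matches_permutation_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(4):
            x, y = rng.normal(0, 1, 4), rng.normal(0.8, 1, 4)
            res = mann_whitney_u(x, y)
            pooled = np.concatenate([x, y])
            ranks = rankdata(pooled)
            Us = np.array([
                ranks[list(c)].sum() - 10 for c in itertools.combinations(range(8), 4)
            ])
            lo, hi = min(res["U"], 16 - res["U"]), max(res["U"], 16 - res["U"])
            p_oracle = ((Us <= lo).sum() + (Us >= hi).sum()) / len(Us)
            assert res["p"] == pytest.approx(p_oracle, abs=1e-9)


class TestShiftVectors:
    def test_constant_offset_recovered(self):
        rng = np.random.default_rng(9)
        Xa = rng.normal(size=(500, 6))
        c = np.array([1.0, -2.0, 0.5, 0, 0, 3.0])
        X = np.vstack([Xa, Xa + c])
        labels = pd.concat([_labels("m0", "A", 500), _labels("m0", "B", 500)],
                           ignore_index=True)
        shift = mean_latent_shift(X, labels, "m0")
        assert shift.shape == (6,)
        assert np.allclose(shift, c)

    def test_null_shift_small_norm(self):
        rng = np.random.default_rng(10)
        n, d = 2000, 5
        X = rng.normal(size=(2 * n, d))
        labels = pd.concat([_labels("m0", "A", n), _labels("m0", "B", n)],
                           ignore_index=True)
        shift = mean_latent_shift(X, labels, "m0")
        assert np.linalg.norm(shift) <= 3 * np.sqrt(2 * d / n)

    @pytest.mark.parametrize("u,v,expected", [
        ((1, 0), (0, 1), 0.0), ((1, 1), (2, 2), 1.0), ((1, 0), (-1, 0), -1.0),
    ])
    def test_cosine_similarity_cases(self, u, v, expected):
        assert cosine_similarity(u, v) == pytest.approx(expected)

    def test_cosine_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])


def _multi_mouse_data(n_mice, n_per, shift_vec, seed):
    rng = np.random.default_rng(seed)
    X, frames = [], []
    for i in range(n_mice):
        center = rng.normal(scale=0.5, size=len(shift_vec))
        X.append(rng.normal(size=(n_per, len(shift_vec))) + center)
        X.append(rng.normal(size=(n_per, len(shift_vec))) + center + shift_vec)
        frames.append(_labels(f"m{i}", "A", n_per))
        frames.append(_labels(f"m{i}", "B", n_per))
    return np.vstack(X), pd.concat(frames, ignore_index=True)


class TestShuffleTest:
    def test_common_shift_saturates_p(self):
        X, labels = _multi_mouse_data(6, 80, np.array([3.0, 0, 0, 0]), seed=11)
        res = shift_consistency_shuffle_test(X, labels, n_shuffles=200, seed=0)
        assert res.observed_mean_cosine > 0.9
        assert res.p == pytest.approx(1 / 201)

    def test_add_one_rule_and_determinism(self):
        X, labels = _multi_mouse_data(4, 40, np.zeros(4), seed=12)
        r1 = shift_consistency_shuffle_test(X, labels, n_shuffles=150, seed=5)
        r2 = shift_consistency_shuffle_test(X, labels, n_shuffles=150, seed=5)
        assert r1.p == (1 + np.sum(r1.null_sample >= r1.observed_mean_cosine)) / 151
        assert r1.p == r2.p
        assert np.array_equal(r1.null_sample, r2.null_sample)

    def test_observed_invariant_to_mouse_ordering(self):
        X, labels = _multi_mouse_data(5, 30, np.array([1.0, 0, 0, 0]), seed=13)
        perm = np.random.default_rng(0).permutation(len(X))
        r1 = shift_consistency_shuffle_test(X, labels, n_shuffles=100, seed=1)
        r2 = shift_consistency_shuffle_test(
            X[perm], labels.iloc[perm].reset_index(drop=True), n_shuffles=100, seed=1
        )
        assert r1.observed_mean_cosine == pytest.approx(r2.observed_mean_cosine)

    def test_requires_three_mice(self):
        X, labels = _multi_mouse_data(2, 20, np.zeros(3), seed=14)
        with pytest.raises(ValueError, match="3 mice"):
            shift_consistency_shuffle_test(X, labels, n_shuffles=100, seed=0)


class TestPairedComparison:
    def test_per_mouse_rows_and_shifted_data_significant(self):
        X, labels = _multi_mouse_data(15, 100, np.array([1.5, 0, 0, 0]), seed=15)
        res = paired_repertoire_comparison(X, labels)
        assert len(res.per_mouse) == 15
        assert res.n_cross_greater >= 12
        assert res.p < 0.05

    def test_missing_condition_names_mouse(self):
        labels = pd.concat([_labels("m0", "A", 10), _labels("m1", "A", 10),
                            _labels("m1", "B", 10)], ignore_index=True)
        X = np.zeros((30, 3))
        with pytest.raises(ValueError, match="m0"):
            paired_repertoire_comparison(X, labels)


class TestConditionInformation:
    def test_independent_labels_carry_no_information(self):
        rng = np.random.default_rng(16)
        bits = []
        for seed in range(5):
            X = rng.normal(size=(400, 6))
            y = np.array(["A", "B"])[rng.integers(0, 2, 400)]
            bits.append(condition_information(X, y, seed=seed).bits)
        assert np.mean(bits) <= 0.05

    def test_separable_classes_near_one_bit(self):
        rng = np.random.default_rng(17)
        X = np.vstack([rng.normal(size=(200, 4)), rng.normal(size=(200, 4)) + 8.0])
        y = np.array(["A"] * 200 + ["B"] * 200)
        res = condition_information(X, y, seed=0)
        assert res.bits >= 0.9
        assert res.bits <= res.base_rate_entropy

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            condition_information(np.zeros((20, 2)), ["A"] * 20)


class TestUmap:
    def test_embedding_shape_determinism_and_cluster_preservation(self):
        rng = np.random.default_rng(18)
        X = np.vstack([rng.normal(size=(60, 5)), rng.normal(size=(60, 5)) + 6.0])
        labels = np.array([0] * 60 + [1] * 60)
        E1 = umap_embed(X, seed=4)
        E2 = umap_embed(X, seed=4)
        assert E1.shape == (120, 2)
        assert np.allclose(E1, E2)
        # nearest-neighbor label purity in the embedding
        from scipy.spatial.distance import cdist

        D = cdist(E1, E1)
        np.fill_diagonal(D, np.inf)
        purity = (labels[D.argmin(1)] == labels).mean()
        assert purity >= 0.9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            umap_embed(np.zeros((5, 3)), seed=0)


class TestAcousticFeatures:
    def test_energy_scales_quadratically(self):
        s1 = synth.SyllableSpec(amplitude=0.04)
        s2 = synth.SyllableSpec(amplitude=0.08)
        feats = []
        for s in (s1, s2):
            wav = synth.render_syllable(s, 250_000)
            sp = segment.compute_spectrogram(wav, 250_000)
            feats.append(syllable_acoustic_features(sp, 0.0, s.duration))
        assert feats[1]["total_energy"] == pytest.approx(4 * feats[0]["total_energy"], rel=0.05)

    def test_constant_tone_has_flat_track(self):
        s = synth.SyllableSpec(duration=0.05, f_start=60_000, f_end=60_000, jump_offset=0.0)
        sp = segment.compute_spectrogram(synth.render_syllable(s, 250_000), 250_000)
        feats = syllable_acoustic_features(sp, 0.0, s.duration)
        assert feats["bandwidth_hz"] <= 2 * 244.140625

    def test_shifted_condition_louder_and_broader(self, base_cond):
        cond_b = synth.shift_condition(
            base_cond, synth.ConditionShift(amplitude_gain=2.0, bandwidth_delta_hz=20_000.0)
        )
        rng = np.random.default_rng(19)
        out = {}
        for name, cond in (("A", base_cond), ("B", cond_b)):
            e, bw = [], []
            for _ in range(100):
                s = synth.sample_syllable_spec(cond, rng)
                sp = segment.compute_spectrogram(synth.render_syllable(s, 250_000), 250_000)
                f = syllable_acoustic_features(sp, 0.0, s.duration)
                e.append(f["total_energy"])
                bw.append(f["bandwidth_hz"])
            out[name] = (np.mean(e), np.mean(bw))
        assert out["B"][0] > out["A"][0]
        assert out["B"][1] > out["A"][1]


class TestPlots:
    def test_umap_scatter_writes_categorical_and_continuous(self, tmp_path):
        from usvkit.plots import umap_scatter

        rng = np.random.default_rng(20)
        emb = rng.normal(size=(50, 2))
        umap_scatter(emb, np.array(["A"] * 25 + ["B"] * 25),
                     tmp_path / "cond.png", label="condition")
        umap_scatter(emb, rng.random(50), tmp_path / "energy.svg", label="energy")
        assert (tmp_path / "cond.png").stat().st_size > 0
        assert (tmp_path / "energy.svg").stat().st_size > 0
        with pytest.raises(ValueError):
            umap_scatter(np.zeros((5, 3)), np.zeros(5))
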