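import itertools

import numpy as np
import pytest

from thalcort.stats import (PairedSample, binomial_subjects, bisymlog,
                            lempel_ziv, modulation_index,
                            normalize_to_baseline, perm_ancova,
                            wilcoxon_one_tailed)


def _paired(diffs):
    base = np.linspace(1.0, 2.0, len(diffs))
    return PairedSample(subjects=list(range(len(diffs))), baseline=base,
                        condition=base + np.asarray(diffs, dtype=float))


def _exact_wilcoxon_oracle(diffs, direction="less"):
    """Brute-force enumeration of the signed-rank null distribution."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    dist = np.asarray(dist)
    if direction == "less":
        return np.mean(dist <= w_obs)
    return np.mean(dist >= w_obs)


class TestWilcoxon:
    @pytest.mark.parametrize("n,expected", [(9, 0.001953125),
                                            (7, 0.0078125),
                                            (5, 0.03125)])
    def test_all_one_direction_dyadic(self, n, expected):
        diffs = -np.linspace(0.5, 1.5, n)
        p = wilcoxon_one_tailed(_paired(diffs), "less")
        assert p == pytest.approx(expected, rel=1e-9)

    def test_statistic_three_at_n9(self):
        # positive ranks sum to 3: only subsets {},{1},{2},{3},{1,2} are <= 3
        diffs = -np.linspace(0.5, 1.5, 9)
        diffs[0] = +0.1   # rank 1 positive
        diffs[1] = +0.2   # rank 2 positive -> W+ = 3
        p = wilcoxon_one_tailed(_paired(diffs), "less")
        assert p == pytest.approx(5 / 512, rel=1e-9)
        assert round(p, 4) == 0.0098

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        diffs = rng.standard_normal(8)
        while len(np.unique(np.abs(diffs))) < len(diffs):
            diffs = rng.standard_normal(8)
        p = wilcoxon_one_tailed(_paired(diffs), "less")
        assert p == pytest.approx(_exact_wilcoxon_oracle(diffs, "less"),
                                  rel=1e-9)

    def test_ties_warn_and_approximate(self):
        diffs = np.array([-1.0, -1.0, -2.0, -3.0, -4.0, -5.0])
        with pytest.warns(UserWarning, match="tied"):
            p = wilcoxon_one_tailed(_paired(diffs), "less")
        assert 0 < p < 0.1

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_one_tailed(_paired(np.zeros(6)), "less")

    def test_minimum_pairs(self):
        with pytest.raises(ValueError):
            wilcoxon_one_tailed(_paired([-1.0] * 4), "less")


class TestBinomial:
    def test_all_subjects_significant_underflows(self):
        p = binomial_subjects(31, 31, 0.05)
        assert p == pytest.approx(0.05**31, rel=1e-9)
        assert f"{p:.4f}" == "0.0000"  # prints as zero at display precision

    def test_zero_successes(self):
        assert binomial_subjects(0, 12) == pytest.approx(1.0)

    def test_single_trial(self):
        assert binomial_subjects(1, 1) == pytest.approx(0.05)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            binomial_subjects(5, 3)


class TestModulationIndex:
    fs = 416.0

    def _pac(self, depth, seed=0, n=10400):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / self.fs
        slow = np.sin(2 * np.pi * 6 * t)
        fast = np.sin(2 * np.pi * 78 * t)
        x = slow + 0.1 * rng.standard_normal(n)
        y = (1 + depth * slow) * fast + 0.1 * rng.standard_normal(n)
        return x, y

    def test_independent_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10400)
        y = rng.standard_normal(10400)
        assert modulation_index(x, y, self.fs) < 0.01

    def test_depth_ordering(self):
        wins = 0
        for seed in range(8):
            x5, y5 = self._pac(0.9, seed)
            x1, y1 = self._pac(0.1, seed)
            if modulation_index(x5, y5, self.fs) > \
                    modulation_index(x1, y1, self.fs):
                wins += 1
        assert wins >= 7

    def test_amplitude_rescaling_invariant(self):
        x, y = self._pac(0.6, 3)
        a = modulation_index(x, y, self.fs)
        b = modulation_index(5 * x, 0.2 * y, self.fs)
        assert a == pytest.approx(b, rel=1e-9)

    def test_zero_amplitude_flagged(self):
        x = np.sin(2 * np.pi * 6 * np.arange(4160) / self.fs)
        assert modulation_index(x, np.zeros(4160), self.fs) == 0.0


def _lz_phrase_oracle(bits):
    """Independent LZ76 parser: count exhaustive production steps."""
    s = "".join(str(b) for b in bits)
    phrases = 0
    i = 0
    while i < len(s):
        k = 1
        # extend while s[i:i+k] appears in s[:i+k-1]
        while i + k <= len(s) and s[i:i + k] in s[:i + k - 1]:
            k += 1
        phrases += 1
        i += k
    return phrases


class TestLempelZiv:
    def test_constant_is_zero_complexity(self):
        assert lempel_ziv(np.full(500, 3.3)) == 0.0

    def test_alternating_low(self):
        x = np.tile([0.0, 1.0], 5000)
        assert lempel_ziv(x) <= 0.1

    def test_random_near_one(self):
        rng = np.random.default_rng(0)
        assert 0.9 <= lempel_ziv(rng.standard_normal(10000)) <= 1.1

    def test_ordering_random_vs_periodic(self):
        rng = np.random.default_rng(1)
        periodic = np.tile(np.sin(np.linspace(0, 2 * np.pi, 25)), 400)
        assert lempel_ziv(rng.standard_normal(10000)) > lempel_ziv(periodic)

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            lempel_ziv(np.arange(50.0))


class TestBisymlog:
    def test_zero_maps_to_zero(self):
        assert bisymlog(0.0) == 0.0

    def test_odd_symmetry(self):
        x = np.array([-100.0, -1.0, -0.01, 0.01, 1.0, 100.0])
        assert np.allclose(bisymlog(-x), -bisymlog(x))

    def test_decade_point(self):
        assert bisymlog(99.0, C=1.0) == pytest.approx(2.0)

    def test_monotone(self):
        x = np.linspace(-50, 50, 1001)
        assert np.all(np.diff(bisymlog(x)) > 0)

    def test_positive_scale_required(self):
        with pytest.raises(ValueError):
            bisymlog(1.0, C=0.0)


class TestPermAncova:
    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(0)
        n, n_sim = 36, 120
        hits = 0
        for i in range(n_sim):
            y = rng.standard_normal(n)
            labels = np.repeat(["a", "b", "c"], n // 3)
            cov = rng.standard_normal(n)
            p = perm_ancova(y, labels, cov, n_perm=199, seed=i)
            hits += p <= 0.05
        assert 0.01 <= hits / n_sim <= 0.12

    def test_strong_effect_hits_floor(self):
        rng = np.random.default_rng(1)
        labels = np.repeat(["a", "b"], 20)
        y = rng.standard_normal(40) + np.where(labels == "b", 5.0, 0.0)
        p = perm_ancova(y, labels, None, n_perm=499, seed=0)
        assert p == pytest.approx(1 / 500)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(30)
        labels = np.repeat(["a", "b", "c"], 10)
        p1 = perm_ancova(y, labels, None, n_perm=299, seed=11)
        p2 = perm_ancova(y, labels, None, n_perm=299, seed=11)
        assert p1 == p2

    def test_rank_deficiency_rejected(self):
        labels = np.repeat(["a", "b"], 10)
        cov = (labels == "b").astype(float)  # collinear with the state dummy
        with pytest.raises(ValueError):
            perm_ancova(np.random.default_rng(0).standard_normal(20), labels,
                        cov, n_perm=99, seed=0)


class TestNormalize:
    def test_baseline_maps_to_one(self):
        assert normalize_to_baseline(2.5, 2.5) == pytest.approx(1.0)

    def test_ratio_and_order_preserved(self):
        vals = np.array([1.0, 2.0, 4.0])
        out = normalize_to_baseline(vals, 2.0)
        assert np.allclose(out, [0.5, 1.0, 2.0])
        assert np.all(np.diff(out) > 0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_baseline([1.0], 0.0)


class TestLZOracleAgreement:
    @pytest.mark.parametrize("pattern", ["0001101001000101" * 8,
                                         "01" * 64, "0" * 64 + "1" * 64])
    def test_phrase_count_against_independent_parser(self, pattern):
        bits = np.array([int(c) for c in pattern], dtype=float)
        # binary values pass through the median binarization unchanged
        from thalcort.stats import lempel_ziv as lz
        n = len(pattern)
        expected = _lz_phrase_oracle([int(c) for c in pattern])
        got = lz(bits) * n / np.log2(n)
        assert got == pytest.approx(expected, abs=1.5)
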