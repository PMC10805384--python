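import numpy as np
import pytest

from thalcort.benchmarks import gen_var_pair
from thalcort.spectral import (BandPair, EmbeddingSpec, band_swap_surrogate,
                               harmonic_mean_p, iaaft_surrogate, imodwt,
                               kraskov_te, level_band_hz, modwt_bands,
                               select_embedding, soso_test, spectral_sweep)


def _ar1(n, phi=0.8, seed=0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    e = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


class TestMODWT:
    def test_band_edges_at_working_rate(self):
        assert level_band_hz(2, 416.0) == (52.0, 104.0)
        assert level_band_hz(5, 416.0) == (6.5, 13.0)
        assert level_band_hz(8, 416.0) == pytest.approx((0.8125, 1.625))

    def test_roundtrip_machine_precision(self):
        x = _ar1(4160)
        W, V = modwt_bands(x)
        err = np.abs(imodwt(W, V) - x).max()
        assert err < 1e-8 * np.ptp(x)

    def test_sine_lands_in_level2(self):
        fs = 416.0
        t = np.arange(4160) / fs
        x = np.sin(2 * np.pi * 78.0 * t)
        W, _ = modwt_bands(x)
        energies = (W**2).sum(axis=1)
        assert np.argmax(energies) == 1  # level 2 (row index 1)
        assert energies[1] / energies.sum() > 0.8

    def test_slow_sine_lands_in_levels_5_to_8(self):
        fs = 416.0
        t = np.arange(4160) / fs
        x = np.sin(2 * np.pi * 5.0 * t)
        W, V = modwt_bands(x)
        energies = (W**2).sum(axis=1)
        low = energies[4:8].sum()
        assert low / (energies.sum() + (V**2).sum()) > 0.8

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            modwt_bands(np.zeros(100), J=8)


class TestIAAFT:
    def test_exact_amplitude_multiset(self):
        x = _ar1(4160)
        s = iaaft_surrogate(x, seed=0)
        assert np.array_equal(np.sort(s), np.sort(x))

    def test_spectrum_match_within_2pct(self):
        x = _ar1(4160, phi=0.9, seed=1)
        s = iaaft_surrogate(x, seed=2)
        a0 = np.abs(np.fft.rfft(x))
        a1 = np.abs(np.fft.rfft(s))
        assert np.linalg.norm(a1 - a0) / np.linalg.norm(a0) < 0.02

    def test_seed_determinism(self):
        x = _ar1(512)
        assert np.array_equal(iaaft_surrogate(x, seed=9),
                              iaaft_surrogate(x, seed=9))

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            iaaft_surrogate(np.arange(32.0))


class TestBandSwap:
    def test_empty_levels_identity(self):
        x = _ar1(2048)
        assert np.array_equal(band_swap_surrogate(x, ()), x)

    def test_out_of_band_content_preserved(self):
        fs = 416.0
        t = np.arange(4160) / fs
        x = np.sin(2 * np.pi * 78 * t) + np.sin(2 * np.pi * 5 * t)
        s = band_swap_surrogate(x, (2,), seed=0)

        def low_band(v):
            V = np.fft.rfft(v)
            f = np.fft.rfftfreq(v.size, 1 / fs)
            V[(f < 0.8125) | (f > 13.0)] = 0.0
            return np.fft.irfft(V, n=v.size)

        r = np.corrcoef(low_band(x), low_band(s))[0, 1]
        assert r > 0.99
        # and the high-band content was actually scrambled
        assert np.corrcoef(x - low_band(x), s - low_band(s))[0, 1] < 0.9

    def test_energy_preserved(self):
        x = _ar1(4160, seed=4)
        s = band_swap_surrogate(x, (2, 3), seed=1)
        assert s.var() == pytest.approx(x.var(), rel=0.05)


class TestKraskovTE:
    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        te = kraskov_te(rng.standard_normal(10000), rng.standard_normal(10000),
                        EmbeddingSpec(1, 1, 1), seed=0)
        assert abs(te) < 0.01

    def test_strong_lagged_coupling(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(8000)
        y = np.roll(x, 5) + 0.1 * rng.standard_normal(8000)
        te5 = kraskov_te(x, y, EmbeddingSpec(1, 1, 5), seed=0)
        te1 = kraskov_te(x, y, EmbeddingSpec(1, 1, 1), seed=0)
        assert te5 > 0.5
        assert te5 > te1 + 0.3

    def test_var_benchmark_close_to_analytic(self):
        x, y, te_true = gen_var_pair(n=4096, seed=5)
        est = kraskov_te(x, y, EmbeddingSpec(1, 1, 1), seed=0)
        assert est == pytest.approx(te_true, abs=0.03)

    def test_bias_bounded_across_seeds(self):
        # estimator bias on independent noise stays within a narrow band
        tes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tes.append(kraskov_te(rng.standard_normal(2000),
                                  rng.standard_normal(2000),
                                  EmbeddingSpec(1, 1, 1), seed=0))
        assert -0.005 < np.mean(tes) < 0.02

    def test_length_guard(self):
        with pytest.raises(ValueError):
            kraskov_te(np.zeros(8), np.zeros(8), EmbeddingSpec(1, 1, 1))


class TestSelectEmbedding:
    def test_pure_delay_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(4000)
        y = np.roll(x, 7)
        emb = select_embedding(x, y, u_candidates=range(1, 15))
        assert emb.u == 7

    def test_smooth_series_small_history(self):
        # slow, noise-dominated band-limited signals need little history
        from scipy.signal import butter, sosfiltfilt
        rng = np.random.default_rng(3)
        sos = butter(4, 0.05, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(4000)) \
            + 1.0 * rng.standard_normal(4000)
        y = np.roll(x, 3) + 1.0 * rng.standard_normal(4000)
        emb = select_embedding(x, y, u_candidates=(1, 3, 5))
        assert emb.k <= 2 and emb.l <= 2


class TestSOSO:
    def test_identity_swap_zero_strength(self):
        x = _ar1(2048, seed=6)
        y = _ar1(2048, seed=7)
        with pytest.warns(UserWarning):
            r = soso_test(x, y, BandPair((), ()), n_surr=5, seed=0,
                          emb=EmbeddingSpec(1, 1, 1))
        assert r.strength == 0.0
        assert r.p == 1.0

    def test_p_floor_honored(self):
        x = _ar1(4160, seed=8)
        rng = np.random.default_rng(9)
        y = np.roll(x, 3) + 0.05 * rng.standard_normal(x.size)
        with pytest.warns(UserWarning):
            r = soso_test(x, y, BandPair((1, 2, 3), (1, 2, 3)), n_surr=10,
                          seed=0, emb=EmbeddingSpec(1, 1, 3))
        assert r.p >= 1.0 / (r.n_surr + 1) - 1e-12
        assert r.te_surrogates.size == 10

    def test_add_one_floor_with_100_surrogates(self):
        # the smallest attainable per-trial p with 100 surrogates
        assert 1.0 / 101.0 == pytest.approx(0.0099, abs=5e-5)


class TestSweepMatrix:
    def test_shape_and_zscore(self):
        rng = np.random.default_rng(10)
        x = _ar1(2560, seed=11)
        y = np.roll(x, 2) + 0.3 * rng.standard_normal(x.size)
        m = spectral_sweep(x, y, n_surr=2, J=4, seed=0,
                           emb=EmbeddingSpec(1, 1, 2))
        assert m.shape == (4, 4)
        assert m.mean() == pytest.approx(0.0, abs=1e-12)
        assert m.std() == pytest.approx(1.0, rel=1e-9)


class TestHarmonicMeanP:
    def test_idempotent_on_equal_ps(self):
        assert harmonic_mean_p([0.0099] * 3) == pytest.approx(0.0099)

    def test_two_value_example(self):
        assert harmonic_mean_p([0.01, 0.1]) == pytest.approx(0.0182, abs=5e-5)

    def test_permutation_invariance_and_bounds(self):
        ps = [0.03, 0.2, 0.7, 0.04]
        a = harmonic_mean_p(ps)
        b = harmonic_mean_p(ps[::-1])
        assert a == b
        assert min(ps) <= a <= max(ps)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_p([0.0, 0.5])
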