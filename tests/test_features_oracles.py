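"""Independent brute-force oracles for every derived feature value.

Each oracle here is written from the defining formula (direct summation,
O(N^2) DFT, explicit histogram, textbook Yule-Walker solve, Monte-Carlo
limits) and never calls into the implementation path it checks.
"""

import math

import numpy as np
import pytest

from armsign.features import (
    FeatureConfig,
    amplitude_shape_features,
    ar_features,
    entropy_features,
    fractal_features,
    hjorth,
    mav,
    rms,
    spectral_features,
    wamp,
    zcr,
)


def random_signals(count, n, seed):
    rng = np.random.default_rng(seed)
    for _ in range(count):
        yield rng.normal(0, rng.uniform(0.5, 30), n)


class TestBasicOracles:
    def test_mav_direct_summation(self):
        for x in random_signals(100, 64, 0):
            expected = sum(abs(v) for v in x) / len(x)
            assert mav(x) == pytest.approx(expected, abs=1e-12)

    def test_rms_ge_mav_power_mean_inequality(self):
        for x in random_signals(1000, 32, 1):
            assert rms(x) >= mav(x) - 1e-12

    def test_zcr_brute_force_count(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.choice([-1.0, 1.0], 50)
            expected = sum(1 for i in range(49) if x[i] * x[i + 1] < 0) / 49
            assert zcr(x) == pytest.approx(expected)

    def test_wamp_monotone_nonincreasing_in_threshold(self):
        for x in random_signals(50, 64, 3):
            values = [wamp(x, th) for th in np.linspace(0, 60, 25)]
            assert all(a >= b for a, b in zip(values, values[1:]))

    def test_wamp_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.normal(0, 10, 40)
            th = float(rng.uniform(0, 20))
            expected = sum(1 for i in range(39) if abs(x[i + 1] - x[i]) > th)
            assert wamp(x, th) == expected


class TestAmplitudeShapeOracles:
    def test_each_feature_against_direct_formula(self):
        fs = 200.0
        for x in random_signals(100, 60, 5):
            f = amplitude_shape_features(x, fs=fs, inactive_threshold=3.0)
            n = len(x)
            assert f["iemg"] == pytest.approx(np.sum(np.abs(x)), abs=1e-9)
            tk = [x[i] ** 2 - x[i - 1] * x[i + 1] for i in range(1, n - 1)]
            assert f["nonlinear_energy"] == pytest.approx(np.mean(tk), abs=1e-9)
            t = np.arange(n) / fs
            slope_expected = np.polyfit(t, x, 1)[0]
            assert f["slope"] == pytest.approx(slope_expected, abs=1e-6)
            assert f["line_length"] == pytest.approx(
                sum(abs(x[i + 1] - x[i]) for i in range(n - 1)), abs=1e-9
            )
            assert f["std"] == pytest.approx(float(np.std(x)), abs=1e-12)
            assert f["min"] == x.min() and f["max"] == x.max()
            minima = sum(1 for i in range(1, n - 1) if x[i] < x[i - 1] and x[i] < x[i + 1])
            maxima = sum(1 for i in range(1, n - 1) if x[i] > x[i - 1] and x[i] > x[i + 1])
            assert f["minima"] == minima and f["maxima"] == maxima
            m = x.mean()
            m2 = np.mean((x - m) ** 2)
            assert f["skewness"] == pytest.approx(np.mean((x - m) ** 3) / m2**1.5, abs=1e-9)
            assert f["kurtosis"] == pytest.approx(np.mean((x - m) ** 4) / m2**2 - 3, abs=1e-9)
            d1 = np.diff(x)
            d2 = np.diff(d1)
            assert f["zc_d1"] == pytest.approx(zcr(d1))
            assert f["zc_d2"] == pytest.approx(zcr(d2))
            assert f["inactive"] == sum(1 for v in x if abs(v) < 3.0)


class TestHjorthOracles:
    def test_variance_ratio_definition(self):
        for x in random_signals(100, 128, 6):
            activity, mobility, complexity = hjorth(x)
            assert activity == pytest.approx(np.var(x), abs=1e-9)
            assert mobility == pytest.approx(math.sqrt(np.var(np.diff(x)) / np.var(x)), abs=1e-9)
            expected_c = math.sqrt(
                np.var(np.diff(x, 2)) / np.var(np.diff(x))
            ) / math.sqrt(np.var(np.diff(x)) / np.var(x))
            assert complexity == pytest.approx(expected_c, abs=1e-9)


class TestFractalOracles:
    def test_white_noise_dfa_and_hurst_half(self):
        # standard stochastic-process property, Monte-Carlo over 50 seeds
        dfas, hursts = [], []
        for s in range(50):
            x = np.random.default_rng(1000 + s).standard_normal(4096)
            _, _, dfa, hurst = fractal_features(x)
            dfas.append(dfa)
            hursts.append(hurst)
        assert 0.45 <= float(np.mean(dfas)) <= 0.55
        assert 0.45 <= float(np.mean(hursts)) <= 0.55

    def test_petrosian_direct_formula(self):
        for x in random_signals(50, 100, 7):
            _, pet, _, _ = fractal_features(x)
            d = np.diff(x)
            n_delta = sum(1 for i in range(len(d) - 1) if d[i] * d[i + 1] < 0)
            n = len(x)
            expected = math.log10(n) / (math.log10(n) + math.log10(n / (n + 0.4 * n_delta)))
            assert pet == pytest.approx(expected, abs=1e-12)


def direct_dft(x):
    """O(N^2) DFT oracle straight from the defining sum."""
    n = len(x)
    ks = np.arange(n // 2 + 1)
    out = np.empty(len(ks), dtype=complex)
    for j, k in enumerate(ks):
        out[j] = sum(x[m] * np.exp(-2j * math.pi * k * m / n) for m in range(n))
    return out


class TestSpectralOracles:
    def test_all_features_match_direct_dft(self):
        fs = 200.0
        for x in random_signals(100, 32, 8):
            f = spectral_features(x, fs)
            X = direct_dft(x)
            amp = np.abs(X)
            power = amp**2
            freqs = np.arange(len(X)) * fs / len(x)
            total_p, total_a = power.sum(), amp.sum()
            assert f["peak_freq"] == pytest.approx(freqs[int(np.argmax(power))], abs=1e-9)
            cum = np.cumsum(power)
            assert f["median_freq"] == pytest.approx(
                freqs[int(np.argmax(cum >= total_p / 2))], abs=1e-9
            )
            cum_a = np.cumsum(amp)
            assert f["mod_median_freq"] == pytest.approx(
                freqs[int(np.argmax(cum_a >= total_a / 2))], abs=1e-9
            )
            assert f["mod_mean_freq"] == pytest.approx(float((freqs * amp).sum() / total_a), abs=1e-9)
            iw = float((freqs * power).sum() / total_p)
            assert f["iw_mean_freq"] == pytest.approx(iw, abs=1e-9)
            assert f["iw_bandwidth"] == pytest.approx(
                math.sqrt(float(((freqs - iw) ** 2 * power).sum() / total_p)), abs=1e-9
            )
            assert f["total_spectrum"] == pytest.approx(total_p, rel=1e-9)
            assert f["mean_power"] == pytest.approx(total_p / len(power), rel=1e-9)


class TestArOracles:
    def test_yule_walker_solve_oracle(self):
        # solve the Toeplitz normal equations directly per order
        from scipy.linalg import toeplitz

        for x in random_signals(50, 200, 9):
            n = len(x)
            r = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(9)])
            f = ar_features(x)
            for p in (1, 2, 4, 8):
                a = np.linalg.solve(toeplitz(r[:p]), r[1 : p + 1])
                err = r[0] - float(np.dot(a, r[1 : p + 1]))
                assert f[f"ar_coef_{p}"] == pytest.approx(a[0], abs=1e-8)
                assert f[f"ar_err_{p}"] == pytest.approx(err, abs=1e-8)

    def test_simulated_ar1_coefficient_recovery(self):
        rng = np.random.default_rng(10)
        n = 10_000
        x = np.empty(n)
        x[0] = 0.0
        e = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = 0.5 * x[i - 1] + e[i]
        assert ar_features(x)["ar_coef_1"] == pytest.approx(0.5, abs=0.05)

    def test_white_noise_coefficient_near_zero(self):
        x = np.random.default_rng(11).standard_normal(10_000)
        assert abs(ar_features(x)["ar_coef_1"]) < 0.05


class TestEntropyOracles:
    def test_all_four_against_brute_force(self):
        cfg = FeatureConfig()
        fs = 200.0
        for x in random_signals(100, 64, 12):
            shannon, spectral, svd_e, fisher = entropy_features(x, fs, cfg)

            counts, _ = np.histogram(x, bins=cfg.hist_bins, range=(x.min(), x.max()))
            probs = counts / counts.sum()
            expected_sh = -sum(p * math.log(p) for p in probs if p > 0)
            assert shannon == pytest.approx(expected_sh, abs=1e-9)

            power = np.abs(np.fft.rfft(x)) ** 2
            pn = power / power.sum()
            expected_sp = -sum(p * math.log(p) for p in pn if p > 0) / math.log(len(power))
            assert spectral == pytest.approx(expected_sp, abs=1e-9)

            d = cfg.svd_embed_dim
            emb = np.array([x[i : i + d] for i in range(len(x) - d + 1)])
            s = np.linalg.svd(emb, compute_uv=False)
            sn = s / s.sum()
            expected_svd = -sum(p * math.log(p) for p in sn if p > 0)
            assert svd_e == pytest.approx(expected_svd, abs=1e-9)

            expected_fi = sum(
                (sn[i + 1] - sn[i]) ** 2 / sn[i] for i in range(len(sn) - 1) if sn[i] > 1e-15
            )
            assert fisher == pytest.approx(expected_fi, abs=1e-9)


class TestScalingProperties:
    def test_mav_rms_scale_linearly(self):
        x = np.random.default_rng(13).normal(0, 5, 100)
        for c in (2.0, 7.5):
            assert mav(c * x) == pytest.approx(c * mav(x), rel=1e-12)
            assert rms(c * x) == pytest.approx(c * rms(x), rel=1e-12)

    def test_zcr_invariant_to_positive_scaling(self):
        x = np.random.default_rng(14).standard_normal(100)
        assert zcr(3.7 * x) == zcr(x)

    def test_shannon_invariant_to_monotone_relabeling_of_levels(self):
        cfg = FeatureConfig(hist_bins=4)
        x = np.tile([0.0, 1.0, 2.0, 3.0], 32)
        y = np.tile([10.0, 20.0, 30.0, 40.0], 32)  # strictly monotone relabeling
        sx, _, _, _ = entropy_features(x, 200.0, cfg, hist_range=(0.0, 4.0))
        sy, _, _, _ = entropy_features(y, 200.0, cfg, hist_range=(10.0, 50.0))
        assert sx == pytest.approx(sy, abs=1e-12)
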