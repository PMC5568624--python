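import numpy as np
import pytest
import pywt

from psgrank import features as ft
from psgrank.features import FeatureConfig
from psgrank.synthetic_data import generate_stage_epoch
from psgrank.types import ARModel, EpochSignal

from oracles import (apen_oracle, curve_length_oracle, hjorth_oracle,
                     hurst_oracle, permen_oracle, petrosian_oracle,
                     renyi_oracle, spectral_entropy_oracle,
                     standardize_oracle, teager_oracle, zcr_oracle)


def _epoch(x, fs=100.0, channel="EEG"):
    return EpochSignal(np.asarray(x, dtype=float), fs, channel)


class TestStatisticalFeatures:
    def test_small_example(self):
        v = ft.statistical_features(_epoch([1, 2, 3, 4]))
        assert v[0] == 1 and v[1] == 4
        assert v[2] == pytest.approx(2.5)
        assert v[7] == pytest.approx(2.5)
        assert v[3] ** 2 == pytest.approx(v[4], abs=1e-12)

    def test_constant_epoch_conventions(self):
        v = ft.statistical_features(_epoch(np.full(100, 3.0)))
        assert list(v) == [3, 3, 3, 0, 0, 0, 0, 3]

    def test_gaussian_moments(self, rng):
        x = rng.standard_normal(3000)
        v = ft.statistical_features(_epoch(x))
        assert abs(v[5]) < 0.2           # skewness ~ 0
        assert abs(v[6] - 3.0) < 0.5     # raw kurtosis ~ 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ft.statistical_features(np.array([]))


class TestZeroCrossingRate:
    @pytest.mark.parametrize("x,expected", [
        ([1, 1, 1, 1], 0),
        ([1, -1, 1, -1], 3),
    ])
    def test_examples(self, x, expected):
        assert ft.zero_crossing_rate(_epoch(x)) == expected

    def test_sine_crossings(self):
        t = np.arange(3000) / 100
        x = np.sin(2 * np.pi * 10 * t)
        assert abs(ft.zero_crossing_rate(_epoch(x)) - 600) <= 1

    def test_matches_oracle(self, rng):
        x = rng.standard_normal(500)
        assert ft.zero_crossing_rate(_epoch(x)) == zcr_oracle(x)


class TestHjorth:
    def test_white_noise_complexity_above_one(self, rng):
        _, _, comp = ft.hjorth(_epoch(rng.standard_normal(3000)))
        assert comp > 1

    def test_sine_mobility_and_complexity(self):
        omega = 0.3  # rad/sample
        x = np.sin(omega * np.arange(20000))
        act, mob, comp = ft.hjorth(_epoch(x))
        assert mob == pytest.approx(omega, rel=0.01)
        assert comp == pytest.approx(1.0, rel=0.01)

    def test_constant_signal(self):
        assert ft.hjorth(_epoch(np.ones(10))) == (0.0, 0.0, 0.0)


class TestWaveletPacketFeatures:
    def test_delta_epoch_dominates(self, delta_spec, cfg):
        eeg, _, _ = generate_stage_epoch(delta_spec, seed=2)
        v = ft.wavelet_packet_features(eeg, cfg)
        assert v[1] / v[6] >= 0.8              # delta energy / total
        ratios = v[7:12]
        assert np.argmax(ratios) == 3          # delta/theta largest

    def test_zero_signal_all_zero(self, cfg):
        v = ft.wavelet_packet_features(_epoch(np.zeros(3000)), cfg)
        assert np.allclose(v, 0.0)

    def test_total_energy_is_leaf_sum(self, random_epoch, cfg):
        v = ft.wavelet_packet_features(random_epoch, cfg)
        wp = pywt.WaveletPacket(random_epoch.samples, cfg.wp_wavelet,
                                mode="periodization", maxlevel=cfg.wp_level)
        leaf_sum = sum(
            float(np.sum(n.data ** 2))
            for n in wp.get_level(cfg.wp_level, order="freq")
        )
        assert v[6] == pytest.approx(leaf_sum, rel=1e-6)
        # near-orthogonality: leaf energies track the signal energy
        assert leaf_sum == pytest.approx(float(np.sum(random_epoch.samples ** 2)),
                                         rel=0.05)


class TestEntropies:
    def test_spectral_entropy_white_noise_high(self, random_epoch, cfg):
        assert ft.spectral_entropy(random_epoch, cfg) >= 0.9

    def test_spectral_entropy_tone_low(self, cfg):
        t = np.arange(3000) / 100
        tone = _epoch(np.sin(2 * np.pi * 10 * t))
        assert ft.spectral_entropy(tone, cfg) < 0.3

    def test_spectral_entropy_zero_signal(self, cfg):
        assert ft.spectral_entropy(_epoch(np.zeros(3000)), cfg) == 0.0

    def test_renyi_two_balanced_bins(self, cfg):
        x = np.concatenate([np.zeros(100), np.ones(100)])
        assert ft.renyi_entropy(_epoch(x), cfg) == pytest.approx(np.log(2))

    def test_renyi_uniform_over_k_bins(self, cfg):
        centers = (np.arange(16) + 0.5) / 16
        x = np.repeat(centers, 10)
        assert ft.renyi_entropy(_epoch(x), cfg) == pytest.approx(np.log(16),
                                                                 rel=1e-6)

    def test_renyi_constant_is_zero(self, cfg):
        assert ft.renyi_entropy(_epoch(np.ones(50)), cfg) == 0.0

    def test_apen_constant_zero(self, cfg):
        assert ft.approximate_entropy(_epoch(np.ones(100)), cfg) == 0.0

    def test_apen_periodic_below_random(self, rng, cfg):
        n = 600
        periodic = np.tile([1.0, 0.0], n // 2)
        random = rng.uniform(size=n)
        assert (ft.approximate_entropy(_epoch(periodic), cfg)
                < ft.approximate_entropy(_epoch(random), cfg))

    def test_apen_matches_bruteforce(self, rng, cfg):
        x = rng.standard_normal(300)
        ours = ft.approximate_entropy(_epoch(x), cfg)
        theirs = apen_oracle(x, cfg.apen_m, cfg.apen_r)
        assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    def test_permen_monotone_zero(self, cfg):
        assert ft.permutation_entropy(_epoch(np.arange(100.0)), cfg) == 0.0

    def test_permen_hand_example(self):
        cfg = FeatureConfig(perm_m=2)
        got = ft.permutation_entropy(_epoch([1, 3, 2, 4]), cfg)
        expected = -(2 / 3) * np.log(2 / 3) - (1 / 3) * np.log(1 / 3)
        assert got == pytest.approx(expected)

    def test_permen_iid_near_log6(self, rng):
        cfg = FeatureConfig(perm_m=3)
        x = rng.uniform(size=3000)
        assert ft.permutation_entropy(_epoch(x), cfg) == pytest.approx(
            np.log(6), rel=0.02)

    def test_permen_matches_oracle(self, rng, cfg):
        x = rng.standard_normal(400)
        assert ft.permutation_entropy(_epoch(x), cfg) == pytest.approx(
            permen_oracle(x, cfg.perm_m), rel=1e-12)


class TestNonlinear:
    def test_petrosian_monotone_is_one(self):
        assert ft.petrosian_fd(_epoch(np.arange(100.0))) == pytest.approx(1.0)

    def test_petrosian_alternating(self):
        n = 64
        x = np.tile([1.0, -1.0], n // 2)
        n_delta = n - 2
        expected = np.log10(n) / (
            np.log10(n) + np.log10(n / (n + 0.4 * n_delta)))
        assert ft.petrosian_fd(_epoch(x)) == pytest.approx(expected)

    def test_petrosian_matches_oracle(self, rng):
        x = rng.standard_normal(500)
        assert ft.petrosian_fd(_epoch(x)) == pytest.approx(
            petrosian_oracle(x), rel=1e-12)

    def test_teager_examples(self):
        assert ft.teager_energy(_epoch(np.full(10, 2.0))) == 0.0
        assert ft.teager_energy(_epoch([1, 2, 3])) == pytest.approx(1.0)

    def test_teager_cosine(self):
        omega, amp = 0.4, 2.0
        x = amp * np.cos(omega * np.arange(30000))
        assert ft.teager_energy(_epoch(x)) == pytest.approx(
            amp ** 2 * np.sin(omega) ** 2, rel=1e-3)

    def test_energy_examples(self):
        assert ft.energy(_epoch([1, -1, 1, -1])) == 1.0
        assert ft.energy(_epoch(np.zeros(10))) == 0.0

    def test_energy_ratio_conventions(self):
        assert ft.energy_ratio(2.0, 2.0) == 1.0
        assert ft.energy_ratio(2.0, None) == 1.0
        assert ft.energy_ratio(2.0, 0.0) == 1.0
        assert ft.energy_ratio(3.0, 2.0) == 1.5

    def test_curve_length(self, rng):
        assert ft.mean_curve_length(_epoch(np.ones(5))) == 0.0
        assert ft.mean_curve_length(_epoch([0, 1, 0, 1])) == 3.0
        x = rng.standard_normal(200)
        assert ft.mean_curve_length(_epoch(3 * x)) == pytest.approx(
            3 * ft.mean_curve_length(_epoch(x)))

    def test_hurst_white_noise_near_half(self):
        vals = [
            ft.hurst_exponent(_epoch(np.random.default_rng(s).standard_normal(3000)))
            for s in range(50)
        ]
        assert 0.4 <= np.mean(vals) <= 0.65

    def test_hurst_cumsum_higher(self, rng):
        x = rng.standard_normal(3000)
        assert (ft.hurst_exponent(_epoch(np.cumsum(x)))
                > ft.hurst_exponent(_epoch(x)))

    def test_hurst_matches_oracle(self, rng):
        x = rng.standard_normal(1000)
        assert ft.hurst_exponent(_epoch(x)) == pytest.approx(
            hurst_oracle(x), rel=1e-12)


def _simulate_ar(coeffs, n, seed, burn=500):
    rng = np.random.default_rng(seed)
    p = len(coeffs)
    x = np.zeros(n + burn)
    e = rng.standard_normal(n + burn)
    for t in range(p, n + burn):
        x[t] = np.dot(coeffs, x[t - p:t][::-1]) + e[t]
    return x[burn:]


class TestARAndItakura:
    def test_yule_walker_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        x = rng.standard_normal(2000)
        ours = ft.yule_walker(x, 4)
        theirs, _ = sm.regression.yule_walker(x - x.mean(), 4, method="mle")
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_wake_model_recovers_ar2(self):
        cfg = FeatureConfig(ar_order=2)
        true = np.array([0.75, -0.5])
        eps = [_epoch(_simulate_ar(true, 3000, s)) for s in range(12)]
        model, selected = ft.fit_wake_ar_model(eps, cfg, seed=0)
        assert selected.size == 6
        assert np.all(np.abs(model.coefficients - true) < 0.1)

    def test_half_selection_and_determinism(self, rng):
        eps = [_epoch(rng.standard_normal(300)) for _ in range(10)]
        _, sel_a = ft.fit_wake_ar_model(eps, seed=5)
        _, sel_b = ft.fit_wake_ar_model(eps, seed=5)
        assert sel_a.size == 5
        assert np.array_equal(sel_a, sel_b)

    def test_too_few_wake_epochs(self, rng):
        with pytest.raises(ValueError):
            ft.fit_wake_ar_model([_epoch(rng.standard_normal(100))])

    def test_isd_self_distance_near_zero(self):
        cfg = FeatureConfig(ar_order=4)
        true = np.array([0.6, -0.3, 0.1, 0.05])
        eps = [_epoch(_simulate_ar(true, 3000, s)) for s in range(6)]
        model, _ = ft.fit_wake_ar_model(eps, cfg, seed=1)
        d = ft.itakura_spectral_distance(model, _epoch(_simulate_ar(true, 10000, 99)),
                                         cfg)
        assert 0 <= d <= 0.05

    def test_isd_separates_processes(self):
        cfg = FeatureConfig(ar_order=2)
        low = np.array([0.9, 0.0])    # low-pass pole
        high = np.array([-0.9, 0.0])  # high-pass pole
        eps = [_epoch(_simulate_ar(low, 2000, s)) for s in range(6)]
        model, _ = ft.fit_wake_ar_model(eps, cfg, seed=2)
        d_same = ft.itakura_spectral_distance(model, _epoch(_simulate_ar(low, 3000, 7)), cfg)
        d_other = ft.itakura_spectral_distance(model, _epoch(_simulate_ar(high, 3000, 7)), cfg)
        assert d_other > d_same

    def test_isd_rejects_constant_epoch(self):
        model = ARModel(np.array([0.5]), 1)
        with pytest.raises(ValueError):
            ft.itakura_spectral_distance(model, _epoch(np.ones(100)))

    def test_ar_autocovariance_matches_simulation(self):
        coeffs = np.array([0.75, -0.5])
        r = ft.ar_autocovariance(coeffs, 2)
        x = _simulate_ar(coeffs, 400000, 3)
        emp = [np.mean(x[: x.size - k] * x[k:]) for k in range(3)]
        assert np.allclose(r, emp, rtol=0.05)


class TestEMGSpectralFeatures:
    def test_zero_epoch(self):
        assert np.allclose(ft.emg_spectral_features(_epoch(np.zeros(3000), channel="EMG")), 0)

    def test_amplitude_scaling(self, rng):
        x = rng.standard_normal(3000)
        a = ft.emg_spectral_features(_epoch(x, channel="EMG"))
        b = ft.emg_spectral_features(_epoch(2 * x, channel="EMG"))
        assert b[0] == pytest.approx(4 * a[0], rel=1e-9)
        assert np.all(b > a)

    def test_max_at_least_mean(self, rng):
        v = ft.emg_spectral_features(_epoch(rng.standard_normal(1000), channel="EMG"))
        assert v[1] >= v[2]


class TestExtractEpochFeatures:
    @pytest.fixture
    def wake_model(self, rng):
        eps = [_epoch(rng.standard_normal(3000)) for _ in range(4)]
        model, _ = ft.fit_wake_ar_model(eps, seed=0)
        return model

    def test_output_shape_and_names(self, stage_specs, wake_model, cfg):
        eeg, eog, emg = generate_stage_epoch(stage_specs["S2"], seed=1)
        v = ft.extract_epoch_features(eeg, eog, emg, (None, None), wake_model, cfg)
        assert v.shape == (49,)
        assert np.all(np.isfinite(v))
        assert ft.FEATURE_NAMES == [f"F{i}" for i in range(1, 50)]

    @pytest.mark.parametrize("missing", ["EEG", "EOG", "EMG"])
    def test_missing_channel_named(self, stage_specs, wake_model, cfg, missing):
        chans = dict(zip(("EEG", "EOG", "EMG"),
                         generate_stage_epoch(stage_specs["W"], seed=2)))
        chans[missing] = None
        with pytest.raises(ValueError, match=missing):
            ft.extract_epoch_features(chans["EEG"], chans["EOG"], chans["EMG"],
                                      (None, None), wake_model, cfg)

    def test_wake_emg_power_exceeds_sws(self, stage_specs, wake_model, cfg):
        rng = np.random.default_rng(4)
        f43 = {}
        for stage in ("W", "SWS"):
            vals = []
            for _ in range(10):
                eeg, eog, emg = generate_stage_epoch(stage_specs[stage], seed=rng)
                vals.append(ft.extract_epoch_features(
                    eeg, eog, emg, (None, None), wake_model, cfg)[42])
            f43[stage] = np.mean(vals)
        assert f43["W"] > f43["SWS"]

    def test_sws_delta_energy_exceeds_wake(self, stage_specs, wake_model, cfg):
        rng = np.random.default_rng(5)
        f14 = {}
        for stage in ("W", "SWS"):
            vals = []
            for _ in range(10):
                eeg, eog, emg = generate_stage_epoch(stage_specs[stage], seed=rng)
                vals.append(ft.wavelet_packet_features(eeg, cfg)[1]
                            / ft.wavelet_packet_features(eeg, cfg)[6])
            f14[stage] = np.mean(vals)
        assert f14["SWS"] > f14["W"]


class TestScalingProperties:
    """Amplitude-scaling behavior of feature families on random epochs."""

    @pytest.mark.parametrize("seed", range(5))
    def test_scaling(self, seed, cfg):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(500)
        c = float(rng.uniform(1.5, 4.0))
        a, b = _epoch(x), _epoch(c * x)
        assert ft.energy(b) == pytest.approx(c ** 2 * ft.energy(a), rel=1e-9)
        assert ft.mean_curve_length(b) == pytest.approx(
            c * ft.mean_curve_length(a), rel=1e-9)
        assert ft.zero_crossing_rate(b) == ft.zero_crossing_rate(a)
        assert ft.permutation_entropy(b, cfg) == pytest.approx(
            ft.permutation_entropy(a, cfg), rel=1e-9)
        assert ft.petrosian_fd(b) == pytest.approx(ft.petrosian_fd(a), rel=1e-9)
        assert ft.spectral_entropy(b, cfg) == pytest.approx(
            ft.spectral_entropy(a, cfg), rel=1e-6)


class TestStandardize:
    def test_hand_example(self):
        from psgrank.types import FeatureTable
        t = FeatureTable(np.array([[1.0], [2.0], [3.0]]), ["F1"],
                         np.array(["W", "S1", "S2"]), np.array(["a"] * 3))
        out = ft.standardize(t)
        assert np.allclose(out.values[:, 0], standardize_oracle([1, 2, 3]))

    def test_idempotent_and_constant_column(self, rng):
        from psgrank.types import FeatureTable
        vals = np.column_stack([rng.standard_normal(50), np.full(50, 7.0)])
        t = FeatureTable(vals, ["F1", "F2"], np.array(["W"] * 50),
                         np.array(["a"] * 50))
        once = ft.standardize(t)
        twice = ft.standardize(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)
        assert np.allclose(once.values[:, 1], 0.0)
        assert abs(once.values[:, 0].mean()) < 1e-10
        assert once.values[:, 0].std() == pytest.approx(1.0, abs=1e-10)


class TestHjorthOracle:
    def test_matches_independent_formulas(self, rng):
        x = rng.standard_normal(800)
        ours = ft.hjorth(_epoch(x))
        theirs = hjorth_oracle(x)
        assert np.allclose(ours, theirs, rtol=1e-12)
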