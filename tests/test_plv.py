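"""PLV formula, permutation/cluster test, and Sig.P.Ratio selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from streamsync.plv import (
    PLV_FREQS,
    compute_plv,
    multitaper_spectra,
    permutation_plv_test,
    sig_pair_ratio,
    average_plv_periods,
    TrialSpectra,
)


def make_spectra(coeffs, period="delay1", window_s=1.9):
    return TrialSpectra(coefficients=np.asarray(coeffs, complex),
                        freqs=PLV_FREQS, period=period, window_s=window_s,
                        channel_names=[f"c{i}" for i in
                                       range(np.shape(coeffs)[2])])


def phase_spectra(rng, phases_i, phases_j, n_tapers=2):
    """Spectra whose unit coefficients carry the given per-trial phases."""
    n_trials, n_freq = phases_i.shape
    mag = rng.uniform(0.5, 2.0, size=(n_trials, n_tapers, 1, n_freq))
    xi = mag * np.exp(1j * phases_i)[:, None, None, :]
    xj = rng.uniform(0.5, 2.0, size=(n_trials, n_tapers, 1, n_freq)) * \
        np.exp(1j * phases_j)[:, None, None, :]
    return make_spectra(np.concatenate([xi, xj], axis=2))


class TestMultitaper:
    def test_peak_at_tone_frequency(self):
        rate, n = 512.0, int(1.9 * 512)
        t = np.arange(n) / rate
        x = np.sin(2 * np.pi * 5 * t)[None, None, :].repeat(3, axis=0)
        spec = multitaper_spectra(x, rate, "delay1")
        power = np.abs(spec.coefficients[0, 0, 0])
        assert spec.freqs[np.argmax(power)] == 5.0

    def test_zero_signal_zero_coefficients(self):
        spec = multitaper_spectra(np.zeros((2, 1, 973)), 512.0, "delay1")
        assert np.allclose(spec.coefficients, 0.0)

    def test_two_tones_two_peaks(self):
        # FFT oracle: distinct maxima at both injected frequencies
        rate, n = 512.0, int(1.9 * 512)
        t = np.arange(n) / rate
        x = (np.sin(2 * np.pi * 4 * t) + np.sin(2 * np.pi * 12 * t))[None, None, :]
        spec = multitaper_spectra(x, rate, "delay1")
        power = np.abs(spec.coefficients[0, 0, 0]) ** 2
        top2 = set(spec.freqs[np.argsort(power)[-2:]])
        assert top2 == {4.0, 12.0}

    def test_short_window_flags_unreliable(self):
        spec = multitaper_spectra(np.zeros((2, 1, 256)), 512.0, "recall")
        assert not spec.unreliable.any()  # 2 Hz = 1 cycle in 0.5 s
        spec2 = multitaper_spectra(np.zeros((2, 1, 128)), 512.0, "recall")
        assert spec2.unreliable[0]  # 2 Hz < 1 / 0.25 s


class TestComputePLV:
    def test_constant_offset_gives_unity(self, rng):
        phases = rng.uniform(0, 2 * np.pi, size=(20, 19))
        spec = phase_spectra(rng, phases, phases + 0.7)
        plv = compute_plv(spec, (0, 1))
        assert np.allclose(plv, 1.0, atol=1e-12)

    def test_opposite_phases_cancel(self, rng):
        phases = np.zeros((2, 19))
        offs = np.stack([np.zeros(19), np.full(19, np.pi)])
        spec = phase_spectra(rng, phases, phases + offs, n_tapers=1)
        plv = compute_plv(spec, (0, 1))
        assert np.allclose(plv, 0.0, atol=1e-12)

    def test_self_plv_is_unity(self, rng):
        phases = rng.uniform(0, 2 * np.pi, size=(30, 19))
        spec = phase_spectra(rng, phases, phases)
        assert np.allclose(compute_plv(spec, (0, 0)), 1.0, atol=1e-12)

    def test_formula_matches_phase_difference_oracle(self, rng):
        # independent oracle: |mean exp(i * delta-phi)| over trials/tapers
        x = rng.normal(size=(15, 2, 2, 19)) + 1j * rng.normal(size=(15, 2, 2, 19))
        spec = make_spectra(x)
        plv = compute_plv(spec, (0, 1))
        dphi = np.angle(x[:, :, 0, :]) - np.angle(x[:, :, 1, :])
        oracle = np.abs(np.exp(1j * dphi).mean(axis=(0, 1)))
        assert np.max(np.abs(plv - oracle)) < 1e-12

    def test_uniform_phase_expectation(self, rng):
        # E[resultant] ~ sqrt(pi) / (2 sqrt(N)) under uniform phases
        n, reps = 200, 1000
        phases = rng.uniform(0, 2 * np.pi, size=(reps, n))
        r = np.abs(np.exp(1j * phases).mean(axis=1))
        expect = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert r.mean() == pytest.approx(expect, abs=3 * r.std() / np.sqrt(reps))

    def test_zero_coefficient_excluded_with_count_adjustment(self, rng):
        phases = rng.uniform(0, 2 * np.pi, size=(10, 19))
        spec = phase_spectra(rng, phases, phases + 0.3, n_tapers=1)
        spec.coefficients[0, 0, 0, :] = 0.0
        plv = compute_plv(spec, (0, 1))
        assert np.allclose(plv, 1.0, atol=1e-12)  # remaining trials coherent

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_bounds_and_phase_shift_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 2, 2, 19)) + 1j * rng.normal(size=(8, 2, 2, 19))
        spec = make_spectra(x)
        plv = compute_plv(spec, (0, 1))
        assert np.all(plv >= 0) and np.all(plv <= 1 + 1e-12)
        shift = np.exp(1j * rng.uniform(0, 2 * np.pi))
        spec2 = make_spectra(x * np.array([shift, 1.0])[None, None, :, None])
        assert np.allclose(compute_plv(spec2, (0, 1)), plv, atol=1e-12)


class TestPermutationTest:
    def test_exact_null_no_clusters(self, rng):
        # task identical to baseline by construction: exact null
        phases = rng.uniform(0, 2 * np.pi, size=(30, 19))
        spec = phase_spectra(rng, phases, rng.uniform(0, 2 * np.pi, (30, 19)))
        res = permutation_plv_test(spec, spec, (0, 1), n_perm=100, seed=0)
        assert not res.sig_mask.any()
        assert np.allclose(res.observed_dplv, 0.0, atol=1e-12)

    def test_strong_coupling_detected(self, rng):
        base_i = rng.uniform(0, 2 * np.pi, size=(40, 19))
        base_j = rng.uniform(0, 2 * np.pi, size=(40, 19))
        task_i = rng.uniform(0, 2 * np.pi, size=(40, 19))
        task_j = rng.uniform(0, 2 * np.pi, size=(40, 19))
        bins = (PLV_FREQS >= 4) & (PLV_FREQS <= 6)
        task_j[:, bins] = task_i[:, bins] + rng.vonmises(0, 4.0, (40, 1))
        task = phase_spectra(rng, task_i, task_j)
        base = phase_spectra(rng, base_i, base_j)
        res = permutation_plv_test(task, base, (0, 1), n_perm=200, seed=1)
        assert res.sig_mask[bins].all()

    def test_too_few_permutations_rejected(self, rng):
        phases = rng.uniform(0, 2 * np.pi, size=(10, 19))
        spec = phase_spectra(rng, phases, phases)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_plv_test(spec, spec, (0, 1), n_perm=10)


class TestSigPairRatio:
    def test_single_hot_bin_detected(self):
        # exact binomial oracle: P(X >= 60 | n=100, p=0.10) << 0.05/19
        n_pairs = 100
        masks = np.zeros((n_pairs, 19), dtype=bool)
        for b in range(19):
            masks[:10, b] = True
        masks[:60, 9] = True
        spr = sig_pair_ratio(masks)
        p_exact = stats.binomtest(60, 100, 0.10, alternative="greater").pvalue
        assert p_exact < 0.05 / 19
        assert spr.sig_bins[9]
        assert spr.selected_ranges == [(float(PLV_FREQS[9]), float(PLV_FREQS[9]))]

    def test_uniform_ratios_nothing_selected(self):
        masks = np.zeros((50, 19), dtype=bool)
        masks[:10, :] = True  # ratio 0.2 everywhere = median
        spr = sig_pair_ratio(masks)
        assert not spr.sig_bins.any()

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            sig_pair_ratio(np.zeros((0, 19), dtype=bool))


class TestAveragePLVPeriods:
    def test_single_bin_mean_equals_bin(self, rng):
        phases = rng.uniform(0, 2 * np.pi, size=(24, 19))
        spec = phase_spectra(rng, phases, phases + 0.2)
        conditions = np.array(["same", "different"] * 12)
        tab = average_plv_periods({"delay1": spec}, [(0, 1)], (4.0, 4.0),
                                  conditions)
        plv_same = compute_plv(spec, (0, 1), trials=conditions == "same")
        got = tab[(tab.period == "delay1") & (tab.condition == "same")]
        assert got["mean_plv"].iloc[0] == pytest.approx(
            plv_same[PLV_FREQS == 4.0][0], abs=1e-12)

    def test_row_count(self, rng):
        phases = rng.uniform(0, 2 * np.pi, size=(24, 19))
        spec = phase_spectra(rng, phases, phases)
        conditions = np.array(["same", "different"] * 12)
        tab = average_plv_periods({"delay1": spec, "baseline": spec},
                                  [(0, 1)], (2.0, 5.0), conditions)
        assert len(tab) == 2 * 2  # periods x conditions for one pair
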