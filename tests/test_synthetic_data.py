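"""Simulator contracts: schedule, determinism, ground-truth calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from streamsync.synthetic_data import (
    BandEffect,
    Coupling,
    SimulationConfig,
    expected_plv,
    schedule_trials,
    score_response,
    simulate_session,
)
from streamsync.task import period_windows


def small_cfg(**kw):
    base = dict(
        n_trials_per_condition=10, block_size=5,
        channels_per_region={"IPL": 2, "VTC": 1, "HIP": 1},
        spike_rate_per_min=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSchedule:
    def test_trial_totals_match_task_design(self):
        ev = schedule_trials(small_cfg(n_trials_per_condition=20,
                                       block_size=10), seed=3)
        total = ev["fixation_s"] + ev["encoding_s"] + ev["delay_s"] + \
            ev["action_s"] + ev["question_s"].fillna(0)
        same = total[ev.trial_type == "same"]
        diff = total[ev.trial_type == "different"]
        assert (same >= 9.8 - 1e-9).all() and (same <= 10.2 + 1e-9).all()
        assert (diff >= 11.8 - 1e-9).all() and (diff <= 12.2 + 1e-9).all()

    def test_counterbalanced_blocks(self):
        ev = schedule_trials(small_cfg(n_trials_per_condition=20,
                                       block_size=10), seed=5)
        order = ev.groupby("block")["trial_type"].first().tolist()
        # ABBA pattern: both block orders occur equally often
        transitions = list(zip(order[::2], order[1::2]))
        ab = sum(1 for a, b in transitions if (a, b) == (order[0], order[1]))
        ba = sum(1 for a, b in transitions if (a, b) == (order[1], order[0]))
        assert ab == ba
        counts = ev["trial_type"].value_counts()
        assert counts["same"] == counts["different"] == 20

    def test_deterministic(self):
        cfg = small_cfg()
        a = schedule_trials(cfg, seed=11)
        b = schedule_trials(cfg, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_block_divisibility_enforced(self):
        with pytest.raises(ValueError):
            schedule_trials(small_cfg(n_trials_per_condition=7), seed=0)


class TestScoreResponse:
    def test_through_target_is_correct(self):
        ok, rt = score_response([(0.0, 0.0), (0.5, 0.5)], (0.5, 0.5))
        assert ok and rt == 1

    def test_closest_approach_outside_square(self):
        ok, rt = score_response([(0.5 + 0.2, 0.5)], (0.5, 0.5),
                                half_min_distance=0.105)
        assert not ok and rt is None

    def test_boundary_inclusive(self):
        ok, _ = score_response([(0.5 + 0.105, 0.5)], (0.5, 0.5),
                               half_min_distance=0.105)
        assert ok

    def test_reaction_time_uses_times(self):
        ok, rt = score_response([(0, 0), (0.2, 0.2), (0.5, 0.5)], (0.5, 0.5),
                                times=[0.0, 0.1, 0.2])
        assert ok and rt == 0.2

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            score_response([], (0.5, 0.5))


class TestSimulateSession:
    def test_bit_identical_determinism(self):
        cfg = small_cfg(spike_rate_per_min=2.0,
                        couplings=(Coupling(regions=("IPL", "VTC"), freq=4.0,
                                            periods=("delay1",), kappa=2.0),))
        r1, e1, g1 = simulate_session(cfg, 42)
        r2, e2, g2 = simulate_session(cfg, 42)
        assert np.array_equal(r1.samples, r2.samples)
        pd.testing.assert_frame_equal(e1, e2)
        assert g1.spike_epochs == g2.spike_epochs

    def test_trial_conservation(self):
        cfg = small_cfg()
        _, ev, _ = simulate_session(cfg, 0)
        assert len(ev) == 2 * cfg.n_trials_per_condition

    def test_channel_layout(self, small_session):
        cfg, rec, events, gt = small_session
        n_contacts = sum(v + 1 for v in cfg.channels_per_region.values())
        assert rec.n_channels == n_contacts
        for region, names in gt.bipolar_names.items():
            assert len(names) == cfg.channels_per_region[region]

    def test_coupling_above_gc_nyquist_rejected(self):
        cfg = small_cfg(couplings=(Coupling(regions=("IPL", "VTC"), freq=25.0,
                                            periods=("delay1",)),))
        with pytest.raises(ValueError, match="20 Hz"):
            simulate_session(cfg, 0)

    def test_injected_phase_offsets_match_von_mises_resultant(self):
        # analytic von Mises resultant length I1(k)/I0(k) as the oracle
        kappa = 2.0
        cfg = small_cfg(
            n_trials_per_condition=40, block_size=10,
            couplings=(Coupling(regions=("IPL", "VTC"), freq=4.0,
                                periods=("delay1", "delay2"), kappa=kappa),),
        )
        _, _, gt = simulate_session(cfg, 7)
        d = gt.couplings[0]["deltas"]
        assert d.shape[0] == 80
        r = np.abs(np.exp(1j * d).mean(axis=0))
        n = d.shape[0]
        target = expected_plv(kappa)
        se = np.sqrt((1 - target**2) / (2 * n)) + 1 / np.sqrt(n)
        assert np.all(np.abs(r - target) < 3 * se)

    def test_gain_profile_matches_configured_change(self):
        gain = 1.5
        cfg = small_cfg(
            n_trials_per_condition=20, block_size=10,
            band_effects=(BandEffect(region="IPL", band=(8, 13),
                                     periods=("delay1", "delay2"), gain=gain),),
        )
        _, ev, gt = simulate_session(cfg, 9)
        profile = gt.gain_profiles[0].astype(float)
        rate = gt.rate
        in_effect, in_base = [], []
        for _, row in ev.iterrows():
            wins = period_windows(row["onset"], row["fixation_s"],
                                  row["delay_s"], kind="power")
            for p in ("delay1", "delay2"):
                i0, i1 = (int(round(t * rate)) for t in wins[p])
                in_effect.append(profile[i0:i1])
            i0, i1 = (int(round(t * rate)) for t in wins["baseline"])
            in_base.append(profile[i0:i1])
        ratio = np.concatenate(in_effect).mean() / np.concatenate(in_base).mean()
        assert abs(ratio - gain) / gain < 0.05

    def test_measured_envelope_change_tracks_gain(self):
        # high-SNR oscillator: the whitened-envelope ratio between the
        # affected period and baseline approaches the configured gain
        gain = 1.5
        cfg = small_cfg(
            n_trials_per_condition=20, block_size=10,
            channels_per_region={"IPL": 1, "VTC": 1, "HIP": 1},
            band_effects=(BandEffect(region="IPL", band=(8, 13),
                                     periods=("delay1", "delay2"), gain=gain,
                                     amplitude=80.0),),
        )
        rec, ev, gt = simulate_session(cfg, 13)
        from streamsync import bandpower, preprocess

        bip = preprocess.bipolar_rereference(rec)
        env = bandpower.filter_hilbert_envelope(bip, f_lo=8, f_hi=13)
        es = bandpower.aggregate_band(env, (8, 13), ev, baseline_correct=False)
        ep = es.epochs
        c = ep.channel_names.index(gt.bipolar_names["IPL"][0])
        base = ep.data[:, c, ep.periods["baseline"]].mean()
        delay = ep.data[:, c, ep.periods["delay1"]].mean()
        assert abs(delay / base - gain) / gain < 0.05

    def test_directed_coupling_direction_via_cross_correlation(self):
        # the target's coupled band content must lag the source's
        cfg = small_cfg(
            n_trials_per_condition=10, block_size=5,
            channels_per_region={"IPL": 1, "HIP": 1},
            couplings=(Coupling(regions=("IPL", "HIP"), freq=4.0,
                                periods=("delay1", "delay2"), kappa=20.0,
                                direction="a->b", lag_s=0.05, amplitude=60.0),),
        )
        rec, ev, gt = simulate_session(cfg, 3)
        from streamsync import preprocess

        bip = preprocess.bipolar_rereference(rec)
        names = list(bip.channels["name"])
        sos = signal.butter(3, [3, 5], btype="bandpass", fs=rec.rate,
                            output="sos")
        x = signal.sosfiltfilt(sos, bip.samples[names.index("P2-P1")])
        y = signal.sosfiltfilt(sos, bip.samples[names.index("H2-H1")])
        lags = signal.correlation_lags(len(x), len(y))
        cc = signal.correlate(y, x)  # peak at positive lag => y delayed
        window = np.abs(lags) < int(0.2 * rec.rate)
        best = lags[window][np.argmax(cc[window])]
        assert best > 0
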