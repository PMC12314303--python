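"""Notch, bipolar derivation, epoch assembly and artifact exclusion."""

import numpy as np
import pandas as pd
import pytest

from streamsync import preprocess
from streamsync.io_core import ContinuousRecording
from streamsync.preprocess import (
    bipolar_rereference,
    epoch,
    exclude_incorrect,
    extract_period_segments,
    flag_spike_epochs,
    notch_filter,
)
from streamsync.synthetic_data import SimulationConfig, simulate_session


def _channels(n, shaft="A", region="IPL"):
    return pd.DataFrame(
        {
            "name": [f"{shaft}{i + 1}" for i in range(n)],
            "shaft": shaft,
            "contact_index": np.arange(1, n + 1),
            "region": region,
            "hemisphere": "R",
            "status": "good",
            "soz": 0,
        }
    )


def _sine(freq, dur=10.0, rate=512.0, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


class TestNotch:
    def test_line_frequency_removed(self):
        x = _sine(50.0)[None, :]
        rec = ContinuousRecording(x, 512.0, _channels(1))
        out = notch_filter(rec).samples[0]
        # ignore filtfilt edges
        mid = slice(1024, -1024)
        assert np.max(np.abs(out[mid])) < 0.05 * 1.0

    def test_passband_preserved(self):
        for f in (10.0, 45.0):
            x = _sine(f)[None, :]
            rec = ContinuousRecording(x, 512.0, _channels(1))
            out = notch_filter(rec).samples[0]
            mid = slice(1024, -1024)
            ratio = np.max(np.abs(out[mid])) / 1.0
            assert abs(ratio - 1.0) < 0.01, f

    def test_zero_in_zero_out(self):
        rec = ContinuousRecording(np.zeros((2, 4096)), 512.0, _channels(2))
        assert np.allclose(notch_filter(rec).samples, 0.0)


class TestBipolar:
    def test_eight_contacts_give_seven_channels(self, rng):
        rec = ContinuousRecording(rng.normal(size=(8, 1024)), 512.0, _channels(8))
        bip = bipolar_rereference(rec)
        assert bip.n_channels == 7
        assert list(bip.channels["name"])[0] == "A2-A1"

    def test_common_mode_rejected_exactly(self, rng):
        base = rng.normal(size=(4, 2048))
        common = rng.normal(size=2048)
        rec1 = ContinuousRecording(base, 512.0, _channels(4))
        rec2 = ContinuousRecording(base + common, 512.0, _channels(4))
        # annihilation is exact up to float addition roundoff
        assert np.allclose(bipolar_rereference(rec1).samples,
                           bipolar_rereference(rec2).samples,
                           atol=1e-10, rtol=0)

    def test_soz_contact_removes_adjacent_pairs(self, rng):
        # contact 3 flagged on an 8-contact shaft: pairs (2,3) and (3,4)
        # vanish, 5 bipolar channels remain (enumeration oracle)
        ch = _channels(8)
        ch.loc[2, "soz"] = 1
        rec = ContinuousRecording(rng.normal(size=(8, 512)), 512.0, ch)
        bip = bipolar_rereference(rec)
        assert bip.n_channels == 5
        assert "A3-A2" not in list(bip.channels["name"])
        assert "A4-A3" not in list(bip.channels["name"])

    def test_short_shaft_dropped_with_warning(self, rng):
        ch = pd.concat([_channels(4, "A"), _channels(1, "B")],
                       ignore_index=True)
        rec = ContinuousRecording(rng.normal(size=(5, 512)), 512.0, ch)
        with pytest.warns(UserWarning, match="'B'"):
            bip = bipolar_rereference(rec)
        assert bip.n_channels == 3

    def test_region_label_from_deeper_contact(self, rng):
        ch = _channels(3)
        ch["region"] = ["HIP", "VTC", "VTC"]
        rec = ContinuousRecording(rng.normal(size=(3, 512)), 512.0, ch)
        bip = bipolar_rereference(rec)
        assert list(bip.channels["region"]) == ["HIP", "VTC"]


class TestEpoch:
    def _session(self):
        cfg = SimulationConfig(n_trials_per_condition=10, block_size=5,
                               channels_per_region={"IPL": 1, "VTC": 1},
                               spike_rate_per_min=0.0)
        rec, ev, _ = simulate_session(cfg, 2)
        return bipolar_rereference(rec), ev

    def test_period_lengths_and_tiling(self):
        bip, ev = self._session()
        ep = epoch(bip, ev)
        expected = {"baseline": 0.5, "encoding": 2.0, "delay1": 1.9,
                    "delay2": 1.9, "recall": 2.0}
        for k, sl in ep.periods.items():
            assert sl.stop - sl.start == int(round(expected[k] * ep.rate)), k
        assert ep.data.shape[2] == sum(v.stop - v.start
                                       for v in ep.periods.values())

    def test_constant_length_regardless_of_jitter(self):
        bip, ev = self._session()
        assert ev["delay_s"].nunique() > 1  # jitter present
        ep = epoch(bip, ev)
        assert ep.data.shape[0] == len(ev)

    def test_delay_head_skip_indexing(self):
        # a linear time ramp makes sample indices directly readable:
        # delay1 must start exactly 2.2 s after encoding onset
        rate = 512.0
        n = int(40 * rate)
        ramp = (np.arange(n) / rate)[None, :]
        rec_arr = np.vstack([ramp, 2 * ramp])
        ev = pd.DataFrame([
            {"onset": 10.0, "trial_type": "same", "block": 0,
             "fixation_s": 2.0, "encoding_s": 2.0, "delay_s": 4.1,
             "action_s": 2.0, "question_s": np.nan,
             "correct_position": 1, "correct_identity": np.nan},
        ])
        ep = epoch(rec_arr, ev, rate=rate)
        d1 = ep.data[0, 0, ep.periods["delay1"]]
        assert d1[0] == pytest.approx(12.2, abs=1.5 / rate)
        d2 = ep.data[0, 0, ep.periods["delay2"]]
        assert d2[0] == pytest.approx(14.1, abs=1.5 / rate)
        rec_ = ep.data[0, 0, ep.periods["recall"]]
        assert rec_[0] == pytest.approx(10.0 + 2.0 + 4.1, abs=1.5 / rate)

    def test_epoch_outside_recording_names_trial(self):
        bip, ev = self._session()
        ev2 = ev.copy()
        ev2.loc[len(ev2) - 1, "onset"] = bip.duration + 100
        with pytest.raises(ValueError, match=f"trial {len(ev2) - 1}"):
            epoch(bip, ev2)

    def test_connectivity_windows(self):
        bip, ev = self._session()
        segs = extract_period_segments(bip, ev, kind="plv")
        assert segs["baseline"].shape[2] == int(round(1.9 * bip.rate))
        assert segs["recall"].shape[2] == int(round(0.5 * bip.rate))
        gc = extract_period_segments(bip, ev, kind="gc")
        assert "recall" not in gc
        assert all(v.shape[2] == int(round(1.9 * bip.rate))
                   for v in gc.values())


class TestSpikeFlagging:
    def test_simulator_spikes_recovered(self):
        cfg = SimulationConfig(n_trials_per_condition=10, block_size=5,
                               channels_per_region={"IPL": 2, "VTC": 2},
                               spike_rate_per_min=3.0)
        hit = tot = 0
        for seed in range(4):
            rec, ev, gt = simulate_session(cfg, seed)
            bip = bipolar_rereference(notch_filter(rec))
            ep = epoch(bip, ev)
            mask = flag_spike_epochs(ep)
            names = list(bip.channels["name"])
            flagged = {(t, names[c]) for t, c in zip(*np.nonzero(mask))}
            hit += len(gt.spike_epochs & flagged)
            tot += len(gt.spike_epochs)
        assert tot > 30
        assert hit / tot >= 0.9

    def test_pure_oscillation_not_flagged(self):
        rate = 512.0
        t = np.arange(int(60 * rate)) / rate
        x = 40 * np.sin(2 * np.pi * 6 * t)[None, :]
        ev = pd.DataFrame([
            {"onset": 5.0 + 12 * k, "trial_type": "same", "block": 0,
             "fixation_s": 2.0, "encoding_s": 2.0, "delay_s": 4.0,
             "action_s": 2.0, "question_s": np.nan, "correct_position": 1,
             "correct_identity": np.nan} for k in range(4)
        ])
        ep = epoch(x, ev, rate=rate)
        assert flag_spike_epochs(ep).sum() == 0

    def test_all_zero_channel_not_flagged(self):
        rate = 512.0
        x = np.zeros((1, int(60 * rate)))
        ev = pd.DataFrame([
            {"onset": 5.0, "trial_type": "same", "block": 0,
             "fixation_s": 2.0, "encoding_s": 2.0, "delay_s": 4.0,
             "action_s": 2.0, "question_s": np.nan, "correct_position": 1,
             "correct_identity": np.nan},
        ])
        ep = epoch(x, ev, rate=rate)
        assert flag_spike_epochs(ep).sum() == 0


class TestExcludeIncorrect:
    def _epochs(self, ev):
        n = len(ev)
        data = np.zeros((n, 2, int(8.3 * 64)))
        return epoch(np.zeros((2, int((ev['onset'].max() + 15) * 64))),
                     ev, rate=64.0)

    def test_counts(self):
        cfg = SimulationConfig(n_trials_per_condition=10, block_size=5,
                               channels_per_region={"IPL": 1, "VTC": 1},
                               p_correct_position=1.0, p_correct_identity=1.0,
                               spike_rate_per_min=0.0)
        rec, ev, _ = simulate_session(cfg, 5)
        bip = bipolar_rereference(rec)
        ep = epoch(bip, ev)
        assert exclude_incorrect(ep, ev).sum() == 0
        ev2 = ev.copy()
        ev2.loc[[1, 5, 9], "correct_position"] = 0
        mask = exclude_incorrect(ep, ev2)
        assert mask.all(axis=1).sum() == 3

    def test_identity_error_excludes_different_trial(self):
        cfg = SimulationConfig(n_trials_per_condition=10, block_size=5,
                               channels_per_region={"IPL": 1, "VTC": 1},
                               spike_rate_per_min=0.0)
        rec, ev, _ = simulate_session(cfg, 6)
        bip = bipolar_rereference(rec)
        ep = epoch(bip, ev)
        ev2 = ev.copy()
        diff_idx = ev2.index[ev2.trial_type == "different"][0]
        ev2.loc[diff_idx, "correct_position"] = 1
        ev2.loc[diff_idx, "correct_identity"] = 0.0
        mask = exclude_incorrect(ep, ev2)
        assert mask[diff_idx].all()
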