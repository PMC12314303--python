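"""Preprocessing: notch filtering, bipolar derivation, epoching, exclusion.

The order follows the recording workflow: zero-phase notch at 50 Hz and
harmonics on the contact signals, bipolar derivation between adjacent
contacts of each shaft (dropping pairs touching bad or seizure-onset-zone
contacts), then epoching into fixed-length task-period segments and
per-epoch artifact/behaviour exclusion masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import signal

from streamsync.io_core import ContinuousRecording
from streamsync.task import (
    EPOCH_START,
    GC_PERIODS,
    PERIOD_ORDER,
    PLV_PERIODS,
    POWER_PERIODS,
    period_windows,
)

__all__ = [
    "EpochSet",
    "notch_filter",
    "bipolar_rereference",
    "epoch",
    "extract_period_segments",
    "flag_spike_epochs",
    "exclude_incorrect",
]


@dataclass
class EpochSet:
    """Fixed-length epochs (trials x channels x time) with period boundaries.

    The epoch is the concatenation of baseline (0.5 s), encoding (2.0 s),
    delay1 (1.9 s), delay2 (1.9 s) and recall (2.0 s) segments, i.e.
    -0.5 s to +7.8 s around encoding onset with the jittered 0.0-0.2 s
    head of the delay removed.  ``periods`` maps period name to a
    ``slice`` into the time axis; the slices tile the epoch exactly.
    """

    data: np.ndarray
    rate: float
    periods: dict
    conditions: np.ndarray
    channel_names: list
    channel_regions: list
    events: pd.DataFrame
    exclusion_mask: np.ndarray = field(default=None)
    exclusion_reasons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exclusion_mask is None:
            self.exclusion_mask = np.zeros(self.data.shape[:2], dtype=bool)
        n = sum(s.stop - s.start for s in self.periods.values())
        if n != self.data.shape[2]:
            raise ValueError("period slices do not tile the epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Nominal epoch time axis (s relative to encoding onset)."""
        return EPOCH_START + np.arange(self.data.shape[2]) / self.rate

    def add_exclusions(self, mask: np.ndarray, reason: str) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.exclusion_mask.shape:
            raise ValueError("exclusion mask shape mismatch")
        self.exclusion_mask |= mask
        self.exclusion_reasons[reason] = mask


def notch_filter(rec: ContinuousRecording, freqs=(50.0, 100.0, 150.0, 200.0),
                 width: float = 1.0, order: int = 4) -> ContinuousRecording:
    """Zero-phase Butterworth band-stop at the line frequency and harmonics.

    ``order`` is the overall filter order (4 = two second-order sections
    per edge); harmonics at or above Nyquist are skipped.
    """
    if rec.rate < 200:
        raise ValueError("notch filtering expects rate >= 200 Hz")
    x = rec.samples.copy()
    for f0 in freqs:
        if f0 >= rec.rate / 2:
            continue
        sos = signal.butter(order // 2, [f0 - width / 2, f0 + width / 2],
                            btype="bandstop", fs=rec.rate, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=-1)
    return ContinuousRecording(samples=x, rate=rec.rate, channels=rec.channels,
                               session_id=rec.session_id)


def bipolar_rereference(rec: ContinuousRecording,
                        channels: pd.DataFrame | None = None) -> ContinuousRecording:
    """Bipolar derivation between adjacent contacts of each shaft.

    Output channel k is ``contact(j+1) - contact(j)`` for consecutive
    contact indices on one shaft, named ``"<hi>-<lo>"``.  Pairs involving
    contacts flagged bad or in the seizure-onset zone are excluded; a
    shaft with fewer than two usable contacts is dropped with a warning.
    The derived channel inherits the deeper (lower-index) contact's
    region, which can be overridden in the channel table.
    """
    table = (rec.channels if channels is None else channels).reset_index(drop=True)
    usable = (table["status"] == "good") & (table["soz"] == 0)
    rows, signals = [], []
    for shaft, grp in table.groupby("shaft", sort=False):
        ok = grp[usable.loc[grp.index]]
        if len(ok) < 2:
            warnings.warn(f"shaft {shaft!r} has < 2 usable contacts; dropped",
                          stacklevel=2)
            continue
        by_idx = {int(r["contact_index"]): i for i, r in ok.iterrows()}
        n_pairs = 0
        for ci in sorted(by_idx):
            if ci + 1 not in by_idx:
                continue
            lo, hi = by_idx[ci], by_idx[ci + 1]
            signals.append(rec.samples[hi] - rec.samples[lo])
            rows.append(
                {
                    "name": f"{table.at[hi, 'name']}-{table.at[lo, 'name']}",
                    "shaft": shaft,
                    "contact_index": ci,
                    "region": table.at[lo, "region"],
                    "hemisphere": table.at[lo, "hemisphere"],
                    "status": "good",
                    "soz": 0,
                }
            )
            n_pairs += 1
        if n_pairs == 0:
            warnings.warn(f"shaft {shaft!r} yields no adjacent usable pairs",
                          stacklevel=2)
    if not signals:
        raise ValueError("no bipolar channels could be derived")
    return ContinuousRecording(
        samples=np.asarray(signals), rate=rec.rate,
        channels=pd.DataFrame(rows), session_id=rec.session_id,
    )


def _segment(samples: np.ndarray, rate: float, t0: float, dur: float,
             trial: int) -> np.ndarray:
    i0 = int(round(t0 * rate))
    n = int(round(dur * rate))
    if i0 < 0 or i0 + n > samples.shape[1]:
        raise ValueError(
            f"trial {trial}: segment [{t0:.3f}, {t0 + dur:.3f}) s falls "
            "outside the recording"
        )
    return samples[:, i0:i0 + n]


def epoch(rec: ContinuousRecording | np.ndarray, events: pd.DataFrame,
          rate: float | None = None,
          channel_names: list | None = None,
          channel_regions: list | None = None) -> EpochSet:
    """Assemble fixed-length power epochs on any sampling grid.

    Accepts a :class:`ContinuousRecording` or a raw (channels x time)
    array plus ``rate``.  Each period segment is cut independently at its
    own anchor so the per-epoch sample count is constant regardless of
    the trial's jitter.
    """
    if isinstance(rec, ContinuousRecording):
        samples, rate = rec.samples, rec.rate
        channel_names = list(rec.channels["name"])
        channel_regions = list(rec.channels["region"])
    else:
        samples = np.asarray(rec)
        if rate is None:
            raise ValueError("rate is required when passing a bare array")
        if channel_names is None:
            channel_names = [f"ch{i}" for i in range(samples.shape[0])]
        if channel_regions is None:
            channel_regions = ["OTHER"] * samples.shape[0]

    per_trial, slices = [], {}
    start = 0
    for name in PERIOD_ORDER:
        n = int(round(POWER_PERIODS[name] * rate))
        slices[name] = slice(start, start + n)
        start += n
    for ti, ev in events.iterrows():
        wins = period_windows(ev["onset"], ev["fixation_s"], ev["delay_s"],
                              kind="power")
        segs = [
            _segment(samples, rate, wins[name][0], POWER_PERIODS[name], ti)
            for name in PERIOD_ORDER
        ]
        per_trial.append(np.concatenate(segs, axis=1))
    data = np.stack(per_trial)
    return EpochSet(
        data=data, rate=rate, periods=slices,
        conditions=events["trial_type"].to_numpy(),
        channel_names=channel_names, channel_regions=channel_regions,
        events=events.reset_index(drop=True),
    )


def extract_period_segments(rec: ContinuousRecording | np.ndarray,
                            events: pd.DataFrame,
                            kind: str = "plv",
                            rate: float | None = None) -> dict:
    """Cut per-period windows on the signal grid for connectivity stages.

    Returns ``{period: (trials x channels x n_samples) array}`` using the
    PLV windows (1.9 s fixation baseline, 2.0 s encoding, 1.9 s delay
    halves, 0.5 s pre-response recall) or the GC windows (all 1.9 s,
    recall excluded).
    """
    if isinstance(rec, ContinuousRecording):
        samples, rate = rec.samples, rec.rate
    else:
        samples = np.asarray(rec)
        if rate is None:
            raise ValueError("rate is required when passing a bare array")
    durations = PLV_PERIODS if kind == "plv" else GC_PERIODS
    out: dict[str, np.ndarray] = {}
    for name, dur in durations.items():
        segs = []
        for ti, ev in events.iterrows():
            wins = period_windows(ev["onset"], ev["fixation_s"], ev["delay_s"],
                                  kind=kind)
            segs.append(_segment(samples, rate, wins[name][0], dur, ti))
        out[name] = np.stack(segs)
    return out


def flag_spike_epochs(epochs: EpochSet, amp_sd: float = 6.0,
                      diff_sd: float = 8.0) -> np.ndarray:
    """Stand-in interictal-spike detector on epoched raw-band data.

    Flags a (trial, channel) epoch when the absolute z-scored amplitude
    exceeds ``amp_sd`` or the z-scored first difference exceeds
    ``diff_sd`` anywhere in the epoch.  The per-channel scale is a robust
    (MAD-based) sigma across all epochs so that the spikes themselves do
    not inflate it; zero-variance channels are never flagged (they are
    dead, not spiking).
    """
    x = epochs.data  # trials x channels x time
    flat = x.transpose(1, 0, 2).reshape(x.shape[1], -1)
    eps = 1e-12 * max(1.0, float(np.max(np.abs(flat))) if flat.size else 1.0)
    med = np.median(flat, axis=1)
    sd = 1.4826 * np.median(np.abs(flat - med[:, None]), axis=1)
    ok = sd > eps
    mask = np.zeros(x.shape[:2], dtype=bool)
    if not ok.any():
        return mask
    z = np.abs(x[:, ok, :] - med[ok][None, :, None]) / sd[ok][None, :, None]
    # first differences within each period segment only: the concatenated
    # epoch has artificial jumps at segment boundaries
    d = np.concatenate(
        [np.abs(np.diff(x[:, ok, sl], axis=2)) for sl in epochs.periods.values()],
        axis=2,
    )
    dflat = d.transpose(1, 0, 2).reshape(int(ok.sum()), -1)
    dmed = np.median(dflat, axis=1)
    dsd = 1.4826 * np.median(np.abs(dflat - dmed[:, None]), axis=1)
    dsd = np.maximum(dsd, eps)
    hit = (z.max(axis=2) > amp_sd) | (
        (d / dsd[None, :, None]).max(axis=2) > diff_sd
    )
    mask[:, ok] = hit
    return mask


def exclude_incorrect(epochs: EpochSet, events: pd.DataFrame | None = None) -> np.ndarray:
    """Trial-level exclusion of incorrect position or identity responses."""
    ev = epochs.events if events is None else events
    bad_pos = ev["correct_position"].fillna(1).astype(float).to_numpy() == 0
    ident = ev["correct_identity"].astype(float).to_numpy()
    bad_id = np.where(np.isnan(ident), False, ident == 0)
    bad_trial = bad_pos | bad_id
    mask = np.zeros(epochs.data.shape[:2], dtype=bool)
    mask[bad_trial, :] = True
    return mask
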