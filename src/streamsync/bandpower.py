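"""Whitened filter-Hilbert band power and active-channel detection.

The continuous signal is band-pass filtered in consecutive 1 Hz bands
(zero-phase 3rd-order Butterworth), the Hilbert amplitude envelope of
each band is decimated to 64 Hz (anti-aliased) and divided by its mean
over the whole session (x100), flattening the 1/f spectrum.  Theta
(2-7 Hz) and alpha (8-13 Hz) power are the averages of the 1 Hz envelopes
in those ranges, epoched and baseline-corrected.  A channel is 'active'
in a band when a sliding-window Wilcoxon test against the pre-stimulus
baseline survives Benjamini-Hochberg FDR across all time points and
channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.fft import next_fast_len
from scipy.ndimage import maximum_filter1d
from statsmodels.stats.multitest import multipletests

from streamsync.io_core import ContinuousRecording
from streamsync.preprocess import EpochSet, epoch as make_epochs
from streamsync.task import PERIOD_ORDER

__all__ = [
    "BAND_DEFINITIONS",
    "EnvelopeBands",
    "EnvelopeSet",
    "ActiveChannelReport",
    "filter_hilbert_envelope",
    "aggregate_band",
    "detect_active_channels",
    "average_task_periods",
]

#: Band k covers [k, k+1) Hz: theta aggregates k = 2..6, alpha k = 8..12.
#: The inclusive printed endpoints (2-7, 8-13 Hz) make the last 1 Hz bin
#: ambiguous; this convention is configurable via ``aggregate_band``.
BAND_DEFINITIONS = {"theta": (2, 7), "alpha": (8, 13)}

ENVELOPE_RATE = 64.0


@dataclass
class EnvelopeBands:
    """Whitened 1 Hz-band amplitude envelopes on the 64 Hz session grid.

    ``values[b, c, t]`` is channel c's envelope in band
    ``[band_starts[b], band_starts[b]+1)`` Hz, in percent of its session
    mean (session mean = 100 by construction).
    """

    values: np.ndarray
    band_starts: np.ndarray
    rate: float
    channel_names: list
    channel_regions: list
    session_id: str = ""


@dataclass
class EnvelopeSet:
    """Epoched band-aggregate envelope (percent units) for one band."""

    epochs: EpochSet
    band: str
    band_range: tuple
    baseline_corrected: bool = False

    @property
    def data(self) -> np.ndarray:
        return self.epochs.data


@dataclass
class ActiveChannelReport:
    """Active-channel decisions for one (band, condition).

    ``table`` has one row per channel (active flag, minimum corrected p,
    number of significant time points); ``sig_masks`` is the
    channels x post-stimulus-time boolean significance matrix.
    """

    table: pd.DataFrame
    sig_masks: np.ndarray
    times: np.ndarray
    band: str
    condition: str

    @property
    def active_channels(self) -> list:
        return list(self.table.loc[self.table["active"], "channel"])


def _analytic_envelope(x: np.ndarray) -> np.ndarray:
    """Hilbert amplitude envelope along the last axis (padded FFT)."""
    n = x.shape[-1]
    nfft = next_fast_len(n)
    return np.abs(signal.hilbert(x, N=nfft, axis=-1)[..., :n])


def filter_hilbert_envelope(rec: ContinuousRecording, f_lo: float = 2.0,
                            f_hi: float = 120.0,
                            env_rate: float = ENVELOPE_RATE,
                            order: int = 3) -> EnvelopeBands:
    """Per-1 Hz-band whitened amplitude envelopes of a continuous recording.

    For each band [k, k+1) Hz, k = f_lo..f_hi-1: zero-phase Butterworth
    band-pass, analytic-signal magnitude, anti-aliased decimation to
    ``env_rate``, division by the session mean and x100.  Bands reaching
    Nyquist are skipped with a warning.
    """
    if rec.rate < 256:
        raise ValueError("filter-Hilbert stage expects rate >= 256 Hz")
    ratio = rec.rate / env_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("sampling rate must be an integer multiple of env_rate")
    down = int(round(ratio))

    starts = []
    env_rows = []
    for k in range(int(f_lo), int(f_hi)):
        if k + 1 >= rec.rate / 2:
            warnings.warn(f"band [{k}, {k + 1}) Hz at/above Nyquist; skipped",
                          stacklevel=2)
            continue
        sos = signal.butter(order, [k, k + 1], btype="bandpass", fs=rec.rate,
                            output="sos")
        bp = signal.sosfiltfilt(sos, rec.samples, axis=-1)
        env = _analytic_envelope(bp)
        env64 = signal.resample_poly(env, up=1, down=down, axis=-1)
        env64 = np.maximum(env64, 0.0)  # FIR decimation can undershoot
        mean = env64.mean(axis=-1, keepdims=True)
        mean = np.where(mean > 0, mean, 1.0)
        env_rows.append(100.0 * env64 / mean)
        starts.append(k)
    if not env_rows:
        raise ValueError("no band below Nyquist")
    return EnvelopeBands(
        values=np.stack(env_rows), band_starts=np.asarray(starts),
        rate=env_rate, channel_names=list(rec.channels["name"]),
        channel_regions=list(rec.channels["region"]),
        session_id=rec.session_id,
    )


def aggregate_band(env: EnvelopeBands, band: str | tuple, events: pd.DataFrame,
                   baseline_correct: bool = True) -> EnvelopeSet:
    """Average the 1 Hz envelopes of a named band, epoch, baseline-correct.

    ``band`` is "theta"/"alpha" or an explicit ``(lo, hi)`` range whose
    1 Hz bins ``lo..hi-1`` must all be present.  Baseline correction
    subtracts each trial/channel's mean over [-0.5, 0) s.
    """
    if isinstance(band, str):
        name, (lo, hi) = band, BAND_DEFINITIONS[band]
    else:
        lo, hi = band
        name = f"{lo}-{hi}Hz"
    wanted = np.arange(int(lo), int(hi))
    idx = []
    for k in wanted:
        hits = np.nonzero(env.band_starts == k)[0]
        if hits.size == 0:
            raise ValueError(f"1 Hz band starting at {k} Hz missing from envelopes")
        idx.append(hits[0])
    agg = env.values[idx].mean(axis=0)  # channels x time

    ep = make_epochs(agg, events, rate=env.rate,
                     channel_names=env.channel_names,
                     channel_regions=env.channel_regions)
    if baseline_correct:
        bsl = ep.data[:, :, ep.periods["baseline"]].mean(axis=2, keepdims=True)
        ep.data = ep.data - bsl
    return EnvelopeSet(epochs=ep, band=name, band_range=(lo, hi),
                       baseline_corrected=baseline_correct)


def _wilcoxon_p(diffs: np.ndarray) -> float:
    """Signed-rank p across trials; all-zero differences mean no evidence."""
    d = diffs[~np.isnan(diffs)]
    if d.size < 5 or np.all(d == 0):
        return 1.0
    try:
        return float(stats.wilcoxon(d, zero_method="wilcox",
                                    method="approx").pvalue)
    except ValueError:
        return 1.0


def detect_active_channels(env: EnvelopeSet, condition: str,
                           q: float = 0.05, window: int = 6,
                           min_trials: int = 10) -> ActiveChannelReport:
    """Sliding-window Wilcoxon/FDR detection of task-responsive channels.

    For each post-stimulus time point, the envelope is compared across
    trials of ``condition`` against each trial's baseline mean (paired
    signed-rank).  Each point's p is replaced by the largest p within a
    centred six-sample (93.75 ms) window — a conservative smoothing —
    then Benjamini-Hochberg FDR is applied jointly across time points
    and channels.  A channel is active if any corrected point is
    significant.
    """
    ep = env.epochs
    post = slice(ep.periods["encoding"].start, ep.data.shape[2])
    times = ep.times[post]
    cond_trials = ep.conditions == condition
    n_ch = ep.n_channels
    n_t = times.size

    pvals = np.ones((n_ch, n_t))
    tested = np.zeros(n_ch, dtype=bool)
    for c in range(n_ch):
        keep = cond_trials & ~ep.exclusion_mask[:, c]
        if keep.sum() < min_trials:
            warnings.warn(
                f"channel {ep.channel_names[c]}: only {int(keep.sum())} usable "
                f"trials (< {min_trials}); skipped", stacklevel=2,
            )
            continue
        tested[c] = True
        x = ep.data[keep, c, :]
        # per-trial baseline mean is exactly zero after baseline correction,
        # so this paired difference is valid on either representation
        base = x[:, ep.periods["baseline"]].mean(axis=1)
        diffs = x[:, post] - base[:, None]
        for t in range(n_t):
            pvals[c, t] = _wilcoxon_p(diffs[:, t])

    # conservative smoothing: max p in a centred 6-sample window,
    # truncated at the epoch edges
    smoothed = maximum_filter1d(pvals, size=window, axis=1, mode="constant",
                                cval=-np.inf)
    flat = smoothed[tested].ravel()
    sig = np.zeros_like(smoothed, dtype=bool)
    corrected = np.ones_like(smoothed)
    if flat.size:
        rej, p_adj, _, _ = multipletests(flat, alpha=q, method="fdr_bh")
        sig[tested] = rej.reshape(tested.sum(), n_t)
        corrected[tested] = p_adj.reshape(tested.sum(), n_t)

    rows = [
        {
            "channel": ep.channel_names[c],
            "region": ep.channel_regions[c],
            "band": env.band,
            "condition": condition,
            "active": bool(sig[c].any()),
            "min_corrected_p": float(corrected[c].min()),
            "n_sig_points": int(sig[c].sum()),
        }
        for c in range(n_ch)
    ]
    return ActiveChannelReport(table=pd.DataFrame(rows), sig_masks=sig,
                               times=times, band=env.band, condition=condition)


def average_task_periods(env: EnvelopeSet, active_channels: list) -> pd.DataFrame:
    """Per (channel, condition, period) mean power of active channels.

    ``active_channels`` is normally the union of channels active in
    either condition.  Means use each channel's non-excluded trials of
    the respective condition; all five periods (baseline included) are
    reported, ready for the mixed-model stage.
    """
    ep = env.epochs
    rows = []
    for name in active_channels:
        c = ep.channel_names.index(name)
        for cond in ("same", "different"):
            keep = (ep.conditions == cond) & ~ep.exclusion_mask[:, c]
            if not keep.any():
                continue
            x = ep.data[keep, c, :]
            for period in PERIOD_ORDER:
                rows.append(
                    {
                        "channel": name,
                        "region": ep.channel_regions[c],
                        "band": env.band,
                        "condition": cond,
                        "period": period,
                        "mean_power": float(x[:, ep.periods[period]].mean()),
                        "n_trials": int(keep.sum()),
                    }
                )
    return pd.DataFrame(rows)
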