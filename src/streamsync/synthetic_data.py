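"""Task-structured iEEG session generator with known ground truth.

A simulated session reproduces the statistical structure the analyses are
designed to detect, so every downstream stage can be validated without
patient data:

* counterbalanced blocks of 'same'/'different' trials with the task's
  jittered fixation (1.9-2.1 s) and delay (3.9-4.1 s);
* per-channel 1/f background, 50 Hz line noise and harmonics, and
  interictal-spike transients;
* band-limited oscillators whose amplitude is scaled inside chosen task
  periods (the band-power ground truth);
* phase coupling between region pairs realised as a shared narrowband
  oscillator plus von Mises phase jitter of concentration kappa, so the
  expected phase-locking value is the analytic resultant length
  ``I1(kappa)/I0(kappa)``;
* directed coupling realised by adding a lagged, scaled copy of the
  source oscillator into the target region, giving a positive net
  Granger causality in the injected direction.

Contacts are synthesised so that bipolar derivation (next contact minus
current) recovers exactly the per-channel content: contact ``k+1`` is the
cumulative sum of the first ``k`` channel signals plus a common-mode
reference signal, which cancels in every bipolar difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import i0, i1

from streamsync.io_core import ContinuousRecording, validate_channels, validate_events
from streamsync.task import period_windows

__all__ = [
    "BandEffect",
    "Coupling",
    "SimulationConfig",
    "GroundTruth",
    "expected_plv",
    "schedule_trials",
    "simulate_session",
    "score_response",
]

REGION_SHAFTS = {"IPL": "P", "VTC": "T", "HIP": "H", "OTHER": "O"}

#: Half the minimum inter-object distance, as a fraction of screen width.
HALF_MIN_DISTANCE = 0.105


def expected_plv(kappa: float) -> float:
    """Analytic resultant length of a von Mises distribution, I1(k)/I0(k)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


@dataclass
class BandEffect:
    """Multiplicative amplitude change of a band-limited oscillator.

    The oscillator (narrowband Gaussian noise in ``band``) runs at RMS
    ``amplitude`` throughout the session and is scaled by ``gain`` inside
    the listed task periods of trials of the listed conditions
    (None = both conditions).  ``gain`` multiplies the Hilbert amplitude
    envelope, so a +50 % envelope effect is ``gain=1.5``.
    """

    region: str
    band: tuple[float, float]
    periods: tuple[str, ...]
    gain: float
    conditions: tuple[str, ...] | None = None
    amplitude: float = 8.0


@dataclass
class Coupling:
    """Phase coupling between two regions at one frequency.

    All channels of ``regions[0]`` receive a shared narrowband oscillator
    (``freq`` +- ``bandwidth/2``); each channel of ``regions[1]`` receives
    a copy rotated by a per-trial von Mises phase offset of concentration
    ``kappa`` and, if ``direction`` is set, delayed by ``lag_s`` and
    scaled by ``strength`` so that Granger causality points from the
    source to the target.  ``direction`` is ``None`` (zero-lag shared
    phase), ``"a->b"`` or ``"b->a"``.
    """

    regions: tuple[str, str]
    freq: float
    periods: tuple[str, ...]
    kappa: float = 2.0
    conditions: tuple[str, ...] | None = None
    direction: str | None = None
    lag_s: float = 0.05
    strength: float = 1.0
    amplitude: float = 8.0
    bandwidth: float = 1.0

    @property
    def expected_plv(self) -> float:
        return expected_plv(self.kappa)


@dataclass
class SimulationConfig:
    """Stated world of a simulated session.

    Defaults follow the task design: 80 trials per condition in
    counterbalanced blocks of 10, recorded at 512 Hz.  ``channels_per_region``
    counts *bipolar* channels; the generator emits one shaft per region
    with one extra contact.
    """

    n_trials_per_condition: int = 80
    block_size: int = 10
    channels_per_region: dict = field(
        default_factory=lambda: {"IPL": 4, "VTC": 4, "HIP": 3}
    )
    rate: float = 512.0
    background_exponent: float = 1.0
    background_scale: float = 20.0  # uV RMS of the 1/f background
    common_mode_scale: float = 20.0
    line_noise_amp: float = 5.0  # uV at 50 Hz; harmonics at 1/3, 1/5, 1/7
    band_effects: tuple = ()
    couplings: tuple = ()
    spike_rate_per_min: float = 1.0
    spike_duration_s: float = 0.07
    spike_amp_sd: tuple[float, float] = (5.0, 10.0)
    p_correct_position: float = 0.98
    p_correct_identity: float = 0.91
    block_break_s: float = 2.0
    ramp_s: float = 0.1

    def validate(self) -> None:
        n_blocks, rem = divmod(2 * self.n_trials_per_condition, self.block_size)
        if rem:
            raise ValueError("block_size must divide the total trial count")
        if n_blocks % 4:
            raise ValueError(
                "counterbalancing needs a number of blocks divisible by 4"
            )
        for c in self.couplings:
            if c.freq > 20.0:
                raise ValueError(
                    f"coupling frequency {c.freq} Hz exceeds the 20 Hz Nyquist "
                    "frequency of the 40 Hz Granger-causality stage"
                )
            if c.kappa < 0:
                raise ValueError("coupling kappa must be >= 0")
            if c.direction not in (None, "a->b", "b->a"):
                raise ValueError(f"unknown coupling direction {c.direction!r}")
        for e in self.band_effects:
            if e.band[1] >= self.rate / 2:
                raise ValueError("band effect above Nyquist")


@dataclass
class GroundTruth:
    """What the generator injected, keyed by bipolar channel names."""

    bipolar_names: dict  # region -> list of bipolar channel names
    band_effects: list  # dicts: channels, band, periods, conditions, gain
    couplings: list  # dicts incl. drawn von Mises offsets and expected PLV
    spike_epochs: set  # {(trial_index, bipolar_channel_name)}
    gain_profiles: list  # per band effect, float32 gain time-course (session grid)
    rate: float = 512.0


# ---------------------------------------------------------------------------
# Trial scheduling and response scoring
# ---------------------------------------------------------------------------

def schedule_trials(cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    """Counterbalanced block schedule with the task's jittered durations.

    Blocks of ``block_size`` trials alternate conditions in an ABBA
    pattern (leading condition chosen by the seed), so both block orders
    occur equally often.  Fixation ~ U(1.9, 2.1) s, encoding 2.0 s,
    delay ~ U(3.9, 4.1) s, action 2.0 s; 'different' trials append a
    2.0 s identity question.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    n_blocks = 2 * cfg.n_trials_per_condition // cfg.block_size
    first, second = ("same", "different") if rng.integers(2) else ("different", "same")
    pattern = [first, second, second, first]
    block_conditions = [pattern[i % 4] for i in range(n_blocks)]

    rows = []
    t = 3.0  # lead-in before the first fixation
    trial = 0
    for b, cond in enumerate(block_conditions):
        for _ in range(cfg.block_size):
            fixation = rng.uniform(1.9, 2.1)
            delay = rng.uniform(3.9, 4.1)
            onset = t + fixation
            correct_pos = int(rng.random() < cfg.p_correct_position)
            if cond == "different":
                question = 2.0
                correct_id = float(rng.random() < cfg.p_correct_identity)
            else:
                question = np.nan
                correct_id = np.nan
            rows.append(
                {
                    "onset": onset,
                    "trial_type": cond,
                    "block": b,
                    "fixation_s": fixation,
                    "encoding_s": 2.0,
                    "delay_s": delay,
                    "action_s": 2.0,
                    "question_s": question,
                    "correct_position": correct_pos,
                    "correct_identity": correct_id,
                }
            )
            t = onset + 2.0 + delay + 2.0 + (2.0 if cond == "different" else 0.0)
            trial += 1
        t += cfg.block_break_s
    return validate_events(pd.DataFrame(rows))


def score_response(
    trajectory: Sequence[tuple[float, float]],
    target_xy: tuple[float, float],
    half_min_distance: float = HALF_MIN_DISTANCE,
    times: Sequence[float] | None = None,
):
    """Score a joystick reach against the axis-aligned target square.

    A response is correct iff some trajectory point lies inside the
    square ``target +- half_min_distance`` (boundary inclusive).  Returns
    ``(correct, rt)`` where ``rt`` is the time of first entry (from
    ``times``, or the sample index when ``times`` is None); ``rt`` is
    None for incorrect responses.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.size == 0:
        raise ValueError("empty trajectory")
    if half_min_distance <= 0:
        raise ValueError("half_min_distance must be positive")
    traj = traj.reshape(-1, 2)
    tx, ty = target_xy
    inside = (np.abs(traj[:, 0] - tx) <= half_min_distance) & (
        np.abs(traj[:, 1] - ty) <= half_min_distance
    )
    if not inside.any():
        return False, None
    k = int(np.argmax(inside))
    rt = float(times[k]) if times is not None else k
    return True, rt


# ---------------------------------------------------------------------------
# Signal synthesis helpers
# ---------------------------------------------------------------------------

def _one_over_f(rng: np.random.Generator, n: int, rate: float,
                exponent: float, scale: float) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (scale / rms) if rms > 0 else x


def _narrowband(rng: np.random.Generator, n: int, rate: float,
                band: tuple[float, float], rms: float) -> np.ndarray:
    """Band-limited Gaussian noise with the requested RMS amplitude."""
    sos = signal.butter(3, band, btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    cur = np.sqrt(np.mean(x**2))
    return x * (rms / cur) if cur > 0 else x


def _window_gain(gain_profile: np.ndarray, rate: float, t0: float, t1: float,
                 gain: float) -> None:
    """Set a multiplicative gain in [t0, t1) (hard step, smoothed later)."""
    n = gain_profile.shape[0]
    i0_, i1_ = max(int(round(t0 * rate)), 0), min(int(round(t1 * rate)), n)
    if i1_ > i0_:
        gain_profile[i0_:i1_] = gain


def _smooth_profile(profile: np.ndarray, rate: float, ramp_s: float) -> np.ndarray:
    """Turn gain steps into raised-cosine ramps of ~ramp_s width."""
    nr = int(round(ramp_s * rate))
    if nr < 2:
        return profile
    kernel = np.hanning(nr + 2)[1:-1]
    kernel /= kernel.sum()
    return signal.fftconvolve(profile, kernel, mode="same")


def _cos_taper(n: int, nr: int) -> np.ndarray:
    """Unit window with raised-cosine on/off ramps of nr samples."""
    w = np.ones(n)
    nr = min(nr, n // 2)
    if nr > 0:
        ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, nr)))
        w[:nr] = ramp
        w[-nr:] = ramp[::-1]
    return w


def _spike_waveform(rate: float, duration: float, amp: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Biphasic sharp transient (one sine cycle under a Hann window).

    Normalised so the waveform's peak equals ``amp``.
    """
    n = max(int(round(duration * rate)), 4)
    t = np.arange(n) / n
    w = np.sin(2 * np.pi * t) * np.hanning(n)
    return amp * w / np.max(np.abs(w))


def _matches(trial_cond: str, conditions: tuple[str, ...] | None) -> bool:
    return conditions is None or trial_cond in conditions


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------

def simulate_session(cfg: SimulationConfig, seed: int):
    """Generate a full session: recording (contacts), events, ground truth.

    Returns ``(ContinuousRecording, events DataFrame, GroundTruth)``.
    Identical (cfg, seed) give bit-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    events = schedule_trials(cfg, int(rng.integers(2**31 - 1)))

    last = events.iloc[-1]
    session_end = (
        last["onset"] + 2.0 + last["delay_s"] + 2.0
        + (2.0 if last["trial_type"] == "different" else 0.0) + 3.0
    )
    rate = cfg.rate
    n_times = int(np.ceil(session_end)) * int(rate)

    regions = list(cfg.channels_per_region)
    bipolar_names: dict[str, list[str]] = {}
    contents: dict[str, np.ndarray] = {}
    for region in regions:
        n_ch = cfg.channels_per_region[region]
        shaft = REGION_SHAFTS.get(region, region[0])
        bipolar_names[region] = [f"{shaft}{k + 2}-{shaft}{k + 1}" for k in range(n_ch)]
        x = np.empty((n_ch, n_times))
        for k in range(n_ch):
            x[k] = _one_over_f(rng, n_times, rate, cfg.background_exponent,
                               cfg.background_scale)
            t = np.arange(n_times) / rate
            for h, div in ((50.0, 1.0), (100.0, 3.0), (150.0, 5.0), (200.0, 7.0)):
                if h < rate / 2:
                    x[k] += (cfg.line_noise_amp / div) * np.sin(
                        2 * np.pi * h * t + rng.uniform(0, 2 * np.pi)
                    )
        contents[region] = x

    nr = int(round(cfg.ramp_s * rate))

    # --- band-limited oscillators with task-period amplitude effects ----
    gt_effects, gain_profiles = [], []
    for eff in cfg.band_effects:
        if eff.region not in contents:
            raise ValueError(f"band effect region {eff.region!r} has no channels")
        profile = np.ones(n_times, dtype=np.float64)
        for _, ev in events.iterrows():
            if not _matches(ev["trial_type"], eff.conditions):
                continue
            wins = period_windows(ev["onset"], ev["fixation_s"], ev["delay_s"],
                                  kind="power")
            for p in eff.periods:
                t0, t1 = wins[p]
                _window_gain(profile, rate, t0, t1, eff.gain)
        profile = _smooth_profile(profile, rate, cfg.ramp_s)
        for k in range(contents[eff.region].shape[0]):
            osc = _narrowband(rng, n_times, rate, eff.band, eff.amplitude)
            contents[eff.region][k] += osc * profile
        gt_effects.append(
            {
                "channels": list(bipolar_names[eff.region]),
                "region": eff.region,
                "band": tuple(eff.band),
                "periods": tuple(eff.periods),
                "conditions": eff.conditions,
                "gain": eff.gain,
            }
        )
        gain_profiles.append(profile.astype(np.float32))

    # --- phase / directed couplings -------------------------------------
    # undirected: a shared narrowband oscillator enters both regions, the
    # target side rotated by a per-trial von Mises phase offset of
    # concentration kappa (closed-form expected PLV = I1(k)/I0(k)).
    # directed: the target receives a *causally* band-passed, lagged,
    # scaled copy of the source channel's band content (including any
    # oscillator injected here) — lagged linear mixing, so the source's
    # past genuinely predicts the target; the von Mises offset is
    # realised as an extra per-trial time shift of delta/(2*pi*f), which
    # stays causal thanks to the copy filter's group delay.
    sos_causal: dict = {}
    gt_couplings = []
    for cpl in cfg.couplings:
        reg_a, reg_b = cpl.regions
        if cpl.direction == "b->a":
            src_reg, dst_reg = reg_b, reg_a
        else:
            src_reg, dst_reg = reg_a, reg_b
        n_src = contents[src_reg].shape[0]
        n_dst = contents[dst_reg].shape[0]
        lag_n = int(round(cpl.lag_s * rate)) if cpl.direction else 0
        band = (cpl.freq - cpl.bandwidth / 2, cpl.freq + cpl.bandwidth / 2)
        if band not in sos_causal:
            sos_causal[band] = signal.butter(2, band, btype="bandpass",
                                             fs=rate, output="sos")
        deltas = []
        for ti, ev in events.iterrows():
            if not _matches(ev["trial_type"], cpl.conditions):
                continue
            wins = period_windows(ev["onset"], ev["fixation_s"], ev["delay_s"],
                                  kind="plv")
            d_trial = rng.vonmises(0.0, cpl.kappa, size=n_dst) if cpl.kappa > 0 \
                else rng.uniform(-np.pi, np.pi, size=n_dst)
            deltas.append(d_trial)
            for p in cpl.periods:
                t0, t1 = wins[p]
                pad = 0.5
                j0 = max(int(round((t0 - pad) * rate)), 0)
                j1 = min(int(round((t1 + pad) * rate)), n_times)
                seg_n = j1 - j0
                if seg_n <= 4 * nr:
                    continue
                w0 = int(round(t0 * rate)) - j0
                w1 = min(int(round(t1 * rate)) - j0, seg_n)
                taper = _cos_taper(w1 - w0, nr)

                if cpl.amplitude > 0:
                    s = _narrowband(rng, seg_n, rate, band, cpl.amplitude)
                    src_seg = s[w0:w1] * taper
                    for ch in contents[src_reg]:
                        ch[j0 + w0:j0 + w1] += src_seg
                    a_shared = signal.hilbert(s)
                else:
                    a_shared = None

                for k in range(n_dst):
                    if cpl.direction is None:
                        if a_shared is None:
                            continue
                        rot = np.real(a_shared * np.exp(1j * d_trial[k]))
                    else:
                        m = k % n_src
                        seg = contents[src_reg][m, j0:j1]
                        cp = signal.sosfilt(sos_causal[band], seg)
                        tau = lag_n + int(round(
                            d_trial[k] / (2 * np.pi * cpl.freq) * rate))
                        rot = np.roll(cp, tau)
                    contents[dst_reg][k, j0 + w0:j0 + w1] += (
                        cpl.strength * rot[w0:w1] * taper
                    )
        gt_couplings.append(
            {
                "regions": (reg_a, reg_b),
                "source_region": src_reg,
                "target_region": dst_reg,
                "freq": cpl.freq,
                "band": band,
                "periods": tuple(cpl.periods),
                "conditions": cpl.conditions,
                "kappa": cpl.kappa,
                "expected_plv": cpl.expected_plv,
                "direction": cpl.direction,
                "lag_s": cpl.lag_s,
                "deltas": np.array(deltas) if deltas else np.empty((0, n_dst)),
            }
        )

    # --- interictal spikes ----------------------------------------------
    # a spike contaminates a (trial, channel) epoch iff its waveform
    # overlaps one of the analysis windows (the jittered delay head and
    # tail are dropped from epochs and do not count)
    trial_windows = [
        list(period_windows(ev["onset"], ev["fixation_s"], ev["delay_s"],
                            kind="power").values())
        for _, ev in events.iterrows()
    ]
    spike_epochs: set[tuple[int, str]] = set()
    for region in regions:
        for k, name in enumerate(bipolar_names[region]):
            n_spikes = rng.poisson(cfg.spike_rate_per_min * n_times / rate / 60.0)
            for _ in range(n_spikes):
                t_spike = rng.uniform(0, n_times / rate - cfg.spike_duration_s)
                amp = rng.uniform(*cfg.spike_amp_sd) * cfg.background_scale
                w = _spike_waveform(rate, cfg.spike_duration_s, amp, rng)
                j = int(round(t_spike * rate))
                contents[region][k, j:j + len(w)] += w[: n_times - j]
                t_end = t_spike + cfg.spike_duration_s
                for ti, wins in enumerate(trial_windows):
                    if any(t_spike < w1 and t_end > w0 for w0, w1 in wins):
                        spike_epochs.add((int(ti), name))

    # --- contacts: cumulative sums + common mode ------------------------
    chan_rows, contact_signals = [], []
    for region in regions:
        n_ch = cfg.channels_per_region[region]
        shaft = REGION_SHAFTS.get(region, region[0])
        common = _one_over_f(rng, n_times, rate, cfg.background_exponent,
                             cfg.common_mode_scale)
        c = common.copy()
        for k in range(n_ch + 1):
            contact_signals.append(c.copy())
            chan_rows.append(
                {
                    "name": f"{shaft}{k + 1}",
                    "shaft": shaft,
                    "contact_index": k + 1,
                    "region": region,
                    "hemisphere": "R",
                    "status": "good",
                    "soz": 0,
                }
            )
            if k < n_ch:
                c = c + contents[region][k]
    channels = validate_channels(pd.DataFrame(chan_rows))
    rec = ContinuousRecording(
        samples=np.asarray(contact_signals),
        rate=rate,
        channels=channels,
        session_id=f"sim-{seed}",
    )
    gt = GroundTruth(
        bipolar_names=bipolar_names,
        band_effects=gt_effects,
        couplings=gt_couplings,
        spike_epochs=spike_epochs,
        gain_profiles=gain_profiles,
        rate=rate,
    )
    return rec, events, gt
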