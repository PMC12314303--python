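"""Canonical task-period timing shared by the simulator and all analyses.

A trial is fixation (jittered 1.9-2.1 s) -> encoding (2.0 s) -> delay
(jittered 3.9-4.1 s) -> action/recall (2.0 s), with a 2.0 s identity
question appended on 'different' trials only.  Event onsets are encoding
onsets, in seconds from session start.

Epochs run from -0.5 s to +7.8 s around encoding onset and are assembled
by concatenating fixed-length segments, dropping the jittered 0.0-0.2 s
head of the delay: baseline 0.5 s, encoding 2.0 s, delay1 1.9 s,
delay2 1.9 s, recall 2.0 s.  Connectivity stages use their own windows
(1.9 s fixation baseline, 0.5 s pre-response recall; Granger causality
trims encoding to 1.9 s and skips recall).
"""

from __future__ import annotations

__all__ = [
    "PERIOD_ORDER",
    "POWER_PERIODS",
    "PLV_PERIODS",
    "GC_PERIODS",
    "EPOCH_START",
    "EPOCH_END",
    "period_windows",
]

PERIOD_ORDER = ("baseline", "encoding", "delay1", "delay2", "recall")

#: Period durations (s) on the power-epoch grid.
POWER_PERIODS = {
    "baseline": 0.5,
    "encoding": 2.0,
    "delay1": 1.9,
    "delay2": 1.9,
    "recall": 2.0,
}

#: Window lengths used by the PLV stage.
PLV_PERIODS = {
    "baseline": 1.9,
    "encoding": 2.0,
    "delay1": 1.9,
    "delay2": 1.9,
    "recall": 0.5,
}

#: Windows used by spectral Granger causality (all 1.9 s; recall excluded).
GC_PERIODS = {
    "baseline": 1.9,
    "encoding": 1.9,
    "delay1": 1.9,
    "delay2": 1.9,
}

EPOCH_START = -0.5
EPOCH_END = 7.8

ENCODING_DUR = 2.0
ACTION_DUR = 2.0
DELAY_HEAD_SKIP = 0.2  # jittered head of the delay, dropped from epochs


def period_windows(onset: float, fixation_s: float, delay_s: float,
                   kind: str = "power") -> dict[str, tuple[float, float]]:
    """Absolute ``[t0, t1)`` windows of each task period for one trial.

    Parameters
    ----------
    onset
        Encoding onset in seconds from session start.
    fixation_s, delay_s
        Jittered fixation and delay durations of this trial.
    kind
        ``"power"`` (0.5 s baseline, 2.0 s recall), ``"plv"`` (1.9 s
        fixation baseline, 0.5 s pre-response recall) or ``"gc"``
        (1.9 s windows, no recall).
    """
    delay_on = onset + ENCODING_DUR
    action_on = delay_on + delay_s
    delay1 = (delay_on + DELAY_HEAD_SKIP, delay_on + DELAY_HEAD_SKIP + 1.9)
    delay2 = (delay1[1], delay1[1] + 1.9)
    if kind == "power":
        return {
            "baseline": (onset - 0.5, onset),
            "encoding": (onset, onset + ENCODING_DUR),
            "delay1": delay1,
            "delay2": delay2,
            "recall": (action_on, action_on + ACTION_DUR),
        }
    if kind == "plv":
        return {
            "baseline": (onset - 1.9, onset),
            "encoding": (onset, onset + ENCODING_DUR),
            "delay1": delay1,
            "delay2": delay2,
            "recall": (action_on, action_on + 0.5),
        }
    if kind == "gc":
        return {
            "baseline": (onset - 1.9, onset),
            "encoding": (onset, onset + 1.9),
            "delay1": delay1,
            "delay2": delay2,
        }
    raise ValueError(f"unknown window kind {kind!r}")
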