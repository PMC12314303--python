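"""Reference synthetic scenario mirroring the reported effect pattern.

The generated world contains the qualitative findings the pipeline is
designed to recover:

* alpha (8-13 Hz) envelope increase of +50 % in IPL and VTC during both
  delay halves, in both conditions;
* IPL-VTC phase coupling in the slow-theta range (4 Hz, kappa = 2)
  during encoding, delay and recall, with the VTC driving the IPL
  (50 ms lag) during the second half of the delay;
* HIP-IPL coupling with the hippocampus leading at 3 Hz during encoding
  and the IPL leading the hippocampus at 10 Hz during the delay, i.e.
  two opposite-sign net-GC peaks.
"""

from __future__ import annotations

from streamsync.synthetic_data import BandEffect, Coupling, SimulationConfig

__all__ = ["reference_scenario"]


def reference_scenario(n_trials_per_condition: int = 20,
                       channels_per_region: dict | None = None,
                       osc_amplitude: float = 25.0,
                       spike_rate_per_min: float = 1.0) -> SimulationConfig:
    """Scaled-down session emulating the reported effect structure.

    Defaults (20 trials per condition, 3/3/2 bipolar channels in
    IPL/VTC/HIP) keep an end-to-end run on one CPU in a few minutes; the
    full-size world uses 80 trials per condition.
    """
    channels = channels_per_region or {"IPL": 3, "VTC": 3, "HIP": 2}
    return SimulationConfig(
        n_trials_per_condition=n_trials_per_condition,
        block_size=10,
        channels_per_region=channels,
        band_effects=(
            BandEffect(region="IPL", band=(8, 13), periods=("delay1", "delay2"),
                       gain=1.5, amplitude=osc_amplitude),
            BandEffect(region="VTC", band=(8, 13), periods=("delay1", "delay2"),
                       gain=1.5, amplitude=osc_amplitude),
        ),
        couplings=(
            # slow-theta IPL-VTC coupling; VTC leads during delay2
            Coupling(regions=("IPL", "VTC"), freq=4.0,
                     periods=("encoding", "delay1", "recall"), kappa=2.0,
                     amplitude=osc_amplitude),
            Coupling(regions=("IPL", "VTC"), freq=4.0, periods=("delay2",),
                     kappa=6.0, direction="b->a", lag_s=0.05, bandwidth=2.0,
                     amplitude=osc_amplitude),
            # HIP leads IPL at 3 Hz during encoding
            Coupling(regions=("IPL", "HIP"), freq=3.0, periods=("encoding",),
                     kappa=6.0, direction="b->a", lag_s=0.05, bandwidth=2.0,
                     amplitude=osc_amplitude),
            # IPL leads HIP at 10 Hz during the delay; the transmitted
            # signal is the IPL's own (task-boosted) alpha-band content
            Coupling(regions=("IPL", "HIP"), freq=10.0,
                     periods=("delay1", "delay2"), kappa=6.0,
                     direction="a->b", lag_s=0.025, bandwidth=4.0,
                     amplitude=0.0),
        ),
        spike_rate_per_min=spike_rate_per_min,
    )
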