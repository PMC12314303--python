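"""Readers and writers for the formats the pipeline touches.

Signals travel as EDF (European Data Format, 16-bit), events and channel
metadata as tab-separated tables with BIDS-iEEG-flavoured column names,
and analysis parameters as a versioned YAML document.  All internal times
are seconds from session start (float64); sample indices are always
derived from times, never stored.

The EDF layer is deliberately minimal: uniform sampling rate across
channels, one-second data records, int16 samples.  That is the subset the
pipeline produces and consumes; anything else raises
:class:`UnsupportedFormatError`.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "UnsupportedFormatError",
    "SchemaError",
    "ConfigError",
    "ValidationWarning",
    "ContinuousRecording",
    "AnalysisConfig",
    "EVENT_COLUMNS",
    "CHANNEL_COLUMNS",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_channels",
    "write_channels",
    "load_config",
    "validate_events",
    "validate_channels",
]


class FormatError(ValueError):
    """File cannot be parsed as the expected format."""


class UnsupportedFormatError(FormatError):
    """Valid file, but outside the subset this pipeline supports."""


class SchemaError(ValueError):
    """Tabular file violates the documented schema."""


class ConfigError(ValueError):
    """Configuration file violates the versioned schema."""


class ValidationWarning(UserWarning):
    """Non-fatal deviation from documented value ranges."""


REGIONS = ("IPL", "VTC", "HIP", "OTHER")
CONDITIONS = ("same", "different")

#: Mandatory event-table columns.  ``trial_type`` holds the condition
#: (same/different); onsets and durations are seconds from session start.
EVENT_COLUMNS = [
    "onset",
    "trial_type",
    "block",
    "fixation_s",
    "encoding_s",
    "delay_s",
    "action_s",
    "question_s",
    "correct_position",
    "correct_identity",
]

#: Mandatory channel-table columns.  ``status`` is "good"/"bad";
#: ``soz`` flags seizure-onset-zone contacts (0/1).
CHANNEL_COLUMNS = [
    "name",
    "shaft",
    "contact_index",
    "region",
    "hemisphere",
    "status",
    "soz",
]

# Stated jitter ranges for the task; violations warn, they do not fail.
FIXATION_RANGE = (1.9, 2.1)
DELAY_RANGE = (3.9, 4.1)


@dataclass
class ContinuousRecording:
    """Multichannel continuous signal with channel metadata.

    Parameters
    ----------
    samples
        ``(n_channels, n_times)`` float array, microvolts.
    rate
        Sampling rate in Hz.
    channels
        Channel table (one row per row of ``samples``).
    session_id
        Free-text identifier written into file headers.
    """

    samples: np.ndarray
    rate: float
    channels: pd.DataFrame
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError(
                f"channel table has {len(self.channels)} rows for "
                f"{self.samples.shape[0]} signal channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.rate


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

# symmetric digital range so that 0 uV maps exactly to digital 0
_EDF_DIG_MIN, _EDF_DIG_MAX = -32767, 32767


def _fixed(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def write_recording(rec: ContinuousRecording, path: str | Path,
                    physical_range: tuple[float, float] | None = None) -> Path:
    """Write a recording as 16-bit EDF with one-second data records.

    The true sample count is stored in the header's reserved field
    (``NSAMP=<n>``) so that :func:`read_recording` can trim the zero
    padding of the final record.

    Parameters
    ----------
    physical_range
        Optional ``(min, max)`` physical calibration in microvolts shared
        by all channels.  Default: symmetric range covering the data.
    """
    path = Path(path)
    x = rec.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot write non-finite samples")
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise UnsupportedFormatError("EDF writer requires an integer sampling rate")
    rate = int(round(rate))

    n_ch, n_times = x.shape
    n_records = max(1, int(np.ceil(n_times / rate)))
    if physical_range is None:
        amp = float(np.max(np.abs(x))) if x.size else 0.0
        amp = max(amp, 1.0)
        phys_min, phys_max = -amp, amp
    else:
        phys_min, phys_max = map(float, physical_range)
        if phys_max <= phys_min:
            raise ValueError("physical_range must be (min, max) with max > min")

    scale = (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    offset = phys_min - _EDF_DIG_MIN * scale
    digital = np.round((x - offset) / scale)
    if digital.min() < _EDF_DIG_MIN or digital.max() > _EDF_DIG_MAX:
        raise ValueError("samples exceed the declared physical range")
    digital = digital.astype("<i2")
    pad = n_records * rate - n_times
    if pad:
        zero_dig = np.int16(round(-offset / scale))
        digital = np.hstack([digital, np.full((n_ch, pad), zero_dig, dtype="<i2")])

    header_bytes = 256 * (1 + n_ch)
    labels = [str(n) for n in rec.channels["name"]] if "name" in rec.channels else [
        f"ch{i}" for i in range(n_ch)
    ]

    with open(path, "wb") as fh:
        fh.write(_fixed("0", 8))
        fh.write(_fixed(rec.session_id, 80))
        fh.write(_fixed("streamsync", 80))
        fh.write(_fixed("01.01.00", 8))
        fh.write(_fixed("00.00.00", 8))
        fh.write(_fixed(str(header_bytes), 8))
        fh.write(_fixed(f"NSAMP={n_times}", 44))
        fh.write(_fixed(str(n_records), 8))
        fh.write(_fixed("1", 8))
        fh.write(_fixed(str(n_ch), 4))
        for lab in labels:
            fh.write(_fixed(lab, 16))
        for _ in range(n_ch):
            fh.write(_fixed("", 80))
        for _ in range(n_ch):
            fh.write(_fixed("uV", 8))
        for _ in range(n_ch):
            fh.write(_fixed(f"{phys_min:.8g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_fixed(f"{phys_max:.8g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_fixed(str(_EDF_DIG_MIN), 8))
        for _ in range(n_ch):
            fh.write(_fixed(str(_EDF_DIG_MAX), 8))
        for _ in range(n_ch):
            fh.write(_fixed("", 80))
        for _ in range(n_ch):
            fh.write(_fixed(str(rate), 8))
        for _ in range(n_ch):
            fh.write(_fixed("", 32))
        # data records: per record, all samples of signal 0, then signal 1, ...
        for r in range(n_records):
            fh.write(digital[:, r * rate:(r + 1) * rate].tobytes())
    return path


def _read_ascii(fh, width: int) -> str:
    return fh.read(width).decode("ascii", errors="replace").strip()


def read_recording(path: str | Path,
                   channels: pd.DataFrame | str | Path | None = None,
                   session_id: str | None = None) -> ContinuousRecording:
    """Read an EDF file into a :class:`ContinuousRecording`.

    All signals must share one sampling rate; mixed rates raise
    :class:`UnsupportedFormatError`.  Channel metadata comes from, in
    order of preference: the ``channels`` argument (table or TSV path), a
    sidecar ``<stem>_channels.tsv`` next to the file, or the EDF labels
    alone (region/shaft fields then default to OTHER).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        version = _read_ascii(fh, 8)
        if version != "0":
            raise FormatError(f"not an EDF file (version field {version!r})")
        patient = _read_ascii(fh, 80)
        _read_ascii(fh, 80)  # recording id
        _read_ascii(fh, 8)   # start date
        _read_ascii(fh, 8)   # start time
        try:
            header_bytes = int(_read_ascii(fh, 8))
        except ValueError as exc:
            raise FormatError("unreadable EDF header") from exc
        reserved = _read_ascii(fh, 44)
        try:
            n_records = int(_read_ascii(fh, 8))
            record_dur = float(_read_ascii(fh, 8))
            n_ch = int(_read_ascii(fh, 4))
        except ValueError as exc:
            raise FormatError("unreadable EDF header") from exc
        if header_bytes != 256 * (1 + n_ch):
            raise FormatError("EDF header length inconsistent with signal count")

        labels = [_read_ascii(fh, 16) for _ in range(n_ch)]
        _ = [fh.read(80) for _ in range(n_ch)]  # transducer
        _ = [fh.read(8) for _ in range(n_ch)]   # physical dimension
        try:
            phys_min = np.array([float(_read_ascii(fh, 8)) for _ in range(n_ch)])
            phys_max = np.array([float(_read_ascii(fh, 8)) for _ in range(n_ch)])
            dig_min = np.array([float(_read_ascii(fh, 8)) for _ in range(n_ch)])
            dig_max = np.array([float(_read_ascii(fh, 8)) for _ in range(n_ch)])
        except ValueError as exc:
            raise FormatError("unreadable EDF signal calibration") from exc
        _ = [fh.read(80) for _ in range(n_ch)]  # prefiltering
        try:
            samples_per_record = [int(_read_ascii(fh, 8)) for _ in range(n_ch)]
        except ValueError as exc:
            raise FormatError("unreadable samples-per-record field") from exc
        _ = [fh.read(32) for _ in range(n_ch)]

        if len(set(samples_per_record)) != 1:
            raise UnsupportedFormatError(
                "mixed sampling rates across EDF signals are not supported"
            )
        spr = samples_per_record[0]
        rate = spr / record_dur
        if abs(rate - round(rate)) > 1e-6:
            raise UnsupportedFormatError("non-integer sampling rate")
        rate = int(round(rate))

        raw = np.frombuffer(fh.read(n_records * n_ch * spr * 2), dtype="<i2")
    if raw.size != n_records * n_ch * spr:
        raise FormatError("EDF data section truncated")
    digital = raw.reshape(n_records, n_ch, spr).transpose(1, 0, 2).reshape(n_ch, -1)

    scale = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - dig_min * scale
    x = digital.astype(np.float64) * scale[:, None] + offset[:, None]

    if reserved.startswith("NSAMP="):
        n_times = int(reserved.split("=", 1)[1])
        x = x[:, :n_times]

    if isinstance(channels, (str, Path)):
        chan_df = read_channels(channels)
    elif isinstance(channels, pd.DataFrame):
        chan_df = validate_channels(channels)
    else:
        sidecar = path.with_name(path.stem + "_channels.tsv")
        if sidecar.exists():
            chan_df = read_channels(sidecar)
        else:
            chan_df = pd.DataFrame(
                {
                    "name": labels,
                    "shaft": ["" for _ in labels],
                    "contact_index": np.arange(1, n_ch + 1),
                    "region": ["OTHER"] * n_ch,
                    "hemisphere": ["L"] * n_ch,
                    "status": ["good"] * n_ch,
                    "soz": [0] * n_ch,
                }
            )
    if len(chan_df) != n_ch:
        raise SchemaError(
            f"channel table has {len(chan_df)} rows but EDF has {n_ch} signals"
        )
    if not np.all(np.isfinite(x)):
        raise FormatError("decoded samples contain non-finite values")
    return ContinuousRecording(
        samples=x, rate=float(rate), channels=chan_df.reset_index(drop=True),
        session_id=session_id or patient or path.stem,
    )


# ---------------------------------------------------------------------------
# Event / channel tables (TSV)
# ---------------------------------------------------------------------------

def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table; raises :class:`SchemaError` with row numbers."""
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"events table missing mandatory columns: {missing}")
    df = df.copy()
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        rows = np.nonzero(np.diff(onsets) <= 0)[0] + 1
        raise SchemaError(f"event onsets not strictly increasing at rows {rows.tolist()}")
    bad_cond = ~df["trial_type"].isin(CONDITIONS)
    if bad_cond.any():
        raise SchemaError(
            f"unknown trial_type at rows {df.index[bad_cond].tolist()}"
        )
    for col, (lo, hi) in (("fixation_s", FIXATION_RANGE), ("delay_s", DELAY_RANGE)):
        vals = df[col].to_numpy(dtype=float)
        out = (vals < lo - 1e-9) | (vals > hi + 1e-9)
        if out.any():
            warnings.warn(
                f"{col} outside [{lo}, {hi}] at rows {df.index[out].tolist()}",
                ValidationWarning,
                stacklevel=2,
            )
    # question phase exists only for 'different' trials
    has_q = df["question_s"].notna() & (df["question_s"].astype(float) > 0)
    mism = has_q != (df["trial_type"] == "different")
    if mism.any():
        raise SchemaError(
            "question_s present iff trial_type='different' violated at rows "
            f"{df.index[mism].tolist()}"
        )
    return df


def validate_channels(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CHANNEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"channel table missing mandatory columns: {missing}")
    df = df.copy()
    dup = df["name"].duplicated()
    if dup.any():
        raise SchemaError(f"duplicate channel names at rows {df.index[dup].tolist()}")
    bad_region = ~df["region"].isin(REGIONS)
    if bad_region.any():
        raise SchemaError(f"unknown region at rows {df.index[bad_region].tolist()}")
    for shaft, grp in df.groupby("shaft", sort=False):
        idx = grp["contact_index"].to_numpy(dtype=int)
        if np.any(np.diff(idx) <= 0):
            raise SchemaError(
                f"contact_index not strictly increasing within shaft {shaft!r}"
            )
    return df


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate an events TSV."""
    df = pd.read_csv(path, sep="\t")
    return validate_events(df)


def write_events(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_events(df).to_csv(path, sep="\t", index=False)
    return path


def read_channels(path: str | Path) -> pd.DataFrame:
    """Read and validate a channels TSV."""
    df = pd.read_csv(path, sep="\t")
    return validate_channels(df)


def write_channels(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_channels(df).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

CONFIG_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """Pipeline parameters with the published defaults.

    Frequencies must stay below the Nyquist rate of the stage they apply
    to (64 Hz envelope grid for band power, 40 Hz signals for Granger
    causality).
    """

    schema_version: int = CONFIG_SCHEMA_VERSION
    bands: dict = field(default_factory=lambda: {"theta": (2.0, 7.0), "alpha": (8.0, 13.0)})
    envelope_rate: float = 64.0
    envelope_f_lo: float = 2.0
    envelope_f_hi: float = 120.0
    gc_rate: float = 40.0
    n_permutations: int = 200
    alpha_point: float = 0.05
    alpha_cluster: float = 0.05
    fdr_q: float = 0.05
    notch_order: int = 4
    bandpass_order: int = 3
    spike_amp_sd: float = 6.0
    spike_diff_sd: float = 8.0
    region_pairs: tuple = (("IPL", "VTC"), ("IPL", "HIP"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        for name, (lo, hi) in dict(self.bands).items():
            if not (0 < lo < hi):
                raise ConfigError(f"band {name!r} has invalid range ({lo}, {hi})")
            if hi > self.envelope_rate / 2:
                raise ConfigError(
                    f"band {name!r} upper edge {hi} Hz exceeds the Nyquist "
                    f"frequency of the {self.envelope_rate} Hz envelope grid"
                )


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a YAML configuration; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported config schema_version {version} "
            f"(expected {CONFIG_SCHEMA_VERSION})"
        )
    known = set(AnalysisConfig.__dataclass_fields__) - {"schema_version"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "bands" in raw:
        raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
    if "region_pairs" in raw:
        raw["region_pairs"] = tuple(tuple(p) for p in raw["region_pairs"])
    return AnalysisConfig(schema_version=version, **raw)
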