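"""End-to-end orchestration: session preprocessing through cohort models.

A *session* is one patient's recording plus events.  The cohort level
pools pair-significance masks across patients for the Sig.P.Ratio band
selection, aggregates net-GC spectra for the peak-band selection, and
fits the period x condition mixed models on the pooled summary tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from streamsync import bandpower, granger, lmm_stats, plv as plv_mod, preprocess
from streamsync.io_core import AnalysisConfig, ContinuousRecording
from streamsync.task import GC_PERIODS, PLV_PERIODS

__all__ = [
    "SessionResult",
    "CohortResult",
    "preprocess_session",
    "run_power_stage",
    "run_plv_stage",
    "run_gc_stage",
    "run_session",
    "run_cohort",
]

TASK_PERIODS_PLV = ("encoding", "delay1", "delay2", "recall")


@dataclass
class SessionResult:
    """Per-session artifacts consumed by the cohort level."""

    session_id: str
    bipolar: ContinuousRecording
    events: pd.DataFrame
    exclusion_mask: np.ndarray  # trials x bipolar channels
    active_reports: dict = field(default_factory=dict)
    power_tables: dict = field(default_factory=dict)
    plv_spectra: dict = field(default_factory=dict)  # period -> TrialSpectra
    pairs: dict = field(default_factory=dict)  # region pair -> list of pair info
    gc_spectra: dict = field(default_factory=dict)  # region pair -> [GCSpectrum]


@dataclass
class CohortResult:
    sessions: list
    power_table: pd.DataFrame
    active_summary: pd.DataFrame
    sig_pair_ratios: dict
    plv_tables: dict  # (region pair, range) -> DataFrame
    gc_ranges: dict  # region pair -> selected ranges
    netgc_tables: dict  # region pair -> DataFrame
    lmm_fits: dict = field(default_factory=dict)


def preprocess_session(rec: ContinuousRecording, events: pd.DataFrame,
                       config: AnalysisConfig):
    """Notch -> bipolar -> raw epochs -> spike/behaviour exclusion masks."""
    clean = preprocess.notch_filter(rec, order=config.notch_order)
    bip = preprocess.bipolar_rereference(clean)
    raw_epochs = preprocess.epoch(bip, events)
    spike_mask = preprocess.flag_spike_epochs(
        raw_epochs, amp_sd=config.spike_amp_sd, diff_sd=config.spike_diff_sd
    )
    raw_epochs.add_exclusions(spike_mask, "spike")
    incorrect = preprocess.exclude_incorrect(raw_epochs, events)
    raw_epochs.add_exclusions(incorrect, "incorrect")
    return bip, raw_epochs.exclusion_mask


def run_power_stage(bip: ContinuousRecording, events: pd.DataFrame,
                    exclusion_mask: np.ndarray, config: AnalysisConfig,
                    f_hi: float | None = None):
    """Envelopes, active-channel detection and period means per band."""
    needed = max(hi for _, hi in config.bands.values())
    f_hi = f_hi if f_hi is not None else max(config.envelope_f_hi, needed)
    env = bandpower.filter_hilbert_envelope(
        bip, f_lo=config.envelope_f_lo, f_hi=f_hi,
        env_rate=config.envelope_rate, order=config.bandpass_order,
    )
    reports, tables, env_sets = {}, {}, {}
    for band in config.bands:
        es = bandpower.aggregate_band(env, band, events)
        es.epochs.add_exclusions(exclusion_mask, "carried")
        env_sets[band] = es
        active = set()
        for cond in ("same", "different"):
            rep = bandpower.detect_active_channels(es, cond, q=config.fdr_q)
            reports[(band, cond)] = rep
            active |= set(rep.active_channels)
        tables[band] = bandpower.average_task_periods(es, sorted(active))
    return env_sets, reports, tables


def _region_pairs(channels: pd.DataFrame, region_pairs) -> dict:
    """Within-hemisphere cross-region channel-index pairs, region-ordered."""
    out = {}
    for ra, rb in region_pairs:
        pairs = []
        for i, rowa in channels.iterrows():
            if rowa["region"] != ra:
                continue
            for j, rowb in channels.iterrows():
                if rowb["region"] != rb:
                    continue
                if rowa["hemisphere"] != rowb["hemisphere"]:
                    continue
                pairs.append(
                    {
                        "idx": (i, j),
                        "label": f"{rowa['name']}|{rowb['name']}",
                        "regions": (ra, rb),
                    }
                )
        out[(ra, rb)] = pairs
    return out


def run_plv_stage(bip: ContinuousRecording, events: pd.DataFrame,
                  exclusion_mask: np.ndarray, config: AnalysisConfig,
                  seed: int = 0):
    """Trial spectra, per-pair permutation tests, per-pair frequency masks."""
    segments = preprocess.extract_period_segments(bip, events, kind="plv")
    names = list(bip.channels["name"])
    spectra = {
        p: plv_mod.multitaper_spectra(segments[p], bip.rate, p,
                                      channel_names=names)
        for p in PLV_PERIODS
    }
    pairs = _region_pairs(bip.channels.reset_index(drop=True),
                          config.region_pairs)
    rng = np.random.default_rng(seed)
    for rp, plist in pairs.items():
        for info in plist:
            i, j = info["idx"]
            valid = ~exclusion_mask[:, i] & ~exclusion_mask[:, j]
            info["trial_mask"] = valid
            freq_mask = np.zeros(len(plv_mod.PLV_FREQS), dtype=bool)
            per_period = {}
            pair_seed = int(rng.integers(2**31 - 1))
            for period in TASK_PERIODS_PLV:
                res = plv_mod.permutation_plv_test(
                    spectra[period], spectra["baseline"], (i, j),
                    n_perm=config.n_permutations, seed=pair_seed,
                    alpha_point=config.alpha_point,
                    alpha_cluster=config.alpha_cluster, trials=valid,
                )
                per_period[period] = res
                freq_mask |= res.sig_mask
            info["freq_mask"] = freq_mask
            info["significant"] = bool(freq_mask.any())
            info["period_results"] = per_period
    return spectra, pairs


def run_gc_stage(bip: ContinuousRecording, events: pd.DataFrame,
                 pairs: dict, config: AnalysisConfig,
                 min_trials: int = 10):
    """Spectral GC for PLV-significant pairs, per period and condition."""
    segments = preprocess.extract_period_segments(bip, events, kind="gc")
    seg40 = granger.downsample_for_gc(segments, bip.rate, config.gc_rate)
    conditions = events["trial_type"].to_numpy()
    out = {}
    for rp, plist in pairs.items():
        spectra = []
        for info in plist:
            if not info.get("significant"):
                continue
            i, j = info["idx"]
            for period in GC_PERIODS:
                for cond in ("same", "different"):
                    keep = (conditions == cond) & info["trial_mask"]
                    if keep.sum() < min_trials:
                        warnings.warn(
                            f"pair {info['label']} {period}/{cond}: "
                            f"{int(keep.sum())} trials < {min_trials}; skipped",
                            stacklevel=2,
                        )
                        continue
                    seg = seg40[period][keep][:, (i, j), :]
                    csd = granger.compute_csd(
                        seg, rate=config.gc_rate, pair=info["label"].split("|"),
                        period=period, condition=cond, min_trials=min_trials,
                    )
                    fact = granger.wilson_factorize(csd)
                    spectra.append(
                        granger.spectral_gc(fact, pair=tuple(
                            info["label"].split("|")), period=period,
                            condition=cond)
                    )
        out[rp] = spectra
    return out


def run_session(rec: ContinuousRecording, events: pd.DataFrame,
                config: AnalysisConfig, seed: int = 0,
                envelope_f_hi: float | None = None) -> SessionResult:
    """Run preprocessing, power, PLV and GC stages for one session."""
    bip, excl = preprocess_session(rec, events, config)
    env_sets, reports, tables = run_power_stage(
        bip, events, excl, config, f_hi=envelope_f_hi
    )
    spectra, pairs = run_plv_stage(bip, events, excl, config, seed=seed)
    gc = run_gc_stage(bip, events, pairs, config)
    return SessionResult(
        session_id=rec.session_id, bipolar=bip, events=events,
        exclusion_mask=excl, active_reports=reports, power_tables=tables,
        plv_spectra=spectra, pairs=pairs, gc_spectra=gc,
    )


def run_cohort(sessions: list, config: AnalysisConfig,
               fit_models: bool = True) -> CohortResult:
    """Pool session results, select bands, build tables, fit mixed models.

    ``sessions`` is a list of (patient_id, SessionResult).
    """
    # --- power ----------------------------------------------------------
    power_rows, active_rows = [], []
    for pid, s in sessions:
        for band, tab in s.power_tables.items():
            t = tab.copy()
            t["patient"] = pid
            power_rows.append(t)
        for (band, cond), rep in s.active_reports.items():
            t = rep.table.copy()
            t["patient"] = pid
            active_rows.append(t)
    power_table = (pd.concat(power_rows, ignore_index=True)
                   if power_rows else pd.DataFrame())
    active_summary = (pd.concat(active_rows, ignore_index=True)
                      if active_rows else pd.DataFrame())

    # --- PLV band selection (pooled across patients) ---------------------
    sig_ratios, plv_tables = {}, {}
    for rp in config.region_pairs:
        rp = tuple(rp)
        masks, owners = [], []
        for pid, s in sessions:
            for info in s.pairs.get(rp, []):
                masks.append(info["freq_mask"])
                owners.append((pid, s, info))
        if not masks:
            continue
        spr = plv_mod.sig_pair_ratio(np.asarray(masks), region_pair=rp,
                                     alpha=config.alpha_point)
        sig_ratios[rp] = spr
        for rng_ in spr.selected_ranges:
            rows = []
            for pid, s, info in owners:
                if not info["significant"]:
                    continue
                tab = plv_mod.average_plv_periods(
                    s.plv_spectra, [info["idx"]], rng_,
                    s.events["trial_type"].to_numpy(),
                    trial_masks={0: info["trial_mask"]},
                    pair_labels=[info["label"]],
                )
                tab["patient"] = pid
                rows.append(tab)
            if rows:
                plv_tables[(rp, rng_)] = pd.concat(rows, ignore_index=True)

    # --- net-GC band selection (pooled) ----------------------------------
    gc_ranges, netgc_tables = {}, {}
    for rp in config.region_pairs:
        rp = tuple(rp)
        all_spectra = []
        for pid, s in sessions:
            for gc in s.gc_spectra.get(rp, []):
                all_spectra.append((pid, gc))
        if not all_spectra:
            continue
        freqs = all_spectra[0][1].freqs
        net_mean = np.mean([gc.net for _, gc in all_spectra], axis=0)
        ranges = granger.select_peak_band(net_mean, freqs)
        gc_ranges[rp] = ranges
        if ranges:
            rows = []
            for pid, gc in all_spectra:
                t = granger.average_netgc_periods([gc], ranges)
                t["patient"] = pid
                rows.append(t)
            netgc_tables[rp] = pd.concat(rows, ignore_index=True)

    result = CohortResult(
        sessions=sessions, power_table=power_table,
        active_summary=active_summary, sig_pair_ratios=sig_ratios,
        plv_tables=plv_tables, gc_ranges=gc_ranges, netgc_tables=netgc_tables,
    )

    if not fit_models:
        return result

    n_patients = len({pid for pid, _ in sessions})
    if n_patients >= 2:
        for (band), grp in (power_table.groupby(["region", "band"])
                            if len(power_table) else []):
            tab = grp.rename(columns={"channel": "unit"})
            if tab["patient"].nunique() < 2:
                continue
            try:
                result.lmm_fits[("power",) + tuple(band)] = \
                    lmm_stats.fit_period_condition_lmm(tab, "power")
            except ValueError:
                pass
        for key, tab in plv_tables.items():
            t = tab.rename(columns={"pair_id": "unit"})
            if t["patient"].nunique() < 2:
                continue
            try:
                result.lmm_fits[("plv",) + (key,)] = \
                    lmm_stats.fit_period_condition_lmm(t, "plv")
            except ValueError:
                pass
        for rp, tab in netgc_tables.items():
            t = tab.rename(columns={"pair_id": "unit"})
            if t["patient"].nunique() < 2:
                continue
            try:
                result.lmm_fits[("netgc", rp)] = \
                    lmm_stats.fit_period_condition_lmm(t, "netgc")
            except ValueError:
                pass
    return result
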