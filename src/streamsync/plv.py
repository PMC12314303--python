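"""Phase-locking value (PLV) connectivity with permutation/cluster statistics.

Per task period, per-trial Fourier coefficients are computed with a
two-taper DPSS multitaper transform on the 2-20 Hz grid (1 Hz steps).
The PLV between channels i and j is

    PLV_ij(f) = | mean_n  X_i(f) X_j(f)* / (|X_i(f)| |X_j(f)|) |

with tapers pooled as additional observations inside the trial mean.
Task-vs-baseline differences are tested with a label-swap permutation
null (200 permutations), a per-frequency 95th-percentile point threshold
and cluster-mass correction across the 2-20 Hz range.  The fraction of
significant pairs per 1 Hz bin (Sig.P.Ratio) is tested against the
median ratio across bins with one-sided binomial tests (FDR-corrected)
to select the coupled frequency ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import windows
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TrialSpectra",
    "PairPermutationResult",
    "SigPairRatio",
    "multitaper_spectra",
    "compute_plv",
    "permutation_plv_test",
    "sig_pair_ratio",
    "average_plv_periods",
]

PLV_FREQS = np.arange(2.0, 21.0)  # 2..20 Hz inclusive, 1 Hz steps


@dataclass
class TrialSpectra:
    """Per-trial multitaper Fourier coefficients for one task period.

    ``coefficients`` is complex ``(trials, tapers, channels, freqs)`` on
    the 2-20 Hz 1 Hz grid.  ``unreliable`` flags frequencies below one
    cycle per window (still computed).
    """

    coefficients: np.ndarray
    freqs: np.ndarray
    period: str
    window_s: float
    channel_names: list
    unreliable: np.ndarray = None

    def __post_init__(self) -> None:
        if self.unreliable is None:
            self.unreliable = self.freqs < 1.0 / self.window_s


def multitaper_spectra(segments: np.ndarray, rate: float, period: str,
                       channel_names: list | None = None,
                       freqs: np.ndarray = PLV_FREQS,
                       n_tapers: int = 2, nw: float = 1.5) -> TrialSpectra:
    """Two-taper DPSS Fourier coefficients on an exact integer-Hz grid.

    ``segments`` is (trials x channels x samples).  Windows are
    zero-padded to the next whole second so the FFT grid contains every
    integer frequency exactly.
    """
    x = np.asarray(segments, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("segments must be trials x channels x time")
    n = x.shape[2]
    window_s = n / rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("integer sampling rate required")
    n_fft = int(round(rate)) * int(np.ceil(n / rate))
    df = rate / n_fft
    idx = np.round(freqs / df).astype(int)
    if not np.allclose(idx * df, freqs, atol=1e-9):
        raise ValueError("frequency grid not representable at this rate")

    tapers = windows.dpss(n, nw, Kmax=n_tapers)  # (tapers, n)
    tapered = x[:, None, :, :] * tapers[None, :, None, :]
    spec = np.fft.rfft(tapered, n=n_fft, axis=-1)[..., idx]
    names = channel_names if channel_names is not None else [
        f"ch{i}" for i in range(x.shape[1])
    ]
    return TrialSpectra(coefficients=spec, freqs=np.asarray(freqs, float),
                        period=period, window_s=window_s, channel_names=names)


def _unit_cross(spec: TrialSpectra, pair: tuple[int, int],
                trials: np.ndarray | None = None) -> np.ndarray:
    """Unit-modulus cross-spectral terms (trials, tapers, freqs).

    Entries with a zero-magnitude coefficient are NaN (excluded from the
    mean with count adjustment downstream).
    """
    i, j = pair
    xi = spec.coefficients[:, :, i, :]
    xj = spec.coefficients[:, :, j, :]
    if trials is not None:
        xi, xj = xi[trials], xj[trials]
    mag = np.abs(xi) * np.abs(xj)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(mag > 0, xi * np.conj(xj) / np.where(mag > 0, mag, 1.0),
                     np.nan + 0j)
    return r


def _resultant(r: np.ndarray, axis=None) -> np.ndarray:
    """|mean| of unit phasors ignoring NaN entries."""
    valid = ~np.isnan(r)
    total = np.where(valid, r, 0).sum(axis=axis)
    count = valid.sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.abs(total) / count
    return np.where(count > 0, out, np.nan)


def compute_plv(spec: TrialSpectra, pair: tuple[int, int],
                trials: np.ndarray | None = None) -> np.ndarray:
    """PLV(f) for a channel pair, pooling tapers as observations."""
    r = _unit_cross(spec, pair, trials)
    if r.shape[0] < 2:
        raise ValueError("PLV requires at least 2 trials")
    return _resultant(r, axis=(0, 1))


def _clusters(mask: np.ndarray) -> list[slice]:
    """Maximal runs of True as slices."""
    out, start = [], None
    for k, m in enumerate(mask):
        if m and start is None:
            start = k
        elif not m and start is not None:
            out.append(slice(start, k))
            start = None
    if start is not None:
        out.append(slice(start, len(mask)))
    return out


def _max_cluster_mass(values: np.ndarray, thresh: np.ndarray) -> np.ndarray:
    """Per row: largest suprathreshold-cluster mass (0 if none)."""
    supra = values > thresh
    n_rows = values.shape[0]
    out = np.zeros(n_rows)
    for row in range(n_rows):
        best = 0.0
        for cl in _clusters(supra[row]):
            best = max(best, float(values[row, cl].sum()))
        out[row] = best
    return out


@dataclass
class PairPermutationResult:
    """Permutation/cluster outcome of one (pair, period) comparison."""

    pair: tuple
    period: str
    freqs: np.ndarray
    observed_dplv: np.ndarray
    point_threshold: np.ndarray  # 95th percentile of the null per frequency
    sig_mask: np.ndarray  # frequency bins inside surviving clusters
    clusters: list  # (slice, mass, p) of suprathreshold clusters
    n_perm: int
    seed: int


def permutation_plv_test(task_spec: TrialSpectra, baseline_spec: TrialSpectra,
                         pair: tuple[int, int], n_perm: int = 200,
                         seed: int = 0, alpha_point: float = 0.05,
                         alpha_cluster: float = 0.05,
                         trials: np.ndarray | None = None) -> PairPermutationResult:
    """Cluster-corrected permutation test of task-vs-baseline PLV increase.

    The null swaps each trial's baseline and task segments at random
    (preserving the within-trial pairing and any frequency-dependent
    smoothness bias), recomputing Delta-PLV ``n_perm`` times.  Bins above
    the per-frequency 95th percentile of the null form clusters whose
    mass (sum of Delta-PLV) is compared with the permutation distribution
    of the maximal cluster mass at ``alpha_cluster``.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 leaves the 95th percentile undefined")
    r_task = _unit_cross(task_spec, pair, trials)
    r_base = _unit_cross(baseline_spec, pair, trials)
    if r_task.shape[0] != r_base.shape[0]:
        raise ValueError("task and baseline spectra must pair the same trials")
    n_trials, n_tapers, n_freq = r_task.shape
    if n_trials < 2:
        raise ValueError("need at least 2 trials")

    t_sum = np.nansum(r_task, axis=(0, 1))
    b_sum = np.nansum(r_base, axis=(0, 1))
    n_obs_t = (~np.isnan(r_task)).sum(axis=(0, 1))
    n_obs_b = (~np.isnan(r_base)).sum(axis=(0, 1))
    observed = np.abs(t_sum) / np.maximum(n_obs_t, 1) \
        - np.abs(b_sum) / np.maximum(n_obs_b, 1)

    # per-trial taper-summed difference terms; a swap of trial n moves
    # d[n] out of the task sum and into the baseline sum
    d = np.nansum(r_task, axis=1) - np.nansum(r_base, axis=1)  # (trials, freqs)
    rng = np.random.default_rng(seed)
    swaps = rng.integers(0, 2, size=(n_perm, n_trials)).astype(float)
    moved = swaps @ d  # (n_perm, freqs)
    null = (
        np.abs(t_sum[None, :] - moved) / np.maximum(n_obs_t, 1)[None, :]
        - np.abs(b_sum[None, :] + moved) / np.maximum(n_obs_b, 1)[None, :]
    )

    point_thr = np.quantile(null, 1.0 - alpha_point, axis=0)
    null_max_mass = _max_cluster_mass(null, point_thr[None, :])

    clusters = []
    sig_mask = np.zeros(n_freq, dtype=bool)
    for cl in _clusters(observed > point_thr):
        mass = float(observed[cl].sum())
        p = (1.0 + np.sum(null_max_mass >= mass)) / (1.0 + n_perm)
        clusters.append((cl, mass, p))
        if p <= alpha_cluster:
            sig_mask[cl] = True

    return PairPermutationResult(
        pair=pair, period=task_spec.period, freqs=task_spec.freqs,
        observed_dplv=observed, point_threshold=point_thr,
        sig_mask=sig_mask, clusters=clusters, n_perm=n_perm, seed=seed,
    )


@dataclass
class SigPairRatio:
    """Ratio of significant pairs per 1 Hz bin and the selected ranges."""

    region_pair: tuple
    freqs: np.ndarray
    n_significant: np.ndarray
    n_total: int
    ratio: np.ndarray
    median_ratio: float
    pvalues: np.ndarray  # FDR-corrected one-sided binomial p per bin
    sig_bins: np.ndarray
    selected_ranges: list  # (f_lo, f_hi) inclusive bin edges


def sig_pair_ratio(pair_masks: np.ndarray, freqs: np.ndarray = PLV_FREQS,
                   region_pair: tuple = ("", ""),
                   alpha: float = 0.05) -> SigPairRatio:
    """Binomial selection of frequency bins with above-chance pair ratios.

    ``pair_masks`` is (n_pairs x n_freqs) boolean: pair significant at
    that bin in any task period.  Each bin's count of significant pairs
    is tested one-sided against the median ratio across bins (the chance
    level), with Benjamini-Hochberg correction across bins.  Selected
    ranges are maximal runs of significant bins.
    """
    masks = np.asarray(pair_masks, dtype=bool)
    if masks.ndim != 2 or masks.shape[1] != len(freqs):
        raise ValueError("pair_masks must be n_pairs x n_freqs")
    n_total = masks.shape[0]
    if n_total == 0:
        raise ValueError("no channel pairs analyzed")
    n_sig = masks.sum(axis=0)
    ratio = n_sig / n_total
    p0 = float(np.median(ratio))
    pvals = np.array([
        stats.binomtest(int(k), n_total, min(max(p0, 0.0), 1.0),
                        alternative="greater").pvalue
        for k in n_sig
    ])
    rej, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    ranges = [(float(freqs[cl.start]), float(freqs[cl.stop - 1]))
              for cl in _clusters(rej)]
    return SigPairRatio(
        region_pair=tuple(region_pair), freqs=np.asarray(freqs, float),
        n_significant=n_sig, n_total=n_total, ratio=ratio, median_ratio=p0,
        pvalues=p_adj, sig_bins=rej, selected_ranges=ranges,
    )


def average_plv_periods(spectra_by_period: dict, pairs: list,
                        selected_range: tuple, conditions: np.ndarray,
                        trial_masks: dict | None = None,
                        pair_labels: list | None = None) -> pd.DataFrame:
    """Mean PLV over a selected frequency range per (pair, period, condition).

    ``spectra_by_period`` maps period name to :class:`TrialSpectra`;
    ``trial_masks`` optionally maps pair index to a per-trial validity
    mask.  One row per pair x condition x period, ready for the
    mixed-model stage.
    """
    lo, hi = selected_range
    rows = []
    for k, pair in enumerate(pairs):
        label = pair_labels[k] if pair_labels else f"{pair[0]}-{pair[1]}"
        base_mask = trial_masks.get(k) if trial_masks else None
        for period, spec in spectra_by_period.items():
            bins = (spec.freqs >= lo) & (spec.freqs <= hi)
            for cond in ("same", "different"):
                keep = conditions == cond
                if base_mask is not None:
                    keep = keep & base_mask
                if keep.sum() < 2:
                    continue
                plv = compute_plv(spec, pair, trials=keep)
                rows.append(
                    {
                        "pair_id": label,
                        "range": f"{lo:g}-{hi:g}Hz",
                        "period": period,
                        "condition": cond,
                        "mean_plv": float(np.nanmean(plv[bins])),
                        "n_trials": int(keep.sum()),
                    }
                )
    return pd.DataFrame(rows)
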