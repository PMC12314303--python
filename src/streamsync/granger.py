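"""Non-parametric spectral Granger causality via Wilson factorization.

Signals are decimated to 40 Hz, per-period 1.9 s windows are transformed
with a two-taper multitaper FFT zero-padded to 20 s (0.05 Hz grid), and
the trial/taper-averaged 2x2 cross-spectral density matrix S(f) is
factorized with Wilson's iterative algorithm into a minimum-phase
transfer function and innovation covariance, S(f) = H(f) Sigma H*(f).
The directed spectral measure from Y to X is

    GC_{Y->X}(f) = ln( S_xx(f) / Stilde_xx(f) )

where Stilde_xx is X's intrinsic power once Y's innovations are
partialled out:  Stilde_xx = S_xx - (Sigma_yy - Sigma_xy^2/Sigma_xx) |H_xy|^2.
The net measure Delta-GC = GC_{Y->X} - GC_{X->Y} is aggregated across
pairs/periods/conditions to pick the peak frequency ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "GC_RATE",
    "CSDMatrix",
    "SpectralFactorization",
    "GCSpectrum",
    "downsample_for_gc",
    "sine_tapers",
    "compute_csd",
    "wilson_factorize",
    "spectral_gc",
    "select_peak_band",
    "average_netgc_periods",
]

GC_RATE = 40.0
GC_PAD_S = 20.0  # zero-padding target -> 0.05 Hz frequency grid
GC_WINDOW_S = 1.9


def downsample_for_gc(segments, rate: float, gc_rate: float = GC_RATE):
    """Anti-aliased decimation of per-period segments to the GC rate.

    ``segments`` is either a single (trials x channels x time) array or a
    dict of them per period.  Output lengths are trimmed to
    ``round(duration * gc_rate)`` samples so period boundaries stay exact
    in seconds (1.9 s -> 76 samples at 40 Hz).
    """
    if isinstance(segments, dict):
        return {k: downsample_for_gc(v, rate, gc_rate) for k, v in segments.items()}
    x = np.asarray(segments, dtype=np.float64)
    frac = gc_rate / rate
    from fractions import Fraction

    f = Fraction(frac).limit_denominator(10000)
    y = signal.resample_poly(x, up=f.numerator, down=f.denominator, axis=-1)
    n_target = int(round(x.shape[-1] / rate * gc_rate))
    return y[..., :n_target]


def sine_tapers(n: int, k: int = 2) -> np.ndarray:
    """Orthonormal sine-taper family (k tapers of length n)."""
    t = np.arange(1, n + 1)
    return np.stack([
        np.sqrt(2.0 / (n + 1)) * np.sin(np.pi * (j + 1) * t / (n + 1))
        for j in range(k)
    ])


@dataclass
class CSDMatrix:
    """Trial/taper-averaged 2x2 cross-spectral density on a 0.05 Hz grid."""

    S: np.ndarray  # (freqs, 2, 2) complex, Hermitian
    freqs: np.ndarray
    n_trials: int
    n_tapers: int
    pair: tuple = ("x", "y")
    period: str = ""
    condition: str = ""


def compute_csd(segments: np.ndarray, rate: float = GC_RATE,
                pair: tuple = ("x", "y"), period: str = "",
                condition: str = "", n_tapers: int = 2,
                min_trials: int = 10,
                window_s: float = GC_WINDOW_S) -> CSDMatrix:
    """Multitaper CSD of a channel pair from (trials x 2 x time) segments.

    Uses two orthonormal sine (Hann-family) tapers and zero-padding to
    20 s.  Windows that are not ``window_s`` long are refused — the
    recall period is too short for reliable spectral estimation.
    """
    x = np.asarray(segments, dtype=np.float64)
    if x.ndim != 3 or x.shape[1] != 2:
        raise ValueError("segments must be trials x 2 x time")
    n = x.shape[2]
    if abs(n / rate - window_s) > 0.5 / rate:
        raise ValueError(
            f"GC windows must be {window_s} s long (got {n / rate:.3f} s); "
            "shorter periods such as recall are excluded"
        )
    if x.shape[0] < min_trials:
        raise ValueError(f"need >= {min_trials} trials for a stable CSD")
    x = x - x.mean(axis=-1, keepdims=True)
    tapers = sine_tapers(n, n_tapers)
    n_fft = int(round(GC_PAD_S * rate))
    spec = np.fft.rfft(x[:, None, :, :] * tapers[None, :, None, :], n=n_fft,
                       axis=-1)
    spec = spec.reshape(-1, 2, spec.shape[-1])  # (trials*tapers, 2, freqs)
    S = np.einsum("oaf,obf->fab", spec, np.conj(spec)) / spec.shape[0]
    freqs = np.fft.rfftfreq(n_fft, 1.0 / rate)
    return CSDMatrix(S=S, freqs=freqs, n_trials=x.shape[0], n_tapers=n_tapers,
                     pair=pair, period=period, condition=condition)


@dataclass
class SpectralFactorization:
    """Wilson factorization output: S(f) = H(f) Sigma H*(f)."""

    H: np.ndarray  # (freqs, 2, 2) complex, minimum phase
    Sigma: np.ndarray  # (2, 2) real innovation covariance
    freqs: np.ndarray
    converged: bool
    n_iter: int
    residual: float  # max_f ||S - H Sigma H*|| / ||S||


def _plus_operator(g: np.ndarray, n_onesided: int) -> np.ndarray:
    """Causal part of a two-sided matrix spectrum (Wilson's []+)."""
    gam = np.fft.ifft(g, axis=0)
    beta0 = 0.5 * gam[0]
    gam[0] = np.triu(beta0)
    gam[n_onesided:] = 0.0
    return np.fft.fft(gam, axis=0)


def wilson_factorize(csd: CSDMatrix, tol: float = 1e-8, max_iter: int = 100,
                     check_psd: bool = True) -> SpectralFactorization:
    """Wilson's iterative spectral-matrix factorization.

    The one-sided CSD (0..Nyquist) is extended to a two-sided spectrum,
    initialised with the Cholesky factor of the zero-lag covariance, and
    iterated until the relative change of the factor falls below ``tol``
    or ``max_iter`` is reached (reported in ``converged``, not silent).
    Near-singular input is ridge-regularized (logged via warning).
    """
    S1 = np.asarray(csd.S, dtype=complex).copy()
    n_f = S1.shape[0]
    if check_psd:
        eig = np.linalg.eigvalsh(S1)
        if eig.min() < 0:
            eps = 1e-8 * float(np.mean(np.real(S1[:, 0, 0] + S1[:, 1, 1])) / 2)
            warnings.warn(
                f"CSD not PSD (min eigenvalue {eig.min():.3g}); adding "
                f"ridge {eps:.3g}", stacklevel=2,
            )
            S1 += eps * np.eye(2)[None, :, :]
            if np.linalg.eigvalsh(S1).min() < 0:
                raise ValueError("CSD not positive semi-definite after ridge")

    # two-sided extension: S(-f) = conj(S(f))
    n2 = 2 * (n_f - 1)
    S = np.empty((n2, 2, 2), dtype=complex)
    S[:n_f] = S1
    S[n_f:] = np.conj(S1[-2:0:-1])

    gam0 = np.real(np.fft.ifft(S, axis=0)[0])
    gam0 = (gam0 + gam0.T) / 2 + 1e-14 * np.eye(2) * max(np.trace(gam0), 1.0)
    h0 = np.linalg.cholesky(gam0).T.conj()  # upper triangular, h0^H h0 = gam0
    psi = np.broadcast_to(h0.astype(complex), (n2, 2, 2)).copy()

    eye = np.eye(2, dtype=complex)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ S @ np.conj(np.swapaxes(psi_inv, 1, 2)) + eye
        gp = _plus_operator(g, n_f)
        psi_new = psi @ gp
        delta = np.linalg.norm(psi_new - psi) / max(np.linalg.norm(psi), 1e-300)
        psi = psi_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"Wilson factorization did not converge in {max_iter} "
                      "iterations", stacklevel=2)

    A0 = np.real(np.fft.ifft(psi, axis=0)[0])
    Sigma = A0 @ A0.T
    H = psi[:n_f] @ np.linalg.inv(A0)

    recon = H @ Sigma @ np.conj(np.swapaxes(H, 1, 2))
    num = np.linalg.norm(recon - S1, axis=(1, 2))
    den = np.maximum(np.linalg.norm(S1, axis=(1, 2)), 1e-300)
    residual = float(np.max(num / den))
    return SpectralFactorization(H=H, Sigma=Sigma, freqs=csd.freqs,
                                 converged=converged, n_iter=n_iter,
                                 residual=residual)


@dataclass
class GCSpectrum:
    """Directed GC spectra of a pair, plus the net difference.

    With pair = (x, y), ``gc_yx`` is the flow y -> x and
    ``net = gc_yx - gc_xy``; ordering pairs as (IPL channel, other
    region's channel) makes positive net GC mean the other region leads.
    """

    freqs: np.ndarray
    gc_xy: np.ndarray  # x -> y
    gc_yx: np.ndarray  # y -> x
    net: np.ndarray
    pair: tuple = ("x", "y")
    period: str = ""
    condition: str = ""


def spectral_gc(fact: SpectralFactorization, pair: tuple = ("x", "y"),
                period: str = "", condition: str = "") -> GCSpectrum:
    """Directed spectral GC in both directions from a converged factorization."""
    H, Sig = fact.H, fact.Sigma
    S = H @ Sig @ np.conj(np.swapaxes(H, 1, 2))
    sxx = np.real(S[:, 0, 0])
    syy = np.real(S[:, 1, 1])

    # intrinsic power of x with y's innovations partialled out, and vice versa
    part_y = Sig[1, 1] - Sig[0, 1] ** 2 / Sig[0, 0]
    part_x = Sig[0, 0] - Sig[0, 1] ** 2 / Sig[1, 1]
    sxx_tilde = sxx - part_y * np.abs(H[:, 0, 1]) ** 2
    syy_tilde = syy - part_x * np.abs(H[:, 1, 0]) ** 2

    floor = 1e-300
    if np.any(sxx_tilde <= 0) or np.any(syy_tilde <= 0):
        warnings.warn("non-positive intrinsic power clipped", stacklevel=2)
    gc_yx = np.log(np.maximum(sxx, floor) / np.maximum(sxx_tilde, floor))
    gc_xy = np.log(np.maximum(syy, floor) / np.maximum(syy_tilde, floor))
    # numerical floor: tiny negatives are zeroed, real negatives are a bug
    gc_yx = np.where(gc_yx > -1e-10, np.maximum(gc_yx, 0.0), gc_yx)
    gc_xy = np.where(gc_xy > -1e-10, np.maximum(gc_xy, 0.0), gc_xy)
    return GCSpectrum(freqs=fact.freqs, gc_xy=gc_xy, gc_yx=gc_yx,
                      net=gc_yx - gc_xy, pair=pair, period=period,
                      condition=condition)


def select_peak_band(net_mean: np.ndarray, freqs: np.ndarray,
                     f_range: tuple = (1.0, 20.0), half_width: float = 1.0,
                     floor_sd: float = 3.0) -> list[dict]:
    """Data-driven frequency ranges around the net-GC extrema.

    The grand-average net GC (across pairs, periods, conditions) is
    scanned in ``f_range`` for its maximum and minimum; each extremum
    whose magnitude exceeds a robust noise floor (``floor_sd`` x the
    MAD-based sigma of the spectrum) yields a range of extremum
    +- ``half_width`` Hz with the extremum's sign.  A flat spectrum
    yields an empty selection.
    """
    net = np.asarray(net_mean, float)
    sel = (freqs >= f_range[0]) & (freqs <= f_range[1])
    f, v = freqs[sel], net[sel]
    if v.size == 0 or np.allclose(v, 0):
        return []
    sigma = 1.4826 * np.median(np.abs(v - np.median(v)))
    floor = floor_sd * max(sigma, 1e-300)
    out = []
    for extremum in (np.argmax(v), np.argmin(v)):
        val = v[extremum]
        if abs(val) <= floor:
            continue
        fp = float(f[extremum])
        out.append(
            {
                "f_peak": fp,
                "f_lo": max(fp - half_width, f_range[0]),
                "f_hi": min(fp + half_width, f_range[1]),
                "sign": int(np.sign(val)),
                "value": float(val),
            }
        )
    # drop a duplicate when max == min position (constant spectrum)
    uniq = []
    for r in out:
        if not any(abs(r["f_peak"] - u["f_peak"]) < 1e-9 for u in uniq):
            uniq.append(r)
    return uniq


def average_netgc_periods(gc_spectra: list[GCSpectrum],
                          ranges: list[dict]) -> pd.DataFrame:
    """Mean net GC per (pair, period, condition) over each selected range."""
    rows = []
    for rng_ in ranges:
        lo, hi = rng_["f_lo"], rng_["f_hi"]
        for gc in gc_spectra:
            bins = (gc.freqs >= lo) & (gc.freqs <= hi)
            rows.append(
                {
                    "pair_id": f"{gc.pair[0]}-{gc.pair[1]}",
                    "range": f"{lo:g}-{hi:g}Hz",
                    "period": gc.period,
                    "condition": gc.condition,
                    "mean_net_gc": float(gc.net[bins].mean()),
                }
            )
    return pd.DataFrame(rows)
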