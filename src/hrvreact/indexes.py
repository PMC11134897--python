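"""Time-domain, frequency-domain and Poincaré HRV indexes for an NN segment.

Conventions (documented, configurable where meaningful):

* standard deviations use the sample (N-1) denominator throughout;
* pNN50 counts successive differences strictly greater than 50 ms;
* mean HR is 60000 / mean NN (not the mean of instantaneous rates);
* the spectrum comes from linear-interpolation resampling of the tachogram
  (interval value at its closing beat time) followed by a Welch periodogram;
  band powers are trapezoidal integrals of the one-sided PSD over
  LF = [0.04, 0.15) Hz and HF = [0.15, 0.4] Hz (the 0.15 Hz boundary belongs
  to HF), and normalised units are relative to LF + HF by default;
* Poincaré SD1/SD2 are the exact standard deviations of the lag-1 return map
  rotated 45 degrees, i.e. the ellipse axes perpendicular to / along the
  identity line;
* undefined ratios (zero denominators) are flagged as NaN, never infinity.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import signal

from .config import WelchSettings
from .errors import InsufficientDataError
from .series import NNSegment

PNN_THRESHOLD_MS = 50.0

INDEX_FIELDS = (
    "mean_nn_ms", "mean_hr_bpm", "sdnn_ms", "pnn50_pct",
    "lf_power_ms2", "hf_power_ms2", "lf_nu", "hf_nu", "log10_lf_hf",
    "sd1_ms", "sd2_ms", "sd2_sd1_ratio", "sd1_sd2_ratio",
)


@dataclass(frozen=True)
class HRVIndexSet:
    """The full index panel for one segment; NaN marks a flagged-undefined value."""

    mean_nn_ms: float
    mean_hr_bpm: float
    sdnn_ms: float
    pnn50_pct: float
    lf_power_ms2: float
    hf_power_ms2: float
    lf_nu: float
    hf_nu: float
    log10_lf_hf: float
    sd1_ms: float
    sd2_ms: float
    sd2_sd1_ratio: float
    sd1_sd2_ratio: float
    settings: Optional[WelchSettings] = None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in INDEX_FIELDS}


@dataclass(frozen=True)
class SpectrumEstimate:
    frequencies_hz: np.ndarray
    psd_ms2_per_hz: np.ndarray
    settings: WelchSettings

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        p = np.asarray(self.psd_ms2_per_hz, dtype=float)
        if f.ndim != 1 or f.shape != p.shape:
            raise ValueError("frequency grid and PSD must be aligned 1-D arrays")
        if np.any(f < 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be nonnegative and increasing")
        if np.any(p < 0):
            raise ValueError("PSD must be nonnegative")


def time_domain(segment: NNSegment) -> Tuple[float, float, float, float]:
    """(mean NN ms, mean HR bpm, SDNN ms, pNN50 %)."""
    x = segment.nn_ms
    if x.size < 2:
        raise InsufficientDataError("time_domain needs at least 2 intervals")
    mean_nn = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    diffs = np.abs(np.diff(x))
    pnn50 = 100.0 * float(np.sum(diffs > PNN_THRESHOLD_MS)) / (x.size - 1)
    return mean_nn, 60000.0 / mean_nn, sdnn, pnn50


def resample_tachogram(segment: NNSegment, rate_hz: float = 3.0) -> Tuple[np.ndarray, np.ndarray]:
    """Uniformly resample the tachogram (interval value at its closing beat
    time) by linear interpolation.  Returns (times_s, values_ms)."""
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    t = segment.end_times_s
    if t.size < 2:
        raise InsufficientDataError("resampling needs at least 2 tachogram points")
    n = int(math.floor((t[-1] - t[0]) * rate_hz + 1e-9)) + 1
    grid = t[0] + np.arange(n) / rate_hz
    return grid, np.interp(grid, t, segment.nn_ms)


def welch_psd(samples: np.ndarray, settings: WelchSettings = WelchSettings()) -> SpectrumEstimate:
    """One-sided Welch PSD of the resampled tachogram, density-normalised so
    the integral over frequency approximates the detrended sample variance.

    Falls back to a single full-length window (with a warning) when the
    series is shorter than the configured window.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("welch_psd needs at least 2 samples")
    nperseg = settings.nperseg
    if x.size < nperseg:
        warnings.warn(
            f"series of {x.size} samples shorter than Welch window {nperseg}; "
            "falling back to a single window", stacklevel=2)
        nperseg = x.size
    freqs, psd = signal.welch(
        x, fs=settings.resample_hz, window=settings.window, nperseg=nperseg,
        noverlap=int(settings.overlap * nperseg), detrend=settings.detrend,
        scaling="density", return_onesided=True)
    return SpectrumEstimate(frequencies_hz=freqs, psd_ms2_per_hz=np.maximum(psd, 0.0),
                            settings=settings)


def _band_integral(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    lo = max(lo, float(f[0]))
    hi = min(hi, float(f[-1]))
    if hi <= lo:
        return 0.0
    inner = (f > lo) & (f < hi)
    fseg = np.concatenate(([lo], f[inner], [hi]))
    pseg = np.interp(fseg, f, p)
    return float(np.trapezoid(pseg, fseg))


def band_powers(spectrum: SpectrumEstimate) -> Tuple[float, float, float, float, float]:
    """(LF ms^2, HF ms^2, LF nu, HF nu, log10 LF/HF); undefined values are NaN."""
    f, p = spectrum.frequencies_hz, spectrum.psd_ms2_per_hz
    st = spectrum.settings
    lf = _band_integral(f, p, *st.lf_band)
    hf = _band_integral(f, p, *st.hf_band)
    if st.nu_denominator == "total":
        denom = _band_integral(f, p, 0.0, st.hf_band[1])
    else:
        denom = lf + hf
    if denom > 0:
        lf_nu = 100.0 * lf / denom
        hf_nu = 100.0 * hf / denom
    else:
        lf_nu = hf_nu = math.nan
    log_ratio = math.log10(lf / hf) if (lf > 0 and hf > 0) else math.nan
    return lf, hf, lf_nu, hf_nu, log_ratio


def poincare(segment: NNSegment) -> Tuple[float, float, float, float]:
    """(SD1 ms, SD2 ms, SD2/SD1, SD1/SD2) from the 45-degree-rotated lag-1 map."""
    x = segment.nn_ms
    if x.size < 3:
        raise InsufficientDataError("poincare needs at least 3 intervals")
    u = (x[1:] - x[:-1]) / math.sqrt(2.0)
    v = (x[1:] + x[:-1]) / math.sqrt(2.0)
    # shift by the first element so a constant map yields exactly zero SDs
    sd1 = float(np.std(u - u[0], ddof=1))
    sd2 = float(np.std(v - v[0], ddof=1))
    sd2_sd1 = sd2 / sd1 if sd1 > 0 else math.nan
    sd1_sd2 = sd1 / sd2 if sd2 > 0 else math.nan
    return sd1, sd2, sd2_sd1, sd1_sd2


def compute_all(segment: NNSegment,
                settings: WelchSettings = WelchSettings()) -> HRVIndexSet:
    """Populate the full index panel for one segment."""
    try:
        mean_nn, mean_hr, sdnn, pnn50 = time_domain(segment)
        _, samples = resample_tachogram(segment, settings.resample_hz)
        spectrum = welch_psd(samples, settings)
        lf, hf, lf_nu, hf_nu, log_ratio = band_powers(spectrum)
        sd1, sd2, sd2_sd1, sd1_sd2 = poincare(segment)
    except InsufficientDataError as exc:
        raise InsufficientDataError(
            f"subject {segment.subject_id!r} {segment.timepoint}/{segment.condition}: {exc}"
        ) from exc
    return HRVIndexSet(
        mean_nn_ms=mean_nn, mean_hr_bpm=mean_hr, sdnn_ms=sdnn, pnn50_pct=pnn50,
        lf_power_ms2=lf, hf_power_ms2=hf, lf_nu=lf_nu, hf_nu=hf_nu,
        log10_lf_hf=log_ratio, sd1_ms=sd1, sd2_ms=sd2,
        sd2_sd1_ratio=sd2_sd1, sd1_sd2_ratio=sd1_sd2, settings=settings)
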