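"""PPG preprocessing and peak-based statistical features.

Motion-artifact suppression follows the classic subtract-the-baseline
scheme: a long-window Savitzky–Golay (SG) fit estimates the slow offset,
and the corrected signal is ``raw - baseline``. Pulse peaks are then
detected on the corrected signal and six statistics of the peak
amplitudes — mean, variance, skewness, excess kurtosis, standard
deviation, and Shannon entropy — are computed per wavelength, yielding
12 features per dual-channel recording.

Conventions (frozen here because the downstream regressor only needs
consistency, not a particular scale): population (divide-by-n) moments,
excess kurtosis, skewness/kurtosis = 0 when the variance is 0, and
entropy over an equal-width 8-bin amplitude histogram, in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import peak_prominences, savgol_filter

from .errors import DataError, InsufficientPeaksError, ParameterError
from .synthetic import DualPPGRecording

__all__ = [
    "FilterConfig",
    "PeakConfig",
    "ChannelStats",
    "PPGFeatureVector",
    "PPG_FEATURE_NAMES",
    "sg_smooth",
    "baseline_correct",
    "detect_peaks",
    "peak_statistics",
    "shannon_entropy",
    "extract_ppg_features",
]


@dataclass(frozen=True)
class FilterConfig:
    """Baseline-estimation SG filter settings.

    A 2 s window spans at least one full cardiac cycle at any plausible
    heart rate, so the polynomial fit tracks the drift, not the pulses.
    ``edge_mode='interp'`` fits the edge windows with their own
    polynomials, which preserves polynomial signals exactly at the
    boundaries; 'mirror' padding is available but bends polynomial
    trends at the edges.
    """

    baseline_window_s: float = 2.0
    poly_order: int = 3
    edge_mode: str = "interp"

    def window_samples(self, rate_hz: float) -> int:
        """Odd window length in samples covering ``baseline_window_s``."""
        w = int(round(self.baseline_window_s * rate_hz))
        if w % 2 == 0:
            w += 1
        if w < self.poly_order + 2:
            raise ParameterError(
                f"window of {w} samples too short for order {self.poly_order}")
        return w


@dataclass(frozen=True)
class PeakConfig:
    """Peak-detection settings: a refractory distance (default caps the
    admissible rate at 180 bpm) and a prominence floor as a fraction of
    the corrected signal's standard deviation."""

    min_distance_s: float = 0.333
    min_prominence_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.min_distance_s <= 0:
            raise ParameterError("min_distance_s must be positive")
        if self.min_prominence_factor < 0:
            raise ParameterError("min_prominence_factor must be >= 0")


def sg_smooth(signal: np.ndarray, window: int, order: int,
              mode: str = "interp") -> np.ndarray:
    """Savitzky–Golay smoothing: per-window least-squares polynomial fit
    evaluated at the window center.

    Parameters
    ----------
    signal : array
        Input samples; length must be >= ``window``.
    window : int
        Odd window length in samples, > ``order``.
    order : int
        Polynomial order of the local fit.
    mode : str
        Edge handling handed to scipy ('interp' or a padding mode).
    """
    x = np.asarray(signal, dtype=float)
    if window % 2 == 0 or window <= order:
        raise ParameterError(f"window must be odd and > order, got {window}/{order}")
    if x.ndim != 1 or len(x) < window:
        raise ParameterError("signal must be 1-D with length >= window")
    return savgol_filter(x, window_length=window, polyorder=order, mode=mode)


def baseline_correct(signal: np.ndarray, rate_hz: float,
                     fc: FilterConfig | None = None) -> np.ndarray:
    """Remove slow drift: ``signal - sg_smooth(signal)`` with a long window."""
    fc = fc or FilterConfig()
    w = fc.window_samples(rate_hz)
    return np.asarray(signal, dtype=float) - sg_smooth(signal, w, fc.poly_order,
                                                       mode=fc.edge_mode)


def detect_peaks(signal: np.ndarray, rate_hz: float,
                 pc: PeakConfig | None = None) -> np.ndarray:
    """Detect pulse peaks: strict local maxima, kept greedily by
    descending prominence subject to a minimum mutual distance, with
    prominence at least ``min_prominence_factor * std(signal)``.

    Returns an ascending index array; may be empty.
    """
    pc = pc or PeakConfig()
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("signal contains non-finite samples")
    if len(x) < 3:
        return np.array([], dtype=int)
    cand = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
    if len(cand) == 0:
        return cand
    prom = peak_prominences(x, cand)[0]
    floor = pc.min_prominence_factor * float(np.std(x))
    keep = prom >= floor
    cand, prom = cand[keep], prom[keep]
    min_dist = pc.min_distance_s * rate_hz
    accepted: list[int] = []
    for idx in cand[np.argsort(-prom, kind="stable")]:
        if all(abs(idx - a) >= min_dist for a in accepted):
            accepted.append(int(idx))
    return np.array(sorted(accepted), dtype=int)


def shannon_entropy(values: np.ndarray, n_bins: int = 8) -> float:
    """Shannon entropy (bits) of an equal-width histogram over [min, max].

    When all values coincide the mass sits in one bin and the entropy is
    0; the result is always within [0, log2(n_bins)].
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("entropy of an empty sample is undefined")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / v.size
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class ChannelStats:
    """Six statistics of one channel's peak amplitudes."""

    mean: float
    variance: float
    skewness: float
    kurtosis: float  # excess
    std: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.variance, self.skewness,
                         self.kurtosis, self.std, self.entropy])


def peak_statistics(amplitudes: np.ndarray, n_bins: int = 8) -> ChannelStats:
    """Population moments + entropy of a peak-amplitude sample.

    skewness = m3 / m2^1.5, kurtosis = m4 / m2^2 - 3 (excess); both are 0
    by convention when m2 = 0.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 2:
        raise InsufficientPeaksError(f"need >= 2 peak amplitudes, got {a.size}")
    mean = float(a.mean())
    d = a - mean
    m2 = float(np.mean(d ** 2))
    if m2 == 0.0:
        skew, kurt = 0.0, 0.0
    else:
        skew = float(np.mean(d ** 3)) / m2 ** 1.5
        kurt = float(np.mean(d ** 4)) / m2 ** 2 - 3.0
    return ChannelStats(mean=mean, variance=m2, skewness=skew, kurtosis=kurt,
                        std=float(np.sqrt(m2)),
                        entropy=shannon_entropy(a, n_bins))


#: Canonical ordering of the 12 PPG network inputs (IR/Red interleaved).
PPG_FEATURE_NAMES = [
    "ir_mean", "red_mean",
    "ir_variance", "red_variance",
    "ir_skewness", "red_skewness",
    "ir_kurtosis", "red_kurtosis",
    "ir_std", "red_std",
    "ir_entropy", "red_entropy",
]


@dataclass(frozen=True)
class PPGFeatureVector:
    """The 12 statistical PPG features plus peak-count diagnostics."""

    ir: ChannelStats
    red: ChannelStats
    n_peaks_ir: int
    n_peaks_red: int
    valid: bool = True

    def as_array(self) -> np.ndarray:
        """Features in the canonical interleaved order (12 values)."""
        i, r = self.ir.as_array(), self.red.as_array()
        out = np.empty(12)
        out[0::2], out[1::2] = i, r
        return out


_NAN_STATS = ChannelStats(*([float("nan")] * 6))


def extract_ppg_features(rec: DualPPGRecording,
                         fc: FilterConfig | None = None,
                         pc: PeakConfig | None = None,
                         n_bins: int = 8) -> PPGFeatureVector:
    """Baseline-correct both channels, detect peaks, compute 6 stats each.

    If either channel yields fewer than 2 peaks the vector is returned
    flagged invalid (all-NaN statistics) rather than raising, so cohort
    runs can drop and log the participant.
    """
    fc = fc or FilterConfig()
    pc = pc or PeakConfig()
    stats, npk = [], []
    for channel in (rec.infrared, rec.red):
        corrected = baseline_correct(channel, rec.sampling_rate_hz, fc)
        peaks = detect_peaks(corrected, rec.sampling_rate_hz, pc)
        npk.append(len(peaks))
        if len(peaks) < 2:
            stats.append(None)
        else:
            stats.append(peak_statistics(corrected[peaks], n_bins))
    if stats[0] is None or stats[1] is None:
        return PPGFeatureVector(ir=_NAN_STATS, red=_NAN_STATS,
                                n_peaks_ir=npk[0], n_peaks_red=npk[1], valid=False)
    return PPGFeatureVector(ir=stats[0], red=stats[1],
                            n_peaks_ir=npk[0], n_peaks_red=npk[1], valid=True)
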