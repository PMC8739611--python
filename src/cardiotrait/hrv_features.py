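"""Heart rate variability features over time, frequency and geometry domains.

Seventeen features computed from the RR-interval series:

* time domain: HR_mean, RR_mean, rmssd, sdnn, m_nn (maximal RR), nn50,
  pnn50, sdsd;
* geometry: the HRV triangular index (total interval count over the modal
  histogram bin) and the Poincare descriptors SD1/SD2;
* frequency domain: LF (0.04-0.15 Hz), HF (0.15-0.40 Hz), their ratio and
  normalised forms, and total spectral power.

Conventions (configurable where noted): sample (n-1) standard deviations;
HR_mean as the mean of instantaneous rates 60/RR; pnn50 with the total
number of RR intervals in the denominator; spectra via Welch's method on a
cubic-spline resampled 4 Hz tachogram, with a Lomb-Scargle alternative for
validation.  SD2 uses the ellipse-fitting identity SD2^2 = 2*sdnn^2 - SD1^2,
which agrees with the rotated-scatter dispersion up to O(1/n) edge terms and
makes SD1^2 + SD2^2 = 2*sdnn^2 hold exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .exceptions import InsufficientDataError, ParameterError

logger = logging.getLogger("cardiotrait")

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TOTAL_POWER_FLOOR_HZ = 0.003


@dataclass(frozen=True)
class RRSeries:
    """Successive RR intervals (s) and their cumulative occurrence times."""

    rr: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr, dtype=float)
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "rr", rr)
        object.__setattr__(self, "t", t)
        if rr.size != t.size:
            raise ParameterError("rr and t must have equal length")
        if (rr <= 0).any():
            raise ParameterError("RR intervals must be positive")
        if rr.size >= 2 and not (np.diff(t) > 0).all():
            raise ParameterError("occurrence times must strictly increase")

    def __len__(self) -> int:
        return self.rr.size


def rr_from_rpeaks(rpeaks: np.ndarray, fs: float) -> RRSeries:
    """Convert R-peak sample indices to an RR series in seconds."""
    rpeaks = np.asarray(rpeaks)
    if rpeaks.size < 2:
        raise InsufficientDataError("need at least 2 R peaks for an RR series")
    if not (np.diff(rpeaks) > 0).all():
        raise ParameterError("R peaks must strictly increase")
    if fs <= 0:
        raise ParameterError("fs must be positive")
    rr = np.diff(rpeaks) / fs
    t = rpeaks[1:] / fs
    return RRSeries(rr=rr, t=t)


def time_domain(rr: RRSeries, hr_mean_mode: str = "instantaneous") -> dict[str, float]:
    """Time-domain HRV statistics.

    ``hr_mean_mode``: ``"instantaneous"`` averages 60/RR per beat (default);
    ``"overall"`` uses 60/mean(RR).
    """
    x = rr.rr
    if x.size < 2:
        raise InsufficientDataError("time-domain HRV needs >= 2 RR intervals")
    d = np.diff(x)
    if hr_mean_mode == "instantaneous":
        hr = float(np.mean(60.0 / x))
    elif hr_mean_mode == "overall":
        hr = 60.0 / float(np.mean(x))
    else:
        raise ParameterError(f"unknown hr_mean_mode {hr_mean_mode!r}")
    nn50 = int(np.count_nonzero(np.abs(d) > 0.050))
    return {
        "HR_mean": hr,
        "RR_mean": float(np.mean(x)),
        "rmssd": float(np.sqrt(np.mean(d ** 2))),
        "sdnn": float(np.std(x, ddof=1)),
        "m_nn": float(np.max(x)),
        "nn50": float(nn50),
        "pnn50": 100.0 * nn50 / x.size,
        "sdsd": float(np.std(d, ddof=1)) if d.size >= 2 else 0.0,
    }


def hrv_triangular_index(rr: RRSeries, bin_width: float) -> float:
    """Total RR count divided by the modal histogram bin count.

    The histogram spans [min(rr), max(rr)] at the given bin width — the
    study convention is one sampling period (1/fs) per bin, with the
    conventional 1/128 s available through configuration.
    """
    if len(rr) < 2:
        raise InsufficientDataError("triangular index needs >= 2 RR intervals")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    x = rr.rr
    span = float(x.max() - x.min())
    n_bins = max(int(math.ceil(span / bin_width)), 1)
    counts, _ = np.histogram(x, bins=n_bins, range=(float(x.min()),
                                                    float(x.min()) + n_bins * bin_width))
    return x.size / int(counts.max())


def _band_power(f: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    mask = (f >= lo) & (f < hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], f[mask]))


def frequency_domain(
    rr: RRSeries,
    min_span_s: float = 60.0,
    resample_hz: float = 4.0,
    segment_s: float = 64.0,
    method: str = "welch",
) -> dict[str, float]:
    """Spectral HRV features from the tachogram.

    Default estimator: cubic-spline interpolation to a uniform grid, mean
    removal, Welch periodogram (Hann window, 50% overlap).  ``method``
    ``"lombscargle"`` computes the spectrum on the irregular series directly.
    Powers are in s^2.  When HF is zero, LFHF is reported as NaN (flagged)
    rather than infinity.
    """
    if len(rr) < 4:
        raise InsufficientDataError("frequency-domain HRV needs >= 4 RR intervals")
    span = float(rr.t[-1] - rr.t[0])
    if span < min_span_s:
        raise InsufficientDataError(
            f"recording spans {span:.1f}s; need >= {min_span_s}s for spectral HRV")

    if method == "welch":
        grid = np.arange(rr.t[0], rr.t[-1], 1.0 / resample_hz)
        tach = CubicSpline(rr.t, rr.rr)(grid)
        tach = tach - tach.mean()
        nperseg = min(int(segment_s * resample_hz), tach.size)
        f, psd = sps.welch(tach, fs=resample_hz, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2)
    elif method == "lombscargle":
        f = np.linspace(TOTAL_POWER_FLOOR_HZ, HF_BAND[1] + 0.05, 400)
        x = rr.rr - rr.rr.mean()
        power = sps.lombscargle(rr.t, x, 2.0 * np.pi * f)
        # a density-like rescaling; band *ratios* are comparable to Welch,
        # absolute powers are estimator-dependent
        psd = 4.0 * power / (len(x) / span)
    else:
        raise ParameterError(f"unknown spectral method {method!r}")

    lf = _band_power(f, psd, *LF_BAND)
    hf = _band_power(f, psd, *HF_BAND)
    total = _band_power(f, psd, TOTAL_POWER_FLOOR_HZ, HF_BAND[1] + 1e-12)
    if hf > 0.0:
        lfhf = lf / hf
    else:
        lfhf = float("nan")
        logger.warning("HF power is zero; LFHF flagged as missing")
    denom = lf + hf
    lfnu = lf / denom if denom > 0 else float("nan")
    hfnu = hf / denom if denom > 0 else float("nan")
    return {"LF": lf, "HF": hf, "LFHF": lfhf, "LFnu": lfnu, "HFnu": hfnu,
            "total_power": total}


def poincare(rr: RRSeries) -> tuple[float, float]:
    """Poincare plot descriptors (SD1, SD2).

    SD1 is the dispersion across the identity line, sdsd/sqrt(2); SD2 follows
    the ellipse identity SD2^2 = 2*sdnn^2 - SD1^2 (clipped at zero), so
    SD1^2 + SD2^2 = 2*sdnn^2 exactly.
    """
    x = rr.rr
    if x.size < 3:
        raise InsufficientDataError("Poincare descriptors need >= 3 RR intervals")
    sdsd = float(np.std(np.diff(x), ddof=1))
    sdnn = float(np.std(x, ddof=1))
    sd1 = sdsd / math.sqrt(2.0)
    sd2 = math.sqrt(max(2.0 * sdnn ** 2 - sd1 ** 2, 0.0))
    return sd1, sd2


def hrv_features(rr: RRSeries, fs: float,
                 triangular_bin_width: float | None = None,
                 hr_mean_mode: str = "instantaneous",
                 min_span_s: float = 60.0) -> dict[str, float]:
    """All 17 HRV features keyed by their canonical names."""
    out = time_domain(rr, hr_mean_mode=hr_mean_mode)
    width = triangular_bin_width if triangular_bin_width is not None else 1.0 / fs
    out["HRV_index"] = hrv_triangular_index(rr, width)
    out.update(frequency_domain(rr, min_span_s=min_span_s))
    sd1, sd2 = poincare(rr)
    out["SD1"] = sd1
    out["SD2"] = sd2
    return out
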