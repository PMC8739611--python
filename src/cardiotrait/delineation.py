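"""ECG preprocessing, R-peak detection and P-QRS-T wave delineation.

The fiducial substrate for all downstream features: per beat, the P/Q/R/S/T
peak indices plus the P-wave, QRS-complex and T-wave onsets/offsets.

Conventions
-----------
* 0-based sample indices over the half-open record interval; conversion to
  seconds happens only inside feature computation.
* Delineation runs on a zero-phase 0.5-40 Hz band-passed copy of the signal;
  fiducial *amplitudes* are measured on a baseline-corrected copy that is not
  low-pass narrowed, so wave heights are not attenuated by the search filter.
* Beats whose fiducials cannot all be placed in the canonical order are
  dropped, never imputed; the dropped count is logged and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .exceptions import (
    DelineationQualityError,
    DetectionError,
    InsufficientDataError,
    ParameterError,
    SignalTooShortError,
)
from .signal_io import EcgRecord

logger = logging.getLogger("cardiotrait")


@dataclass(frozen=True)
class DelineationConfig:
    """Tunables of the detector and delineator (windows in ms relative to R)."""

    bandpass_hz: tuple[float, float] = (0.5, 40.0)
    qrs_band_hz: tuple[float, float] = (5.0, 25.0)
    lowpass_cutoff_hz: float = 55.0
    lowpass_width_hz: float = 10.0
    notch_hz: float = 50.0
    notch_half_width_hz: float = 1.0
    refractory_s: float = 0.25
    integration_window_s: float = 0.15
    threshold_fraction: float = 0.30
    min_detect_duration_s: float = 10.0
    # peak search windows, ms relative to the R peak
    p_window_ms: tuple[float, float] = (-300.0, -70.0)
    q_window_ms: tuple[float, float] = (-80.0, -10.0)
    s_window_ms: tuple[float, float] = (10.0, 80.0)
    t_window_ms: tuple[float, float] = (100.0, 450.0)
    slope_fraction: float = 0.05     # onset/offset: stop below this x max slope
    min_wave_rel_amplitude: float = 0.03  # vs |R|; smaller -> wave missing
    deriv_smooth_s: float = 0.005
    max_dropped_fraction: float = 0.5


_PEAK_FIDUCIALS = ("p", "q", "r", "s", "t")
_ALL_FIDUCIALS = ("p_on", "p", "p_off", "qrs_on", "q", "r", "s", "qrs_off",
                  "t_on", "t", "t_off")


@dataclass
class FiducialSet:
    """Per-beat fiducial sample indices with signed amplitudes."""

    fs: float
    indices: dict[str, np.ndarray]       # name -> int array, one per beat
    amplitudes: dict[str, np.ndarray]    # peak name -> signed amplitude
    n_dropped: int = 0
    n_candidates: int = 0

    @property
    def n_beats(self) -> int:
        return len(self.indices["r"])

    def validate(self, record_length: int | None = None) -> None:
        cols = np.stack([self.indices[f] for f in _ALL_FIDUCIALS])
        # Pon < P < Poff <= QRSon <= Q < R < S <= QRSoff <= Ton < T < Toff
        strict = {0, 1, 4, 5, 8, 9}
        for j in range(cols.shape[0] - 1):
            diff = cols[j + 1] - cols[j]
            ok = (diff > 0) if j in strict else (diff >= 0)
            if not ok.all():
                raise ParameterError(
                    f"fiducial ordering violated: {_ALL_FIDUCIALS[j]} !< "
                    f"{_ALL_FIDUCIALS[j + 1]}")
        if not (np.diff(self.indices["r"]) > 0).all():
            raise ParameterError("R indices must strictly increase")
        if record_length is not None:
            if cols.min(initial=0) < 0 or cols.max(initial=-1) >= record_length:
                raise ParameterError("fiducial index outside record")


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(band[1], 0.95 * nyq)
    sos = sps.butter(2, [band[0] / nyq, hi / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, x)


def preprocess(record: EcgRecord, config: DelineationConfig | None = None) -> EcgRecord:
    """Attenuate baseline wander, powerline interference and high-frequency
    noise; length and sampling rate are unchanged, pure DC is removed exactly.

    Stages: zero-phase FIR low-pass (55 Hz cutoff), then a spectral mask that
    zeroes the sub-0.5 Hz band and the powerline bins.  The mask has a binary
    magnitude response and the FIR passband is flat, so reapplying the whole
    operation is almost a no-op (approximate idempotence).
    """
    config = config or DelineationConfig()
    if record.duration_s < 2.0:
        raise SignalTooShortError(
            f"record of {record.duration_s:.2f}s is shorter than the 2s filter warm-up")
    fs = record.fs
    x = record.samples - record.samples.mean()
    if np.ptp(x) == 0.0:
        return EcgRecord(np.zeros_like(x), fs=fs, subject_id=record.subject_id)
    cutoff = min(config.lowpass_cutoff_hz, 0.9 * fs / 2.0)
    numtaps = min(int(round(3.3 * fs / config.lowpass_width_hz)) | 1, len(x) | 1)
    taps = sps.firwin(numtaps, cutoff, width=config.lowpass_width_hz, fs=fs)
    y = sps.fftconvolve(x, taps, mode="same")
    # spectral mask: zero the baseline-wander band (DC removed exactly) and
    # the powerline bins; binary magnitude response, exactly idempotent
    spec = np.fft.rfft(y)
    freqs = np.fft.rfftfreq(len(y), d=1.0 / fs)
    mask = freqs < config.bandpass_hz[0]
    if config.notch_hz < fs / 2.0:
        mask |= np.abs(freqs - config.notch_hz) <= config.notch_half_width_hz
    spec[mask] = 0.0
    y = np.fft.irfft(spec, n=len(y))
    return EcgRecord(y, fs=fs, subject_id=record.subject_id)


def baseline_corrected(record: EcgRecord) -> np.ndarray:
    """Zero the isoelectric line without narrowing the band.

    Two-stage median-filter baseline estimation (0.2 s then 0.6 s windows):
    the first stage strides over P waves and QRS complexes, the second over
    T waves, leaving the slow baseline, which is then subtracted.  Wave
    amplitudes are preserved and referenced to the isoelectric level.
    """
    x = record.samples
    if np.ptp(x) == 0.0:
        return np.zeros_like(x)
    k1 = int(round(0.2 * record.fs)) | 1
    k2 = int(round(0.6 * record.fs)) | 1
    baseline = ndimage.median_filter(x, size=k1, mode="nearest")
    baseline = ndimage.median_filter(baseline, size=k2, mode="nearest")
    return x - baseline


def detect_r_peaks(record: EcgRecord, config: DelineationConfig | None = None) -> np.ndarray:
    """Locate R peaks with a derivative-energy detector.

    Pan-Tompkins-style: band-pass to the QRS band, differentiate, square,
    integrate over a moving window, pick peaks above an adaptive threshold
    with a refractory period, then refine each detection to the local signal
    maximum within +/-50 ms.
    """
    config = config or DelineationConfig()
    if record.duration_s < config.min_detect_duration_s:
        raise InsufficientDataError(
            f"need >= {config.min_detect_duration_s}s for R detection, "
            f"got {record.duration_s:.1f}s")
    fs = record.fs
    x = record.samples - record.samples.mean()
    if np.ptp(x) == 0.0:
        raise DetectionError("flat signal: no beats detectable")

    qrs = _bandpass(x, fs, config.qrs_band_hz)
    energy = np.gradient(qrs) ** 2
    win = max(int(round(config.integration_window_s * fs)), 1)
    envelope = np.convolve(energy, np.ones(win) / win, mode="same")

    distance = max(int(round(config.refractory_s * fs)), 1)
    candidates, props = sps.find_peaks(envelope, distance=distance, height=0.0)
    if candidates.size == 0:
        raise DetectionError("no QRS-energy peaks found")
    heights = props["peak_heights"]
    order = np.sort(heights)[::-1]
    signal_level = np.median(order[:max(1, len(order) // 3)])
    keep = candidates[heights >= config.threshold_fraction * signal_level]
    if keep.size == 0:
        raise DetectionError("no peaks above the adaptive threshold")

    # refine to the local maximum of the band-passed signal within +/-50 ms
    half = int(round(0.05 * fs))
    search = _bandpass(x, fs, config.bandpass_hz)
    refined = []
    for c in keep:
        lo, hi = max(c - half, 0), min(c + half + 1, len(search))
        refined.append(lo + int(np.argmax(search[lo:hi])))
    rpeaks = np.unique(np.asarray(refined, dtype=int))

    # refractory enforcement after refinement: keep the larger of close pairs
    while True:
        rr = np.diff(rpeaks)
        too_close = np.flatnonzero(rr < distance)
        if too_close.size == 0:
            break
        j = too_close[0]
        drop = j if search[rpeaks[j]] < search[rpeaks[j + 1]] else j + 1
        rpeaks = np.delete(rpeaks, drop)

    if rpeaks.size < 2:
        raise DetectionError("fewer than two beats detected")
    hr = 60.0 * fs / np.median(np.diff(rpeaks))
    if not (30.0 <= hr <= 200.0):
        raise DetectionError(f"implausible median heart rate {hr:.0f} bpm")
    return rpeaks


def _first_slope_drop(deriv_abs: np.ndarray, start: int, step: int,
                      limit: int, fraction: float,
                      noise_floor: float = 0.0,
                      shoulder_span: int | None = None) -> int | None:
    """Walk from ``start`` in ``step`` direction; return the first index where
    |slope| falls below ``fraction`` of the wave's shoulder slope (its maximum
    within ``shoulder_span`` of the peak) or sinks to the derivative noise
    floor. ``limit`` is the last admissible index."""
    if step > 0:
        seg = deriv_abs[start:limit + 1]
    else:
        seg = deriv_abs[limit:start + 1][::-1]
    if seg.size < 3:
        return None
    shoulder = int(np.argmax(seg if shoulder_span is None else seg[:shoulder_span]))
    threshold = max(fraction * float(seg[shoulder]), 4.0 * noise_floor)
    hit = np.flatnonzero(seg[shoulder:] < threshold)
    if hit.size == 0:
        return None
    k = shoulder + int(hit[0])
    return start + step * k


def delineate(record: EcgRecord, rpeaks: np.ndarray,
              config: DelineationConfig | None = None) -> FiducialSet:
    """Place P/Q/S/T peaks and wave onsets/offsets around each R peak.

    First and last beats are excluded (incomplete neighbourhoods).  A beat is
    dropped when a wave is too small to locate or the fiducials come out in a
    non-canonical order.
    """
    config = config or DelineationConfig()
    rpeaks = np.asarray(rpeaks, dtype=int)
    if rpeaks.size < 2:
        raise InsufficientDataError("need at least 2 R peaks to delineate")
    fs = record.fs
    n = len(record)

    search = _bandpass(record.samples - record.samples.mean(), fs, config.bandpass_hz)
    amp = baseline_corrected(record)
    # QRS onset/offset are measured on the full-band baseline-corrected copy
    # (the 40 Hz search filter smears the narrow QRS edges); the slow P/T wave
    # edges use the band-limited copy, which suppresses broadband noise
    smooth_win = max(int(round(config.deriv_smooth_s * fs)) | 1, 5)
    deriv_abs = {
        "wide": np.abs(np.gradient(sps.savgol_filter(amp, smooth_win, 3))),
        "narrow": np.abs(np.gradient(sps.savgol_filter(search, smooth_win, 3))),
    }
    # derivative noise floors from a low quantile: the flattest fifth of the
    # record is isoelectric baseline even at high heart rates
    noise_floor = {k: 2.0 * float(np.percentile(v, 20)) for k, v in deriv_abs.items()}

    def ms2i(ms: float) -> int:
        return int(round(ms * fs / 1000.0))

    windows = {
        "p": (config.p_window_ms, +1),   # positive wave in Lead I
        "q": (config.q_window_ms, -1),
        "s": (config.s_window_ms, -1),
        "t": (config.t_window_ms, +1),
    }

    results: dict[str, list[int]] = {f: [] for f in _ALL_FIDUCIALS}
    amps: dict[str, list[float]] = {f: [] for f in _PEAK_FIDUCIALS}
    n_dropped = 0
    inner = rpeaks[1:-1] if rpeaks.size > 2 else rpeaks[:0]
    n_candidates = inner.size

    for bi, r in enumerate(inner):
        rr_prev = int(r - rpeaks[bi])          # inner[bi] == rpeaks[bi + 1]
        rr_next = int(rpeaks[bi + 2] - r)
        beat: dict[str, int] = {"r": int(r)}
        ok = abs(amp[r]) > 0
        if ok:
            r_abs = abs(amp[r])
            for wave, ((w_lo, w_hi), sign) in windows.items():
                lo = max(r + ms2i(w_lo), 0)
                hi = min(r + ms2i(w_hi), n - 1)
                if wave == "p":
                    # keep clear of the previous beat's T wave at short RR
                    lo = max(lo, r - int(0.45 * rr_prev))
                elif wave == "t":
                    # keep clear of the next beat's P wave at short RR
                    hi = min(hi, r + int(0.62 * rr_next))
                if hi <= lo:
                    ok = False
                    break
                seg = sign * search[lo:hi + 1]
                idx = lo + int(np.argmax(seg))
                if abs(amp[idx]) < config.min_wave_rel_amplitude * r_abs:
                    ok = False
                    break
                beat[wave] = idx
        if ok:
            # QRS edges first; they then bound the P-offset and T-onset walks
            # so a neighbouring wave's shoulder cannot capture the argmax
            walk = [
                ("qrs_on", "q", -1, lambda b: ms2i(60), "wide"),
                ("qrs_off", "s", +1, lambda b: ms2i(60), "wide"),
                ("p_on", "p", -1,
                 lambda b: min(ms2i(150), b["p"] - (r - int(0.45 * rr_prev))), "narrow"),
                ("p_off", "p", +1,
                 lambda b: min(ms2i(120), b["qrs_on"] - ms2i(15) - b["p"]), "narrow"),
                ("t_on", "t", -1,
                 lambda b: min(ms2i(200), b["t"] - b["qrs_off"] - ms2i(15)), "narrow"),
                ("t_off", "t", +1,
                 lambda b: min(ms2i(250), r + rr_next - ms2i(150) - b["t"]), "narrow"),
            ]
            for name, wave, step, span_of, band in walk:
                start = beat[wave]
                limit = min(max(start + step * span_of(beat), 0), n - 1)
                edge = _first_slope_drop(deriv_abs[band], start, step, limit,
                                         config.slope_fraction, noise_floor[band],
                                         shoulder_span=ms2i(130))
                if edge is None:
                    ok = False
                    break
                beat[name] = edge
        if ok:
            order = [beat[f] for f in _ALL_FIDUCIALS]
            strict = {0, 1, 4, 5, 8, 9}
            for j in range(len(order) - 1):
                gap = order[j + 1] - order[j]
                if (gap <= 0) if j in strict else (gap < 0):
                    ok = False
                    break
        if not ok:
            n_dropped += 1
            continue
        for f in _ALL_FIDUCIALS:
            results[f].append(beat[f])
        for f in _PEAK_FIDUCIALS:
            amps[f].append(float(amp[beat[f]]))

    if n_candidates and n_dropped / n_candidates > config.max_dropped_fraction:
        raise DelineationQualityError(
            f"{n_dropped}/{n_candidates} beats dropped during delineation")
    if len(results["r"]) == 0:
        raise DelineationQualityError("no beat could be fully delineated")

    fset = FiducialSet(
        fs=fs,
        indices={f: np.asarray(results[f], dtype=int) for f in _ALL_FIDUCIALS},
        amplitudes={f: np.asarray(amps[f], dtype=float) for f in _PEAK_FIDUCIALS},
        n_dropped=n_dropped,
        n_candidates=n_candidates,
    )
    fset.validate(record_length=n)
    logger.info("%s: %d beats delineated, %d dropped",
                record.subject_id or "record", fset.n_beats, n_dropped)
    return fset
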