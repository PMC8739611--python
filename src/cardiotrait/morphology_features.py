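"""Temporal and amplitude-based ECG features from the fiducial set.

Thirty-one temporal features: min/max/mean/median/sd of the peak-to-peak
distances PR (P peak to R peak), ST (S to T) and QRS (Q to S), plus mean/sd
of the eight clinical intervals — PR interval (P onset to QRS onset), PR
segment, ST interval, ST segment, QRS complex, P wave, T wave and the
Bazett-corrected QT (QTnorm).

Fourteen amplitude features: mean/sd of six relative amplitude differences
(PRa, RQa, RSa, RTa, STa, QSa) and of the per-beat Ek index, a weighted
linear combination of the five wave amplitudes proposed as a BMI-independent
cardiac correlate of emotionality.  The published Ek weights live in
configuration, not code: the package ships a clearly labelled placeholder
(zero intercept, equal weights) that is *not* the published calibration.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .delineation import FiducialSet
from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    ParameterError,
    StructuralError,
)
from .features import (
    ALL_FEATURES,
    AMPLITUDE_FEATURES,
    HRV_FEATURES,
    TEMPORAL_FEATURES,
)

logger = logging.getLogger("cardiotrait")

#: placeholder Ek calibration — NOT the published weights (those are supplied
#: via configuration); equal weighting keeps the index well-defined for
#: pipeline runs on synthetic data.
PLACEHOLDER_EK_WEIGHTS: dict[str, float] = {
    "w_0": 0.0, "w_P": 0.2, "w_Q": 0.2, "w_R": 0.2, "w_S": 0.2, "w_T": 0.2,
}

RELATIVE_AMPLITUDE_MODES = ("r_relative", "difference", "abs_ratio")


def bazett_qtc(qt: float, rr: float, literal: bool = False) -> float:
    """Heart-rate-corrected QT: QT/sqrt(RR) (Bazett).

    ``literal=True`` computes QT/RR instead — the form the study's table
    footnote prints, where the radical was lost in typesetting — for
    sensitivity checks only.
    """
    if qt <= 0 or rr <= 0:
        raise ParameterError(f"qt and rr must be positive, got qt={qt}, rr={rr}")
    return qt / rr if literal else qt / math.sqrt(rr)


def _stats5(x: np.ndarray, prefix: str) -> dict[str, float]:
    return {
        f"{prefix}_min": float(np.min(x)),
        f"{prefix}_max": float(np.max(x)),
        f"{prefix}_mean": float(np.mean(x)),
        f"{prefix}_median": float(np.median(x)),
        f"{prefix}_sd": float(np.std(x, ddof=1)),
    }


def _stats2(x: np.ndarray, prefix: str) -> dict[str, float]:
    return {
        f"{prefix}_mean": float(np.mean(x)),
        f"{prefix}_sd": float(np.std(x, ddof=1)),
    }


def temporal_features(
    fiducials: FiducialSet,
    rpeaks: np.ndarray | None = None,
    bazett_literal: bool = False,
) -> dict[str, float]:
    """The 31 temporal features, in seconds.

    Per-beat QTc uses the RR interval immediately preceding the beat's QRS,
    taken from the full R-peak series when given (beats without a preceding
    RR are dropped for QTnorm only).
    """
    idx = fiducials.indices
    fs = fiducials.fs
    if fiducials.n_beats < 2:
        raise InsufficientDataError("temporal features need >= 2 retained beats")

    out: dict[str, float] = {}
    out.update(_stats5((idx["r"] - idx["p"]) / fs, "PR"))
    out.update(_stats5((idx["t"] - idx["s"]) / fs, "ST"))
    out.update(_stats5((idx["s"] - idx["q"]) / fs, "QRS"))

    intervals = {
        "PRinterval": (idx["qrs_on"] - idx["p_on"]) / fs,
        "PRsegment": (idx["qrs_on"] - idx["p_off"]) / fs,
        "STinterval": (idx["t_off"] - idx["qrs_off"]) / fs,
        "STsegment": (idx["t_on"] - idx["qrs_off"]) / fs,
        "QRScomplex": (idx["qrs_off"] - idx["qrs_on"]) / fs,
        "Pwave": (idx["p_off"] - idx["p_on"]) / fs,
        "Twave": (idx["t_off"] - idx["t_on"]) / fs,
    }
    for name, values in intervals.items():
        out.update(_stats2(values, name))

    qt = (idx["t_off"] - idx["qrs_on"]) / fs
    r_beats = idx["r"]
    if rpeaks is None:
        rpeaks = r_beats
    rpeaks = np.asarray(rpeaks)
    pos = np.searchsorted(rpeaks, r_beats)
    have_prev = pos > 0
    if np.count_nonzero(have_prev) < 2:
        raise InsufficientDataError("QTnorm needs >= 2 beats with a preceding RR")
    rr_prev = (r_beats[have_prev] - rpeaks[pos[have_prev] - 1]) / fs
    qtc = np.array([bazett_qtc(q, r, literal=bazett_literal)
                    for q, r in zip(qt[have_prev], rr_prev)])
    out.update(_stats2(qtc, "QTnorm"))
    return out


def relative_amplitude(a_x: float, a_y: float, a_r: float,
                       mode: str = "r_relative") -> float:
    """Relative amplitude difference between two waves, referenced to R.

    Default ``r_relative``: (a_y - a_x)/|a_r| — signed, scale-free, Lead-I
    sign preserved.  Alternatives (the study never prints its formula):
    ``difference`` (a_y - a_x, not scale-free) and ``abs_ratio``
    (|a_y|/|a_x|).
    """
    if mode == "r_relative":
        if a_r == 0:
            raise ParameterError("R amplitude is zero; relative amplitude undefined")
        return (a_y - a_x) / abs(a_r)
    if mode == "difference":
        return a_y - a_x
    if mode == "abs_ratio":
        if a_x == 0:
            raise ParameterError("reference amplitude is zero")
        return abs(a_y) / abs(a_x)
    raise ParameterError(
        f"unknown relative_amplitude_mode {mode!r}; expected one of "
        f"{RELATIVE_AMPLITUDE_MODES}")


_AMPLITUDE_PAIRS: dict[str, tuple[str, str]] = {
    # name -> (x wave, y wave); value = (a_y - a_x)/|a_R|
    "PRa": ("p", "r"),
    "RQa": ("r", "q"),
    "RSa": ("r", "s"),
    "RTa": ("r", "t"),
    "STa": ("s", "t"),
    "QSa": ("q", "s"),
}


def amplitude_features(
    fiducials: FiducialSet,
    ek_weights: dict[str, float] | None = PLACEHOLDER_EK_WEIGHTS,
    mode: str = "r_relative",
) -> dict[str, float]:
    """The 14 amplitude-based features (dimensionless).

    ``ek_weights`` must provide w_0 and w_P..w_T; beats with zero R amplitude
    are dropped from all amplitude features and logged.
    """
    if ek_weights is None:
        raise ConfigurationError(
            "ek_weights not configured: supply the published Ek calibration "
            "(keys w_0, w_P, w_Q, w_R, w_S, w_T) or use the documented "
            "placeholder PLACEHOLDER_EK_WEIGHTS")
    missing = {"w_0", "w_P", "w_Q", "w_R", "w_S", "w_T"} - set(ek_weights)
    if missing:
        raise ConfigurationError(f"ek_weights missing keys: {sorted(missing)}")

    amps = fiducials.amplitudes
    keep = amps["r"] != 0.0
    n_zero = int(np.count_nonzero(~keep))
    if n_zero:
        logger.warning("%d beats dropped from amplitude features (zero R amplitude)",
                       n_zero)
    if np.count_nonzero(keep) < 2:
        raise InsufficientDataError("amplitude features need >= 2 beats with all peaks")
    a = {w: amps[w][keep] for w in ("p", "q", "r", "s", "t")}

    out: dict[str, float] = {}
    for name, (wx, wy) in _AMPLITUDE_PAIRS.items():
        values = np.array([
            relative_amplitude(ax, ay, ar, mode=mode)
            for ax, ay, ar in zip(a[wx], a[wy], a["r"])
        ])
        out.update(_stats2(values, name))
    ek = (ek_weights["w_0"]
          + ek_weights["w_P"] * a["p"] + ek_weights["w_Q"] * a["q"]
          + ek_weights["w_R"] * a["r"] + ek_weights["w_S"] * a["s"]
          + ek_weights["w_T"] * a["t"])
    out.update(_stats2(ek, "Ek"))
    return out


def assemble_feature_vector(
    hrv: dict[str, float],
    temporal: dict[str, float],
    amplitude: dict[str, float],
) -> dict[str, float]:
    """Merge the three blocks into the canonical 62-feature vector."""
    merged = {**hrv, **temporal, **amplitude}
    for block, names in (("hrv", HRV_FEATURES), ("temporal", TEMPORAL_FEATURES),
                         ("amplitude", AMPLITUDE_FEATURES)):
        for name in names:
            if name not in merged:
                raise StructuralError(f"missing {block} feature {name!r}")
    return {name: float(merged[name]) for name in ALL_FEATURES}
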