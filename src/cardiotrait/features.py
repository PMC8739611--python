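"""Canonical registry of the 62 ECG-based features.

Three groups are computed per record:

* ``hrv`` (17): time-, frequency- and geometry-domain heart rate variability.
* ``temporal`` (31): peak-to-peak distances (min/max/mean/median/sd of PR, ST,
  QRS) plus mean/sd of the eight clinical intervals (PR interval, PR segment,
  ST interval, ST segment, QRS complex, P wave, T wave, Bazett-corrected QT).
* ``amplitude`` (14): mean/sd of the six relative amplitude differences
  referenced to the R peak, plus the Ek index (a weighted linear combination
  of P/Q/R/S/T amplitudes proposed as a cardiac correlate of emotionality).

The *clinically relevant* subset (34 features) comprises every HRV feature
except the triangular index (which is defined for 24-h ambulatory recordings,
not 2-min segments), the sixteen clinical-interval features, and the two Ek
features.
"""

from __future__ import annotations

from .exceptions import ParameterError, StructuralError

HRV_FEATURES: tuple[str, ...] = (
    "HR_mean", "RR_mean", "rmssd", "sdnn", "m_nn", "nn50", "pnn50", "sdsd",
    "HRV_index",
    "LF", "HF", "LFHF", "LFnu", "HFnu", "total_power",
    "SD1", "SD2",
)

_PEAK_DISTANCES = ("PR", "ST", "QRS")
_PEAK_SUFFIXES = ("min", "max", "mean", "median", "sd")
_CLINICAL_INTERVALS = (
    "PRinterval", "PRsegment", "STinterval", "STsegment",
    "QRScomplex", "Pwave", "Twave", "QTnorm",
)

TEMPORAL_FEATURES: tuple[str, ...] = tuple(
    f"{d}_{s}" for d in _PEAK_DISTANCES for s in _PEAK_SUFFIXES
) + tuple(f"{i}_{s}" for i in _CLINICAL_INTERVALS for s in ("mean", "sd"))

_AMPLITUDE_PAIRS = ("PRa", "RQa", "RSa", "RTa", "STa", "QSa")

AMPLITUDE_FEATURES: tuple[str, ...] = tuple(
    f"{p}_{s}" for p in _AMPLITUDE_PAIRS for s in ("mean", "sd")
) + ("Ek_mean", "Ek_sd")

ALL_FEATURES: tuple[str, ...] = HRV_FEATURES + TEMPORAL_FEATURES + AMPLITUDE_FEATURES

#: clinical subset: 16 HRV + 16 interval + 2 Ek = 34
CLINICAL_FEATURES: tuple[str, ...] = tuple(
    f for f in HRV_FEATURES if f != "HRV_index"
) + tuple(
    f"{i}_{s}" for i in _CLINICAL_INTERVALS for s in ("mean", "sd")
) + ("Ek_mean", "Ek_sd")

FEATURE_GROUPS: dict[str, str] = (
    {f: "hrv" for f in HRV_FEATURES}
    | {f: "temporal" for f in TEMPORAL_FEATURES}
    | {f: "amplitude" for f in AMPLITUDE_FEATURES}
)

FEATURE_SETS = ("all62", "no_hrv_index", "clinical34")

TRAITS: tuple[str, ...] = (
    "Honesty/Humility", "Emotionality", "Extraversion", "Agreeableness",
    "Conscientiousness", "Openness", "Disintegration",
)


def feature_set_columns(mode: str) -> tuple[str, ...]:
    """Return the canonical column list for one of the three feature sets."""
    if mode == "all62":
        return ALL_FEATURES
    if mode == "no_hrv_index":
        return tuple(f for f in ALL_FEATURES if f != "HRV_index")
    if mode == "clinical34":
        return CLINICAL_FEATURES
    raise ParameterError(
        f"unknown feature set {mode!r}; expected one of {FEATURE_SETS}"
    )


def validate_feature_names(names) -> None:
    """Check that ``names`` is exactly the canonical 62-feature set."""
    names = set(names)
    missing = set(ALL_FEATURES) - names
    extra = names - set(ALL_FEATURES)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing features: {sorted(missing)}")
        if extra:
            parts.append(f"unknown features: {sorted(extra)}")
        raise StructuralError("; ".join(parts))
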