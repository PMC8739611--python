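"""Synthetic single-lead ECG and cohort generator with exact ground truth.

The beat template is a sum of five compactly supported raised-cosine (Hann)
bumps, one per wave (P, Q, R, S, T), with disjoint supports laid out around
each R peak.  Because every bump is zero outside its support and peaks exactly
at its centre, the generator knows the true sample index of every peak and
every wave onset/offset — the oracle used to validate the delineator.

Beat-to-beat variability comes from an RR process

    RR(t) = 60/hr_mean + lf_amp*sin(2*pi*lf_freq*t) + hf_amp*sin(2*pi*hf_freq*t) + jitter

with low-frequency (default 0.10 Hz) and high-frequency (default 0.25 Hz)
components placed inside the conventional LF (0.04-0.15 Hz) and HF
(0.15-0.40 Hz) HRV bands, so spectral HRV features have known provenance.
Wave offsets are fixed relative to each R peak (no per-beat warping): planted
intervals are then exactly constant across beats, which keeps the ground
truth trivial to state and test against.

The cohort generator draws seven personality-trait scores per subject from
truncated normal distributions on [1, 5] and, for each *planted link*, couples
an ECG template knob to the trait z-score through a Gaussian copula so that
the rank correlation between the downstream extracted feature and the trait
approaches a configured Spearman rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .exceptions import ParameterError
from .signal_io import EcgRecord
from .features import TRAITS

__all__ = [
    "EcgSimConfig", "GroundTruth", "CohortSimConfig", "PlantedLink",
    "generate_ecg", "generate_cohort", "LINKABLE_FEATURES",
]


@dataclass(frozen=True)
class EcgSimConfig:
    """Knobs of the synthetic ECG generator (times in s, amplitudes in mV)."""

    hr_mean: float = 70.0          # bpm
    lf_amp: float = 0.02           # RR modulation depth at lf_freq
    hf_amp: float = 0.02           # RR modulation depth at hf_freq
    lf_freq: float = 0.10          # Hz
    hf_freq: float = 0.25          # Hz
    rr_jitter_sd: float = 0.0      # white RR jitter, s
    p_amplitude: float = 0.15
    q_amplitude: float = -0.10
    r_amplitude: float = 1.00
    s_amplitude: float = -0.20
    t_amplitude: float = 0.30
    p_duration: float = 0.10       # P-wave width (Pon..Poff)
    t_duration: float = 0.18       # T-wave width (Ton..Toff)
    pr_interval: float = 0.16      # Pon..QRSon
    qrs_duration: float = 0.08     # QRSon..QRSoff
    qt_duration: float = 0.40      # QRSon..Toff
    noise_sd: float = 0.0          # additive white noise, mV
    fs: float = 2000.0
    duration_s: float = 120.0
    seed: int = 0

    def validate(self) -> None:
        if not (30.0 <= self.hr_mean <= 200.0):
            raise ParameterError(f"hr_mean must be in [30, 200] bpm, got {self.hr_mean}")
        for name in ("p_duration", "t_duration", "pr_interval", "qrs_duration",
                     "qt_duration"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.p_duration > self.pr_interval:
            raise ParameterError("p_duration cannot exceed pr_interval")
        if self.qt_duration < self.qrs_duration + self.t_duration:
            raise ParameterError(
                "qt_duration must cover qrs_duration + t_duration "
                f"({self.qt_duration} < {self.qrs_duration} + {self.t_duration})"
            )
        span = self.pr_interval + self.qt_duration  # Pon..Toff
        if span >= 60.0 / self.hr_mean:
            raise ParameterError(
                f"beat template span {span:.3f}s does not fit the mean RR "
                f"{60.0 / self.hr_mean:.3f}s"
            )


_FIDUCIALS = ("p_on", "p", "p_off", "qrs_on", "q", "r", "s", "qrs_off",
              "t_on", "t", "t_off")


@dataclass
class GroundTruth:
    """True per-beat fiducial sample indices and the true RR series."""

    p_on: np.ndarray
    p: np.ndarray
    p_off: np.ndarray
    qrs_on: np.ndarray
    q: np.ndarray
    r: np.ndarray
    s: np.ndarray
    qrs_off: np.ndarray
    t_on: np.ndarray
    t: np.ndarray
    t_off: np.ndarray
    rr: np.ndarray  # seconds

    @property
    def n_beats(self) -> int:
        return len(self.r)

    def validate(self) -> None:
        cols = [getattr(self, f) for f in _FIDUCIALS]
        stacked = np.stack(cols)  # (11, n_beats)
        # Pon < P < Poff <= QRSon < Q < R < S < QRSoff <= Ton < T < Toff
        strict = [0, 1, 3, 4, 5, 6, 8, 9]
        for j in range(stacked.shape[0] - 1):
            diff = stacked[j + 1] - stacked[j]
            ok = (diff > 0) if j in strict else (diff >= 0)
            if not ok.all():
                raise ParameterError(
                    f"fiducial ordering violated between {_FIDUCIALS[j]} and "
                    f"{_FIDUCIALS[j + 1]}"
                )
        if not (np.diff(self.r) > 0).all():
            raise ParameterError("R indices must strictly increase")
        if (self.rr <= 0).any():
            raise ParameterError("RR entries must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f: getattr(self, f) for f in _FIDUCIALS})


def _hann_bump(n_half: int) -> np.ndarray:
    """Unit-amplitude raised-cosine bump over 2*n_half+1 samples."""
    u = np.arange(-n_half, n_half + 1) / n_half
    return np.cos(0.5 * np.pi * u) ** 2


def _wave_layout(cfg: EcgSimConfig) -> dict[str, tuple[float, float, float]]:
    """Per wave: (centre offset from R, half-width, amplitude), in seconds/mV.

    The QRS complex splits its duration 1:2:1 over Q, R, S with adjoining
    supports, so the R bump peaks exactly at the beat origin and Q/S minima
    sit at known offsets.
    """
    h_r = cfg.qrs_duration / 4.0
    h_q = cfg.qrs_duration / 8.0
    h_s = cfg.qrs_duration / 8.0
    qrs_on = -cfg.qrs_duration / 2.0
    qrs_off = cfg.qrs_duration / 2.0
    p_on = qrs_on - cfg.pr_interval
    t_off = qrs_on + cfg.qt_duration
    return {
        "p": (p_on + cfg.p_duration / 2.0, cfg.p_duration / 2.0, cfg.p_amplitude),
        "q": (qrs_on + h_q, h_q, cfg.q_amplitude),
        "r": (0.0, h_r, cfg.r_amplitude),
        "s": (qrs_off - h_s, h_s, cfg.s_amplitude),
        "t": (t_off - cfg.t_duration / 2.0, cfg.t_duration / 2.0, cfg.t_amplitude),
    }


def generate_ecg(config: EcgSimConfig) -> tuple[EcgRecord, GroundTruth]:
    """Synthesise one record plus its exact fiducial ground truth.

    Deterministic given ``config.seed``.  With ``noise_sd=0`` the sample at
    each true peak index equals the configured wave amplitude exactly,
    because wave centres and edges are snapped to the sample grid.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n_total = int(round(config.duration_s * fs))

    layout = _wave_layout(config)
    qrs_on_off = -config.qrs_duration / 2.0
    pre_span = config.pr_interval - qrs_on_off   # Pon..R
    post_span = qrs_on_off + config.qt_duration  # R..Toff

    rr_mean = 60.0 / config.hr_mean
    r_times: list[float] = []
    rr_true: list[float] = []
    t = pre_span + 2.0 / fs
    while t + post_span + 2.0 / fs < config.duration_s:
        r_times.append(t)
        rr = (rr_mean
              + config.lf_amp * math.sin(2.0 * math.pi * config.lf_freq * t)
              + config.hf_amp * math.sin(2.0 * math.pi * config.hf_freq * t))
        if config.rr_jitter_sd > 0:
            rr += config.rr_jitter_sd * rng.standard_normal()
        rr = max(rr, pre_span + post_span + 4.0 / fs)
        rr_true.append(rr)
        t += rr
    if not r_times:
        raise ParameterError("duration too short to fit a single beat")
    rr_true = rr_true[:-1]  # last RR has no following beat

    r_idx = np.round(np.asarray(r_times) * fs).astype(int)

    signal = np.zeros(n_total)
    gt_cols: dict[str, list[int]] = {f: [] for f in _FIDUCIALS}
    # sample-grid-snapped wave supports, shared across beats
    bumps = {}
    for wave, (centre, half, amp) in layout.items():
        c = int(round(centre * fs))
        h = max(int(round(half * fs)), 1)
        bumps[wave] = (c, h, amp * _hann_bump(h))

    edge_cols = {
        "p": ("p_on", "p_off"), "t": ("t_on", "t_off"),
    }
    for r0 in r_idx:
        for wave in ("p", "q", "r", "s", "t"):
            c, h, bump = bumps[wave]
            lo, hi = r0 + c - h, r0 + c + h
            if lo < 0 or hi >= n_total:
                raise ParameterError("beat support out of record bounds")
            signal[lo:hi + 1] += bump
            gt_cols[wave].append(r0 + c)
            if wave in edge_cols:
                on, off = edge_cols[wave]
                gt_cols[on].append(lo)
                gt_cols[off].append(hi)
        gt_cols["qrs_on"].append(r0 + bumps["q"][0] - bumps["q"][1])
        gt_cols["qrs_off"].append(r0 + bumps["s"][0] + bumps["s"][1])

    if config.noise_sd > 0:
        signal = signal + config.noise_sd * rng.standard_normal(n_total)

    record = EcgRecord(signal, fs=fs, subject_id=f"sim{config.seed}")
    truth = GroundTruth(
        **{f: np.asarray(gt_cols[f], dtype=int) for f in _FIDUCIALS},
        rr=np.asarray(rr_true, dtype=float),
    )
    truth.validate()
    return record, truth


# ---------------------------------------------------------------------------
# cohort generation

#: trait descriptive statistics of the study sample used as generator defaults
DEFAULT_TRAIT_STATS: dict[str, tuple[float, float]] = {
    "Honesty/Humility": (3.57, 0.66),
    "Emotionality": (3.47, 0.67),
    "Extraversion": (3.34, 0.71),
    "Agreeableness": (3.13, 0.71),
    "Conscientiousness": (3.67, 0.67),
    "Openness": (3.85, 0.59),
    "Disintegration": (2.07, 0.50),
}

#: feature -> (EcgSimConfig knob, sign of the feature response to the knob)
LINKABLE_FEATURES: dict[str, tuple[str, float]] = {
    "HR_mean": ("hr_mean", +1.0),
    "RR_mean": ("hr_mean", -1.0),
    "m_nn": ("hr_mean", -1.0),
    "RTa_mean": ("t_amplitude", +1.0),
    "STa_mean": ("t_amplitude", +1.0),
    "QTnorm_mean": ("qt_duration", +1.0),
    "PRinterval_mean": ("pr_interval", +1.0),
    "Pwave_mean": ("p_duration", +1.0),
    "Twave_mean": ("t_duration", +1.0),
    "QRScomplex_mean": ("qrs_duration", +1.0),
    "PRa_mean": ("p_amplitude", -1.0),
    "rmssd": ("hf_amp", +1.0),
    "sdsd": ("hf_amp", +1.0),
    "SD1": ("hf_amp", +1.0),
    "HF": ("hf_amp", +1.0),
    "sdnn": ("hf_amp", +1.0),
    "LF": ("lf_amp", +1.0),
}

#: every template knob that varies across subjects:
#: knob -> (per-z-score scale, lower bound, upper bound)
_KNOB_SPECS: dict[str, tuple[float, float, float]] = {
    "hr_mean": (8.0, 45.0, 110.0),
    "p_amplitude": (0.03, 0.08, 0.25),
    "q_amplitude": (0.02, -0.18, -0.05),
    "r_amplitude": (0.10, 0.70, 1.40),
    "s_amplitude": (0.04, -0.35, -0.08),
    "t_amplitude": (0.08, 0.10, 0.60),
    "qt_duration": (0.020, 0.32, 0.48),
    "pr_interval": (0.015, 0.12, 0.22),
    "p_duration": (0.010, 0.06, 0.12),
    "t_duration": (0.020, 0.12, 0.22),
    "qrs_duration": (0.008, 0.06, 0.11),
    "hf_amp": (0.008, 0.002, 0.045),
    "lf_amp": (0.008, 0.002, 0.045),
}


@dataclass(frozen=True)
class PlantedLink:
    """A monotone trait-feature association with a target Spearman rho."""

    trait: str
    feature: str
    rho: float

    def validate(self) -> None:
        if self.trait not in TRAITS:
            raise ParameterError(f"unknown trait {self.trait!r}")
        if self.feature not in LINKABLE_FEATURES:
            raise ParameterError(
                f"feature {self.feature!r} cannot be planted; mappable features: "
                f"{sorted(LINKABLE_FEATURES)}"
            )
        if not -1.0 <= self.rho <= 1.0:
            raise ParameterError("|rho| must be <= 1")


@dataclass(frozen=True)
class CohortSimConfig:
    n_subjects: int = 71
    trait_stats: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_STATS))
    planted_links: tuple[PlantedLink, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        for link in self.planted_links:
            link.validate()


def _truncnorm_scores(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    a, b = (1.0 - mean) / sd, (5.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(
    config: CohortSimConfig,
    ecg_defaults: EcgSimConfig | None = None,
    with_ecg: bool = True,
) -> tuple[pd.DataFrame, list[EcgRecord], list[GroundTruth]]:
    """Draw a cohort of trait scores and per-subject ECGs.

    Every linkable ECG knob receives unit-variance inter-subject variability
    at its documented scale; a planted link replaces part of that variability
    with the trait z-score via a Gaussian copula (Pearson r = 2*sin(pi*rho/6)
    to hit the requested Spearman rho in the bivariate-normal limit).
    """
    config.validate()
    base = ecg_defaults if ecg_defaults is not None else EcgSimConfig()
    base.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    scores = pd.DataFrame(
        {trait: _truncnorm_scores(m, sd, n, rng)
         for trait, (m, sd) in config.trait_stats.items()},
        index=[f"S{i:03d}" for i in range(n)],
    )
    scores.index.name = "subject_id"

    # latent z per knob: independent noise unless a link claims the knob
    knob_z = {knob: rng.standard_normal(n) for knob in _KNOB_SPECS}
    links_by_knob: dict[str, PlantedLink] = {}
    for link in config.planted_links:
        knob, _ = LINKABLE_FEATURES[link.feature]
        if knob in links_by_knob:
            raise ParameterError(
                f"links {links_by_knob[knob]} and {link} both drive knob {knob!r}")
        links_by_knob[knob] = link

    for knob, link in links_by_knob.items():
        _, sign = LINKABLE_FEATURES[link.feature]
        m, sd = config.trait_stats[link.trait]
        z_trait = (scores[link.trait].to_numpy() - m) / sd
        r = 2.0 * math.sin(math.pi * link.rho / 6.0) * sign
        r = float(np.clip(r, -1.0, 1.0))
        knob_z[knob] = r * z_trait + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)

    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    records: list[EcgRecord] = []
    truths: list[GroundTruth] = []
    if not with_ecg:
        return scores, records, truths
    for i, subject in enumerate(scores.index):
        knobs = {}
        for knob, (scale, lo, hi) in _KNOB_SPECS.items():
            value = getattr(base, knob) + scale * knob_z[knob][i]
            knobs[knob] = float(np.clip(value, lo, hi))
        cfg = replace(base, seed=int(child_seeds[i]), **knobs)
        # re-validate combined knob draws; nudge QT if the draw broke the nesting
        if cfg.qt_duration < cfg.qrs_duration + cfg.t_duration:
            cfg = replace(cfg, qt_duration=cfg.qrs_duration + cfg.t_duration + 0.02)
        if cfg.p_duration > cfg.pr_interval - 0.03:  # keep PR segment >= 30 ms
            cfg = replace(cfg, p_duration=cfg.pr_interval - 0.03)
        hr_fit = 0.95 * 60.0 / (cfg.pr_interval + cfg.qt_duration)
        if cfg.hr_mean > hr_fit:
            cfg = replace(cfg, hr_mean=hr_fit)
        record, truth = generate_ecg(cfg)
        record = EcgRecord(record.samples, record.fs, subject_id=subject)
        records.append(record)
        truths.append(truth)
    return scores, records, truths
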