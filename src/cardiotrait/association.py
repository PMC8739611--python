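"""Spearman correlation screening between top-ranked features and traits.

For each trait, the top-k features by random-forest importance are correlated
with both the raw 1-5 trait score and its five-level category.  Significance
is flagged at the nominal .05/.01/.001 thresholds without multiplicity
correction (the screening convention this pipeline mirrors); an optional
Benjamini-Hochberg column is available as an extension.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .exceptions import ParameterError, UndefinedCorrelationError
from .trait_pipeline import bin_scores

logger = logging.getLogger("cardiotrait")

_EXACT_N_MAX = 9


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise UndefinedCorrelationError("constant input: rank correlation undefined")
    return float(rx @ ry) / denom


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with midrank ties and a two-sided p-value.

    p comes from the t-approximation for n >= 10 and from exact enumeration
    of all rank permutations for n <= 9 (the approximation is poor there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 4:
        raise ParameterError("need at least 4 paired observations")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = _rho_of_ranks(rx, ry)

    if n <= _EXACT_N_MAX:
        perms = np.array(list(permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        rhos = (rx_c[perms] @ ry_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            stat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(t_dist.sf(abs(stat), df=n - 2))
    return rho, max(min(p, 1.0), 1e-300)


def sig_flag(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (extension; off by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_pos in range(n - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, p[i] * n / (rank_pos + 1))
        adj[i] = running
    return adj


@dataclass(frozen=True)
class CorrelationRecord:
    trait: str
    feature: str
    target_kind: str   # "raw_score" | "category"
    rho: float
    p_value: float
    sig_flag: str


def correlate_top_features(
    features: pd.DataFrame,
    traits: pd.DataFrame,
    trait: str,
    importances: list[tuple[str, float]],
    k: int = 10,
    include_bh: bool = False,
) -> pd.DataFrame:
    """Correlate the top-k ranked features with the trait score and category.

    Returns one row per (feature, target_kind); columns trait, feature,
    target_kind, rho, p, flag (+ p_bh when requested).
    """
    if trait not in traits.columns:
        raise ParameterError(f"trait {trait!r} not in trait table")
    if k > len(importances):
        logger.warning("k=%d exceeds %d ranked features; truncating", k,
                       len(importances))
        k = len(importances)
    top = [name for name, _ in importances[:k]]
    scores = traits[trait].dropna()
    common = features.index.intersection(scores.index)
    raw = scores.loc[common].to_numpy()
    cats = bin_scores(raw).astype(float)

    rows = []
    for feature in top:
        x = features.loc[common, feature].to_numpy(dtype=float)
        for kind, target in (("raw_score", raw), ("category", cats)):
            try:
                rho, p = spearman(x, target)
            except UndefinedCorrelationError:
                rho, p = float("nan"), float("nan")
            rows.append(CorrelationRecord(trait, feature, kind, rho, p,
                                          sig_flag(p) if np.isfinite(p) else "ns"))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if include_bh:
        finite = df["p_value"].notna()
        df.loc[finite, "p_bh"] = bh_adjust(df.loc[finite, "p_value"].to_numpy())
    return df
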