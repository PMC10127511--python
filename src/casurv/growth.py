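"""Tumor volume arithmetic and growth-curve comparison.

Caliper width/length pairs convert to volume via the ellipsoid formula
V = pi/6 * W^2 * L after subtracting the skin thickness (default 2 mm) from
each dimension; volume-versus-day series per treatment arm are fit to
second-order polynomials and compared with the extra sum-of-squares F-test
(pooled single-curve fit against separate per-arm fits).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def tumor_volume(width_mm: float, length_mm: float, skin_mm: float = 2.0) -> float:
    """Ellipsoid tumor volume in microliters with skin-thickness correction.

    Dimensions are orientation-normalized (W <= L); V = pi/6 * (W-s)^2 *
    (L-s) with negative corrected dimensions clamped to zero (a palpable but
    sub-skin-thickness tumor has zero estimated volume; a warning is
    emitted).  Raw dimensions must be positive.
    """
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("raw tumor dimensions must be > 0")
    w, ln = sorted((float(width_mm), float(length_mm)))
    wc = max(w - skin_mm, 0.0)
    lc = max(ln - skin_mm, 0.0)
    if wc == 0.0 or lc == 0.0:
        warnings.warn(
            f"dimension at or below skin thickness ({skin_mm} mm); volume set to 0",
            stacklevel=2,
        )
        return 0.0
    return np.pi / 6.0 * wc**2 * lc


def volumes_from_measurements(df: pd.DataFrame, skin_mm: float = 2.0) -> pd.DataFrame:
    """Add a ``volume_uL`` column to a (animal_id, day, width_mm, length_mm) table."""
    out = df.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["volume_uL"] = [
            tumor_volume(w, ln, skin_mm) for w, ln in zip(df["width_mm"], df["length_mm"])
        ]
    return out


@dataclass
class GrowthFit:
    """Per-arm quadratic fits and the extra sum-of-squares F comparison."""

    coef_a: np.ndarray  # (c0, c1, c2), ascending powers
    coef_b: np.ndarray
    coef_pooled: np.ndarray
    ss_separate: float
    df_separate: int
    ss_pooled: float
    df_pooled: int
    f_statistic: float
    p_value: float


def _quadfit(day: np.ndarray, vol: np.ndarray) -> tuple[np.ndarray, float]:
    if np.unique(day).size < 3:
        raise ValueError("quadratic fit needs >=3 distinct days (rank-deficient design)")
    coef_desc = np.polyfit(day, vol, 2)
    resid = vol - np.polyval(coef_desc, day)
    return coef_desc[::-1], float((resid**2).sum())


def fit_growth_and_compare(arm_a: pd.DataFrame, arm_b: pd.DataFrame) -> GrowthFit:
    """Quadratic growth fits per arm, compared by extra sum-of-squares F-test.

    Each arm is a DataFrame with ``day`` and ``volume_uL`` columns; all
    measurements of an arm are pooled into one residual (per-arm pooled
    curves).  The null (pooled) model fits one quadratic to both arms;
    F = ((SS_pooled - SS_sep)/3) / (SS_sep/df_sep), p from F(3, df_sep).
    """
    da, va = arm_a["day"].to_numpy(float), arm_a["volume_uL"].to_numpy(float)
    db, vb = arm_b["day"].to_numpy(float), arm_b["volume_uL"].to_numpy(float)
    for name, d in (("A", da), ("B", db)):
        if np.unique(d).size < 4:
            raise ValueError(f"arm {name}: need >=4 distinct time points")
    coef_a, ss_a = _quadfit(da, va)
    coef_b, ss_b = _quadfit(db, vb)
    dp = np.concatenate([da, db])
    vp = np.concatenate([va, vb])
    coef_p, ss_p = _quadfit(dp, vp)
    ss_sep = ss_a + ss_b
    df_sep = len(dp) - 6
    df_pooled = len(dp) - 3
    if df_sep <= 0:
        raise ValueError("not enough measurements for separate fits")
    extra_df = df_pooled - df_sep  # = 3 shared coefficients
    f_stat = ((ss_p - ss_sep) / extra_df) / (ss_sep / df_sep)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, extra_df, df_sep))
    return GrowthFit(
        coef_a=coef_a,
        coef_b=coef_b,
        coef_pooled=coef_p,
        ss_separate=ss_sep,
        df_separate=df_sep,
        ss_pooled=ss_p,
        df_pooled=df_pooled,
        f_statistic=float(f_stat),
        p_value=p,
    )


def fit_growth_per_animal(arm: pd.DataFrame) -> pd.DataFrame:
    """Per-animal quadratic coefficients (the non-pooled option)."""
    rows = []
    for animal, sub in arm.groupby("animal_id"):
        coef, ss = _quadfit(sub["day"].to_numpy(float), sub["volume_uL"].to_numpy(float))
        rows.append({"animal_id": animal, "c0": coef[0], "c1": coef[1], "c2": coef[2], "ss": ss})
    return pd.DataFrame(rows)


def fold_increase(volumes) -> float:
    """Final over initial volume of a series."""
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two volumes")
    if v[0] <= 0:
        raise ValueError("initial volume must be > 0")
    return float(v[-1] / v[0])
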