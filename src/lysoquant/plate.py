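"""Plate-based readout calculators.

Deterministic formulas for the bench assays: LDH-release cytotoxicity,
propidium-iodide death fraction, luciferase autophagic-flux ratio,
cytosolic-vs-total hydrolase leakage, drug-combination synergy excess and
time-course AUC. Input absorbances are expected blank- and 690 nm-corrected;
:func:`correct_absorbance` performs that preprocessing and clamps negative
corrected values to zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "correct_absorbance",
    "cytotoxicity_pct",
    "pi_death_pct",
    "flux_ratio",
    "leakage_fraction",
    "synergy_excess",
    "timecourse_auc",
]


def correct_absorbance(a_signal, a_background=0.0, blank=0.0):
    """Subtract the 690 nm background and blank-well readings.

    Negative corrected absorbances (possible with noisy blanks) are clamped
    to 0 so downstream percentages stay in [0, 100].
    """
    corrected = np.asarray(a_signal, dtype=float) - np.asarray(a_background, dtype=float) - blank
    return np.maximum(corrected, 0.0)


def cytotoxicity_pct(abs_medium, abs_lysate):
    """LDH-release cytotoxicity: ``100 * medium / (medium + lysate)``.

    Inputs are corrected absorbances (medium = LDH released by dead cells,
    lysate = LDH retained by surviving cells). Negative inputs clamp to 0; a
    non-positive total yields NaN rather than an error so plate maps with
    empty wells survive. Vectorized.
    """
    med = np.maximum(np.asarray(abs_medium, dtype=float), 0.0)
    lys = np.maximum(np.asarray(abs_lysate, dtype=float), 0.0)
    total = med + lys
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * med / np.where(total > 0, total, 1.0), np.nan)
    return np.clip(pct, 0.0, 100.0) if pct.ndim else float(np.clip(pct, 0.0, 100.0))


def pi_death_pct(n_pi_positive: int, n_total: int) -> float:
    """Percent PI-positive (membrane-permeabilized) cells.

    Warns below the 500-cells-per-slide sampling convention.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_pi_positive > n_total:
        raise ValueError("positive count exceeds total count")
    if n_pi_positive < 0:
        raise ValueError("counts must be non-negative")
    if n_total < 500:
        warnings.warn(
            f"only {n_total} cells counted (< 500); estimate may be noisy",
            stacklevel=2,
        )
    return 100.0 * n_pi_positive / n_total


def flux_ratio(series_wt: pd.Series, series_mut: pd.Series) -> pd.DataFrame:
    """Autophagic-flux ratio time course, normalized to time 0.

    ``series_wt`` holds luminescence of the degradable reporter and
    ``series_mut`` the non-degradable mutant, both indexed by time (h) on the
    same grid. Returns ``R(t) = 100 * [wt(t)/mut(t)] / [wt(0)/mut(0)]`` so
    the first time point is 100% by construction; active autophagy lowers R.
    Zero mutant luminescence yields NaN at that time point.
    """
    wt = pd.Series(series_wt, dtype=float)
    mut = pd.Series(series_mut, dtype=float)
    if not wt.index.equals(mut.index):
        raise ValueError("wild-type and mutant series must share the same time grid")
    if len(wt) < 1:
        raise ValueError("empty series")
    if wt.iloc[0] <= 0 or mut.iloc[0] <= 0:
        raise ValueError("luminescence at time 0 must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mut.to_numpy() != 0, wt.to_numpy() / mut.to_numpy(), np.nan)
    r0 = r[0]
    return pd.DataFrame({"time_h": wt.index.to_numpy(dtype=float), "ratio_pct": 100.0 * r / r0})


def leakage_fraction(vmax_cytosolic, vmax_total, ldh_cytosolic, ldh_total):
    """Cytosolic hydrolase activity as percent of total, LDH-normalized.

    Both the cytosolic and total hydrolase Vmax are divided by the matching
    LDH activity (correcting for extraction efficiency and cell number)
    before taking the ratio: ``100 * (vmax_cyt/ldh_cyt) / (vmax_tot/ldh_tot)``.
    Zero denominators yield NaN.
    """
    vc = np.asarray(vmax_cytosolic, dtype=float)
    vt = np.asarray(vmax_total, dtype=float)
    lc = np.asarray(ldh_cytosolic, dtype=float)
    lt = np.asarray(ldh_total, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.where(lc > 0, vc / np.where(lc > 0, lc, 1.0), np.nan)
        den = np.where(lt > 0, vt / np.where(lt > 0, lt, 1.0), np.nan)
        pct = np.where(den > 0, 100.0 * num / np.where(den > 0, den, 1.0), np.nan)
    return float(pct) if pct.ndim == 0 else pct


def synergy_excess(death_combo, death_a, death_b, death_vehicle=0.0):
    """Excess cell death over the additive expectation, in percentage points.

    All deaths are vehicle-corrected before summing the single-drug effects:
    ``excess = (combo - vehicle) - [(a - vehicle) + (b - vehicle)]``.
    Positive excess indicates supra-additive (synergistic) killing.
    """
    for v in np.broadcast_arrays(
        np.asarray(death_combo, float),
        np.asarray(death_a, float),
        np.asarray(death_b, float),
        np.asarray(death_vehicle, float),
    ):
        if np.any((v < 0) | (v > 100)):
            raise ValueError("death percentages must lie in [0, 100]")
    combo = np.asarray(death_combo, dtype=float)
    a = np.asarray(death_a, dtype=float)
    b = np.asarray(death_b, dtype=float)
    veh = np.asarray(death_vehicle, dtype=float)
    excess = (combo - veh) - ((a - veh) + (b - veh))
    return float(excess) if excess.ndim == 0 else excess


def timecourse_auc(times, values) -> float:
    """Trapezoidal area under a time course (value * h).

    Exact for piecewise-linear curves and additive over abutting intervals;
    times must be strictly increasing (no interpolation or extrapolation).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be 1D and equally long")
    if t.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(y, t))
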