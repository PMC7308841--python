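"""Goodness-of-fit statistics for observed vs. predicted trait values.

Given paired series of observed (reference) and predicted (cloud-derived)
trait values, this module computes:

* **R^2** — in the default ``standard`` mode, ``1 - SS_res / SS_tot``;
  the ``literal`` mode returns the raw ratio ``SS_res / SS_tot`` (a
  residual-over-total convention under which 0 is a perfect fit) and the
  two modes sum to one by construction.
* **rRMSE** — RMSE divided by the observed mean, in percent, with the
  customary accuracy bands: excellent (<= 10%), good (10–20%], fair
  (20–30%], poor (> 30%).
* **AIC** — ``2k - 2 ln(L_hat)`` under a Gaussian residual likelihood at
  the maximum-likelihood variance, i.e. ``-2 ln(L_hat) = n ln(2 pi s2) + n``
  with ``s2 = SS_res / n``; ``k`` defaults to 1 (the residual variance).
* **Sw** — a completeness weighting ``Sw = S * (1 - mv / n)`` that
  penalizes statistics computed on reconstructions with missing values.

The grid experiment sweeps the synthetic degradation presets (image
quantity x quality) and reports the per-trait statistics per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .core import TraitRecord
from .io import traits_to_frame
from .morphometry import ExtractionConfig, extract_traits

#: sentinel returned by :func:`aic` when residuals are exactly zero (the
#: Gaussian log-likelihood diverges); explicit rather than a silent number.
AIC_PERFECT_FIT = float("-inf")

BANDS = ("excellent", "good", "fair", "poor")


class EvaluationError(ValueError):
    pass


def _pair(observed, predicted):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise EvaluationError("observed and predicted must be 1-D of equal length")
    if len(o) < 2:
        raise EvaluationError("need at least 2 observations")
    return o, p


def r_squared(observed, predicted, mode: str = "standard") -> float:
    """Coefficient of determination of predictions against observations.

    ``standard``: 1 - SS_res/SS_tot.  ``literal``: the raw SS_res/SS_tot
    ratio (0 = perfect).  A constant observed series has no variance to
    explain and raises.
    """
    o, p = _pair(observed, predicted)
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0:
        raise EvaluationError("observed series is constant: R^2 is undefined")
    ratio = float(((o - p) ** 2).sum()) / ss_tot
    if mode == "literal":
        return ratio
    if mode == "standard":
        return 1.0 - ratio
    raise EvaluationError(f"unknown R^2 mode {mode!r}")


def rrmse(observed, predicted) -> float:
    """Relative RMSE in percent: RMSE(P, O) / mean(O) * 100."""
    o, p = _pair(observed, predicted)
    mean = float(o.mean())
    if mean == 0:
        raise EvaluationError("observed mean is zero: rRMSE is undefined")
    return math.sqrt(float(((p - o) ** 2).mean())) / mean * 100.0


def aic(observed, predicted, k: int = 1) -> float:
    """Akaike Information Criterion of the prediction residuals.

    Gaussian residual likelihood at the ML variance gives
    ``AIC = n ln(2 pi SS/n) + n + 2k``.  Zero residuals return
    :data:`AIC_PERFECT_FIT`.
    """
    o, p = _pair(observed, predicted)
    n = len(o)
    ss = float(((p - o) ** 2).sum())
    if ss == 0:
        return AIC_PERFECT_FIT
    return n * math.log(2.0 * math.pi * ss / n) + n + 2.0 * k


def weight_adjust(statistic: float, mv: int, n: int) -> float:
    """Completeness weighting Sw = S * (1 - mv/n) for mv missing of n."""
    if n <= 0 or mv < 0 or mv > n:
        raise EvaluationError(f"need 0 <= mv <= n with n > 0, got mv={mv}, n={n}")
    return statistic * (1.0 - mv / n)


def accuracy_band(rrmse_pct: float) -> str:
    """Accuracy class of an rRMSE value: excellent <= 10 < good <= 20 <
    fair <= 30 < poor."""
    if rrmse_pct < 0:
        raise EvaluationError("rRMSE cannot be negative")
    if rrmse_pct <= 10.0:
        return "excellent"
    if rrmse_pct <= 20.0:
        return "good"
    if rrmse_pct <= 30.0:
        return "fair"
    return "poor"


# ---------------------------------------------------------------------------
# trait-table evaluation
# ---------------------------------------------------------------------------

@dataclass
class FitStats:
    """Per-trait goodness of fit, before and after Sw completeness weighting."""

    trait: str
    n: int                    # observed values considered (complete + missing)
    mv: int                   # predictions missing for an observed value
    r2: float
    r2_literal: float         # residual/total ratio convention (0 = perfect)
    rrmse: float
    aic: float
    k: int
    r2_weighted: float
    rrmse_weighted: float
    aic_weighted: float
    band: str                 # from the weighted rRMSE
    sw_applied: bool


def evaluate_series(observed, predicted, mv: int = 0, k: int = 1,
                    trait: str = "trait", weight_aic: bool = True) -> FitStats:
    """Full statistics on one complete-pair series with ``mv`` missing values."""
    o, p = _pair(observed, predicted)
    n = len(o) + mv
    r2 = r_squared(o, p)
    rr = rrmse(o, p)
    a = aic(o, p, k=k)
    rr_w = weight_adjust(rr, mv, n)
    return FitStats(trait=trait, n=n, mv=mv, r2=r2,
                    r2_literal=r_squared(o, p, mode="literal"),
                    rrmse=rr, aic=a, k=k,
                    r2_weighted=weight_adjust(r2, mv, n),
                    rrmse_weighted=rr_w,
                    aic_weighted=weight_adjust(a, mv, n) if weight_aic else a,
                    band=accuracy_band(rr_w), sw_applied=mv > 0)


def evaluate_traits(observed: pd.DataFrame, predicted: pd.DataFrame, k: int = 1,
                    weight_aic: bool = True) -> pd.DataFrame:
    """Join observed and predicted long-format trait tables and score each trait.

    Both tables need columns ``plant_id, trait, organ_index, value``.  Rows
    are joined on the first three; an observed row whose predicted value is
    absent (no row, or NaN) counts as a missing value for the Sw weighting.
    Returns one row of :class:`FitStats` fields per trait.
    """
    key = ["plant_id", "trait", "organ_index"]
    overlap = observed[key].merge(predicted[key], on=key, how="inner")
    if overlap.empty:
        raise EvaluationError("observed and predicted tables share no keys")
    merged = observed.merge(predicted, on=key, how="left", suffixes=("_obs", "_pred"))
    merged = merged[~merged["value_obs"].isna()]
    rows = []
    for trait, grp in merged.groupby("trait", sort=False):
        missing = grp["value_pred"].isna()
        mv = int(missing.sum())
        complete = grp[~missing]
        if len(complete) < 2:
            continue
        stats = evaluate_series(complete["value_obs"], complete["value_pred"],
                                mv=mv, k=k, trait=str(trait), weight_aic=weight_aic)
        rows.append(stats.__dict__)
    if not rows:
        raise EvaluationError("no trait had at least 2 complete observation pairs")
    return pd.DataFrame(rows)


def records_to_frame(records: Sequence[TraitRecord]) -> pd.DataFrame:
    return pd.concat([traits_to_frame(r) for r in records], ignore_index=True)


# ---------------------------------------------------------------------------
# quantity x quality grid experiment
# ---------------------------------------------------------------------------

def evaluate_grid(archetype: str, quantities: Sequence[int] = (90, 45, 30),
                  qualities: Sequence[str] = ("H", "M", "L"), reps: int = 5,
                  k: int = 1, seed: int = 0,
                  config: Optional[ExtractionConfig] = None,
                  merge_diameters: bool = True) -> pd.DataFrame:
    """Trait-recovery statistics over the image quantity x quality grid.

    For each cell, ``reps`` synthetic plants are generated, degraded with
    the cell's presets, re-measured, and scored against their ground truth.
    The same plants and the same per-point thinning/jitter fields are used
    in every cell (common random numbers), so cells differ only by the
    degradation level — the paired design the factor comparison needs.
    With ``merge_diameters`` the three stem diameters are pooled into one
    ``D`` series, the way sparse diameter measurements are usually reported.
    """
    if reps < 2:
        raise EvaluationError("grid experiment needs reps >= 2")
    base = np.random.default_rng((seed, 0xC0FFEE))
    plant_seeds = base.integers(0, 2 ** 31 - 1, size=reps)
    degrade_seeds = base.integers(0, 2 ** 31 - 1, size=reps)
    plants = []
    for r in range(reps):
        spec = synthetic.default_spec(archetype, seed=int(plant_seeds[r]))
        plant, truth = synthetic.generate_plant(spec)
        truth.record.plant_id = f"{archetype}_{r}"
        plants.append((plant, truth))
    observed = records_to_frame([t.record for _, t in plants])
    if merge_diameters:
        observed = _merge_diameters(observed)

    rows = []
    for quality in qualities:
        for quantity in quantities:
            predicted = []
            for r, (plant, truth) in enumerate(plants):
                deg = synthetic.degradation_for(quality, int(quantity),
                                                seed=int(degrade_seeds[r]))
                rec = extract_traits(synthetic.degrade(plant, deg), config=config,
                                     plant_id=f"{archetype}_{r}")
                predicted.append(rec)
            pred_df = records_to_frame(predicted)
            if merge_diameters:
                pred_df = _merge_diameters(pred_df)
            stats = evaluate_traits(observed, pred_df, k=k)
            stats.insert(0, "quality", quality)
            stats.insert(0, "quantity", int(quantity))
            rows.append(stats)
    return pd.concat(rows, ignore_index=True)


def _merge_diameters(df: pd.DataFrame) -> pd.DataFrame:
    """Pool BD/HD/AD rows into a single 'D' trait (organ 1, 2, 3)."""
    df = df.copy()
    is_d = df["trait"].isin(["BD", "HD", "AD"])
    organ = df.loc[is_d, "trait"].map({"BD": 1, "HD": 2, "AD": 3})
    df.loc[is_d, "organ_index"] = organ
    df.loc[is_d, "trait"] = "D"
    return df
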