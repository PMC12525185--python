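"""Validation statistics and diagnostics.

Implements every criterion reported for the four modeling sets — R², CCC
(Lin's concordance), IIC (index of ideality of correlation), leave-one-out
Q², RMSE, MAE and the Fischer F-ratio of the univariate model — plus the
residual-sign clustering diagnostic used to explain why training-set R² can
look poor while the within-cluster fits are good.

IIC is the product of the Pearson correlation and the ratio of the smaller
to the larger one-sided mean absolute error of the residuals Δ = observed −
predicted (negative residuals on one side, non-negative on the other).  It
is therefore simultaneously sensitive to correlation strength and residual
asymmetry, and |IIC| ≤ |r| always.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import UndefinedStatisticError

__all__ = [
    "StatBundle",
    "ClusterReport",
    "r2",
    "ccc",
    "iic",
    "q2_loo",
    "f_from_r2",
    "rmse_mae",
    "cluster_r2",
    "compute_bundle",
]


@dataclass(frozen=True)
class StatBundle:
    """The statistics reported for one modeling set."""

    n: int
    r2: Optional[float] = None
    ccc: Optional[float] = None
    iic: Optional[float] = None
    q2: Optional[float] = None
    rmse: Optional[float] = None
    mae: Optional[float] = None
    f: Optional[float] = None


@dataclass(frozen=True)
class ClusterReport:
    """Overall and residual-sign-cluster R² values.

    The low cluster holds points with observed < predicted (Δ < 0); ties
    Δ = 0 belong to the high cluster.  Per-cluster R² is ``None`` when a
    cluster has fewer than 3 points or is degenerate.
    """

    overall_r2: Optional[float]
    low_cluster_r2: Optional[float]
    high_cluster_r2: Optional[float]
    n_low: int
    n_high: int

    @property
    def n(self) -> int:
        return self.n_low + self.n_high


def _as_pair(observed, predicted):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    return obs, pred


def _pearson(obs: np.ndarray, pred: np.ndarray) -> float:
    if obs.size < 2:
        raise UndefinedStatisticError("need at least 2 points for correlation")
    oc = obs - obs.mean()
    pc = pred - pred.mean()
    sso = float(oc @ oc)
    ssp = float(pc @ pc)
    if sso == 0.0 or ssp == 0.0:
        raise UndefinedStatisticError("correlation undefined for constant vector")
    return float(oc @ pc) / np.sqrt(sso * ssp)


def r2(observed, predicted) -> float:
    """Determination coefficient: squared Pearson correlation."""
    obs, pred = _as_pair(observed, predicted)
    return _pearson(obs, pred) ** 2


def ccc(observed, predicted) -> float:
    """Lin's concordance: 2·cov / (var_obs + var_pred + (Δmean)²)."""
    obs, pred = _as_pair(observed, predicted)
    if obs.size < 2:
        raise UndefinedStatisticError("need at least 2 points for CCC")
    oc = obs - obs.mean()
    pc = pred - pred.mean()
    n = obs.size
    cov = float(oc @ pc) / n
    var_o = float(oc @ oc) / n
    var_p = float(pc @ pc) / n
    shift = (obs.mean() - pred.mean()) ** 2
    denom = var_o + var_p + shift
    if denom == 0.0:
        raise UndefinedStatisticError("CCC undefined: both vectors constant and equal")
    return 2.0 * cov / denom


def _one_sided_ratio(delta: np.ndarray) -> float:
    neg = delta < 0
    pos = ~neg
    mae_neg = float(np.abs(delta[neg]).mean()) if neg.any() else 0.0
    mae_pos = float(np.abs(delta[pos]).mean()) if pos.any() else 0.0
    hi = max(mae_neg, mae_pos)
    if hi == 0.0:
        return 1.0
    return min(mae_neg, mae_pos) / hi


def iic(observed, predicted) -> float:
    """Index of ideality of correlation.

    r · min(MAE⁻, MAE⁺)/max(MAE⁻, MAE⁺), where MAE⁻ and MAE⁺ are the mean
    absolute residuals over Δ < 0 and Δ ≥ 0.  Conventions: both one-sided
    MAEs zero → ratio 1 (perfect fit gives IIC = r = 1); exactly one residual
    class empty with the other non-zero → ratio 0 (maximal asymmetry).
    """
    obs, pred = _as_pair(observed, predicted)
    r = _pearson(obs, pred)
    return r * _one_sided_ratio(obs - pred)


def q2_loo(dcw_values, endpoints) -> float:
    """Leave-one-out cross-validated R² of the univariate calibration line.

    Uses the closed form via leverages h_i = 1/n + (x_i − x̄)²/SSX:
    the deleted residual is e_i/(1 − h_i), Q² = 1 − PRESS/TSS.
    """
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    n = x.size
    if n < 4:
        raise UndefinedStatisticError(f"Q² needs at least 4 points, got {n}")
    xc = x - x.mean()
    ssx = float(xc @ xc)
    if ssx == 0.0:
        raise UndefinedStatisticError("Q² undefined: degenerate descriptor")
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0.0:
        raise UndefinedStatisticError("Q² undefined: constant endpoint")
    c1 = float(xc @ yc) / ssx
    resid = yc - c1 * xc
    leverage = 1.0 / n + xc**2 / ssx
    press = float(np.sum((resid / (1.0 - leverage)) ** 2))
    return 1.0 - press / tss


def f_from_r2(r2_value: float, n: int) -> float:
    """Fischer F-ratio of the univariate model: R²(n−2)/(1−R²).

    Reported rounded to the nearest integer in summary tables.
    """
    if not 0.0 <= r2_value < 1.0:
        raise UndefinedStatisticError(f"F requires 0 <= R² < 1, got {r2_value}")
    if n < 3:
        raise ValueError(f"F requires n >= 3, got {n}")
    return r2_value * (n - 2) / (1.0 - r2_value)


def rmse_mae(observed, predicted) -> tuple:
    """Root mean squared error and mean absolute error of the residuals."""
    obs, pred = _as_pair(observed, predicted)
    if obs.size < 1:
        raise ValueError("need at least one point")
    delta = obs - pred
    return float(np.sqrt(np.mean(delta**2))), float(np.mean(np.abs(delta)))


def _safe_r2(obs: np.ndarray, pred: np.ndarray) -> Optional[float]:
    try:
        return r2(obs, pred)
    except UndefinedStatisticError:
        return None


def cluster_r2(observed, predicted) -> ClusterReport:
    """Split points by residual sign and report overall/per-cluster R².

    Points with observed < predicted form the low cluster; observed ≥
    predicted (including exact ties) the high cluster.  Undefined entries
    are flagged as ``None`` rather than raised.
    """
    obs, pred = _as_pair(observed, predicted)
    if obs.size < 4:
        raise ValueError(f"cluster diagnostic needs n >= 4, got {obs.size}")
    low = obs < pred
    high = ~low
    low_r2 = _safe_r2(obs[low], pred[low]) if low.sum() >= 3 else None
    high_r2 = _safe_r2(obs[high], pred[high]) if high.sum() >= 3 else None
    return ClusterReport(
        overall_r2=_safe_r2(obs, pred),
        low_cluster_r2=low_r2,
        high_cluster_r2=high_r2,
        n_low=int(low.sum()),
        n_high=int(high.sum()),
    )


def compute_bundle(observed, predicted, descriptor=None) -> StatBundle:
    """All set-level statistics in one pass; undefined entries are ``None``.

    ``descriptor`` (the DCW values) is required for Q², which cross-validates
    the calibration line rather than the fixed predictions.
    """
    obs, pred = _as_pair(observed, predicted)
    n = int(obs.size)
    r2_val = _safe_r2(obs, pred)
    try:
        ccc_val = ccc(obs, pred)
    except UndefinedStatisticError:
        ccc_val = None
    try:
        iic_val = iic(obs, pred)
    except UndefinedStatisticError:
        iic_val = None
    q2_val = None
    if descriptor is not None and n >= 4:
        try:
            q2_val = q2_loo(descriptor, obs)
        except UndefinedStatisticError:
            q2_val = None
    rmse_val, mae_val = rmse_mae(obs, pred)
    f_val = None
    if r2_val is not None and r2_val < 1.0 and n >= 3:
        f_val = f_from_r2(r2_val, n)
    return StatBundle(
        n=n, r2=r2_val, ccc=ccc_val, iic=iic_val,
        q2=q2_val, rmse=rmse_val, mae=mae_val, f=f_val,
    )
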