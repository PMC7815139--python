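"""Global ordinary spatio-temporal kriging.

The predictor uses the semivariogram formulation of the ordinary-kriging
equations: for data locations x_1..x_n and a target x_0,

    [Gamma  1] [w  ]   [gamma_0]
    [1^T    0] [mu ] = [1      ]

with Gamma_ab = gamma(h_ab, u_ab) and gamma_0 the data-to-target
semivariances. The prediction is w^T z and the kriging variance
w^T gamma_0 + mu. Every data point participates in every prediction
(global neighbourhood), and the single LU factorization of the bordered
matrix is reused across all targets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .exceptions import KrigingError, ParameterError
from .geo import cross_distance_km
from .variogram import STCovModel, STDataset, eval_st_model

log = logging.getLogger(__name__)

#: kriging variances above this (negative) floor are clamped to zero
VAR_TOL = -1e-8


@dataclass
class KrigingResult:
    """Predictions and kriging variances on a space-time target grid."""

    region_id: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    t: np.ndarray
    pred: np.ndarray
    krig_var: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "region_id": self.region_id, "lon": self.lon, "lat": self.lat,
            "time": self.t, "pred": self.pred, "krig_var": self.krig_var})


def build_gamma_system(m: STCovModel, d: STDataset) -> np.ndarray:
    """The (n+1) x (n+1) bordered semivariance matrix of the ordinary-kriging
    system: data-pair semivariances framed by the unbiasedness row/column."""
    n = len(d)
    if n < 2:
        raise ParameterError("need at least 2 data points")
    h = cross_distance_km(d.lon, d.lat, d.lon, d.lat)
    u = np.abs(d.t[:, None] - d.t[None, :])
    gamma = eval_st_model(m, h, u)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = (gamma + gamma.T) / 2.0
    np.fill_diagonal(A[:n, :n], 0.0)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    return A


def ok_predict(
    m: STCovModel,
    d: STDataset,
    target_lon: Sequence[float],
    target_lat: Sequence[float],
    target_t: Sequence[float],
    target_ids: Optional[Sequence[str]] = None,
) -> KrigingResult:
    """Ordinary-kriging predictions at arbitrary space-time targets.

    Exact interpolator: a target coinciding with a data point reproduces that
    observation, with (numerically) zero kriging variance. A singular system
    gets one ridge retry (1e-10 on the data diagonal) before raising.
    """
    target_lon = np.asarray(target_lon, float)
    target_lat = np.asarray(target_lat, float)
    target_t = np.asarray(target_t, float)
    n = len(d)
    A = build_gamma_system(m, d)

    h0 = cross_distance_km(d.lon, d.lat, target_lon, target_lat)
    u0 = np.abs(d.t[:, None] - target_t[None, :])
    B = np.empty((n + 1, len(target_t)))
    B[:n, :] = eval_st_model(m, h0, u0)
    B[n, :] = 1.0

    sol = _solve_bordered(A, B, n)
    w = sol[:n, :]
    mu = sol[n, :]
    pred = w.T @ d.z
    krig_var = np.einsum("ij,ij->j", w, B[:n, :]) + mu
    bad = krig_var < VAR_TOL
    if np.any(bad):
        raise KrigingError(
            f"kriging variance below tolerance (min {krig_var.min():.3e}); "
            "the covariance model is likely invalid")
    krig_var = np.maximum(krig_var, 0.0)
    wsum = w.sum(axis=0)
    if np.any(np.abs(wsum - 1.0) > 1e-8):
        log.warning("kriging weight sums deviate from 1 by up to %.3e",
                    np.abs(wsum - 1.0).max())
    ids = (np.asarray(target_ids, dtype=object) if target_ids is not None
           else np.array([""] * len(target_t), dtype=object))
    return KrigingResult(ids, target_lon, target_lat, target_t, pred, krig_var)


def _solve_bordered(A: np.ndarray, B: np.ndarray, n: int) -> np.ndarray:
    try:
        lu = lu_factor(A)
        sol = lu_solve(lu, B)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError("non-finite solution")
        return sol
    except (np.linalg.LinAlgError, ValueError):
        log.warning("bordered kriging system singular; retrying with 1e-10 ridge")
        A2 = A.copy()
        A2[:n, :n] += np.eye(n) * 1e-10
        try:
            sol = lu_solve(lu_factor(A2), B)
            if not np.all(np.isfinite(sol)):
                raise np.linalg.LinAlgError("non-finite solution")
            return sol
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise KrigingError(f"singular kriging system after ridge retry: {exc}")


def rmse_at_data(m: STCovModel, d: STDataset) -> float:
    """Root mean squared error of predictions at the observed data points,
    each predicted from the full dataset (ordinary kriging is an exact
    interpolator, so this measures pure numerical error)."""
    res = ok_predict(m, d, d.lon, d.lat, d.t, d.site_id)
    return float(np.sqrt(np.mean((res.pred - d.z) ** 2)))
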