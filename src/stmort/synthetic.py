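"""Synthetic data with known truth for every pipeline stage.

Three generators: Gaussian random fields on a space-time grid with a
prescribed joint variogram (stand-in for observed borough rate surfaces),
longitudinal rate panels with known fixed effects, AR(1) coefficient and
age-group variance weights, and toy polygon grids for the geometry layer.
All generators are pure functions of their parameters and a seed.

The default space-time scene mirrors the study conditions the package is
aimed at: 16 sites on a perturbed grid inside a ~30 km box, 17 annual time
points, and five age groups whose variance multipliers are ordered with
infant and post-productive mortality far noisier than the school-age group.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ModelError, ParameterError
from .geo import Region, RegionSet, cross_distance_km
from .trend import AGE_LEVELS, LongDataset, Term
from .variogram import (STCovModel, STDataset, VariogramComponent,
                        eval_st_model, total_sill)

MAX_GRF_POINTS = 5000


def simulate_grf(
    m: STCovModel,
    lon: Sequence[float],
    lat: Sequence[float],
    times: Sequence[float],
    mean: float,
    seed: int,
) -> STDataset:
    """Draw one Gaussian random field realization on the (site x time) grid.

    The covariance is C(h, u) = sill_total - gamma(h, u); the draw is
    mean + L eps with L the (jittered) Cholesky factor. Dense Cholesky is the
    deliberate choice at the package's target sizes (<= 5000 points).
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    times = np.asarray(times, float)
    n_pts = len(lon) * len(times)
    if n_pts > MAX_GRF_POINTS:
        raise ParameterError(f"grid of {n_pts} points exceeds the dense "
                             f"Cholesky contract ({MAX_GRF_POINTS})")
    site_ids = np.array([f"s{i:02d}" for i in range(len(lon))], dtype=object)
    # observation order: site-major, time-minor
    ss = np.repeat(np.arange(len(lon)), len(times))
    tt = np.tile(times, len(lon))
    h = cross_distance_km(lon[ss], lat[ss], lon[ss], lat[ss])
    u = np.abs(tt[:, None] - tt[None, :])
    sill = total_sill(m)
    C = sill - eval_st_model(m, h, u)
    C = (C + C.T) / 2.0
    if np.all(C == 0.0):  # degenerate zero-variance model
        return STDataset(site_ids[ss], lon[ss], lat[ss], tt,
                         np.full(n_pts, float(mean)))
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        try:
            L = np.linalg.cholesky(C + 1e-10 * np.eye(n_pts))
        except np.linalg.LinAlgError:
            raise ModelError("covariance not positive semidefinite after "
                             "jitter; the variogram model is invalid")
    rng = np.random.default_rng(seed)
    z = mean + L @ rng.standard_normal(n_pts)
    return STDataset(site_ids[ss], lon[ss], lat[ss], tt, z)


@dataclass
class TrendTruth:
    """Ground truth for the longitudinal generator.

    Factor effects sum to zero (identifiability under sum-to-zero contrasts);
    ``time_coefs`` are the linear/quadratic/cubic coefficients on centered
    unit-step time; ``interactions`` maps term labels (e.g. "age:t") to
    effect arrays shaped like the term's level grid.
    """

    mu: float
    alpha: np.ndarray                  # 5 age effects, sum 0
    beta: np.ndarray                   # J area effects, sum 0
    time_coefs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    interactions: dict = field(default_factory=dict)
    phi: float = 0.0
    sigma2: float = 1.0
    var_weights: np.ndarray = None     # 5 multipliers, first = 1

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, float)
        self.beta = np.asarray(self.beta, float)
        if self.var_weights is None:
            self.var_weights = np.ones(len(self.alpha))
        self.var_weights = np.asarray(self.var_weights, float)
        for name, eff in (("alpha", self.alpha), ("beta", self.beta)):
            if abs(eff.sum()) > 1e-8 * max(1.0, np.abs(eff).max()):
                raise ParameterError(f"{name} effects must sum to zero")
        if not -1.0 < self.phi < 1.0:
            raise ParameterError("phi must lie in (-1, 1)")
        if self.sigma2 < 0:
            raise ParameterError("sigma2 must be >= 0")


def simulate_trend_data(truth: TrendTruth, J: int, K: int, seed: int,
                        age_levels: Sequence[str] = AGE_LEVELS,
                        start_year: float = 2000.0) -> LongDataset:
    """Longitudinal panel from the fixed-effects model with AR(1) serial
    errors (stationary initialization) scaled by sigma2 * g(age)^2."""
    if K < 3:
        raise ParameterError("need at least 3 time points")
    if len(truth.beta) != J:
        raise ParameterError("beta length must equal J")
    n_age = len(age_levels)
    if len(truth.alpha) != n_age or len(truth.var_weights) != n_age:
        raise ParameterError("alpha / var_weights length must match age levels")
    rng = np.random.default_rng(seed)
    times = start_year + np.arange(K, dtype=float)
    ts = (times - times.mean()) / 1.0  # centered unit-step time
    gamma, delta, zeta = truth.time_coefs
    phi = truth.phi
    rows = []
    for i, age in enumerate(age_levels):
        for j in range(J):
            mean = (truth.mu + truth.alpha[i] + truth.beta[j]
                    + gamma * ts + delta * ts ** 2 + zeta * ts ** 3)
            mean = mean + _interaction_mean(truth.interactions, i, j, ts)
            s = math.sqrt(truth.sigma2) * truth.var_weights[i]
            e = np.empty(K)
            e[0] = s * rng.standard_normal()
            innov_sd = s * math.sqrt(1.0 - phi * phi)
            eps = rng.standard_normal(K - 1)
            for k in range(1, K):
                e[k] = phi * e[k - 1] + innov_sd * eps[k - 1]
            y = mean + e
            rows.append(pd.DataFrame({
                "age_group": age, "area": f"a{j:02d}", "time": times,
                "rate": y}))
    return LongDataset(pd.concat(rows, ignore_index=True))


def _interaction_mean(interactions: dict, i: int, j: int,
                      ts: np.ndarray) -> np.ndarray:
    out = np.zeros_like(ts)
    for label, eff in interactions.items():
        term = Term.parse(label)
        eff = np.asarray(eff, float)
        tpart = ts ** term.tpow if term.tpow else 1.0
        if term.factors == ("age", "area"):
            out = out + eff[i, j] * tpart
        elif term.factors == ("age",):
            out = out + eff[i] * tpart
        elif term.factors == ("area",):
            out = out + eff[j] * tpart
        else:
            raise ParameterError(f"interaction '{label}' needs at least one factor")
    return out


def make_toy_regions(nx: int, ny: int, parents: int) -> RegionSet:
    """nx x ny grid of unit-square child polygons with contiguous (row-major)
    parent assignment."""
    from shapely.geometry import Polygon

    if nx * ny < parents or parents < 1:
        raise ParameterError("need nx*ny >= parents >= 1")
    regions = []
    total = nx * ny
    rank = 0
    for iy in range(ny):
        for ix in range(nx):
            poly = Polygon([(ix, iy), (ix + 1, iy), (ix + 1, iy + 1),
                            (ix, iy + 1), (ix, iy)])
            parent = min(rank * parents // total, parents - 1)
            regions.append(Region(f"c{rank:03d}", f"P{parent}", poly))
            rank += 1
    return RegionSet(regions)


# ---------------------------------------------------------------------------
# default study-scale scene
# ---------------------------------------------------------------------------

def default_st_model() -> STCovModel:
    """A sum-metric model with ranges on the scale the package targets:
    spatial correlation over ~13 km, temporal over ~12 years, in rate^2 units
    of order one."""
    return STCovModel(
        "sumMetric",
        space=VariogramComponent("Gau", 0.05, 0.6, 13.0 / math.sqrt(3.0)),
        time=VariogramComponent("Gau", 0.05, 0.5, 12.0 / math.sqrt(3.0)),
        joint=VariogramComponent("Gau", 0.02, 0.3, 8.0),
        stAni=1.2)


def borough_scene(seed: int, n_sites: int = 16, years: Sequence[float] = None,
                  mean: float = 5.0,
                  model: Optional[STCovModel] = None) -> STDataset:
    """A borough-scale synthetic field: ``n_sites`` sites on a perturbed grid
    inside a ~30 km box centred near 19.4 N, annual times 2000..2016."""
    if years is None:
        years = np.arange(2000, 2017, dtype=float)
    model = model or default_st_model()
    rng = np.random.default_rng(seed)
    side = int(math.ceil(math.sqrt(n_sites)))
    lat0, box_km = 19.4, 30.0
    deg_lat = box_km / 111.195
    deg_lon = deg_lat / math.cos(math.radians(lat0))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    gx = gx.ravel()[:n_sites] / max(side - 1, 1)
    gy = gy.ravel()[:n_sites] / max(side - 1, 1)
    jitter = 0.25 / max(side - 1, 1)
    lon = -99.15 + (gx + rng.uniform(-jitter, jitter, n_sites)) * deg_lon
    lat = lat0 + (gy + rng.uniform(-jitter, jitter, n_sites)) * deg_lat
    return simulate_grf(model, lon, lat, np.asarray(years, float), mean,
                        seed=seed + 1)


def default_trend_truth(J: int = 16) -> TrendTruth:
    """Study-scale longitudinal truth: five age groups whose variance
    multipliers echo the real ordering (infant and post-productive noisiest),
    moderate serial correlation, and a gentle cubic time trend."""
    alpha = np.array([10.0, -4.0, -6.0, -3.0, 3.0])
    rng = np.random.default_rng(12345)  # fixed area effects, part of the truth
    beta = rng.normal(0.0, 1.5, J)
    beta -= beta.mean()
    return TrendTruth(
        mu=8.0, alpha=alpha, beta=beta,
        time_coefs=(0.4, 0.05, -0.02),
        phi=0.12,
        sigma2=0.25,
        var_weights=np.array([3.0, 0.9, 0.4, 0.8, 2.5]),
    )
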