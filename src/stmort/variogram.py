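"""Empirical spatio-temporal variograms, joint covariance structures and
weighted-least-squares model fitting.

The semivariogram gamma(h, u) is half the expected squared difference between
rates separated by spatial lag h (km, great-circle) and temporal lag u
(fractional years). Five joint structures are supported — metric, separable,
product-sum, sum-metric and simple sum-metric — each assembled from
exponential, Gaussian or spherical components. Model selection fits every
admissible family permutation (75 candidates) and ranks by pair-count-weighted
mean squared error against the empirical variogram matrix.

Range convention: ``range`` is the distance at which the spherical model
reaches its sill; the exponential and Gaussian models use the e-folding
parameterization gamma(h) = nugget + psill*(1 - exp(-h/range)) and
nugget + psill*(1 - exp(-(h/range)^2)), whose effective ranges are 3*range
and sqrt(3)*range. This matches the convention of the gstat family of tools;
check it before comparing ranges across software.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .exceptions import EstimationError, ModelError, ParameterError
from .geo import pairwise_distance_km

FAMILIES = ("Exp", "Gau", "Sph")
STRUCTURES = ("metric", "separable", "productSum", "sumMetric", "simpleSumMetric")

#: lower box bound applied to every free parameter during fitting
LOWER_BOUND = 0.001


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class STDataset:
    """Point-referenced space-time observations for one age group.

    Arrays are aligned per observation; ``t`` is in fractional years and
    ``z`` is a rate per 1,000.
    """

    site_id: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    t: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.site_id = np.asarray(self.site_id, dtype=object)
        self.lon = np.asarray(self.lon, float)
        self.lat = np.asarray(self.lat, float)
        self.t = np.asarray(self.t, float)
        self.z = np.asarray(self.z, float)
        n = len(self.site_id)
        if not (len(self.lon) == len(self.lat) == len(self.t) == len(self.z) == n):
            raise ParameterError("STDataset arrays must share one length")
        if not np.all(np.isfinite(self.z)):
            raise ParameterError("rates must be finite")
        keys = set(zip(self.site_id.tolist(), self.t.tolist()))
        if len(keys) != n:
            raise ParameterError("duplicated (site_id, t) observation")

    def __len__(self) -> int:
        return len(self.z)

    @classmethod
    def from_dataframe(cls, df, site="site_id", lon="lon", lat="lat",
                       time="time", rate="rate") -> "STDataset":
        return cls(df[site].to_numpy(), df[lon].to_numpy(), df[lat].to_numpy(),
                   df[time].to_numpy(), df[rate].to_numpy())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"site_id": self.site_id, "lon": self.lon,
                             "lat": self.lat, "time": self.t, "rate": self.z})


@dataclass
class EmpiricalSTVariogram:
    """Binned semivariance matrix gamma(h, u) with pair counts.

    Rows index spatial bins, columns index temporal lags. Cells with no
    contributing pair hold NaN in ``gamma`` and 0 in ``npairs``.
    """

    spatial_bin_centers: np.ndarray  # km
    temporal_lags: np.ndarray        # years
    gamma: np.ndarray                # [n_spatial_bins, n_temporal_lags]
    npairs: np.ndarray               # same shape, integer counts

    def cells(self):
        """(h, u, gamma, npairs) arrays over non-missing cells."""
        H, U = np.meshgrid(self.spatial_bin_centers, self.temporal_lags,
                           indexing="ij")
        mask = self.npairs > 0
        return H[mask], U[mask], self.gamma[mask], self.npairs[mask]


@dataclass
class VariogramComponent:
    """One Exp/Gau/Sph component: gamma(0) = 0, then nugget + partial sill
    rising toward nugget + psill at the component's range."""

    family: str
    nugget: float
    psill: float
    range_: float

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ModelError(f"unknown variogram family '{self.family}'")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ModelError("component parameters out of domain")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def __call__(self, h) -> np.ndarray:
        return eval_component(self, h)


def eval_component(c: VariogramComponent, h) -> np.ndarray:
    """Semivariance of a single component at lag(s) h >= 0."""
    h = np.asarray(h, float)
    if np.any(h < 0):
        raise ParameterError("negative lag")
    scalar = h.ndim == 0
    r = h / c.range_
    if c.family == "Exp":
        g = 1.0 - np.exp(-r)
    elif c.family == "Gau":
        g = 1.0 - np.exp(-(r ** 2))
    else:  # Sph
        g = np.where(r < 1.0, 1.5 * r - 0.5 * r ** 3, 1.0)
    out = np.where(h > 0, c.nugget + c.psill * g, 0.0)
    return float(out) if scalar else out


@dataclass
class STCovModel:
    """A joint space-time variogram model.

    Which components are present is dictated by ``structure``:

    - ``metric``: joint only, evaluated at sqrt(h^2 + (stAni*u)^2);
    - ``separable``/``productSum``: space + time marginals;
    - ``sumMetric``: space + time + joint metric term;
    - ``simpleSumMetric``: as sumMetric but components are nugget-free and a
      single global ``nugget`` applies away from the origin.
    """

    structure: str
    space: Optional[VariogramComponent] = None
    time: Optional[VariogramComponent] = None
    joint: Optional[VariogramComponent] = None
    stAni: Optional[float] = None      # km per year
    sill: Optional[float] = None       # separable only
    k: Optional[float] = None          # productSum only
    nugget: float = 0.0                # simpleSumMetric global nugget

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ModelError(f"unknown structure '{self.structure}'")
        need = {
            "metric": ("joint",),
            "separable": ("space", "time"),
            "productSum": ("space", "time"),
            "sumMetric": ("space", "time", "joint"),
            "simpleSumMetric": ("space", "time", "joint"),
        }[self.structure]
        for name in need:
            if getattr(self, name) is None:
                raise ModelError(f"{self.structure} model requires a {name} component")
        for name in ("space", "time", "joint"):
            if name not in need and getattr(self, name) is not None:
                raise ModelError(f"{self.structure} model must not carry a {name} component")
        if self.structure in ("metric", "sumMetric", "simpleSumMetric"):
            if self.stAni is None or self.stAni <= 0:
                raise ModelError(f"{self.structure} model requires stAni > 0")
        if self.structure == "separable" and (self.sill is None or self.sill < 0):
            raise ModelError("separable model requires a global sill")
        if self.structure == "productSum" and (self.k is None or self.k <= 0):
            raise ModelError("productSum model requires k > 0")
        if self.structure == "simpleSumMetric":
            for name in ("space", "time", "joint"):
                comp = getattr(self, name)
                if comp.nugget != 0:
                    raise ModelError("simpleSumMetric components must be nugget-free")

    def families(self) -> tuple:
        return tuple(
            getattr(self, name).family
            for name in ("space", "time", "joint")
            if getattr(self, name) is not None
        )

    def semivariance(self, h, u) -> np.ndarray:
        return eval_st_model(self, h, u)

    def n_free_params(self) -> int:
        return len(_pack(self))

    def to_dict(self) -> dict:
        d = {"structure": self.structure, "stAni": self.stAni, "sill": self.sill,
             "k": self.k, "nugget": self.nugget}
        for name in ("space", "time", "joint"):
            comp = getattr(self, name)
            d[name] = None if comp is None else {
                "family": comp.family, "nugget": comp.nugget,
                "psill": comp.psill, "range": comp.range_}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "STCovModel":
        comps = {}
        for name in ("space", "time", "joint"):
            c = d.get(name)
            comps[name] = None if c is None else VariogramComponent(
                c["family"], c["nugget"], c["psill"], c["range"])
        return cls(structure=d["structure"], stAni=d.get("stAni"),
                   sill=d.get("sill"), k=d.get("k"),
                   nugget=d.get("nugget", 0.0), **comps)


def _scaled(c: VariogramComponent, h) -> np.ndarray:
    """Component rescaled to total sill 1 (for the separable product form)."""
    s = c.sill
    if s <= 0:
        return np.zeros_like(np.asarray(h, float))
    return eval_component(c, h) / s


def eval_st_model(m: STCovModel, h, u) -> np.ndarray:
    """Joint semivariance gamma(h, u); gamma(0, 0) = 0 for every structure."""
    h = np.asarray(h, float)
    u = np.asarray(u, float)
    if np.any(h < 0) or np.any(u < 0):
        raise ParameterError("negative lag")
    scalar = h.ndim == 0 and u.ndim == 0
    h, u = np.broadcast_arrays(np.atleast_1d(h), np.atleast_1d(u))
    if m.structure == "metric":
        out = eval_component(m.joint, np.hypot(h, m.stAni * u))
    elif m.structure == "separable":
        gs, gt = _scaled(m.space, h), _scaled(m.time, u)
        out = m.sill * (gs + gt - gs * gt)
    elif m.structure == "productSum":
        gs = eval_component(m.space, h)
        gt = eval_component(m.time, u)
        sill_s, sill_t = m.space.sill, m.time.sill
        out = (m.k * sill_t + 1) * gs + (m.k * sill_s + 1) * gt - m.k * gs * gt
    elif m.structure == "sumMetric":
        hm = np.hypot(h, m.stAni * u)
        out = (eval_component(m.space, h) + eval_component(m.time, u)
               + eval_component(m.joint, hm))
    else:  # simpleSumMetric
        hm = np.hypot(h, m.stAni * u)
        out = (eval_component(m.space, h) + eval_component(m.time, u)
               + eval_component(m.joint, hm))
        out = out + np.where((h > 0) | (u > 0), m.nugget, 0.0)
    return float(out[0]) if scalar else out


def total_sill(m: STCovModel) -> float:
    """Semivariance plateau, evaluated far beyond every range."""
    scale = max(
        [c.range_ for c in (m.space, m.time, m.joint) if c is not None] + [1.0]
    )
    return float(eval_st_model(m, 1e6 * scale, 1e6 * scale))


# ---------------------------------------------------------------------------
# empirical variogram
# ---------------------------------------------------------------------------

def empirical_st_variogram(
    d: STDataset,
    n_spatial_bins: int = 15,
    spatial_cutoff: Optional[float] = None,
    max_temporal_lag: Optional[float] = None,
) -> EmpiricalSTVariogram:
    """Bin half squared differences of all unordered observation pairs into a
    (spatial bin x temporal lag) matrix.

    Temporal lags sit on the native time spacing of the data; spatial bins are
    equal-width on [0, cutoff]. The default cutoff is the maximum inter-site
    distance.
    """
    if n_spatial_bins < 2:
        raise ParameterError("need at least 2 spatial bins")
    sites, site_idx = np.unique(d.site_id.astype(str), return_inverse=True)
    if len(sites) < 2:
        raise ParameterError("need at least 2 sites")
    times = np.unique(d.t)
    # representative coordinate per site
    lon = np.empty(len(sites))
    lat = np.empty(len(sites))
    for i in range(len(sites)):
        rows = np.nonzero(site_idx == i)[0]
        lon[i], lat[i] = d.lon[rows[0]], d.lat[rows[0]]
    dist = pairwise_distance_km(list(zip(lon, lat)))
    if spatial_cutoff is None:
        spatial_cutoff = float(dist.max())
    if spatial_cutoff <= 0:
        raise ParameterError("spatial cutoff must be positive")
    dt = np.min(np.diff(times)) if len(times) > 1 else 1.0
    if max_temporal_lag is None:
        max_temporal_lag = float(times.max() - times.min())
    n_t = int(round(max_temporal_lag / dt)) + 1
    lags = np.arange(n_t) * dt
    width = spatial_cutoff / n_spatial_bins

    i, j = np.triu_indices(len(d), k=1)
    h = dist[site_idx[i], site_idx[j]]
    u = np.abs(d.t[i] - d.t[j])
    sq = (d.z[i] - d.z[j]) ** 2
    ui = np.rint(u / dt).astype(int)
    keep = (h <= spatial_cutoff + 1e-12) & (ui < n_t)
    h, sq, ui = h[keep], sq[keep], ui[keep]
    hi = np.minimum((h / width).astype(int), n_spatial_bins - 1)

    acc = np.zeros((n_spatial_bins, n_t))
    cnt = np.zeros((n_spatial_bins, n_t), dtype=int)
    np.add.at(acc, (hi, ui), sq)
    np.add.at(cnt, (hi, ui), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(cnt > 0, acc / (2.0 * np.maximum(cnt, 1)), np.nan)
    centers = (np.arange(n_spatial_bins) + 0.5) * width
    return EmpiricalSTVariogram(centers, lags, gamma, cnt)


def marginal_means(ev: EmpiricalSTVariogram, axis: str) -> np.ndarray:
    """Row (spatial) or column (temporal) means of the empirical variogram
    matrix, skipping missing cells; an all-missing line yields NaN."""
    if axis not in ("spatial", "temporal"):
        raise ParameterError("axis must be 'spatial' or 'temporal'")
    masked = np.where(ev.npairs > 0, ev.gamma, np.nan)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return (np.nanmean(masked, axis=1) if axis == "spatial"
                else np.nanmean(masked, axis=0))


def estimate_stani(ev: EmpiricalSTVariogram) -> float:
    """Spatio-temporal anisotropy (km per year) from the ratio of the least
    squares slopes of the purely temporal margin (first spatial bin) and the
    purely spatial margin (temporal lag zero).

    Falls back to range_s / range_t (the initial-guess ranges) when the slope
    ratio is non-positive or undefined.
    """
    g_s = ev.gamma[:, 0]
    ok_s = ev.npairs[:, 0] > 0
    g_t = ev.gamma[0, :]
    ok_t = ev.npairs[0, :] > 0
    if ok_s.sum() < 2 or ok_t.sum() < 2:
        raise EstimationError("need >= 2 points on each pure margin")
    b_s = _slope(ev.spatial_bin_centers[ok_s], g_s[ok_s])
    b_t = _slope(ev.temporal_lags[ok_t], g_t[ok_t])
    if b_s > 0 and b_t > 0 and np.isfinite(b_t / b_s):
        return float(b_t / b_s)
    range_s = float(ev.spatial_bin_centers.max()) / 3.0
    range_t = float(ev.temporal_lags.max())
    if range_t <= 0:
        raise EstimationError("anisotropy fallback undefined (zero temporal span)")
    return range_s / range_t


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    den = float(xc @ xc)
    if den == 0:
        return np.nan
    return float(xc @ y / den)


@dataclass
class InitialGuess:
    """Starting values for the joint-model fits, derived from the empirical
    variogram matrix marginals."""

    nugget_s: float
    nugget_t: float
    sill_s: float
    sill_t: float
    range_s: float       # km
    range_t: float       # years
    stAni: float         # km per year
    nugget_j: float
    sill_j: float
    range_j: float


def initial_guess(ev: EmpiricalSTVariogram) -> InitialGuess:
    """Heuristic starting parameters.

    Nugget: median of the first three marginal means per axis. Sill: median of
    the last five. Spatial range: one third of the maximum lagged spatial
    value; temporal range: the maximum temporal lag. Joint values are means of
    the marginal pairs, with the joint range averaging the spatial range and
    the time range folded through stAni. With short margins all available
    means are used.
    """
    mm_s = marginal_means(ev, "spatial")
    mm_t = marginal_means(ev, "temporal")
    mm_s = mm_s[np.isfinite(mm_s)]
    mm_t = mm_t[np.isfinite(mm_t)]
    if len(mm_s) < 2 or len(mm_t) < 2:
        raise EstimationError("fewer than 2 usable marginal means on an axis")
    nugget_s = float(np.median(mm_s[:3]))
    nugget_t = float(np.median(mm_t[:3]))
    sill_s = float(np.median(mm_s[-5:]))
    sill_t = float(np.median(mm_t[-5:]))
    range_s = float(ev.spatial_bin_centers.max()) / 3.0
    range_t = float(ev.temporal_lags.max())
    st_ani = estimate_stani(ev)
    return InitialGuess(
        nugget_s=nugget_s, nugget_t=nugget_t, sill_s=sill_s, sill_t=sill_t,
        range_s=range_s, range_t=range_t, stAni=st_ani,
        nugget_j=(nugget_s + nugget_t) / 2.0,
        sill_j=(sill_s + sill_t) / 2.0,
        range_j=(range_s + st_ani * range_t) / 2.0,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedSTModel:
    model: STCovModel
    wmse: float
    converged: bool
    n_iter: int


def _psill(nugget: float, sill: float) -> float:
    return max(sill - nugget, LOWER_BOUND)


def _pack(m: STCovModel) -> np.ndarray:
    """Free-parameter vector for a model, by structure."""
    s = m.structure
    if s == "metric":
        j = m.joint
        return np.array([j.nugget, j.psill, j.range_, m.stAni])
    if s == "separable":
        # components are kept at unit sill; their nugget is the relative nugget
        return np.array([m.space.nugget, m.space.range_,
                         m.time.nugget, m.time.range_, m.sill])
    if s == "productSum":
        kfrac = m.k * max(m.space.sill, m.time.sill)
        return np.array([m.space.nugget, m.space.psill, m.space.range_,
                         m.time.nugget, m.time.psill, m.time.range_, kfrac])
    if s == "sumMetric":
        return np.array([m.space.nugget, m.space.psill, m.space.range_,
                         m.time.nugget, m.time.psill, m.time.range_,
                         m.joint.nugget, m.joint.psill, m.joint.range_,
                         m.stAni])
    # simpleSumMetric
    return np.array([m.space.psill, m.space.range_,
                     m.time.psill, m.time.range_,
                     m.joint.psill, m.joint.range_,
                     m.stAni, m.nugget])


def _unpack(theta: np.ndarray, template: STCovModel) -> STCovModel:
    s = template.structure
    fams = template.families()
    if s == "metric":
        n, p, r, ani = theta
        return STCovModel("metric", joint=VariogramComponent(fams[0], n, p, r),
                          stAni=ani)
    if s == "separable":
        ns, rs, nt, rt, sill = theta
        ns = min(ns, 0.999)
        nt = min(nt, 0.999)
        return STCovModel(
            "separable",
            space=VariogramComponent(fams[0], ns, 1.0 - ns, rs),
            time=VariogramComponent(fams[1], nt, 1.0 - nt, rt),
            sill=sill)
    if s == "productSum":
        ns, ps, rs, nt, pt, rt, kfrac = theta
        sp = VariogramComponent(fams[0], ns, ps, rs)
        tm = VariogramComponent(fams[1], nt, pt, rt)
        k = min(kfrac, 0.999) / max(sp.sill, tm.sill)
        return STCovModel("productSum", space=sp, time=tm, k=k)
    if s == "sumMetric":
        ns, ps, rs, nt, pt, rt, nj, pj, rj, ani = theta
        return STCovModel(
            "sumMetric",
            space=VariogramComponent(fams[0], ns, ps, rs),
            time=VariogramComponent(fams[1], nt, pt, rt),
            joint=VariogramComponent(fams[2], nj, pj, rj),
            stAni=ani)
    ps, rs, pt, rt, pj, rj, ani, nug = theta
    return STCovModel(
        "simpleSumMetric",
        space=VariogramComponent(fams[0], 0.0, ps, rs),
        time=VariogramComponent(fams[1], 0.0, pt, rt),
        joint=VariogramComponent(fams[2], 0.0, pj, rj),
        stAni=ani, nugget=nug)


def _bounds(structure: str, n: int) -> list[tuple[float, Optional[float]]]:
    b: list[tuple[float, Optional[float]]] = [(LOWER_BOUND, None)] * n
    if structure == "separable":
        b[0] = (LOWER_BOUND, 0.999)   # relative nuggets must stay below 1
        b[2] = (LOWER_BOUND, 0.999)
    if structure == "productSum":
        b[6] = (LOWER_BOUND, 0.999)   # k*max(sill) <= 1 keeps the model valid
    return b


def weighted_mse(m: STCovModel, ev: EmpiricalSTVariogram,
                 weights: str = "npairs") -> float:
    """Pair-count-weighted mean squared error between model and empirical
    semivariances over the non-missing cells."""
    h, u, g, npairs = ev.cells()
    w = npairs.astype(float) if weights == "npairs" else np.ones_like(g)
    resid = g - eval_st_model(m, h, u)
    return float(np.sum(w * resid ** 2) / np.sum(w))


def fit_st_model(ev: EmpiricalSTVariogram, init: STCovModel,
                 weights: str = "npairs", maxiter: int = 500) -> FittedSTModel:
    """Box-constrained quasi-Newton (L-BFGS-B) minimization of the weighted
    MSE, every free parameter bounded below by 0.001. Optimizer failure is
    reported through the ``converged`` flag, never raised."""
    h, u, g, npairs = ev.cells()
    if len(g) < len(_pack(init)):
        raise ParameterError("fewer non-missing cells than free parameters")
    w = npairs.astype(float) if weights == "npairs" else np.ones_like(g)
    wsum = float(np.sum(w))
    template = init

    def objective(theta):
        try:
            m = _unpack(theta, template)
        except ModelError:
            return 1e30
        resid = g - eval_st_model(m, h, u)
        return float(np.sum(w * resid ** 2) / wsum)

    def clip(x, bnds):
        return np.array([
            max(xi, lo) if hi is None else min(max(xi, lo), hi)
            for xi, (lo, hi) in zip(x, bnds)])

    bounds = _bounds(init.structure, len(_pack(init)))
    x0 = clip(_pack(init), bounds)
    try:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-14,
                                "gtol": 1e-12, "maxfun": 20 * maxiter})
        # Nelder-Mead polish helps escape flat finite-difference gradients
        res2 = minimize(objective, res.x, method="Nelder-Mead",
                        options={"maxiter": 200 * len(x0), "fatol": 1e-16,
                                 "xatol": 1e-12})
        x1, x2 = clip(res.x, bounds), clip(res2.x, bounds)
        f1, f2 = objective(x1), objective(x2)
        x, fval = (x2, f2) if f2 < f1 else (x1, f1)
        model = _unpack(x, template)
        return FittedSTModel(model, fval, bool(res.success),
                             int(res.nit) + int(getattr(res2, "nit", 0)))
    except (ValueError, FloatingPointError):
        return FittedSTModel(init, objective(x0), False, 0)


def make_initial_model(structure: str, fams: Sequence[str],
                       ig: InitialGuess) -> STCovModel:
    """Instantiate one grid-search candidate from the heuristic guesses."""
    if structure == "metric":
        return STCovModel("metric", joint=VariogramComponent(
            fams[0], ig.nugget_j, _psill(ig.nugget_j, ig.sill_j), ig.range_j),
            stAni=ig.stAni)
    if structure == "separable":
        ns = min(ig.nugget_s / ig.sill_s if ig.sill_s > 0 else 0.1, 0.9)
        nt = min(ig.nugget_t / ig.sill_t if ig.sill_t > 0 else 0.1, 0.9)
        return STCovModel(
            "separable",
            space=VariogramComponent(fams[0], ns, 1.0 - ns, ig.range_s),
            time=VariogramComponent(fams[1], nt, 1.0 - nt, ig.range_t),
            sill=(ig.sill_s + ig.sill_t) / 2.0)
    if structure == "productSum":
        sp = VariogramComponent(fams[0], ig.nugget_s,
                                _psill(ig.nugget_s, ig.sill_s), ig.range_s)
        tm = VariogramComponent(fams[1], ig.nugget_t,
                                _psill(ig.nugget_t, ig.sill_t), ig.range_t)
        return STCovModel("productSum", space=sp, time=tm,
                          k=0.5 / max(sp.sill, tm.sill))
    if structure == "sumMetric":
        return STCovModel(
            "sumMetric",
            space=VariogramComponent(fams[0], ig.nugget_s,
                                     _psill(ig.nugget_s, ig.sill_s), ig.range_s),
            time=VariogramComponent(fams[1], ig.nugget_t,
                                    _psill(ig.nugget_t, ig.sill_t), ig.range_t),
            joint=VariogramComponent(fams[2], ig.nugget_j,
                                     _psill(ig.nugget_j, ig.sill_j), ig.range_j),
            stAni=ig.stAni)
    return STCovModel(
        "simpleSumMetric",
        space=VariogramComponent(fams[0], 0.0,
                                 _psill(0.0, ig.sill_s), ig.range_s),
        time=VariogramComponent(fams[1], 0.0,
                                _psill(0.0, ig.sill_t), ig.range_t),
        joint=VariogramComponent(fams[2], 0.0,
                                 _psill(0.0, ig.sill_j), ig.range_j),
        stAni=ig.stAni,
        nugget=max((ig.nugget_s + ig.nugget_t) / 2.0, LOWER_BOUND))


def candidate_models(ig: InitialGuess) -> list[STCovModel]:
    """The full 75-candidate grid: every Exp/Gau/Sph permutation admitted by
    each structure (3 + 9 + 9 + 27 + 27)."""
    out: list[STCovModel] = []
    for fam in FAMILIES:
        out.append(make_initial_model("metric", (fam,), ig))
    for structure in ("separable", "productSum"):
        for fams in itertools.product(FAMILIES, repeat=2):
            out.append(make_initial_model(structure, fams, ig))
    for structure in ("sumMetric", "simpleSumMetric"):
        for fams in itertools.product(FAMILIES, repeat=3):
            out.append(make_initial_model(structure, fams, ig))
    return out


def grid_search(ev: EmpiricalSTVariogram, ig: InitialGuess,
                weights: str = "npairs") -> list[FittedSTModel]:
    """Fit all 75 candidates and rank ascending by weighted MSE; ties break on
    fewer free parameters, then on fixed structure order. Failed fits sink to
    the bottom with ``converged=False``."""
    fits: list[FittedSTModel] = []
    for cand in candidate_models(ig):
        try:
            fits.append(fit_st_model(ev, cand, weights=weights))
        except ParameterError:
            raise
        except Exception:  # a candidate must never abort the search
            fits.append(FittedSTModel(cand, np.inf, False, 0))
    order = {s: i for i, s in enumerate(STRUCTURES)}
    fits.sort(key=lambda f: (
        f.wmse if np.isfinite(f.wmse) else np.inf,
        f.model.n_free_params(), order[f.model.structure]))
    return fits


def fits_to_dataframe(fits: Sequence[FittedSTModel]):
    """One row per candidate: structure, families, parameters, wmse."""
    import pandas as pd

    rows = []
    for f in fits:
        m = f.model
        rows.append({
            "structure": m.structure,
            "families": "+".join(m.families()),
            "n_params": m.n_free_params(),
            "stAni": m.stAni, "sill": m.sill, "k": m.k, "nugget": m.nugget,
            "wmse": f.wmse, "converged": f.converged, "n_iter": f.n_iter,
        })
    return pd.DataFrame(rows)
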