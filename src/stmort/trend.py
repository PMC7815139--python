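"""Longitudinal fixed-effects modeling of age- and area-specific mortality.

The model is

    y_ijk = mu + alpha_i + beta_j + gamma*t_k + delta*t_k^2 + zeta*t_k^3
            + (all double and triple interactions) + eps_ijk

for age group alpha_i, area beta_j and centered time t_k, with serially
correlated errors: within each (age, area) series the errors follow an AR(1)
process with coefficient phi, and the error variance is sigma^2 * g(alpha_i)^2
with one variance multiplier per age group (varIdent; the first level is the
reference with g = 1). Variance parameters are estimated by REML with the
fixed effects profiled out by generalized least squares; a maximum-likelihood
log-likelihood evaluated at the REML variance structure supports
likelihood-ratio back-step selection of fixed terms.

Time is centered at the midpoint of the observed span and scaled to unit
steps before forming t, t^2, t^3, which tames the collinearity of the cubic.
Factors use sum-to-zero contrasts, so the Type III marginal F test of a term
is the Wald test of its contrast block given all other terms.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .exceptions import FitError, ParameterError

#: canonical age-group ordering used whenever the data's labels allow it
AGE_LEVELS = ("Infant", "Pre-school", "School", "Productive", "Post-productive")


# ---------------------------------------------------------------------------
# model terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """A fixed-effect term: a subset of the factors {age, area} times an
    optional power of centered time (tpow in 0..3)."""

    factors: tuple[str, ...]
    tpow: int = 0

    def __post_init__(self):
        if any(f not in ("age", "area") for f in self.factors):
            raise ParameterError(f"unknown factor in term: {self.factors}")
        if tuple(sorted(self.factors)) != self.factors:
            object.__setattr__(self, "factors", tuple(sorted(self.factors)))
        if not (0 <= self.tpow <= 3):
            raise ParameterError("time power must be in 0..3")
        if not self.factors and self.tpow == 0:
            raise ParameterError("the empty term is the intercept; not listable")

    @property
    def label(self) -> str:
        parts = list(self.factors)
        if self.tpow == 1:
            parts.append("t")
        elif self.tpow > 1:
            parts.append(f"t{self.tpow}")
        return ":".join(parts)

    @classmethod
    def parse(cls, s: str) -> "Term":
        factors = []
        tpow = 0
        for p in s.split(":"):
            p = p.strip()
            if p in ("age", "area"):
                factors.append(p)
            elif p == "t":
                tpow = 1
            elif p in ("t2", "t3"):
                tpow = int(p[1])
            else:
                raise ParameterError(f"cannot parse term part '{p}'")
        return cls(tuple(sorted(factors)), tpow)

    def marginals(self) -> set["Term"]:
        """Immediate lower-order terms implied by this one."""
        out: set[Term] = set()
        for f in self.factors:
            reduced = tuple(x for x in self.factors if x != f)
            if reduced or self.tpow > 0:
                out.add(Term(reduced, self.tpow))
        if self.tpow > 1 or (self.tpow == 1 and self.factors):
            out.add(Term(self.factors, self.tpow - 1))
        return out

    def ancestors_of(self, other: "Term") -> bool:
        """True when ``other`` is a (transitive) marginal of this term."""
        frontier = self.marginals()
        seen = set()
        while frontier:
            t = frontier.pop()
            if t == other:
                return True
            if t not in seen:
                seen.add(t)
                frontier |= t.marginals()
        return False


@dataclass
class ModelSpec:
    """Ordered fixed-effect term list plus the two variance switches."""

    terms: list[Term]
    ar1: bool = True
    var_by_age: bool = True
    shared_phi: bool = True

    def __post_init__(self):
        seen = set(self.terms)
        if len(seen) != len(self.terms):
            raise ParameterError("duplicate terms in model spec")
        for t in self.terms:
            for m in t.marginals():
                if m not in seen:
                    raise ParameterError(
                        f"term '{t.label}' present without its marginal '{m.label}'")

    @classmethod
    def full(cls, ar1: bool = True, var_by_age: bool = True) -> "ModelSpec":
        """All 15 terms of the complete double/triple-interaction model."""
        terms = []
        for factors in ((), ("age",), ("area",), ("age", "area")):
            for tpow in range(4):
                if not factors and tpow == 0:
                    continue
                terms.append(Term(tuple(sorted(factors)), tpow))
        return cls(terms, ar1=ar1, var_by_age=var_by_age)

    @classmethod
    def from_labels(cls, labels: Sequence[str], **kw) -> "ModelSpec":
        return cls([Term.parse(s) for s in labels], **kw)

    def without(self, term: Term) -> "ModelSpec":
        return ModelSpec([t for t in self.terms if t != term],
                         ar1=self.ar1, var_by_age=self.var_by_age,
                         shared_phi=self.shared_phi)

    def removable(self) -> list[Term]:
        """Terms whose removal keeps the spec hierarchical: no remaining term
        has them as a (transitive) marginal."""
        return [t for t in self.terms
                if not any(o != t and o.ancestors_of(t) for o in self.terms)]


# ---------------------------------------------------------------------------
# data and design
# ---------------------------------------------------------------------------

@dataclass
class LongDataset:
    """Long-format panel: one row per (age group, area, time) with a rate."""

    df: pd.DataFrame

    def __post_init__(self):
        need = {"age_group", "area", "time", "rate"}
        missing = need - set(self.df.columns)
        if missing:
            raise ParameterError(f"LongDataset missing columns: {sorted(missing)}")
        df = self.df.copy()
        df["area"] = df["area"].astype(str)
        df["age_group"] = df["age_group"].astype(str)
        self.df = df.sort_values(["age_group", "area", "time"],
                                 kind="mergesort").reset_index(drop=True)

    def age_levels(self) -> list[str]:
        uniq = set(self.df["age_group"])
        if uniq <= set(AGE_LEVELS):
            return [a for a in AGE_LEVELS if a in uniq]
        return sorted(uniq)

    def area_levels(self) -> list[str]:
        return sorted(set(self.df["area"]))


class DesignEncoder:
    """Sum-to-zero design-matrix encoder shared by fitting and marginal-mean
    contrasts."""

    def __init__(self, d: LongDataset, spec: ModelSpec):
        self.spec = spec
        self.ages = d.age_levels()
        self.areas = d.area_levels()
        times = np.unique(d.df["time"].to_numpy(float))
        self.t_mid = (times.min() + times.max()) / 2.0
        diffs = np.diff(times)
        self.t_step = float(diffs.min()) if len(diffs) else 1.0
        self.times = times
        self._c_age = _sum_to_zero(len(self.ages))
        self._c_area = _sum_to_zero(len(self.areas))

    def tstar(self, t) -> np.ndarray:
        return (np.asarray(t, float) - self.t_mid) / self.t_step

    def term_width(self, term: Term) -> int:
        w = 1
        if "age" in term.factors:
            w *= len(self.ages) - 1
        if "area" in term.factors:
            w *= len(self.areas) - 1
        return w

    def term_block(self, term: Term, age_idx: np.ndarray, area_idx: np.ndarray,
                   ts: np.ndarray) -> np.ndarray:
        cols = np.ones((len(ts), 1))
        if "age" in term.factors:
            cols = _colwise_product(cols, self._c_age[age_idx])
        if "area" in term.factors:
            cols = _colwise_product(cols, self._c_area[area_idx])
        if term.tpow:
            cols = cols * (ts ** term.tpow)[:, None]
        return cols

    def matrix(self, age_idx: np.ndarray, area_idx: np.ndarray,
               ts: np.ndarray) -> tuple[np.ndarray, dict, list[str]]:
        blocks = [np.ones((len(ts), 1))]
        slices = {"mu": slice(0, 1)}
        names = ["mu"]
        start = 1
        for term in self.spec.terms:
            b = self.term_block(term, age_idx, area_idx, ts)
            blocks.append(b)
            stop = start + b.shape[1]
            slices[term.label] = slice(start, stop)
            names += [f"{term.label}[{i}]" for i in range(b.shape[1])]
            start = stop
        return np.hstack(blocks), slices, names

    def row(self, age_level: str, area_level: str, t: float) -> np.ndarray:
        ai = np.array([self.ages.index(age_level)])
        bi = np.array([self.areas.index(area_level)])
        X, _, _ = self.matrix(ai, bi, self.tstar([t]))
        return X[0]


def _sum_to_zero(levels: int) -> np.ndarray:
    c = np.zeros((levels, levels - 1))
    c[: levels - 1, :] = np.eye(levels - 1)
    c[levels - 1, :] = -1.0
    return c


def _colwise_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, :, None] * b[:, None, :]).reshape(len(a), -1)


def build_design(d: LongDataset, spec: ModelSpec):
    """Design matrix, term -> column-slice map and encoder for a model spec.

    Raises a design error naming the first collinear term block when the
    assembled matrix is rank-deficient.
    """
    enc = DesignEncoder(d, spec)
    age_idx = np.array([enc.ages.index(a) for a in d.df["age_group"]])
    area_idx = np.array([enc.areas.index(a) for a in d.df["area"]])
    ts = enc.tstar(d.df["time"].to_numpy(float))
    X, slices, names = enc.matrix(age_idx, area_idx, ts)
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        for label, sl in slices.items():
            other = np.delete(np.arange(X.shape[1]), np.arange(sl.start, sl.stop))
            if np.linalg.matrix_rank(X) == np.linalg.matrix_rank(X[:, other]):
                raise FitError(f"design is rank deficient; block '{label}' is collinear")
        raise FitError("design is rank deficient")
    return X, slices, names, enc


# ---------------------------------------------------------------------------
# REML fitting
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    """A REML-fitted longitudinal model."""

    beta_hat: np.ndarray
    vcov_beta: np.ndarray
    phi: float
    sigma2: float
    var_weights: dict[str, float]
    loglik_reml: float
    loglik_ml: float
    df_resid: int
    n_obs: int
    term_slices: dict[str, slice]
    colnames: list[str]
    spec: ModelSpec
    encoder: DesignEncoder
    converged: bool
    objective_trace: list[float] = field(default_factory=list)

    def coef(self) -> pd.Series:
        return pd.Series(self.beta_hat, index=self.colnames)


def _series_slices(d: LongDataset) -> list[slice]:
    key = d.df["age_group"].astype(str) + "\x00" + d.df["area"].astype(str)
    change = np.nonzero(key.to_numpy()[1:] != key.to_numpy()[:-1])[0] + 1
    bounds = [0, *change.tolist(), len(d.df)]
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def _whiten(X: np.ndarray, y: np.ndarray, slices: list[slice],
            phi: float, g_row: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Transform (X, y) so the error covariance becomes sigma^2 * I; returns
    the log-determinant of the correlation/weight matrix D as well."""
    Xw = X / g_row[:, None]
    yw = y / g_row
    logdet = 2.0 * float(np.sum(np.log(g_row)))
    if phi != 0.0:
        c = np.sqrt(1.0 - phi * phi)
        for sl in slices:
            T = sl.stop - sl.start
            if T < 2:
                continue
            Xw[sl.start + 1: sl.stop] = (
                Xw[sl.start + 1: sl.stop] - phi * Xw[sl.start: sl.stop - 1]) / c
            yw[sl.start + 1: sl.stop] = (
                yw[sl.start + 1: sl.stop] - phi * yw[sl.start: sl.stop - 1]) / c
            logdet += (T - 1) * np.log(1.0 - phi * phi)
    return Xw, yw, logdet


def _gls(Xw: np.ndarray, yw: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    return beta, rss


def reml_fit(d: LongDataset, spec: ModelSpec) -> TrendFit:
    """Fit the heteroscedastic AR(1) longitudinal model by REML.

    phi is kept inside (-1, 1) by a hyperbolic-tangent reparameterization and
    the age-group variance multipliers are optimized on the log scale
    (reference group fixed at 1). The fixed effects are profiled out by
    generalized least squares at every variance-parameter candidate.
    """
    X, slices, names, enc = build_design(d, spec)
    y = d.df["rate"].to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise FitError(f"not enough observations ({n}) for {p} fixed effects")
    ser = _series_slices(d)
    if spec.ar1:
        for sl in ser:
            if sl.stop - sl.start < 2:
                raise FitError("AR(1) requires >= 2 time points per series")
    ages = enc.ages
    age_of_row = d.df["age_group"].to_numpy()
    age_pos = np.array([ages.index(a) for a in age_of_row])

    n_phi = 1 if spec.ar1 else 0
    n_g = len(ages) - 1 if spec.var_by_age else 0

    def unpack(theta):
        phi = float(np.tanh(theta[0])) if n_phi else 0.0
        g = np.ones(len(ages))
        if n_g:
            g[1:] = np.exp(theta[n_phi: n_phi + n_g])
        return phi, g

    trace: list[float] = []

    def neg2_reml(theta):
        phi, g = unpack(theta)
        g_row = g[age_pos]
        try:
            Xw, yw, logdet = _whiten(X, y, ser, phi, g_row)
            beta, rss = _gls(Xw, yw)
            sign, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        except np.linalg.LinAlgError:
            return 1e30
        if sign <= 0 or rss <= 0 or not np.isfinite(rss):
            return 1e30
        return ((n - p) * np.log(rss / (n - p)) + logdet + logdet_xx
                + (n - p) * (1.0 + np.log(2 * np.pi)))

    converged = True
    if n_phi + n_g:
        x0 = np.zeros(n_phi + n_g)
        # |phi| <= tanh(4) ~ 0.9993 and weight ratios within e^(+-8)
        bnds = [(-4.0, 4.0)] * n_phi + [(-8.0, 8.0)] * n_g
        res = minimize(neg2_reml, x0, method="L-BFGS-B", bounds=bnds,
                       callback=lambda xk: trace.append(neg2_reml(xk)),
                       options={"maxiter": 200, "ftol": 1e-12})
        theta = res.x
        converged = bool(res.success)
        if not converged and res.fun >= 1e29:
            raise FitError("REML optimization failed to find a valid point")
    else:
        theta = np.zeros(0)

    phi, g = unpack(theta)
    g_row = g[age_pos]
    Xw, yw, logdet = _whiten(X, y, ser, phi, g_row)
    beta, rss = _gls(Xw, yw)
    sigma2 = rss / (n - p)
    XtX = Xw.T @ Xw
    vcov = sigma2 * np.linalg.inv(XtX)
    vcov = (vcov + vcov.T) / 2.0
    _, logdet_xx = np.linalg.slogdet(XtX)
    loglik_reml = -0.5 * ((n - p) * np.log(sigma2) + logdet + logdet_xx
                          + (n - p) * (1.0 + np.log(2 * np.pi)))
    sigma2_ml = rss / n
    loglik_ml = -0.5 * (n * np.log(sigma2_ml) + logdet
                        + n * (1.0 + np.log(2 * np.pi)))
    return TrendFit(
        beta_hat=beta, vcov_beta=vcov, phi=phi, sigma2=sigma2,
        var_weights={a: float(w) for a, w in zip(ages, g)},
        loglik_reml=float(loglik_reml), loglik_ml=float(loglik_ml),
        df_resid=n - p, n_obs=n, term_slices=slices, colnames=names,
        spec=spec, encoder=enc, converged=converged,
        objective_trace=trace)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def type3_anova(fit: TrendFit) -> pd.DataFrame:
    """Marginal (Type III) Wald F tests: each term's whole contrast block is
    tested given every other term, with denominator df = residual df."""
    rows = []
    for label, sl in fit.term_slices.items():
        q = sl.stop - sl.start
        b = fit.beta_hat[sl]
        V = fit.vcov_beta[sl, sl]
        try:
            F = float(b @ np.linalg.solve(V, b)) / q
        except np.linalg.LinAlgError:
            rows.append({"term": label, "df": q, "F": np.nan, "p": np.nan,
                         "error": "singular contrast covariance"})
            continue
        p = float(stats.f.sf(F, q, fit.df_resid))
        rows.append({"term": label, "df": q, "F": F, "p": p, "error": ""})
    return pd.DataFrame(rows)


def lrt(fit_full: TrendFit, fit_reduced: TrendFit) -> tuple[float, int, float]:
    """Maximum-likelihood ratio test between nested fixed-effect models,
    evaluated at each model's REML variance structure."""
    stat = 2.0 * (fit_full.loglik_ml - fit_reduced.loglik_ml)
    df = len(fit_full.beta_hat) - len(fit_reduced.beta_hat)
    stat = max(stat, 0.0)
    return stat, df, float(stats.chi2.sf(stat, max(df, 1)))


def backstep_select(d: LongDataset, full: ModelSpec, alpha: float = 0.05):
    """Backward elimination of fixed-effect terms.

    At each step the removable (hierarchy-preserving) term with the largest
    Type III p-value is dropped first; the removal is accepted when the ML
    likelihood-ratio test against the larger model is non-significant
    (p > alpha). Candidates are tried in descending Type III p order; the
    procedure stops when no removable term can be dropped.
    """
    spec = full
    fit = reml_fit(d, spec)
    trace: list[dict] = []
    while True:
        removable = spec.removable()
        if not removable:
            break
        an = type3_anova(fit).set_index("term")
        cand = sorted(removable, key=lambda t: -an.loc[t.label, "p"])
        accepted = False
        for term in cand:
            reduced_spec = spec.without(term)
            reduced_fit = reml_fit(d, reduced_spec)
            stat, df, p_lrt = lrt(fit, reduced_fit)
            rec = {"term": term.label, "p_type3": float(an.loc[term.label, "p"]),
                   "lrt_stat": stat, "lrt_df": df, "p_lrt": p_lrt,
                   "removed": p_lrt > alpha}
            trace.append(rec)
            if p_lrt > alpha:
                spec, fit = reduced_spec, reduced_fit
                accepted = True
                break
        if not accepted:
            break
    return fit, trace


def emmeans(fit: TrendFit, term: str):
    """Estimated marginal means for 'age', 'area' or 'age:area'.

    Each level's mean is the model prediction averaged over a balanced grid of
    the other factor's levels and the observed time points; standard errors
    come from the fixed-effect covariance through the averaging contrast.
    Returns (levels, means, ses, joint covariance).
    """
    if term not in ("age", "area", "age:area"):
        raise ParameterError("term must be one of 'age', 'area', 'age:area'")
    present = set(fit.term_slices)
    if term == "age:area":
        if "age:area" not in present:
            raise ParameterError("term 'age:area' not in the fitted model")
    elif term not in present:
        raise ParameterError(f"term '{term}' not in the fitted model")
    enc = fit.encoder
    ts = enc.tstar(enc.times)
    if term == "age":
        combos = [(a, None) for a in enc.ages]
    elif term == "area":
        combos = [(None, b) for b in enc.areas]
    else:
        combos = [(a, b) for a in enc.ages for b in enc.areas]
    p = len(fit.beta_hat)
    C = np.zeros((len(combos), p))
    for r, (a_fix, b_fix) in enumerate(combos):
        a_list = [a_fix] if a_fix is not None else enc.ages
        b_list = [b_fix] if b_fix is not None else enc.areas
        rows = []
        for a in a_list:
            ai = np.full(len(ts), enc.ages.index(a))
            for b in b_list:
                bi = np.full(len(ts), enc.areas.index(b))
                X, _, _ = enc.matrix(ai, bi, ts)
                rows.append(X.mean(axis=0))
        C[r] = np.mean(rows, axis=0)
    means = C @ fit.beta_hat
    vc = C @ fit.vcov_beta @ C.T
    ses = np.sqrt(np.maximum(np.diag(vc), 0.0))
    labels = [":".join(x for x in (a, b) if x is not None) for a, b in combos]
    return labels, means, ses, vc


def lsd_letters(levels: Sequence[str], means: np.ndarray, vcov: np.ndarray,
                df_resid: int, alpha: float = 0.05,
                correction: str = "bonferroni") -> pd.DataFrame:
    """Fisher's-LSD pairwise t tests with Bonferroni correction, summarised as
    a compact letter display (insert-and-absorb).

    Two levels share at least one letter exactly when their adjusted p-value
    exceeds alpha. Letters follow levels sorted by descending mean.
    """
    m = len(levels)
    if m < 2:
        raise ParameterError("need at least 2 levels for pairwise letters")
    means = np.asarray(means, float)
    npairs = m * (m - 1) // 2
    mult = npairs if correction == "bonferroni" else 1
    diff_sig = np.zeros((m, m), dtype=bool)
    pmat = np.ones((m, m))
    for i, j in itertools.combinations(range(m), 2):
        se2 = vcov[i, i] + vcov[j, j] - 2 * vcov[i, j]
        if se2 <= 0:
            p_adj = 1.0 if means[i] == means[j] else 0.0
        else:
            tval = (means[i] - means[j]) / np.sqrt(se2)
            p_adj = min(2.0 * float(stats.t.sf(abs(tval), df_resid)) * mult, 1.0)
        pmat[i, j] = pmat[j, i] = p_adj
        diff_sig[i, j] = diff_sig[j, i] = p_adj <= alpha

    order = np.argsort(-means, kind="mergesort")
    columns: list[set[int]] = [set(range(m))]
    for a, b in itertools.combinations(range(m), 2):
        i, j = order[a], order[b]
        if not diff_sig[i, j]:
            continue
        new_cols: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new_cols.append(col - {int(i)})
                new_cols.append(col - {int(j)})
            else:
                new_cols.append(col)
        # absorb: drop empties and strict subsets, then dedupe
        uniq: list[set[int]] = []
        for col in new_cols:
            if not col or any(col < other for other in new_cols):
                continue
            if col not in uniq:
                uniq.append(col)
        columns = uniq
    # order columns by the best (largest-mean) level they contain
    rank = {int(lv): pos for pos, lv in enumerate(order)}
    columns.sort(key=lambda col: min(rank[lv] for lv in col))
    import string

    alphabet = string.ascii_uppercase + string.ascii_lowercase
    letters = {lv: "" for lv in range(m)}
    for ci, col in enumerate(columns):
        ch = alphabet[ci % len(alphabet)]
        for lv in col:
            letters[lv] += ch
    rows = []
    for pos in order:
        rows.append({"level": levels[pos], "mean": means[pos],
                     "se": float(np.sqrt(max(vcov[pos, pos], 0.0))),
                     "letters": "".join(sorted(letters[pos]))})
    out = pd.DataFrame(rows)
    out.attrs["p_adjusted"] = pd.DataFrame(pmat, index=list(levels),
                                           columns=list(levels))
    return out
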