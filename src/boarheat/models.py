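"""The three activity models and their derived effect summaries.

* ``fit_gam_hourly`` — hourly activity (sum of smoothed VeDBA) against
  hourly temperature, hour of day (cyclic) and their tensor-product
  interaction, every smooth split by the binary precipitation factor, plus
  a linear precipitation main effect and an animal random intercept.
* ``fit_gam_seasonal`` — daily mean activity (or a daily movement metric)
  against daily maximum temperature, day of year and their interaction,
  again by precipitation, with an animal random intercept.
* ``fit_lmm_heatwave`` — heatwave-period mean activity against scaled mean
  daily maximum temperature, heatwave length and precipitation presence
  with both temperature x precipitation and length x precipitation
  interactions; a Gaussian linear mixed model with an animal intercept.

The additive models are penalized regression splines (P-splines) estimated
by penalized least squares; smoothing parameters — including the ridge
parameter that makes the animal intercepts a random effect — are chosen by
generalized cross-validation, an REML-equivalent criterion for Gaussian
smoothing problems.  Smooth-term significance uses an approximate Wald
test on the Bayesian coefficient covariance and should be read as a
screening statistic, conservative under heavy penalization.

Population-level predictions set the animal effect to zero; since the
reported effect contrasts are ratios of predicted window means, this
intercept-level choice is part of the contrast definition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import optimize, stats

from ._pspline import (
    bspline_design,
    cyclic_design,
    cyclic_diff_penalty,
    diff_penalty,
    row_kron,
    sum_to_zero,
)

__all__ = [
    "FitResult",
    "LmmResult",
    "fit_gam_hourly",
    "fit_gam_seasonal",
    "fit_lmm_heatwave",
    "percent_change",
    "night_day_elevation",
    "temp_response_curve",
    "doy_response_curve",
]

log = logging.getLogger(__name__)

NIGHT_WINDOW = (22, 23, 0, 1, 2, 3)
DAY_WINDOW = tuple(range(5, 22))


# ------------------------------------------------------------------ terms


class _Term:
    name: str
    penalties: list[np.ndarray]

    def build(self, df: pd.DataFrame) -> np.ndarray:  # training design
        raise NotImplementedError

    def build_predict(self, df: pd.DataFrame, population: bool) -> np.ndarray:
        return self.build(df)


class _Intercept(_Term):
    def __init__(self):
        self.name = "(intercept)"
        self.penalties = []

    def build(self, df):
        return np.ones((len(df), 1))


class _Linear(_Term):
    def __init__(self, var: str):
        self.name = var
        self.var = var
        self.penalties = []

    def build(self, df):
        return df[self.var].to_numpy(dtype=float)[:, None]


class _Smooth(_Term):
    """Univariate P-spline, optionally cyclic, optionally by a binary factor."""

    def __init__(self, var, k=8, cyclic=False, period=24.0, by=None, by_level=None):
        self.var, self.k, self.cyclic, self.period = var, k, cyclic, period
        self.by, self.by_level = by, by_level
        lvl = f",{by}={by_level}" if by else ""
        self.name = f"s({var}{lvl})" if not cyclic else f"s({var},cc{lvl})"
        self.Z = None

    def _raw(self, x):
        if self.cyclic:
            return cyclic_design(x, self.period, self.k)
        return bspline_design(x, self.lo, self.hi, self.k)

    def _mask(self, df):
        if self.by is None:
            return np.ones(len(df))
        return (df[self.by].to_numpy() == self.by_level).astype(float)

    def build(self, df):
        x = df[self.var].to_numpy(dtype=float)
        if not self.cyclic:
            self.lo, self.hi = float(np.min(x)), float(np.max(x))
        B = self._raw(x) * self._mask(df)[:, None]
        self.Z = sum_to_zero(B)
        S = cyclic_diff_penalty(self.k) if self.cyclic else diff_penalty(self.k)
        self.penalties = [self.Z.T @ S @ self.Z]
        return B @ self.Z

    def build_predict(self, df, population):
        x = df[self.var].to_numpy(dtype=float)
        return (self._raw(x) * self._mask(df)[:, None]) @ self.Z


class _Tensor(_Term):
    """Tensor-product interaction smooth of two covariates (pure interaction)."""

    def __init__(self, var1, var2, k1=5, k2=5, cyclic2=False, period2=24.0, by=None, by_level=None):
        self.var1, self.var2, self.k1, self.k2 = var1, var2, k1, k2
        self.cyclic2, self.period2 = cyclic2, period2
        self.by, self.by_level = by, by_level
        lvl = f",{by}={by_level}" if by else ""
        self.name = f"ti({var1},{var2}{lvl})"
        self.Z1 = self.Z2 = None

    def _mask(self, df):
        if self.by is None:
            return np.ones(len(df))
        return (df[self.by].to_numpy() == self.by_level).astype(float)

    def _marginals(self, df):
        x1 = df[self.var1].to_numpy(dtype=float)
        x2 = df[self.var2].to_numpy(dtype=float)
        B1 = bspline_design(x1, self.lo1, self.hi1, self.k1)
        B2 = (
            cyclic_design(x2, self.period2, self.k2)
            if self.cyclic2
            else bspline_design(x2, self.lo2, self.hi2, self.k2)
        )
        return B1, B2

    def build(self, df):
        x1 = df[self.var1].to_numpy(dtype=float)
        x2 = df[self.var2].to_numpy(dtype=float)
        self.lo1, self.hi1 = float(x1.min()), float(x1.max())
        if not self.cyclic2:
            self.lo2, self.hi2 = float(x2.min()), float(x2.max())
        B1, B2 = self._marginals(df)
        m = self._mask(df)[:, None]
        self.Z1 = sum_to_zero(B1 * m)
        self.Z2 = sum_to_zero(B2 * m)
        X = row_kron(B1 @ self.Z1, B2 @ self.Z2) * m
        S1 = self.Z1.T @ diff_penalty(self.k1) @ self.Z1
        S2c = cyclic_diff_penalty(self.k2) if self.cyclic2 else diff_penalty(self.k2)
        S2 = self.Z2.T @ S2c @ self.Z2
        p1, p2 = S1.shape[0], S2.shape[0]
        self.penalties = [np.kron(S1, np.eye(p2)), np.kron(np.eye(p1), S2)]
        return X

    def build_predict(self, df, population):
        B1, B2 = self._marginals(df)
        return row_kron(B1 @ self.Z1, B2 @ self.Z2) * self._mask(df)[:, None]


class _RandomIntercept(_Term):
    """Ridge-penalized group dummies == Gaussian random intercept.

    The dummies are reparameterized to sum to zero over the data so the
    grand mean stays in the fixed intercept and setting the random effect
    to zero predicts at the population level.
    """

    def __init__(self, var):
        self.var = var
        self.name = f"re({var})"
        self.levels = None
        self.Z = None

    def _dummies(self, df):
        idx = pd.Categorical(df[self.var], categories=self.levels).codes
        X = np.zeros((len(df), len(self.levels)))
        valid = idx >= 0
        X[np.where(valid)[0], idx[valid]] = 1.0
        return X

    def build(self, df):
        self.levels = np.array(sorted(pd.unique(df[self.var])))
        D = self._dummies(df)
        self.Z = sum_to_zero(D)
        self.penalties = [self.Z.T @ self.Z]
        return D @ self.Z

    def build_predict(self, df, population):
        if population:
            return np.zeros((len(df), len(self.levels) - 1))
        return self._dummies(df) @ self.Z


# ---------------------------------------------------------------- fitting


@dataclass
class FitResult:
    """A fitted penalized additive mixed model."""

    terms: list
    slices: dict
    beta: np.ndarray
    cov: np.ndarray  # Bayesian coefficient covariance
    lam: np.ndarray  # smoothing parameters, one per penalty
    edf_by_term: dict
    edf_total: float
    sigma2: float
    rss: float
    n: int
    r2_adj: float
    dev_expl: float
    term_pvalues: dict
    response: str
    meta: dict = field(default_factory=dict)

    def predict(self, df: pd.DataFrame, population: bool = True) -> np.ndarray:
        """Predicted response; ``population=True`` sets the animal effect to 0."""
        X = np.hstack([t.build_predict(df, population) for t in self.terms])
        out = X @ self.beta
        if not np.isfinite(out).all():
            raise FloatingPointError("non-finite predictions")
        return out

    def term_effect(self, name: str, df: pd.DataFrame) -> np.ndarray:
        """Partial (centred) contribution of one term to the linear predictor."""
        for t in self.terms:
            if t.name == name:
                return t.build_predict(df, True) @ self.beta[self.slices[name]]
        raise KeyError(name)

    def summary(self) -> str:
        lines = [
            f"Penalized additive mixed model: {self.response}",
            f"n = {self.n}; adj R^2 = {self.r2_adj:.3f}; deviance explained = {self.dev_expl:.3f}",
            f"residual sd = {np.sqrt(self.sigma2):.3f}; total edf = {self.edf_total:.2f}",
            "",
            f"{'term':34s} {'edf':>7s} {'p(approx)':>10s}",
        ]
        for name, edf in self.edf_by_term.items():
            p = self.term_pvalues.get(name)
            ptxt = "--" if p is None else f"{p:.4f}"
            lines.append(f"{name:34s} {edf:7.2f} {ptxt:>10s}")
        return "\n".join(lines)


def _gcv_fit(y: np.ndarray, X: np.ndarray, pen_entries: list, n: int):
    """Select smoothing parameters by GCV; return solver state at the optimum."""
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    ridge = 1e-9 * np.trace(XtX) / p * np.eye(p)

    def solve(loglam):
        A = XtX + ridge
        for (sl, S), ll in zip(pen_entries, loglam):
            A = A.copy() if A is XtX else A
            A[sl, sl] += np.exp(ll) * S
        try:
            cho = scipy.linalg.cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            return None
        beta = scipy.linalg.cho_solve(cho, Xty)
        H = scipy.linalg.cho_solve(cho, XtX)
        edf = float(np.trace(H))
        rss = max(yty - 2.0 * beta @ Xty + beta @ (XtX @ beta), 1e-12)
        return beta, H, edf, rss, cho

    def gcv(loglam):
        out = solve(loglam)
        if out is None:
            return np.inf
        _, _, edf, rss, _ = out
        if n - edf < 1.0:
            return np.inf
        return n * rss / (n - edf) ** 2

    d = len(pen_entries)
    cur = np.full(d, 4.0)
    if d:
        grid = np.arange(-2.0, 17.0, 2.0)
        for _ in range(2):  # coordinate descent passes
            for j in range(d):
                vals = []
                for g in grid:
                    trial = cur.copy()
                    trial[j] = g
                    vals.append(gcv(trial))
                cur[j] = grid[int(np.argmin(vals))]
        res = optimize.minimize(
            gcv,
            cur,
            method="Nelder-Mead",
            options={"maxfev": 60 * d, "xatol": 0.25, "fatol": 1e-3, "adaptive": True},
        )
        if np.isfinite(res.fun):
            cur = res.x
    out = solve(cur)
    if out is None:
        raise FloatingPointError("penalized fit failed to converge (singular system)")
    beta, H, edf, rss, cho = out
    return cur, beta, H, edf, rss, cho, XtX


def _fit_terms(df: pd.DataFrame, response: str, terms: list, meta: dict) -> FitResult:
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    blocks, slices, pen_entries = [], {}, []
    col = 0
    for t in terms:
        B = t.build(df)
        sl = slice(col, col + B.shape[1])
        slices[t.name] = sl
        for S in t.penalties:
            pen_entries.append((sl, S))
        blocks.append(B)
        col += B.shape[1]
    X = np.hstack(blocks)
    loglam, beta, H, edf, rss, cho, XtX = _gcv_fit(y, X, pen_entries, n)
    sigma2 = rss / max(n - edf, 1.0)
    cov = scipy.linalg.cho_solve(cho, np.eye(X.shape[1])) * sigma2

    edf_by_term, pvals = {}, {}
    for t in terms:
        sl = slices[t.name]
        edf_j = float(np.trace(H[sl, sl]))
        edf_by_term[t.name] = edf_j
        if t.penalties or isinstance(t, _Linear):
            b = beta[sl]
            V = cov[sl, sl]
            r = max(1, int(round(min(edf_j, sl.stop - sl.start))))
            # Wald statistic restricted to the r leading covariance directions,
            # so the statistic and its reference df agree (rank-truncated test)
            w, U = np.linalg.eigh(V)
            order = np.argsort(w)[::-1][:r]
            proj = U[:, order].T @ b
            stat = float(np.sum(proj**2 / np.maximum(w[order], 1e-300)))
            pvals[t.name] = float(stats.chi2.sf(stat, df=r))
    tss = float(((y - y.mean()) ** 2).sum())
    if tss > 0:
        r2_adj = 1.0 - (rss / max(n - edf, 1.0)) / (tss / (n - 1))
        dev_expl = 1.0 - rss / tss
    else:  # constant response: the model explains everything there is (nothing)
        r2_adj = dev_expl = 0.0
    return FitResult(
        terms=terms,
        slices=slices,
        beta=beta,
        cov=cov,
        lam=np.exp(loglam),
        edf_by_term=edf_by_term,
        edf_total=edf,
        sigma2=sigma2,
        rss=rss,
        n=n,
        r2_adj=r2_adj,
        dev_expl=dev_expl,
        term_pvalues=pvals,
        response=response,
        meta=meta,
    )


def _precip_levels(df: pd.DataFrame, var: str) -> list:
    levels = sorted(pd.unique(df[var]))
    if len(levels) == 1:
        warnings.warn(
            f"only one level of {var} present; by-factor smooths collapse to plain smooths",
            stacklevel=3,
        )
    return levels


def fit_gam_hourly(
    table: pd.DataFrame,
    response: str = "vedba_sum",
    k: int = 12,
    k_tensor: int = 5,
) -> FitResult:
    """Hourly weather-activity model (diel scale).

    Requires columns ``vedba_sum`` (or ``response``), ``temp``,
    ``clock_hour``, ``precip_presence`` (0/1, the hour's own precipitation)
    and ``animal_id``.
    """
    need = {response, "temp", "clock_hour", "precip_presence", "animal_id"}
    if not need <= set(table.columns):
        raise ValueError(f"missing columns: {sorted(need - set(table.columns))}")
    df = table.reset_index(drop=True)
    levels = _precip_levels(df, "precip_presence")
    terms: list = [_Intercept()]
    if len(levels) > 1:
        terms.append(_Linear("precip_presence"))
    for lv in levels:
        by = "precip_presence" if len(levels) > 1 else None
        terms.append(_Smooth("temp", k=k, by=by, by_level=lv))
        terms.append(_Smooth("clock_hour", k=k, cyclic=True, period=24.0, by=by, by_level=lv))
        terms.append(
            _Tensor("temp", "clock_hour", k1=k_tensor, k2=k_tensor, cyclic2=True, by=by, by_level=lv)
        )
        if by is None:
            break
    terms.append(_RandomIntercept("animal_id"))
    meta = {
        "kind": "hourly",
        "temp_var": "temp",
        "hour_var": "clock_hour",
        "precip_var": "precip_presence",
        "obs_temp": df["temp"].to_numpy(dtype=float),
        "precip_freq": df["precip_presence"].value_counts(normalize=True).to_dict(),
    }
    return _fit_terms(df, response, terms, meta)


def fit_gam_seasonal(
    table: pd.DataFrame,
    response: str = "vedba_daily_mean",
    k: int = 10,
    k_tensor: int = 5,
) -> FitResult:
    """Seasonal model: daily response vs daily maximum temperature and DOY.

    Used both for daily mean VeDBA and, post hoc, for the daily movement
    metrics (distance, max NSD, mean speed) as alternative responses.
    """
    need = {response, "temp_max", "doy", "precip_presence", "animal_id"}
    if not need <= set(table.columns):
        raise ValueError(f"missing columns: {sorted(need - set(table.columns))}")
    df = table.reset_index(drop=True)
    levels = _precip_levels(df, "precip_presence")
    terms: list = [_Intercept()]
    if len(levels) > 1:
        terms.append(_Linear("precip_presence"))
    for lv in levels:
        by = "precip_presence" if len(levels) > 1 else None
        terms.append(_Smooth("temp_max", k=k, by=by, by_level=lv))
        terms.append(_Smooth("doy", k=k, by=by, by_level=lv))
        terms.append(_Tensor("temp_max", "doy", k1=k_tensor, k2=k_tensor, by=by, by_level=lv))
        if by is None:
            break
    terms.append(_RandomIntercept("animal_id"))
    meta = {
        "kind": "seasonal",
        "temp_var": "temp_max",
        "doy_var": "doy",
        "precip_var": "precip_presence",
        "obs_temp": df["temp_max"].to_numpy(dtype=float),
        "obs_doy": df["doy"].to_numpy(dtype=float),
        "precip_freq": df["precip_presence"].value_counts(normalize=True).to_dict(),
    }
    return _fit_terms(df, response, terms, meta)


# ------------------------------------------------------------- LMM


@dataclass
class LmmResult:
    """Gaussian linear mixed model for heatwave-period activity."""

    coef: pd.DataFrame  # estimate, se, ci_lo, ci_hi, p per fixed effect
    var_animal: float
    var_resid: float
    r2_marginal: float
    r2_conditional: float
    n: int
    n_heatwaves: int
    n_animals: int
    scaling: dict  # covariate -> (mean, sd) used for z-scoring

    def summary(self) -> str:
        lines = [
            f"Heatwave LMM: n = {self.n} ({self.n_heatwaves} heatwaves, {self.n_animals} animals)",
            f"marginal R^2 = {self.r2_marginal:.3f}; conditional R^2 = {self.r2_conditional:.3f}",
            "",
            self.coef.to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


def fit_lmm_heatwave(table: pd.DataFrame) -> LmmResult:
    """Mixed model of heatwave-period mean activity.

    Fixed effects: z-scored mean daily maximum temperature, z-scored
    heatwave length (days), precipitation presence, and the two
    temperature x precipitation and length x precipitation interactions.
    Random: animal intercept.  Estimated by maximum likelihood.
    """
    import statsmodels.formula.api as smf

    need = {"vedba_mean", "tmax_mean", "length_days", "precip_presence", "animal_id", "heatwave_id"}
    if not need <= set(table.columns):
        raise ValueError(f"missing columns: {sorted(need - set(table.columns))}")
    if table["heatwave_id"].nunique() < 2:
        raise ValueError("need at least 2 heatwaves to fit the mixed model")
    if table["animal_id"].nunique() < 2:
        raise ValueError("need at least 2 animals to fit the mixed model")
    per_level = table.drop_duplicates("heatwave_id").groupby("precip_presence").size()
    if len(per_level) == 2 and per_level.min() < 2:
        raise ValueError(
            "need at least 2 heatwaves per precipitation level to estimate the "
            "precipitation interactions; inestimable"
        )
    df = table.copy()
    scaling = {}
    for v, z in [("tmax_mean", "tmax_z"), ("length_days", "length_z")]:
        mu, sd = float(df[v].mean()), float(df[v].std(ddof=0))
        sd = sd if sd > 0 else 1.0
        df[z] = (df[v] - mu) / sd
        scaling[v] = (mu, sd)
    df["precip"] = df["precip_presence"].astype(float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "vedba_mean ~ tmax_z + length_z + precip + tmax_z:precip + length_z:precip",
            data=df,
            groups=df["animal_id"],
        )
        X = np.asarray(model.exog)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "heatwave fixed-effect design is rank-deficient (too few heatwaves "
                "per precipitation level to separate the interactions); inestimable"
            )
        res = model.fit(reml=False)

    fe = res.fe_params
    se = res.bse_fe
    # Wald intervals on a t reference with cluster-level df: the weather
    # covariates vary only between heatwaves, so the effective replication
    # for their coefficients is the number of heatwaves, not of rows.
    ddf = max(int(df["heatwave_id"].nunique()) - len(fe), 1)
    tcrit = stats.t.ppf(0.975, ddf)
    tstat = fe / se
    coef = pd.DataFrame(
        {
            "estimate": fe,
            "se": se,
            "ci_lo": fe - tcrit * se,
            "ci_hi": fe + tcrit * se,
            "p": 2.0 * stats.t.sf(np.abs(tstat), ddf),
        }
    )
    var_animal = float(res.cov_re.iloc[0, 0])
    var_resid = float(res.scale)
    X = model.exog
    var_fixed = float(np.var(X @ fe.to_numpy()))
    denom = var_fixed + var_animal + var_resid
    return LmmResult(
        coef=coef,
        var_animal=var_animal,
        var_resid=var_resid,
        r2_marginal=var_fixed / denom,
        r2_conditional=(var_fixed + var_animal) / denom,
        n=len(df),
        n_heatwaves=int(df["heatwave_id"].nunique()),
        n_animals=int(df["animal_id"].nunique()),
        scaling=scaling,
    )


# -------------------------------------------------------------- contrasts


def _window_grid(fit: FitResult, hours, temp: float, precip: int) -> pd.DataFrame:
    m = fit.meta
    return pd.DataFrame(
        {
            m["hour_var"]: list(hours),
            m["temp_var"]: temp,
            m["precip_var"]: precip,
        }
    )


def percent_change(fit: FitResult, window_a, window_b, temp: float, precip: int) -> float:
    """Percent change in predicted activity from hour window A to window B.

    Population-level predictions are averaged over each window's hour grid
    at a fixed temperature and precipitation level; the return value is
    ``100 * (mean_B - mean_A) / mean_A``.
    """
    mean_a = float(fit.predict(_window_grid(fit, window_a, temp, precip)).mean())
    mean_b = float(fit.predict(_window_grid(fit, window_b, temp, precip)).mean())
    if mean_a <= 0:
        raise ValueError(f"window A mean prediction is {mean_a:.3g} <= 0; contrast undefined")
    return 100.0 * (mean_b - mean_a) / mean_a


def night_day_elevation(fit: FitResult, n_temp: int = 11) -> float:
    """Percent elevation of night (22:00-04:00) over day (05:00-21:00) activity.

    Predictions are averaged over a quantile grid of the observed
    temperature distribution and over both precipitation levels weighted by
    their observed frequencies; the elevation is the ratio of the weighted
    night-window mean to the weighted day-window mean, minus one.
    """
    temps = np.quantile(fit.meta["obs_temp"], np.linspace(0.05, 0.95, n_temp))
    freq = fit.meta["precip_freq"]
    num = den = wsum = 0.0
    for precip, w in freq.items():
        for tmp in temps:
            a = float(fit.predict(_window_grid(fit, DAY_WINDOW, tmp, precip)).mean())
            b = float(fit.predict(_window_grid(fit, NIGHT_WINDOW, tmp, precip)).mean())
            num += w * b
            den += w * a
            wsum += w
    if den <= 0:
        raise ValueError("day-window mean prediction <= 0; contrast undefined")
    return 100.0 * (num - den) / den


def temp_response_curve(fit: FitResult, precip: int, n: int = 21) -> pd.DataFrame:
    """Predicted activity vs temperature at one precipitation level.

    Temperatures span the observed 5th-95th percentile range; predictions
    are averaged over the full 24-hour grid (hourly model) or the observed
    DOY quantiles (seasonal model).  Columns: the temperature variable and
    ``pred``.
    """
    m = fit.meta
    temps = np.quantile(m["obs_temp"], np.linspace(0.05, 0.95, n))
    preds = []
    for tmp in temps:
        if m["kind"] == "hourly":
            grid = _window_grid(fit, range(24), tmp, precip)
        else:
            doys = np.quantile(m["obs_doy"], np.linspace(0.05, 0.95, 9))
            grid = pd.DataFrame(
                {m["doy_var"]: doys, m["temp_var"]: tmp, m["precip_var"]: precip}
            )
        preds.append(float(fit.predict(grid).mean()))
    return pd.DataFrame({m["temp_var"]: temps, "pred": preds})


def doy_response_curve(fit: FitResult, precip: int | None = None, n: int = 21) -> pd.DataFrame:
    """Predicted seasonal-model response vs day of year.

    Averaged over the observed temperature quantiles; if ``precip`` is
    None, both levels are averaged with their observed frequencies.
    """
    m = fit.meta
    if m["kind"] != "seasonal":
        raise ValueError("doy_response_curve applies to seasonal fits")
    doys = np.quantile(m["obs_doy"], np.linspace(0.05, 0.95, n))
    temps = np.quantile(m["obs_temp"], np.linspace(0.05, 0.95, 9))
    freq = m["precip_freq"] if precip is None else {precip: 1.0}
    preds = []
    for d in doys:
        acc = 0.0
        for lv, w in freq.items():
            grid = pd.DataFrame({m["doy_var"]: d, m["temp_var"]: temps, m["precip_var"]: lv})
            acc += w * float(fit.predict(grid).mean())
        preds.append(acc)
    return pd.DataFrame({"doy": doys, "pred": preds})
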