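"""Daily closure frequency vs environmental covariates.

Three analyses:

* an additive model of daily closure count on spline-smoothed log
  chlorophyll-a, log phycoerythrin, pH and DO plus linear light, reported as
  an ANOVA-for-parametric-effects table (sequential Type-I F-tests on each
  term's linear component, one df each, the convention of mainstream additive
  model software) alongside the penalized-spline smooth fit itself;
* lead/lag cross-correlation between a daily covariate and daily closure
  counts, with the classic normalization (divide by N and the lag-0 standard
  deviations) so the +/-1.96/sqrt(N) white-noise bounds apply;
* the dark-vs-light rank-sum comparison of percent closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.gam.api import BSplines, GLMGam

from .events import rank_sum_test
from .gape import GapeSeries, LightPartition, closure_by_regime
from .series import EnvSeries

COVARIATE_COLUMNS = {
    "PAR": "mean_light",
    "pH": "mean_pH",
    "DO": "mean_DO",
    "chlorophyll_a": "mean_chl_rfu",
    "phycoerythrin": "mean_pe_rfu",
}


def build_daily_table(
    summaries: pd.DataFrame,
    env: list[EnvSeries],
    log_base: str = "natural",
) -> pd.DataFrame:
    """Join daily closure counts to daily-mean covariates (inner join on date).

    RFU columns get log columns (``log_chl``, ``log_pe``) floored at the
    smallest positive observed value before the log; rows missing any
    covariate are dropped and counted in ``table.attrs['n_dropped']``.
    """
    if log_base not in ("natural", "log10"):
        raise ValueError("log_base must be 'natural' or 'log10'")
    daily = summaries.copy()
    if "date" in daily.columns:
        daily = daily.set_index("date")
    daily.index = pd.to_datetime(daily.index)

    cov = {}
    for e in env:
        col = COVARIATE_COLUMNS.get(e.variable)
        if col is None:
            continue
        cov[col] = e.data.resample("1D").mean()
    if not cov:
        raise ValueError("no usable environmental series")
    covdf = pd.DataFrame(cov)
    covdf.index = pd.to_datetime(covdf.index)

    table = daily.join(covdf, how="inner")
    if table.empty:
        raise ValueError("daily join is empty: no overlapping dates")
    logf = np.log if log_base == "natural" else np.log10
    for raw, logged in (("mean_chl_rfu", "log_chl"), ("mean_pe_rfu", "log_pe")):
        if raw in table.columns:
            pos = table[raw][table[raw] > 0]
            floor = float(pos.min()) if len(pos) else np.nan
            table[logged] = logf(table[raw].clip(lower=floor))
    n0 = len(table)
    table = table.dropna()
    table.attrs["n_dropped"] = n0 - len(table)
    return table


@dataclass
class GamResult:
    """Additive-model summary: per-term ANOVA table plus the smooth fit."""

    anova: pd.DataFrame            # index: term; Df, sum_sq, mean_sq, F, p
    residual_df: float
    residual_ms: float
    edf: dict = field(default_factory=dict)   # effective df of each smooth
    model: object = None                      # fitted GLMGam results
    linear_fit: object = None                 # fitted OLS used for the ANOVA

    def term_p(self, term: str) -> float:
        return float(self.anova.loc[term, "p"])


def fit_gam(
    table: pd.DataFrame,
    response: str = "closure_count",
    smooth_terms: tuple = ("log_chl", "log_pe", "mean_pH", "mean_DO"),
    linear_terms: tuple = ("mean_light",),
    spline_df: int = 9,
    alpha: float | str = "gcv",
) -> GamResult:
    """Fit the Gaussian additive model of daily closure count.

    Smooth terms enter as penalized cubic B-splines (<= ``spline_df`` basis
    functions each, smoothing parameter by GCV when ``alpha='gcv'``); light
    enters linearly. The reported ANOVA table is the sequential Type-I ANOVA
    of the parametric (linear) components, one df per term — the table that
    additive-model software prints as "Anova for Parametric Effects" — so the
    residual df is n minus one per term minus the intercept.
    """
    cols = list(smooth_terms) + list(linear_terms)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    if len(table) < 20:
        raise ValueError(f"need >= 20 rows to fit; got {len(table)}")
    for c in cols:
        if np.ptp(table[c].to_numpy()) == 0:
            raise ValueError(f"covariate {c!r} is constant (rank deficient)")

    data = table[[response] + cols].astype(float).reset_index(drop=True)

    # Sequential one-df ANOVA on the parametric components.
    formula = f"{response} ~ " + " + ".join(cols)
    ols = smf.ols(formula, data=data).fit()
    aov = sm.stats.anova_lm(ols, typ=1)
    anova = aov.rename(
        columns={"df": "Df", "mean_sq": "mean_sq", "F": "F", "PR(>F)": "p"}
    )[["Df", "sum_sq", "mean_sq", "F", "p"]]
    resid_df = float(anova.loc["Residual", "Df"])
    resid_ms = float(anova.loc["Residual", "mean_sq"])
    anova = anova.drop(index="Residual")

    # Penalized-spline smooth fit for curves/prediction.
    x_s = data[list(smooth_terms)].to_numpy()
    n = len(data)
    df_eff = min(spline_df, max(4, n // 5))
    bs = BSplines(x_s, df=[df_eff] * len(smooth_terms), degree=[3] * len(smooth_terms))
    exog = sm.add_constant(data[list(linear_terms)])
    gam = GLMGam(data[response], exog=exog, smoother=bs,
                 family=sm.families.Gaussian())
    if alpha == "gcv":
        try:
            alphas = gam.select_penweight()[0]
        except Exception:
            alphas = np.ones(len(smooth_terms))
    else:
        alphas = np.full(len(smooth_terms), float(alpha))
    gam = GLMGam(data[response], exog=exog, smoother=bs,
                 family=sm.families.Gaussian(), alpha=alphas)
    res = gam.fit()
    edf = {}
    try:
        hat = res.get_hat_matrix_diag()
        edf["total"] = float(np.sum(hat))
    except Exception:
        pass

    return GamResult(anova=anova, residual_df=resid_df, residual_ms=resid_ms,
                     edf=edf, model=res, linear_fit=ols)


@dataclass
class CcfResult:
    """Lead/lag cross-correlation. Positive lag means y (closure) lags x
    (the covariate) — y responds ``lag`` days after x moves."""

    lags: np.ndarray
    r: np.ndarray
    conf_bound: float
    n: int

    @property
    def significant_lags(self) -> np.ndarray:
        return self.lags[np.abs(self.r) > self.conf_bound]

    def best_positive_lag(self) -> int:
        """The positive lag (>=0) with the largest correlation."""
        sel = self.lags >= 0
        return int(self.lags[sel][np.argmax(self.r[sel])])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_days": self.lags, "r": self.r,
                             "significant": np.abs(self.r) > self.conf_bound})


def ccf(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    max_lag_days: int = 14,
) -> CcfResult:
    """Cross-correlation r(k) between covariate x and closure counts y.

    r(k) correlates x_t with y_{t+k}; the estimator divides by N and the
    lag-0 standard deviations (the R ``ccf`` convention), and the white-noise
    confidence bound is 1.96/sqrt(N).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must share dates (equal length)")
    n = len(x)
    if n < 3 * max_lag_days:
        import warnings

        warnings.warn(
            f"series length {n} < 3 x max_lag ({3 * max_lag_days}); "
            "high-lag estimates are noisy",
            stacklevel=2,
        )
    sx = x.std(ddof=0)
    sy = y.std(ddof=0)
    if sx == 0 or sy == 0:
        raise ValueError("ccf: zero-variance series")
    xc = x - x.mean()
    yc = y - y.mean()
    lags = np.arange(-max_lag_days, max_lag_days + 1)
    r = np.empty(lags.shape, dtype=float)
    for i, k in enumerate(lags):
        if k >= 0:
            num = np.sum(xc[: n - k] * yc[k:])
        else:
            num = np.sum(xc[-k:] * yc[: n + k])
        r[i] = num / (n * sx * sy)
    return CcfResult(lags=lags, r=r, conf_bound=1.96 / np.sqrt(n), n=n)


def regime_median_test(
    gapes: list[GapeSeries] | GapeSeries, partition: LightPartition
) -> dict:
    """Dark vs light-present rank-sum test on pooled per-observation closure.

    W is the rank sum of the dark group; the medians of both regimes are
    reported alongside.
    """
    if isinstance(gapes, GapeSeries):
        gapes = [gapes]
    dark, light = [], []
    for g in gapes:
        if g.pct_closure is None:
            raise ValueError(f"clam {g.clam_id}: pct_closure not computed")
        reg = partition.regime_at(g.pct_closure.index).to_numpy()
        vals = g.pct_closure.to_numpy()
        ok = np.isfinite(vals)
        dark.append(vals[ok & (reg == "dark")])
        light.append(vals[ok & (reg != "dark")])
    dark = np.concatenate(dark)
    light = np.concatenate(light)
    if dark.size == 0 or light.size == 0:
        raise ValueError("regime_median_test: a regime is empty")
    res = rank_sum_test(dark, light)
    res["median_dark"] = float(np.median(dark))
    res["median_light"] = float(np.median(light))
    return res


def summarize_regimes(gapes, partition) -> pd.DataFrame:
    """Convenience: mean/SD and median summaries per light regime."""
    means = closure_by_regime(gapes, partition, statistic="mean", sd=True)
    medians = closure_by_regime(gapes, partition, statistic="median", sd=False)
    return means.join(medians["median"])
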