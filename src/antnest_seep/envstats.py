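"""Environmental association statistics.

Correlation-matrix PCA of the weather table, sequential (type-I) ANOVA of
a response regressed on the first three weather principal components,
additive trend/seasonal/residual decomposition, lagged cross-correlation,
and a 2-D Gaussian kernel density of earthquake epicenters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("antnest_seep")

WEATHER_VARS = ["temperature", "pressure", "dewpoint", "humidity",
                "rainfall", "windspeed"]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Correlation-matrix PCA of a weather table.

    ``loadings`` (variables x components) are unit-norm eigenvectors with a
    deterministic sign (largest-magnitude loading positive);
    ``cumulative_variance`` runs over all components and ends at 1.
    """

    loadings: pd.DataFrame
    cumulative_variance: np.ndarray
    center: pd.Series
    scale: pd.Series
    scores: pd.DataFrame


def weather_pca(table: pd.DataFrame,
                variables: list[str] | None = None) -> PCAResult:
    """PCA on centred and scaled weather variables."""
    variables = variables or [v for v in WEATHER_VARS if v in table.columns]
    data = table[variables].dropna()
    if len(data) < len(variables) + 1:
        raise ValueError("need more rows than variables for PCA")
    sd = data.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) for PCA: {constant}")
    center = data.mean()
    z = (data - center) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    var = s ** 2 / (len(data) - 1)
    # deterministic sign: the largest-|loading| entry of each PC positive
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    comps = [f"PC{j + 1}" for j in range(vt.shape[0])]
    loadings = pd.DataFrame(vt.T, index=variables, columns=comps)
    scores = pd.DataFrame(u * s, index=data.index, columns=comps)
    cumvar = np.cumsum(var) / var.sum()
    return PCAResult(loadings=loadings, cumulative_variance=cumvar,
                     center=center, scale=sd, scores=scores)


# ---------------------------------------------------------------------------
# PC regression ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Sequential (type-I) ANOVA of a response on PC-1..PC-3.

    ``terms`` rows carry estimate (OLS slope), df, sum_sq, MS, F and p per
    component plus a residual row; ``r2`` and the overall F summarise the
    three-term model.
    """

    terms: pd.DataFrame
    r2: float
    f_overall: float
    df_model: int
    df_resid: int
    p_overall: float
    n: int


def pc_regression_anova(y: pd.Series, pcs: pd.DataFrame,
                        n_components: int = 3) -> AnovaTable:
    """OLS of ``y`` on the first ``n_components`` PC scores with sequential
    sums of squares (PC orthogonality makes term order immaterial when the
    alignment is complete)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    comps = [f"PC{j + 1}" for j in range(n_components)]
    df = pd.concat([pd.Series(np.asarray(y, dtype=float), index=pcs.index,
                              name="y"), pcs[comps]], axis=1).dropna()
    n_dropped = len(pcs) - len(df)
    if n_dropped:
        logger.info("pc_regression_anova: %d rows dropped for missing values",
                    n_dropped)
    if len(df) <= n_components + 1:
        raise ValueError("too few aligned rows for the PC regression")
    model = ols("y ~ " + " + ".join(comps), data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova_lm F on well-posed fits only
        an = anova_lm(model, typ=1)
    terms = an.rename(columns={"sum_sq": "sum_sq", "mean_sq": "MS",
                               "F": "F", "PR(>F)": "p"})
    terms["MS"] = terms["sum_sq"] / terms["df"]
    est = model.params.reindex(terms.index)
    terms.insert(0, "estimate", est)
    return AnovaTable(terms=terms, r2=float(model.rsquared),
                      f_overall=float(model.fvalue),
                      df_model=int(model.df_model),
                      df_resid=int(model.df_resid),
                      p_overall=float(model.f_pvalue), n=len(df))


# ---------------------------------------------------------------------------
# Additive decomposition
# ---------------------------------------------------------------------------

@dataclass
class Decomposition:
    """Additive observed = trend + seasonal + residual split."""

    observed: np.ndarray
    trend: np.ndarray
    seasonal: np.ndarray
    residual: np.ndarray
    period: int


def additive_decompose(series, period: int,
                       trend_method: str = "moving_average",
                       poly_degree: int = 6) -> Decomposition:
    """Decompose a regular series into trend + seasonal + residual.

    Trend by centred moving average (statsmodels convention, edge values
    extrapolated) or by a least-squares polynomial of ``poly_degree`` in
    time; the seasonal component is the period-position mean of the
    detrended series, centred to sum to ~0 over one period; the residual is
    the exact remainder, so the additive identity holds everywhere.
    """
    x = np.asarray(series, dtype=float)
    if period < 2:
        raise ValueError("period must be >= 2")
    if x.size < 2 * period:
        raise ValueError("need at least two full periods")
    if trend_method == "moving_average":
        from statsmodels.tsa.seasonal import seasonal_decompose

        res = seasonal_decompose(x, model="additive", period=period,
                                 extrapolate_trend="freq")
        trend = np.asarray(res.trend, dtype=float)
        seasonal = np.asarray(res.seasonal, dtype=float)
    elif trend_method == "polynomial":
        t = np.arange(x.size, dtype=float)
        t = (t - t.mean()) / t.std()  # conditioning for high degrees
        coef = np.polynomial.polynomial.polyfit(t, x, poly_degree)
        trend = np.polynomial.polynomial.polyval(t, coef)
        detr = x - trend
        pos = np.arange(x.size) % period
        means = np.array([detr[pos == p].mean() for p in range(period)])
        means -= means.mean()
        seasonal = means[pos]
    else:
        raise ValueError("trend_method must be 'moving_average' or "
                         "'polynomial'")
    residual = x - trend - seasonal
    return Decomposition(observed=x, trend=trend, seasonal=seasonal,
                         residual=residual, period=int(period))


# ---------------------------------------------------------------------------
# Cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class CrossCorrelation:
    """Lagged Pearson cross-correlation r(lag) = corr(x_t, y_{t+lag}).

    Positive-lag extrema mean y trails x. A pure shift y_t = x_{t+k}
    (y leading by k samples) peaks at lag = -k.
    """

    lags: np.ndarray
    r: np.ndarray

    def argmax_lag(self) -> int:
        return int(self.lags[np.argmax(np.abs(self.r))])


def cross_correlation(x, y, max_lag: int) -> CrossCorrelation:
    """Standard sample CCF: overlap cross-products normalised by the
    full-series n, mean and SD (so |r| <= 1 by Cauchy-Schwarz)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    if n - max_lag < 10:
        raise ValueError("series too short for the requested max_lag")
    sx, sy = x.std(ddof=0), y.std(ddof=0)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    u, v = x - x.mean(), y - y.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            prod = u[:n - lag] * v[lag:]
        else:
            prod = u[-lag:] * v[:n + lag]
        r[i] = prod.sum() / (n * sx * sy)
    return CrossCorrelation(lags=lags, r=r)


# ---------------------------------------------------------------------------
# Epicenter kernel density
# ---------------------------------------------------------------------------

def gaussian_kde2d(lon, lat, bandwidth="silverman", gridsize: int = 128,
                   pad_bw: float = 4.0
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D Gaussian kernel density of epicenters on a regular grid.

    Bandwidth by Silverman's rule (or a scalar factor); the grid extends
    ``pad_bw`` bandwidths beyond the data so the surface integrates to ~1.
    A singular sample covariance falls back to an independent per-axis
    (diagonal-bandwidth) product kernel with a warning.

    Returns (lon_axis, lat_axis, density) with density indexed
    [lat, lon].
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size < 2:
        raise ValueError("need >= 2 points")
    pts = np.vstack([lon, lat])
    n = lon.size
    sig = np.maximum(pts.std(axis=1, ddof=1), 1e-9)
    h = sig * n ** (-1.0 / 6.0)  # Silverman, d = 2
    xs = np.linspace(lon.min() - pad_bw * h[0], lon.max() + pad_bw * h[0],
                     gridsize)
    ys = np.linspace(lat.min() - pad_bw * h[1], lat.max() + pad_bw * h[1],
                     gridsize)
    xx, yy = np.meshgrid(xs, ys)
    cov = np.cov(pts)
    degenerate = np.linalg.det(cov) <= 1e-10 * cov[0, 0] * cov[1, 1]
    if not degenerate:
        kde = stats.gaussian_kde(pts, bw_method=bandwidth)
        dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    else:
        warnings.warn("singular covariance; falling back to diagonal "
                      "bandwidths", RuntimeWarning, stacklevel=2)
        dens = np.zeros_like(xx)
        for px, py in zip(lon, lat):
            dens += (np.exp(-0.5 * (((xx - px) / h[0]) ** 2
                                    + ((yy - py) / h[1]) ** 2))
                     / (2 * np.pi * h[0] * h[1]))
        dens /= n
    return xs, ys, dens


def grid_integral(xs: np.ndarray, ys: np.ndarray,
                  density: np.ndarray) -> float:
    """Quadrature (trapezoid) integral of a density grid."""
    return float(np.trapezoid(np.trapezoid(density, xs, axis=1), ys))


def aggregate_median(df: pd.DataFrame, value_cols: list[str],
                     interval: str = "5min") -> pd.DataFrame:
    """Median of ``value_cols`` per time bin, indexed by bin start."""
    g = df.set_index("timestamp")[value_cols].resample(interval).median()
    return g
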