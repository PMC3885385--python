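"""Air-temperature trends from station series via a crossed-effects LMM.

Monthly station records are aggregated to two yearly measures — the summer
half-year mean (April–September, the community field season) and the
coldest-month mean — and each is modelled as

    temp ~ intercept + altitude + trend·(year − year₀) + altitude × trend

with crossed random intercepts for station and year (measures from the same
station, and from the same year, are dependent).  The question of interest
is the trend × altitude interaction: does warming differ across altitudes?

The model is fit by REML through direct maximization of the marginal
Gaussian likelihood on the dense n × n covariance matrix — stations × years
rows stay small — rather than through sparse mixed-model machinery.  The
REML log-likelihood uses the error-contrast (orthonormal) convention, so it
equals the exact multivariate-normal density of the contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LmmFit",
    "summer_mean",
    "coldest_month_mean",
    "fit_temperature_lmm",
]

logger = logging.getLogger(__name__)

SUMMER_MONTHS = (4, 5, 6, 7, 8, 9)
FIXED_TERMS = ("intercept", "altitude", "trend", "trend_x_altitude")


@dataclass
class LmmFit:
    """Fixed effects and variance components of the temperature LMM.

    ``p_value`` uses a t reference with n − p residual degrees of freedom
    (approximate; no small-sample df correction is attempted).
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p_value: np.ndarray
    term_names: tuple[str, ...]
    var_station: float
    var_year: float
    var_resid: float
    logl_reml: float
    n: int
    notes: list[str]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "t": self.t, "p": self.p_value},
            index=list(self.term_names),
        )

    def __getitem__(self, term: str) -> float:
        return float(self.beta[self.term_names.index(term)])


def _yearly_table(series) -> pd.DataFrame:
    records = series.records if hasattr(series, "records") else series
    return records


def summer_mean(series) -> pd.DataFrame:
    """Per (station, year) mean of the April–September monthly means.

    Station-years missing any of the six summer months are dropped with a
    logged warning.
    """
    records = _yearly_table(series)
    summer = records[records["month"].isin(SUMMER_MONTHS)]
    grouped = summer.groupby(["station_id", "year"]).agg(
        value=("mean_temp_c", "mean"),
        n_months=("mean_temp_c", "size"),
        altitude_m=("altitude_m", "first"),
    )
    incomplete = grouped[grouped["n_months"] < len(SUMMER_MONTHS)]
    if len(incomplete):
        logger.warning("dropping %d station-years with incomplete summer months: %s",
                       len(incomplete), list(incomplete.index))
    out = grouped[grouped["n_months"] == len(SUMMER_MONTHS)].drop(columns="n_months")
    return out.reset_index()


def coldest_month_mean(series) -> pd.DataFrame:
    """Per (station, year) mean temperature of the coldest month."""
    records = _yearly_table(series)
    grouped = records.groupby(["station_id", "year"]).agg(
        value=("mean_temp_c", "min"),
        altitude_m=("altitude_m", "first"),
    )
    return grouped.reset_index()


def _reml_logl(X, y, Zs, Zy, gamma_s, gamma_y):
    """Profiled REML log-likelihood at given variance ratios (γ = var/resid)."""
    n, p = X.shape
    V0 = np.eye(n) + gamma_s * (Zs @ Zs.T) + gamma_y * (Zy @ Zy.T)
    L = np.linalg.cholesky(V0)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
    Xi = np.linalg.solve(L, X)    # L^-1 X
    yi = np.linalg.solve(L, y)
    XtVX = Xi.T @ Xi
    beta = np.linalg.solve(XtVX, Xi.T @ yi)
    r = yi - Xi @ beta
    rss = float(r @ r)
    sigma2 = rss / (n - p)
    _, logdet_w = np.linalg.slogdet(XtVX)
    _, logdet_x = np.linalg.slogdet(X.T @ X)
    logl = (
        -0.5 * (n - p) * (np.log(2 * np.pi) + 1.0 + np.log(sigma2))
        - 0.5 * logdet_v
        - 0.5 * logdet_w
        + 0.5 * logdet_x
    )
    return logl, beta, sigma2, XtVX


def fit_temperature_lmm(
    values: pd.DataFrame,
    *,
    force_zero_random: bool = False,
) -> LmmFit:
    """REML fit of the trend × altitude LMM with crossed random intercepts.

    ``values`` needs columns station_id, altitude_m, year, value (one row
    per station-year, e.g. from :func:`summer_mean`).  Year is centred at
    the first year of the window; altitude enters uncentred so the trend ×
    altitude interaction is per metre.  Variance ratios are optimized under
    non-negativity bounds; a ratio driven to the boundary is pinned at 0
    with a note, as is the year variance when only one year is present.
    ``force_zero_random`` pins both random-effect variances to 0, reducing
    the fit to pooled OLS (useful as a degenerate-model check).
    """
    for col in ("station_id", "altitude_m", "year", "value"):
        if col not in values.columns:
            raise ValueError(f"values table missing column {col!r}")
    stations = pd.unique(values["station_id"])
    years = np.sort(pd.unique(values["year"]))
    if len(stations) < 2:
        raise ValueError("need at least 2 stations")
    n = len(values)
    y = values["value"].to_numpy(dtype=float)
    alt = values["altitude_m"].to_numpy(dtype=float)
    yearc = values["year"].to_numpy(dtype=float) - float(years[0])

    notes: list[str] = []
    single_year = len(years) < 2
    if single_year:
        # both the year variance and the trend terms are unidentifiable
        notes.append("single year: year variance unidentifiable, pinned to 0; "
                     "trend terms dropped")
        logger.warning("single year in input; year random variance pinned to 0 "
                       "and trend terms dropped")
        X = np.column_stack([np.ones(n), alt])
        term_names = FIXED_TERMS[:2]
    else:
        X = np.column_stack([np.ones(n), alt, yearc, alt * yearc])
        term_names = FIXED_TERMS
    p = X.shape[1]
    if n <= p:
        raise ValueError("too few station-years for the fixed effects")

    Zs = (values["station_id"].to_numpy()[:, None] == stations[None, :]).astype(float)
    Zy = (values["year"].to_numpy()[:, None] == years[None, :]).astype(float)

    if force_zero_random:
        gamma = np.array([0.0, 0.0])
        notes.append("random-effect variances forced to 0 (pooled OLS)")
    else:

        def neg(g):
            try:
                return -_reml_logl(X, y, Zs, Zy, g[0], 0.0 if single_year else g[1])[0]
            except np.linalg.LinAlgError:
                return np.inf

        best = None
        for start in ((0.5, 0.5), (2.0, 0.1), (0.05, 2.0)):
            res = optimize.minimize(neg, np.asarray(start), method="L-BFGS-B",
                                    bounds=[(0.0, 1e6), (0.0, 1e6)])
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"LMM variance optimization failed: {best}")
        gamma = np.where(best.x < 1e-10, 0.0, best.x)
        if single_year:
            gamma[1] = 0.0
        if gamma[0] == 0.0:
            notes.append("station variance pinned at 0 (boundary)")
        if gamma[1] == 0.0 and not single_year:
            notes.append("year variance pinned at 0 (boundary)")

    logl, beta, sigma2, XtVX = _reml_logl(X, y, Zs, Zy, gamma[0], gamma[1])
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), n - p)
    return LmmFit(
        beta=beta, se=se, t=t, p_value=pvals, term_names=term_names,
        var_station=float(gamma[0] * sigma2), var_year=float(gamma[1] * sigma2),
        var_resid=float(sigma2), logl_reml=float(logl), n=n, notes=notes,
    )
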