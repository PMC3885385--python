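"""Heteroscedastic generalized least squares for altitude models of shifts.

Standardized community shifts (metres) are modelled against polynomial
altitude, centred at 500 m, plus the within-square altitudinal range.
Because an index averaged over a richer community is measured more
precisely, the residual standard deviation is allowed to depend on species
richness through one of three variance functions:

==================  =============================
kind                residual SD of observation i
==================  =============================
``fixed``           σ
``power``           σ · richnessᵢ^δ
``constpower``      σ · (c + richnessᵢ^δ)
==================  =============================

The Gaussian likelihood is maximized by profiling β (weighted least
squares) and σ for each value of the variance parameters and optimizing the
profile numerically.  Model building follows the standard protocol for
mixed/extended linear models: the variance structure is chosen by REML AIC
with the full fixed-effect model held fixed, the fixed effects are then
backward-selected by ML AIC respecting the polynomial hierarchy, the final
model is refit by REML, terms are tested with REML likelihood-ratio tests,
and inference on predictions uses a nonparametric case bootstrap over
squares with percentile intervals.

The REML log-likelihood is defined as the exact Gaussian log-density of an
orthonormal basis of error contrasts (it therefore includes a ``−½log|XᵀX|``
term that some software treats as an omitted constant); all likelihood
ratios and AIC comparisons are unaffected by that convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "VarianceStructure",
    "GlsFit",
    "BootstrapResult",
    "SingularDesignError",
    "build_design",
    "fit_gls",
    "fit_model",
    "select_variance_structure",
    "backward_select",
    "lrt_reml",
    "predict",
    "bootstrap_predictions",
    "refit_without_outliers",
]

VARIANCE_KINDS = ("fixed", "power", "constpower")
_N_VARPARAMS = {"fixed": 0, "power": 1, "constpower": 2}
_AIC_TIE = 1e-6


class SingularDesignError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect terms and variance structure of a shift–altitude model.

    ``poly_degree`` is the highest altitude polynomial included (0 =
    intercept only); the polynomial hierarchy is implicit — degree 3 means
    linear, quadratic and cubic terms are all present.  Altitude is centred
    at ``center_altitude`` so the intercept is the predicted shift there.
    The altitudinal-range covariate enters raw by default (predictions hold
    it at its sample mean); ``center_range`` subtracts the sample mean
    instead, making the intercept directly the prediction at the centring
    altitude.
    """

    poly_degree: int = 3
    include_range: bool = True
    variance: str = "power"
    center_altitude: float = 500.0
    center_range: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.poly_degree <= 3:
            raise ValueError("poly_degree must be in 0..3")
        if self.variance not in VARIANCE_KINDS:
            raise ValueError(f"unknown variance kind {self.variance!r}")

    @property
    def term_names(self) -> list[str]:
        names = ["intercept"]
        names += [f"altitude^{d}" if d > 1 else "altitude" for d in range(1, self.poly_degree + 1)]
        if self.include_range:
            names.append("altitudinal_range")
        return names

    def replace(self, **kw) -> "ModelSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class VarianceStructure:
    """Fitted variance-function parameters: SD(i) = sigma * g(richness_i)."""

    kind: str
    sigma: float
    delta: float = 0.0
    const: float = 0.0

    def g(self, richness: np.ndarray) -> np.ndarray:
        r = np.asarray(richness, dtype=float)
        if self.kind == "fixed":
            return np.ones_like(r)
        if self.kind == "power":
            return r**self.delta
        return self.const + r**self.delta

    def sd(self, richness: np.ndarray) -> np.ndarray:
        return self.sigma * self.g(richness)

    @property
    def n_params(self) -> int:
        return _N_VARPARAMS[self.kind]


@dataclass
class GlsFit:
    """A fitted heteroscedastic linear model.

    Log-likelihoods under ML and REML are both evaluated at the fitted
    variance parameters and stored separately; AIC uses the criterion the
    model was fitted under and counts every estimated parameter (β, σ and
    the variance-function parameters).
    """

    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    variance: VarianceStructure
    term_names: list[str]
    criterion: str               # "ML" or "REML"
    logl_ml: float
    logl_reml: float
    n: int
    fitted_sd: np.ndarray = field(repr=False)
    spec: ModelSpec | None = None

    @property
    def k(self) -> int:
        return len(self.beta) + 1 + self.variance.n_params

    @property
    def logl(self) -> float:
        return self.logl_reml if self.criterion == "REML" else self.logl_ml

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.logl

    @property
    def aic_ml(self) -> float:
        return 2.0 * self.k - 2.0 * self.logl_ml

    @property
    def aic_reml(self) -> float:
        return 2.0 * self.k - 2.0 * self.logl_reml

    def summary_frame(self) -> pd.DataFrame:
        t = np.divide(self.beta, self.se, out=np.full_like(self.beta, np.nan),
                      where=self.se > 0)
        return pd.DataFrame({"estimate": self.beta, "se": self.se, "t": t},
                            index=self.term_names)


def build_design(changes: pd.DataFrame, spec: ModelSpec):
    """Design matrix, response and variance covariate from a change set.

    ``changes`` must carry shift_m, altitude_m, altitudinal_range_m and
    richness per square (see :func:`thermocomm.standardize.standardized_changes`).
    Altitude is centred before the polynomial expansion, so a square at the
    centring altitude contributes zeros to every polynomial column.
    """
    required = ["shift_m", "altitude_m", "richness"]
    if spec.include_range:
        required.append("altitudinal_range_m")
    missing_cols = [c for c in required if c not in changes.columns]
    if missing_cols:
        raise ValueError(f"change set missing columns: {missing_cols}")
    bad = changes.index[changes[required].isna().any(axis=1)]
    if len(bad):
        ids = changes.loc[bad, "square_id"].tolist() if "square_id" in changes else list(bad)
        raise ValueError(f"missing covariates for squares: {ids}")

    y = changes["shift_m"].to_numpy(dtype=float)
    a = changes["altitude_m"].to_numpy(dtype=float) - spec.center_altitude
    cols = [np.ones_like(a)]
    for d in range(1, spec.poly_degree + 1):
        cols.append(a**d)
    if spec.include_range:
        rng_col = changes["altitudinal_range_m"].to_numpy(dtype=float)
        if spec.center_range:
            rng_col = rng_col - rng_col.mean()
        cols.append(rng_col)
    X = np.column_stack(cols)
    richness = changes["richness"].to_numpy(dtype=float)
    return X, y, richness


def _wls(X: np.ndarray, y: np.ndarray, g: np.ndarray):
    """Weighted LS for SD proportional to g; returns beta, weighted RSS, XtWX."""
    # extreme variance-parameter proposals can overflow the weights; the
    # resulting non-finite likelihood is rejected by the optimizer wrappers
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        sw = 1.0 / g
        Xw = X * sw[:, None]
        yw = y * sw
        XtWX = Xw.T @ Xw
        if not np.all(np.isfinite(XtWX)):
            raise FloatingPointError("non-finite weighted design")
        try:
            beta = np.linalg.solve(XtWX, Xw.T @ yw)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError("singular weighted design matrix") from exc
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
    return beta, rss, XtWX


def _profile_logl(X, y, g, criterion: str):
    """Profile log-likelihood over beta and sigma at fixed variance shape g."""
    n, p = X.shape
    beta, rss, XtWX = _wls(X, y, g)
    sum_log_g = float(np.sum(np.log(g)))
    if rss <= 0:
        rss = 1e-300  # degenerate exact fit; keep the likelihood finite
    if criterion == "ML":
        sigma2 = rss / n
        logl = -0.5 * n * (np.log(2 * np.pi) + 1.0 + np.log(sigma2)) - sum_log_g
    else:
        sigma2 = rss / (n - p)
        sign, logdet_w = np.linalg.slogdet(XtWX)  # log|X' V0^-1 X|
        if sign <= 0:
            raise SingularDesignError("weighted normal matrix not positive definite")
        _, logdet_x = np.linalg.slogdet(X.T @ X)
        with np.errstate(invalid="ignore"):  # inf - inf at absurd variance proposals
            logl = (
                -0.5 * (n - p) * (np.log(2 * np.pi) + 1.0 + np.log(sigma2))
                - sum_log_g
                - 0.5 * logdet_w
                + 0.5 * logdet_x
            )
    return beta, sigma2, logl, XtWX


def _g_for(kind: str, richness: np.ndarray, delta: float, const: float) -> np.ndarray:
    if kind == "fixed":
        return np.ones_like(richness)
    if kind == "power":
        return richness**delta
    g = const + richness**delta
    if np.any(g <= 0):
        raise FloatingPointError("non-positive variance function")
    return g


def fit_gls(
    X: np.ndarray,
    y: np.ndarray,
    richness: np.ndarray,
    variance: str | VarianceStructure = "fixed",
    criterion: str = "ML",
    spec: ModelSpec | None = None,
) -> GlsFit:
    """Fit the Gaussian model y ~ N(Xβ, σ²·g(richness)²) by ML or REML.

    β and σ are profiled out; the variance-function parameters (δ, and c for
    the constant-plus-power form) are optimized numerically with jittered
    restarts.  Passing a fully specified :class:`VarianceStructure` (rather
    than a kind name) skips the variance optimization and holds δ/c fixed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    richness = np.asarray(richness, dtype=float)
    n, p = X.shape
    if criterion not in ("ML", "REML"):
        raise ValueError("criterion must be 'ML' or 'REML'")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError("design matrix is rank deficient")

    fixed_params = isinstance(variance, VarianceStructure)
    kind = variance.kind if fixed_params else variance
    if kind not in VARIANCE_KINDS:
        raise ValueError(f"unknown variance kind {kind!r}")
    if kind != "fixed" and np.any(richness <= 0):
        raise ValueError("richness must be > 0 for power variance structures")

    if fixed_params:
        delta, const = variance.delta, variance.const
    elif kind == "fixed":
        delta, const = 0.0, 0.0
    elif kind == "power":

        def neg(d):
            try:
                g = _g_for("power", richness, d, 0.0)
                ll = _profile_logl(X, y, g, criterion)[2]
            except (FloatingPointError, SingularDesignError, OverflowError):
                return np.inf
            return -ll if np.isfinite(ll) else np.inf

        res = optimize.minimize_scalar(neg, bounds=(-5.0, 5.0), method="bounded",
                                       options={"xatol": 1e-7})
        delta, const = float(res.x), 0.0
    else:

        def neg2(params):
            d, logc = params
            try:
                g = _g_for("constpower", richness, d, np.exp(logc))
                ll = _profile_logl(X, y, g, criterion)[2]
            except (FloatingPointError, SingularDesignError, OverflowError):
                return np.inf
            return -ll if np.isfinite(ll) else np.inf

        best = None
        for start in ((0.0, 0.0), (0.5, -1.0), (-0.5, 1.0), (1.0, 0.5)):
            res = optimize.minimize(neg2, np.asarray(start), method="Nelder-Mead",
                                    options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"variance optimization failed: {best}")
        delta, const = float(best.x[0]), float(np.exp(best.x[1]))

    g = _g_for(kind, richness, delta, const)
    beta, sigma2_ml, logl_ml, _ = _profile_logl(X, y, g, "ML")
    _, sigma2_reml, logl_reml, XtWX = _profile_logl(X, y, g, "REML")
    sigma2 = sigma2_reml if criterion == "REML" else sigma2_ml
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    var = VarianceStructure(kind=kind, sigma=float(np.sqrt(sigma2)),
                            delta=delta, const=const)
    names = spec.term_names if spec is not None else [f"x{j}" for j in range(p)]
    return GlsFit(
        beta=beta, se=se, cov_beta=cov_beta, variance=var, term_names=names,
        criterion=criterion, logl_ml=float(logl_ml), logl_reml=float(logl_reml),
        n=n, fitted_sd=var.sd(richness), spec=spec,
    )


def fit_model(changes: pd.DataFrame, spec: ModelSpec, criterion: str = "REML",
              variance: VarianceStructure | None = None) -> GlsFit:
    """Build the design from a change set and fit it (convenience wrapper)."""
    X, y, richness = build_design(changes, spec)
    return fit_gls(X, y, richness, variance if variance is not None else spec.variance,
                   criterion, spec=spec)


def select_variance_structure(
    X: np.ndarray,
    y: np.ndarray,
    richness: np.ndarray,
    kinds: tuple[str, ...] = VARIANCE_KINDS,
) -> tuple[str, dict[str, GlsFit]]:
    """Choose the variance function by REML AIC on the full fixed model.

    All candidate structures are fitted with the same fixed effects and
    compared on REML AIC; AIC differences below 1e−6 count as ties and are
    resolved toward the structure with fewer parameters.  Returns the
    winning kind and the candidate fits (for the selection trail).
    """
    fits: dict[str, GlsFit] = {}
    errors: dict[str, Exception] = {}
    for kind in kinds:
        try:
            fits[kind] = fit_gls(X, y, richness, kind, criterion="REML")
        except (ValueError, SingularDesignError, RuntimeError) as exc:
            errors[kind] = exc
    if not fits:
        raise RuntimeError(f"all variance-structure fits failed: {errors}")
    best = None
    for kind, f in fits.items():
        if best is None or f.aic < fits[best].aic - _AIC_TIE or (
            abs(f.aic - fits[best].aic) <= _AIC_TIE
            and _N_VARPARAMS[kind] < _N_VARPARAMS[best]
        ):
            best = kind
    return best, fits


def backward_select(
    changes: pd.DataFrame,
    variance: str = "power",
    start: ModelSpec | None = None,
) -> tuple[ModelSpec, GlsFit, list[dict]]:
    """Backward selection of fixed effects by ML AIC, then a REML refit.

    Starting from the full model (cubic altitude polynomial plus the
    altitudinal-range covariate), the term whose deletion most lowers the ML
    AIC is removed, respecting the polynomial hierarchy (only the
    highest-order altitude term may be dropped; the intercept never is),
    until no deletion lowers AIC.  Ties within 1e−6 resolve toward the
    simpler model.  Returns the selected spec, its REML refit, and the AIC
    trail.
    """
    spec = (start or ModelSpec()).replace(variance=variance)
    current = fit_model(changes, spec, criterion="ML")
    trail = [{"spec": spec, "aic_ml": current.aic, "action": "start"}]
    while True:
        candidates: list[tuple[ModelSpec, str]] = []
        if spec.poly_degree > 0:
            candidates.append((spec.replace(poly_degree=spec.poly_degree - 1),
                               f"drop altitude^{spec.poly_degree}"))
        if spec.include_range:
            candidates.append((spec.replace(include_range=False), "drop altitudinal_range"))
        best_fit, best_spec, best_action = None, None, None
        for cand, action in candidates:
            fit = fit_model(changes, cand, criterion="ML")
            if best_fit is None or fit.aic < best_fit.aic - _AIC_TIE:
                best_fit, best_spec, best_action = fit, cand, action
        if best_fit is None or best_fit.aic > current.aic + _AIC_TIE:
            break
        spec, current = best_spec, best_fit
        trail.append({"spec": spec, "aic_ml": current.aic, "action": best_action})
    final = fit_model(changes, spec, criterion="REML")
    return spec, final, trail


def lrt_reml(full: GlsFit, reduced: GlsFit) -> tuple[float, int, float]:
    """REML likelihood-ratio test of a reduced model nested in a full model.

    Valid for comparing variance structures with identical fixed effects
    (REML likelihoods are not comparable across different fixed effects).
    Returns (statistic, df, p) with p from the χ² distribution.
    """
    if full.n != reduced.n:
        raise ValueError("models fit to different numbers of observations")
    if len(full.beta) != len(reduced.beta):
        raise ValueError("REML LRT requires identical fixed effects in both models")
    df = full.k - reduced.k
    if df < 0:
        raise ValueError("reduced model is not nested in full (more parameters)")
    stat = max(0.0, 2.0 * (full.logl_reml - reduced.logl_reml))
    if df == 0:
        # identical parameterizations: the test degenerates to stat 0, p 1
        if stat > 1e-8:
            raise ValueError("models have equal parameter counts but differ; not nested")
        return 0.0, 0, 1.0
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


def _design_row(spec: ModelSpec, altitude: float, range_value: float) -> np.ndarray:
    a = altitude - spec.center_altitude
    row = [1.0] + [a**d for d in range(1, spec.poly_degree + 1)]
    if spec.include_range:
        row.append(range_value)
    return np.asarray(row)


def predict(fit: GlsFit, altitudes, range_value: float = 0.0) -> np.ndarray:
    """Model prediction (m of shift) at given altitudes, range held fixed."""
    if fit.spec is None:
        raise ValueError("fit carries no ModelSpec; cannot build prediction rows")
    rows = np.array([_design_row(fit.spec, a, range_value) for a in np.atleast_1d(altitudes)])
    return rows @ fit.beta


@dataclass
class BootstrapResult:
    """Percentile-bootstrap inference for predictions at target altitudes."""

    targets: np.ndarray
    point: np.ndarray        # prediction from the full-data fit
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: np.ndarray      # two-sided, (+1)/(B+1) convention
    draws: np.ndarray        # (B, n_targets) bootstrap predictions
    B: int
    seed: int
    n_redrawn: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"altitude_m": self.targets, "prediction_m": self.point,
             "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p_value}
        )


def bootstrap_predictions(
    changes: pd.DataFrame,
    spec: ModelSpec,
    targets=(500.0, 2350.0),
    B: int = 1000,
    seed: int = 0,
    range_value: float | None = None,
    level: float = 0.95,
    index_records: pd.DataFrame | None = None,
    index_kind: str = "cti",
) -> BootstrapResult:
    """Nonparametric case bootstrap of model predictions at target altitudes.

    Squares are resampled with replacement B times; the already-selected
    model (fixed effects and variance structure both held fixed — no
    re-selection inside the loop) is refit to each resample and evaluated at
    each target altitude with the altitudinal-range covariate held at the
    observed sample mean.  Confidence intervals are percentile intervals and
    the two-sided p-value is ``2·min(#{pred ≤ 0}+1, #{pred ≥ 0}+1)/(B+1)``.
    Resamples whose fit fails are redrawn (their count is reported); more
    than 10% failures aborts.

    By default the standardization slope *b* stays fixed at its full-data
    first-survey estimate, so resampling propagates only the shift-model
    uncertainty.  Passing ``index_records`` (the per-square index table the
    changes were built from) switches on a sensitivity variant in which each
    resample re-estimates *b* from its own first-survey values before
    re-standardizing.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    if range_value is None:
        range_value = float(changes["altitudinal_range_m"].mean()) if spec.include_range else 0.0
    full = fit_model(changes, spec, criterion="REML")
    point = predict(full, targets, range_value)

    rng = np.random.default_rng(seed)
    n = len(changes)
    draws = np.empty((B, targets.size))
    failures = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        if index_records is not None:
            from . import standardize as _stdz

            square_ids = changes["square_id"].iloc[idx]
            resampled = pd.concat(
                [index_records[index_records["square_id"] == sq].assign(
                    square_id=f"{sq}#{j}")
                 for j, sq in enumerate(square_ids)],
                ignore_index=True,
            )
            try:
                sample, _ = _stdz.standardized_changes(resampled, kind=index_kind)
            except (ValueError, _stdz.NonNegativeSlopeError):
                failures += 1
                if failures > 0.1 * B:
                    raise RuntimeError(
                        f"more than 10% of bootstrap refits failed ({failures} of {B})"
                    )
                continue
        else:
            sample = changes.iloc[idx]
        try:
            fit = fit_model(sample, spec, criterion="REML")
            pred = predict(fit, targets, range_value)
            if not np.all(np.isfinite(pred)):
                raise FloatingPointError("non-finite prediction")
        except (ValueError, SingularDesignError, RuntimeError, FloatingPointError):
            failures += 1
            if failures > 0.1 * B:
                raise RuntimeError(
                    f"more than 10% of bootstrap refits failed ({failures} of {B})"
                )
            continue
        draws[b] = pred
        b += 1

    alpha = 1.0 - level
    ci_low = np.quantile(draws, alpha / 2, axis=0)
    ci_high = np.quantile(draws, 1 - alpha / 2, axis=0)
    n_le = (draws <= 0).sum(axis=0)
    n_ge = (draws >= 0).sum(axis=0)
    p = np.minimum(1.0, 2.0 * (np.minimum(n_le, n_ge) + 1) / (B + 1))
    return BootstrapResult(
        targets=targets, point=point, ci_low=ci_low, ci_high=ci_high,
        p_value=p, draws=draws, B=B, seed=seed, n_redrawn=failures,
    )


def refit_without_outliers(
    changes: pd.DataFrame,
    spec: ModelSpec,
    shift_bounds: tuple[float, float],
) -> tuple[GlsFit, int]:
    """Robustness refit excluding squares with extreme standardized shifts.

    Returns the REML refit on the retained squares and the number excluded —
    the influence check that the altitude effects survive without the
    low-richness outliers the variance function already downweights.
    """
    lo, hi = shift_bounds
    keep = changes["shift_m"].between(lo, hi)
    excluded = int((~keep).sum())
    fit = fit_model(changes[keep].reset_index(drop=True), spec, criterion="REML")
    return fit, excluded
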