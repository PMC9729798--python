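"""Sequential linear mixed-effects modelling of longitudinal ROI data.

The response (a per-ROI mean of T2, ADC or MTR) is log-transformed and
fitted to a chain of nine nested mixed models,

    B < A < AT < ATrs < ATrsD < ATrsD.TA < ATrsD.TA.DT
      < ATrsD.TA.DT.DA < ATrsD.TA.DT.DA.DAT,

growing from "random components only" to all fixed effects of area, time
(categorical day) and diet plus their two- and three-way interactions.
"rs" marks the addition of a per-mouse random slope in (rescaled) day.
Every model shares the random structure: a random intercept per mouse, a
random intercept per area nested within mouse, and an AR(1) correlation
among the residuals of successive time points within each mouse x area
series.

Writing the marginal covariance of mouse i as

    V_i = sigma_m^2 J + sigma_a^2 blockdiag_a(J) + sigma_s^2 s s'
          + sigma_e^2 blockdiag_a(R_AR1(phi)),

the likelihood is profiled over the fixed effects (GLS) and the residual
scale, leaving a 3-4 dimensional optimisation over the variance ratios and
the AR(1) coefficient.  Models are compared by ML AIC (fixed effects differ
across the ladder, so REML AICs would not be comparable); the selected
model is refit by REML for reported coefficients and contrasts.

Type III Wald chi-square tests per fixed term are valid under the
sum-to-zero contrast coding used throughout; day-versus-baseline contrasts
per diet x region family are multiplicity-adjusted with a Dunnett
correction computed from the joint multivariate normal distribution of the
four contrast statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import DesignInfo, build_design, prediction_row

logger = logging.getLogger(__name__)

_AIC_TIE_TOL = 1e-6

LADDER_NAMES = (
    "B",
    "A",
    "AT",
    "ATrs",
    "ATrsD",
    "ATrsD.TA",
    "ATrsD.TA.DT",
    "ATrsD.TA.DT.DA",
    "ATrsD.TA.DT.DA.DAT",
)

#: Table-style spellings accepted as aliases of the canonical chain names.
MODEL_ALIASES = {
    "ATrsD.AT": "ATrsD.TA",
    "ATrsD.AT.DT": "ATrsD.TA.DT",
    "ATrsD.AT.DT.DA": "ATrsD.TA.DT.DA",
    "ATrsD.AT.DT.DA.DAT": "ATrsD.TA.DT.DA.DAT",
}

_FIXED_TERMS = {
    "B": (),
    "A": ("area",),
    "AT": ("area", "time"),
    "ATrs": ("area", "time"),
    "ATrsD": ("area", "time", "diet"),
    "ATrsD.TA": ("area", "time", "diet", "area:time"),
    "ATrsD.TA.DT": ("area", "time", "diet", "area:time", "diet:time"),
    "ATrsD.TA.DT.DA": ("area", "time", "diet", "area:time", "diet:time", "diet:area"),
    "ATrsD.TA.DT.DA.DAT": (
        "area",
        "time",
        "diet",
        "area:time",
        "diet:time",
        "diet:area",
        "diet:area:time",
    ),
}


@dataclass(frozen=True)
class ModelSpec:
    """One rung of the model ladder."""

    name: str
    fixed_terms: tuple[str, ...]
    random_slope: bool
    ar1: bool = True
    transform: str = "log"

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        name = MODEL_ALIASES.get(name, name)
        if name not in _FIXED_TERMS:
            raise ValueError(f"unknown model name {name!r}")
        return cls(name, _FIXED_TERMS[name], random_slope="rs" in name)

    @property
    def n_variance_params(self) -> int:
        # mouse intercept, area-in-mouse intercept, residual scale, AR(1) phi,
        # plus the optional random slope
        return 4 + (1 if self.random_slope else 0)


def model_ladder() -> list[ModelSpec]:
    """The nine-model chain, simplest to most complex."""
    return [ModelSpec.from_name(n) for n in LADDER_NAMES]


@dataclass
class FitResult:
    model: ModelSpec
    params: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    aic: float
    phi: float
    variance_components: dict[str, float]
    converged: bool
    n_obs: int
    n_groups: int
    estimation: str
    design_info: DesignInfo = field(repr=False)
    data: pd.DataFrame = field(repr=False)
    _whiten: object = field(repr=False, default=None)

    @property
    def k_params(self) -> int:
        return len(self.params) + self.model.n_variance_params

    def fitted_values(self) -> np.ndarray:
        X, _ = build_design(self.data, self.model.fixed_terms, levels=self.design_info.levels)
        return X @ self.params.to_numpy()


# ---------------------------------------------------------------------------
# covariance machinery


def _group_layout(df: pd.DataFrame) -> tuple[list[np.ndarray], list[dict]]:
    """Row indices and covariance layout per mouse.

    Rows within a mouse are ordered by (area, time) so that the AR(1)
    blocks are contiguous and time-ordered.
    """
    days = np.sort(df["day"].unique().astype(float))
    span = days.max() - days.min() if days.max() > days.min() else 1.0
    indices, layouts = [], []
    for _, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values(["region", "day"], kind="mergesort")
        idx = sub.index.to_numpy()
        areas = sub["region"].to_numpy()
        day = sub["day"].to_numpy(dtype=float)
        s = (day - days.min()) / span  # rescaled day in [0, 1]
        # contiguous area blocks with their time ranks
        blocks = []
        start = 0
        for i in range(1, len(areas) + 1):
            if i == len(areas) or areas[i] != areas[start]:
                trank = stats.rankdata(day[start:i], method="ordinal") - 1
                blocks.append((start, i, trank))
                start = i
        indices.append(idx)
        layouts.append({"s": s, "blocks": blocks, "n": len(idx)})
    return indices, layouts


def _group_cov(layout: dict, g_m: float, g_a: float, g_s: float, phi: float) -> np.ndarray:
    """W_i such that V_i = sigma_e^2 * W_i (variance ratios g_* = sigma_*^2/sigma_e^2)."""
    n = layout["n"]
    W = np.full((n, n), g_m)
    s = layout["s"]
    if g_s > 0:
        W += g_s * np.outer(s, s)
    for start, stop, trank in layout["blocks"]:
        blk = slice(start, stop)
        W[blk, blk] += g_a
        # AR(1) correlation over time-point index within the mouse x area series
        W[blk, blk] += phi ** np.abs(trank[:, None] - trank[None, :])
    return W


class _Whitener:
    """Per-group Cholesky whitening, cached by identical layout."""

    def __init__(self, layouts: list[dict], g_m: float, g_a: float, g_s: float, phi: float):
        self.chols = []
        self.logdet = 0.0
        cache: dict = {}
        for lay in layouts:
            key = (tuple(np.round(lay["s"], 12)), tuple((b[0], b[1], tuple(b[2])) for b in lay["blocks"]))
            if key not in cache:
                W = _group_cov(lay, g_m, g_a, g_s, phi)
                L = np.linalg.cholesky(W)
                cache[key] = L
            L = cache[key]
            self.chols.append(L)
            self.logdet += 2.0 * np.log(np.diag(L)).sum()

    def whiten(self, arrs: list[np.ndarray]) -> list[np.ndarray]:
        from scipy.linalg import solve_triangular

        return [
            solve_triangular(L, a, lower=True, check_finite=False)
            for L, a in zip(self.chols, arrs)
        ]


def _profile_loglik(
    theta: np.ndarray,
    X_groups: list[np.ndarray],
    y_groups: list[np.ndarray],
    layouts: list[dict],
    random_slope: bool,
    reml: bool,
) -> float:
    # clip to a flat plateau at the boundary so the simplex can terminate
    # when a variance ratio is driven to zero (or blows up)
    theta = np.clip(theta, -18.0, 18.0)
    g_m, g_a = np.exp(theta[0]), np.exp(theta[1])
    if random_slope:
        g_s = np.exp(theta[2])
        phi = np.tanh(theta[3])
    else:
        g_s = 0.0
        phi = np.tanh(theta[2])
    try:
        wh = _Whitener(layouts, g_m, g_a, g_s, phi)
    except np.linalg.LinAlgError:
        return np.inf
    Xw = np.concatenate(wh.whiten(X_groups))
    yw = np.concatenate(wh.whiten(y_groups))
    n, p = Xw.shape
    beta, rss, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        return np.inf
    resid = yw - Xw @ beta
    # exactly-interpolated (noise-free) data: clamp so the fit stays finite
    rss = max(float(resid @ resid), 1e-280)
    if reml:
        sigma2 = rss / (n - p)
        _, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sigma2) + wh.logdet + logdet_xtx + (n - p)
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + wh.logdet + n)
    return -ll


def fit_lme(
    table: pd.DataFrame,
    spec: ModelSpec | str,
    estimation: str = "ML",
    value_col: str = "value",
) -> FitResult:
    """Fit one ladder model to a long-format ROI table.

    The response is log-transformed; rows with non-positive values raise
    with their identities.  ``estimation`` is "ML" (ladder comparison) or
    "REML" (reported coefficients of the selected model).
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    if estimation not in ("ML", "REML"):
        raise ValueError("estimation must be 'ML' or 'REML'")
    required = {"animal_id", "region", "day", value_col}
    if "diet" in {t for term in spec.fixed_terms for t in term.split(":")}:
        required.add("diet")
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")
    df = table.reset_index(drop=True).copy()
    vals = df[value_col].to_numpy(dtype=float)
    if spec.transform == "log":
        bad = ~(vals > 0)
        if bad.any():
            rows = df.index[bad].tolist()[:10]
            raise ValueError(f"non-positive response values at rows {rows}; cannot log-transform")
        y = np.log(vals)
    else:
        y = vals

    X, info = build_design(df, spec.fixed_terms)
    indices, layouts = _group_layout(df)
    X_groups = [X[i] for i in indices]
    y_groups = [y[i] for i in indices]

    n_theta = 3 + (1 if spec.random_slope else 0)
    x0 = np.zeros(n_theta)
    x0[:2] = np.log(0.5)
    if spec.random_slope:
        x0[2] = np.log(0.25)
    x0[-1] = np.arctanh(0.2)

    def obj(theta: np.ndarray) -> float:
        return _profile_loglik(theta, X_groups, y_groups, layouts, spec.random_slope, estimation == "REML")

    # degenerate perfect-interpolation data (noise-free simulations): the
    # variance surface is unbounded, so keep the neutral starting values
    ols_beta, ols_rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    perfect = float(np.sum((y - X @ ols_beta) ** 2)) < 1e-20 * max(1.0, float(y @ y))
    if perfect:
        theta = x0
        converged = True
    else:
        opts = {"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000, "maxfev": 2000}
        res = optimize.minimize(obj, x0, method="Nelder-Mead", options=opts)
        if not res.success:  # one restart from the best point so far
            res = optimize.minimize(obj, res.x, method="Nelder-Mead", options=opts)
        theta = np.clip(res.x, -18.0, 18.0)
        converged = bool(res.success) and np.isfinite(res.fun)

    g_m, g_a = np.exp(theta[0]), np.exp(theta[1])
    g_s = np.exp(theta[2]) if spec.random_slope else 0.0
    phi = float(np.tanh(theta[-1]))
    wh = _Whitener(layouts, g_m, g_a, g_s, phi)
    Xw = np.concatenate(wh.whiten(X_groups))
    yw = np.concatenate(wh.whiten(y_groups))
    n, p = Xw.shape
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = max(float(resid @ resid), 1e-280)
    if estimation == "REML":
        sigma2 = rss / (n - p)
    else:
        sigma2 = rss / n
    xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    cov = sigma2 * xtx_inv
    loglik = -obj(theta)
    k = p + spec.n_variance_params
    aic = -2.0 * loglik + 2.0 * k

    vc = {
        "sigma2_mouse": g_m * sigma2,
        "sigma2_area_in_mouse": g_a * sigma2,
        "sigma2_residual": sigma2,
    }
    if spec.random_slope:
        vc["sigma2_time_slope"] = g_s * sigma2

    params = pd.Series(beta, index=info.column_names)
    cov_df = pd.DataFrame(cov, index=info.column_names, columns=info.column_names)
    if not converged:
        logger.warning("fit_lme(%s): optimizer did not converge (%s)", spec.name, res.message)
    return FitResult(
        model=spec,
        params=params,
        cov_params=cov_df,
        loglik=float(loglik),
        aic=float(aic),
        phi=phi,
        variance_components=vc,
        converged=converged,
        n_obs=int(n),
        n_groups=len(indices),
        estimation=estimation,
        design_info=info,
        data=df,
        _whiten=(wh, indices, y, X),
    )


def select_best_model(
    table: pd.DataFrame,
    ladder: list[ModelSpec] | None = None,
    value_col: str = "value",
) -> tuple[FitResult, pd.DataFrame]:
    """Fit the whole ladder with ML and return the lowest-AIC converged fit.

    Ties within 1e-6 of the minimum go to the simpler (earlier) model.
    The returned table lists name, k, logLik, AIC and convergence per model.
    """
    ladder = ladder or model_ladder()
    fits: list[FitResult | None] = []
    rows = []
    for spec in ladder:
        try:
            fit = fit_lme(table, spec, estimation="ML", value_col=value_col)
        except Exception as exc:  # rank deficiency on degenerate inputs
            logger.warning("select_best_model: %s failed (%s)", spec.name, exc)
            fits.append(None)
            rows.append(dict(model=spec.name, k=np.nan, logLik=np.nan, AIC=np.nan, converged=False))
            continue
        fits.append(fit)
        rows.append(
            dict(model=spec.name, k=fit.k_params, logLik=fit.loglik, AIC=fit.aic, converged=fit.converged)
        )
    aic_table = pd.DataFrame(rows)
    ok = [f for f in fits if f is not None and f.converged]
    if len(ok) < 2:
        raise RuntimeError("fewer than two ladder models fitted successfully")
    best_aic = min(f.aic for f in ok)
    for f in ok:  # ladder order = simplest first
        if f.aic <= best_aic + _AIC_TIE_TOL:
            return f, aic_table
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# inference on a fitted model


def anova_type3(fit: FitResult) -> pd.DataFrame:
    """Marginal (Type III) Wald chi-square test per fixed term."""
    if not fit.converged:
        raise ValueError("cannot test a non-converged fit")
    rows = []
    for term in fit.model.fixed_terms:
        sl = fit.design_info.term_slices[term]
        b = fit.params.to_numpy()[sl]
        V = fit.cov_params.to_numpy()[sl, sl]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"aliased (rank-deficient) term {term!r}") from exc
        df_term = len(b)
        rows.append(
            dict(term=term, chi2=stat, df=df_term, p=float(stats.chi2.sf(stat, df_term)))
        )
    return pd.DataFrame(rows)


def dunnett_adjust(z: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Two-sided Dunnett-type adjustment for jointly normal statistics.

    For each statistic, the adjusted p is 1 - P(max_j |Z_j| <= |z_obs|)
    under the joint N(0, corr) law — the probability that at least one of
    the family's statistics would exceed the observed one by chance.
    """
    z = np.asarray(z, dtype=float)
    k = len(z)
    mvn = stats.multivariate_normal(mean=np.zeros(k), cov=corr, allow_singular=True)
    out = np.empty(k)
    for j, zj in enumerate(np.abs(z)):
        if not np.isfinite(zj):
            out[j] = np.nan
            continue
        rect = float(mvn.cdf(np.full(k, zj), lower_limit=np.full(k, -zj)))
        out[j] = min(1.0, max(0.0, 1.0 - rect))
    raw = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(out, raw)  # adjustment can never go below the raw p


def time_contrasts(fit: FitResult, diet: str | None, region: str) -> pd.DataFrame:
    """Day-versus-baseline contrasts for one diet cohort and region.

    Returns one row per non-baseline day with the log-scale estimate, its
    standard error, raw and Dunnett-adjusted p-values (family size = number
    of non-baseline days, 4 in the default design).
    """
    if "time" not in {t for term in fit.model.fixed_terms for t in term.split(":")}:
        raise ValueError("model has no time effect; contrasts undefined")
    info = fit.design_info
    days = info.levels["time"]
    base = days[0]
    cell = {"time": base, "area": region}
    if "diet" in info.levels:
        if diet is None:
            raise ValueError("model conditions on diet; a diet level is required")
        cell["diet"] = diet
    if "area" not in info.levels:
        cell.pop("area")
    x0 = prediction_row(info, cell)
    L = []
    for d in days[1:]:
        cd = dict(cell, time=d)
        L.append(prediction_row(info, cd) - x0)
    L = np.array(L)
    beta = fit.params.to_numpy()
    V = fit.cov_params.to_numpy()
    est = L @ beta
    cov_c = L @ V @ L.T
    se = np.sqrt(np.diag(cov_c))
    z = est / se
    corr = cov_c / np.outer(se, se)
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = dunnett_adjust(z, corr)
    return pd.DataFrame(
        dict(
            diet=diet,
            region=region,
            day=days[1:],
            estimate=est,
            se=se,
            z=z,
            p_raw=p_raw,
            p_dunnett=p_adj,
        )
    )


def residual_diagnostics(fit: FitResult) -> dict:
    """Standardized (whitened) residuals, fitted values and normality summary.

    Under a correctly specified model the whitened residuals are i.i.d.
    standard normal; the report carries what is needed for residual-vs-fitted
    and normal-quantile plots, plus a Shapiro-Wilk test.
    """
    if not fit.converged:
        raise ValueError("cannot diagnose a non-converged fit")
    wh, indices, y, X = fit._whiten
    beta = fit.params.to_numpy()
    resid_groups = [y[i] - X[i] @ beta for i in indices]
    white = np.concatenate(wh.whiten(resid_groups))
    sigma = np.sqrt(fit.variance_components["sigma2_residual"])
    std_resid = white / sigma
    fitted = np.concatenate([X[i] @ beta for i in indices])
    order = np.argsort(np.argsort(std_resid))
    n = len(std_resid)
    theo_q = stats.norm.ppf((order + 0.5) / n)
    sw_stat, sw_p = stats.shapiro(std_resid if n <= 5000 else std_resid[:5000])
    report = pd.DataFrame(
        dict(fitted=fitted, std_resid=std_resid, normal_quantile=theo_q)
    )
    return {
        "table": report,
        "shapiro_stat": float(sw_stat),
        "shapiro_p": float(sw_p),
        "resid_mean": float(std_resid.mean()),
        "resid_se": float(std_resid.std(ddof=1) / np.sqrt(n)),
        "n_obs": int(n),
    }
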