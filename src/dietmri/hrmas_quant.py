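"""Linear-combination metabolite quantification of 1-D HRMAS spectra.

Each spectrum is modelled as a non-negative linear combination of
metabolite basis spectra plus a low-order polynomial baseline.  The
relative precision of every fitted amount, sd_percent = 100 * SE / amount,
is a covariance-based relative standard error playing the role of an
LCModel-style %SD; amounts with sd_percent above 20 are conventionally
discarded.  Fitted amounts are reported as ratios to total creatine
(Cr + PCr), together with the conventional composite sums
(Cho+GPC+PCh, mI+Gly, Glu+Gln, ...).

Group comparisons per metabolite use a linear mixed model with diet, area
and optionally their interaction as fixed effects and a random intercept
per mouse (the "area/mouse" random structure collapses to this when there
is one observation per mouse x area); the interaction is kept when a
likelihood-ratio test between the two ML fits is significant at 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import build_design
from .synthetic_data import COMPOSITE_SUMS, BasisSet, SpectrumRecord

logger = logging.getLogger(__name__)

SD_PERCENT_THRESHOLD = 20.0

METABOLITE_TABLE_COLUMNS = (
    "animal_id",
    "sex",
    "diet",
    "region",
    "metabolite",
    "ratio_to_tCr",
    "sd_percent",
)


@dataclass
class LinearCombinationFit:
    amounts: dict[str, float]
    sd_percent: dict[str, float]
    baseline_coefs: np.ndarray
    noise_sigma: float
    residual: np.ndarray


def _signal_free_window(basis: BasisSet, rel_threshold: float = 1e-4) -> np.ndarray:
    total = np.sum([s for s in basis.spectra.values()], axis=0)
    quiet = total < rel_threshold * total.max()
    if quiet.sum() < 16:
        raise ValueError("basis covers the whole ppm axis; no signal-free window")
    return quiet


def fit_linear_combination(
    spectrum: SpectrumRecord,
    basis: BasisSet,
    baseline_order: int = 2,
) -> LinearCombinationFit:
    """Non-negative least-squares fit of a spectrum against a basis set.

    Metabolite amounts are constrained >= 0; the polynomial baseline
    coefficients are unconstrained.  The noise level is estimated from the
    signal-free ppm window of the basis and propagated into sd_percent
    through the unconstrained-fit covariance.
    """
    if spectrum.ppm.shape != basis.ppm.shape or not np.allclose(spectrum.ppm, basis.ppm):
        raise ValueError("spectrum and basis must share the ppm grid (resample first)")
    names = basis.metabolites
    A_met = basis.matrix()
    if np.linalg.matrix_rank(A_met) < A_met.shape[1]:
        raise ValueError("rank-deficient basis (duplicated or collinear metabolites)")
    x = np.linspace(-1.0, 1.0, len(basis.ppm))
    A_base = np.column_stack([x**k for k in range(baseline_order + 1)])
    A = np.column_stack([A_met, A_base])
    y = spectrum.intensity

    n_met = len(names)
    lb = np.concatenate([np.zeros(n_met), np.full(baseline_order + 1, -np.inf)])
    ub = np.full(A.shape[1], np.inf)
    res = optimize.lsq_linear(A, y, bounds=(lb, ub), method="bvls")
    coef = res.x
    resid = y - A @ coef

    quiet = _signal_free_window(basis)
    sigma = float(np.std(spectrum.intensity[quiet] - A_base[quiet] @ coef[n_met:], ddof=1))
    cov = np.linalg.pinv(A.T @ A) * sigma**2
    se = np.sqrt(np.diag(cov)[:n_met])
    amounts = dict(zip(names, coef[:n_met]))
    sd_percent = {
        m: (100.0 * se[j] / amounts[m] if amounts[m] > 0 else np.inf)
        for j, m in enumerate(names)
    }
    return LinearCombinationFit(amounts, sd_percent, coef[n_met:], sigma, resid)


def to_tcr_ratios(amounts: dict[str, float]) -> dict[str, float]:
    """Metabolite amounts (and composite sums) divided by total creatine.

    Total creatine is Cr + PCr; by construction its own ratio is 1.
    """
    if "Cr" not in amounts or "PCr" not in amounts:
        raise ValueError("amounts must include Cr and PCr")
    tcr = amounts["Cr"] + amounts["PCr"]
    if tcr <= 0:
        raise ValueError("Cr+PCr must be positive to form ratios")
    ratios = {m: v / tcr for m, v in amounts.items()}
    for name, members in COMPOSITE_SUMS.items():
        if all(m in amounts for m in members):
            ratios[name] = sum(amounts[m] for m in members) / tcr
    return ratios


def quantify_spectra(
    spectra: list[SpectrumRecord],
    basis: BasisSet,
    baseline_order: int = 2,
) -> pd.DataFrame:
    """MetaboliteTable (long format) from a batch of spectra."""
    rows = []
    for spec in spectra:
        fit = fit_linear_combination(spec, basis, baseline_order)
        ratios = to_tcr_ratios(fit.amounts)
        for m, r in ratios.items():
            if m in fit.sd_percent:
                sd = fit.sd_percent[m]
            else:  # composite: conservative max of the members
                sd = max(fit.sd_percent[x] for x in COMPOSITE_SUMS[m])
            rows.append(
                dict(
                    animal_id=spec.metadata.get("animal_id"),
                    sex=spec.metadata.get("sex"),
                    diet=spec.metadata.get("diet"),
                    region=spec.metadata.get("region"),
                    metabolite=m,
                    ratio_to_tCr=r,
                    sd_percent=sd,
                )
            )
    return pd.DataFrame(rows, columns=list(METABOLITE_TABLE_COLUMNS))


def filter_sd(table: pd.DataFrame, threshold: float = SD_PERCENT_THRESHOLD) -> pd.DataFrame:
    """Keep rows with sd_percent <= threshold (boundary inclusive)."""
    if table.empty:
        return table.copy()
    return table.loc[table["sd_percent"] <= threshold].copy()


# ---------------------------------------------------------------------------
# per-metabolite mixed models


def _mixedlm(df: pd.DataFrame, with_interaction: bool, reml: bool = False):
    import statsmodels.regression.mixed_linear_model as mlm

    terms = ("diet", "area", "diet:area") if with_interaction else ("diet", "area")
    X, info = build_design(df, terms)
    model = mlm.MixedLM(
        endog=df["ratio_to_tCr"].to_numpy(dtype=float),
        exog=pd.DataFrame(X, columns=info.column_names),
        groups=df["animal_id"].to_numpy(),
    )
    import warnings

    with warnings.catch_warnings():
        # boundary (zero) random-effect variances are expected under the null
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml, method=["bfgs"], maxiter=300, disp=False)
    return fit, info


def metabolite_model_compare(table: pd.DataFrame, metabolite: str, alpha: float = 0.05):
    """Choose between diet+area and diet+area+diet:area for one metabolite.

    Both models are fitted by ML with a mouse random intercept; a
    likelihood-ratio test at ``alpha`` decides whether the interaction is
    kept.  Returns (chosen_fit, design_info, chosen_name, lrt_p).
    """
    df = table.loc[table["metabolite"] == metabolite].copy()
    if df["diet"].nunique() < 2 or df["region"].nunique() < 2:
        raise ValueError("need >= 2 diets and >= 2 areas represented")
    counts = df.groupby(["diet", "region"], observed=True).size()
    if (counts < 2).any():
        raise ValueError("insufficient replication in some diet x area cell")
    fit0, info0 = _mixedlm(df, with_interaction=False)
    fit1, info1 = _mixedlm(df, with_interaction=True)
    lr = 2.0 * (fit1.llf - fit0.llf)
    df_diff = info1.n_columns - info0.n_columns
    p = float(stats.chi2.sf(max(lr, 0.0), df_diff))
    keep_interaction = p < alpha
    # ML decides the structure; the chosen model is refit by REML for inference
    fit, info = _mixedlm(df, with_interaction=keep_interaction, reml=True)
    name = "diet+area+diet:area" if keep_interaction else "diet+area"
    return fit, info, name, p


def metabolite_tests(fit, info, table: pd.DataFrame, metabolite: str) -> dict:
    """Type III Wald chi-square per fixed term, plus per-area diet post-hocs.

    When the chosen model contains diet:area, the diet effect is tested
    within each area with Bonferroni adjustment over the (4) areas.
    """
    params = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[: len(params), : len(params)]
    # containment denominator df: between-mouse terms are tested against the
    # number of mice, within-mouse terms against the residual observations
    n_obs = int(fit.nobs)
    n_mice = fit.model.n_groups
    X = np.asarray(fit.model.exog)
    groups = np.asarray(fit.model.groups)
    codes = pd.factorize(groups)[0]
    n_between = 0
    between_term: dict[str, bool] = {}
    for term in ("Intercept",) + tuple(info.terms):
        sl = info.term_slices[term]
        cols = X[:, sl]
        is_between = all(
            np.ptp(cols[codes == g], axis=0).max() == 0 for g in range(n_mice)
        )
        between_term[term] = is_between
        if is_between:
            n_between += sl.stop - sl.start
    p_total = X.shape[1]
    ddf_between = max(n_mice - n_between, 1)
    ddf_within = max(n_obs - n_mice - (p_total - n_between), 1)
    rows = []
    for term in info.terms:
        sl = info.term_slices[term]
        b = params[sl]
        V = cov[sl, sl]
        stat = float(b @ np.linalg.solve(V, b))
        df_num = len(b)
        ddf = ddf_between if between_term[term] else ddf_within
        p = float(stats.f.sf(stat / df_num, df_num, ddf))
        rows.append(dict(term=term, chi2=stat, df=df_num, ddf=ddf, p=p))
    anova = pd.DataFrame(rows)

    posthoc = None
    if "diet:area" in info.terms:
        from .design import prediction_row

        diets = info.levels["diet"]
        areas = info.levels["area"]
        ph = []
        for area in areas:
            xa = prediction_row(info, {"diet": diets[1], "area": area})
            xb = prediction_row(info, {"diet": diets[0], "area": area})
            L = xa - xb
            est = float(L @ params)
            se = float(np.sqrt(L @ cov @ L))
            z = est / se
            p_raw = 2.0 * float(stats.t.sf(abs(z), ddf_between))
            ph.append(
                dict(
                    metabolite=metabolite,
                    area=area,
                    contrast=f"{diets[1]} - {diets[0]}",
                    estimate=est,
                    se=se,
                    z=z,
                    p_raw=p_raw,
                    p_bonferroni=min(1.0, p_raw * len(areas)),
                )
            )
        posthoc = pd.DataFrame(ph)
    return {"anova": anova, "posthoc": posthoc}
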