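import numpy as np
import pandas as pd
import pytest

from dietmri import (
    filter_sd,
    fit_linear_combination,
    quantify_spectra,
    simulate_spectra,
    to_tcr_ratios,
)
from dietmri.hrmas_quant import metabolite_model_compare, metabolite_tests
from dietmri.synthetic_data import BasisSet

REGIONS = ("hypothalamus", "hippocampus", "NAc", "ILA")

MIXTURE = {"NAA": 8.0, "Cr": 4.0, "PCr": 4.0, "Lac": 2.0, "mI": 5.0}


def simulate_metabolite_table(
    seed: int, interaction_sds: float = 0.0, diet_effect: float = 0.0,
    sigma: float = 0.05, n_per_diet: int = 8
) -> pd.DataFrame:
    """Mouse x region tCr-ratio table with a controllable diet:area interaction
    expressed in residual-SD units."""
    rng = np.random.default_rng(seed)
    pattern = np.array([[1, -1], [-1, 1], [1, -1], [-1, 1]], dtype=float)
    if interaction_sds:
        pattern = pattern / np.sqrt((pattern**2).mean()) * interaction_sds * sigma
    else:
        pattern = np.zeros((4, 2))
    rows = []
    for di, diet in enumerate(("SD", "HFD")):
        for k in range(n_per_diet):
            mouse = f"{diet}{k:02d}"
            b = rng.normal(0.0, 0.03)
            for ri, region in enumerate(REGIONS):
                mu = 1.0 + diet_effect * (di - 0.5) + 0.04 * ri + pattern[ri, di]
                rows.append(
                    dict(
                        animal_id=mouse, sex="male", diet=diet, region=region,
                        metabolite="NAA",
                        ratio_to_tCr=mu + b + rng.normal(0.0, sigma),
                        sd_percent=5.0,
                    )
                )
    return pd.DataFrame(rows)


# --- linear-combination fitting ------------------------------------------


def test_single_component_identity(basis):
    rec = simulate_spectra(basis, {"NAA": 1.0}, 0.0, 0.0, 1, 0)[0]
    fit = fit_linear_combination(rec, basis)
    assert fit.amounts["NAA"] == pytest.approx(1.0, abs=1e-9)
    others = [v for k, v in fit.amounts.items() if k != "NAA"]
    assert max(others) == pytest.approx(0.0, abs=1e-9)


def test_noise_free_mixture_machine_precision(basis):
    rec = simulate_spectra(basis, MIXTURE, 0.0, 0.0, 1, 0)[0]
    fit = fit_linear_combination(rec, basis)
    for m, amount in MIXTURE.items():
        assert fit.amounts[m] == pytest.approx(amount, abs=1e-8)


def test_noisy_mixture_within_three_se(basis):
    rec = simulate_spectra(basis, MIXTURE, noise_sigma=0.01 * 8.0 * 12.0, seed=3)[0]
    fit = fit_linear_combination(rec, basis)
    for m, amount in MIXTURE.items():
        se = fit.sd_percent[m] / 100.0 * max(fit.amounts[m], 1e-12)
        assert abs(fit.amounts[m] - amount) <= 3.0 * se + 1e-9


def test_duplicated_basis_column_rejected(basis):
    dup = BasisSet(basis.ppm, {**basis.spectra, "NAA_copy": basis.spectra["NAA"].copy()})
    rec = simulate_spectra(basis, {"NAA": 1.0}, 0.0, 0.0, 1, 0)[0]
    with pytest.raises(ValueError, match="rank"):
        fit_linear_combination(rec, dup)


def test_sd_percent_decreases_with_noise(basis):
    lo, hi = [], []
    for i in range(20):
        for sigma, store in ((0.5, lo), (2.0, hi)):
            rec = simulate_spectra(basis, MIXTURE, noise_sigma=sigma, seed=100 + i)[0]
            store.append(fit_linear_combination(rec, basis).sd_percent["NAA"])
    assert np.mean(lo) < np.mean(hi)


# --- ratios ---------------------------------------------------------------


def test_tcr_ratio_arithmetic():
    ratios = to_tcr_ratios({"Cr": 4.0, "PCr": 4.0, "NAA": 8.0})
    assert ratios["NAA"] == pytest.approx(1.0)
    assert ratios["Cr+PCr"] == pytest.approx(1.0)


def test_composite_sums_are_linear():
    amounts = {"Cr": 2.0, "PCr": 2.0, "Cho": 1.0, "GPC": 0.5, "PCh": 0.25}
    r = to_tcr_ratios(amounts)
    assert r["Cho+GPC+PCh"] == pytest.approx(r["Cho"] + r["GPC"] + r["PCh"])


def test_tcr_zero_rejected():
    with pytest.raises(ValueError):
        to_tcr_ratios({"Cr": 0.0, "PCr": 0.0, "NAA": 1.0})


def test_ratios_invariant_to_spectrum_scaling(basis):
    rec = simulate_spectra(basis, MIXTURE, 0.0, 0.0, 1, 0)[0]
    fit1 = fit_linear_combination(rec, basis)
    rec.intensity = rec.intensity * 11.0
    fit2 = fit_linear_combination(rec, basis)
    r1, r2 = to_tcr_ratios(fit1.amounts), to_tcr_ratios(fit2.amounts)
    for m in MIXTURE:
        assert r2[m] == pytest.approx(r1[m], rel=1e-9)


def test_quantify_spectra_roundtrip_ratios(basis):
    recs = simulate_spectra(basis, MIXTURE, 0.0, 0.0, 1, 0, metadata={"animal_id": "a1"})
    table = quantify_spectra(recs, basis)
    naa = table[table.metabolite == "NAA"]["ratio_to_tCr"].iloc[0]
    assert naa == pytest.approx(1.0, abs=1e-9)
    tcr = table[table.metabolite == "Cr+PCr"]["ratio_to_tCr"].iloc[0]
    assert tcr == pytest.approx(1.0)


# --- precision filter -----------------------------------------------------


def test_sd_filter_boundary_inclusive():
    table = pd.DataFrame(dict(metabolite=["a", "b"], sd_percent=[20.0, 25.0]))
    out = filter_sd(table)
    assert out["metabolite"].tolist() == ["a"]


def test_sd_filter_empty_and_idempotent():
    empty = pd.DataFrame(columns=["metabolite", "sd_percent"])
    assert filter_sd(empty).empty
    table = pd.DataFrame(dict(metabolite=list("abc"), sd_percent=[5.0, 20.0, 30.0]))
    once = filter_sd(table)
    pd.testing.assert_frame_equal(filter_sd(once), once)


# --- per-metabolite mixed models -----------------------------------------


def test_interaction_model_chosen_under_strong_interaction():
    fit, info, name, p = metabolite_model_compare(
        simulate_metabolite_table(7, interaction_sds=2.0), "NAA"
    )
    assert name == "diet+area+diet:area"
    assert p < 0.05


def test_model_compare_needs_replication():
    table = simulate_metabolite_table(1)
    with pytest.raises(ValueError):
        metabolite_model_compare(table[table.region == "NAc"], "NAA")
    with pytest.raises(ValueError):
        metabolite_model_compare(table.groupby(["diet", "region"]).head(1), "NAA")


def test_metabolite_tests_wald_identity_and_posthoc_family():
    table = simulate_metabolite_table(7, interaction_sds=2.0)
    fit, info, name, _ = metabolite_model_compare(table, "NAA")
    res = metabolite_tests(fit, info, table, "NAA")
    an = res["anova"].set_index("term")
    est = np.asarray(fit.fe_params)[info.term_slices["diet"]][0]
    se = np.sqrt(np.asarray(fit.cov_params())[info.term_slices["diet"], info.term_slices["diet"]][0, 0])
    assert an.loc["diet", "chi2"] == pytest.approx((est / se) ** 2, rel=1e-6)
    assert res["posthoc"] is not None
    assert len(res["posthoc"]) == 4  # one diet contrast per area
    assert (res["posthoc"]["p_bonferroni"] >= res["posthoc"]["p_raw"] - 1e-12).all()


def test_additive_model_reports_no_posthoc():
    table = simulate_metabolite_table(21, interaction_sds=0.0, diet_effect=0.08)
    fit, info, name, _ = metabolite_model_compare(table, "NAA")
    if name == "diet+area":  # the usual outcome without an interaction
        res = metabolite_tests(fit, info, table, "NAA")
        assert res["posthoc"] is None
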