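import numpy as np
import pandas as pd
import pytest

from dietmri import (
    CohortDesign,
    Geometry,
    make_basis_set,
    make_phantom,
    make_protocol,
    simulate_cohort,
    simulate_series,
    simulate_spectra,
)
from dietmri.design import build_design
from dietmri.synthetic_data import DEFAULT_COHORT_BETA, cohort_frame


# --- phantom --------------------------------------------------------------


def test_phantom_csf_outside_retention_filters(phantom):
    assert phantom.truth["CSF"]["T2"] > 80.0
    assert phantom.truth["CSF"]["ADC"] > 1200.0
    assert phantom.truth["CSF"]["MTR"] <= 0.0
    assert phantom.region_mask("CSF").sum() > 0


def test_phantom_truth_override():
    ph = make_phantom({"hypothalamus": {"T2": 47.0}})
    assert ph.truth["hypothalamus"]["T2"] == 47.0
    assert ph.truth["hippocampus"]["T2"] == 50.0


def test_phantom_every_voxel_single_region(phantom):
    # label image partitions the voxels by construction
    labels = phantom.label_image
    assert labels.min() >= 0 and labels.max() <= 6


def test_phantom_degenerate_geometry():
    with pytest.raises(ValueError):
        Geometry(matrix=0)


def test_phantom_unknown_region_rejected():
    with pytest.raises(ValueError):
        make_phantom({"cerebellum": {"T2": 40.0}})


# --- image series ---------------------------------------------------------


def test_series_noiseless_matches_closed_form(phantom):
    p = make_protocol("t2map")
    series = simulate_series(phantom, p, 0.0, "none")
    te = np.array(p.echo_times_ms)
    mask = phantom.region_mask("NAc")
    expected = 1000.0 * np.exp(-te / 48.0)
    assert np.allclose(series.data[mask], expected)


def test_series_seed_determinism(phantom):
    p = make_protocol("dwi_female")
    a = simulate_series(phantom, p, 5.0, "rician", seed=42)
    b = simulate_series(phantom, p, 5.0, "rician", seed=42)
    assert np.array_equal(a.data, b.data)
    c = simulate_series(phantom, p, 5.0, "rician", seed=43)
    assert not np.array_equal(a.data, c.data)


def test_rician_mean_at_zero_signal(rng):
    # E|N(0,s) + i N(0,s)| = s*sqrt(pi/2)
    sigma, n = 10.0, 10_000
    draws = np.hypot(rng.normal(0, sigma, n), rng.normal(0, sigma, n))
    expected = sigma * np.sqrt(np.pi / 2.0)
    se = sigma * np.sqrt(2.0 - np.pi / 2.0) / np.sqrt(n)
    assert abs(draws.mean() - expected) < 3 * se


def test_rician_bias_vanishes_at_high_snr(rng):
    # SNR 50: relative mean bias ~ 1/(2*SNR^2) = 2e-4
    s, sigma, n = 500.0, 10.0, 100_000
    draws = np.hypot(s + rng.normal(0, sigma, n), rng.normal(0, sigma, n))
    assert abs(draws.mean() - s) / s < 1e-3


def test_series_rejects_negative_sigma(phantom):
    with pytest.raises(ValueError):
        simulate_series(phantom, make_protocol("t2map"), -1.0)


# --- cohort ---------------------------------------------------------------


def test_cohort_shape_and_factors():
    table = simulate_cohort(CohortDesign(seed=0))
    assert set(table["diet"]) == {"SD", "HFD"}
    assert sorted(table["day"].unique()) == [0.0, 7.0, 14.0, 28.0, 70.0]
    assert table["region"].nunique() == 4
    per_mouse = table.groupby("animal_id").size()
    assert (per_mouse == 20).all()  # 5 time points x 4 regions


def test_cohort_noise_free_equals_exp_xbeta():
    d = CohortDesign(
        sigma_mouse=0.0,
        sigma_area_in_mouse=0.0,
        sigma_time_slope=0.0,
        sigma_residual=0.0,
        rho_ar=0.0,
        seed=1,
    )
    table = simulate_cohort(d)
    frame = cohort_frame(d)
    X, info = build_design(
        frame, ("area", "time", "diet", "area:time", "diet:time", "diet:area", "diet:area:time")
    )
    beta = np.zeros(info.n_columns)
    for name, v in DEFAULT_COHORT_BETA.items():
        beta[info.column_names.index(name)] = v
    assert np.allclose(np.log(table["value"].to_numpy()), X @ beta)


def test_cohort_seed_determinism():
    a = simulate_cohort(CohortDesign(seed=9))
    b = simulate_cohort(CohortDesign(seed=9))
    pd.testing.assert_frame_equal(a, b)


def test_cohort_ar1_autocorrelation_recovered():
    d = CohortDesign(
        n_per_group=1000,
        sigma_mouse=0.0,
        sigma_area_in_mouse=0.0,
        sigma_time_slope=0.0,
        rho_ar=0.6,
        seed=7,
    )
    table = simulate_cohort(d)
    table["log"] = np.log(table["value"])
    table["resid"] = table["log"] - table.groupby(["diet", "day", "region"])["log"].transform("mean")
    w = table.sort_values(["animal_id", "region", "day"])
    series = w.groupby(["animal_id", "region"])["resid"].apply(np.array)
    arr = np.stack(series.values)
    acf1 = np.corrcoef(arr[:, :-1].ravel(), arr[:, 1:].ravel())[0, 1]
    assert acf1 == pytest.approx(0.6, abs=0.05)


def test_cohort_marginal_variance_is_sum_of_components():
    d = CohortDesign(
        n_per_group=1500,
        sigma_mouse=0.05,
        sigma_area_in_mouse=0.04,
        sigma_time_slope=0.06,
        sigma_residual=0.05,
        rho_ar=0.3,
        seed=8,
    )
    table = simulate_cohort(d)
    last = table[table["day"] == 70.0].copy()  # rescaled day s = 1
    last["log"] = np.log(last["value"])
    last["dev"] = last["log"] - last.groupby(["diet", "region"])["log"].transform("mean")
    expected = d.sigma_mouse**2 + d.sigma_area_in_mouse**2 + d.sigma_time_slope**2 + d.sigma_residual**2
    assert last["dev"].var() == pytest.approx(expected, rel=0.08)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_per_group=1),
        dict(rho_ar=1.0),
        dict(sigma_mouse=-0.1),
        dict(days=(7.0, 14.0)),  # no baseline day
    ],
)
def test_cohort_design_invariants(kwargs):
    with pytest.raises(ValueError):
        CohortDesign(**kwargs)


def test_cohort_unknown_beta_name():
    with pytest.raises(ValueError):
        simulate_cohort(CohortDesign(beta={"no_such_column": 1.0}, seed=0))


# --- spectra --------------------------------------------------------------


def test_basis_unit_area(basis):
    d = basis.ppm[1] - basis.ppm[0]
    for name, spec in basis.spectra.items():
        assert spec.min() >= 0
        assert spec.sum() * d == pytest.approx(1.0)


def test_single_component_spectrum_equals_basis(basis):
    rec = simulate_spectra(basis, {"NAA": 1.0}, 0.0, 0.0, 1, 0)[0]
    assert np.array_equal(rec.intensity, basis.spectra["NAA"])


def test_spectra_seed_determinism(basis):
    a = simulate_spectra(basis, {"NAA": 2.0}, 0.5, 0.1, 3, seed=5)
    b = simulate_spectra(basis, {"NAA": 2.0}, 0.5, 0.1, 3, seed=5)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.intensity, rb.intensity)


def test_spectra_negative_amount_rejected(basis):
    with pytest.raises(ValueError):
        simulate_spectra(basis, {"NAA": -1.0})


def test_spectra_unknown_metabolite_rejected(basis):
    with pytest.raises(ValueError):
        simulate_spectra(basis, {"Unobtainium": 1.0})
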