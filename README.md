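# dietmri

A tested, reusable Python pipeline for **longitudinal multiparametric MRI
and HRMAS spectroscopy analysis in diet-intervention mouse studies**. It is
aimed at preclinical imaging groups who acquire multi-echo T2, multi-b
diffusion and magnetization-transfer series over several weeks of dietary
treatment and want the downstream analysis — map fitting, region-of-interest
statistics, mixed-model selection, metabolite quantification and power
analysis — to be reproducible and validated against known ground truth.

## What it computes

**Parametric maps.** Voxelwise least-squares fits of

- T2 relaxometry: S(TE) = S₀·e^(−TE/T2) (50 echoes, 12–600 ms),
- diffusion: S(b) = S₀·e^(−b·ADC) with b = γ²δ²G²(Δ−δ/3) in s·mm⁻² and
  ADC in μm²/s,
- magnetization transfer ratio: MTR = (S₀−S_MT)/S₀·100 (%),

on a 21 mm field of view, 128×128 matrix (164 μm in-plane voxels).

**ROI statistics.** Deterministic region templates (hypothalamus 70 voxels,
hippocampus 2×30, nucleus accumbens 2×40, infralimbic area 20), strict
physiologic retention filters (30 < T2 < 80 ms, 0 < ADC < 1200 μm²/s,
MTR > 0) that remove CSF and artifacts, and Tukey-fence outlier removal
(Q1/Q3 ± 1.5·IQR) per diet × day × region group.

**Mixed-model ladder.** log-responses fitted to a nine-model chain
B → A → AT → ATrs → ATrsD → … → ATrsD.TA.DT.DA.DAT with mouse and
area-within-mouse random intercepts, optional per-mouse time slope, and
AR(1) residual correlation; ML/AIC selection, REML inference, Type III Wald
tests under sum-to-zero coding, and Dunnett-corrected day-vs-baseline
contrasts per diet × region (4 comparisons per family).

**HRMAS quantification.** Non-negative linear-combination fitting of 1-D
spectra against a metabolite basis set with polynomial baseline, %SD-style
precision estimates (filter at ≤ 20), total-creatine (Cr+PCr) ratios, and
per-metabolite mixed-model comparisons (diet × area, LRT-guided interaction
inclusion).

**Power analysis.** Repeated-measures ANOVA power from the noncentral F
distribution with λ = f²·N·m·ε/(1−ρ), and smallest-n / consensus-n solvers.

A synthetic-data module generates every input — digital phantoms with
per-region ground truth and a CSF rim, noisy (Rician) image series,
longitudinal cohorts with nested random effects and AR(1) serial
correlation, and basis-set spectra — so the full pipeline is testable
end-to-end without any animal data.

## Worked example

```python
import dietmri as dm

# image a noise-free digital phantom through the three protocols
phantom = dm.make_phantom()
t2map, _ = dm.fit_t2_map(dm.simulate_series(phantom, dm.make_protocol("t2map")))
masks = dm.make_roi_masks()
entry = dict(animal_id="m01", sex="male", diet="SD", day=0, maps={"T2": t2map})
print(dm.build_roi_table([entry], masks))

# a study-sized longitudinal cohort and the model ladder
table = dm.simulate_cohort(dm.CohortDesign(seed=1))
best, aic = dm.select_best_model(table)
print(best.model.name)
refit = dm.fit_lme(table, best.model, estimation="REML")
print(dm.time_contrasts(refit, "HFD", "hippocampus").round(4))
```

This prints the per-region T2 table (each region recovering its generating
value, e.g. hypothalamus 45.0 ms from 70 voxels), then the AIC-selected
model name for the simulated cohort (`ATrsD.TA.DT` — area, time, random
slope, diet plus the area:time and diet:time interactions, matching the
generating structure) and the four Dunnett-adjusted day-versus-baseline
contrasts for the HFD hippocampus, e.g.

```
  diet       region   day  estimate      se       z   p_raw  p_dunnett
0  HFD  hippocampus   7.0    0.0571  0.0167  3.4150  0.0006     0.0024
1  HFD  hippocampus  14.0    0.0689  0.0179  3.8522  0.0001     0.0004
2  HFD  hippocampus  28.0    0.0989  0.0182  5.4319  0.0000     0.0000
3  HFD  hippocampus  70.0    0.0971  0.0193  5.0355  0.0000     0.0000
```

where `estimate` is the log-scale change from day 0 (0.0571 ≈ +5.9% on the
natural scale) and `p_dunnett` the multiplicity-adjusted p-value.

A thin CLI wraps the same functions:

```bash
dietmri simulate cohort --seed 1 --out roi.csv
dietmri lme run --roi roi.csv --out results/
dietmri power --design within --f 0.35 --m 5 --rho 0.8 --target 0.8
```

## Layout

- `src/dietmri/protocols.py` — acquisition protocols, b-value arithmetic
- `src/dietmri/synthetic_data.py` — phantoms, image series, cohorts, spectra
- `src/dietmri/param_maps.py` — T2 / ADC / MTR map fitting
- `src/dietmri/roi_stats.py` — ROI templates, filters, outlier rule, tables
- `src/dietmri/lme_ladder.py` — mixed-model chain, AIC selection, contrasts
- `src/dietmri/hrmas_quant.py` — spectral fitting, tCr ratios, metabolite stats
- `src/dietmri/power_design.py` — repeated-measures power and sample size
- `docs/methods.md` — models, assumptions, defaults and limitations
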