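# spacerselect

Decision support for **rectal hydrogel spacer patient selection** in prostate
external-beam radiotherapy.

A polyethylene-glycol spacer injected between the prostate and the rectum
pushes the rectum out of the high-dose region, but the dosimetric benefit
varies widely between patients and the implant has costs and risks. This
package implements the full analysis chain needed to decide, *before*
implant, which patients stand to gain the most:

1. **Geometry** — from a pre-implant structure set (rectum, CTV) it derives
   the standard planning structures (PTV by anisotropic margin expansion,
   7 mm / 5 mm posterior; a 3 mm inner rectal wall RW; the height-limited
   wall RW17.5 truncated 17.5 mm beyond the PTV) and measures the predictor
   metrics: absolute and rectum-normalized volumes, the rectum-in-PTV
   overlap (RinPTV), and the mean slice-wise 2D Hausdorff distance between
   rectal wall and CTV (RWtoCTV).
2. **Dose endpoints** — cumulative DVHs on arbitrary dose grids and the
   rectal V55Gy endpoints for 60 Gy / 20-fraction plans: Pre-RV55 (percent
   of rectal volume at ≥ 55 Gy pre-implant) and ΔRV55 (its pre-to-post
   reduction). V55Gy is the hypofractionated analogue of the conventional
   V70Gy toxicity threshold.
3. **Modelling** — the linear-model pipeline used to build the predictive
   models: Pearson screening, OLS (y = β₀ + Σ βᵢxᵢ), backward stepwise AIC,
   VIF pruning (VIF < 5), squared structure coefficients
   (r²s = r²_pears / R²), and leave-one-out cross-validation reporting
   predicted R² = 1 − PRESS/SST, MAE and %MAE.
4. **Decision support** — the four published models are shipped as a frozen
   registry, rendered as nomograms, and applied through the two-stage
   selection flowchart: recommend implant iff predicted Pre-RV55 ≥ ω₁
   (default 3.0 %) **and** predicted ΔRV55 ≥ ω₂ (default 3.5 %).
5. **Synthetic data** — pelvic phantoms, spacer displacement, a surrogate
   dose engine and statistically calibrated cohort simulation, so the whole
   chain is testable without clinical data.

## Worked example

Simulate a 21-patient cohort calibrated to the published cohort statistics,
refit the dose-reduction model from TPS-derivable candidates, validate it,
and run the selection flowchart:

```bash
$ spacerselect simulate --n 21 --seed 1 --out cohort.csv
wrote 21-patient cohort to cohort.csv
$ spacerselect fit cohort.csv --dependent delta_rv55_pct --candidates model2 --out model.json
selected terms: ['norm_ctv_pct', 'norm_rinptv_pct'] (R^2 = 0.826)
AIC trace: drop start (AIC -10.52) -> drop ctv_vol_cc (AIC -12.51) -> drop rw_vol_cc (AIC -14.32) -> drop rinptv_cc (AIC -16.15)
$ spacerselect validate cohort.csv --model-json model.json
predicted R^2 = 0.762, MAE = 0.528, %MAE = 10.52
$ spacerselect decide cohort.csv --out decisions.csv
8/21 recommended (38%); 3 removed at stage 1, 10 at stage 2
```

The fitted model retains the normalized rectum-in-PTV overlap — the
dominant predictor of spacer benefit — with an R² close to the published
0.81, and the flowchart splits the cohort into patients predicted to gain a
worthwhile dose reduction and those predicted to gain little.

The same works from the library, e.g. scoring a single patient at the
published cohort means:

```python
>>> from spacerselect import decide
>>> out = decide({"norm_rinptv_pct": 3.4, "norm_ctv_pct": 62.3,
...               "rectum_vol_cc": 79.2, "rw_to_ctv_cm": 2.18,
...               "rw_to_ctv_inv_cubed": 2.18**-3})
>>> round(out.predicted_pre_rv55, 2), round(out.predicted_delta_rv55, 2)
(5.89, 4.47)
>>> out.recommend_implant
True
```

A mean-anatomy patient is predicted at Pre-RV55 = 5.89 % and ΔRV55 =
4.47 % — above both cutoffs, so the implant is recommended.

Feature extraction starts from a structure set (internal JSON or DICOM
RTSTRUCT): `spacerselect extract --structures structs.json` emits the
canonical feature CSV; `spacerselect nomogram` emits machine-readable (and
optionally rendered) nomograms for the published models.

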