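# hemomap

Voxelwise hemodynamic parameter mapping from MRI:

- **forward_model** — closed-form two-compartment asymmetric-spin-echo (ASE)
  signal model: asymptotic tissue dephasing (short/long displacement-time
  regimes), Fresnel-integral blood compartment, and the physical relations
  linking oxygen extraction fraction (OEF), deoxygenated blood volume (DBV),
  the characteristic frequency and the reversible relaxation rate
  R2' = DBV · δω.
- **qbold_fit** — voxelwise Bayesian (MAP + Laplace) estimation of
  (S0, R2', DBV) from ASE τ-series with Gaussian priors, OEF map computation,
  physiological exclusion thresholds, Gaussian smoothing, and ≥50 %-support
  group-average maps.
- **asl_quant** — multi-delay pcASL general-kinetic-model fitting for
  calibrated CBF and arterial-transit-time maps.
- **synthetic_data** — a seeded digital phantom: nine cortical regions on a
  3-D grid with published per-region parameter means/SDs for two
  physiological conditions (pre/post vasodilation), plus ASE and ASL signal
  simulation at configurable SNR.
- **roi_stats** — regional aggregation, CMRO2, paired t-tests with
  Bonferroni correction, random-intercept linear mixed models
  (parameter ~ CBF + (1|subject) + (1|region)), and derived group summaries.

## Command-line interface

All volumes are NIfTI-1; τ/PLD timings are plain-text sidecars (one value in
seconds per line).

```bash
# generate a synthetic two-condition study with ground truth
hemomap simulate --spec builtin:table1 --out study/ --seed 1 --n-subjects 8

# fit the qBOLD model: R2', DBV, OEF maps + exclusion report
hemomap fit-qbold --ase study/sub00_pre_ase.nii.gz --taus study/taus.txt \
    --mask study/atlas.nii.gz --out-prefix maps/sub00_pre

# fit the ASL kinetic model: CBF and ATT maps
hemomap fit-asl --dm study/sub00_pre_asl_dm.nii.gz --m0 study/sub00_pre_m0.nii.gz \
    --plds study/plds.txt --out-prefix maps/sub00_pre

# regional table + summary statistics over all fitted subjects/conditions
hemomap roi-report --maps maps/ --atlas study/atlas.nii.gz --out report
```

`fit-qbold`, `fit-asl` and `roi-report` are also installed as standalone
commands.  Physical constants, priors and protocol timings can be overridden
with a flat YAML config (`--config`), keys: `te_s`, `tr_s`, `taus_s`, `b0_T`,
`gamma`, `dchi0`, `r2t_s`, `hct`, `mu0_r2p_s`, `mu0_dbv`, `sigma0_r2p_s`,
`sigma0_dbv`, `plds_s`, `label_duration_s`, `t1b_s`, `t1t_s`, `lambda_ml_g`,
`alpha`.

## Units

SI internally (seconds, s⁻¹, tesla, fractions).  Percent, milliseconds and
mL/100 g/min appear only at I/O and reporting boundaries: OEF/DBV maps are
fractions on disk, regional tables and summaries are in percent; CBF is
mL/100 g/min; CMRO2 is µmol/100 g/min.
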