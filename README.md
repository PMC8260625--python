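# petquant

Threshold-calibrated quantification of FDG-PET lesions, built for studying
how measurement conventions change the numbers clinicians act on.

PET analysis workstations all report the same semiquantitative parameters —
SUVmax, SUVmean, metabolic tumour volume (MTV) and total lesion glycolysis
(TLG) — yet return different values for the same scan, because they differ
in delineation thresholds, maximum-uptake estimation and calibration.
`petquant` implements the full measurement chain end to end on synthetic
data, so every stage is testable against known ground truth:

1. **Phantom simulation** — a NEMA-style body phantom with hot spheres of
   known volume (13–37 mm; 1.150–26.522 cm³), Gaussian blur standing in for
   the effective image resolution, and proportional Gaussian noise; plus a
   synthetic patient cohort with log-normal lesion SUVmax (mean 9.9, SD 4.7)
   and volume (mean 20 cm³), injected activity 364 ± 75 MBq and 50–70 min
   uptake times.
2. **SUV arithmetic** — `SUV = C[kBq/mL] / (A[MBq]/m[kg])` with mass `m`
   either body weight or the sex-specific James lean body mass
   (`1.10·BW − 128·BW²/h²` men, `1.07·BW − 148·BW²/h²` women), decay-corrected
   administered activity, and the raw Bq/mL readout.
3. **Delineation** — %-of-max threshold VOI (inclusive comparison,
   face-connected component of the hottest voxel), MTV = voxel count ×
   voxel volume, TLG = SUVmean × MTV.
4. **Calibration** — per sphere size and per simulated software variant,
   exhaustive search of the integer threshold (1–99%) that recovers the
   true sphere volume; equal-weight averaging across variants and half-up
   rounding gives the consensus threshold per size bin; a fixed-point
   iteration assigns each lesion to its size bin.
5. **Comparison statistics** — Pearson correlation with strength bands
   (|r| ≥ 0.7 very strong, ≥ 0.5 strong, ≥ 0.3 moderate, else low),
   Shapiro–Wilk-gated paired t-test / Wilcoxon signed-rank difference
   tests, and mean ± SD summary tables across variants.

## Worked example

```python
import petquant as pq

phantom = pq.PhantomSpec(noise_sd_fraction=0.0, seed=7)
table = pq.calibrate_thresholds(phantom, pq.DEFAULT_VARIANTS)
print(table.to_dataframe().to_string(index=False))
```

```
 volume_cm3 th_A th_B th_C  mean_percent  consensus_percent
   1.150347   65   65   72     67.333333                 67
   2.572441   54   54   58     55.333333                 55
   5.575280   47   47   49     47.666667                 48
  11.494040   46   46   47     46.333333                 46
  26.521849   48   48   48     48.000000                 48
```

Each row is one sphere size: the per-variant columns hold the threshold
(% of max) that best recovered that sphere's true volume in that variant's
readout, and the consensus column their rounded equal-weight mean. The
partial-volume trend is visible: the 1.15 cm³ sphere needs a 67% cut-off,
the large spheres ≈ 46–48%. Variant C reads a smoothed maximum, so its
optima run higher; variant B's pure calibration offset cancels in a
%-of-max rule and leaves thresholds untouched.

```python
cohort = pq.generate_patient_cohort(pq.CohortSpec(n_patients=98, seed=7))
report = pq.build_comparison_report(pq.quantify_cohort(cohort, table))
print(report.summaries.query("parameter == 'suv_mean_bw'").to_string(index=False))
print(report.difference_tests.query("parameter == 'suv_mean_bw'").to_string(index=False))
```

```
  parameter variant     mean       sd
suv_mean_bw       A 7.103291 2.909723
suv_mean_bw       B 6.889348 2.822653
suv_mean_bw       C 7.242499 2.988253

  parameter   pair                 test      p_value  significant
suv_mean_bw A vs B wilcoxon signed-rank 8.330397e-18         True
suv_mean_bw A vs C        paired t-test 1.454021e-24         True
suv_mean_bw B vs C wilcoxon signed-rank 8.330397e-18         True
```

The three variants' SUVmean(BW) agree to r > 0.999 yet differ
systematically (the ±3% calibration offsets), and the paired tests flag
every pair — the same pattern of "highly correlated but significantly
different" that motivates comparing software before pooling measurements.

## Command line

```sh
petquant workflow --config config.yaml --seed 1 --out results/
```

chains phantom → calibration → cohort → quantification → report and writes
the threshold table, per-variant metric tables and the comparison report as
CSV + JSON. The stages are also available individually
(`simulate-phantom`, `simulate-cohort`, `calibrate`, `quantify`,
`compare`), passing data through NIfTI volumes and CSV/JSON sidecars; DICOM
PET series can be read in place of NIfTI. Every run writes `run_log.json`
with the config hash and seed; identical config + seed reproduces identical
bytes.

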