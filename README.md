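# petquant

Quantification and internal-dosimetry pipeline for first-in-human brain PET
radioligand studies, built around the workflow used to evaluate the
¹⁸F-labelled BACE1 (beta-secretase 1) tracer class: arterial input-function
construction with radiometabolite correction, compartment-model and Logan
estimation of the total distribution volume, test–retest reliability
statistics, and MIRD-style whole-body dosimetry.

## Who this is for

PET kinetic modellers and medical physicists who start from extracted
time–activity curves (TACs) and blood sample tables — not from images — and
need a scriptable, reproducible replacement for the usual GUI chain
(kinetic-modelling software for the fits, compartmental software for organ
retention, phantom software for doses).

## The models

**Kinetics.** Tissue activity follows the serial one- or two-tissue
compartment model driven by the metabolite-corrected arterial plasma input
C_p:

    dC1/dt = K1·Cp − (k2 + k3)·C1 + k4·C2
    dC2/dt = k3·C1 − k4·C2

The primary outcome is the total distribution volume,
V_T = K1/k2 (1TCM) or V_T = (K1/k2)(1 + k3/k4) (2TCM), also estimated as
the late-time slope of the Logan plot.  Models are compared with the
least-squares AIC and the F-test for nested models.  Time stability refits
V_T on scans truncated from 123 to 63 min in 12-min steps.

**Reliability.**  TRV(%) = |PET2 − PET1| / ((PET1 + PET2)/2) × 100 and the
one-way random-effects ICC = (s_b² − s_w²)/(s_b² + (n−1)·s_w²) with n = 2
sessions, computed per region and summarised across regions.

**Dosimetry.**  Organ %ID curves (decay-corrected, urine voids added back to
the bladder) are fitted with non-negative sums of exponentials; residence
times τ = Σ aᵢ/(λᵢ + λ_phys)/100 are folded through an S-value matrix into
absorbed doses, and the effective dose is the ICRP-60 tissue-weighted sum
(with the standard remainder splitting rule).

A fully tested synthetic-data generator reproduces the study conditions
(123-min brain schedule 20 s × 9, 1 min × 3, 3 min × 5, 6 min × 17; 12
gray-matter regions at published kinetic magnitudes; ≈70% parent fraction
at 60 min; test–retest cohorts with controllable variance components;
4-session whole-body %ID curves with ≈10 %ID urinary excretion).

## Worked example

Simulate a small test–retest cohort, run the full quantification, and look
at the 2TCM reliability table:

```
$ petquant simulate cohort --subjects 3 --seed 5 --out cohort/
$ petquant quantify --config cohort/cohort.yaml --out results/
$ cat results/reliability_vt_2tcm.csv
# petquant 0.1.0 | config_sha256=1f5f475954c3 | seed=5
,trv_mean,trv_sd,icc,n_subjects
CERCX,4.0529005,3.2117884,0.96069674,3
CAU,12.327003,6.4358742,0.85047502,3
PUT,15.705841,15.290507,0.85606997,3
THA,13.338496,7.5696236,0.84621736,3
LFC,16.060055,10.508147,0.59782104,3
LTC,7.258867,5.0134793,0.38744057,3
HIP,12.395761,11.51391,0.88110376,3
LOC,23.505546,20.356908,0.22549667,3
LPC,15.811734,15.960005,0.6942646,3
ACC,21.004949,16.018411,-0.12059834,3
PCC,13.701402,4.9654122,0.9440385,3
AMG,9.102549,7.760087,0.84872044,3
mean,13.688759,10.383679,0.66431219,3
```

Each row is one region: the across-subject mean and SD of the per-subject
test–retest variability of V_T (percent), the one-way ICC, and the number
of complete test–retest pairs used; the `mean` row averages the regions.

The dosimetry study runs the same way from organ %ID tables:

```
$ petquant simulate biodistribution --seed 1 --out bio/
$ petquant dose --config bio/dose.yaml --out dose/
$ head -6 dose/residence_times.csv
# petquant 0.1.0 | config_sha256=dddc10ad0802 | seed=1
organ,residence_time_h,method
liver,0.43309847,1-exp
lung,0.152618,1-exp
brain,0.082513277,1-exp
heart_wall,0.033789077,1-exp
```

`dose/dose_report.csv` then lists per-organ absorbed doses (μSv/MBq,
through the bundled toy S-matrix) and the effective dose.  The repository
ships a synthetic diagonal-dominant S-matrix for tests and examples;
reproducing published organ doses requires real phantom S-values, which are
an input file.

Everything is also available as a library (`petquant.fit_compartment`,
`petquant.logan_vt`, `petquant.effective_dose`, ...) for use in notebooks
and scripts.

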