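# ctri — epifascial fibrosis quantification in paired-limb CT

Lymphedema-induced fibrosis shows up on axial CT as honeycomb/trabecular
strands ("reticulation") in the subcutaneous fat between the skin and the
muscle fascia. `ctri` implements a digital-subtraction algorithm that counts
those reticulation pixels per slice and per limb, and summarises a whole
scanned limb pair as the **CT reticulation index**:

```
CTRI = Σ_s  a_s / u_s        (summated over evaluable slices s)
```

where `a_s` and `u_s` are the reticulation pixel counts of the affected and
unaffected limb on slice *s* (a `ratio_of_sums` alternative, `Σa / Σu`, is
also available). Because the noise clean-up step carries run-to-run
variability, the processing is repeated (default 10 times, seeded) and the
index is reported as **CTRI_MAX / CTRI_MEAN / CTRI_MIN** over runs.

The per-slice chain: eliminate the soft-tissue HU band [−50, 26] → remove
noise (opening + small-object removal, the seedable surrogate for manual
clean-up) → peel the outermost skin → close the remaining pattern into the
subfascial core → re-add the skin line → black-white reversion → the
donut-shaped epifascial region between skin and core → count the nonblack
pixels of the original slice inside the donut.

The package is for imaging researchers who want a reproducible, testable
implementation of this index: it ships a ground-truth paired-limb phantom
generator (so every stage is verifiable without patient data), readers for
DICOM series and NIfTI volumes, and the statistics layer used to relate the
index to clinical measures (normality triage, Spearman with log transform,
Mann-Whitney U, ROC/AUC with Youden cutoff and bootstrap CI).
See `docs/methods.md` for the full method description.

## Worked example

```python
from ctri.phantom import PhantomSpec, generate_phantom
from ctri.index import run_ctri

# 10-slice phantom; affected (left) trabecular density 2x the unaffected side
spec = PhantomSpec(n_slices=10, noise_sd=5.0, reticulation_density=(0.2, 0.1), seed=42)
volume, truth = generate_phantom(spec)

result = run_ctri(volume, affected_side="left", n_runs=10, base_seed=17)
print(f"CTRI_MAX  = {result.ctri_max:.2f}")
print(f"CTRI_MEAN = {result.ctri_mean:.2f}")
print(f"CTRI_MIN  = {result.ctri_min:.2f}")
```

prints

```
CTRI_MAX  = 19.79
CTRI_MEAN = 19.79
CTRI_MIN  = 19.79
```

With 10 slices and a true per-slice count ratio of ~2 (e.g. slice 0 counts:
affected 1508, unaffected 758, ratio 1.989), the summated index lands within
1 % of 2 × 10 = 20. On this clean phantom the three CTRI variants coincide —
the parameter jitter does not move counts when trabeculae are well separated
from skin and muscle; on realistic data the max/mean/min spread reflects the
clean-up variability the repeated-run protocol is designed to absorb.

## Command line

```
ctri phantom --out fixtures/                           # synthetic volume + truth CSV
ctri compute --manifest manifest.csv --out results/ \
             --runs 10 --seed 17 --aggregation sum_of_ratios
ctri stats   --results-csv results/cohort_ctri.csv \
             --covariates-csv clinical.csv --out report/
```

`manifest.csv` has columns `patient_id, volume_path, affected_side`
(the affected side is a clinical annotation, never inferred from images).
Exit codes: 0 success, 1 partial patient failures, 2 config/manifest error.

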