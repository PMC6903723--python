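# Methods

## The problem and the measurement

Chronic lymphedema drives fibrotic remodelling of the subcutaneous
(epifascial) compartment: honeycomb/trabecular strands of connective tissue
appear in the fat between the skin and the muscle fascia. These reticulations
attenuate X-rays more than the surrounding fat, so on a calibrated axial CT
slice they appear as bright strands (tens of HU) embedded in a dark annulus
(fat, roughly −100 HU). This package quantifies them by digital subtraction
and summarises a whole scanned limb pair as the CT reticulation index (CTRI).

### Per-slice chain

For one limb region of one axial slice (all morphology is 2-D, in-plane,
with digital-disk structuring elements `dx² + dy² ≤ r²`):

1. **Body silhouette** — pixels ≥ `body_mask_hu` (default −300 HU),
   hole-filled, speckle below `min_object_px` removed. Needed because the HU
   band elimination alone would leave background air in the picture.
2. **Band elimination** — the soft-tissue band `[hu_band_low, hu_band_high]`
   (default [−50, 26] HU, bounds inclusive) is blacked out. The working
   binary pattern is the remaining *nonblack* tissue, i.e. pixels above the
   band: skin, muscle, bone and the fibrotic trabeculae. Tissue darker than
   the band (fat, air) is already black and never joins the pattern; the
   lower bound documents the floor of the targeted band. Within-band
   edematous tissue is the background the method subtracts away.
3. **Noise removal** — morphological opening (`opening_radius_px`, default
   1 px) followed by removal of connected components smaller than
   `min_object_px` (default 9 px). This is an automated, seedable surrogate
   for interactive clean-up; see *Repeated-run protocol*.
4. **Skin peel** — the outer shell of the body silhouette, `skin_peel_px`
   thick (default 2 px), is removed from the pattern and retained as the
   skin line.
5. **Closing** — the peeled pattern is closed with a disk of
   `closing_radius_px` (default 5 px; performed on a padded array so the
   image border is inert). The connected component containing the limb
   centroid is taken as the subfascial core (muscle + bone). Residual
   components — typically detached reticulation fragments — are counted and
   logged, *not* merged: escalating the closing until everything fuses
   (available via `closing_escalations`, default 0) would annex the
   reticulations into the core and zero the signal.
6. **Skin re-addition, reversion, donut** — the skin line is added back
   around the core; the merged pattern is black-white reverted; restricting
   the reversion to the body yields the donut-shaped epifascial region
   between skin and core.
7. **Count** — the nonblack pixels of the *original* slice (the stage-2
   pattern) inside the donut are the epifascial reticulation; their number is
   the slice count.

### Limb separation

Both limbs are scanned simultaneously. Disjoint limbs are separated by
8-connected components (two largest kept; smaller specks logged and
discarded); limbs that touch are split at the image column with the fewest
body pixels between the two column-histogram mass peaks, the cut column
going to the side with the nearer centroid (ties to the left). The affected
side is a per-patient clinical annotation, never inferred from images.

### The index and the repeated-run protocol

Per slice *s*, let `a_s` and `u_s` be the affected and unaffected
reticulation counts. The default aggregation is the summated ratio

CTRI = Σ_s a_s / u_s over evaluable slices,

so two identical limbs over S slices give CTRI = S. This reading is
consistent with reported index magnitudes of tens-to-hundreds for scans of
~100 slices; a `ratio_of_sums` alternative (Σa / Σu, giving 1 for identical
limbs) is provided for sensitivity analyses. Slices with `u_s = 0` are
excluded (with a warning when `a_s > 0`) rather than epsilon-regularised —
any epsilon would dominate the sum arbitrarily — and per-run slice coverage
is reported.

The interactive clean-up step of the original procedure makes repeated
processing of the same volume give slightly different counts. The package
reproduces this as *seeded jitter*: the whole pipeline is run `n_runs` times
(default 10); run *k* draws its denoise parameters
(`opening_radius_px ∈ {1, 2}`, `min_object_px ∈ [5, 15]`) deterministically
from `base_seed + k`, one draw per run applied to all slices, like one
operator pass over the volume. CTRI_MAX / CTRI_MEAN / CTRI_MIN are the
max / arithmetic mean / min over runs. With jitter disabled all runs are
identical and the three values coincide; the same base seed always
reproduces results bit-for-bit.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `hu_band_low`, `hu_band_high` | −50, 26 | HU | the eliminated soft-tissue band; bounds inclusive (a pixel at exactly 26 HU is eliminated — the closed-interval reading is fixed once, the 1-HU choice is immaterial) |
| `body_mask_hu` | −300 | HU | separates air (≈ −1000) from every tissue including fat (≈ −100) |
| `opening_radius_px` | 1 | px | removes speckle while sparing trabeculae wider than the disk diameter |
| `min_object_px` | 9 | px | small-object floor of the clean-up surrogate |
| `skin_peel_px` | 2 | px | thick enough to survive later closing; must be ≥ the skin's apparent thickness for an exact peel |
| `closing_radius_px` | 5 | px | bridges intramuscular dropouts of the band threshold; structures within one disk diameter of the core are absorbed by it, so reticulation must sit further away to be counted |
| `n_runs` | 10 | — | repetitions of the protocol |

## The phantom

`ctri.phantom` generates paired-limb volumes with exact, pre-noise ground
truth. Each slice holds two concentric-disk limbs on air: bone core (700 HU)
inside a muscle disk (45 HU), a fat annulus (−100 HU), and a skin ring
(35 HU) drawn as the morphological outer shell of the limb disk — so a skin
peel with the same element removes it exactly. Reticulation is emulated by
radial trabecular spokes (60 HU, 3 px wide) placed in the fat annulus on
non-overlapping, seeded angular slots until the requested per-side area
density is reached (granularity: one spoke). Spokes keep `core_clearance_px`
(default 12 px, i.e. more than the closing diameter) from the muscle core so
the closing cannot annex them, and `skin_clearance_px` from the skin.
Gaussian HU noise (default sd 5) is applied after the truth masks are
recorded. A `mirror` mode builds the right limb (noise field included) as
the exact horizontal mirror of the left, for exactness tests. Default
in-plane geometry is 256×256 px at 1 mm with a 5 mm slice thickness
(a leg-protocol scale); limb radius 58 px so the two limbs fit disjointly.

What the phantom does *not* emulate: anatomical texture, partial-volume
blur, beam hardening, contrast phases, touching limbs, or reticulation that
contacts the fascia. Passing the recovery tests therefore shows the chain is
correct on well-separated, band-respecting geometry; it does not establish
clinical accuracy on patient scans, where reticulation adjacent to the
muscle fascia will be partially absorbed into the core and counts will be
conservative.

## Statistics layer

* **Normality triage** — Shapiro-Wilk for n ≤ 50, Lilliefors otherwise;
  `non_normal` iff p < 0.05; constant vectors are non-normal by convention.
* **Spearman** — average-rank ties; exact two-sided p by full permutation
  enumeration for n ≤ 9, t-approximation otherwise; pairwise-complete
  deletion with per-analysis n reported. Non-normal positive variables are
  log-transformed first, per protocol; a strictly increasing transform
  cannot change a rank correlation, so this is a documented no-op on rho.
* **Mann-Whitney U** — two-sided, min-U convention; exact null when
  `n_a·n_b ≤ 400` and no ties, otherwise normal approximation with tie and
  continuity correction.
* **ROC** — empirical curve with the convention *score ≥ cutoff is
  positive*; AUC by the trapezoidal rule (equal to pairwise concordance with
  ties as 1/2); cutoff at the Youden-J maximum with ties broken toward
  higher specificity, then higher cutoff; stratified percentile bootstrap
  for the AUC interval, seeded. Dichotomies for lymphoscintigraphy staging:
  stage ≥ 4 vs below, and stage ≥ 3 vs below.
* **Report** — one row per CTRI type × covariate with test, statistic, p and
  n; primary p-values are uncorrected, and a Benjamini-Hochberg column
  (`p_bh`) is emitted alongside as a clearly-labelled addition.

`simulate_cohort` builds a synthetic 24-patient covariate table with known
monotone links (duration and substage increase with log CTRI; the
bio-impedance ratio decreases with CTRI_MIN; distal circumference and
albumin are pure noise) for recovery testing of the battery. It is not a
model of real patients.

## Numerical conventions and degenerate inputs

* Band bounds inclusive for elimination; HU comparisons on float64.
* Loaded HU values are clipped to [−1024, 3072]; clips are counted.
* All labelling is 8-connected; closing is padded so borders are inert.
* An all-air slice raises "no body found"; in the repeated-run protocol a
  failing slice is excluded from that run with a log entry rather than
  aborting it. A volume with no evaluable slice in any run raises.
* Zero-component body masks, overlapping limb regions, negative counts,
  one-class ROC inputs and empty Mann-Whitney groups raise immediately.
* Tie-breaks are all deterministic (documented above), so the whole
  phantom → compute → stats path is bit-reproducible from its seeds.

## Problem sizes used in tests and in the acceptance script

Tests and `scripts/acceptance.py` use 20-slice, 256×256 phantoms at
densities 0.2 (affected) / 0.1 (unaffected), the 10-run protocol, a
2000-point ROC null simulation, and 100 simulated 24-patient cohorts —
desk-scale sizes chosen so the whole suite runs in well under a minute per
check while the spoke-placement granularity (one spoke ≈ 2–5 % of a side's
count) stays inside the stated tolerances.

## Known limitations

* The splitting rule for touching limbs assumes one limb per image half.
* Reticulation within one closing diameter of the subfascial core is
  absorbed into the core and not counted (conservative bias on real scans).
* The ROC cutoff convention is one of several; a different tie-break can
  report a different cutoff for the same curve.
* DICOM support assumes axial, single-orientation series with rescale
  metadata; no gantry tilt or multi-frame support.
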