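# Methods

`femhu` implements an opportunistic-osteoporosis-screening analysis on
proximal-femur CT: Hounsfield-unit histogram analysis (HUHA) and mean HU over
a 3D proximal-femur volume of interest (`3D_Femur`) and a 2D true-coronal
femoral-neck region of interest (`2D_coronal`), evaluated against DXA
T-score groups. Because no patient scans are available, the package ships a
synthetic phantom cohort whose statistical structure mirrors a screening
population of 430 women, and every downstream step — segmentation,
reformation, measurement, diagnostics — operates on those phantoms exactly
as it would on clinical volumes.

## Screening indexes

For any region with HU values $v_1,\dots,v_n$:

* $\mathrm{HUHA_{Fat}} = 100\,|\{v_i < 0\}|/n$ — percentage of the region in
  the fat band (fatty marrow attenuates below water);
* $\mathrm{HUHA_{Bone}} = 100\,|\{v_i \ge 126\}|/n$ — percentage at or above
  the bone band edge (the 126 HU edge is inclusive);
* mean-HU — the arithmetic mean of the raw values.

Percentages are formed from exact integer counts (rational arithmetic before
the float conversion), so the fat/mid/bone triplet always sums to 100.
Membership of a pixel/voxel in a region is decided by its center
(center-in-region rule), and HU values enter the statistics raw — no binning
beyond the two band edges at 0 and 126 HU.

## Phantom cohort

### Subject sampling

`sample_cohort(n_osteo, n_non, ...)` draws exact group counts. Group-wise
age, femoral-neck T-score and BMD are truncated-Gaussian: T-scores are
constrained to the group's side of −2.5 (resampling via the truncated
distribution, not whole-cohort rejection, so the configured moments are
preserved up to the truncation shift), BMD to be positive, age to the
study-inclusion minimum of 50 years. Default moments (mean ± SD):

| group | n (default) | age (y) | T-score | BMD (g/cm²) |
|---|---|---|---|---|
| osteoporosis | 96 | 78.5 ± 8.7 | −3.1 ± 0.5 | 0.57 ± 0.06 |
| non-osteoporosis | 334 | 61.7 ± 10.2 | −1.6 ± 0.8 | 0.84 ± 0.12 |

T-score and BMD are drawn independently within a group (the clinical
reference standard uses the *lowest* femoral-neck T-score, which is not a
deterministic function of the total-hip BMD either). Consequence: index
correlations with BMD are driven by the BMD→tissue coupling and are very
strong, while correlations with T-score are mediated only by group structure
and come out moderate. `t_score_from_bmd` exposes the standard densitometric
map T = (BMD − ref_mean)/ref_sd with documented defaults ref_mean = 0.94,
ref_sd = 0.12 g/cm² (a plausible young-adult femoral-neck reference; the
densitometer's true reference population is not public).

### BMD → tissue coupling

Bone loss raises marrow fat and removes trabecular bone. The coupling
(`CouplingConfig`) maps BMD linearly over `bmd_range` = (0.40, 1.20) g/cm²:

* marrow-fat voxel probability: 0.55 → 0.05 (strictly decreasing),
* trabecular-bone voxel probability: 0.05 → 0.50 (strictly increasing),
* red marrow takes the remainder.

Values outside the range are clipped. The profile stores the fat fraction
and the implied expected interior HU ("trabecular_hu_mean"); the renderer
recovers the bone fraction from those two numbers, so the profile alone
fully determines the interior mixture. The coupling *strength* is a modeling
choice — the study only established that the correlations exist, not their
functional form — so the simulated effect sizes (AUC ≈ 0.97–0.99) sit
somewhat above the clinical ones (0.94–0.96) and no test asserts equality.

### Rendering

The left proximal femur is a union of analytic solids on a
0.67 × 0.67 × 1 mm grid (default 128³): spherical head (17 mm), capsule neck
(radius 10.5 mm, length 24 mm) at a 130° neck-shaft angle, cylindrical
shaft (11 mm), and ellipsoidal greater/lesser-trochanter bosses. A
per-subject isotropic anatomy scale (SD 4%, clipped at ±3 SD) varies femur
size across the cohort the way real anatomy does — without it, region sizes
would be degenerate across subjects and reliability coefficients for
area/volume undefined. All landmark positions (head center, neck center and
axis, inferior lesser-trochanter slice) are known in closed form and are
emitted as a ground-truth channel together with the exact femur mask and
per-voxel composition labels.

The cortical shell is the set of femur voxels within the cortical thickness
(1.5 mm, never less than the largest voxel dimension, which guarantees the
shell seals the interior against 6-connected hole filling). Interior voxels
are labeled by thresholding one uniform field per subject: fat if
u < q_fat, trabecular if u ≥ 1 − q_bone, red marrow otherwise. Using one
field with two moving thresholds makes every HUHA fraction analytically
predictable *and* strictly monotone in BMD for a fixed seed. Tissue HU
constants: fat −80, red marrow +40, trabecular 400, cortex 1200, soft
tissue 30; additive Gaussian noise (default SD 10 HU) is applied last.
With noise off, the measured HUHA fractions equal the planted label
fractions exactly.

What the phantom does *not* emulate: CT physics (beam hardening, scatter,
iterative-reconstruction texture, partial-volume blur at the cortex),
adjacent bones (no acetabulum, so segmentation leakage across the hip joint
is untested), cortical thinning with age, and any nonlinearity of the
BMD–composition relation. Passing tests therefore demonstrate correctness of
the measurement and statistics machinery under the generative model, not
clinical performance.

## Segmentation (3D_Femur VOI)

`region_grow` is a deterministic flood fill over the HU band [126, 3071]
(26-connectivity by default) — the interactive tool's outcome reproduced
deterministically; the band's lower edge is the HUHA bone edge. It captures
cortex and trabecular lattice; `fill_interior` then adds the enclosed marrow
(3D hole filling, optional morphological closing for perforated shells,
always a superset of its input and idempotent). `detect_cut_plane` automates
the "horizontal line below the lesser trochanter": scanning slices from
inferior, it returns the first slice whose medial reach exceeds the shaft
baseline (median of the most inferior occupied slices) by a 2 mm prominence;
an explicit override reproduces manual placement. `crop_to_voi` drops
everything inferior to that slice (the slice itself is kept — a literal
reading of the cut line).

## Neck frame and true-coronal reformation

The study's software reconstructed a "true coronal" plane under 3D
central-point guidance; the algorithm is proprietary, so the package defines
the operationalization:

1. **Head center** — argmax of the interior Euclidean distance transform
   (center of the maximal inscribed sphere). With multiple components the
   one with the largest inscribed sphere wins (warning emitted).
2. **Neck axis / central point** — initial direction from the head center
   toward the centroid of the peri-capital shell (mask voxels between 1.35
   and 2.6 head radii); then, iteratively (3 rounds): sliding 3 mm windows
   along the axis locate the waist (minimal cross-section count), the
   centroids of all near-minimal windows (≤ 1.35× the minimum) are fitted
   with a principal-component line, and that line becomes the new axis. For
   a tubular neck every planar slab centroid lies exactly on the axis, which
   is what makes the fit robust to window placement; the plain argmin of a
   slab histogram proved unstable to sub-voxel mask changes. The neck center
   is the mid-segment centroid of the near-minimal run.
3. **True-coronal plane** — contains the neck axis; its normal is the
   anteroposterior direction orthogonalized against the axis. HU are sampled
   by trilinear interpolation (monotone — no overshoot across the 0/126 HU
   band edges), masks by nearest neighbor; out-of-volume samples are marked
   invalid and excluded downstream. Default extent 80 × 80 mm at 0.67 mm
   pixels.

On 50 seeded phantoms with varying anatomy the recovered axis is within
5° (observed ≤ 2.3°), the neck center within 3 mm (≤ 0.8 mm) and the cut
plane within 2 slices (0) of ground truth.

## 2D ROI

`largest_inscribed_circle` grows the circle around the neck's central point
until it touches the nearest non-femur (or invalid) pixel center, so the
outer cortex lies *inside* the ROI — this raises HUHA_Bone relative to a
marrow-only ROI and is intentional. Pixels belong to the ROI if their
centers lie strictly within the radius.

## Diagnostic statistics

* **T-score classes** — osteoporosis T ≤ −2.5 (inclusive), normal T ≥ −1.0
  (inclusive), osteopenia between; binary screening label at −2.5.
* **AUC** — pairwise Mann–Whitney probability (ties ½), identical to the
  trapezoidal area under the empirical ROC curve; 95% CI from the DeLong
  structural-component variance, truncated to [0, 1].
* **Youden cutoff** — maximizes J = sens + spec − 1 over *observed* score
  values, so reported cutoffs are data values. Indexes low in disease
  (mean-HU, HUHA_Bone) use "positive if ≤ cutoff"; HUHA_Fat uses
  "positive if > cutoff". J-ties break toward higher sensitivity, then the
  smaller cutoff magnitude.
* **Predictive values** — from the integer confusion matrix; when
  reconstructing from printed rates, tp = round(sens·n_pos/100) with
  half-away-from-zero rounding (and analogously tn).
* **DeLong test** — correlated-AUC z-test from placement-value covariances;
  a zero-variance difference (e.g. an index against its own monotone
  transform) returns p = 1 with a degeneracy flag.
* **Spearman ρ** — mid-rank Pearson correlation; CI by Fisher z with the
  variance-inflated standard error √((1 + ρ²/2)/(n − 3)) (the study reports
  CIs without naming a method; this is a documented choice). Magnitude bins:
  negligible < 0.20 ≤ weak < 0.40 ≤ moderate < 0.60 ≤ strong < 0.80 ≤ very
  strong.
* **ICC(A,1)** — single-measure absolute agreement from the two-way ANOVA
  decomposition, (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)); CI by the
  McGraw–Wong F construction. When the error mean square vanishes (ICC ≈ 1)
  the F-quantile construction degenerates and the interval collapses to the
  point estimate. Bins: poor < 0.50, moderate 0.50–0.75, good 0.76–0.90,
  excellent > 0.90 (the conventional reading of the bins; the clinical
  source contains an obvious typo at the excellent edge).
* **Group differences** — two-sided Mann–Whitney by default (the source does
  not name its test), Welch t optional.
* **Box-plot summaries** — five-number summaries with linear-interpolation
  quartiles.

## Pipeline and the observer model

`run_pipeline` drives simulate → segment → reformat → measure → report for a
whole cohort; all randomness flows from one root seed through per-subject
spawned streams, so a config + seed reproduces the report byte-for-byte
(`DiagnosticReport.sha256`). The region-growing seed point is the global HU
maximum (always cortical bone) — deterministic and truth-channel-free.

`run_reliability` re-measures each subject under two simulated observers.
The jittered quantities are exactly the interactive steps: the region-grow
seed point (±2 voxels uniform, snapped back into the HU band), the cut-plane
slice (Gaussian, SD 1 slice), and the ROI center in 3D (Gaussian, SD 2 mm;
the out-of-plane component moves the reformation plane, the in-plane
components move the circle). Magnitudes are configuration, not measured
values — the study does not quantify its observers' variability. Under this
model the volumetric measurement is almost insensitive to the jitter (ICC ≥
0.99) while the 2D ROI inherits plane- and center-placement variance (ICC
≈ 0.18–0.96, area lowest), reproducing the qualitative 3D > 2D reliability
ordering.

## Problem sizes and runtime choices

Default problem sizes were chosen so the whole analysis runs comfortably on
one CPU: 128³ voxel phantoms (≈ 0.9 s per subject through the full chain),
430-subject cohort for the diagnostics (≈ 3.5 min), 50 subjects × 2
observers for reliability (≈ 1 min). `PhantomSpec.scaled()` provides
proportionally reduced phantoms used in unit tests where full resolution is
not the point.

## Known limitations

* The phantom's cortical compartment is a uniform 1200 HU shell; cortical
  and trabecular bone are deliberately not analyzed separately (out of the
  analysis's scope).
* Simulated HU scales differ from clinical femora (e.g. the 3D mean-HU
  Youden cutoff lands near 330 HU rather than 231 HU): absolute cutoffs are
  phantom-specific and only the sign structure and orderings are
  transportable.
* `estimate_neck_frame` assumes a single femur mask with a head and some
  distal structure; it is not a general-purpose landmark detector for
  arbitrary clinical segmentations.
* DICOM support is read-only, single-frame CT series with uniform geometry;
  NIfTI is the native fixture format.
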