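# Methods

`planrbe` evaluates radiotherapy dose distributions radiobiologically: it
converts voxel doses to isoeffective doses, maps them to tumour control and
normal-tissue complication probabilities, combines those into the
complication-free tumour control statistic P+, and compares competing plans
with paired exact statistics.  Because no patient dataset ships with the
package, a seeded phantom generator produces cohorts whose geometric and
dosimetric statistics emulate a focal dose-escalation planning study of the
prostate (60 Gy whole gland with a 70 Gy simultaneous integrated boost in
20 fractions, with and without urethral sparing).

## Dose-response models

**Isoeffect conversion.** All models work on isoeffective doses computed
voxelwise from the linear-quadratic model,

    EQDx = D * (1 + d / (α/β)) / (1 + x / (α/β)),   d = D / N,

where `D` is the voxel's total dose over `N` fractions and `x` the
reference fraction size.  The tumour model uses `x = 0` (the biologically
effective dose limit), the normal-tissue models use `x = 2` (EQD2) with the
organ's own α/β.

**Tumour control (Poisson-LQ).** With clonogen density ρ_cl (cells/cm³)
and voxel volume v (cm³),

    TCP = exp( − ρ_cl · Σ_i v · exp(−α · EQD0_i) ),

accumulated in the log domain so that extreme doses cannot overflow.
Defaults: ρ_cl = 2.8·10⁸ cells/cm³, α/β = 1.6 Gy, α = 0.12050 Gy⁻¹.  The
α values of the three shipped parameter sets (α/β = 1.2, 1.6, 2.7 →
α = 0.10099, 0.12050, 0.15740) correspond to refitting α per α/β so that a
conventional uniform 60 Gy in 3 Gy fractions reaches 70 % control;
`calibrate_alpha` reproduces this fit either on the cohort-mean TCP or per
volume (both aggregations are offered because the anchoring rule is
ambiguous; the cohort mean is the default).

**Urethra (LKB).** NTCP = Φ((gEUD − D50)/(m·D50)) with
gEUD = (Σ Δv_i · D_i^{1/n})^n computed on EQD2 doses (α/β = 5 Gy) in the
log domain.  Defaults D50 = 116.7 Gy, m = 0.23, n = 0.3 (urethral
stricture).  Φ is evaluated through the error function, not a table.
The `(D50, m)` uncertainty scan evaluates the probit on an inclusive
Cartesian grid built from integer multiples of the step to avoid
floating-point drift; a 28 × 13 grid (1 Gy and 0.01 steps) gives the
364-combination scan the analysis scripts run.

**Bladder and rectum (relative seriality).** The Källman Poisson form

    P(D) = 2^(−exp(e·γ·(1 − D/D50))),
    NTCP = [ 1 − Π_i (1 − P(D_i)^s)^{Δv_i} ]^{1/s},

on EQD2 doses (α/β = 3 Gy).  Bladder: D50 = 80 Gy (EQD2), γ = 2.59,
s = 1.3; rectum: D50 = 80 Gy, γ = 1.79, s = 0.75.  The voxel response
`P(D)` is isolated in one function so a different response shape can be
substituted without touching the volume-combination rule.  The product is
a sum of logs with the `P^s → 1` limit clipped, so probabilities stay in
[0, 1] for arbitrary doses.

**Composite outcome.** P_I = 1 − Π_j w_j (1 − NTCP_j) with unit weights by
default; the weighted form is implemented literally (weights inside the
product), which makes P_I > 0 at zero NTCP when w < 1 — non-unit weights
therefore trigger a warning.  P+ = TCP · (1 − P_I) assumes independent
tumour and organ response; the general joint-response form is not
modelled because no joint distribution is available.

## Motion

Intrafractional prostate motion is simulated by convolving the dose matrix
with an anisotropic Gaussian (default σ = 0.92 / 1.59 / 1.54 mm in
left-right / anterior-posterior / cranio-caudal, a published population
estimate) while the structures stay fixed: the convolution is the
expectation of dose-to-structure under random rigid displacements.  The
kernel is truncated at 4σ and renormalized; the grid edge is
replicate-padded so a constant field is invariant and no dose is lost at
the patient surface.  An explicit sampling mode (one rigid displacement
per fraction, averaged) exists for studies of the per-fraction variance;
convolution is the default and the two agree in expectation.

## DVH metrics and geometry

DX% is computed by exact order statistics (the largest dose received by at
least X % of the structure's voxels), not by interpolating a binned DVH;
the binned cumulative DVH exists for plotting only.  Planning systems
interpolate, so the last decimal of a DX% may differ from a TPS readout.
Structure overlap uses voxel counting (Dice, intersection volume, directed
coverage); minimum distances are Euclidean distances between voxel
centres (computed via an exact distance transform, anisotropic spacing
respected), which biases distances by up to half a voxel relative to
surface distances — accepted for determinism at the 1.5 mm grid scale.
Per-slice distances fix the slice axis to cranio-caudal (axial slices).

Masks are binary occupancy at voxel centres on the dose grid; no
partial-volume weighting (volume = count × voxel volume).  Contour
rasterization uses the even-odd rule on voxel centres with boundary points
counting as inside; multiple contours on a slice combine by XOR so holes
subtract.  Margin expansion is morphological dilation with a Euclidean
ball measured in millimetres.  DICOM RT Dose / RT Structure Set support
covers one common dialect (axis-aligned HFS grids, uniform frame offsets,
grid scaling); oblique orientations are rejected rather than silently
resampled.  The internal case bundle (`case.json` + compressed arrays) is
the primary interchange format and round-trips losslessly.

## Statistics

Plan comparisons use the two-sided exact Wilcoxon matched-pairs
signed-rank test: midranks for tied absolute differences, zero differences
dropped (the Pratt variant is available by flag), and the exact null
distribution of the positive-rank sum built by the subset-sum recursion —
identical to enumerating all 2^m sign assignments, feasible up to m = 25.
p = min(1, 2·min(lower tail, upper tail)).  No multiple-testing
correction is applied; the analysis is exploratory and raw p-values are
reported.

## The phantom generator

The generator is the package's stand-in for patient data and defines the
conditions every end-to-end test runs under.  One case consists of:

- a prostate ellipsoid (≈ 40 cm³) with a straight 3 mm-radius urethra tube
  and its 2 mm isotropic expansion (PRV);
- an imaging-defined tumour, GTV-Union, of one or two ellipsoids clipped
  to the prostate (two by default — the dominant lesion abutting the
  urethra and a smaller contralateral one — so the boost volume and the
  urethral wrap resemble multi-lesion plans);
- a ground-truth tumour, GTV-Histo, excluded from the urethra lumen and
  placed by bisection along a fixed direction so its coverage by GTV-Union
  hits a per-case target (default 0.79, drawn per case from a clipped
  normal); its overlap with the PRV is bounded at 1 % of its volume by
  pushing it outward, matching the near-zero tumour/PRV intersections such
  studies report;
- boost volumes PTV3_1 = GTV-Union + 2 mm, PTV3_2 = PTV3_1 − urethra,
  PTV3_3 = PTV3_1 − PRV, plus PTV2 = prostate + 5 mm, bladder and rectum.

Dose painting is analytic — the pipeline evaluates dose distributions, it
does not run an optimizer.  The base 60 Gy plateau is a blurred indicator
of the margin-expanded prostate (penumbra 2.5 mm); the 70 Gy boost adds a
blurred plateau over the plan's boost volume (penumbra 2 mm) plus a broad
low-amplitude spill halo (60 % amplitude, 8 mm reach) emulating the dose
bath a simultaneous integrated boost leaves in the gland.  Spatially
correlated noise (sd 0.4 Gy, 8 mm correlation length, independent per
case and plan) emulates plan-to-plan optimizer variability; its scale was
chosen to match the few-tenths-of-a-Gy spread published per-plan target
D50% values show, and it is what makes tiny TCP differences between plans
mix in sign rather than being systematically ordered.

Urethral sparing (plans 2 and 3) is modelled as clipping the dose against
a spatial maximum-dose field: 98 % of the 62.4 Gy D2% constraint at the
spared structure's surface (the 2 % headroom is the planning margin an
optimizer leaves), descending at 1 Gy/mm into the structure (floored at
59 Gy) and rising at 3 Gy/mm outside it.  The outward slope reproduces the
steep gradient IMRT achieves when the boost target excludes only the
spared structure; the inward descent is what keeps the spared D2% under
the constraint even after motion blurring partially refills the dose
valley.  Plan 2 spares the urethra only, plan 3 the PRV.

Per-case jitter (seeded): a global tumour volume factor uniform within
±30 %, ±10 % per-axis semi-axis jitter, ±2 mm lesion displacement, and the
coverage draw.  Across 50 seeded cases the median GTV-Histo volume falls
inside the reported patient interquartile range (1.8–6.9 cm³).

**What the phantom does not emulate:** realistic beam/fluence physics,
inter-patient anatomical diversity beyond ellipsoidal jitter, seminal
vesicles and femoral heads, deformable or interfractional motion, imaging
noise, and histology co-registration error.  Passing end-to-end tests
therefore demonstrates that the evaluation pipeline reproduces the
*direction and rough magnitude* of urethra-sparing effects under
controlled conditions — not that it predicts clinical outcomes.

## Numerical choices

- Probabilities are accumulated in log space; comparisons in tests use
  1e−9 absolute tolerance (1e−10 relative for the TCP closed form).
- α calibration brackets adaptively and solves to 1e−8 in α.
- Scan grids use inclusive endpoints generated as integer multiples of the
  step.
- Median/IQR use the midpoint convention for even counts.
- Rasterization treats boundary points as inside (tiny positive path
  radius); degenerate contours (< 3 points) warn and contribute nothing.
- The exact Wilcoxon doubles midranks to integers so the subset-sum
  distribution is exact in floating point.

## Problem sizes

Default grids are 64 × 68 × 56 voxels at 1.5 mm (≈ 244k voxels), chosen to
hold the full anatomy at the published calculation grid size while keeping
a 10-case × 3-plan × 2-motion-state evaluation around ten seconds on one
core.  The end-to-end cohort checks run at seed 1; the directional
conclusions were verified to be stable across several other seeds.

## Known limitations

- The relative-seriality voxel response is the standard Källman form; the
  original parameter sources do not print their exact variant, so the
  response function is deliberately swappable.
- LKB operates on EQD2-corrected doses; whether the source parameter fit
  used physical or EQD2 doses is not documented, so the conversion is
  configurable via the α/β parameter.
- Distances are centre-to-centre, not surface-to-surface (half-voxel
  bias).
- The DICOM readers cover one dialect and are best-effort; the internal
  bundle format is the tested interchange surface.
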