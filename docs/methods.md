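# Methods

This note records the models implemented in `arcdose`, the assumptions they
make, and the numerical and design choices a maintainer would want stated.

## Coordinates, units and containers

All geometry lives in patient-style millimetre coordinates; arrays are
indexed (z, y, x) with voxel values at voxel centres. Doses are stored in Gy
(organ doses are *reported* in cGy, matching clinical convention), distances
in mm, volumes in cm³. DICOM RT Dose files are read with the grid scaling
applied; frames stored with descending z are re-sorted ascending and the
flip recorded. Intermediate artifacts use a portable format — a raw
little-endian array plus a JSON sidecar with shape, spacing, origin and
provenance — so downstream modules never touch DICOM.

## Target shape statistics

Sphericity compares the surface area of the volume-equivalent sphere with
the actual surface area, Ψ = π¹ᐟ³(6V)²ᐟ³/A ∈ (0, 1], with 1 for a perfect
sphere. Because treatment planning systems report volumes but not areas, a
shell surrogate uses only the CTV and PTV volumes and the isotropic margin d
that produced the PTV: the shell is treated as a layer of thickness d, so
Ã = (V_PTV − V_CTV)/d and Ṽ = (V_CTV + V_PTV)/2 give
Ψ̃ = π¹ᐟ³ d (3(V_CTV + V_PTV))²ᐟ³ / (V_PTV − V_CTV). For concentric spheres
the layer approximation underestimates the mid-shell area, so Ψ̃ can exceed
1 (≈ 1.020 for r = 20 mm, d = 5 mm); it converges to the mid-shell
sphericity as d → 0. Ψ̃ is most comparable across targets built with the
same margin; when the margin was anisotropic a scalar d must be chosen.

**Surface area from masks.** The binary mask is smoothed with a one-voxel
Gaussian and triangulated at the 0.5 level (marching cubes). Face counting
overestimates a sphere's area by a constant factor, and triangulating the
*raw* binary field leaves a staircase surface whose area error (~9% for a
digitized sphere) does not shrink with refinement; the smoothed level set
converges (measured Ψ error for an r = 20 mm sphere: 2.1% at 2 mm spacing,
0.3% at 1 mm, 0.1% at 0.5 mm). Volume is always the voxel count times the
voxel volume. A consequence of smoothing is that Ψ of coarse digitized
spheres can marginally exceed 1.

**Margin expansion** is a Euclidean dilation through a distance transform:
a voxel joins the output iff its centre lies within the (possibly
anisotropic, per-axis normalised) margin of the input set. Voxel-centre
semantics carry a half-voxel inward bias: an r = 20 mm digitized sphere
expanded by 5 mm at 1 mm spacing is ~2.4% below the analytic r = 25 mm
volume, ~1% at 0.5 mm. **Rasterization** includes a voxel iff its centre is
inside any contour polygon of the nearest slice (even-odd rule), with no
partial-volume weighting. **Minimum distances** are exact Euclidean
centre-to-centre distances via a distance transform; a per-slice 2D variant
(never smaller than the 3D distance) reproduces slice-scanning scripts.

## DVH and plan metrics

The cumulative DVH is fraction(t) = volume receiving ≥ t over structure
volume, evaluated exactly (sorted-sample counting) at uniform bin edges,
default width 0.01 Gy. D2/D98 invert the curve by linear interpolation
between edges; Vx interpolates the curve at x; D1cc is the hottest-volume
dose (the k-th hottest voxel with k = ⌈vol/voxel volume⌉) rather than an
interpolated absolute-volume lookup — the two conventions differ by at most
one voxel layer. DHD uses the sample SD (n−1). CN counts the
reference-isodose volume inside the external contour when one is supplied,
otherwise over the whole grid, and is 0 by convention when nothing reaches
the reference isodose (95% of the prescription by default). Planning
restrictions are strict inequalities — a metric exactly on the limit fails —
and the cord limit uses D1cc as the maximum-dose surrogate. The lung is one
combined structure with the target *not* excluded, so PTV overlap counts in
lung metrics. Monitor units are a recorded plan attribute, never computed.

## Gamma analysis

γ(r) = min over r′ of √(δ²(r,r′)/ΔD² + |r′−r|²/Δd²), evaluated for every
reference point at or above the low-dose threshold (default 10% of the
normalisation dose). The normalisation dose is the global maximum of the
reference distribution (the measurement, by convention); "local" mode scales
ΔD by each point's own dose. Points below threshold are excluded from both
the numerator and denominator of the pass fraction, and γ = 1 exactly counts
as failing γ < 1. The evaluation distribution is interpolated bi/trilinearly.

The production search walks a displacement lattice (step Δd/10, cap 3Δd) in
order of increasing displacement, pruning once the distance term alone
exceeds the worst current per-point minimum, then refines each point on a
fine local lattice (step/12 within ± one coarse step) around its best
displacement. The test oracle is a plain exhaustive lattice minimisation
with no pruning or refinement at step Δd/60 (2D grids pre-sample the
evaluation once on a fine lattice anchored to the reference grid, reducing
the search to strided slicing). The two agree to ≤ 5×10⁻³ in γ on smooth
fields; the residual is dominated by the oracle's own lattice resolution.
Search cap, steps and threshold handling are package choices — dose-
comparison practice varies and no single convention is canonical.

## Per-medium error decomposition

The relative difference 100·(D_eval − D_ref)/D_ref is computed pointwise,
masking points where the reference is below 5% of its maximum (the floor
prevents blow-up where film dose ≈ 0; configurable). Per plan and medium the
mean and sample SD are taken; across a cohort, M = mean of per-plan means,
Σ = SD (n−1) of per-plan means, and the random error σ = RMS of within-plan
SDs. The RMS definition is isolated in one function so a pooled-SD variant
can be swapped in. Signed values are reported throughout; prose summaries
may quote magnitudes. A one-sample Wilcoxon signed-rank test (p = 1 by
convention on all-zero input) checks symmetry of the per-plan means about
zero.

## Cohort statistics

Paired comparisons apply a Shapiro–Wilk gate at α = 0.05 to the differences:
normal-looking differences get a two-tailed paired t-test with a t-based CI;
the rest get a Wilcoxon signed-rank test (zero differences dropped, average
ranks for ties) with a Hodges–Lehmann pseudo-median and its order-statistic
CI from the normal approximation to the signed-rank distribution. Note the
gate itself has a 5% false-alarm rate on genuinely normal differences — by
design. Raw p-values are reported with no multiple-testing correction,
matching common practice in small dosimetric cohorts. Rank correlations are
Spearman with two-sided p. Best-variant ranking counts strict winners per
patient, splits ties equally among tied variants (flagged), and excludes
patients with missing cells.

## Synthetic data generator

The generator emulates a film-dosimetry thorax study, not patient data:

* **Phantom** — elliptical body (300 × 200 mm half-axes 150/100 mm), two
  lung ellipsoids, a spine insert with a cord channel, an oesophageal tube;
  default grid 4 mm isotropic, 240 × 240 × 320 mm. Media partition the body
  exactly; lungs overlapping bone is a spec error.
* **Targets** — a main sphere plus 0–3 attached lobes (0.55× radius at 0.9×
  offset, seeded directions); more lobes strictly lower the mask-derived Ψ.
  The PTV is the CTV dilated by an isotropic margin (5–10 mm sampled per
  patient); PTVs escaping the body are clipped to it with a warning.
* **Dose engine** — primary-photon exponential attenuation (water
  0.005 mm⁻¹ scaled by relative attenuation lung 0.25 / soft tissue 1.0 /
  bone 1.6) along rotated beam axes, inside an aperture shaped to the
  beam's-eye-view PTV projection expanded by the field margins (8 mm
  cranio-caudal / 5 mm transversal for static fields, 5 mm isotropic for the
  arc), with an analytic Gaussian penumbra (CDF of the signed distance to
  the field edge, σ = 4 mm). Static plans use 3–5 fields (frequencies
  25:9:1); the arc runs 182° clockwise to 178° sampled every 4° (89 control
  points). Doses are normalised to PTV median = prescription. There is no
  scatter, no buildup, no MU physics — the analysis, not the physics, is the
  product. The engine nevertheless reproduces the qualitative trade-off the
  statistics must detect: the arc conforms better (higher CN) while bathing
  more lung in low dose (higher V5Gy).
* **Collimator variants** — the engine cannot model collimator rotation, so
  the 0°/30°/45°/90° variant axis is an explicit synthetic perturbation
  (extra dose blur of 0 / 1.2 / 1.8 / 3.0 mm plus an MU offset) whose only
  purpose is to exercise the ranking and Table-shaped reports. Blurs below
  ~1 mm would vanish at the 4 mm cohort grid.
* **Film emulation** — an axial plane is extracted (e.g. 26 mm caudal to
  the isocentre), per-medium multiplicative offsets, Gaussian noise (% of
  the plane maximum) and a rigid sub-pixel shift are applied. With all three
  at zero the plane is returned bit-identically.
* **Cohorts** — per patient, PTV volumes are sampled log-uniformly within
  145.2–2686.5 cm³ (the clinical range the study design targets), total
  prescriptions from the modelled fractionation table (36 Gy in 12 the
  mode), and MU proxies at ~105 MU per Gy of fraction dose with the arc
  ~50 MU lower. Everything is deterministic under the master seed.
* **Lightweight statistical generators** — `simulate_diff_cohort` builds
  difference-plane cohorts with known M/Σ/σ structure for recovery studies;
  `simulate_metric_cohort` builds paired samples with Gaussian or
  lognormal-skewed differences for the gate tests.

What passing tests show — and what they do not: the pipeline recovers
effects *it injected itself* under the generator's idealisations (rigid
geometry, no breathing, primary-only dose, label-perfect media). Agreement
here demonstrates the correctness of the analysis chain, not the clinical
accuracy of any dose algorithm or the behaviour of real film.

## Problem sizes and numerical conventions

Cohort grids default to 4 mm spacing with 10 patients — the size at which a
full cohort builds in well under a minute — while geometry convergence
studies use 0.5–2 mm grids and gamma oracle comparisons use 32² planes at
2 mm. Degenerate inputs have explicit conventions: empty masks raise;
all-zero paired differences yield a flagged degenerate result (p = 1,
estimate 0); a reference distribution with no point above the gamma
threshold raises; V_RI = 0 gives CN = 0 with a log message. Random numbers
come from numpy Generators seeded at every level; replicate seeds are
spawned from a single SeedSequence rather than consecutive integers.

## Known limitations

* The beam engine is primary-only; absolute organ doses are plausible in
  shape but not calibrated, so constraint pass rates on synthetic cohorts
  describe the generator, not a clinic.
* Ψ from coarse masks can slightly exceed 1 (smoothing bias); Ψ̃ inflates
  when the PTV is clipped at the body surface (thinner shell).
* The Hodges–Lehmann CI uses the normal approximation to the signed-rank
  distribution; exact small-sample intervals are not implemented.
* 3D gamma works but is quadratic in the displacement-lattice size; the
  dense 2D oracle path does not extend to 3D.
* No 4D (breathing) geometry, no film calibration chain, no RT Plan
  (beam/MLC sequence) parsing.
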