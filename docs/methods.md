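# Methods

This note documents the models, numerical conventions and design choices
behind `asymbone`, and what the synthetic data do and do not establish.

## Study design emulated by the generator

The pipeline targets a paired-limb loading experiment: nine individuals,
six of which received repeated unilateral stimulation of the **left**
hind limb, three unstimulated controls — 18 limbs in total. The grouping
variable ("stimulation") is coded at the **limb** level by default
(stimulated limb = 1; both limbs of controls and the right limbs of
stimulated animals = 0); an animal-level coding is available
(`RunConfig(coding="animal")`) because group-wise colouring of whole
animals is also common in this literature.

## Synthetic bone model

Each limb is a tubular diaphysis represented as a stack of paired
periosteal/endosteal contours. Contours are sums of low-order Fourier
harmonics in polar form about a level-specific centre:

* periosteal radius r_p(p, θ) = R₀(p)·(1 + a₂cos 2(θ − φ(p)) + a₃cos 3θ),
  with R₀(p) flaring at both ends (more proximally — this is how the
  proximal end is identified during alignment), a slow axial twist φ(p)
  and a gentle sagittal curvature of the centreline;
* endosteal radius r_e = R₀·c(p)·(1 + 0.8·a₂cos 2(θ − φ)), with the
  cortex thickest near midshaft and the endosteal centre slightly offset.

Harmonic amplitudes are kept small (a₂ = 0.12, a₃ = 0.05) so every section
is star-shaped about the periosteal area centroid and equiangular ray
sampling is single-valued; this is validated (strict endosteal enclosure,
counter-clockwise orientation) and violations are hard errors.

Defaults: length 40 mm, midshaft periosteal radius 1.4 mm, endosteal
fraction ≈ 0.5–0.62 — the scale and proportions of a small-rodent tibia.

### Sources of variation, and why they are split this way

* `individual_sd` (default 0.05): a per-individual **isometric size**
  factor (lognormal), shared by both limbs. Being purely isometric it is
  removed exactly downstream — by Procrustes unit-size scaling, by
  length-power CSG standardisation, and by the dimensionless thickness
  ratio. Consequently, at zero effect the 18 limbs are *exchangeable* in
  every analysis space: limb pairs differ only by noise, and the
  free-permutation null used for inference holds exactly. Any
  individual-level *shape* component shared by a pair would instead
  cluster antimeres and make the free-permutation test conservative; the
  generator deliberately excludes it so that type-I-error calibration is a
  property of the test, not an accident of the noise model.
* `noise_sd` (default 0.01, as a fraction of the local radius): per-limb
  variation with two components — a smooth low-order harmonic field
  (biological fluctuating asymmetry and positioning error; amplitude
  `noise_sd`) and independent per-vertex radial noise (measurement error;
  s.d. `0.5·noise_sd·mean radius`), both applied multiplicatively to both
  contours so enclosure is preserved.

### The asymmetry field

The stimulated-limb effect is a smooth raised-cosine bump in an axial ×
angular window, applied before mirroring (side is encoded by reflecting
x): the periosteal radius is expanded by `δ·periosteal_gain·bump` and the
endosteal radius displaced inward by `δ·endosteal_shift·bump` (cortical
thickening). Defaults: axial window 10–40 % of biomechanical length
**measured from the distal end**, angular window 180–270° (the
medial-posterior quadrant), gains 0.10 / 0.15 at δ = 1 — a distal
periosteal expansion with medial-posterior thickening of order 10–15 %,
the qualitative pattern this class of loading experiment produces. The
window covers the 20 % (distal) CSG level and excludes the 50 % midshaft,
so distal analyses respond to δ while midshaft analyses stay null. δ is a
free simulation parameter (default 1.0), not an estimate of any real
experiment's geometric effect size.

Synthetic entheseal areas (`generate_entheseal_areas`) are a labelled
stand-in for externally measured 3D muscle-attachment surfaces: three
structures, of which the two "stimulated-muscle" sites are inflated by
15 % / 20 % · δ on the stimulated limb; areas scale with the individual
size factor squared and carry 5 % lognormal measurement noise. Because
areas are analysed *unadjusted* for size (the convention for this class of
entheseal analysis), the shared size factor clusters antimeres and makes
this the noisiest channel at n = 9 animals; its R² varies considerably
across seeds while the percent-asymmetry contrast (stimulated ≈ 11 % vs
control ≈ 1 %) remains stable.

## Sectioning and alignment

Percent length runs **0 % = distal → 100 % = proximal** in all inputs and
outputs. The reference scheme extracts 28 sections — 12.5–25.0 % and
37.5–90 % at 2.5 % steps — excluding the 25–37.5 % band where the two
bones of the lower-leg complex are fused; levels are generated
endpoint-inclusive and validated against the excluded band (open
interval).

Meshes are aligned by the principal axes of the vertex scatter (z = long
axis); the proximal end is the one with the larger mean in-plane radius in
its terminal 10 % slab, and the in-plane sign is fixed by the third moment
of the x distribution — deterministic, and invariant to the input pose.
Contour stacks are generated aligned and only re-zeroed. Biomechanical
length L is the axial extent after alignment. Cross-sections of meshes
take the largest-area closed intersection curve as periosteal and the
largest curve strictly inside it as endosteal; disjoint curves (the second
bone outside the fused band) are discarded. All contours are resampled by
arc length to 1000 vertices, counter-clockwise.

Left limbs are mirrored across the sagittal plane to right-hand
orientation before any shape comparison, so antimeres superimpose without
reflections.

## Semilandmarks

k equiangular rays (24 for GM, 1000 for thickness maps; θ₀ on the section
frame's +x axis) leave the periosteal polygon's **area centroid**; each
ray's single periosteal and endosteal crossing is located by binary search
on the unwrapped vertex angles and intersected exactly. Non-star-shaped
sections raise an error naming the section and angle rather than silently
picking a crossing. Landmark order is section-major, ray-minor,
periosteal before endosteal — identical for every specimen, which is what
makes the scheme homologous by construction.

## GPA and PCA

GPA centres each configuration, scales it to unit centroid size (full
Procrustes; centroid sizes are stored separately), and iteratively rotates
each configuration onto the mean of the *others* — exact block ascent on
the joint Procrustes criterion; rotating onto the including-self mean
stalls measurably short of the optimum for small n. Rotations are proper
(no reflections; sides are pre-mirrored). After each sweep the whole
solution is re-oriented so the new mean sits on the old one (removing
global rotational drift), and convergence is declared when the mean-shape
change drops below 1e-10 (cap 100 iterations). On convergence the
solution is put in a canonical frame — the mean shape's principal axes
with a deterministic sign rule — so outputs are reproducible and invariant
to similarity transforms of the inputs.

Shape variables are the flattened aligned coordinates; tangent-space
projection is available (`pca(fit, tangent=True)`) but off by default —
at these Procrustes distances the difference is far below the
permutation-test resolution. PCA is an SVD of the column-centred matrix;
component signs are fixed by making each loading's largest-magnitude
element positive; constant input yields an explicit degenerate result
(NaN variance percentages) rather than a division by zero.

## Targeted GM

N-cores (default 15 = the focal semilandmark plus its 14 nearest
neighbours, Euclidean distance on the mean shape, ties broken by lower
index) are defined once on the GPA mean shape — deterministic and
label-free. Per core: subset GPA (with scaling, matching the global GPA),
then R² = trace(SS_between)/trace(SS_total) of the shape variables against
the binary label; geometrically degenerate cores contribute 0. Each
landmark's R̄² is the unweighted mean over all covering cores. The
threshold is the linear-interpolation empirical quantile at p = 0.75 with
≥ comparison, so a constant map selects everything and the full-set core
reduces the whole targeted pipeline exactly to the global GPA + PCA (a
tested identity). No smoothing beyond core averaging and no multiplicity
correction are applied to the map.

## Cross-sectional geometry

Areas, perimeters and second moments use the exact Green's-theorem polygon
formulas. Ring moments are periosteal minus endosteal integrals referred
to the **cortical-ring centroid** (the mechanical convention for bending
of the load-bearing ring, rather than the periosteal centroid); Imin/Imax
are the eigenvalues of the 2×2 area-moment tensor, J = Imin + Imax holds
identically (perpendicular-axis theorem), and the Imax axis angle is
exported but not analysed. Verification is dual-route: closed forms
(annulus, ellipse) and an independent pixel-integration oracle on random
star-shaped sections (0.5 % agreement on all eight parameters).

Standardisation divides each parameter by L^e with e per class — default
*isometric* (areas/L², perimeters/L, moments/L⁴), with a *mass-proxy*
alternative (L³, L^1.5, L^5.33) selectable; the exponents used travel in
the table metadata, since the literature is not unanimous. Region PCA uses
the correlation matrix because the eight parameters span mm¹–mm⁴.

## Cortical-thickness maps

Map entry (level, ray) = |periosteal − endosteal crossing| / |periosteal
crossing − centroid|: thickness normalised by the local periosteal radius,
hence dimensionless and scale-invariant. Maps are flattened row-major
(level, then angle) for PCA; PC-extreme variations are mean + score ×
loading reshaped to map form.

## Permutation inference

R² is the between-group fraction of the total sum of squares of the
selected PC scores (smallest prefix reaching 90 % cumulative variance,
boundary inclusive). Labels are permuted freely across limbs (default
B = 999; add-one p-value, never exactly zero; exhaustive enumeration of
all C(n, n₁) assignments available and used as the oracle in tests). The
pairing of antimeres within individuals is ignored by the permutation —
the convention of the analyses this pipeline reproduces — and the
resulting non-independence caveat for real paired data is recorded in
every result object. Within the synthetic model the null is exactly
exchangeable (see above), and the type-I error at δ = 0 is verified to sit
inside the binomial 95 % CI of the nominal 0.05 over 500 replicate
cohorts. Per-PC ANOVAs are reported without multiplicity correction. The
optional multivariate-normality diagnostic delegates to pingouin's
Henze-Zirkler test.

## Problem sizes used in the tests

The acceptance-style tests run the full pipeline logic at reduced
resolution chosen for quick, deterministic runs: cohorts of 18 limbs on
5–9 sections with 6–12 rays and 36-ray maps for replicate-heavy checks
(500-replicate null calibration, 20-replicate effect-size monotonicity),
and the full 28 × 24 × 2 scheme for the structural-count and end-to-end
checks. `scripts/acceptance.py` always runs the full reference scheme.

## Known limitations

* The synthetic bone is a smooth star-shaped tube: no trabecular
  structure, no entheseal surface relief, no fused-region geometry beyond
  its exclusion from sectioning, and no remodeling dynamics. Passing tests
  demonstrate the pipeline's correctness and statistical calibration, not
  the biological realism of any particular effect size.
* The anatomical axis conventions (which in-plane direction is "anterior")
  are internally consistent but may differ from any given laboratory
  protocol by an in-plane rotation; θ₀ is configurable.
* Free permutation of limb labels is anti-conservative in principle for
  real paired data with strong individual-level shape covariance; a
  mixed-model or restricted-permutation treatment is out of scope.
* Sliding-semilandmark relaxation and symmetric/asymmetric component
  decomposition are not implemented; equiangular points are treated as
  homologous as placed.
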