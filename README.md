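# asymbone

Detection of **bilateral asymmetry** in paired long bones — the skeletal
signature of lateralised mechanical loading — along the whole diaphysis.

Biological anthropologists and skeletal biologists infer habitual activity
(side preference, occupational loading) from left/right differences in long
bones. `asymbone` implements, as one tested pipeline, the four complementary
methods used for this inference, plus the permutation statistics that tie
them together:

1. **3D geometric morphometrics (GM)** — paired equiangular semilandmarks
   on periosteal and endosteal contours of cross-sections along the
   diaphysis (reference scheme: 28 sections × 24 rays × 2 surfaces = 1344
   semilandmarks), superimposed by generalized Procrustes analysis (GPA)
   and summarised by PCA.
2. **Targeted GM** — for every semilandmark, a local neighbourhood of 15
   semilandmarks (*N-core*) is superimposed on its own and the fraction of
   shape variance attributable to the grouping variable ("stimulation") is
   computed; per-landmark averages are thresholded at the third quartile to
   define a targeted subset, re-analysed by GPA + PCA.
3. **Cross-sectional geometry (CSG)** — the eight beam-theory parameters
   per section (TotA, MedA, CorA, TotP, MedP, Imin, Imax, J = Imin + Imax),
   standardised by biomechanical length and analysed by correlation-matrix
   PCA at distal (20 %), midshaft (50 %) and proximal (80 %) levels.
4. **Relative cortical-thickness maps** — sections × 1000 equiangular rays
   matrices of cortical thickness divided by the local periosteal radius,
   compared across specimens by PCA, with map variations reconstructed at
   PC extremes.

Downstream, measured 3D entheseal (muscle-attachment) surface areas are
analysed by correlation-matrix PCA and left/right percent asymmetry,
100·(L − R)/((L + R)/2).

Inference throughout is permutation-based: for PC scores **Y** (selected to
90 % cumulative variance) and binary group g,

> R² = trace(SS_model) / trace(SS_total),  p = (#{R²_perm ≥ R²_obs} + 1)/(B + 1)

with B label permutations (exhaustive enumeration available for small n).

A seeded **synthetic paired-limb generator** produces cohorts of tubular
diaphyses (star-shaped Fourier-harmonic contours) with a localised,
tunable stimulated-side effect — distal periosteal expansion plus
medial-posterior cortical thickening — so every stage of the pipeline runs
and is tested without any scan data.

## Worked example

```python
from asymbone import BilateralAsymmetryStudy, CohortParams

study = BilateralAsymmetryStudy.from_synthetic(CohortParams(seed=1))
results = study.fit()
print(results.summary())
```

```
Bilateral asymmetry analysis
================================================================
specimens: 18  (stimulated limbs: 6)
sections: 28   semilandmarks: 1344   CSG variables: 224
targeted threshold (Q75): 0.091  (336 semilandmarks selected)
----------------------------------------------------------------
     channel pc1_percent pc2_percent  n_pcs_90 r_squared p_value
          gm       53.99        7.56        10     0.587  0.0010
    targeted       83.41        3.79         3     0.917  0.0010
  csg_distal       94.41        3.41         1     0.987  0.0010
csg_midshaft       51.73       19.76         4     0.062  0.3990
csg_proximal       49.03       21.06         4     0.028  0.7520
    cortical       83.39        2.08         6     0.916  0.0010
   entheseal       85.59       12.41         2     0.315  0.0090
----------------------------------------------------------------
permutations: 999   coding: limb   seed: 0
```

The cohort is nine individuals (six with a stimulated left limb, three
controls), 18 limbs. Because the seeded effect is **distal**, the distal
CSG regression is strongly significant while midshaft and proximal levels
are null — analysing only the midshaft would miss the lateralisation
entirely. The targeted-GM channel concentrates the signal relative to the
global GM analysis (R² 0.92 vs 0.59), and the cortical-thickness maps
separate stimulated limbs as well. Each row reports the PC1/PC2 variance
percentages, the number of PCs needed to reach 90 % cumulative variance,
and the permutation R² / p-value for the stimulation label.

`results` also carries the full objects: `results.variance_map` (per-
semilandmark R̄² and the Q3-selected subset), `results.csg_table`,
`results.thickness_maps`, `results.asymmetry_table`, and plotting helpers
(`results.plot_scores("targeted")`, `results.plot_percent_asymmetry()`).

A command-line interface wraps the same pipeline:

```bash
asymbone generate -o cohort/ --seed 1      # synthetic cohort (CSV + JSON)
asymbone validate cohort/                  # pairing + geometry checks
asymbone run-all cohort/ -o out/           # all four channels -> summary.json
```

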