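# murimorph

Landmark-based geometric morphometrics of murine upper-first-molar (M1)
outlines, built for the question of how tooth shape diverges between
coexisting rodent lineages through time. The package implements the full
analysis chain used in studies of Miocene Siwalik murines: two clades
(*Karnimata*-like and *Progonomys*-like rats and mice) descend from one
basal population and drift apart in molar shape as their diets diverge,
and the analysis quantifies when and how fast that happens.

## What it computes

- **Superimposition.** Configurations of 16 outline points (7 fixed
  landmarks, 9 sliding semilandmarks) are scaled to unit centroid size
  (CS = √Σᵢ‖xᵢ − x̄‖²) and aligned by generalized Procrustes analysis.
  Semilandmarks slide along the tangent (neighbor chord) to minimize the
  thin-plate-spline bending energy of the deformation from the consensus —
  minimizing (y₀ + Ut − ȳ)ᵀ(E ⊗ I₂)(y₀ + Ut − ȳ) over slide amounts t,
  with E the bending-energy matrix of the consensus — then re-project onto
  the outline; a minimum-Procrustes-distance criterion (E = I) is also
  available, and the two can be compared by a PROTEST-style Procrustes
  correlation with permutation test.
- **Shape variables.** Partial-warp scores plus the linearized uniform
  component at α = 0, an isometric rotation of the tangent-space
  coordinates (2k − 4 = 28 variables for k = 16).
- **Morphospace.** PCA on the covariance matrix; Euclidean distances
  between species means and from the basal species on the PCs exceeding
  95% cumulative variance; BCa bootstrap confidence intervals (9999
  resamples by default) with the Cumming–Finch "rule of eye" for
  significance; 55% concentration ellipses on PC1/PC2 and
  intersection-over-union overlap proportions between coexisting species.
- **Association.** Two-block PLS (SVD of the between-block correlation
  matrix) between shape and an ecomorphological grazing index (VD index =
  tooth width / anterocone–protocone gap) or ln centroid size; the RV
  coefficient tr(S₁₂S₂₁)/√(tr S₁₁² · tr S₂₂²); permutation tests with
  p = (1 + exceedances)/(1 + n_perm); multivariate regression of shape on
  ln CS with Wilks' Λ and percent shape variance predicted.
- **Dental metrics.** ln(length × width) tooth size, VD index,
  anterostyle minor/major axis ratio, and the acute angles of the
  anterostyle axis and the protocone–enterostyle line against the
  longitudinal tooth axis (the chord through landmarks 8 and 16).
- **Synthetic data.** A two-clade generator (basal population, per-lineage
  divergence schedules with a lag/catch-up structure, allometry, an index
  coupled to shape at a target correlation) that provides ground truth for
  every statistic above.

## Worked example

```sh
murimorph run --seed 1 --out results/demo
```

runs the whole pipeline on the default two-clade scenario (325 synthetic
specimens across seven assemblage ages, 13.8–6.5 Ma) and prints

```
pipeline complete: 325 specimens, 17 PCs retained, PC1 27.2% of variance
```

`results/demo/` then holds the aligned landmarks (TPS), shape scores,
PCA table, divergence and overlap tables, association and regression
results, the dental-metrics table, figures, and a manifest. The overlap
table shows the two clades sharing ~55% of their PC1/PC2 ellipse area at
11.2 Ma, shrinking monotonically to 0% by 9.2 Ma; the distance-from-basal
table shows the *Progonomys*-like lineage stalling near the basal shape
until 8.2 Ma and catching up by 7.4 Ma — the delayed-divergence pattern.
The same pipeline consumes real data via `input_tps`/`input_csv` in a YAML
config, and `murimorph simulate` writes scenario data in exactly that
format.

Library use mirrors the CLI:

```python
from murimorph import PipelineConfig, run
result = run(PipelineConfig(seed=1, n_boot=999, n_perm=999))
print(result.association)         # PLS r, RV, permutation p per block
print(result.basal_distances)     # distances from the basal mean with CIs
```

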