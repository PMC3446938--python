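# Methods

## Model and procedure

The pipeline estimates, for each insect taxon, a directional association
with three broad land-use types — urban (artificial surfaces), agricultural,
and natural (forests/semi-natural areas lumped with wetlands) — from
presence records collected at point locations ("collections"). Water bodies
sit outside the typology.

1. **Buffer composition.** Around every collection the proportion
   *P*<sub>c,l</sub> of each type in a 1-km-radius disc is computed on a
   categorical raster. A cell belongs to the buffer when its *centre* is
   within the radius (no polygon clipping); the denominator is all buffer
   cells, excluded (water/nodata) cells included. With 100-m cells a 1-km
   disc holds ~314 cells, so the centre-in/centre-out approximation of the
   true area fraction is below 2%.
2. **Relative land-use index.** *M*<sub>c,l</sub> = *P*<sub>c,l</sub> minus
   the mean *P*<sub>r,l</sub> over all collections *r* within 100 km of
   *c*, the focal collection included (an `include_focal=False` variant
   exists for sensitivity analysis). Collections with fewer than 30
   regional neighbours (focal counted, threshold inclusive) are discarded:
   their regional baseline would be too noisy. This local centring is what
   removes the effect of spatially biased sampling effort: a taxon recorded
   mostly at collections that are *locally* more urban than their
   neighbourhood shows a positive urban index even if the whole scheme
   over-samples cities.
3. **Frequency classes.** A taxon is *infrequent* when present in strictly
   less than 2% of the collections made in each land-use type (type taken
   at the sampling point; retained collections only; collections on
   excluded cells count toward no type), *frequent* otherwise (≥ 2% in at
   least one type).
4. **Affinity and labels.** *A*<sub>t,l</sub> is the mean of
   *M*<sub>c,l</sub> over the taxon's occupied collections. A 95% BCa
   bootstrap interval (statistic = the mean; resampling unit = the occupied
   collection, since the affinity is a mean over collections) yields the
   label: entirely positive → specialist, entirely negative → avoider,
   overlapping zero (endpoints inclusive) → tolerant.
5. **Group tests.** One row per taxon-occurrence (taxon × collection)
   carries that collection's three *M* values. A type-III MANOVA (Pillai's
   trace) on `order * frequency_class` under sum-to-zero contrasts is
   followed by three univariate type-III ANOVAs, each reduced by backward
   elimination (interaction first; a main effect is removable only once the
   interaction is gone; a term at exactly p = α is kept; α = 0.05), and by
   Tukey HSD comparisons among orders on the fitted minimum model's
   residual variance, reported as a compact letter display.

## BCa details

With B bootstrap means θ*₁…θ*_B and point estimate θ̂:
z₀ = Φ⁻¹(#{θ*_b < θ̂}/B) (strict inequality; the proportion is clamped to
[1/(B+1), B/(B+1)] before the quantile), acceleration
a = Σd³ᵢ / (6 (Σd²ᵢ)^{3/2}) with dᵢ the deviations of the jackknife
leave-one-out means from their average (a = 0 when the deviations vanish),
adjusted tails α₁,₂ = Φ(z₀ + (z₀ + z_{α/2 or 1−α/2})/(1 − a(z₀ + …))), and
the interval is the pair of empirical quantiles (linear interpolation) of
the replicate means. Forcing z₀ = a = 0 reproduces the plain percentile
interval on the same replicate stream, which is how the implementation is
unit-checked; it is also cross-checked against an independent BCa
implementation on identical data. Degenerate inputs: a single value or a
zero-range sample give the zero-width interval (v, v) (the former with a
warning). Taxa occupying fewer than 3 collections are reported as tolerant
with an `unstable` flag rather than excluded — interval estimation is
meaningless there, and the substantive analysis concerns frequent taxa,
whose K is large.

Each taxon × land-use draws from its own RNG substream seeded by
(master seed, CRC32(taxon id), CRC32(land-use name)), so results are
invariant to evaluation order and reproducible taxon by taxon.

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| buffer radius | 1000 | m | landscape context scale of the protocol |
| regional radius | 100 000 | m | regional baseline for the index |
| min. neighbours | 30 | collections | stable regional mean |
| frequency threshold | 0.02 | fraction | frequent/infrequent split |
| confidence | 0.95 | — | interval level for labels |
| bootstrap B | 9999 | replicates | quantile resolution ≈ 10⁻⁴ |
| α | 0.05 | — | model simplification and Tukey tests |

Coordinates are planar metres (an equal-area projection is assumed
upstream); all distances are Euclidean, which at ≤ 100-km scales within one
country introduces negligible error. Neighbour search is the exact
all-pairs distance matrix — O(n²) is trivial at the ~2000-collection scale.
Distance and threshold comparisons are inclusive; floating-point ties are
taken as-is. Point-in-cell membership is half-open on both axes.

## The synthetic generator

The generator emulates the *statistical structure* such an analysis relies
on, not any real landscape: (i) a patchy categorical map — per category, a
Gaussian-smoothed white-noise field at a 1.5-km patch scale,
rank-thresholded sequentially so realised fractions match the mixing
weights (default 10% urban / 55% agricultural / 33% natural / 2% water)
to within rounding; (ii) collections placed uniformly on non-water cells
and accepted with probability ∝ exp(bias × local urban buffer proportion)
(default bias 2), reproducing the urban skew of volunteer sampling;
(iii) occupancy P(t in c) = logistic(β₀ₜ + Σ βₜ,ₗ P_c,l), independent
across taxon–collection pairs, with one picture per occurrence.

The default community plants, per order, specialists and avoiders of each
type (β = ±6 on that type's buffer proportion, zero elsewhere) plus fully
neutral taxa, in two tiers. Frequent-tier taxa use β₀ = −2. For the
infrequent tier the baseline must keep the per-type presence rate under 2%:
a +6 preference delivers almost its full boost inside near-pure buffers of
the preferred type (patch scale > buffer radius), so infrequent specialists
use β₀ = −10.5 while avoiders and neutrals (boosted nowhere) use β₀ = −5.
The scenario defaults — 300 × 300 grid of 100-m cells, 2000 collections,
160 taxa — run end-to-end in well under a minute on one CPU.

Deliberately not emulated: temporal dynamics, observer skill, detection or
misidentification error, abundance (only presence), spatial correlation of
occupancy beyond what land-use composition induces, and real-geometry
land-cover (patches are isotropic blobs). Passing recovery tests therefore
demonstrates that the estimator chain is correct and calibrated under its
own assumptions — not that those assumptions hold for any particular field
scheme.

Because a taxon's preference acts on a composition (the three proportions
sum to ~1), planting +6 on one axis mechanically induces realised
*avoidance* on the other axes. Ground truth therefore expects the planted
label only on the planted axis, and "expected tolerant everywhere" only for
taxa neutral on all three axes (flagged `neutral_all`). The recovery tests
score specialists/avoiders on their planted axis and the tolerant error
rate pooled over the three land-uses: with 64 neutral taxa a per-axis rate
estimate has a binomial standard deviation of ~2.7 percentage points around
the nominal 5% non-coverage, so only the pooled rate (192 labels) separates
a calibration defect from Monte-Carlo noise.

## Numerical and design choices

- Type-III tests require sum-to-zero contrasts; formulas use `C(f, Sum)`
  throughout. With a single response the multivariate test reduces exactly
  to the univariate F, which is what is computed then.
- A constant response (zero variance) is reported as F = 0, p = 1 rather
  than as the 0/0 ratio a naive fit produces.
- Rank-deficient factorial designs (an empty cell with the interaction
  present) raise an error suggesting the interaction be dropped.
- Tukey comparisons use the Tukey–Kramer standard error for unbalanced
  groups and the studentized-range distribution on the minimum adequate
  model's residual df; the compact letter display uses the
  insert-and-absorb algorithm and is invariant to level ordering.
- The analysis unit for group tests is the taxon-occurrence; aggregating to
  per-taxon affinities first is possible through the library but is not the
  default (occurrence-level rows carry the within-taxon spread that the
  factorial tests partition).
- No multiplicity correction is applied across the 3 × n-taxa intervals or
  across the three ANOVAs; the labels are per-interval statements.
- Pipeline outputs embed a run id (SHA-256 of the analytic config); reruns
  are byte-identical and refuse to overwrite without `force`.

## Known limitations

- Buffer membership by cell centre slightly misweights edge cells; the
  error shrinks with cell size and is irrelevant at the default 100-m
  cells / 1-km radius.
- The ESRI ASCII grid is the only raster format; grids must be axis-aligned
  with square cells.
- BCa intervals at very small K (3–10) can be erratic; labels there should
  be read with the `K` column in hand. K < 3 is flagged `unstable`.
- The index controls for sampling *location* bias, not for effort or
  detectability differences among land-uses.
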