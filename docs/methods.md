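# Methods

## Problem and model

The package completes partial 3D point clouds without paired
supervision. A generative prior `G(y; δ)` over complete shapes of one
object class is pretrained adversarially; at test time each partial
scan `X_in` is explained by searching the prior:

```
y*, δ* = argmin_{y,δ} E( N(G(y; δ)), X_in )
```

`N` is the multi-resolution degradation: the generated cloud is
farthest-point-sampled into nested levels of 2048/1024/512 points, and
each level is reduced to the union of the `K` nearest generated points
around every partial point (the Mk-Mask). The objective `E` combines a
multi-stage squared-Chamfer reconstruction term (stage weights 1, α, β)
with an L1 feature-matching term over three per-level discriminators,
mixed as `h_C·T_C + h_D·T_D` with `h_C + h_D = 1`.

Key assumptions: one model per object class; inputs normalized to the
(-1, 1) box; the partial scan is a subset-like observation of a single
object (no scene clutter); at least 512 observed points so the partial
pyramid is constructible.

## Geometry conventions

* **Centering** uses the axis-aligned bounding-box midpoint
  (`min + (max − min)/2` per axis), not the centroid; the two differ
  for clouds with asymmetric point density, and the box midpoint is
  what makes the subsequent (-1, 1) bound exact.
* **Normalization** divides by half the longest-axis extent, so the
  cloud touches ±1 on that axis and stays inside ±1 elsewhere.
  Degenerate clouds (zero extent) are rejected.
* **Rotation augmentation** composes three uniform angles in [0, 2π)
  about x, y, z (applied in that order). The parameterization is not
  canonical—any proper rotation sampler would serve—but it is fixed and
  seeded for reproducibility.
* **Dataset splitting** shuffles with a seeded generator and assigns
  ⌊0.6n⌋ / ⌊0.2n⌋ / remainder to train/val/test, so leftover samples
  enlarge the test partition.

## Sampling and degradation

* IFPS is greedy maximin with the seed point defaulting to index 0 and
  distance ties broken by the lowest input index; both choices are
  arbitrary but fixed, making pyramids deterministic. The inner loop is
  a numba kernel (pure-numpy fallback with identical selections).
* Pyramid levels are sampled sequentially (coarse from fine), which
  guarantees nesting as point sets. Partial inputs with fewer than 2048
  points use level sizes capped at the input size.
* `knn_query` is exact: a brute-force distance matrix with stable
  lowest-index tie-breaking below ~3·10⁵ pairs, a k-d tree beyond
  (identical on generic data, where exact ties have measure zero).
* The Mk-Mask output is a deduplicated, ascending-index subset of the
  generated cloud — the union in its definition discards multiplicity.
  The same `K` (default 50) is used at every level; no canonical value
  of `K` exists for this family of methods, and 50 keeps neighborhoods
  large enough for stable loss gradients at 2048-point resolution while
  staying well below the coarsest level size. A per-level schedule is
  exposed (`k_schedule`) but defaults to uniform.

## Metrics

CD-T uses squared nearest-neighbor distances in both directions; CD-P
averages unsquared means; UCD/UHD are the partial→complete mean-squared
and max unsquared distances. The F-score threshold τ defaults to 0.01,
i.e. 1% of the normalized unit scale, the convention of the completion
benchmarks this package mirrors. Reporting scales (CD/UCD ×10⁴, UHD
×10²) are applied only in `MetricReport.to_report_dict`, never inside
losses. Nearest-neighbor search is exact (k-d tree or brute force).

## Networks and pretraining

The networks are deliberately compact CPU-scale stand-ins; the fidelity
target is the completion framework, not any particular backbone
capacity.

* Generator: MLP set decoder 96 → 128 → 256 → 2048×3 with tanh output
  (so generations live in the normalized box). ~1.6 M parameters.
* Discriminators (one per pyramid level, identical structure): shared
  per-point MLP 3 → 32 → 64, symmetric max pooling, head 64 → 32 → 1.
  The pooled global feature is the vector compared by the
  feature-matching loss; it is exposed on a per-dimension scale
  (divided by the feature width) so that L1 feature distances are O(1)
  and the convex weights `h_C/h_D` compare commensurate quantities —
  with raw pooled features the adversarial term is ~10²·the Chamfer
  term and silently dominates any reasonable weight pair. A
  max-plus-mean pooling variant was evaluated (denser gradients to the
  generator) but destabilized desk-scale adversarial training, so
  classical max pooling stands.
* All forward/backward passes are explicit numpy; optimization is a
  hand-rolled Adam. Batched pretraining math runs in float32 for
  throughput; single-cloud passes (used inside the inversion loop and
  by finite-difference tests) run in float64.

Pretraining uses the standard non-saturating GAN loss, one model per
class. The full preset mirrors the reference configuration (Adam,
lr 1e-4, batch 64, 2000 epochs). The desk preset — the configuration
exercised by the tests and the acceptance script — trains 200 epochs at
batch 32 on 64 shapes (400 optimizer steps). At that step budget the
full-scale learning rate underfits (generated samples do not move
toward the training distribution), so the desk preset uses 2e-3 —
chosen by a small sweep of the sample-quality statistic (mean CD-T of
generated samples to their nearest training shape) — while the full
preset keeps 1e-4.
Real clouds for D2/D3 are IFPS-downsampled once before training;
generated clouds are downsampled per step with seeded random subsets
(an order-of-magnitude cheaper than per-batch IFPS, and a random subset
of a generator output is statistically equivalent coverage at these
sizes). The inversion loop always uses true IFPS pyramids.

## Inversion

* The latent is initialized by scoring `n_init_samples = 256` standard
  normal draws with the degraded reconstruction objective (CD-T of the
  masked generation against the partial input; no discriminator term
  during initialization) and keeping the argmin.
* Refinement runs Adam jointly on `y` (step 0.01) and `δ` (step 1e-4 by
  default — deliberately small so per-instance adaptation stays near
  the pretrained prior); an alternating schedule is exposed as config.
  200 iterations by default; no early stopping.
* The best-objective iterate is returned rather than the last: the
  adversarial term oscillates, and best-iterate tracking makes the
  returned objective ≤ the initial one by construction.
* Gradients of CD-T are exact wherever nearest-neighbor assignments are
  locally constant (they are piecewise constant in the coordinates);
  feature-matching gradients use the L1 subgradient `sign(Δf)`. A
  non-finite objective raises an error carrying the trace.
* `δ` adaptation happens on an internal copy, so the pretrained model
  is never mutated and consecutive completions are independent.
* Noiseless-recovery sanity checks (a partial input that a generator
  output explains exactly) are run with reconstruction-only weights
  (`h_C = 1, h_D = 0`): the L1 feature term has a non-vanishing
  subgradient at the optimum, so with it the tail convergence is slow
  even though the optimum value is 0.

## Synthetic shapes and scans

The generator emulates a desk-scale scanning benchmark of cartons and
artificial plants:

* Cartons: points uniform by area over the six box faces; every point
  lies exactly on a face. Training sets draw edge ratios uniformly from
  [0.4, 1.0] before normalization.
* Plants: a vertical stem cylinder, branch cylinders attached at spread
  heights with golden-angle azimuths, and an elliptical leaf disc at
  branch tips; points allocated to components by surface area (largest
  remainder). Presets 1..5 increase branch/leaf counts (2·level each),
  spanning simple to intricate silhouettes. These are procedural
  stand-ins — cylinders and discs — with no claim of botanical realism.
* Partial scans apply, in order: an occlusion mask (half-space crop, or
  a back-hemisphere drop for a viewpoint direction), sparsity thinning
  (keep ⌈ρ·n⌉ points, seeded, order-preserving), and isotropic Gaussian
  noise. With σ = 0 every scan point is a member of the source cloud.
  The occlusion/sparsity/noise magnitudes have no canonical published
  values; the defaults here (half-space through the origin, ρ = 1,
  σ = 0) are declared choices, and the test suite exercises ρ down to
  0.25 and σ up to 0.01.

What passing tests show — and what they do not: the synthetic shapes
are noise-free, perfectly segmented, single-object clouds with exactly
2048 points; real LiDAR scans carry outliers, anisotropic beam spacing,
ghost returns and clutter. Desk-scale results demonstrate that the
machinery (pyramid, masking, objective, joint optimization) behaves as
specified, not that field-scan accuracy matches any published
benchmark.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
a deliberate package choice: 64 training cartons (200 epochs, batch 32)
for the carton experiments, 32 training plants (120 epochs, batch 16)
per complexity preset for the plant ordering experiment, 8 carton and
2×4 plant completions at a 300-iteration convergence budget (the
200-iteration default favors interactive latency; the experiments
favor convergence), and oracle-equivalence checks on ≥ 100 random
instances of ≤ 64 points. Half-space scan planes pass through the
origin and are redrawn if a crop keeps fewer than 512 points — a scan
seeing under a quarter of an object is not a usable observation.
The plant-ordering experiment scores completions with F-score@0.1 —
10% of the unit scale rather than the 1% benchmark default, which is
calibrated to GPU-scale completion fidelity; the coarser threshold
keeps the score informative for compact CPU-trained completions.

## Known limitations

* The compact MLP generator has no spatial inductive bias; thin plant
  structures are completed coarsely.
* GAN pretraining at 400 optimizer steps reaches a rough class prior,
  not a high-fidelity generative model; completion quality leans on
  per-instance δ adaptation.
* The Mk-Mask is hard (non-differentiable selection); gradients flow
  only through selected points, which is standard for this family of
  methods but slows recovery of regions the mask never selects.
* Metrics are exact but O(n log n) per query; no GPU path exists.
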