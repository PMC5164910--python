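# Methods

## Problem and model

The package segments blood vessels in 2D grayscale slices of
contrast-enhanced liver CT. In the portal phase, contrast-filled vessels
are the brightest tissue inside the liver parenchyma, so vessel
segmentation can be phrased as intensity clustering: partition the pixels
of a slice into `C` gray-level classes and mark the brightest class(es) as
vessel.

Clustering is fuzzy C-means (FCM) on the 1-D intensity feature. With pixel
gray levels `x_j` (j = 1..N), class centers `c_i` (i = 1..C), memberships
`u_ij ∈ [0,1]` with `Σ_i u_ij = 1`, and fuzzifier `m > 1`, FCM minimises

    J = Σ_i Σ_j u_ij^m (c_i − x_j)²

by alternating the closed-form updates

    u_ij = 1 / Σ_k (d_ij/d_kj)^(2/(m−1)),   d_ij = |c_i − x_j|
    c_i  = Σ_j u_ij^m x_j / Σ_j u_ij^m

Each update is the exact minimiser of `J` in its block, so the cost trace
of the plain alternation is non-increasing; this is asserted on hundreds
of random images in the test suite.

A spatial variant is available (off by default): after each membership
update, every membership is combined with the summed memberships of its
square neighbourhood, `u'_ij ∝ u_ij^p h_ij^q` with
`h_ij = Σ_{k∈NB(j)} u_ik`. This suppresses isolated noise labels but
blurs thin structures, which is why the plain variant is the default for
vessel work. The window is truncated at image borders rather than padded,
so no intensities are invented.

FCM's alternating descent only finds a local minimum of `J`, and with six
classes on a liver histogram the landscape has several basins. The
optimisation layer is a real-coded genetic algorithm over center vectors:

* **chromosome** — a vector of `C` candidate centers in [0, 255];
* **fitness** — the FCM cost after a short burst (default one
  membership+centroid update pair) from the chromosome's centers;
* **selection** — roulette wheel on inverted cost, `w = J_max − J + ε`
  with `ε = 1e−12` so even the worst finite member stays selectable;
* **crossover** — whole-arithmetic: both children are convex mixes of the
  parents with a single `α ~ U(0,1)`, so genes never leave [0, 255];
* **mutation** — additive Gaussian noise (default scale 25.5, i.e. 10% of
  the gene range), clipped to range; an optional per-generation decay
  factor anneals the scale (default 1.0 = no annealing);
* **elitism** — the best 10% carried over unchanged, which makes the
  per-generation best cost monotonically non-increasing;
* **Lamarckian refeeding** — when a chromosome is evaluated inside the
  generation loop, the FCM-updated centers are written back into its
  genes. Every surviving lineage therefore descends its cost basin a step
  per generation while crossover and mutation keep exploring between
  basins. This realises the loop in which the clustering result feeds
  back into the evolving population, and in practice it is what makes the
  best-cost trace flatten by generation ~20 out of 40. (A pure annealing
  alternative was tried first and rejected: cutting exploration early
  made the GA settle in worse basins on 3/20 benchmark phantoms.)

Default generation composition at population 100: 10 elites, 60 crossover
offspring, 30 mutants (fractions 0.10/0.60/0.30 of the population; counts
are rounded, any remainder going to the elites). The run lasts 40
generations and the best-ever chromosome is finally polished by a full
FCM run to convergence — the GA chooses the basin, the alternating
updates find its floor deterministically.

## Pipeline

`segment()` composes: Gaussian low-pass preprocessing → GA-FCM
→ defuzzification by per-pixel argmax (ties to the lowest cluster index)
→ vessel-mask extraction. The classical baseline
(`segment_fcm_baseline()`) shares every stage but replaces the GA with a
single uniform-random center initialisation, isolating the GA's
contribution.

Vessel-mask extraction marks the pixels of the `k` clusters with the
brightest final centers (or an explicit index list). The default is
`k = 2` of `C = 6`: smoothing turns the parenchyma→vessel step into an
intensity ramp, and with six classes the converged centers reliably place
two classes on that ramp; taking only the single brightest class keeps
just the vessel cores (measured Dice ≈ 0.66 versus ≈ 0.97 with `k = 2` on
the synthetic benchmark).

## Tunable parameters

| parameter | default | meaning / why |
|---|---|---|
| `clusters` (C) | 6 | intensity classes; one gene per center |
| `fuzzifier` (m) | 2.0 | the standard choice; exponent 2/(m−1) = 2 |
| `tol` | 1e−5 | stop when |ΔJ| < tol × J_first |
| `max_iter` | 100 | cap on alternating updates |
| `gaussian_sigma` | 1.5 px | denoising scale; 2.0 over-smooths 4–6 px vessels |
| `gaussian_kernel` | 9 | odd kernel side (±4 px ≈ 2.7 σ) |
| `pop_size` | 100 | GA population |
| `generations` | 40 | GA iterations |
| `crossover/mutation/elite` | 0.60/0.30/0.10 | next-generation composition |
| `mutation_scale` | 25.5 | Gaussian mutation SD, 10% of range |
| `k_brightest` | 2 | vessel classes among C by center brightness |
| `spatial p, q, window` | 1, 1, 5 | spatial-variant exponents and window |

## Numerical choices

* Memberships are computed from distances normalised by the per-pixel
  minimum distance, keeping every exponential in (0, 1]; this avoids
  overflow as `m → 1` (near-crisp regime).
* A pixel coinciding exactly with a center receives membership 1 in the
  lowest-indexed coincident cluster — a deterministic resolution of the
  zero-distance singularity.
* A cluster that loses all membership mass during a full FCM run is
  re-seeded once to a uniform-random center; a second degeneracy raises.
  During GA fitness evaluation a degenerate chromosome is instead scored
  `+inf` so the generation continues. On degenerate *inputs* (for example
  a constant image, where crisp assignment starves every other cluster no
  matter how centers are re-seeded), the pipeline falls back to the best
  chromosome's own membership state rather than failing.
* GA fitness is evaluated by a numba-compiled streaming kernel that fuses
  the membership update, the centroid update and the cost sum into one
  pass per iteration; the test suite asserts its agreement with the
  numpy primitives to 1e−10. With ~3 ms per 256×256 evaluation a full
  40-generation run takes ~12 s on one core.
* One master seed fans out to per-stage child streams
  (`numpy.random.SeedSequence.spawn`), so phantom generation, GA and the
  FCM baseline are independently but reproducibly seeded; identical seed
  and configuration give bit-identical results.

## Synthetic phantoms

Real annotated liver CT is not shipped with the package; all quantitative
checks run on a synthetic generator that emulates what makes intensity
clustering a sensible strategy on portal-phase slices: a dark background
(gray 40), an elliptical organ (gray 120, semi-axes 0.40/0.32 of the
image), a branching tree of bright vessel segments (gray 240, 16 straight
segments, root half-width 3.5–5.5 px tapering ×0.7 per level to a 2 px
floor, i.e. full widths ≈ 4–11 px at 256×256), and additive Gaussian
noise (σ = 10). The ground-truth mask is exactly the rasterised vessel
pixels. A 20-phantom suite with deterministically jittered geometry
mirrors a multi-patient test set.

What the phantoms deliberately do **not** model: partial-volume fading of
sub-voxel vessels, intensity inhomogeneity and streak artifacts, curved
vessels, organ-boundary anatomy (stomach, ribs), and Hounsfield
calibration. Passing the phantom benchmark therefore shows that the
optimiser and the clustering machinery work as designed in their intended
intensity regime — not that the defaults transfer to clinical data, where
preprocessing and the vessel rule would need re-tuning.

Vessel widths sit at the lower end of what the pipeline can resolve by
design, but not below it: hardened cluster boundaries are quantised to
midpoints between adjacent centers, so the mask edge can sit a sub-pixel
to a pixel away from the true edge, and overlap scores of thin structures
degrade roughly with (edge error)/(vessel width). With 4–11 px vessels the
measured Dice against exact truth is ≈ 0.95–0.99 per phantom (≈ 0.98 even
noise-free — the residual is the boundary shift, not noise). Markedly
thinner vessels push Dice below 0.9 regardless of the optimiser, which is
a limitation of intensity-only clustering, not of the GA.

## Benchmark problem sizes

The quantitative suite runs 20 phantoms at 256×256 with noise σ = 10 and
the full default GA (population 100, 40 generations) — about six minutes
on one core. The per-slice confusion counts and percent metrics of the
published 20-slice CT evaluation are used as reference inputs for the
metric arithmetic only; the slices themselves are not part of the
package, so those tables are checked for internal consistency
(count-derived specificity and the two printed means) rather than
re-measured. The printed specificity values differ from the exact
count-derived quotients by up to 3×10⁻⁴ — last-digit rounding noise in
the source tables — so agreement is asserted at 5×10⁻⁴. The published
counts-table "mean" row is internally corrupted and is not used.

## Known limitations

* Intensity-only features: no texture, no position, no vesselness filter;
  anything bright segments as vessel (including a bright tumor rim).
* 2D only; no volumetric continuity between slices.
* The brightest-k rule needs `k` chosen for the modality; it is a
  configuration knob, not an adaptive estimator.
* The GA cost `J` is not a segmentation score: on some inputs the global
  cost optimum corresponds to a slightly worse mask than a neighbouring
  basin (observed on 1–2 of 20 phantoms). The package optimises `J`
  faithfully rather than tuning toward the mask.
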