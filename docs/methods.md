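# Methods

This note documents the quantities varishell computes, the assumptions and
defaults behind them, and the choices made where the design was genuinely
open. Units are µm (lengths), µm² (areas), µm³ (volumes) and varicosities
per 1,000 µm³ (densities) throughout.

## Scene model

A *scene* is one imaged ganglion: closed triangle meshes of nerve cell
bodies, one 3D point set per varicosity marker (TH, ENK), an axis-aligned
bounding box for the imaged volume, and the acquisition voxel size (dz
defaults to 1 µm, matching 1 µm optical z-steps; the x–y pixel size is a
config value with no default, as it depends on the acquisition). Meshes are
repaired once on load (hole filling, normal reorientation); a mesh that
cannot be made watertight marks its cell excluded rather than aborting the
run, mirroring how imperfect surface renders are handled during manual
reconstruction. No unit auto-detection is attempted: coordinates are µm by
convention.

## Shell density

For cell surface *S* and half-width *t* (default 1 µm) the perisomatic
shell is {p : |d(p, S)| ≤ t}, where d is the signed Euclidean distance
(negative inside — a convention that had to be fixed; the boundary is
included, a measure-zero choice made for determinism). The density for a
marker is 1000 · count / shell volume.

**Distance queries.** Distances are exact, not sampled: a k-d tree over
triangle centroids yields upper/lower bounds (centroid distance, minus the
largest centroid-to-vertex radius), and surviving candidate triangles are
resolved with an exact point-triangle kernel. Tests assert equality with an
exhaustive all-triangles search. The inside/outside sign uses ray-crossing
parity along a fixed irrational direction, valid for watertight meshes.

**Shell volume** is estimated by counting voxel centers inside the shell at
pitch 0.25 µm (configurable; the invariant pitch ≤ t/2 keeps the estimate
honest). How the original analysis obtained shell volumes is not
reconstructible, so accuracy is anchored to closed forms instead: for a
radius-5 µm sphere the estimate is within 0.5 % of 4π/3·(6³−4³), and the
error shrinks monotonically as the pitch halves. The voxel grid is anchored
to the mesh's own canonical frame (vertex centroid + principal axes, with a
deterministic sign convention), which makes the estimate invariant under
rigid motion of the scene for any mesh with distinct principal axes; for an
exactly spherical mesh the principal axes are degenerate and the grid
orientation — and hence the last ~0.5 % of the estimate — is arbitrary but
deterministic. Shells are *not* clipped to the imaged bounding box by
default; `clip_to_bbox` enables that for sensitivity analyses of cells near
the border.

**Attribution.** Each spot goes to the cell minimising |d|, and only if
that minimum is ≤ t. Exact ties go to the lexicographically smallest
cell_id. Spots nearest an *excluded* cell are dropped, not reassigned:
reassignment would count a terminal for a neighbour it does not appose.
Excluded cells therefore still compete during attribution but produce no
density record.

## Cell typing and exclusions

Cells are one of ChAT+/NOS−, ChAT−/NOS+, ChAT+/NOS+, ChAT−/NOS− from
explicit boolean labels; when only channel mean intensities are available,
a cell is positive iff its mean exceeds the channel threshold (automated
stand-in for manual classification; explicit labels always win). Cells are
excluded when manually flagged (e.g. merged surfaces — no automatic
de-merging is attempted), when their mesh failed repair, or when their
bounds come within `border_margin` (default 0.5 µm, "touching the edge") of
a bounding-box face. ChAT−/NOS− cells stay in basket and morphometry
outputs but never enter the density model — they are too few for inference.
Type proportions are reported as pooled percentages of counts.

## Baskets

The field's "basket" call is visual; varishell formalises it as: at least
`n_min` = 15 attributed in-shell spots **and** angular coverage ≥
`c_min` = 1/3, where coverage is the occupied fraction of 64 quasi-uniform
directional bins (deterministic Fibonacci-sphere lattice; a direction is the
unit vector from the cell's volume centroid to a spot, binned to the nearest
lattice vector). The defaults were chosen so that synthetic full-coverage
rings are called and octant-confined clusters are not; both thresholds are
configurable and echoed in output, and manual basket annotations override
the automatic call. Association between basket status and the four cell
types is the Pearson χ² (no continuity correction) on the
(basket, no-basket) × type table; the implementation reports the exact
statistic, degrees of freedom and upper-tail p.

## The density model

Counts per included cell × marker follow a negative binomial with mean
μ = exp(β_c + u + w + log V) and shape φ = exp(γ_c), Var = μ + μ²/φ; c
indexes the six (3 modelled types) × (2 markers) combinations — cell-mean
coding, one coefficient per combination and no global intercept, so that
exp(β) is itself a mean density (per µm³; reported ×1000). u and w are
components of correlated 6-vectors drawn per subject and per ganglion
within subject: non-centred, u_s = diag(σ_u) L_u z_s with z standard
normal, σ half-normal(0,1) and L the Cholesky factor of an LKJ(2)
correlation.

Priors on β and γ are normal with unit scale *anchored at data-located
centres*: the pooled log density for β and a moment-based pooled log shape
for γ. With a µm³ offset the absolute log density sits near −5, and a
normal(0,1) prior centred at zero is not weakly informative there — it is
actively wrong, and fits showed it pushed the gap into inflated
random-effect scales. Reference fitting packages avoid this by giving the
intercept a data-located default prior while unit-scale normals apply to
contrast-scale coefficients; anchoring is the cell-mean-coding equivalent.
After anchoring, posterior medians track an independent fixed-effects NB
maximum-likelihood fit (statsmodels) to within a few percent.

**Sampling.** In-house HMC with analytic gradients (the LKJ transform has a
hand-derived backward pass verified against complex-step differentiation
and finite differences): jittered static trajectories (nominal integration
time 1.5), dual-averaging step size targetting 0.9 acceptance, Stan-style
windowed diagonal mass adaptation, energy-error divergence counting.
Defaults are 4 chains × (1,000 warmup + 1,000 retained); scaled runs use
2 × (500 + 500). Rhat and ESS come from arviz; any monitored Rhat above
1.05 warns (optionally aborts). Fixed seed ⇒ identical draws.

**Reported quantities.** Population mean densities exp(β)·1000 (random
effects at zero) and, for the three type contrasts per marker, the
posterior of exp(β_a − β_b): median, equal-tailed 95 % credible interval
(the interval flavour is unspecified in most reporting conventions;
equal-tailed matches common package defaults), and Pr(ratio > 1). A ratio
is flagged significant when the 95 % interval excludes 1; no one-sided
"trend" labels are attached.

**Morphometrics.** Surface area and volume per type are compared by
one-way ANOVA with Tukey HSD. The unit of analysis is configurable and
always reported; the default is per-ganglion type means (cells within a
ganglion are not independent), `cell` treats every cell as an observation.
Welch correction is off.

## Synthetic ganglia

The generator emulates the study design the pipeline expects: 7 subjects ×
2 ganglia, Poisson(35) cells per ganglion in proportions 38/42/12/8 %,
per-type soma volumes 4,566/3,177/6,078/2,156 µm³ (lognormal per-cell
scatter, σ = 0.3 on the log scale), two markers with true shell densities
(TH: 7.43/5.59/6.02, ENK: 19.52/12.99/13.22 per 1,000 µm³ for the modelled
types, with background values 5.0/12.0 for ChAT−/NOS−), NB shapes φ = 8
(TH) and 5 (ENK), and multiplicative log-normal group effects with SD 0.2
(subject) and 0.1 (ganglion). Group-effect components across the type ×
marker combinations are exchangeably correlated (ρ = 0.6): staining and
acquisition conditions vary mostly globally within a subject. The variance
parameters are assumptions — no between-subject estimates are published —
chosen to make recovery nontrivial but feasible at the design size.

Cells are ellipsoids (axis ratios b/a ∈ [0.7, 1.0], c/a ∈ [0.5, 0.85];
icosphere subdivision 3, ≈1 µm facets) with random in-plane orientation —
the shortest axis stays along z, as in a flattened stretched wholemount —
packed without overlap in a 400 × 400 × 40 µm slab with ≥2.5 µm surface
separation, so
±1 µm shells never intersect and per-cell ground-truth counts are exact.
Counts are NB draws with mean density × shell volume × group effects; that
many spots are placed in the shell by rejection sampling (and re-verified
with an exhaustive per-triangle distance check, so generation cannot
silently agree with a broken query path). Ordinary innervation is angularly
*patchy*: in-shell candidates are thinned by a von Mises–Fisher mixture
over a few patch directions (1 + capped-Poisson(2) patches, κ = 30),
emulating varicosities strung along passing axon branches — uniform
placement would give every well-innervated cell full angular coverage and
make the basket criterion vacuous. Basket cells (ENK on ChAT+/NOS− with
probability 0.10, TH with 0.02) instead get a 3× count placed
area-uniformly over the whole surface — full angular coverage, the
encirclement that defines a basket. With these defaults the detector
separates generator-truth baskets from patchy innervation exactly on test
scenes. Background
spots are a homogeneous Poisson process (10⁻⁴ µm⁻³ per marker) outside all
shells. Ellipsoid geometry, the absence of fluorescence rendering, and
perfectly known labels are deliberate simplifications: passing tests show
the *pipeline* is correct and calibrated under the stated generative model,
not that real tissue meets its assumptions (real somata are crinkly — their
area/volume ratios exceed an ellipsoid's — and real exclusion/merge calls
are made by eye).

A second layer, `simulate_model_rows`, draws the same count model without
geometry (sphere-equivalent shell volumes from the per-type soma volume
distribution). Model calibration and recovery studies use it so their
replicates spend time on the statistics rather than on voxelization;
geometry correctness is covered separately by the exact-attribution and
shell-volume oracles. Problem sizes in the test suite (e.g. 5 replicate
datasets at the 7 × 2 × 35 design with 2 × (500+500) chains; 2-subject
scenes for end-to-end runs) were chosen as the smallest sizes at which the
checked properties are statistically meaningful.

## Known limitations

- Anisotropic z-resolution is not modelled: distances are Euclidean.
- No partial-volume correction or diffusion-path tortuosity; the shell
  statistic is proximity, not synapse identification.
- Automatic merged-cell detection is out of scope (manual flags only).
- The χ² association test is asymptotic; with very sparse basket tables the
  zero-margin guard may refuse to test.
- With few subjects the posterior upper tails of random-effect scales are
  prior-sensitive; ratio contrasts are much less affected than absolute
  densities.
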