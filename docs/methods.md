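# Methods

## Segregation statistics

Each aggregate is treated as a pair of probability masses over pixel
positions: the red and green intensity matrices restricted to the ROI mask,
each normalized to unit total. All moments are computed from the **raw**
channel intensities — contrast normalization exists only to find the
objects, and rescaling detection intensities would distort the physics the
moments encode. The combined centroid weights the two normalized channels
equally (the midpoint of the two centroids), which makes every statistic
invariant to overall labeling brightness and to unequal dye uptake between
populations.

Two scattering conventions are implemented because the ratio
$g_{red}/g_{green}$ has range $[0,\infty)$ while the behavior it is meant to
capture ("≈ 1 intermixed, toward 0 or 2 under segregation") implies a
bounded symmetric quantity. The bounded form
$2g_{red}/(g_{red}+g_{green})$ is the default and is what the intermixed
window $(0.9, 1.1)$ — an open interval; boundary values are excluded — is
applied to. Under a channel swap the bounded form maps to $2-S$ and the
ratio to $1/S$, and both equal 1 for identical channels; every report
records which convention produced it.

The dipole normalization $8R_{eq}/3\pi$ is a calibration choice: it is the
exact centroid separation of two half-disks of the cluster's
equivalent-circle radius, so the fully bisected uniform disk defines
$P = 1$. This satisfies the intended limiting behaviors ($P \approx 0$ for
mixing and for concentric engulfment, $P \approx 1$ for two-compartment
separation) with no free parameter. Closed forms used by the test suite:
for a uniform disk of radius $R$, $g = R/\sqrt 2$; for a centered core of
radius $R/2$ versus its annulus, $g_{core} = R/(2\sqrt2)$ and
$g_{annulus} = R\sqrt{5/8}$, giving $S_{ratio} = 1/\sqrt5 \approx 0.447$
and $S_{bounded} = 2/(1+\sqrt5) \approx 0.618$.

A structural property worth stating plainly: a *symmetric bisection leaves
S at 1*. Both half-disks have the same second moment about the shared
centroid, so S distinguishes asymmetric configurations (engulfment, unequal
compactness) while P detects two-compartment separation. The two statistics
are complementary, not redundant. A corollary is that in the sorted-mode
synthetic model (below) the distribution of S is independent of the mixing
parameter — the per-channel radial distribution is the same at every mixing
level — so only P tracks sorted-mode mixing, and the intermixed fraction
responds to mixing only in modes that break the symmetry (engulfment).

## Segmentation chain

Maximum z-projection → per-pixel local contrast normalization (window
$(2r+1)^2$, reflect-padded, deviations clamped at ±k local SDs and mapped
onto the dtype range; zero-variance windows map to mid-range) → Gaussian
blur $\sigma=1$ px → Li threshold → 8-connected components → removal of
components smaller than 1000 px ("smaller than" read strictly: area 1000
survives). Defaults $r = 127$ px, $k = 3$: the contrast parameters of the
original recipe are not published, and these suit 10× fields; both are
configuration, and the test suite passes its parameters explicitly.

Two documented additions make the chain total:

* **Filled ROIs.** Each detected object is kept as its filled outline
  (`fill_holes`, default on): an aggregate is a solid region of interest,
  and sub-threshold pinholes inside a confluent cluster are not separate
  background.
* **Signal-free-field guard.** Thresholding a field with no separable
  signal splits its background noise near the median; at ~50% density the
  speckle percolates into image-spanning components the size filter cannot
  remove. If the thresholded foreground exceeds `max_foreground_fraction`
  (default 0.45 — far above the ~5–30% aggregate coverage of real fields),
  the field is reported empty with a warning.

The Li threshold is the mean-of-means fixed point
$t \leftarrow (m_{lo}-m_{hi})/(\ln m_{lo} - \ln m_{hi})$ iterated to a
0.5-gray-level tolerance, followed by an exact minimization of the discrete
cross-entropy criterion over the candidate splits within a few gray levels
of the converged value. The fixed point is a stationary point of the
continuum relaxation and can land one histogram bin away from the discrete
minimum on a shallow valley; the polish makes the returned threshold the
actual criterion minimizer (and exactly scale-equivariant). Thresholds are
compared across implementations via the *effective* threshold — the largest
pixel value at or below $t$ — since any two thresholds inside the same
empty histogram gap binarize identically.

## EVL morphometry

The bench workflow this automates involved three manual steps (hand-set
threshold, hand-corrected borders, hand-counted junctions); each is
replaced by a parameterized equivalent so runs are reproducible: threshold
by Li/Otsu or an explicit fixed value; a small-region merge after the
watershed (regions < 30 px merge into their largest neighbor); and a
pixel-neighborhood junction criterion. Watershed seeds are maxima of the
Gaussian-smoothed distance transform with a minimum separation; the module
default (5 px) is deliberately permissive, and the benchmark suite uses
15 px — about half the expected cell diameter of its 100-cell/512 px
mosaics — which recovers cell counts within 1–2 of truth. Perimeters use
the Crofton four-direction estimator (asymptotically exact on smooth
shapes; a digital disk of radius 50 measures circularity ≈ 1.0, a square
≈ 0.88) and circularity is clamped at 1.

A junction point is a cluster of connected boundary pixels whose
$(2r+1)^2$ neighborhood contains ≥ 3 distinct cell labels; its arity is the
number of distinct labels over the cluster, its position the cluster
centroid, and arity ≥ 5 marks a rosette. $r$ must exceed the boundary
half-width; with the renderer's ~2 px boundaries, $r = 3$ resolves every
wedge of rosettes up to arity 7 and is what the ground-truth-exactness
benchmarks use ($r = 2$ remains the conservative module default).
Two-cell contacts (arity 2) are excluded from junction counts but
retrievable via an option for margin analyses. The mitotic fraction
Li-thresholds the nuclear channel, keeps components above a minimum area,
assigns each to the cell containing its centroid, and reports the
percentage of cells with at least one nucleus; a flat channel is 0%.

## Synthetic data: what it emulates, and what it does not

**Aggregate fields.** Cells are isotropic Gaussian blobs (amplitude
jittered ±20%) summed onto a constant background with additive Gaussian
read noise (optional Poisson resampling), quantized to 8/16 bits. Defaults
— 5 clusters of radius 30–45 px, 120 cells of $\sigma = 6$ px each,
amplitude 150 on a 16-bit range, noise SD 3 (SNR > 5) — emulate 10×
confocal fields of well-separated aggregates 16 h after plating. The high
per-cluster cell count is deliberate: a maximum z-projection of a 3D ball
of cells is densely overlapped, and sparser renderings leave near-background
pockets inside aggregates that no global threshold can claim. Three layouts:
`mixed` (uniform over the cluster disk), `sorted` (red half-disk vs green
half-disk along the column axis), `engulfed` (red core of configurable
radius fraction vs green annulus); in the non-mixed modes each cell is
independently relocated to a uniform position with probability
`mixing_m`, so $m = 1$ is fully intermixed in every mode. The generator
does not model sorting dynamics, cell shape, optics beyond the blob, or
z-structure; conclusions from it concern the measurement chain, not the
biology of sorting.

**EVL mosaics.** Seeds are Lloyd-relaxed (3 iterations) in a rectangle (or
masked disk), and the Voronoi mosaic — computed exactly via mirrored seeds
— is rasterized with bright boundaries (~2 px nominal, intensity 200 over
interior 40) plus a nuclear channel with one bright blob per mitotic cell.
The number of mitotic cells is `round-half-up(fraction × n_cells)`, stated
so tests can be exact. Two generator-side regularizations keep the ground
truth faithful at pixel resolution: (1) seeds incident to Voronoi edges
shorter than 7 px are nudged apart until none remain — near-degenerate
vertex pairs are unresolvable at pixel scale and would read as spurious
arity-4/5 junctions; (2) rosettes are injected by moving the $k$ seeds
nearest a chosen interior site onto a circle around it, making the center a
degenerate Voronoi vertex where exactly those $k$ cells meet with equal
$2\pi/k$ wedges. An edge-collapse injection was tried first and rejected:
collapsing spread-out vertex groups produces arbitrarily thin wedges whose
cells recede tens of pixels behind the rendered boundary, so the collapsed
rosette under-reports its arity when detected. Ground-truth junctions merge
vertices closer than `junction_merge_px` (default 4 px ≈ the detector's
resolution), so a degenerate vertex cluster is one junction with the union
of its incident labels.

**Epiboly tables.** Stage reference times follow standard staging (dome
4.33 h through 100% epiboly 10 h). Each repeat has a technical clock shift
(SD `noise_sd_h`); the wild-type dome record *is* the event that sets that
clock, so it carries the shift and no additional jitter, while every other
record adds independent staging jitter. This matters: the normalization
step subtracts the observed wt dome offset from all records of the repeat,
and if the dome record carried its own noise that noise would propagate
into every record as an unmodeled block effect, making the two-way ANOVA
conservative (non-uniform null p, reduced power). Under the clock-anchor
model, post-normalization records are independent and the ANOVA assumptions
hold exactly. Mutant times add the genotype delay at all post-dome stages;
a running maximum within (genotype, repeat) preserves stage ordering under
jitter.

**qPCR tables.** Perfect efficiency (one cycle per doubling; the efficiency
base is exposed as a parameter), per-sample RNA-loading offsets that cancel
in housekeeping normalization, and triplicate CT noise. A true log2 fold of
$+f$ lowers the mutant CT by $f$ cycles.

## Study-scale statistics

The two-way ANOVA is computed from the balanced sum-of-squares
decomposition (the SS identity is a test invariant), with p-values from the
F distribution. The dome stage is excluded from the model: after
normalization the wild-type dome time is pinned to 4.33 h with zero
variance — it is the anchor, not a measurement — and the genotype delay is
defined at the stages after it. Per-stage post-hoc contrasts use the pooled
residual MS (the standard post-hoc after a two-way ANOVA) with Bonferroni
correction over the post-dome stages, capped at 1. Degenerate inputs are
reported, not raised: zero genotype SS gives $F = 0$, $p = 1$.

Group comparisons default to the repeat as the experimental unit (an
unpaired equal-variance t-test on per-repeat intermixed fractions, Welch
optional), matching a design of a few independent experiments each
contributing many clusters; per-cluster testing is available by passing
cluster-level values directly. Both-groups-constant comparisons report
$t = 0$, $p = 1$.

ΔΔCT: per sample, $\Delta C_T = \overline{C_T}(\text{gene}) -
\overline{C_T}(\text{housekeeping})$; $\Delta\Delta C_T$ subtracts the
calibrator sample's $\Delta C_T$; $RQ = 2^{-\Delta\Delta C_T}$, aggregated
per gene × genotype as mean ± SEM. The calibrator's own RQ is exactly 1.

## Benchmark problem sizes

The benchmark suite (`segmix.benchmarks`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses: calibration
disks of radius 100 px; 50 random 64×64 images for the Li oracle; 30
clusters per mixing level across 5 levels (full segmentation path); group
comparison at 2 groups × 3 repeats × 300 clusters × 50 replicates, with
ROIs taken from manifest disk masks to isolate the statistic from the
detector (which has its own recovery benchmarks); 100-cell mosaics for EVL
recovery; 200 simulations for epiboly power and 500 for null uniformity.
The group benchmark's engulfed-mode mixing levels (0.495 and 0.41 at 20
cells/cluster) were calibrated once so the two groups sit near intermixed
fractions of 0.56 and 0.43 — the scale of contrast the method is meant to
resolve — and are fixed constants of the benchmark.

## Known limitations

* No pixel-size calibration: the emulated 10× optics are not calibrated to
  physical units, and all lengths are reported in pixels.
* The sorted-mode generator preserves each channel's radial distribution,
  so S (and the intermixed fraction) carries no information about
  sorted-mode mixing by construction; benchmarks that need a
  mixing-sensitive intermixed fraction use the engulfed mode.
* Touching aggregates are not split (each connected object is one
  aggregate) and fixed fields only — no time-lapse tracking.
* The watershed's small-region merge is area-based only; it does not
  inspect boundary support, so heavy over-segmentation of genuinely large
  regions would not be corrected.
* Passing the synthetic benchmarks shows the measurement chain recovers
  known ground truth under the stated imaging model; it does not validate
  the chain against unmodeled features of real microscopy (uneven
  illumination, z-bleed-through, debris, touching clusters).
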