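# Methods

This note documents the models, estimators and design choices in `viscmap`,
in the spirit of a methods appendix: what is computed, under which
assumptions, with which defaults, and what the synthetic benchmarks do and
do not demonstrate about real data.

## 1. Diffusion model and simulator

Molecules perform independent 2-D Brownian motion in a rectangular membrane
patch. Per frame interval Δt, displacements are drawn per axis from
N(0, 2·D·Δt). Boundaries — the field edge and, for confined molecules, the
walls of their raft square — are **reflective**, implemented exactly by the
triangle-wave folding of the unbounded path (reflected Brownian motion is
the image of free Brownian motion under that map, so the discretisation
introduces no boundary bias). Reflection conserves molecule count and avoids
edge artefacts in quadrat means; the alternative (absorbing or periodic
edges) would deplete or alias boundary quadrats.

Photobleaching gives each molecule an exponential lifetime with rate
k<sub>bleach</sub> (default 0.2 s⁻¹, typical of a Cy3B-class organic dye
under single-molecule TIRF illumination; an eGFP-class tag is ≈ 0.4 s⁻¹).
Lifetimes are truncated at the end of the video. Fresh molecules can enter
the evanescent field as a Poisson process (`influx_rate`); the default is
**0**, i.e. the visible population decays from its initial density. This is
deliberate: the canonical benchmarks state an *initial* density
(0.8 µm⁻²), and the dispersion of quadrat means they report is only
consistent with the ~720 molecules of a decaying population (a steady-state
population would contribute ~10× more segments per quadrat and shrink the
quadrat-mean SD ~3-fold). `balanced_influx_rate()` provides the
steady-state alternative (influx = density × bleach rate).

Raft domains are non-overlapping axis-aligned squares (default
300 × 300 nm) placed uniformly by rejection sampling. Occupancy is one
confined molecule per raft, confined for its whole lifetime — no hopping in
or out. In the two-region scenario the raft half and the free half start at
the same molecule density, so the raft number density equals the molecule
density.

Positions are sampled at frame instants by default. An optional
substep-averaging mode (`substeps = k`) averages k intra-frame positions to
emulate full-exposure motion blur (which lowers the lag-1 MSD by up to a
factor 2/3); it is off by default because the benchmarks are reproduced
without it.

### Camera model

`render_video` renders each live molecule as a pixel-integrated Gaussian PSF
(error-function integrals per pixel), applies Poisson shot noise to signal +
background photons, multiplies by the camera gain, adds Gaussian read noise
and an offset, and quantises to the bit depth. Defaults (100 nm pixels, PSF
σ = 0.13 µm, 250 signal photons/frame, 10 background photons/pixel, gain 20,
read noise 2 counts, offset 100, 16 bit) are calibrated so that repeated
Gaussian-fit localization of a rendered static spot scatters with ≈ 16 nm
rms per coordinate — a 33 nm 2-D frame-to-frame rms, i.e. an apparent static
MSD (noise floor) of 4σ² ≈ 1.1 × 10⁻³ µm². The fast path
(`observe_tracks`) skips rendering and adds N(0, σ<sub>loc</sub>²) noise per
coordinate directly, with the same default σ<sub>loc</sub> = 16.5 nm.

## 2. Detection and linking

Spots are detected per frame on a matched-filtered image (Gaussian smoothing
at σ = 1 px) — thresholding the raw image instead would admit single-pixel
Poisson spikes, whose tail at 4 background SDs is far heavier than
Gaussian. Candidates above background median + 4 × MAD-SD are refined by
least-squares 2-D Gaussian fits in a 7 × 7 px window; fits that diverge,
leave the window, or return a PSF width outside 0.06–0.35 µm are discarded;
saturated candidates are flagged.

Linking is greedy nearest-neighbour with a 0.7 µm/frame gate and **no gap
closing**. The design premise is auditability over completeness: whenever an
assignment is ambiguous — two active tracks within the gate of one detection
(spots merged during a frame) or one track torn between detections — every
involved track terminates and the merged detection seeds nothing; fresh
tracks start at the next unambiguous detections. This reproduces the
characteristic truncation of tracks at every fluorophore encounter; the cost
is shorter tracks at high density, which is exactly the regime the windowed
estimator is built for. Tracks shorter than 10 frames are excluded from
analysis (kept in the raw output). Long-lived tracks whose rms spread stays
below 2 × (2σ<sub>loc</sub>) ≈ 66 nm for ≥ 50 frames are classed as stuck
objects (non-specifically bound dye) and removed.

Stage drift is estimated per frame by phase cross-correlation against the
average of the first 10 frames with sub-pixel refinement, and subtracted
from detection coordinates. Simulated videos are drift-free, so the
estimator is validated on synthetically injected shifts.

## 3. MSD estimation

MSD curves use **all overlapping pairs** at each lag. The pairs are
correlated, so the per-lag values do not come with analytic standard errors
— none are needed, because only point estimates flow downstream (averaging
over segments and quadrats supplies the dispersion).

D_lat is the initial slope / 4, by OLS over the **first 4 lags with a free
intercept**. The choice of 4 lags balances two regimes: enough points above
the noise floor for a stable slope, but short enough to stay near-linear for
confined motion. The intercept is always free so the localization noise
floor (4σ²) loads on the intercept, not the slope; forcing the line through
the origin would inflate free-diffusion estimates by ≈ 0.003 µm² s⁻¹ at the
default noise level. Negative fitted D_lat values on slow/noisy segments are
**retained** in all statistics (clipping at zero would bias quadrat means
upward); map rendering clips at zero for display only.

Windows are sequential, non-overlapping, exactly 10 points (trailing
remainders dropped), so one window supplies lags 1–9. Consequences: (a)
window estimates from one track are independent given the diffusion model
(non-overlapping increments); (b) curvature diagnostics on quadrat-averaged
curves use the lag-9/lag-1 MSD ratio (≈ 9 for free diffusion, systematically
smaller under confinement) since lag 10 would need 11-point windows.

The distribution of window estimates at fixed D is strongly right-skewed and
well approximated by a gamma distribution. The gamma is an approximation,
not the exact law of the 4-lag OLS slope: its best fit sits at a KS distance
of ≈ 0.03 from the empirical distribution, so a KS *p*-value at very large
sample sizes will reject it even though it describes the data far better
than any normal. The tests therefore assert the adequacy as a CDF-distance
bound plus skewness, not as a large-n p-value.

Photobleaching rates are estimated two ways (both exposed): nonlinear least
squares of A·e^(−kt) to visible-count time courses, and the exact ML
estimator k = 1/mean on track lifetimes.

## 4. Quadrat analysis

The grid is anchored at the lower-left corner of the analysed bounding box
(grid registration is otherwise arbitrary); cells are half-open, so a
centroid exactly on an interior boundary belongs to the higher-index cell.
Each segment is assigned to **the cell containing its window centroid** —
unambiguous for windows that straddle boundaries. Segments outside the grid
fall into a reported overflow bin, so segment counts are conserved.

A quadrat is included when it holds at least **5 trajectory segments of
≥ 10 points** (`count="segments"`, the default; `count="tracks"` counts
distinct parent trajectories instead). The segment reading matches the
benchmark quadrat counts: in tracking practice trajectories are fragmented
at every fluorophore encounter, so "5 trajectories" and "5 segments" nearly
coincide there, whereas idealized (unfragmented) trajectory-mode data under
parent counting would exclude most confined quadrats (~3 long-lived parents
per 2 × 2 µm cell at the default raft density) and misrepresent the method.
Included quadrats average their segments' MSD curves **lag-by-lag,
unweighted** (pair-count weighting is available via `weighting="pairs"`) and
refit the initial slope with the same 4 lags as segment fits, for
comparability.

Named regions (e.g. the raft and free halves) are sets of cells: a cell
belongs to **every region its rectangle overlaps**, so a column of cells
straddling a region boundary is counted in both regions. This mirrors how
adjoining membrane regions share boundary quadrats and makes the two region
sample sizes sum to slightly more than the total.

Maps: the track-level heat map rasterises each segment's path, dilates it to
5 px (0.5 µm at the default 100 nm display pixels) and paints it with the
segment's D_lat; overlapping pixels hold the mean of contributing values,
untouched pixels are masked, never zero-filled. The quadrat raster holds one
value per included cell. Fast/slow classification uses mean ± 1.5 SD of the
included quadrat means.

## 5. Statistics

"Mean D_lat" always means the **mean of the quadrat means**. Normality of
the quadrat means is tested with a one-sample KS test against a normal whose
mean and SD are estimated **from the same sample** (exact finite-n null for
n ≤ 100, asymptotic Kolmogorov law above). Estimating the parameters from
the sample makes this test conservative (its p-values are inflated); the
Lilliefors correction is available (`ks_variant="lilliefors"`) but is not
the default because the uncorrected procedure is the one the quadrat method
is calibrated against, and its conservatism only strengthens a "not normal"
verdict. The verdict threshold is α = 0.05; all tests are two-sided.

Pairwise group comparisons select the test from the two normality verdicts
alone (a pure, auditable rule): Welch's unequal-variance *t* with
Satterthwaite df when both groups are normal, Mann–Whitney *U* otherwise.

## 6. What the benchmarks show — and what they do not

The synthetic scenarios emulate: realistic molecule densities (0.8 µm⁻²),
photobleaching-limited track lengths, localization noise at the measured
noise floor, raft-scale confinement, and (in rendered mode) shot-noise-
limited EMCCD imaging with detection and linking failures. They do **not**
emulate: fluorophore blinking, raft hopping or finite raft lifetimes,
cytoskeletal picket-fence corralling, ER-network geometry, anisotropic or
position-dependent free diffusion, stage drift, or uneven illumination.
Passing benchmarks therefore demonstrates that the estimator and statistics
recover known inputs under idealized-but-realistic imaging physics, not that
every biological source of anomalous diffusion is identified correctly.

Known quantitative behaviours, measured on the benchmarks:

* The free-diffusion pipeline recovers the input D to within a few per cent;
  the quadrat-mean of a D = 0.2 µm² s⁻¹ field reads ≈ 0.198 (mixed-boundary
  cells and estimator noise account for the small deficit in the two-region
  case, where the free half reads ≈ 0.188).
* Confined motion is *systematically* under-read by the free-intercept
  initial-slope fit (≈ 0.015 for true D = 0.02 in 300 nm rafts) because the
  MSD curve already bends over the first 4 lags; this is a property of the
  estimator, shared by any slope-based reader of curved MSDs, and is why
  the curvature diagnostic accompanies the point estimate.
* The quadrat-mean SD is dominated by counting statistics of segments per
  quadrat; it is reproduced only at the correct total segment budget, which
  is why the decaying-population default matters.

## 7. Problem sizes and determinism

Default scenario size is a 30 × 30 µm field for 2000 frames at 33 fps
(≈ 60 s), ≈ 720 molecules, ≈ 11 000 windows, 225 quadrats — a full analysis
runs in well under a second after simulation (~2 s total). Replicated
calibrations in the test suite (type-I error, CLT normality rates) use
reduced fields (15–18 µm) and 50–10 000 replicates as noted per test, chosen
to keep each statistical check's Monte Carlo error well inside its asserted
margin. All randomness flows through `numpy.random.Generator` seeded from
explicit integers; identical seeds give bit-identical tracks, videos and
outputs, and the CLI records seed + config hash + versions in a provenance
file per run.
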