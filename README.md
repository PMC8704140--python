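# viscmap

**Quadrat-sampled membrane viscosity mapping from single-molecule
trajectories, with a Monte Carlo TIRFM simulator.**

Single fluorophore-tagged membrane proteins act as nanometre-sized probes of
their lipid environment: the lateral diffusion coefficient *D*<sub>lat</sub>
of a transmembrane protein is (to first order) inversely proportional to the
local membrane viscosity. `viscmap` turns single-particle tracking data from
total-internal-reflection fluorescence (TIRF) video into **maps of local
membrane viscosity** and **statistical tests for membrane heterogeneity** —
is protein mobility uniform across the cell surface, or are there regions
(lipid-raft-like domains, organelle networks, poorly mixed patches) where
diffusion is measurably slower?

It is written for single-molecule biophysicists who have either trajectory
tables (CSV of track id, frame, *x*, *y*) or raw multi-page TIFF video, and
for method development: a matching object-based Monte Carlo simulator
generates ground-truth diffusion scenarios (free, raft-confined, or mixed),
optionally rendered into realistic EMCCD-like camera frames.

## Method

For each trajectory of at least 10 consecutive frames (linked with a
≤ 0.7 µm/frame displacement gate), the mean squared displacement is computed
over all time intervals d*T*:

```
MSD(dT) = ⟨ (x(t+dT) − x(t))² + (y(t+dT) − y(t))² ⟩
```

For free 2-D Brownian motion `MSD(dT) = 4 D_lat dT + 4 σ_loc²`, where
σ<sub>loc</sub> is the localization error (the noise floor enters as a
constant offset). *D*<sub>lat</sub> is the initial slope / 4, fitted by
ordinary least squares over the first few lags with a free intercept.
Downward curvature of MSD vs d*T* indicates anomalous (confined) diffusion.

Trajectories are chopped into sequential **10-frame windows** (~0.4 s at
33 fps), each yielding a local *D*<sub>lat</sub> estimate at the window's
centroid. The field is then divided into a checkerboard of **quadrats**
(1–4 µm² cells); each quadrat with enough data (≥ 5 trajectory segments)
averages its windows' MSD curves lag-by-lag and refits the initial slope,
giving one local *D*<sub>lat</sub> per quadrat.

The statistics rest on the central limit theorem: individual window
estimates are gamma-distributed (few displacements each), but under spatial
homogeneity the **per-quadrat means are normal**. A one-sample
Kolmogorov–Smirnov test of the quadrat means against a fitted normal
therefore provides the heterogeneity verdict, and named regions are compared
pairwise with Welch's *t* (both normal) or Mann–Whitney *U* (otherwise).

## Worked example

Simulate the two-region benchmark — the left half of a 30 × 30 µm membrane
covered with 300 × 300 nm raft domains, each confining one molecule at
*D* = 0.02 µm² s⁻¹, the right half free at *D* = 0.2 µm² s⁻¹ (both at
0.8 molecules µm⁻², photobleaching 0.2 s⁻¹, 33 fps, ~60 s, 33 nm 2-D
localization noise floor) — and run the full analysis:

```python
import viscmap as v

scen = v.two_region_scenario(seed=1)
trajs = scen.observe()                      # observed tracks, um
W = H = 30.0
model = v.QuadratMobilityModel(
    trajs, scen.config.frame_interval,
    grid=v.QuadratGrid((0, 0), 2.0, 15, 15),
    regions={"raft": (0, 0, W/2, H), "free": (W/2, 0, W, H)})
res = model.fit()
print(res.summary())
```

prints

```
Quadrat mobility analysis
============================================================
trajectories (>= 10 frames): 680
segments (10-frame windows): 11327
grid: 15 x 15 cells of 2.0 um; inclusion: >= 5 segments
------------------------------------------------------------
group               mean      SD     n    KS D         p  verdict
all quadrats       0.108   0.091   224   0.251     1e-12  not-normal
free               0.188   0.040   120   0.126    0.0447  not-normal
raft               0.030   0.043   119   0.377  3.85e-15  not-normal
free vs raft: mann_whitney stat=13937.500, p=4.66e-37
units: D_lat in um^2/s
```

Reading this: 680 tracks of ≥ 10 frames yielded 11 327 windowed estimates;
224 of the 225 quadrats had enough data. The pooled quadrat means
(0.108 µm² s⁻¹) are decisively **not normal** (KS *p* ≈ 10⁻¹²) — the
heterogeneity is detected. Per region (a cell straddling the midline counts
in both regions), the free half reads 0.188 µm² s⁻¹, slightly below the
input 0.2 because boundary cells mix in confined segments; the raft half
reads 0.030 µm² s⁻¹ — interior raft cells sit near 0.015 (confinement
curvature depresses the initial-slope fit below the input 0.02) while
boundary cells visited by free molecules pull the region mean up. The
Mann–Whitney test separates the regions at *p* ≈ 10⁻³⁷. A homogeneous
control (`v.homogeneous_scenario`) instead gives mean ≈ 0.199, SD ≈ 0.027
and a "normal" verdict. `res.plot_map()`, `res.plot_quadrats()` and
`res.plot_hist()` draw the track-level heat map, the quadrat raster and the
quadrat-mean histogram.

The same pipeline runs from the shell:

```sh
viscmap simulate --config cfg.yaml --out run/      # tracks.csv (+ TIFF)
viscmap track    --config cfg.yaml --out run/ video.tif
viscmap analyze  --config cfg.yaml --out run/ run/tracks.csv
viscmap report   --config cfg.yaml --out run/ run/quadrats.csv
```

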