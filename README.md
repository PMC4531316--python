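# fretrack

Automated image analysis for the spatiotemporal coordination between a
FRET-biosensor signal and cell-edge protrusion.

When an endothelial cell is released from a confining micropatterned well it
polarizes and protrudes, and membrane-localized kinase activity (read out as
the donor/acceptor — ECFP/FRET — emission ratio of a biosensor) reorganizes
along the edge within minutes. Quantifying *where* and *when* the signal
changes relative to the motion requires tracking the whole evolving cell
outline, sampling both quantities in small windows along it, and correlating
the resulting spatiotemporal maps. `fretrack` implements that pipeline for
two-channel time-lapse TIFF stacks, plus a ground-truthed synthetic movie/map
generator so every stage is testable without microscopy data. It is aimed at
quantitative cell biologists and image-analysis developers working on edge
dynamics and biosensor imaging.

## Method

**Boundary tracking.** The cell outline Γ(t) in each frame is detected by
k-means clustering of the intensity layers, and embedded as the zero level of
a signed-distance function φ(x, y, t) (negative inside). Consecutive outlines
are connected by evolving φ under the Hamilton–Jacobi equation

    ∂φ/∂t + V |∇φ| = 0,   V = −φ_next ,

so the front moves along its normals and stalls on the next frame's boundary,
producing intermediate contours. Each reference point on Γ(t) is chased
through the intermediates by nearest-point projection and lands on Γ(t+1) as
a 1-D arc-length ("spline index") parameter; geometric conflicts in the raw
matches (missing matches, crossing vector pairs, vectors opposing the local
motion) are repaired by circular interpolation, circular isotonic projection,
and neighbor-consistent re-assignment, each repair flagged.

**Edge sampling.** A peripheral band (pixels with −depth ≤ φ < 0; default
depth 0.5 µm) is divided into windows of fixed arc width (default 1.25 µm).
Windows are material: fixed arc intervals on the first frame, propagated
through the correspondence. Per window and frame the mean ratio S(t) is
sampled, and the mean normal displacement is integrated from the release
frame into the boundary translocation B(t) (protrusion positive, B = 0 at
release).

**Classification.** Windows whose post-release peak translocation reaches
≥ 75% of the cell's maximum are protrusive (P); circularly contiguous P-runs
are the P-regions, and a cell is *polarized* iff it has exactly one.

**Cross-correlation.** Signal/motion coordination is measured by the globally
normalized temporal cross-correlation

    ρ(τ) = Cov(S(t), B(t+τ)) / (σ_S^max σ_B^max),

with the covariance over the overlapping samples after centering each series
by its full-length mean, and σ^max the maximal per-window standard deviations
of the centered time courses across the whole map — windows with little
change are down-weighted rather than inflated. Because S falls while B rises,
coordination appears as a *negative minimum*; a **positive lag τ at the
minimum means the ratio change precedes the motion**. The spatial analog
correlates circular line scans across windows at each time step (zero shift =
co-located). Group comparisons use percentile-bootstrap means (5000
resamples) and Welch t-tests.

## Worked example

Simulate a polarized cell at the window-map level (64 edge windows, 50 frames
at 1 min, release at frame 10, one protruding sector with a programmed
10-minute lead of the ratio drop over the motion) and correlate the maps:

```bash
fretrack simulate --scenario POL-A --seed 7 --out demo/sim
fretrack correlate --ratio-map demo/sim/ratio_map.csv \
                   --transloc-map demo/sim/translocation_map.csv --out demo/cc
```

`demo/cc/cc_minima.csv` then contains, for the protrusive windows 20–31:

```
 window  min_value  min_lag_min  no_negative_minimum
     20  -0.970279         10.0                False
     21  -0.938949         10.0                False
     22  -0.938495         10.0                False
     23  -0.943965         10.0                False
```

The median lag over the sector is **10.0 min** with a median CC minimum of
**−0.93**: the correlation analysis recovers the programmed lead exactly —
the ratio drop precedes protrusion by ten minutes — and the deep negative
minimum says the two time courses are tightly (anti-)coordinated. Windows
outside the sector show no meaningful negative minimum.

The full image pipeline runs on a rendered two-channel movie the same way:

```bash
fretrack simulate --scenario POL-C --seed 11 --out demo/movie
fretrack all --config demo/movie/config.yaml \
             --donor demo/movie/donor.tif --acceptor demo/movie/acceptor.tif \
             --out demo/analysis
```

which prints a summary including `"cell_class": "polarized"` and the peak
window translocation (≈ 28–30 µm at 10 min post-release for this scenario's
programmed 30 µm front advance).

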