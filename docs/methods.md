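# Methods

This note documents the models, numerical choices and known limitations of
`fretrack`, in the order the pipeline runs.

## Ratio imaging

The donor/acceptor ratio represents the biosensor readout; it is computed
pixelwise after per-frame, per-channel background subtraction. Background is
estimated as a low percentile of the whole frame (default the 5th): the cell
occupies a minority of the field of view, so a low percentile tracks the
non-cell background without needing a segmentation first. Negative residuals
are clipped to zero, which makes the operation idempotent up to clipping.

Pixels whose acceptor intensity falls below `min_intensity` are masked
(NaN), never zeroed: a dim denominator makes the quotient noise-dominated,
and only biosensor-expressing regions should be quantified. The default
threshold is 3× the post-subtraction background standard deviation,
estimated from the dimmest 20% of acceptor pixels per frame (median over
frames). Ratio images are not smoothed by default; an optional median filter
(radius in pixels) is exposed in the run configuration because no single
filter suits all data.

## Boundary detection

Frames are segmented by 1-D k-means on intensity with k = 3 layers
(background, dim periphery, bright body) — the minimal choice that admits a
dim-edge layer. Centroids are initialized on evenly spaced intensity
quantiles, making the clustering deterministic. A class counts as foreground
only if its centroid exceeds the background centroid by **both** 3 background
-class standard deviations **and** 10% of the centroid dynamic range: with
fewer true intensity layers than k, k-means splits the unimodal background,
and without the margin roughly half the background pixels enter the mask and
percolate into one giant component. For clean layered images the margin is
inactive and every brighter-than-background class is kept. Detection runs on
the raw acceptor channel (configurable: donor or sum) rather than the
background-subtracted one, because clip-at-zero subtraction distorts the
background statistics the margin relies on.

The mask is closed (radius 1 px), hole-filled, and reduced to its largest
connected component (minimum area 100 px); the outer boundary is extracted
with marching squares at sub-pixel resolution. Contours are stored in
micrometers, positively oriented (interior on the left), with pixel centers
at integer coordinates, x rightward, y downward.

## Level-set tracking

The signed distance is computed exactly — KD-tree queries against the
contour densified to a tenth of the grid spacing, sign from a
point-in-polygon test — rather than by a grid fast-marching sweep; this
keeps the zero level accurate to well under a grid cell, which the
correspondence step needs.

Evolution uses the normal speed V = −φ_next, the signed distance to the
target frame's boundary: the front provably moves toward the target zero
level and stalls on it, the natural morphing speed for contour-pair
interpolation. The speed is clipped at 5 grid cells — this leaves the
zero-level dynamics unchanged near the front but keeps the CFL time step
(CFL number 0.5) from collapsing when far-field distances are large. The
spatial scheme is first-order Godunov upwind with forward-Euler stepping; φ
is reinitialized to exact signed distance every 25 steps. Convergence is
declared when max |φ_next| on the current front falls below half a grid
cell (checked every 5 steps); failure within 500 steps raises a tracking
error carrying the residual. Ten intermediate contours per frame pair are
kept by default — enough for stable point-chasing at the advance rates the
generator produces, without the cost of a very small step length.

Correspondence chases reference points (0.5 µm spacing on Γ(t)) through the
intermediates by nearest-point projection and records the arrival arc
parameter on Γ(t+1). The arc-length origin of each contour is anchored at
the vertex nearest the previous frame's origin (first frame: topmost, then
leftmost vertex) so window identities stay stable. Conflicts are corrected
in a fixed order:

1. **missing** matches → circular linear interpolation of neighboring
   targets;
2. **crossing** pairs → circular isotonic (pool-adjacent-violators)
   projection of the unwrapped target sequence — one deterministic pass
   that also handles runs of crossings, unlike local pair swapping;
3. **direction** conflicts → vectors opposing the local mean motion
   (negative dot product over a ±5-point window) are re-assigned by
   neighbor interpolation. Both the vector and the local mean must exceed
   0.25 µm; below that scale apparent direction flips are detection jitter,
   and correcting them corrupts static boundaries.

Corrections are flagged per point; more than 50% flagged points raises a
tracking-quality error. After correction the target sequence is circularly
non-decreasing (no crossings).

The correspondence is geometric (nearest-normal), not material: on a rigidly
translating circle, side points map with near-zero normal motion. The
consistency that holds — and is tested — is that composing t→t+1→t+2 agrees
with the directly computed t→t+2 map.

## Edge windows and translocation

The sampling band is the set of pixels with −depth ≤ φ < 0 (default depth
0.5 µm); it is divided into ⌊perimeter/width⌋ windows of equal arc width
(default 1.25 µm), each band pixel assigned by the arc parameter of its
nearest boundary point. Windows are material: the frame-0 arc intervals are
propagated through the correspondence's target parameters, so widths drift
where the edge stretches and are deliberately not re-equalized. Window
displacement is the mean of the correspondence vectors whose source
parameter falls in the interval, projected on the outward normal at the
interval midpoint (protrusion positive); windows without reference points
are filled from neighbors and flagged. Displacements are integrated into
the translocation B(w, t), zero at the release frame with negative backward
partial sums before it, so translocation reads as "location change since
the constraint was removed".

With 0.5 µm pixels the 0.5 µm-deep band is a single-pixel ring and a
1.25 µm window holds only ~2–3 pixels, so windows with fewer than 3 valid
ratio pixels report missing values; at that resolution a majority of ratio
samples can be missing while the translocation (which derives from the
correspondence, not band pixels) is unaffected. Finer pixel grids fill the
band; the missing-value contract (NaN, never silent zeros) propagates
through map assembly, which linearly interpolates only single-frame gaps.

## Classification

Per window the peak translocation over post-release frames is computed
(pre-release translocation is ≈ 0 by construction of the baseline); windows
reaching ≥ 75% of the cell maximum are P. The threshold is inclusive, so the
argmax window is always P before filtering. Circular runs shorter than 3
windows are suppressed and runs separated by ≤ 1 NP window merged — both
config-exposed — to keep single-window noise from manufacturing spurious
regions. Peak means positive B (protrusion); magnitude of retraction is not
classified. A cell is polarized iff exactly one P-region survives.

## Cross-correlation

Temporal: ρ(τ) = Cov(S(t), B(t+τ)) / (σ_S^max σ_B^max). Series are centered
once by their full-length means; at non-zero lag the covariance is the mean
product over the truncated overlap (no padding), lags with fewer than 5
overlapping finite pairs are omitted, and missing samples are dropped
pairwise. σ^max are the maxima over windows of the centered time-course
standard deviations, so |ρ| for any window never exceeds its own-normalized
value — low-change windows are down-weighted by design. Default maximum lag
is half the post-release duration; beyond that the overlap is too short to
be meaningful. **Sign convention: positive τ at the minimum means the ratio
series leads the translocation series.** Minima are the most negative
coefficients; ties break to the smallest |lag|, then the positive lag; a
curve with no negative value is flagged rather than erroring.

Spatial: circular line scans across windows at one time step, normalized by
the maxima over time steps of each map's spatial standard deviations
(computed separately per map, mirroring the temporal case). Zero shift at
the minimum means signal change and motion are co-located.

A property worth knowing: with this truncated, full-mean-centered estimator,
two monotone sigmoid series whose transitions are wide relative to the
record show a systematic ~1-frame downward bias of the minimum's lag — the
centered plateaus at the record ends contribute large negative products that
truncation removes asymmetrically. The synthetic scenarios place their
transitions in the sharp regime where the recovered lag equals the
programmed lead exactly (see below).

## Statistics

Bootstrap means use the percentile method, 5000 resamples by default,
deterministic given the seed. Group comparisons use the Welch
unequal-variance t-test (the safe default when variances are not known to
match); one-tailed tests halve the two-sided p-value in the hypothesized
direction, and two zero-variance samples with equal means return p = 1.
Windows are the sampling unit when pooling across cells; per-cell
pseudo-replication is documented here as a caveat but not corrected — a
mixed-effects treatment is out of scope.

## Synthetic data

The generator emulates a single cell confined in a 20 µm × 80 µm elliptic
well, released at a known frame, with one or more edge sectors protruding
while the ratio in the same sectors drops with a programmable lead τ.

*Map level* builds windows × frames matrices directly:
B(w,t) = A·h(t) and S(w,t) = 1 − 0.15·h(t + τ) with one shared logistic
profile h affinely normalized to [0, 1] on the frame grid, plus i.i.d.
Gaussian noise scaled by each signal's dynamic range (default 5%). The
equal-shape construction makes the programmed lead the cross-correlation-
recoverable lag; the logistic steepness is 0.4 min, chosen at design time so
that this identity holds exactly on the 50-frame grid for leads of 0, 10 and
15 min under the truncated estimator (see the bias note above). This implies
a rapid protrusion onset — realistic for a constraint-released cell, whose
stored cortical tension is released at once.

*Image level* renders two-channel movies: the initial ellipse grows outward
along local normals inside the sector, whose angular weight is flat-topped
(full advance over the central 60%, cosine-squared roll-off at the ends) —
a broad uniform front, like a lamellipodium; a fully cosine-tapered front
combined with material window propagation would dilute window-mean
displacement at the highly curved ellipse tip. Boundary pixels are rendered
with area-fraction anti-aliasing (3×3 sub-pixel rasterization), the
acceptor at 1000 counts inside / 50 outside, the donor as acceptor × ratio
field, then Poisson shot noise and Gaussian read noise (SD 10 counts). The
temporal profile completes exactly at release + 10 min, so the programmed
front advance at that time is exactly the scenario's 30 µm. Registered
scenarios: POL-A (single cell, map level, τ = 10 min), POL-B (3-cell
ensemble, τ = 15 min, ±10% per-cell advance jitter), NP-A (three sectors,
τ = 0), POL-C (rendered movie, 256×320 px at 0.5 µm/px, 25 frames at
2 min).

What the generator does **not** emulate: actin/membrane mechanics,
photobleaching, uneven illumination, intracellular texture, touching cells,
or topology changes. Passing tests therefore demonstrate the correctness of
the computational pipeline on controlled kinematics and noise — not
robustness to every artifact of real microscopy.

## Problem sizes and runtimes

Unit tests run on 160×160 half-micron grids; the end-to-end tests use a
128×192 px, 8-frame rendered movie, and the full-scale check a 256×320 px,
25-frame movie (~40 s including generation). The acceptance script runs the
three registered recoveries in a few minutes total.

## Known limitations

- The geometric correspondence under-measures material motion wherever the
  edge slides tangentially (translating flanks) or stretches strongly
  (sharp, fast tips); the flat-topped synthetic front keeps this below a few
  percent, but real filopodia would be harder.
- Marching-squares contours inflate the perimeter by a few percent
  (staircase effect), which slightly raises the window count relative to the
  true perimeter.
- A 0.5 µm band on 0.5 µm pixels leaves most windows below the 3-valid-pixel
  minimum for ratio sampling (see above); choose band depth ≥ 2–3 pixels
  when the pixel size is coarse.
- Topology changes (splitting, fusion), open contours and multi-cell scenes
  are out of scope.
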