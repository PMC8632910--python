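# Models and methods

This note documents the models `omtrack` implements, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices behind the estimators.

## Kinematic model of rotation and constriction

Cluster rotation and apical constriction are modeled as three-parameter
logistics:

    R(t) = R1 / (1 + exp(-(t - t0)/tau_R))            [degrees]
    A(t) = A0 - A1 / (1 + exp(-(t - t0)/tau_A))       [um^2]

The logistic family is pinned by the rate definitions used throughout the
package: the maximum slope of a logistic is amplitude/(4·tau), so scaled to
hours the angular velocity is Ω = 60·R1/(4·tau_R) [°/h] and the constriction
rate is C = 60·A1/(4·tau_A) [µm²/h]. The wild-type preset defaults are
derived by inverting these formulas from the headline values they must
reproduce:

| parameter | value | derivation |
|---|---|---|
| R1 | 90° | the full rotation |
| tau_R | 60·90/(4·11) ≈ 122.73 min | Ω = 11 °/h |
| A0, A1 | 20, 12 µm² | plateau A0−A1 ≈ 8 µm² and ~60% constriction (A1/A0) |
| tau_A | 60·12/(4·2.5) = 72 min | C = 2.5 µm²/h |
| t0 | 250 min | mid-course of a 500-min recording |
| frame interval | 10 min | the study's acquisition rate |

### Pulses

Single clusters rotate and constrict in pulses: intervals of positive
smoothed dR/dt alternating with anti-rotation (and constriction alternating
with re-expansion). No quantitative generative form for the pulses is
published, so the generator uses a zero-mean rate modulation built from a
rectified sinusoid of period P:

    m(t) = beta * r_peak * (|sin(pi t / P)| - 2/pi),

integrated in closed form and added to (rotation) or subtracted from (area)
the logistic backbone. `r_peak = amplitude/(4 tau)` is the backbone's peak
rate and `beta` (`pulse_amplitude`) scales the modulation. Defaults P = 80
min and beta = 4 were chosen so that the rate *as the pipeline measures it* —
sampled every 10 min, differentiated, and smoothed with a 3-frame moving
average — changes sign each period, yielding detectable pulse/anti intervals
whose count matches duration/P to within one. A modulation much below
beta ≈ pi/2 can never drive the rate negative, and sampling/smoothing
attenuation raises the practical threshold well above that. The modulation
integrates to zero over whole periods, so schedules still track the logistic
on average and fits on pulsed trajectories recover the backbone parameters.

Pulse segmentation uses a centered finite difference, a centered 3-frame
(30-min) moving average, and a strict sign rule (pulse ⇔ smoothed rate > 0,
no hysteresis).

### Genotype presets

`lof` (low fluidity) and `gof` (high fluidity) are qualitative
transformations of wild type, since no numeric rates are published for them:
motility ×0.3 / ×2.5; neighbor-exchange schedule 2→1 / 10→6 per ommatidium
per frame-pair (wild type: 7→4; the GOF scaling is capped below a literal
×2.5 because exchange counts are counts of distinct first-level ICs and
cannot exceed the ring size); delaminations reduced / increased; pulse
modulation damped (beta = 2, steadier constriction) / amplified (beta = 6,
longer and more frequent re-expansion); rotation endpoint 50° (under-rotation)
/ 90° with a larger endpoint spread. These orderings — not the absolute
values — are what the comparative tests assert.

## Synthetic tissue movies

The tissue is a Voronoi tessellation of seed points in a 16×16 µm field,
rasterized at 0.04 µm/px by nearest-seed assignment (which *is* the Voronoi
partition, so polygon-level geometry and rendered labels agree to
rasterization error, ≲0.2% in area for these cell sizes).

- **Cluster**: R8 central, R1–R7 on a ring (R2 and R5 diametric, so the
  R2–R5 line starts parallel to the furrow and R(0) = 0), surrounded by a
  collar of ten cone-type accessory cells. The collar co-rotates and
  co-contracts with the photoreceptors; because it encloses them, the
  photoreceptor Voronoi cells — and hence their centroids — rotate rigidly
  instead of dragging against the static IC field (without the collar the
  measured angle systematically lags the applied rotation by ~10%). This
  mirrors the real cluster, where cone cells travel with the rotating unit.
- **Area calibration**: per frame, the rigid cluster+collar block is rotated
  by the rotation schedule, then its radial scale is solved by Brent
  root-finding so the analytic Voronoi area of the eight photoreceptor cells
  equals A*(t) exactly. Ground truth stores exactly what was applied.
- **ICs**: seeds on a jittered hexagonal lattice (1.9 µm spacing) performing
  seeded Gaussian random walks with per-frame step length set by
  `ic_motility_um_per_frame`, reflected at the field boundary and excluded
  from the cluster footprint.
- **Recruitment** is annotational: all eight photoreceptor seeds exist from
  frame 0; R1/R6 and R7 are *counted* from their recruitment frames
  (defaults 2 and 4 — the published recruitment times are not printed, so
  these are tunable). `measure_area` sums only recruited cells, so area
  round trips are exact from the R7 frame on.

What the movies deliberately do **not** emulate: photorealistic microscopy
(PSF, imaging-channel photobleaching), force-based (vertex-model) mechanics,
segmentation errors, and cell events in the rendered geometry — divisions,
delaminations and exchanges are planted in abstract cell-graph ledgers
instead, where their counts can be controlled exactly. Passing round-trip
tests therefore show the *measurement* pipeline is correct on clean tracked
input; they say nothing about segmentation quality on real movies.

## Event ledgers and detectors

Ledgers are per-ommatidium adjacency-graph sequences: cluster (8 cells), a
ring of 18 first-level ICs, and 36 outer cells. Exchanges are planted as
single-focal edge toggles between a first-level IC and an outer cell, with
the per-frame-pair count declining linearly between the preset's start and
end rates — single-focal toggles (rather than four-cell T1 quads) make the
per-frame-pair count of exchanging first-level ICs exactly controllable,
matching how the counts are defined (number of ICs that underwent exchange).
A four-cell T1 helper is provided separately for semantics tests. Divisions
split a cell into two daughters that partition its neighbors (each with half
the area); delaminations shrink a cell monotonically over three frames to
12% of its base area and then remove it, planted no earlier than the fifth
transition so the track's running-median area reflects its healthy size.
Removed cells leave no "healing" edges between their former neighbors, which
keeps planted exchange counts exact.

The exchange detector compares neighbor-identity sets per frame-pair after
(1) remapping each cell in the later frame to its earliest ancestor present
in the earlier frame and (2) discarding ids without a representative in both
frames. Consequences, verified by tests: a division alone never scores (the
daughters' remapped neighbor union equals the parent's set), a delamination
alone never scores, and detector counts equal planted counts exactly across
presets and seeds. The division detector requires a lineage split into
exactly two daughters appearing the frame after the parent's last frame,
combined daughter area within [0.6, 1.4]× the parent's, and both daughters
adjacent to the parent's footprint. The delamination detector requires a
childless track end (not at the last movie frame — censored), a monotone
3-frame area decrease, and a final area below 25% of the track's running
median (both thresholds tunable).

## Trajectories and displacement fields

IC trajectories are centroid positions relative to the instantaneous
area-weighted centroid of the recruited photoreceptors, from R7 recruitment
to 120 min after it. By default cells annotated "IC" are tracked; cone cells
co-move with the cluster and carry no independent motility signal. Each
per-frame step displacement is binned by its start position into a 1.25-µm
grid; a grid cell's vector is the mean of the steps through it, its speed
|vector|/frame-interval, interpolated onto a 4× finer grid for display. The
occupancy-weighted mean of the grid vectors equals the pooled step mean
exactly (a conservation check in the tests). With planted motility zero, the
measured IC movement is not exactly zero: cells bordering the contracting
cluster passively deform (≈0.1 µm over 2 h) — genuine kinematic signal, shown
to vanish exactly when the schedules are also frozen.

## Shape and jamming metrics

p0 = L/√A per cell, perimeter from the traced sub-pixel boundary contour
simplified with a one-pixel Douglas–Peucker pass (marching-squares contours
staircase along straight edges and otherwise inflate perimeters by ~4–9%),
area from the raw traced polygon. Isoperimetry guarantees p0 ≥ 2√π ≈ 3.545;
the regular-pentagon value 3.81 (2 d.p.) is reported as the literature
jamming threshold and is never hard-coded into pass/fail logic. Field
statistics pool first-level (adjacent to any photoreceptor, cone cells
included by default, `exclude_cones` available) and second-level neighbors,
frozen at the R7 frame, excluding border-truncated cells; the SD uses the
population convention. Polygon classes use the topological side count
(= neighbor count) binned 3…9+.

## Cross-correlation

At each integer lag the Pearson correlation of the overlapping segments is
computed, each segment standardized over the overlap. The simpler
"z-score once, average products over the overlap" estimator is biased toward
lag 0 on trend-dominated series (shrinking overlaps drop the largest
|z| values), which can mask a true shift. Note that two smooth sigmoids
correlate at ≈0.97 at *every* lag, so on raw series the lag of the maximum is
nearly degenerate; the informative signal lives in the pulsatile component,
and the coupling tests therefore correlate the first-difference (rate)
series, where the shared pulse clock produces an unambiguous zero-lag peak
and exact shift equivariance.

## FRAP

Pipeline: (1) bleach correction — the ROI is multiplied by c(t) =
ref(0)/ref(t), with ref(t) a fitted exponential decay of the mean reference
junction rather than the raw frame ratio (exact when the acquisition decay is
exponential; avoids injecting reference shot noise into the ROI); (2)
normalization I_N = (I − I_min)/(I_max − I_min) with I_max the mean of the
pre-bleach frames (5 by default) and I_min the single first post-bleach
frame; (3) least-squares fit of I_N(t) = A(1 − e^−kt), reporting mobile
fraction A, recovery rate A·k (the t = 0 slope), and T½ = ln 2/k (the
identity T½·k = ln 2 holds to machine precision by construction).

Because I_min is one noisy frame, the whole normalized trace carries a
common offset error; the fit therefore includes a bounded intercept nuisance
parameter (|c| ≤ 0.2, exactly 0 on noiseless traces, not reported as part of
the mobile fraction, disable with `fit_offset=False`). With it, at 5%
normalized noise over 50 replicate 80-point traces, bias of Â and k̂ is
≈0.3–0.8% and Â's RMSE ≈5%; k̂'s RMSE floor is ≈8–9% — the single-frame
I_min anchor adds irreducible variance on top of the ≈6–7% Cramér–Rao bound
of the exponential itself, which is why the property test checks k̂'s RMSE at
10%. Mobile fractions slightly above 1 (≤1.2) are tolerated with a warning
rather than clipped. Two-component or reaction–diffusion recovery models are
out of scope.

## Ablation recoil

The vertex distance l(t) gives normalized recoil (l(t) − l0)/l0 (exactly 0
at t = 0). The elastic model l(t) − l0 = l_f(1 − e^−t/T) is fitted by least
squares; amplitude l_f and initial speed l_f/T are derived. A trace whose
peak recoil is followed by a resorption of more than 20% of the peak (the
viscoelastic, high-fluidity regime where the junction reforms and shrinks)
rejects the elastic model: `fit_ok=False`, best-attempt parameters still
reported. The threshold is tunable; the published description of that regime
is qualitative. Fits are exposed both for single traces and for
mean-of-experiment traces (fitting the averaged recoil is the primary mode).

## Statistics

Two-sample comparisons use the two-sided Kolmogorov–Smirnov test (D =
sup|ECDF₁ − ECDF₂|, asymptotic p) and the two-tailed t test (Welch variant
by default), via scipy; an independent brute-force ECDF sweep serves as the
oracle in the tests. Binned event statistics report mean ± SEM across
ommatidia in contiguous 90-min bins, with SEM = 0 by convention when only
one ommatidium is available. Adult-eye angles are treated on [0°, 360°) —
linearized, no circular statistics — so an over-rotation peak near 270° is
representable.

## Degenerate inputs and numerical choices

Logistic fits: initialization from data extremes and the mid-amplitude
crossing; bounds tau ∈ (0, duration], amplitude ∈ [0, 2× data range];
constant series raise a fit error (no inflection); tau at the duration bound
sets a warning flag. Ω can be computed from the fitted amplitude (default —
correct for under-rotating clusters) or from a fixed nominal 90°
(`rate_fixed_amplitude`); the two agree on wild-type data. Rotation angles
are unwrapped on the 180° director period and signed so the annotated
chirality is positive; frames with a missing R2/R5 are recorded as gaps,
never interpolated. When the R7 frame is unannotated it is estimated as the
first frame where A(t) drops below 0.85 of its initial 3-frame mean; a
non-constricting series raises an alignment error. Movie generation refuses
fields that cannot hold the cluster plus an IC neighborhood, and fails
loudly if the area schedule becomes unattainable for the current IC
configuration. All generators are deterministic given (preset, seed).

## Known limitations

- Kinematic, not mechanical: schedules are imposed, not emergent from force
  balance, so the generator cannot probe mechanistic hypotheses — only the
  measurement pipeline.
- Rendered movies carry no cell events; detector tests run on graph ledgers
  whose adjacency changes are abstract (no geometry behind a planted T1).
- The pulse form (rectified sinusoid, P = 80 min, beta = 4) is a modeling
  placeholder with the right qualitative signature, not a fit to data.
- Synthetic measurement noise is Gaussian and frame-independent; real
  tracking errors are structured (drift, missegmentation).
- FRAP k̂ at realistic noise has an ~8–9% per-study RMSE floor tied to the
  single-frame I_min convention (see above).
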