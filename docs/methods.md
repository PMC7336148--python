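# Methods

This note documents the models, defaults and numerical choices behind
`dmsi`, what the synthetic cohort does and does not emulate, and the known
limitations.

## Source space and forward model

The source space is a closed triangulated surface with one current dipole
per vertex, oriented along the outward surface normal and expressed in mm.
Distances between sources are Euclidean (chord) distances throughout —
including inside the spatial-dispersion metric — not geodesic ones; this
matches the convention of localization-error metrics that compare positions
in scanner space, and makes every metric a brute-force-checkable function of
vertex coordinates.

The forward operator is the closed-form magnetic field of a current dipole
in a homogeneous conducting sphere, sampled by point magnetometers:

    B(r) = mu0/(4 pi F^2) [ F (Q x r0) - ((Q x r0) . r) grad F ],
    F    = a (r a + r^2 - r0 . r),  a = |r - r0|

with `r0` the source and `r` the sensor position relative to the sphere
center (default: the mesh centroid). Two exact properties of this model are
used as test oracles: dipoles oriented radially are silent, and the radial
field component equals that of the primary current alone (volume currents
contribute nothing to it). Conductivity does not enter the external
magnetic field of a sphere; it is carried as metadata only. Realistic
BEM/FEM head models, gradiometer baselines and coil geometry are out of
scope — externally computed gain matrices can be imported instead (HDF5 or
dense text, validated on load).

Because a perfectly spherical cortex with surface-normal dipoles would be
magnetically silent, the synthetic cortex is a "wavy sphere": a Fibonacci
lattice on the unit sphere, triangulated by its convex hull and radially
modulated (default ±12%) by a smooth deterministic angular function. The
modulation plays the role of cortical folding: normals acquire tangential
components whose magnitude varies smoothly across the surface, giving the
gain columns a realistic spread of sensitivities.

## Sensor model and preprocessing

275 point magnetometers with radial orientation sit on a 120 mm helmet-like
spherical cap; the sampling rate is 600 Hz. Preprocessing is: per-channel DC
removal, a zero-phase Q=30 IIR notch at the line frequency (60 Hz), a
zero-phase 4th-order Butterworth band-pass (0.3–70 Hz), and polyphase
resampling to the target rate. The filter family is a free choice; the
binding contract is behavioral (a pure line tone is attenuated to ≤5% RMS,
passband signals are preserved), and the tests check the contract, not the
coefficients.

Epochs are half-open 2 s windows [-1 s, +1 s) around each marked spike peak
— exactly 1,200 samples at 600 Hz with the peak at index 600. The half-open
convention was chosen over the closed 1,201-sample reading for integer
sample counts and unambiguous concatenation. Studies (averages of ≥5
same-type spikes from one run) are the unit of analysis; epochs overlapping
declared artifact intervals are excluded, and studies with fewer than five
usable epochs are rejected with a machine-readable reason.

The noise covariance is the sample covariance of the averaged epoch's
baseline. A nominal 1 s spike-free baseline cannot fit inside a 2 s epoch
while also avoiding the spike, so the default baseline is [-1.0, -0.1) s —
0.9 s, i.e. 540 samples — keeping a 100 ms guard before the peak.
Diagonal loading (default 0.1 of the mean diagonal) guarantees positive
definiteness of the rank-deficient MEG covariance; the loading fraction is
recorded in the result. The covariance is computed from the averaged
baseline (not pooled single epochs), which matches how the average's
residual noise enters the solvers.

## Linear inverse operators

All three linear solvers share the depth-weighted minimum-norm kernel
`W = R G' (G R G' + lambda C)^(-1)`:

* depth weights `R_ii = ||g_i||^(-2*gamma)`, gamma = 0.5 by default
  (0 disables weighting), clipped at the 99.9th percentile so numerically
  silent near-radial sources do not receive explosive prior variance, then
  normalized to unit mean;
* `lambda = trace(G R G') / (trace(C) snr^2)` with snr = 3 by default, the
  conventional default regularization strength of MEG toolboxes;
* maps are evaluated at the spike-peak sample only and rectified
  (`|W m|`); signed values exist only internally.

dSPM divides each source estimate by its noise sensitivity
`sqrt(w_i C w_i')`; sLORETA by `sqrt(S_ii)` with `S = W G R`, computed
diagonal-only (`S_ii = (w_i . g_i) R_ii`) to stay O(p·channels) in memory.
The sLORETA zero-error property — for noiseless data `m = G e_i` the map
maximum is at `i` — holds for any lambda and any diagonal R by the
Cauchy–Schwarz inequality in the `M^(-1)` inner product, and is verified
empirically over 50 random non-radial sources.

All solvers are invariant to a global rescaling of the gain with a matching
rescaling of the data, so the absolute gain units are internal.

## Maximum entropy on the mean (cMEM)

The MEM reference law factorizes over cortical parcels. Parcels are grown
greedily around seeds ranked by a whitened data-fit score (the cosine
between the whitened gain column and the whitened peak data), each parcel
being the graph ball of radius `neighborhood_order` (default 4) restricted
to unassigned vertices — so parcels are connected, disjoint and cover the
mesh. The activation prior alpha_k is the parcel's median score divided by
the global maximum score (uniform 0.5 for zero data).

Parcel k's reference law mixes an inactive point mass at zero (weight
1 − alpha_k) with an active zero-mean Gaussian N(0, sigma_k² Sigma0_k),
where Sigma0_k = D^(1/2) A_k D^(1/2) carries the depth weights D and
within-parcel spatial coherence A_k = I + 0.5·Adj. Such a matrix need not
be positive semidefinite on a mesh graph, so its eigenvalues are floored at
1% of their mean. The per-parcel scale sigma_k² is set so the parcel's
prior expected energy matches the energy the wMNE solution assigns to the
same vertices. This per-parcel anchoring is what differentiates parcels
spatially: parcels carrying no minimum-norm energy get near-zero active
variance and are switched off by the entropic solution. (A single global
scale anchored to the total wMNE energy was tried first and produced maps
*more* dispersed than MNE — the spatial contrast of MEM comes from the
local anchoring.)

The entropic program — maximize relative entropy subject to reproducing the
whitened peak data in expectation — is solved through its concave dual over
one multiplier per channel,

    D(xi) = xi'm - 1/2 xi'xi
            - sum_k log[(1-a_k) + a_k exp(1/2 xi' P_k xi)],

with `P_k = sigma_k² (G_k L_k)(G_k L_k)'` and `Sigma0_k = L_k L_k'`. The
unit quadratic term is the whitened-noise log-partition. The dual is
maximized by damped Newton iterations with Cholesky solves and a
backtracking line search; convergence requires the gradient infinity-norm
to fall below 1e-8 relative to the whitened data scale (max 500
iterations), and a Newton step below double-precision resolution is
likewise accepted as converged — for ill-conditioned `P_k` the raw gradient
criterion can be unreachable in float64 even at the exact optimum. The
posterior mean of parcel k is `p_k Sigma_k G_k' xi` with activation
probability `p_k`; parcels with `p_k` below `eps_off = 1e-3` (or zero
posterior mean) are set exactly to zero. Relabeling parcels does not change
the map.

## Metrics

Maps are rectified, nonnegative "intensity" vectors. Thresholding at t%
keeps vertices with amplitude ≥ (t/100)·max; at 100% only the maximum (all
tied maxima) survives. Argmax ties are broken at the lowest vertex index
(deterministic; ties have measure zero on real-valued maps). The
spatial-dispersion formula is evaluated with a final square root so the
result is in mm (`sd_squared=True` gives the squared variant); at the 100%
threshold SD collapses to Dmin, a checkable identity. SD over a thresholded
map uses the surviving amplitudes — including the zeroed vertices would not
change the value, since zeros carry no weight. Interquartile ranges use
linear-interpolation quantiles. The Ave map averages the four min–max
rescaled maps; a constant map rescales to all zeros by convention.

## Statistics

Friedman (df = k−1), pairwise Wilcoxon signed-rank with Pratt zero-handling
and Bonferroni correction (×C(k,2), capped at 1; degenerate all-zero
differences report p = 1), and Gaussian GEE with the study as cluster,
exchangeable working correlation and `metric ~ method * threshold` at the
30/60/90% thresholds. Wald chi-squares are computed per factor with the
robust sandwich covariance when the number of clusters exceeds the
parameter count, and the model-based covariance otherwise (the sandwich is
rank-deficient below that). With 5 methods × 3 thresholds the degrees of
freedom are 4, 2 and 8. A constant response (e.g. Map_Dmin identically 0
when every thresholded map touches its focus) yields degenerate p = 1
results with a warning. Patient-level summaries take the median across each
patient's studies first; all of a patient's studies are used.

## Synthetic cohort

Defaults emulate a clinical interictal MEG series: 28 patients; a truncated
geometric number of studies per patient with mean ≈ 7.36 (so the expected
total is ≈ 206; the distribution is a free choice, as clinical counts vary
widely); one 10 mm-radius connected focus patch per patient, seeded at a
vertex whose gain-column norm exceeds the cohort median (excluding
quasi-silent and poorly covered sources, as clinically delineated foci are
cortical and visible to the array); 20 spikes per study (minimum 5); SNR 5;
275 sensors at 600 Hz. Spikes are biphasic (sharp ~20 ms positive lobe
normalized to unit peak at the marker, slower negative undershoot, ~70 ms
total), with amplitudes tapering from the patch seed as a Gaussian of scale
half the patch radius. SNR is defined as the RMS of the clean sensor signal
within ±25 ms of the peaks over the sensor-noise RMS; sensor-space white
noise is the base model, and no quantitative claim is made under any other
SNR definition. Everything is deterministic given the master seed
(per-study substreams via `SeedSequence.spawn`).

What the generator does **not** emulate: ongoing background brain rhythms
and correlated (spatially colored) noise, multiple concurrent spike types
or propagation, realistic folded anatomy, head movement, and environmental
artifacts. Consequently, passing the cohort-level checks shows that the
solvers and metrics behave as designed under the stated noise model — it
does not certify clinical performance, where noise is structured and the
focus is uncertain.

Problem sizes for the shipped evaluations were chosen to keep a full run at
desk scale: unit tests use 300–500-vertex meshes, and the cohort evaluation
uses 10 patients × 5 studies on a 2,000-vertex mesh — large enough for the
solver ranking to be stable across seeds, small enough to run in minutes.

## Known limitations

* The spherical forward model ignores volume-conductor asymmetry; near-
  midline and deep sources are systematically harder, which the synthetic
  seeding (gain-norm filter) sidesteps by construction.
* cMEM hyperparameters (neighborhood order, smoothing 0.5, eps_off,
  the alpha mapping) are declared defaults, not fitted; other MEM
  implementations make different choices and will not match numerically.
* The GEE falls back to the model-based covariance for small cohorts, where
  robust standard errors are unreliable; p-values in that regime are
  indicative only.
* Time-course (non-peak) imaging, free-orientation source models and
  beamformers are out of scope.
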