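# Methods

This note documents the models and numerical choices behind `glomcluster`:
how each parameter is defined and measured, what the synthetic-data
generator does and does not emulate, and where a genuinely open design
decision was resolved.

## Morphometry

A reconstruction is a rooted tree of 3D nodes with radii (SWC). Process
volume is the sum over parent→child segments of the conical-frustum volume
π·L/3·(r₀² + r₀r₁ + r₁²). Where the parent is a soma node, the child's
radius is used at both ends, so a large soma sphere does not inflate the
first dendritic segment. Dendritic length is the summed Euclidean segment
length over dendrite-type nodes (axons excluded). Hull volumes come from
Qhull over all node coordinates; degenerate point sets return 0 with a
warning rather than aborting batch runs. The furthest Sholl intercept is
the largest *Euclidean* distance from the soma root to a dendritic node
(the largest sphere a dendrite reaches, not a path length).

A **dendrite** is the maximal subtree hanging off one soma-attached stem
node; the layer criteria are evaluated per stem:

* **Lateral**: every node of the stem lies strictly on the EPL side of the
  GL–EPL border plane, and the chord from the stem's attachment node to its
  farthest-by-path tip makes an angle < 30° with the plane.
* **Vertical**: at least 85% of the stem's frustum volume (segment
  midpoint test, volume-weighted) lies inside the 60°-aperture cone whose
  apex is the stem's attachment node and whose axis points from the GL into
  the EPL.

The two criteria are mutually exclusive for any one stem (a chord within
30° of the border cannot anchor an ≥85%-in-cone subtree);
`lateral_vertical_overlap` lets cohorts assert this.

Dendritic density defaults to process volume / hull volume; the variant
using only the largest dendrite is available via
`dendritic_density(..., variant="largest")` because both definitions are in
circulation and they differ for multi-stem cells. The soma-size conversion
is `d = 2·√(area / (1.3·π))`: the shorter diameter of an ellipse with
aspect ratio 1.3 and the traced outline area.

Glomerulus contact uses closest approach of the segment axis to the sphere
centre (process radii ignored): a sphere counts when any segment passes
through it.

## Spike features

Detection: a light 5-sample boxcar smooths the voltage before
differentiation; a spike is an upward crossing of dV/dt ≥ 20 mV/ms
(configurable) followed by a local maximum within 2 ms, with a 2 ms
refractory period. The AP threshold is the start of the rising-phase run
for which dV/dt stays above the criterion; amplitude is peak − threshold
voltage; the half-maximum level is threshold + amplitude/2, and the
half-width spans the two half-maximum crossings with linear sub-sample
interpolation. Rise/decay velocities are the interpolated dV/dt at those
crossings; the speed ratio is their quotient.

Input resistance is the least-squares through-origin slope of steady-state
ΔV (mean of the last 20% of the step window, minus the pre-step baseline)
against ΔI over all spike-free step sweeps; mV/pA is GΩ. The time constant
fits V(t) = V∞ + ΔV·e^(−t/τ) on the largest subthreshold hyperpolarising
sweep. The default fit window is 250 ms after step onset, not 100 ms: with
a free asymptote, a 100 ms window cannot identify τ near 90 ms (the fit
trades τ against V∞); `fit_window_s=0.1` restores a strict first-100-ms
fit. A direct 1−1/e crossing is the fallback if the fit fails.

The CV of the ISI distribution pools the within-sweep inter-spike
intervals of all suprathreshold sweeps; fewer than two intervals give 0,
so single-spike (plateau-type) cells score exactly 0.

The average spike shape is the peak-aligned mean over a 25 ms window (5 ms
pre-, 20 ms post-peak), normalised by subtracting the voltage 1 ms before
the peak. Only *isolated* spikes enter the average — no other detected
spike inside the window — so that in bursting cells the following spike of
a doublet does not masquerade as an afterdepolarisation; burst-terminating
spikes, which carry a clean AHP, remain. If no spike is isolated, all
spikes are used.

### ICA of the AHP

Three factors are extracted from the post-peak segments of all cells'
average shapes with fixed-point ICA (FastICA, fixed seed). The first 2 ms
after the peak are excluded from the fit: that stretch is the spike
repolarisation, whose cross-cell variance (tens of mV, driven by width and
amplitude) would otherwise dominate the three components and decouple the
scores from the afterhyperpolarisation. ICA is identifiable only up to
sign and permutation, so a fixed convention is applied: each factor is
oriented so its dominant deflection is negative, and factors are ordered by
the time of their most negative extremum (early < intermediate < late).
Scores are the per-cell mixing coefficients under that convention; new
cells are scored by least-squares projection onto the factors. Because the
score scale is convention-dependent, only ordinal structure across cell
classes is meaningful, never raw score values.

## Clustering

Morphological parameters are asinh-transformed (they are strictly positive
and heavily right-skewed; asinh behaves like log for large values but
tolerates exact zeros), then every column is z-scored with the sample SD.
Linkage is Ward's method on Euclidean distances. Two height conventions
exist: scipy's native Ward (`ward.D2`, the Lance–Williams recurrence on
squared distances with heights on the distance scale) and the older R
`ward.D` that applies the recurrence to raw dissimilarities. `ward.D` is
emulated by feeding √d to scipy's Ward; the height transform is monotone,
so tree cuts are exact. Both are exposed; `ward.D2` is the default.

The number of clusters comes from the gap statistic: W_k is the summed
within-cluster sum of squared distances to the centroid, reference sets
are drawn uniformly over each feature's observed range (B = 100 by
default), Gap(k) = mean log W*_k − log W_k and se(k) = sd·√(1 + 1/B). The
stopping rule is the generalised one-SE rule with multiplier f (default
2): the smallest k with Gap(k) ≥ Gap(k+1) − f·se(k+1). A "local-max"
variant is available behind `select_k(..., rule="local-max")`; the
published phrasing of the rule is ambiguous between the two, and no
attempt is made to guess which produced the original figures. Note that
the axis-aligned reference box makes the gap value not strictly rotation
invariant; feature permutations are exact, rotations preserve the selected
k only when cluster structure is clear.

Cluster stability: for each of n_boot bootstrap resamples the data are
re-clustered at the same k, and each original cluster records its best
Jaccard overlap with any bootstrap cluster, computed on the unique points
present in the resample; the per-cluster means are reported (values near 1
= reproducible cluster, below ~0.75 = dissolved).

Cross-modality agreement uses the adjusted Rand index plus per-class
sensitivity/specificity/accuracy after matching each class to its
largest-overlap partner cluster. Pairwise parameter differences use
two-sided Wilcoxon rank-sum tests with Benjamini–Hochberg correction
applied within each parameter's family of cluster pairs (the grouping is a
package choice; correcting across all parameters at once would be more
conservative).

## Cell-class prediction

The SVM uses exactly six features — early AHP score, input resistance,
speed ratio, half-width, amplitude, 2D hull area — with an RBF kernel at
cost 100 and γ = 0.01. These hyperparameters are scale-sensitive, so
features are always z-scored with statistics of the training split only.
The 85/15 split is stratified by class and re-drawn (up to 100 attempts)
if a class is missing from training. Held-out accuracy is reported per
split; no published accuracy value is asserted.

## Connectivity testing

Per ordered direction: the presynaptic spike onset is the first dV/dt ≥
20 mV/ms crossing of the presynaptic voltage (onset, not peak — the choice
is configurable). The evoked charge is the trapezoidal integral of the
postsynaptic current over [onset, onset + 50 ms] minus the mean current of
the 50 ms immediately before onset times the window length. The null
charge repeats the computation at one uniformly drawn onset per trial
outside [onset, onset + 100 ms] (seeded). A paired t test across trials
decides significance at α = 0.05; zero-variance degeneracies (p = NaN)
count as not significant, and fewer than three trials flag the direction
untestable.

Latency: the postsynaptic current is smoothed with a causal 1 ms boxcar
(first spectral null at 1 kHz; causal so the onset is never smeared
backwards), and the response onset is the first crossing of 3× the
baseline noise SD sustained for 0.5 ms, refined by walking back at most
1 ms to where the smoothed trace still exceeds 1 SD. The refinement
removes most of the filter delay without chasing baseline noise; the
residual bias is below ~0.1 ms at the default signal-to-noise ratio.
Inward (excitatory at −50 mV holding) currents are negative throughout.

## The synthetic cohort generator

The generator's purpose is to make every pipeline stage testable end to
end: it emits SWC + sidecar morphologies, sweep sets and pair-recording
bundles whose *extracted* features reproduce the per-class target table
(seven classes, default counts A=10, B=11, C=16, D=24, E=8, F=14, G=12;
95 cells).

Sampling. Strictly positive parameters are drawn log-normally,
moment-matched to the target mean ± SD (printed SDs of positive quantities
imply right skew); zero-SD entries are exactly the stated value; AHP
scores are Gaussian. Draws are *stratified* (one draw per probability
stratum, randomly permuted, latent z clipped at ±2.8): the cohort is meant
to be the study population itself, so its sample moments should sit close
to the generating values even at n = 8–24 per class. The hull and the
soma × dendritic-volume product share a latent size factor (ρ = 0.8,
big arbors come with big somata), which keeps the implied soma outline
area in a realistic range.

Density, volume and hull are mutually constrained. The target table's
mean density, mean process volume and mean hull are jointly inconsistent
with a per-cell quotient density = V/H: no coupling of the printed V and H
marginals attains the printed mean density for the two largest classes
(the quotient is submodular, so the comonotonic coupling minimises E[V/H],
and even that minimum exceeds the printed value). The generator therefore
samples hull and density and derives V = D·H, with the density mean set to
the geometric compromise between the printed density and the printed
ratio of means — splitting the unavoidable discrepancy evenly — and the
density CV capped at 0.6 so the derived V is not far more dispersed than
its own printed SD. The latent plane of (H, D) is rotated so the product's
z-score is itself stratified, controlling the cohort means of V and H
simultaneously. Lateral/vertical volumes are sampled as moment-matched
shares of the cell's own process volume (an EPL dendrite cannot outweigh
the whole arbor), capped at 80%.

Geometry realisation. The border plane is z = 0 with the normal pointing
into the GL. The GL arbor is a spoke scaffold: tips on an ellipsoid whose
long semi-axis equals the sampled Sholl distance (two tips forced to the
poles pin the maximum) and whose transverse scale is solved by binary
search so the tip hull equals the sampled hull volume; six axis poles are
always included so the tip hull contains a known octahedron. Filler path
length (a random walk confined to the inscribed ellipsoid of normalised
radius 0.55, provably inside that octahedron) tops the total length up to
its target without touching the hull, and per-stem radii are solved so the
frustum volumes hit the sampled volumes exactly. Cluster E gets two
straight-spoke stems inside the vertical cone; cluster G gets one lateral
EPL stem with a near-horizontal chord. Touched glomeruli (radius
40–60 μm) are centred on arbor nodes with sub-radius jitter, plus three
distant decoys that must never be hit.

Physiology realisation. Passive responses are exact RC responses with the
drawn (R_in, τ) plus Ornstein–Uhlenbeck voltage noise (SD 0.25 mV,
τ 1.5 ms — membrane-filtered noise, so the derivative stays well below the
spike-detection criterion). Spikes are asymmetric half-Gaussian templates
whose widths follow from the drawn half-width and speed ratio, with the
amplitude floored at 30·σ_rise so every spike clears the dV/dt criterion.
The AHP is a mixture of three latent source waveforms — sharp, well
separated biphasic bumps at 3.5/9/16 ms — in the sparse super-Gaussian
regime where FastICA provably recovers the mixing; per-cell mixing
coefficients are affine in the target AHP scores, so the ICA stage has a
recoverable ground truth (coefficients, not scores, because ICA scores are
convention-dependent). Spike timing is class-specific: one spike per
suprathreshold sweep for the plateau class A (CV of ISI exactly 0); a
two-point short/long ISI mixture for the bursting class B, whose
inter-burst gap is solved in closed form from the target CV (a two-point
mixture has no heavy tail, so the CV survives window censoring, unlike a
skewed renewal process); log-normal ISIs elsewhere.

Pair recordings place a fixed presynaptic spike template at 0.25 s;
connected directions add a difference-of-exponentials PSC (rise 0.3 ms,
decay 5 ms, peak ≈ 20 pA) at a per-direction latency ~N(1.95, 0.44²) ms
measured from the template's own dV/dt-crossing sample, on OU current
noise (SD 2 pA); unconnected directions are noise only, and all planted
connections are unidirectional. The default configuration mix probes 35
pairs in both directions with 13 connected directions.

What the generator does **not** emulate: conductance-based spike dynamics,
burst rundown, synaptic depression/facilitation, reconstruction artefacts
(shrinkage, slice cuts), or any correlation between a cell's morphology
and its physiology beyond shared class membership. Passing the end-to-end
tests therefore shows the *pipeline* is correct and well calibrated under
the stated population statistics — not that real recordings are this
clean.

## Problem sizes used in the test batteries

The statistical acceptance tests use: 1000 null simulations and 100 power
simulations of the connection test (10 trials each, 5 kHz, 0.45 s traces);
20 seeds for ICA source recovery (95 shapes each); 20 seeded full cohorts
for the end-to-end cluster-number check (gap statistic with B = 100,
k ≤ 10); 20 seeds of seven separable classes for the SVM battery;
1.5–3 million rejection-sampling points per Monte-Carlo volume oracle; and
1000 simulated two-cluster tables (n = 20 per cluster) for the rank-sum
null calibration — two clusters of 20 rather than smaller groups because
the exact rank-sum null is discrete enough at n = 10 to pull the rejection
rate to ~2.4%, which would mask the property being measured. Cohort-mean
fidelity is asserted on the average of three seeded cohorts (285 cells),
which tests the generator's expectation at sampling noise ~√3 below a
single cohort's.

## Known limitations

* The deposited per-cell measurement sheets of the reference 95-cell
  dataset are not redistributable with the package; reproduction of the
  published clustering (`analyze_parameter_sheet`) runs only when the user
  supplies them. Published real-data metrics (93.3% SVM accuracy, ARI 0.37,
  connection fractions, 1.95 ms latency) are reported when data are
  supplied, never asserted.
* The gap statistic's uniform reference box is axis-aligned; k-selection
  is exactly invariant to feature permutation but only approximately to
  rotation.
* ICA scores are identifiable up to the stated sign/order convention;
  cross-study score values are not comparable without re-anchoring.
* The Ward `ward.D` emulation reproduces cuts exactly but reports heights
  through a monotone transform of the R implementation's internal scale.
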