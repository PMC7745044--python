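# Methods

`semifc` implements a semi-metric analysis of functional-connectivity (FC)
networks estimated from functional near-infrared spectroscopy (fNIRS), with
a conventional weighted graph-theory benchmark, heart-rate-variability
(HRV) validation from photoplethysmography (PPG), and the mixed-design
statistical layer used to compare conditions. This note records the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic-data generator does and does not emulate.

## Signal model and preprocessing

A continuous-wave fNIRS instrument records light intensity `I(t)` at two
wavelengths (695 and 830 nm, 10 Hz). Optical density is
`OD(t) = -ln(I(t)/I_ref)`; we take `I_ref` as the **geometric mean** of the
intensity over a configurable reference window (default: whole recording),
which makes the OD average exactly zero over that window. (An
arithmetic-mean reference satisfies the same property only approximately.)

**Motion correction** operates per channel and wavelength on the OD: an
orthogonal discrete wavelet decomposition (Daubechies-5, periodized,
`floor(log2 n) - 4` levels) in which detail coefficients deviating from
their per-level median by more than `1.5 x IQR` are zeroed; the
approximation level is never touched. Motion spikes concentrate energy in
few large detail coefficients, so this removes them while leaving smooth
hemodynamics intact. Re-running the correction is a no-op whenever the
first pass flagged nothing; in general a second pass may flip borderline
coefficients because the quantiles shift slightly — the test suite bounds
this residual at a few percent of the first-pass correction.

**Modified Beer–Lambert.** Concentration changes solve, per sample and
channel, the 2×2 system `dOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ)`.
Extinction coefficients (Gratzer-compiled, mM⁻¹·mm⁻¹), DPF = 6.0 at both
wavelengths, and source–detector distance 30 mm are shipped as an editable
table; outputs are µM under those constants. The forward model is also
exposed (`hemoglobin_to_od`), giving an exact round-trip identity used in
tests and by the signal generator.

**Low-pass.** 3rd-order Butterworth at 1.0 Hz, applied forward–backward
(zero phase). The attenuation at twice the cutoff exceeds 30 dB, well past
the 12 dB contract.

**Hemodynamic modality separation (HMS).** Measured signals are modeled as
a functional (neuronal) component with anti-phase HbR, `ΔHbR_f = k1·ΔHbO_f`
(`k1 < 0`), plus a systemic (circulatory) component with in-phase HbR,
`ΔHbR_s = k2·ΔHbO_s` (`k2 > 0`). The closed form
`ΔHbO_f = (k2·ΔHbO − ΔHbR)/(k2 − k1)` separates them exactly and the two
outputs reconstruct the input to floating-point. Defaults `k1 = −0.6`,
`k2 = +2.0` are fixed, documented constants (per-subject estimation of the
mixing ratios is out of scope); they are overridable everywhere.

Processing order: OD → motion correction → Beer–Lambert → low-pass → HMS.

## Wavelet-transform-coherence FC

Each channel's functional ΔHbO series is transformed with an analytic
Morlet continuous wavelet transform (ω₀ = 6, 12 voices per octave, FFT
implementation, dyadic scales spanning Fourier periods 2/fs to n/(2fs)).
For a channel pair the squared wavelet coherence is

    R²(s,t) = |S(W_xy/s)|² / ( S(|W_x|²/s) · S(|W_y|²/s) )

with the canonical two-stage smoothing `S`: a Gaussian in time whose
standard deviation equals the scale, then a 0.6-octave boxcar across
scales. Smoothing is computed by FFT with zero padding past the widest
kernel's 4σ reach. Self-coherence is identically 1 and values are clipped
to [0, 1].

The FC edge weight is the unweighted mean of R² over scales whose Fourier
frequency lies in the band of interest (0.01–0.2 Hz) and time samples
inside task blocks, averaged per 60 s task block and then across blocks
with equal weight. Rest periods are not used. Cone-of-influence cells are
included by default (`include_coi=False` excludes them). For efficiency,
`build_fc_matrix` restricts the transform to the analysis band plus a
one-octave margin on each side (the margin keeps the scale-boxcar honest
near the band edges); per-channel transforms and smoothed auto-spectra are
cached across the N(N−1)/2 pairs. The result is a symmetric matrix of
weights in [0, 1] with the diagonal ignored — 32×32 with 496 unique edges
for the full prefrontal layout.

## Semi-metric analysis

Weights map to distances through `l_ij = 1/x_ij − 1`, so coherence 1 is
distance 0 and weak edges are far apart. Zero weights are clamped at
`eps = 1e-6` (distance ~10⁶) rather than deleted, keeping the edge count of
the complete graph. All-pairs shortest paths use Johnson's algorithm
(scipy.sparse.csgraph); zero-length edges are encoded with a negligible
positive value because dense csgraph input treats zeros as missing edges,
and the resulting distances are floored back to zero. One path per pair is
reconstructed deterministically with a lowest-index predecessor rule
(ties in path length always resolve the same way, so hop histograms are
reproducible).

An edge is **semi-metric** when its direct distance exceeds the shortest
path, `s_ij = l_ij/l'_ij > 1 + tol` with relative tolerance `1e-9`; ties
count as metric-backbone edges. The **semi-metric percentage** is
`SMP = #semi-metric / E` with `E = N(N−1)/2`. Regional SMP restricts both
endpoints to the region of interest and divides by the intra-ROI edge
count; hemispheric contrasts drop the configured exclusion channels
(defaults ch16/ch37, leaving 15 channels per hemisphere in the shipped
layout). The shared-path histogram counts the node count of each pair's
reconstructed shortest path; entries above 2 quantify path sharing.

The metric backbone (edges with s = 1) reproduces every shortest-path
length of the full graph — asserted on random instances in the tests.

## Weighted graph-theory benchmark

All distances reuse the `1/x − 1` conversion, so the benchmark and the
semi-metric branch see one geometry. On the unthresholded weighted network
we compute:

* **CC** — weighted clustering via geometric-mean triangle intensity on
  max-normalized weights, `C_i = Σ (w'_ij w'_ih w'_jh)^{1/3} / (k_i(k_i−1))`,
  network value the node mean. The printed binary formula `2m/(k_i(k_i−1))`
  is its special case and is degenerate (identically 1) on complete
  weighted graphs, which is why the weighted generalization is used.
* **λ** — characteristic path length, the node-mean of mean shortest-path
  distances.
* **E_global** — mean of `1/d_ij` over ordered pairs; `1/d` is capped at
  10⁶ where a distance collapses to zero (only reachable at coherence
  exactly 1).
* **E_local** — node-mean of `E_global` of each node's neighbor-induced
  subgraph, with distances recomputed inside the subgraph; nodes with
  fewer than two neighbors contribute 0.
* **E_nodal** — per node, mean of `1/d_ij` on the *full* graph; regional
  values average members.

Regional CC and λ are computed on ROI-induced subgraphs; E_nodal keeps
full-graph distances because its sum ranges over the whole network. On a
complete uniform-coherence graph the closed forms `λ = 1/x − 1` and
`E_global = x/(1−x)` hold exactly and are used as acceptance checks.

## HRV from PPG

The PPG trace (200 Hz) is smoothed with a centered one-second moving
average. Beat detection then works on a 2 s moving-average-detrended
version of that trace: local maxima separated by at least the
maximum-heart-rate interval (60/180 s) and exceeding half the rolling 90th
percentile of the detrended trace. Because a one-second moving average
inverts and blurs the beat-rate ripple (its frequency response is negative
near 1.25 Hz), the approximate peaks are lag-corrected by cross-correlation
against the lightly-smoothed raw waveform and snapped to its nearest peak;
this restores beat-to-beat timing, which the heavy smoothing would
otherwise flatten (biasing RMSSD down by tens of percent).

Inter-beat intervals outside [333.3, 1000] ms (the 180/60 bpm bounds) or
deviating more than 20 % from the median of a surrounding five-interval
window are rejected as artifacts (the exact rule of the cited artifact
filter is not published; this median-deviation variant is declared and
configurable). RMSSD is

    RMSSD = sqrt( Σ (NN_{i+1} − NN_i)² / n_pairs )

computed over genuinely successive accepted intervals only — differences
spanning a rejection gap are excluded, and the divisor is the number of
included pairs, which reduces to the contiguous-series `n − 1` formula when
nothing was rejected. RMSSD is computed over the whole session by default
(a task-window restriction is available).

## Statistical layer

The design is one between-subject factor (group) crossed with one or two
within-subject factors (emotional state; brain region). For balanced,
complete designs the mixed ANOVA is computed from the closed-form
sums-of-squares decomposition: the between effect is tested against
subjects-within-groups; each within effect and its interactions with the
between factor are tested against the corresponding
within-by-subjects-within-groups error term. Effect sizes are partial eta
squared `SS_eff/(SS_eff + SS_err)`. This is hand-implemented because no
installed package covers the 1-between × 2-within case; the 2-way case is
cross-checked against pingouin in the tests. Unbalanced or incomplete
tables are rejected rather than approximated.

Pairwise follow-ups use paired/independent t-tests; Cohen's d is
`mean(diff)/sd(diff)` for paired contrasts and the pooled-SD form for
independent ones. Multiplicity is controlled with Benjamini–Hochberg
step-up FDR (statsmodels), one family per comparison table. State-change
correlations compute per-subject Δ = affective − neutral for each index
and Pearson's r across pooled subjects, BH-adjusted across the index
family.

## Synthetic data

The generator produces the study's conditions by default: 10 Hz
dual-wavelength recordings over a paradigm of 20 s rest followed by five
60 s task blocks separated by 30 s rests (the inter-task rest duration is
not specified by the design; 30 s is a declared default), PPG at 200 Hz
with mean heart rate 75 bpm and target RMSSD 50 ms, and two groups of 19
subjects.

Coupled channels share a band-limited (0.01–0.2 Hz) Gaussian latent
oscillation with mixing weight √coupling (default coupling 0.8), amplified
2× during task blocks, plus independent in-band noise and white sensor
noise; this is the minimal generative structure wavelet coherence assumes.
HbR follows the HMS mixing model and both chromophores pass through the
forward Beer–Lambert model to strictly positive intensities — generated
data exercises the real preprocessing path. NN intervals are white
deviations around the mean interval, rescaled so the realized RMSSD equals
the target exactly; each beat renders an asymmetric Gaussian pulse (80 ms
rise, 180 ms decay) with mild baseline wander and sensor noise. Toy FC
networks plant semi-metric edges by giving them coherence ≈ 0.2 (distance
≈ 4) inside a backbone of coherence ≈ 0.5 edges (distance ≈ 1, detours ≈ 2),
so the exact semi-metric edge set is known by construction.

What the generator does **not** emulate: physiologically detailed
hemodynamics (no balloon model, no HRF convolution of a neural point
process), realistic motion artifacts beyond additive spikes, heteroscedastic
or non-Gaussian sensor noise, spatially structured cross-talk between
optodes, and respiratory/cardiac bands in the fNIRS signal beyond the
generic systemic component. Passing tests therefore demonstrate the
correctness of the estimators under the assumed signal model, not their
robustness to every property of real recordings.

## Problem sizes and numerical choices

Tests and the acceptance script scale simulations to what the properties
need: oracle comparisons use 200 random complete graphs with up to 8
nodes; coupling recovery uses 20 seeds of 8-channel recordings under the
full paradigm; the type-I calibration of the end-to-end pipeline uses 200
runs of a reduced study (5 subjects per group, 8 channels, a
10 s + 2×(20 s task + 10 s rest) paradigm at 5 Hz) and checks the
interaction rejection rate against α = 0.05 within three binomial standard
errors. Semi-metric labeling uses relative tolerance 1e-9; oracle
equivalence is asserted at 1e-9 relative; Beer–Lambert round-trips at
1e-9; degenerate inputs (zero-variance contrasts, missing design cells,
infeasible plantings, empty scale selections) raise errors rather than
returning approximations.

## Known limitations

* The exact smoothing constants of the classical wavelet-coherence
  toolboxes are not published alongside the method; ours are declared
  (Gaussian time smoothing with σ = scale, 0.6-octave scale boxcar), so
  coherence values are comparable across runs of this package but not
  bit-identical to other implementations. Acceptance rests on invariants
  (self-coherence, bounds, coupling ordering), not bit-matching.
* Regional SMP's denominator (intra-ROI edges) and the induced-subgraph
  convention for regional CC/λ are declared conventions; an incident-edge
  alternative exists for sensitivity analysis.
* The channel→hemisphere table is a replaceable convention encoded from
  the published channel counts (16 per hemisphere, ch16/ch37 excluded from
  hemispheric contrasts), not from machine-readable probe geometry.
* Beat detection assumes a single dominant pulse per cardiac cycle; PPG
  with strong dicrotic notches may need a narrower snap radius.
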