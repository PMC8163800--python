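# Methods

This note documents the models implemented in `nsf20s`, the defaults and
numerical choices that matter, what the synthetic-data generators do and
do not emulate, and the design decisions taken where the methodology was
genuinely open.

## Ring combinatorics (`ringcomb`)

A hexamer assembled from a random mix of wild-type (WT) and mutant
protomers carries a mutant count *k* ~ Binomial(6, *x*) at mutant
fraction *x*, and, given *k*, a uniformly random arrangement of the
C(6, *k*) placements. Arrangements are grouped under **rotation only**:
the ring is viewed from a fixed face of the complex, so mirror-image
arrangements (e.g. the two chiralities of a 1-2-3 spacing pattern) are
distinct classes. This is why three mutants give four classes —
ABC, ABD, ACD, ACE with fractions 30/30/30/10% — rather than three.

The canonical representative of a class is the rotation whose sorted
mutant-position tuple is smallest in **colexicographic** order (compare
the largest positions first). This anchors a mutant at position A and
reproduces the conventional class names (AB/AC/AD, ABC/ABD/ACD/ACE);
the plain lexicographic rule on the boolean mask would instead pack
mutants at the end of the ring and label classes from the wrong anchor.

Binding competence is a pluggable rotation-invariant predicate. Two
rules ship:

- `three_consecutive_wt_n_domains`: some window of three adjacent
  subunits is all WT — the footprint of one αSNAP dimer engaging three
  neighboring N-domains. This rejects the alternating (ACE) class,
  i.e. it treats binding through only two N-domains as impossible.
- `no_diagonal_pair_missing`: no diametrically opposed pair of subunits
  is simultaneously mutant. This is the weaker rule consistent with the
  FRET observation that the diagonal two-mutant class is selectively
  lost; it still admits ACE.

Whether the alternating class binds weakly or not at all is left to the
rule choice rather than decided, since the two rules bracket the
hypotheses; predicted avidity profiles are computed per rule.

## Photobleaching stoichiometry (`photobleach`)

**Step detection.** Change points are inserted greedily (each insertion
takes the split that most reduces the residual sum of squares; the best
split of a segment is found in O(n) from cumulative sums) and accepted
while the Schwarz information criterion `N log(RSS/N) + k log N`
decreases. The piecewise-constant refit is then cleaned by merging any
level change smaller than `sensitivity × σ_noise` (default 2.5, with
σ_noise estimated robustly from successive differences), and only
downward changes count as bleaching events. Two bleaching events inside
the same ~2-frame window are physically unresolvable and are counted as
one step; the test suite tallies such traces separately. Traces with
more apparent steps than `max_steps` are not reassigned.

**Deconvolution.** With labeling efficiency *r*, a complex with *j*
taggable subunits shows *i* ~ Binomial(*j*, *r*) steps, giving the
mixing operator a_ij = C(j, i) r^i (1−r)^(j−i). Zero-step molecules are
invisible, so the observed histogram covers i = 1..6 and the true j = 0
bin is unidentifiable: the inversion R = A⁻¹X runs on the visible 6×6
block and renormalizes over j ≥ 1. When sampling noise drives the exact
inverse negative, a nonnegativity-constrained least-squares solution
(`scipy.optimize.nnls`) replaces it — distributions must be
nonnegative, and the choice is explicit rather than silent clipping. A
condition number above 10⁹ (tiny *r*) is refused.

**Labeling efficiency.** For the two-site tandem control,
P(2 steps | visible) = r/(2−r); the MLE has the closed form
r̂ = 2f₂/(2f₂+f₁) and the interval is a profile-likelihood CI on the
binomial likelihood of the 1- vs 2-step split.

**Relative avidity** is the enrichment of each subunit-count class among
bound complexes over the unselected pool, normalized to the one-mutant
class; errors propagate by the delta method from multinomial counting
error in all four fractions involved.

**Spots.** Local maxima above median + 4σ (robust MAD scale) with
non-maximum suppression; colocalization is nearest-neighbor matching
within a 2-pixel default radius. No drift correction or PSF fitting —
snapshot-level counting only.

## smFRET populations (`smfret`)

Efficiencies use E = (I_A − l·I_D)/(I_A + γ·I_D) on background-subtracted
intensities averaged over the pre-bleach window (default 20
donor-excitation frames); frames after the first bleach in either
channel are excluded. Defaults l = 0.07, γ = 1.0 are declared detector
corrections, configurable because instrument values vary. Molecules are
kept only if the donor channel bleaches in exactly one step and the
acceptor channel, under direct acceptor excitation, also bleaches in
exactly one step.

The Gaussian mixture is fitted by a purpose-written 1-D EM (restarted,
log-domain responsibilities) rather than a library call so that the
per-iteration log-likelihood trace is available for monotonicity
checks, degenerate components (σ → 0 or emptied) abort a restart
explicitly, and initialization is controlled: quantile-spaced means
with jitter across 20 restarts, pooled SD, uniform weights.
scikit-learn's mixture model is used in the test suite as an
independent cross-check of the same fits. Component count is fixed at 3
for the headline analysis (the study design posits three geometric
populations); BIC-based selection is available. Components closer than
two pooled SDs are flagged `merged`.

## ATPase kinetics (`atpase`)

All rates are **per protomer per minute**, including the coupled rate
β — the coupled event fires all six sites of a hexamer simultaneously,
and dividing the per-hexamer event rate by six puts β on the same scale
as γ. Binding is assumed to pre-equilibrate faster than hydrolysis, so
occupancy distributions are equilibrium quantities that hydrolysis does
not perturb.

Models (all guarded for extreme [ATP]/K_d by log-domain evaluation of
the binomial sums):

- two-mode: V = β f⁶ + γ f, f = p/(1+p), p = [ATP]/K_d;
- concerted (MWC): R/T conformations with affinities K_r, K_t and
  allosteric constant L; the coupled term lives in the R state only, so
  L = 0 recovers the two-mode model and K_t = K_r gives a two-mode curve
  with β diluted to β/(1+L);
- sequential (KNF): the n-th binding event carries α^(n−1) K_d; α = 1
  recovers the two-mode model; the basal variant (no coupled term) is
  algebraically γ⟨m⟩/6;
- single-site Michaelis–Menten (γ only) and the Hill curve.

The mutant-poisoning curve y(x; j) = Σ_{i<j} C(5,i)(1−x)^{6−i}x^i is the
WT-protomer-weighted activity of a random hexamer pool in which ≥ j
hydrolysis-dead subunits kill the coupled mode: it equals
E[(n_WT/6)·1{n_mut<j}], not the plain binomial tail P(n_mut<j) (the two
coincide only at j = 1).

**Fitting.** Weighted Levenberg–Marquardt (lmfit) from a small grid of
documented starts (defaults plus data-driven V_max/half-saturation
guesses at three K scales). When per-concentration replicate SDs are
supplied they are **moderated** before weighting: each variance is
shrunk halfway toward a smooth constant-CV model fitted across the
titration. Sample SDs from 5–6 replicates have so few degrees of
freedom that using them raw as inverse-variance weights inflates the
estimator variance well beyond the reported standard errors;
moderation restores 95% CI coverage to 93–98% in simulation (checked in
the test suite). Confidence intervals use t quantiles with
n_data − n_params degrees of freedom.

**Apparent Hill coefficients** are computed by fitting the Hill curve
to a noise-free model curve sampled on 12 log-spaced points over
1–2000 μM (the grid is a package choice; no measured grid is
available). Because the apparent n depends mildly on the sampled range
and density, the result carries a grid-sensitivity report (refits at
±2 points). On this grid the two-mode model at β=59, γ=7, K_d=4.8 gives
n ≈ 1.27 and the basal sequential model at γ=2.9, K_d=11, α=1.6 gives
n ≈ 0.64 — consistent with measured values of 1.33 ± 0.03 and
0.58 ± 0.09 at their uncertainties plus grid sensitivity.

**Initial rates** from phosphate-release absorbance series use a linear
calibration against Pi standards (R² ≥ 0.98 warned otherwise) and the
slope of the longest prefix window (≥ 5 points) whose linear fit keeps
R² ≥ 0.99 — a concrete operationalization of "the first points of the
linearly increasing interval". On saturating progress curves this rule
biases the slope slightly low; tests use mild saturation where the bias
is within 5%.

**Stochastic cross-check.** A Gillespie simulation of the occupancy
birth–death chain (binding k_on·A·(6−m), unbinding k_on·K_d·m) with Pi
tallied at γ per occupied site plus 6β at full occupancy reproduces the
closed-form two-mode rate — an oracle independent of the algebra.

## Magnetic tweezers (`tweezers`)

Median filtering uses a running window of `sample_rate/target_rate`
frames with block decimation. Allan deviation is the overlapping
estimator at octave-spaced averaging times; for white noise it follows
σ/√(f_s τ), and the test restricts the comparison to averaging times
with ≥ ~128 independent blocks, where the estimator itself is within a
few percent.

**HMM.** Gaussian-emission HMM (hmmlearn) trained by Baum–Welch with
explicit mean initialization spread over the occupied extension range —
k-means initialization reliably swallows rare, short-lived states (a
few-ms intermediate occupies a few percent of frames) into the majority
levels. Restarts jitter the means; solutions in which two state means
sit closer than 1.5× the median emission SD are flagged as collapsed
(a split of one noisy level, not two resolvable states) and are only
accepted if no clean restart exists. States are reported sorted by
mean; paths come from Viterbi. The emission model is Gaussian with
state-specific variance, appropriate for bead-noise-dominated traces.
Three states is the default for disassembly traces (folded level,
intermediate, released coil); two-state analysis is supported.

**Dwells.** Dwells are Viterbi-path run lengths; those touching trace
boundaries are kept as right-censored, contributing survival terms to
the exponential likelihood. Dwells shorter than a 2-frame dead time
(~1.7 ms at 1.2 kHz) are treated as unresolved; for an exponential,
left truncation reduces to subtracting the truncation point, and for
frame-quantized durations an m-frame dead time corresponds to a
continuous truncation at (m − ½) frame periods — using m frames
directly would bias τ̂ low by half a frame. The MLE is
τ̂ = Σ(t_i − d)/n_uncensored with a profile-likelihood CI. Force-jump
latencies are first-passage times to a threshold crossing, censored at
the trace end, fitted the same way.

**Windowed histograms.** Extension samples are pooled across traces in
fixed windows (default 10 ms) indexed by time-to-event, after shifting
each trace so its post-event plateau (the unstructured-coil level,
averaged over 50 ms) sits at zero — the alignment makes level positions
comparable across beads with different absolute offsets.

**State-extension model.** Each conformational state contributes the
worm-like-chain extension of its unfolded residues (Marko–Siggia
interpolation, numerically inverted; persistence length 0.6 nm, contour
0.365 nm/residue for polypeptide) plus a projected folded-core length;
DNA handles (two 500-bp, extensible WLC with 40 nm persistence length
and 1000 pN stretch modulus) can be included but cancel in state-to-
state differences. The per-state unfolded residue counts (FZ 0, LU 14,
I20S 50, HU 66, TU 120, UC 137, with folded cores 2→0 nm) are
plausibility defaults chosen once so the state ladder is monotone and
the full unzipping spans ~28 nm while the final coil step is ~4 nm at
16 pN, matching the measured extension increments; the structural
inventory per zippering layer is configurable because exact values are
construct-specific. Force is taken as given per segment (1–30 pN
validity range); bead-fluctuation force calibration is out of scope.

## Synthetic data (`synth`)

Every generator takes an explicit seed and builds its own
`numpy.random.Generator`; outputs are bitwise reproducible and no
global state is touched. Scenario presets encode the study conditions:

- `fig6c_titration`: two-mode curve at β=59 min⁻¹, γ=7 min⁻¹,
  K_d=4.8 μM; 12 log-spaced points 1–2000 μM; 6 replicates at 5% CV,
  reported as replicate mean ± sample SD (matching how titration error
  bars are constructed).
- `fig6f_titration`: basal sequential curve at γ=2.9 min⁻¹, K_d=11 μM,
  α=1.6; 5 replicates at 7% CV.
- `fig1_disassembly`: 1.2-kHz three-state traces (levels 0/13/30 nm),
  folded dwell 50 ms, intermediate dwell exponential with τ = 7 ms,
  noise SD half the smaller level spacing — detectable but not trivial.
- `dimer_control`: two-site Bernoulli labeling at r = 0.90, 1000
  molecules, zero-label molecules discarded.
- Bleaching traces default to 10 Hz, SNR 5, mean bleach time ~33 s over
  a 240-s record — the regime where nearly all multi-fluorophore traces
  have frame-resolvable steps.
- FRET cohorts draw molecular efficiencies from a 3-component mixture
  (defaults 0.19/0.46/0.70, SDs 0.05, weights 0.16/0.42/0.42), emit
  anticorrelated two-channel intensities under an alternating
  excitation schedule, and bleach acceptor-then-donor in single steps;
  a contaminant fraction carries two donors.

**What the generators do not emulate** — and hence what passing tests
do not establish about real data: camera PSFs and pixelation, bead
hydrodynamics and tether Brownian dynamics (noise is white, real bead
noise is correlated), photophysical blinking, background drift,
non-exponential bleaching, day-to-day instrument variation, and any
deviation of real kinetics from the fitted model families. Recovery
tests certify the estimators on data satisfying the models'
assumptions, not the assumptions themselves.

## Known limitations

- The step detector counts coincident (sub-2-frame) double bleaches as
  one step; at 10 Hz with seconds-scale bleach times this affects a few
  percent of 4-fluorophore traces.
- Reported kinetic-fit standard errors are linearization-based; for
  strongly nonlinear parameters (α) the replicated-pivot tests show
  they are accurate to ~15%, and t-based CIs achieve 93–98% coverage.
- The apparent Hill coefficient is a grid-dependent summary; values are
  only meaningful together with the reported grid sensitivity.
- The state-extension defaults are structural plausibility choices, not
  fitted values; only ordering and approximate spans are asserted.
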