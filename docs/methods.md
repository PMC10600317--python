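# Methods

This note documents the models and procedures implemented in `taprhythm`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Rhythm universe

A rhythm is a cyclic binary indicator over *N* isochronous pulses with *K*
cues.  `enumerate_wf_rhythms` returns all rotation-distinct **nondegenerate
well-formed** rhythms within bounds (defaults: N 3–13, K 2–11, maximum
interonset interval 5 pulses).  Nondegenerate well-formedness is
operationalized as:

1. **Myhill's property** — every generic interval g = 1..K−1 (number of
   intervening cues + 1) takes exactly two specific sizes (number of
   intervening pulses + 1) across the K cyclic cue pairs; and
2. **primitivity** — the IOI sequence has gcd 1.  A pattern whose IOIs share
   a divisor d > 1 (e.g. (4 2) in a 6-pulse cycle) lives entirely on a
   sub-grid and has no generating interval coprime with N; the bare
   cardinality check admits five such patterns within the default bounds
   ((6,2)(4 2), (8,3)(4 2 2), (10,3)(4 4 2), (10,4)(4 2 2 2),
   (12,5)(4 2 2 2 2)) that are excluded here.  Both predicates are exposed
   (`has_myhill_property`, `is_primitive`).

With the defaults the enumeration yields 91 rhythms.  Rhythms are counted up
to rotation only — experiments randomize the starting cue, which identifies
rotations but not reflections.  The canonical rotation starts on a cue and
maximizes the IOI sequence lexicographically, which places small IOIs as late
as possible; ties cannot arise because identical IOI rotations give identical
indicators.

## Rhythm-level predictors

* **evenness** — magnitude of the mean over cues j (temporal order, positions
  t_j) of unit vectors at angle 2π(t_j/N − j/K): the alignment of the cue set
  with a perfectly even K-template, phase optimized out by the modulus.
  Rotation- and relabeling-invariant; equals 1 iff the cues are equally
  spaced.  Worked values: (1 1 0) → 0.866, (1 1 0 0) → 0.707.
* **balance** — 1 − |centroid| of cue unit vectors; equivalently one minus
  the distance of the circular centre of mass from the circle centre.
* **ioi_ent / int_ent** — Shannon entropy (base 2, unnormalized) of the K
  consecutive-cue IOIs, and of all K(K−1) directed inter-cue intervals modulo
  the period.  Bits are a convention; standardization before modelling makes
  the base irrelevant.
* **cq** (coherence quotient) — 1 − failures / max-failures, a failure being
  an unordered pair of directed intervals whose generic and specific sizes
  are oppositely ordered.  The normalizer is the exact maximum failure count
  for K onsets, found by brute force over all patterns with N ≤ 13 and cached
  (about one second for all K once per process).  Undefined (NaN) for K < 3.
* **sq** (sameness quotient) — 1 − Σ_g (distinct sizes at g − 1) / (K−1)².
  The normalizer (K−1)² is the number of generic classes times the maximum
  number of *extra* sizes per class (each class has K instances, hence at
  most K distinct sizes).  On Myhill rhythms the numerator is exactly K−1,
  making sq = 1 − 1/(K−1); across the enumerated universe this reproduces a
  Pearson correlation with K of 0.80.  The alternative normalizer K(K−1)/2
  was rejected because it yields 0.89.
* **duple_triple** — 1 iff N is divisible by 2 or 3 (the cycle can be counted
  in twos or threes without doubling).
* **mean_ioi** — N/K pulses.

## Pulse-level predictors

All pulse-level predictors are exactly rotation-equivariant.

* **markov k** (k = 2, 3, 4) — for each pulse, the proportion of occurrences
  of its preceding length-k context (circular, estimated from the single
  cycle, which by periodicity equals the 30-s stream) that are followed by a
  cue.  The context-frequency-weighted mean is exactly K/N.
* **edge** — absolute circular convolution of the *bipolar* signal
  (indicator − ½) with a derivative-of-Gaussian kernel plus a per-sample DC
  correction: k(t) = A·(t−μ)·exp(−(t−μ)²/2σ²) lattice-summed over the cycle,
  plus dc.  Calibrated once against the reference response of the two-cue
  cluster (0 0 1 1 0 0) → (0.00, 0.22, 0.15, 0.27, 0.20, 0.00); the fitted
  constants are A = 9.836453, μ = −0.0071177, σ = 0.3604842 pulses,
  dc = −0.0249998 (residual < 1e−5).

  Two structural facts forced this parameterization. (i) Any cyclic linear
  filter obeys alternating-sum and DC identities linking its outputs; the
  reference vector is *asymmetric* under time reversal (0.22/0.20 and
  0.15/0.27 at mirror positions), which no time-symmetric kernel can produce
  — hence the shift μ and the dc term.  (ii) Exact invariance under
  complementation (swapping cues and gaps) cannot be had from the raw 0/1
  signal with any kernel matching the reference vector; encoding the signal
  bipolar makes the response flip sign exactly under complementation, so the
  magnitude is invariant for *every* kernel.  One consequence: for equally
  spaced patterns the edge vector is constant across pulses (carrying no
  pulse-level information) rather than exactly zero.
* **mean_offset** — Σ(forward circular distances to cues) − Σ(backward),
  normalized by K·N into [−1, 1]; high near the ends of cue clusters, low
  near their starts.  The normalizer is a convention; standardization
  absorbs it.
* **proj_cent** — signed projection of the cue centroid onto each pulse's
  diameter: |c|·cos(θ_n − arg c).  Values sum to zero over pulses (the pulse
  unit vectors sum to zero) and are bounded by |c|.
* **apm** — circular autocorrelation phase matrix column sums: for each lag
  k = 1..⌊N/2⌋, walk the cycle in steps of k (lcm(N,k)/k steps close the
  orbit) accumulating products of cue indicators at successive steps; each
  lag is normalized by its term count and lags are averaged.  The orbit
  formulation keeps the feature exactly rotation-equivariant for lags that do
  not divide N.
* **seq_exp** — for each pulse and spacing d, the maximal run of m cues at
  constant IOI d leading into the pulse contributes
  (1 − run_gain^(m−1))·ioi_decay^(d−1) when m ≥ 2.  The two shape constants
  (defaults 0.5, 0.5) are exposed in configuration; they encode that
  expectation grows with run length and decays with spacing, and the defaults
  were chosen once as moderate midpoints of (0, 1).
* **iso/start/end accents** — isolated cue; first cue of a run of ≥ 3; last
  cue of a run of ≥ 2 (all circular).

## Tap scoring

Performances are 129 pulses at 234 ms (30.2 s); each pulse owns the centred
window [t−117, t+117) ms, which tiles time.  Each tap is assigned to its
window; when several taps share a window, the smallest |asynchrony| wins and
ties go to the earlier tap.  Taps before t = 0 or after the last window are
dropped and counted.  Per-pulse aggregation yields a binomial table
(`tap_num` of `n_pulses` cycles; for N = 8, positions occur 16 or 17 times
since 129 = 16·8 + 1), the previous-pulse tap proportion, and mean velocity
and asynchrony over tapped cycles.

`tap_accuracy` builds 1-ms-resolution impulse trains for taps and cues over
the performance span, smooths both with a 10-ms-SD Gaussian (zero-padded
linear convolution — a performance is not circular), and returns their cosine
similarity; zero taps score 0.  The 10-ms scale approximates the temporal
just-noticeable difference.  Optional offset correction maximizes the score
over a constant ±117-ms shift of the tap train on a 1-ms grid (implemented
via one FFT cross-correlation plus exact edge-norm bookkeeping).
`smooth_velocity_profile` is the circular counterpart on the cycle domain:
velocity-weighted tap phases, circularly convolved with the same Gaussian,
normalized to unit mass.

## Synthetic cohorts

The simulator draws, for every performance pulse: a tap with probability
logit⁻¹(β₀ + β_cue·cue + Σβ_f·x_f + cue·Σβ_{cue:f}·x_f + participant and
rhythm intercepts + cue×participant and cue×rhythm slopes); if tapped, an
asynchrony from a normal truncated to the assignment window (means −9 ms
cued / +4.8 ms uncued, SD 30 ms) and a velocity from a rounded normal
censored to 1..127 (mean 90, SD 15, participant intercept SD 21.7).  With
probability 0.034 a bounce ("double tap") is appended 15 or 60 ms after a
genuine tap, but only where it stays in the same window with worse timing —
so window assignment provably discards exactly the injected echoes, a
property the tests exploit.  Asynchronies are drawn half a millisecond inside
the window so integer rounding of tap times never crosses a window boundary,
and taps that would precede t = 0 are suppressed.

Cohort shape defaults mirror a large tapping experiment (111 participants, the 91
rhythms in four disjoint sets of 23/23/23/22, each assigned rhythm performed
twice in randomized block order, randomized starting cue).  The default
coefficients are illustrative magnitudes (cue ≈ 2 log-odds, structural
effects ≤ 0.5), not estimates.  Reproducibility: one master seed; participant
substreams are spawned deterministically, so identical configurations yield
byte-identical tap logs.

What the simulator does *not* emulate: within-performance learning, tempo
drift, serial correlation of asynchronies, participant strategy switching,
and any dependence of velocity or timing on the structural predictors beyond
the cued/uncued contrast.  Passing recovery tests therefore demonstrate
correctness of the estimators under the assumed observation families, not
fidelity of those families to human data.

## Inference

Designs standardize continuous inputs to mean 0, SD 1 (binary inputs stay
0/1; velocity and asynchrony responses are divided by their SD but not
centred so censoring/truncation bounds remain interpretable: 127/sd and
±117/sd recomputed from each dataset).  Every pulse-level predictor enters
with its cue interaction; rank deficiency aborts with the aliased columns
named.

All four families are fitted by quasi-Newton maximum likelihood (BFGS; the
binomial with analytic gradients, a zero start, optionally a Student-t(3, 0, 1)
penalty on non-intercept coefficients mirroring a weakly informative prior —
off by default so recovery tests are unbiased; the Gaussian families start
from OLS; the beta from moment estimates).  Standard errors come from the
inverse observed information (numerical Hessian at the optimum).  Likelihood
code is validated against quadrature oracles at 1e−8 and against independent
implementations (statsmodels GLM and BetaModel) where they exist; censored
and truncated likelihoods are written here because no installed package
provides them.

`sdt_decompose` emits, per predictor, the uncued effect β₂, the
discriminability β₃, and the cued effect β₂+β₃ with the covariance-aware
standard error; the identity cued = uncued + discriminability is exact by
construction.  `vif_forward_select` adds externally ranked candidates in
order, skipping any that raises a variance inflation factor above 10
(equivalently: some column regressable on the rest with R² > 0.9); nothing
is ever removed.  The projective-prediction ranking machinery itself is out
of scope — the ranking is an input.

Fixed-effects ML replaces full crossed-random-effects posterior inference:
the substance here is the predictors, the observation families, and the
decomposition identities, not the sampler.  Wald z statistics stand in for
posterior summaries; simulations for recovery tests therefore switch the
random-effect SDs to zero so that the fitted model matches the generative
one.  Recovery/coverage studies use 20 seeds per family at modest sizes
(binomial: cohorts of 8 participants × 12 rhythms; the other families:
400-row designs), chosen to keep the default test run fast while leaving
Monte-Carlo error on a 95% coverage estimate near ±2%.

## Pipeline and formats

Artifacts are TSV (UTF-8) with `#`-prefixed header lines embedding the
package version and a SHA-256 configuration hash, or JSON for fits and ground
truth.  Tap logs carry integer milliseconds and 7-bit velocities; validation
rejects out-of-range rows with a named-row report.  The pipeline chains
enumerate → features → pulse features → simulate-or-load → score → join →
fit, logging row counts per stage; the velocity and asynchrony fits in the
pipeline operate on performance-averaged responses (the variable-selection
convenience path), while the per-tap censored/truncated paths are exercised
by the library API and tests.

## Known limitations

* The edge kernel reproduces its reference response at two decimal places by
  construction; other kernels consistent with the verbal description exist,
  and downstream effect sizes depend mildly on the choice.
* CQ's normalizer maximizes over universes up to 13 pulses; for larger N the
  cached table would need recomputation with a larger bound.
* Beta-regression accuracy fits nudge exact 0/1 scores inward by machine
  epsilon rather than modelling boundary mass.
* The offset-corrected accuracy search is a 1-ms grid, matching the metric
  resolution; sub-millisecond offsets are not resolved.
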