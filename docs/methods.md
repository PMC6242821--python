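# Methods

## Model

The package implements an autoregressive point-process network model for
binned spike counts (default dt = 10 ms). For neuron i at bin u the input
current is

    H_i(u) = h_i + Σ_{m=1..M} Σ_j k_ij(m·dt) S_j(u−m) − Σ_{x=1..5} g^(x) c_i^(x)(u)

with M = 150 ms / dt = 15 lags. The rate of bin u is λ_i(u) = f[H_i(u)]:
counts in a bin never influence that bin's own rate, and the SFA state
used for bin u integrates counts through u−1. The first M bins of any
record serve as history context only (both in the likelihood and in
simulation).

**Raised-cosine kernels.** Cross-neuron kernels use 4 basis functions
(a = 1.153, δ = 0.2560 ms, φ = (π/2)·(−1,0,1,2)); self-kernels (present
only in exponential-transfer variants) use 6 (a = 2.974, δ = 0.3477 ms,
φ = (π/2)·(−2,3,4,5,6,7)). Each bump is ½[1 + cos(a·ln(Δ+δ) − φ)] on its
single period |a·ln(Δ+δ) − φ| ≤ π and zero outside — the standard
windowing, without which the cosine oscillates over all lags — plus a hard
cutoff at 150 ms. δ is in ms and the log is natural. On a 10-ms lag grid
the two earliest off-diagonal bumps and the earliest diagonal bump have
essentially no support; their coefficients are retained (the accounting
follows the basis definition) but carry no gradient.

**Variant constraints.** The transfer function decides the
self-interaction mechanism: sigmoid variants carry it through SFA and have
no self-kernels; exponential variants carry it through diagonal
self-kernels and have g = 0. Off-diagonal weight tensors have structurally
zero diagonals in all variants. The NegBin dispersion r_NB is never
inferred; `calibrate_r_nb` fixes it from the recording's sparseness
(median per-bin count m, threshold 5m, variance-to-mean target 2 ⇒
r_NB = 5m — 0.185 at m = 0.037).

**Numerical safeguards.** Rates are floored at 1e−12 inside log-pmfs;
exponential-transfer currents are capped at H = 30 (e^30 counts/bin is far
beyond physical rates) to keep early optimizer epochs finite; the sigmoid
is evaluated through log-sigmoid/softplus so large |H| never overflows.

## Inference

The teacher-forced log-likelihood Σ_u Σ_i log p(S_i(u) | λ_i(u)) is
maximized with iRprop+. Gradients are analytic throughout, including the
SFA-timescale sensitivities via the recursion
d(u) = (1−α)d(u−1) + (dt/τ²)(c(u−1) − S(u−1)); τ, λ∞ and γ are optimized
in the log domain to preserve positivity. SFA gains are shared across
neurons per timescale by default (a per-neuron option exists); timescales
are always shared.

iRprop+ defaults: η+ = 1.2, η− = 0.5, step_init = 1e−3, bounds
[1e−8, 1], per-parameter steps, update-revert on a sign flip that
coincides with a likelihood drop. Initialization: zero couplings,
intercepts from inverting the transfer at each neuron's mean count,
g = 0.01, τ log-spaced in [50 ms, 5 s], λ∞ = 2× the maximum observed
count, γ = 1. Stopping: relative LL change < 1e−7 for 10 consecutive
epochs, or max_epochs. The external currents h_i are trainable in every
variant (fitting sparse data without an intercept is ill-posed), although
the conventional parameter-count formulas, which `count_parameters`
reproduces, list only kernels (+SFA/transfer) — 4N(N−1)+6N for
exponential variants versus 4N(N−1)+12 for sigmoid ones.

Preprocessing follows standard MEA practice: channels with mean rate
below 0.1 Hz are dropped (`SpikeCountMatrix.drop_silent`, configurable).

## Simulation

Driven mode computes the deterministic one-step-ahead rate from the
reference recording; emitted counts never re-enter. Free mode feeds
sampled counts back into both the synaptic history and the SFA state.
Protocols are ordered segment lists; the history buffer and SFA state are
carried across mode switches, so a driven→free run is bit-identical to
the all-driven run up to the switch. A generator override swaps only the
count distribution ("Poisson replay"), leaving Eqs. for H, c and λ
untouched. All sampling flows through an explicit seeded
`numpy.random.Generator`; (params, protocol, reference, seed) fully
determine a run.

## Subsampling / hidden-input analysis

The marginal count distribution under unobserved inputs,
p(S|H) = ∫ Poisson(S | f[H + h_hid]) p(h_hid) dh_hid, is estimated by
Monte Carlo with h_hid Gaussian or a scaled-and-shifted resampling of
empirical currents. `moment_match` solves for (shift, scale) by nested
bisection under common random numbers — the mixture mean is monotone in
the shift at fixed scale, and the variance at the mean-matched shift is
monotone in the scale. Pmf supports are truncated where the residual mass
is below 1e−10. Poisson mixtures are always super-Poisson (law of total
variance), so sub-Poisson targets are rejected.

## Burst detection and spatio-temporal statistics

The reference detector for these data is not restated in the literature
we build on, so the package adopts a standard dual-threshold hysteresis
rule on the (3-bin moving-average) population rate: a burst opens where
the smoothed rate reaches θ_hi and extends while it stays ≥ θ_lo, with
θ expressed in multiples of the median nonzero *raw* population rate
(equal to 1 count/bin for sparse recordings). Defaults θ_hi = 5×,
θ_lo = 2×, merge gap < 100 ms, discard duration < 50 ms; every parameter
is exposed in `BurstConfig`. Amplitude is the total spike count over the
half-open [onset, offset) interval.

Time-ranks are 0-based first-spike bins since burst onset, with NaN for
neurons silent within a burst. Rank-vector distances default to the
"duration" convention — a silent neuron contributes its burst's length in
bins, padding all bursts into a common space — with a "participating"
alternative (distance over neurons active in both bursts; empty overlaps
excluded and counted). Shuffle surrogates permute each neuron's ranks
independently across bursts, exactly preserving per-neuron rank
multisets. Pearson correlations use sample (n−1) normalization;
the IBI→amplitude correlation pairs each burst's amplitude with the
interval since the previous burst and reports a seeded bootstrap CI.
Kernel-strength versus electrode-distance profiles fit A·exp(−d/ξ) to
distance-binned means of |kernel area| by nonlinear least squares,
separately for positive- and negative-area (excitatory/inhibitory) pairs;
non-decaying profiles are flagged rather than fitted.

The post-burst protocol exploits that the driven-mode state at the
release bin is a deterministic function of the reference: the history
window and SFA state are computed once and shared by all free
continuations, which differ only in their sampled counts.

## Synthetic ground truth

`make_ground_truth` plants a sig_negbin network whose free dynamics
emulate the recordings: sparse counts (target median 0.037/bin),
fluctuation-ignited population bursts, multi-second irregular IBIs.
Construction: neurons occupy an 8×8-minus-corners MEA grid (subsampled
evenly for N < 60); 20% of presynaptic neurons are inhibitory; kernel
magnitudes decay with distance (ξ_exc = 2 < ξ_inh = 4 grid pitches, so
excitation is more local) with lognormal jitter (σ = 0.4); each neuron's
summed excitatory kernel mass is normalized to 4.4·√N (per-pair weights
~1/√N, the balanced-network scaling — the √N total keeps
fluctuation-driven ignition effective across sizes), with inhibitory mass
at 35% of that. SFA is planted on exactly two of the five slots: τ =
(0.1 s, 2 s) with gains (2.2, 8.0) — the fast current terminates bursts,
the slow one spaces them. Transfer: λ∞ = 1 count/bin (100 Hz ceiling),
γ = 1; generator: NegBin r = 0.22.

External currents start at the value putting the uncoupled down-state at
0.02 counts/bin and are tuned by a short secant loop on probe simulations
(default 6 × 300 s probes) toward the target median count. A candidate is
accepted only if a fresh probe shows median count within 3× of target, at
least 5 bursts, IBI CV in (0.3, 1.5), and < 20% of rates near saturation;
failing candidates have their weights redrawn (up to 3 attempts) before
an error with diagnostics is raised. Defaults were chosen once to land in
the bursting regime and are not adjusted per run.

What the generator does *not* emulate: electrode-level artifacts
(cross-talk, thresholding, sorting errors), non-random subsampling of the
culture, slow excitability drifts, and short-term synaptic
facilitation/depression (e.g. the burst "doublets" real cultures show).
Passing tests therefore demonstrate self-consistency of inference and
analysis on data generated by the model class itself — not that real
recordings satisfy the model.

## Problem sizes and determinism

The test suite's recovery check fits N = 10 neurons on T = 2×10⁵ bins
(2000 s) for 300 iRprop+ epochs; the acceptance script's recovery uses
N = 8, T = 10⁵, 200 epochs — sizes chosen so each completes in minutes on
one core while leaving the recovery criteria (kernel-area Pearson r,
SFA-timescale factor) comfortably resolved. Mechanism-direction
experiments use 10 dwell-time repeats on a 5-neuron bistable toy and
80–100 post-burst continuations at horizon 25 s. Every stochastic
operation takes an explicit `numpy.random.Generator`; identical seeds
give bit-identical results on a given platform.

## Known limitations

- The likelihood is evaluated in teacher-forced mode only; there is no
  multi-step predictive scoring (bursts in this regime are intrinsically
  unforecastable more than a few hundred ms ahead).
- No regularization or sparseness priors on connectivity; with short
  records weak kernels are noisy even when the area correlation is high.
- `count_parameters` follows the conventional accounting (kernels + SFA +
  transfer); intercepts, though trainable, are excluded there.
- The NegBin–Poisson comparison at equal parameters ignores that a real
  re-fit under a Poisson generator would partially compensate through the
  couplings; mechanism-direction experiments hold parameters fixed by
  design.
- Hysteresis burst detection has no sub-bin timing; onset/offset accuracy
  is limited to ±1 bin even on clean data.
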