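# Methods

This note documents the models, estimators and numerical conventions the
package implements, the choices made where several were defensible, and the
limits of what the synthetic-data tests demonstrate.

## Gating model and patch simulator

Each channel is an independent two-state (closed ⇌ open) Markov process.
Given a stationary open probability `p_open` and a mean open dwell time
τ_o (`mean_open_dwell`, seconds), the rates are

    closing rate  β = 1/τ_o
    opening rate  α = p_open / ((1 − p_open)·τ_o)

so that α/(α+β) = p_open.  Gating is simulated in discrete time at the
sampling rate: the per-step leave probability is 1 − exp(−rate·Δt), which
is exact for the embedded chain observed at sample resolution.
Implementation-wise the sojourns are drawn as geometric run lengths, which
is distributionally identical to stepping the chain and much faster for
slow gating.  Channels start in their stationary distribution.

The recorded current is `baseline + k(t)·i + ε(t)` with `k(t)` the number
of open channels, `i` the signed unitary amplitude (inward negative,
≈ −0.3 pA for the channels of interest at −60 mV) and ε white Gaussian
noise of SD `noise_sd`, applied before filtering.  Digital filtering is a
zero-phase Gaussian FIR with −3 dB at the configured cutoff (default
0.1 kHz at 10 kHz sampling) — monotone step response, no ringing, the
standard display filter for single-channel records.

**Default kinetics.**  τ_o defaults to 250 ms.  ENaC gating is slow —
reported open and closed dwells run from hundreds of milliseconds to
seconds — and the default must also respect a constraint of the analysis
itself: a 0.1 kHz Gaussian filter effectively erases roughly the first
c ≈ 2.8 ms of every sojourn (the blurred transition never reaches the
level), so a state with mean dwell τ loses about 1 − exp(−c/τ) of its
measured occupancy.  At τ_o = 250 ms every dwell implied by the operating
points used in the tests stays ≥ 10× c and occupancy distortion is below
1%.  Much faster kinetics (τ in the few-ms range) would bias any
histogram-based occupancy method, this one included; kinetics are user
parameters, not estimates, and the simulator will happily demonstrate the
bias if asked.

## Amplitude histogram and constrained mixture fit

Histograms use a fixed bin width (default 0.01 pA) with bin centers
snapped to integer multiples of the width, covering the observed range.
Level detection finds peaks on lightly smoothed log(1+counts) — rare
high-occupancy levels sit orders of magnitude below the modal peak, so
prominence must be judged on a log scale — with a minimum separation of
half the estimated level spacing, and snaps each peak to the local raw
maximum.  The baseline is the least-inward peak; the initial unitary
amplitude is the signed median peak spacing.

The mixture fit minimizes unweighted least squares between per-bin counts
and the model, with the component means constrained structurally to
µ_k = µ_0 + k·i (never penalized).  Numerical conventions:

* Each component's bin contribution is its Gaussian mass integrated over
  the bin (A_k times a CDF difference).  This reduces to the familiar
  density×width approximation for wide components but remains well posed
  when the filtered noise is narrower than a bin.
* The fit is evaluated against the observed bins plus guard bins of zero
  counts extending 4 σ-bounds past each end.  Currents outside the observed
  range genuinely never occurred; without the guard bins the optimizer can
  hide surplus component mass beyond the histogram's support.
* σ_k are free per component (a shared-σ mode exists for sparse levels),
  floored at a quarter bin (narrower is unresolvable) and capped at half
  the level spacing (wider no longer represents a discrete level; without
  the cap a rare top level can degenerate into a trace-wide background
  component).
* µ_0 is bounded to the observed current range.  Initialization comes from
  level detection; five jittered restarts (fixed jitter seed) run only if
  the first fit fails to converge.
* R² is reported against the mean observed count.  Increasing the
  component count cannot lower the achievable R²; extra components park at
  zero weight.

## Occupancies, binomial fit and channel-count scan

Occupation probabilities are the normalized component weights,
P_k = A_k/ΣA_j (enforced to sum to 1 within 1e-9).  For an assumed channel
count N the open probability minimizes

    Σ_k (P_k_obs − B(k | P_o, N))²

over the levels the anchoring maps onto 0..N.  Two conventions:

* `baseline_closed` (default): observed level j ↦ j channels open.  With
  N set to the number of observed open levels (the minimum N that explains
  the record) the estimate is an upper bound: scanning larger N can only
  lower it.
* `top_open`: the most-inward observed level ↦ all N open, the baseline ↦
  0, interior observed levels spread proportionally.  This is the
  treatment for records whose single open level plausibly hides several
  co-gating channels; scanning larger N raises the estimate when the open
  level dominates (occupancy ≥ 0.5 — the direction is provably not
  universal below that, and the anchoring is not scientifically meaningful
  there either).

Levels never observed under a mapping enter the objective with observed
probability 0 by default; an `observed_only` objective that drops them is
available because published analyses are ambiguous on this point.  The
minimizer uses a 1e-4 grid refined by bounded scalar minimization; the
N = 1 fully-observed case uses the closed form P_o = (1 − P_0 + P_1)/2
exactly.  R² = 1 − SS_res/SS_tot with SS_tot about the mean of the fitted
observations; ties across N resolve to the smallest N.

## Whole-cell simulator and estimators

The TEVC simulator produces `I(t) = leak + n·i·P_o(t)·g(t)·r(t)·b(t) + ε`
at 20 Hz: `g` a per-epoch conductance scale, `r(t) = exp(−λ·t/60)` the
run-down factor (λ ≈ fractional loss per minute), `b` the amiloride block
(complete by default, residual fraction configurable).  A protease epoch
multiplies P_o from its end onward (amiloride is co-applied during the
exposure, as in protocols that avoid sodium loading); an MTSET epoch sets
P_o to `p_open_after_mtset` instantly at its start, with the unitary
conductance unchanged unless `mtset_conductance_factor` explores the
conductance-reduction caveat.

ΔI_Ami is the difference between plateau means over the trailing 5 s
(configurable) of the epoch preceding an amiloride application and of the
amiloride epoch itself — leak cancels, so the measure is invariant to a
constant offset.  Fold change is after/before across a treatment; relative
activity is before/after across MTSET and equals the baseline P_o exactly
in a noise-free simulation.  Run-down is deliberately not corrected:
treatment fold changes are meant to be compared against mock-treated
controls, whose fold change (< 1) reflects run-down alone.  Group
summaries report mean, sample SD (n−1) and n.

## What the synthetic tests do and do not show

The simulator reproduces the statistical structure the estimators assume:
independent identical two-state channels, a strict equidistant amplitude
ladder, stationary Gaussian noise, ideal solution exchange, complete
amiloride block.  Passing recovery tests therefore demonstrates
correctness of the inference chain under its own assumptions, at the
stated problem sizes (60 s patches at 10 kHz; ten-seed medians or 7–11
record ensembles).  It does not demonstrate robustness to what real
records add: baseline drift, flickery/bursting gating, heterogeneous
channels, incomplete block, capacitive transients or solution-exchange
artifacts.  Sub-conductance states and multi-state kinetics are out of
scope by design.

## Problem sizes used in the recovery checks

Recovery checks run at the operating points of interest: ten 60 s
six-channel records (true P_o 0.34, i = −0.35 pA) for the median-recovery
and unitary-amplitude checks; seven single-channel records at P_o 0.879;
eleven records with 3–7 channels (mean 4.6) at P_o 0.395; 100 random
profiles against an exhaustive-grid oracle for the binomial fit; 20
simulations across P_o ∈ {0.2, 0.34, 0.5, 0.8, 0.9} for the
median-absolute-error property.  These sizes give each stochastic check a
standard error several times smaller than its tolerance.
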