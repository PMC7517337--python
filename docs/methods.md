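# Methods

`cmboot` infers minimal unifilar hidden-state models (ϵ-machines) from a
single binary (or finite-alphabet) symbol sequence, computes
information-dynamic measures exactly from such models, and quantifies the
uncertainty of the plug-in estimates with a model-based bootstrap expressed
as a confidence distribution. This note records the model assumptions, the
algorithmic and numerical choices that were genuinely open, and what the
built-in simulation studies do and do not establish.

## Process model and measures

A stationary stochastic process over a finite alphabet X is represented by
its causal states: equivalence classes of pasts with identical conditional
distributions over futures. The resulting hidden-state model (the
ϵ-machine) is *unifilar* — the pair (state, emitted symbol) determines the
successor state — which makes three measures exactly computable:

- **Entropy rate** hμ = −Σ_s π(s) Σ_x P(x|s) log₂ P(x|s), the intrinsic
  randomness in bits/symbol, with π the stationary state distribution.
- **Statistical complexity** Cμ = −Σ_s π(s) log₂ π(s), the memory (bits)
  needed for optimal prediction.
- **Excess entropy** E, the past–future mutual information, computed as the
  truncated cumulative sum Σ_{L=1..Ltr} (hμ(L) − hμ) with default
  Ltr = 200, where hμ(L) = H(L) − H(L−1) is the block-entropy difference
  (the L = 1 term conditions on nothing, so it equals H[X₀] − hμ). Under
  this convention H[X₁..X_L] → E + hμ·L, and the truncated sum reproduces
  the exact values of the benchmark processes to eight decimals. Always
  E ≤ Cμ.

Finite-history conditional entropies hμ(L) are obtained from the
*mixed-state* (belief) presentation: the stationary belief over hidden
states is pushed forward through observed words, beliefs equal within an
∞-norm tolerance of 1e-9 are merged, and the next-symbol entropies of the
terminal beliefs are averaged under the word distribution. This works for
nonunifilar sources too, where the entropy rate is taken as the large-L
limit of hμ(L) (stopped when successive values differ by < 1e-10).

For the simple nonunifilar source — whose ϵ-machine has countably many
causal states indexed by the number of 1s since the last 0 — the
statistical complexity is computed over that chain with stationary weights
accumulated until the remaining tail mass is below 1e-10.

### Numerical safeguards in the belief engine

Estimated machines occasionally fail to synchronize (an artifact of
overfitting at deep histories), and their reachable belief sets grow
exponentially. Two safeguards keep the computation exact where it matters
and gracefully approximate where exactness is unattainable:

- If the atom set exceeds 256, the merge tolerance is escalated tenfold at
  a time up to a ceiling of 1e-6; past the ceiling the lightest atoms are
  pruned and the weights renormalized. Synchronizing models (all benchmark
  processes, and virtually all well-fit machines) never trigger either.
- The excess-entropy increments hμ(L) − hμ are nonincreasing. The sum stops
  early when they drop below 1e-13 (omitted tail < Ltr·1e-13), and when
  they plateau at a positive constant — the signature of a
  non-synchronizing presentation, whose observer entropy rate exceeds the
  internal one — the constant tail up to Ltr is added in closed form.

## CSSR estimation

The Causal State Splitting Reconstruction estimator proceeds in three
phases on the table of next-symbol counts after every observed history of
length ≤ Lh (sliding window over the single realization; positions with a
too-short preceding context are skipped; the empty-history row counts all
T symbols).

1. **Splitting.** One state initially holds the empty history. For
   ℓ = 0..Lh−1 each member history is extended one symbol into the past and
   the child's counts are tested against its parent state's pooled counts
   with a two-sample chi-squared homogeneity test at level α (default
   0.001; zero-expectation cells dropped). A rejected child joins the
   non-rejecting state with the largest p-value, or founds a new state.
   Children with fewer than 5 observations are not tested and follow their
   parent.
2. **Determinization.** States whose member histories disagree about the
   successor state under symbol extension are split until every
   (state, symbol) pair has a unique successor. The successor of history w
   on symbol x is the state containing the *full* extension w·x; histories
   whose extension is untracked (length Lh members) impose no constraint.
   Truncating extensions to a length-Lh suffix instead would conflate
   synchronized histories with unsynchronized ones: for the even process
   this provably weaves the ambiguous all-1s suffix classes into the
   recurrent part at every finite Lh, and the correct 2-state architecture
   would never be recovered. With full extensions those classes become
   transient and are removed.
3. **Recurrent core.** Cells whose observed emissions lack a successor at
   this depth (structure not resolvable at Lh) are pruned iteratively; if
   nothing survives the estimator returns the memoryless 1-state machine,
   and order selection moves to a deeper fit. The recurrent communicating
   class of the remainder is kept, with emissions re-estimated from pooled
   member counts.

## Likelihood and order selection

The likelihood of a sequence under a machine is the stationary mixture over
start states. When the candidate-state set collapses to a singleton after
Lsynch observations, the likelihood factors into a head term (mixture up to
Lsynch) and a tail of conditional emissions along the now-deterministic
state path; otherwise a scaled forward pass is used. Both routes agree to
floating-point precision on synchronizing sequences.

The history length is chosen by BIC = −2·lnL + dim·ln T (natural log), with
dim = (|X|−1)·|S| for machines and (|X|−1)·|X|^L for order-L Markov chains,
over L = 1..Lmax with Lmax = ⌊log₂T / log₂|X| − 1⌋ (at least 1). Ties break
toward the smaller order, where a tie means a BIC difference ≤ 1 — the
conventional "no evidence" band. This matters in practice: when the same
small machine is re-estimated at every depth the BIC profile is flat to
within a fraction of a unit, and a raw float argmin would pick an
arbitrary, often deep, order. Markov chains are fit by conditional maximum
likelihood (the first L symbols condition and contribute no factor; unseen
contexts get probability zero — no smoothing).

## Bootstrap confidence distributions

The computational mechanics bootstrap fits a machine at the BIC-chosen L0,
then B times: samples a same-length series from the fitted machine
(stationary start), re-runs CSSR at the *same* L0, and records the plug-in
(hμ, E, Cμ). The Markov-model bootstrap does the same with the BIC-chosen
Markov chain embedded as a machine (one state per context — which inflates
Cμ whenever distinct contexts are predictively equivalent). Per-replicate
seeds are base seed + replicate index; replicates whose refit degenerates
are redrawn with an advanced seed and the redraw count is recorded.

The empirical CDF of the bootstrap estimates is the percentile confidence
distribution C(θ). The bias-corrected variant is
Φ(Φ⁻¹(F̂(θ)) − 2z₀) with z₀ = Φ⁻¹(F̂(θ̂)); F̂ values are clamped to
[1/(B+1), B/(B+1)] before the probit so degenerate bootstrap distributions
cannot produce infinite z-scores. When F̂(θ̂) = 1/2 the two coincide.
P-values are C(θ₀) (right), 1 − C(θ₀) (left), 2·min{C, 1−C} (two-sided);
the confidence curve is |2C − 1|; equi-tailed intervals are
(C⁻¹(α/2), C⁻¹(1−α/2)) with type-1 (inverse-ECDF) quantiles, so interval
endpoints are attained bootstrap estimates.

## The process zoo and what the simulations show

Four binary benchmark families drive the Monte Carlo harness:

- **even(p)** — runs of 1s of odd length forbidden; 2 causal states; sofic
  (not Markov of any order). Default p = 1/2, the unique branch probability
  consistent with hμ = 2/3 and Cμ = 0.91829583 bits jointly; then E = Cμ.
- **sns** — the simple nonunifilar source, canonical all-1/2 parameters:
  state A always emits 1 (to A or B equiprobably), state B emits 0 (to A)
  or 1 (stay). The 0 synchronizes the observer; the process is not
  finitary. Exact values: hμ = 0.67786718, E = 0.14723194, Cμ = 2.71146872
  bits.
- **renewal(interevent)** — chain-structured machine with a unique start
  state; the hazard at waiting position i is w_i / Σ_{j≥i} w_j. A 3-state
  renewal spec reproduces the structural property that pasts (0,1) and
  (1,1) are predictively equivalent.
- **alternating_renewal(runs0, runs1)** — two chained renewal halves, one
  per symbol, with unique start states for the first 0 and the first 1 of
  each run.

The harness simulates S series, bootstraps each, and reports empirical
interval coverage minus nominal (with binomial standard errors
√(p(1−p)/S)), the p-value ECDF at the true value, and rejection rates
across a θ₀ grid. Defaults are S = 100, B = 200 — a reduced but still
informative scale; a full-scale study (S = 2000, B = 2000) is a
configuration change. The power experiment's significance level defaults to
0.05. Per-replicate failures are counted and excluded, never silently
dropped.

The generator emulates exactly the study conditions above: stationary,
noiseless observations of a known finite (or countable) hidden structure.
Passing tests therefore demonstrate calibration *in class* (and the
documented failure modes out of class, e.g. the Markov bootstrap's 0%
coverage on the even process); they say nothing about nonstationary data,
observational noise, or alphabets discretized from continuous signals —
all of which real spike trains or activity records may exhibit.

## Known limitations

- CSSR with history length Lh resolves structure needing memory m only
  when Lh ≥ m + 1 (transitions require fully tracked extensions); BIC
  handles this by moving to deeper fits, at the price of occasional
  overfit refits at large Lh inside the bootstrap.
- Truncating the excess-entropy sum at Ltr = 200 under-reports processes
  with memory longer than ~200 symbols; the truncation depth is a
  parameter.
- The bias-corrected distribution implements the standard z₀ construction;
  no acceleration (BCa) term is estimated.
- Block bootstraps and per-replicate re-selection of L0 are intentionally
  out of scope (re-selection is available behind a flag in the library
  API but off by default).
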