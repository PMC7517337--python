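"""Information-dynamic measures computed exactly from process models.

Three measures are computed, all in bits:

* entropy rate ``h_mu`` — the per-symbol conditional entropy of the next
  symbol given the infinite past.  For a unifilar machine this is the
  stationary average of the state emission entropies; for a nonunifilar
  source it is the large-L limit of the finite-history rates ``h_mu(L)``.
* excess entropy ``E`` — the mutual information between past and future,
  computed as the truncated cumulative sum of ``h_mu(L) - h_mu``.
* statistical complexity ``C_mu`` — the Shannon entropy of the stationary
  distribution over causal states; always ``C_mu >= E``.

The finite-history rates ``h_mu(L) = H[X_0 | X_{-L..-1}]`` are obtained from
the mixed-state (belief) presentation: the stationary belief over hidden
states is pushed forward through every length-L word, beliefs equal within
an infinity-norm tolerance are merged, and the next-symbol entropies of the
terminal beliefs are averaged under the word distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .machines import (
    EpsilonMachine,
    HmmSource,
    MarkovChainModel,
    markov_to_machine,
    stationary_distribution,
)

__all__ = [
    "MeasureSet",
    "entropy_rate",
    "statistical_complexity",
    "block_entropy_rate",
    "block_entropy_series",
    "excess_entropy",
    "measure_set",
]

#: default truncation depth for the excess-entropy cumulative sum
DEFAULT_LTR = 200

#: beliefs whose coordinates agree within this are merged into one atom
BELIEF_MERGE_TOL = 1e-9

#: when the atom set exceeds this, the merge tolerance is escalated (the
#: belief space is coarse-grained) until the set fits again
BELIEF_CAP = 256

#: increments below this are treated as converged (they are nonincreasing,
#: so the truncated tail they replace is bounded by LTR times this value)
_INCREMENT_FLOOR = 1e-13


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


@dataclass
class MeasureSet:
    """Bundle of entropy rate, excess entropy, and statistical complexity."""

    hmu: float
    E: float
    Cmu: float
    Ltr: int = DEFAULT_LTR
    hmu_L: np.ndarray | None = field(default=None, repr=False)
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"h_mu": self.hmu, "E": self.E, "C_mu": self.Cmu, "Ltr": self.Ltr}

    def __iter__(self):
        return iter((self.hmu, self.E, self.Cmu))


def entropy_rate(m: EpsilonMachine | MarkovChainModel) -> float:
    """Entropy rate in bits/symbol of a unifilar machine or Markov chain.

    h_mu = -sum_s pi(s) sum_x P(x|s) log2 P(x|s); the causal state is
    predictively sufficient, so no limit is needed.
    """
    if isinstance(m, MarkovChainModel):
        m = markov_to_machine(m)
    pi = stationary_distribution(m)
    h = 0.0
    for i in range(m.n_states):
        h += pi[i] * _entropy_bits(m.emit[i])
    return float(h)


def statistical_complexity(m: EpsilonMachine) -> float:
    """Shannon entropy (bits) of the stationary causal-state distribution."""
    if isinstance(m, MarkovChainModel):
        m = markov_to_machine(m)
    return _entropy_bits(stationary_distribution(m))


class _BeliefPropagator:
    """Mixed-state push-forward with adaptive belief coarse-graining.

    Atoms map a rounding key to (representative belief, probability).  Each
    ``step`` returns the probability-weighted next-symbol entropy of the
    current atoms (h_mu at the current conditioning depth) and advances the
    atom set by one observed symbol.  Beliefs within ``tol`` (infinity
    norm, via coordinate rounding) are merged; whenever the atom count
    exceeds ``cap`` — which happens only for models whose observer never
    synchronizes — the tolerance is escalated tenfold and the set re-merged,
    trading a bounded entropy error (the next-symbol entropy is continuous
    in the belief) for a finite state space.
    """

    def __init__(self, m, cap: int = BELIEF_CAP, tol: float = BELIEF_MERGE_TOL) -> None:
        pi = stationary_distribution(m)
        self.T = m.symbol_matrices()
        self.k = len(m.alphabet)
        # column j of rowsums is the emission probability of symbol j given
        # a pure hidden state
        self.rowsums = np.stack([self.T[x].sum(axis=1) for x in range(self.k)], axis=1)
        self.cap = cap
        self.tol = tol
        self.beliefs = pi.reshape(1, -1)
        self.weights = np.ones(1)

    #: tolerance is never escalated beyond this; past it the lightest atoms
    #: are pruned instead (weights renormalized), keeping the entropy error
    #: bounded by the pruned mass rather than by arbitrary coarsening
    TOL_MAX = 1e-6

    def _merge(self) -> None:
        keys = np.round(self.beliefs / self.tol).astype(np.int64)
        # 64-bit multiplicative hash of the rounded coordinates: collisions
        # wrap harmlessly modulo 2**64 and are vanishingly unlikely for the
        # few thousand atoms ever held here
        if not hasattr(self, "_hashmul") or self._hashmul.size != keys.shape[1]:
            self._hashmul = np.random.default_rng(0x5EED).integers(
                1, 2**62, size=keys.shape[1], dtype=np.int64
            ) | 1
        with np.errstate(over="ignore"):
            hashed = keys @ self._hashmul
        _, first, inverse = np.unique(hashed, return_index=True, return_inverse=True)
        self.weights = np.bincount(inverse, weights=self.weights)
        self.beliefs = self.beliefs[first]

    def _prune(self) -> None:
        order = np.argsort(self.weights)[-self.cap :]
        total = self.weights.sum()
        self.weights = self.weights[order]
        self.weights *= total / self.weights.sum()
        self.beliefs = self.beliefs[order]

    def step(self) -> float:
        A, w = self.beliefs, self.weights
        pem = A @ self.rowsums  # (atoms, k)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(pem > 0, pem * np.log2(pem), 0.0)
        h = float(-(w * plogp.sum(axis=1)).sum())
        parts_b, parts_w = [], []
        for x in range(self.k):
            px = pem[:, x]
            mask = px > 1e-15
            if not mask.any():
                continue
            nb = (A[mask] @ self.T[x]) / px[mask, None]
            parts_b.append(nb)
            parts_w.append(w[mask] * px[mask])
        self.beliefs = np.concatenate(parts_b, axis=0)
        self.weights = np.concatenate(parts_w)
        self._merge()
        while len(self.weights) > self.cap and self.tol < self.TOL_MAX:
            self.tol *= 10.0
            self._merge()
        if len(self.weights) > self.cap:
            self._prune()
        return h


def block_entropy_series(
    m: EpsilonMachine | HmmSource, Lmax: int
) -> np.ndarray:
    """The series h_mu(L) = H[X_0 | X_{-L..-1}] for L = 1..Lmax, in bits.

    Propagates the stationary belief over hidden states through observed
    words, merging numerically equal beliefs, so the cost is linear in Lmax
    for synchronizable machines and for chain-structured nonunifilar
    sources.
    """
    if Lmax < 1:
        raise ValueError("Lmax must be >= 1")
    prop = _BeliefPropagator(m)
    out = np.empty(Lmax)
    # the atoms after L observed symbols yield H[X_0 | X_{-L..-1}]; the
    # first step conditions on nothing and is discarded here.
    prop.step()
    for L in range(Lmax):
        out[L] = prop.step()
    return out


def block_entropy_rate(m: EpsilonMachine | HmmSource, L: int) -> float:
    """h_mu(L) for a single depth L >= 1."""
    return float(block_entropy_series(m, L)[-1])


def _limit_entropy_rate(m: HmmSource, tol: float = 1e-10, max_L: int = 10_000) -> float:
    """Large-L limit of h_mu(L) for a nonunifilar source (Blackwell limit).

    Stops at the first L where successive values differ by less than tol.
    """
    prop = _BeliefPropagator(m)
    prop.step()
    prev = None
    for _ in range(max_L):
        h = prop.step()
        if prev is not None and abs(h - prev) < tol:
            return h
        prev = h
    raise RuntimeError("entropy-rate limit did not converge")


def excess_entropy(
    m: EpsilonMachine | HmmSource, Ltr: int = DEFAULT_LTR, hmu: float | None = None
) -> float:
    """Truncated excess entropy  sum_{L=1..Ltr} (h_mu(L) - h_mu)  in bits.

    The increments are nonnegative and nonincreasing, so the sum is stopped
    early once they fall below 1e-13; the omitted tail is then bounded by
    Ltr * 1e-13.
    """
    if hmu is None:
        hmu = (
            entropy_rate(m)
            if isinstance(m, EpsilonMachine)
            else _limit_entropy_rate(m)
        )
    prop = _BeliefPropagator(m)
    # The L-th term is h_mu(L) - h_mu with h_mu(L) = H(L) - H(L-1), the
    # entropy of the next symbol given L-1 observed symbols; the L = 1 term
    # is therefore H[X_0] - h_mu.  This is the convention under which the
    # block entropies satisfy H[X_1..X_L] -> E + h_mu * L.
    #
    # The increments are nonincreasing; two stopping rules apply.  If they
    # fall below the floor, the omitted tail is below Ltr * 1e-13.  If they
    # plateau at a positive constant — which happens for non-synchronizing
    # presentations, where h_mu(L) converges to the observer's entropy rate
    # strictly above the internal one — the constant tail up to Ltr is
    # added in closed form.
    E = 0.0
    prev = None
    for L in range(Ltr):
        inc = prop.step() - hmu
        if inc < _INCREMENT_FLOOR:
            break
        E += inc
        if prev is not None and abs(prev - inc) < 1e-6 * inc:
            E += inc * (Ltr - L - 1)
            break
        prev = inc
    return float(E)


def _sns_like_causal_complexity(m: HmmSource, tail_mass: float = 1e-10) -> float:
    """Statistical complexity of a nonunifilar source with a synchronizing
    reset symbol.

    Applies to sources where some symbol is emitted from exactly one belief
    and resets it (here: the causal states are indexed by the count of
    non-reset symbols since the last reset).  The stationary weights of the
    countable causal-state chain are accumulated until the remaining tail
    mass is below ``tail_mass``.
    """
    T = m.symbol_matrices()
    k = len(m.alphabet)
    # find a reset symbol: one whose matrix has a single positive column
    reset = None
    for x in range(k):
        cols = np.nonzero(T[x].sum(axis=0) > 0)[0]
        if len(cols) == 1:
            reset = x
            target = int(cols[0])
            break
    if reset is None:
        raise ValueError(
            "no synchronizing reset symbol found; causal-state chain "
            "construction does not apply"
        )
    others = [x for x in range(k) if x != reset]
    b = np.zeros(m.n_states)
    b[target] = 1.0
    weights = []
    w = 1.0
    while w >= tail_mass:
        weights.append(w)
        p_reset = float(b @ T[reset].sum(axis=1))
        w *= 1.0 - p_reset
        nb = sum(b @ T[x] for x in others)
        s = nb.sum()
        if s == 0:
            break
        b = nb / s
    pi = np.array(weights)
    pi /= pi.sum()
    return _entropy_bits(pi)


def measure_set(
    m: EpsilonMachine | HmmSource | MarkovChainModel, Ltr: int = DEFAULT_LTR
) -> MeasureSet:
    """Compute (h_mu, E, C_mu) with provenance for any supported model."""
    if isinstance(m, MarkovChainModel):
        m = markov_to_machine(m)
    notes = []
    if isinstance(m, EpsilonMachine):
        hmu = entropy_rate(m)
        Cmu = statistical_complexity(m)
    else:
        hmu = _limit_entropy_rate(m)
        Cmu = _sns_like_causal_complexity(m)
        notes.append("C_mu over the synchronized causal-state chain, tail mass < 1e-10")
    E = excess_entropy(m, Ltr=Ltr, hmu=hmu)
    return MeasureSet(hmu=hmu, E=E, Cmu=Cmu, Ltr=Ltr, notes=notes)
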