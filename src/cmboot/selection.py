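"""Likelihood evaluation and BIC-based history-length selection.

Two model families are fit to a symbol sequence:

* epsilon-machines estimated by CSSR at history lengths L = 1 .. Lmax, with
  the full stationary-mixture likelihood (factored through the
  synchronization time when the observer synchronizes);
* Markov chains of order L = 1 .. Lmax with conditional maximum-likelihood
  transition probabilities.

The order is chosen to minimize BIC = -2 log-likelihood + dim * ln T, with
dim = (|X| - 1) * |S| for a machine (the number of free transition
probabilities) and dim = (|X| - 1) * |X|**L for a Markov chain.  Log-
likelihoods use natural log throughout; information measures elsewhere in
the package are in bits.  Lmax = floor(log2 T / log2 |X| - 1), at least 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cssr import cssr_estimate
from .machines import (
    EpsilonMachine,
    MarkovChainModel,
    SymbolSequence,
    stationary_distribution,
)

__all__ = [
    "LikelihoodEvaluation",
    "ModelSelectionResult",
    "loglik_machine",
    "synchronization_time",
    "loglik_markov",
    "fit_markov",
    "bic",
    "max_history",
    "select_model",
]


@dataclass
class LikelihoodEvaluation:
    """Log-likelihood (natural log) plus how it was computed.

    ``method`` is "synchronized" when the likelihood was factored at the
    synchronization time (head by the stationary mixture, tail by the
    deterministic state path), "mixture" when the scaled forward pass over
    all start states was used for the whole sequence.  ``lsynch`` is the
    synchronization time, or None when the observer never synchronizes.
    """

    loglik: float
    method: str
    lsynch: int | None = None

    @property
    def impossible(self) -> bool:
        return self.loglik == -math.inf


def synchronization_time(m: EpsilonMachine, x: SymbolSequence) -> int | None:
    """Smallest t such that x_1..t is consistent with exactly one current state.

    Candidate states are propagated as a set: a start state survives while
    every observed symbol has positive emission probability along its
    (unifilar) path.  Returns 0 for a single-state machine, None if no
    prefix singles out the state ("never"), and raises no errors.  If the
    sequence is impossible from every start state the candidate set becomes
    empty; None is returned (the likelihood path will flag -inf).
    """
    n = m.n_states
    if n == 1:
        return 0
    candidates = set(range(n))
    for t, c in enumerate(x.codes, start=1):
        nxt = set()
        for s in candidates:
            if m.emit[s, c] > 0:
                nxt.add(int(m.next[s, c]))
        candidates = nxt
        if len(candidates) == 1:
            return t
        if not candidates:
            return None
    return None


def _forward_logprob(m: EpsilonMachine, codes: np.ndarray, pi: np.ndarray) -> float:
    """log P(x) under the stationary mixture, by a scaled forward pass."""
    n = m.n_states
    k = len(m.alphabet)
    # per-symbol sparse transition: for state s emitting c, weight emit[s,c]
    v = pi.copy()
    logp = 0.0
    emit = m.emit
    nxt = m.next
    for c in codes:
        new = np.zeros(n)
        for s in range(n):
            w = v[s] * emit[s, c]
            if w > 0:
                new[nxt[s, c]] += w
        tot = new.sum()
        if tot == 0.0:
            return -math.inf
        logp += math.log(tot)
        v = new / tot
    return logp


def loglik_machine(m: EpsilonMachine, x: SymbolSequence) -> LikelihoodEvaluation:
    """Stationary-mixture log-likelihood of x under a unifilar machine.

    If the observer synchronizes at time Lsynch <= T, the likelihood is
    factored as (head mixture up to Lsynch) * (product of conditional
    emissions along the now-known state path); otherwise the scaled forward
    pass is used for the full sequence.  Both routes agree to floating
    point; the factored form avoids carrying the mixture for long series.
    A sequence of probability zero under m yields loglik = -inf.
    """
    pi = stationary_distribution(m)
    codes = x.codes
    T = len(codes)
    ls = synchronization_time(m, x)
    if ls is None or ls >= T:
        return LikelihoodEvaluation(_forward_logprob(m, codes, pi), "mixture", None)
    head = _forward_logprob(m, codes[:ls], pi)
    if head == -math.inf:
        return LikelihoodEvaluation(-math.inf, "synchronized", ls)
    # recover the synchronized state by replaying candidates over the head
    candidates = set(range(m.n_states))
    for c in codes[:ls]:
        candidates = {int(m.next[s, c]) for s in candidates if m.emit[s, c] > 0}
    (s,) = candidates
    tail = 0.0
    emit = m.emit
    nxt = m.next
    for c in codes[ls:].tolist():
        p = emit[s, c]
        if p <= 0.0:
            return LikelihoodEvaluation(-math.inf, "synchronized", ls)
        tail += math.log(p)
        s = int(nxt[s, c])
    return LikelihoodEvaluation(head + tail, "synchronized", ls)


def fit_markov(x: SymbolSequence, order: int) -> MarkovChainModel:
    """Conditional maximum-likelihood Markov chain of the given order.

    Transition probabilities are the relative frequencies of the next
    symbol after each observed length-``order`` context; unseen contexts
    simply do not appear (no smoothing).
    """
    T = len(x)
    if order < 0:
        raise ValueError("order must be >= 0")
    if T <= order:
        raise ValueError("sequence shorter than the conditioning context")
    k = len(x.alphabet)
    codes = x.codes
    if order == 0:
        c = np.bincount(codes, minlength=k).astype(float)
        return MarkovChainModel(x.alphabet, 0, {(): c / c.sum()})
    windows = np.lib.stride_tricks.sliding_window_view(codes, order)
    pw = k ** np.arange(order - 1, -1, -1, dtype=np.int64)
    ctx_codes = windows[: T - order] @ pw
    nxt = codes[order:]
    flat = np.zeros(k**order * k, dtype=np.int64)
    np.add.at(flat, ctx_codes * k + nxt, 1)
    table = flat.reshape(-1, k)
    cond = {}
    for h in np.nonzero(table.sum(axis=1))[0]:
        ctx = tuple(((h // pw) % k).astype(int))
        row = table[h].astype(float)
        cond[ctx] = row / row.sum()
    return MarkovChainModel(x.alphabet, order, cond)


def loglik_markov(mc: MarkovChainModel, x: SymbolSequence) -> float:
    """Conditional log-likelihood sum_{t=L+1..T} ln P(x_t | previous L symbols).

    The first L symbols condition the first factor and contribute none of
    their own.  An unseen context or a zero conditional probability gives
    -inf (maximum likelihood, no smoothing).
    """
    T = len(x)
    L = mc.order
    if T <= L:
        raise ValueError("sequence shorter than the conditioning context")
    codes = x.codes
    total = 0.0
    ctx = tuple(int(c) for c in codes[:L])
    for t in range(L, T):
        p = mc.cond.get(ctx)
        if p is None:
            return -math.inf
        pc = p[codes[t]]
        if pc <= 0.0:
            return -math.inf
        total += math.log(pc)
        if L:
            ctx = ctx[1:] + (int(codes[t]),)
    return total


def bic(model: EpsilonMachine | MarkovChainModel, x: SymbolSequence) -> float:
    """BIC = -2 log-likelihood + dim * ln T (T = full sequence length).

    dim = (|X| - 1) * |S| for a machine and (|X| - 1) * |X|**L for a Markov
    chain.  An impossible sequence (-inf log-likelihood) propagates as +inf.
    """
    T = len(x)
    if isinstance(model, EpsilonMachine):
        ll = loglik_machine(model, x).loglik
        dim = (len(model.alphabet) - 1) * model.n_states
    else:
        ll = loglik_markov(model, x)
        dim = model.dim
    if ll == -math.inf:
        return math.inf
    return -2.0 * ll + dim * math.log(T)


def max_history(T: int, k: int) -> int:
    """Largest history length considered: floor(log2 T / log2 k - 1), >= 1."""
    if T < 2 or k < 2:
        raise ValueError("need T >= 2 and alphabet size >= 2")
    return max(1, math.floor(math.log2(T) / math.log2(k) - 1))


@dataclass
class ModelSelectionResult:
    """BIC values over L = 1..Lmax and the minimizing fit."""

    family: str
    bics: dict[int, float]
    chosen_order: int
    model: EpsilonMachine | MarkovChainModel
    models: dict = field(default_factory=dict, repr=False)


def select_model(
    x: SymbolSequence,
    family: str = "machine",
    alpha: float = 0.001,
    lmax: int | None = None,
) -> ModelSelectionResult:
    """Fit the family at every history length 1..Lmax and minimize BIC.

    Ties break toward the smaller order: the chosen L0 is the smallest L
    whose BIC is within 1 of the minimum, a difference conventionally
    regarded as no evidence at all between models.  Fit failures at a given
    L (degenerate CSSR output, impossible likelihood) contribute BIC = +inf
    and are skipped by the argmin.
    """
    if family not in ("machine", "markov"):
        raise ValueError("family must be 'machine' or 'markov'")
    T = len(x)
    k = len(x.alphabet)
    if lmax is None:
        lmax = max_history(T, k)
    bics: dict[int, float] = {}
    models: dict[int, object] = {}
    for L in range(1, lmax + 1):
        try:
            model = (
                cssr_estimate(x, L, alpha)
                if family == "machine"
                else fit_markov(x, L)
            )
            bics[L] = bic(model, x)
            models[L] = model
        except (ValueError, RuntimeError):
            bics[L] = math.inf
    finite = {L: b for L, b in bics.items() if b < math.inf}
    if not finite:
        raise RuntimeError("no model of any order could be fit")
    best = min(finite.values())
    chosen = min(L for L, b in finite.items() if b <= best + 1.0)
    return ModelSelectionResult(
        family=family,
        bics=bics,
        chosen_order=chosen,
        model=models[chosen],
        models=models,
    )
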