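"""Core representations of discrete stochastic-process models.

The central object is the :class:`EpsilonMachine`, the minimal *unifilar*
hidden-state presentation of a stationary stochastic process: each hidden
(causal) state carries a distribution over the next emitted symbol, and the
pair (state, symbol) determines the successor state uniquely.  Nonunifilar
generative presentations (:class:`HmmSource`) and finite-order Markov chains
(:class:`MarkovChainModel`) are also provided; a Markov chain of order L is a
special case of an epsilon-machine with one state per length-L context.

All probabilities are validated at construction with absolute tolerance
1e-12; quantities obtained from iterative or linear solves (stationary
distributions) are held to 1e-10.  Entropies elsewhere in the package are in
bits; this module is purely structural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Alphabet",
    "SymbolSequence",
    "EpsilonMachine",
    "HmmSource",
    "MarkovChainModel",
    "BeliefState",
    "validate_machine",
    "ValidationReport",
    "stationary_distribution",
    "word_probability",
    "remove_transients",
    "markov_to_machine",
]

_ATOL_CONSTRUCT = 1e-12
_ATOL_DERIVED = 1e-10


@dataclass(frozen=True)
class Alphabet:
    """Ordered finite set of symbol tokens; order fixes serialization."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError("alphabet must be non-empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet contains duplicate symbols")
        object.__setattr__(self, "symbols", tuple(str(s) for s in self.symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def index(self, token: str) -> int:
        try:
            return self.symbols.index(token)
        except ValueError:
            raise ValueError(f"symbol {token!r} not in alphabet {self.symbols}") from None


BINARY = Alphabet(("0", "1"))


class SymbolSequence:
    """A finite-alphabet time series, stored as integer codes.

    Parameters
    ----------
    alphabet:
        The symbol alphabet.
    values:
        Iterable of tokens (strings) or an integer code array.
    """

    __slots__ = ("alphabet", "codes")

    def __init__(self, alphabet: Alphabet, values) -> None:
        self.alphabet = alphabet
        if isinstance(values, np.ndarray) and values.dtype.kind in "iu":
            codes = values.astype(np.int64, copy=True)
            if codes.size and (codes.min() < 0 or codes.max() >= len(alphabet)):
                raise ValueError("code outside alphabet range")
        else:
            lut = {s: i for i, s in enumerate(alphabet.symbols)}
            try:
                codes = np.fromiter((lut[str(v)] for v in values), dtype=np.int64)
            except KeyError as e:
                raise ValueError(f"symbol {e.args[0]!r} not in alphabet") from None
        if codes.size < 1:
            raise ValueError("sequence must have length >= 1")
        self.codes = codes

    @classmethod
    def from_string(cls, s: str, alphabet: Alphabet = BINARY) -> "SymbolSequence":
        return cls(alphabet, list(s))

    def __len__(self) -> int:
        return int(self.codes.size)

    def tokens(self) -> list[str]:
        return [self.alphabet.symbols[c] for c in self.codes]

    def __str__(self) -> str:
        return "".join(self.tokens())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SymbolSequence)
            and self.alphabet == other.alphabet
            and np.array_equal(self.codes, other.codes)
        )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


class EpsilonMachine:
    """Unifilar hidden-state presentation of a stationary process.

    ``emit[i, x]`` is P(X0 = x | S = i); ``next[i, x]`` is the successor
    state index, defined (>= 0) exactly where ``emit[i, x] > 0`` and -1
    elsewhere (unifilarity).
    """

    __slots__ = ("alphabet", "states", "emit", "next", "_stationary")

    def __init__(
        self,
        alphabet: Alphabet,
        states: list[str],
        emit: np.ndarray,
        nxt: np.ndarray,
        stationary: np.ndarray | None = None,
    ) -> None:
        self.alphabet = alphabet
        self.states = [str(s) for s in states]
        self.emit = np.asarray(emit, dtype=float)
        self.next = np.asarray(nxt, dtype=np.int64)
        self._stationary = None if stationary is None else np.asarray(stationary, float)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def transition_matrix(self) -> np.ndarray:
        """State-to-state kernel M[i, j] = sum_x emit[i, x] * 1[next[i, x] == j]."""
        n = self.n_states
        M = np.zeros((n, n))
        for i in range(n):
            for x in range(len(self.alphabet)):
                j = self.next[i, x]
                if j >= 0 and self.emit[i, x] > 0:
                    M[i, j] += self.emit[i, x]
        return M

    def symbol_matrices(self) -> dict[int, np.ndarray]:
        """Per-symbol joint transition-emission matrices T(x)[i, j]."""
        n = self.n_states
        out = {}
        for x in range(len(self.alphabet)):
            Tx = np.zeros((n, n))
            for i in range(n):
                j = self.next[i, x]
                if j >= 0 and self.emit[i, x] > 0:
                    Tx[i, j] = self.emit[i, x]
            out[x] = Tx
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EpsilonMachine)
            and self.alphabet == other.alphabet
            and self.states == other.states
            and np.allclose(self.emit, other.emit, atol=_ATOL_CONSTRUCT)
            and np.array_equal(self.next, other.next)
        )


class HmmSource:
    """General (possibly nonunifilar) hidden Markov source.

    ``T[x][i, j]`` is the joint probability of emitting symbol x and moving
    from hidden state i to hidden state j.  Rows of sum_x T(x) sum to 1.
    """

    __slots__ = ("alphabet", "states", "T")

    def __init__(self, alphabet: Alphabet, states: list[str], T: dict) -> None:
        self.alphabet = alphabet
        self.states = [str(s) for s in states]
        n = len(self.states)
        self.T = {}
        for x in range(len(alphabet)):
            key = x if x in T else alphabet.symbols[x]
            Tx = np.asarray(T[key], dtype=float)
            if Tx.shape != (n, n):
                raise ValueError("transition matrix shape mismatch")
            if (Tx < 0).any():
                raise ValueError("negative transition probability")
            self.T[x] = Tx
        rows = sum(self.T.values()).sum(axis=1)
        if not np.allclose(rows, 1.0, atol=_ATOL_CONSTRUCT):
            raise ValueError("rows of sum_x T(x) must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def transition_matrix(self) -> np.ndarray:
        return sum(self.T.values())

    def symbol_matrices(self) -> dict[int, np.ndarray]:
        return self.T

    def is_unifilar(self) -> bool:
        """True iff every (state, symbol) has at most one positive successor."""
        for Tx in self.T.values():
            if ((Tx > 0).sum(axis=1) > 1).any():
                return False
        return True


class MarkovChainModel:
    """Finite-order Markov chain over a finite alphabet.

    ``cond`` maps each observed length-L context (tuple of symbol codes) to
    a probability vector over the next symbol.  The number of free
    parameters of the full family is (|X| - 1) * |X|**L.
    """

    __slots__ = ("alphabet", "order", "cond")

    def __init__(self, alphabet: Alphabet, order: int, cond: dict) -> None:
        if order < 0:
            raise ValueError("order must be >= 0")
        self.alphabet = alphabet
        self.order = int(order)
        self.cond = {}
        k = len(alphabet)
        for ctx, p in cond.items():
            ctx = tuple(int(c) for c in ctx)
            if len(ctx) != self.order:
                raise ValueError("context length != order")
            p = np.asarray(p, dtype=float)
            if p.shape != (k,) or not math.isclose(p.sum(), 1.0, abs_tol=_ATOL_CONSTRUCT):
                raise ValueError(f"conditional distribution for context {ctx} not normalized")
            self.cond[ctx] = p

    @property
    def dim(self) -> int:
        k = len(self.alphabet)
        return (k - 1) * k**self.order


class BeliefState:
    """Probability distribution over the hidden states of a model."""

    __slots__ = ("p", "word")

    def __init__(self, p: np.ndarray, word: tuple | None = None) -> None:
        p = np.asarray(p, dtype=float)
        if (p < -_ATOL_DERIVED).any() or not math.isclose(p.sum(), 1.0, abs_tol=_ATOL_DERIVED):
            raise ValueError("belief must be a probability vector")
        self.p = np.clip(p, 0.0, None)
        self.word = word


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def validate_machine(m: EpsilonMachine) -> ValidationReport:
    """Check the epsilon-machine invariants, returning a report of violations.

    Checks: emission normalization per state, successor map defined exactly
    on the support of the emissions (unifilarity), successor indices in
    range, and strong connectivity of the positive-probability state graph.
    """
    rep = ValidationReport()
    n, k = m.n_states, len(m.alphabet)
    if m.emit.shape != (n, k) or m.next.shape != (n, k):
        rep.violations.append("shape mismatch between states/alphabet and emit/next")
        return rep
    if (m.emit < 0).any() or (m.emit > 1 + _ATOL_CONSTRUCT).any():
        rep.violations.append("emission probabilities outside [0, 1]")
    if not np.allclose(m.emit.sum(axis=1), 1.0, atol=_ATOL_CONSTRUCT):
        rep.violations.append("emission normalization")
    for i in range(n):
        for x in range(k):
            if m.emit[i, x] > 0 and not (0 <= m.next[i, x] < n):
                rep.violations.append("unifilarity")
                break
            if m.emit[i, x] == 0 and m.next[i, x] != -1:
                rep.violations.append("successor declared on zero-probability emission")
                break
    if not rep.violations:
        G = _state_digraph(m)
        if n > 1 and not nx.is_strongly_connected(G):
            rep.violations.append("recurrent part not strongly connected")
        if m._stationary is not None:
            pi = m._stationary
            M = m.transition_matrix()
            if np.abs(pi @ M - pi).max() > _ATOL_DERIVED:
                rep.violations.append("cached stationary distribution not a fixed point")
    return rep


def _state_digraph(m) -> nx.DiGraph:
    G = nx.DiGraph()
    G.add_nodes_from(range(m.n_states))
    M = m.transition_matrix()
    for i, j in zip(*np.nonzero(M > 0)):
        G.add_edge(int(i), int(j))
    return G


def stationary_distribution(m: EpsilonMachine | HmmSource) -> np.ndarray:
    """Stationary distribution pi solving pi M = pi for the state kernel M.

    Requires a single recurrent communicating class; raises ``ValueError``
    naming the classes otherwise.  The result is cached on epsilon-machines.
    """
    if isinstance(m, EpsilonMachine) and m._stationary is not None:
        return m._stationary
    M = m.transition_matrix()
    classes = _recurrent_classes(m)
    if len(classes) != 1:
        raise ValueError(f"multiple recurrent classes: {classes}")
    n = M.shape[0]
    # solve pi (M - I) = 0 with sum(pi) = 1 as an augmented least-squares system
    A = np.vstack([(M - np.eye(n)).T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    if np.abs(pi @ M - pi).max() > _ATOL_DERIVED:
        raise ValueError("stationary solve did not converge to a fixed point")
    if isinstance(m, EpsilonMachine):
        m._stationary = pi
    return pi


def _recurrent_classes(m) -> list[list[int]]:
    """Strongly connected components with no outgoing edges (recurrent classes)."""
    G = _state_digraph(m)
    cond = nx.condensation(G)
    out = []
    for node in cond.nodes:
        if cond.out_degree(node) == 0:
            out.append(sorted(cond.nodes[node]["members"]))
    return out


def word_probability(m: EpsilonMachine | HmmSource, w: SymbolSequence | str) -> float:
    """Stationary probability of observing the word w.

    Computed as pi T(w1) ... T(wn) 1 using the per-symbol joint
    transition-emission matrices; the empty word has probability 1.
    """
    if isinstance(w, str):
        w = SymbolSequence.from_string(w, m.alphabet) if w else None
    if w is None or len(w) == 0:
        return 1.0
    if w.alphabet != m.alphabet:
        raise ValueError("word alphabet differs from machine alphabet")
    pi = stationary_distribution(m)
    T = m.symbol_matrices()
    v = pi.copy()
    for c in w.codes:
        v = v @ T[int(c)]
        if v.sum() == 0.0:
            return 0.0
    return float(v.sum())


def remove_transients(m: EpsilonMachine) -> EpsilonMachine:
    """Restrict a machine to its recurrent communicating class.

    Edges among recurrent states are unchanged (no re-normalization is
    needed: a recurrent state cannot leak probability out of its class).
    Raises if the machine has more than one recurrent class or none.
    """
    classes = _recurrent_classes(m)
    if len(classes) == 0:
        raise ValueError("no recurrent class reachable")
    if len(classes) > 1:
        raise ValueError(f"multiple recurrent classes: {classes}")
    keep = classes[0]
    if len(keep) == m.n_states:
        return m
    old2new = {old: new for new, old in enumerate(keep)}
    k = len(m.alphabet)
    emit = m.emit[keep, :].copy()
    nxt = np.full((len(keep), k), -1, dtype=np.int64)
    for new_i, old_i in enumerate(keep):
        for x in range(k):
            j = m.next[old_i, x]
            if j >= 0 and m.emit[old_i, x] > 0:
                nxt[new_i, x] = old2new[int(j)]
    return EpsilonMachine(m.alphabet, [m.states[i] for i in keep], emit, nxt)


def markov_to_machine(mc: MarkovChainModel) -> EpsilonMachine:
    """Embed an order-L Markov chain as an epsilon-machine.

    Each observed length-L context becomes its own state; the successor of
    (context, x) is the shifted context.  Predictively equivalent contexts
    are *not* merged.  Transitions into contexts absent from the model
    (possible only through a boundary effect at the end of the training
    sequence) are dropped and the row re-normalized.
    """
    k = len(mc.alphabet)
    if mc.order == 0:
        p = mc.cond[()]
        emit = p.reshape(1, k)
        nxt = np.where(emit > 0, 0, -1).astype(np.int64)
        return EpsilonMachine(mc.alphabet, ["*"], emit, nxt)
    contexts = sorted(mc.cond.keys())
    idx = {c: i for i, c in enumerate(contexts)}
    n = len(contexts)
    emit = np.zeros((n, k))
    nxt = np.full((n, k), -1, dtype=np.int64)
    for c, i in idx.items():
        p = mc.cond[c].copy()
        for x in range(k):
            if p[x] > 0:
                succ = c[1:] + (x,)
                if succ in idx:
                    nxt[i, x] = idx[succ]
                else:
                    p[x] = 0.0  # dangling boundary transition
        s = p.sum()
        if s == 0:
            raise ValueError(f"context {c} has no representable transitions")
        emit[i] = p / s
    machine = EpsilonMachine(
        mc.alphabet, ["".join(mc.alphabet.symbols[x] for x in c) for c in contexts], emit, nxt
    )
    return remove_transients(machine)
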