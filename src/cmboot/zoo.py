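"""Constructors for benchmark stochastic processes and seeded sampling.

The zoo contains four families used throughout the package's simulation
studies, all over the binary alphabet:

* ``even`` — the even process, a sofic process in which runs of 1s of odd
  length are forbidden; 2 causal states, not Markov of any finite order.
* ``sns`` — the simple nonunifilar source, a 2-hidden-state generative
  presentation whose epsilon-machine has countably many causal states.
* ``renewal`` — a discrete-time renewal process specified by its interevent
  distribution (time between 1s), realized as a chain-structured unifilar
  machine with a unique start state.
* ``alternating_renewal`` — run lengths of 0s and of 1s each follow their
  own distribution; two chained renewal halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .machines import (
    BINARY,
    Alphabet,
    EpsilonMachine,
    HmmSource,
    SymbolSequence,
    stationary_distribution,
)

__all__ = ["ZooSpec", "build_zoo_process", "sample_sequence", "even_process", "sns_source"]


@dataclass
class ZooSpec:
    """Named zoo process with its parameters.

    ``params`` keys: even -> ``p`` (probability of branching into a 1-run,
    default 1/2); renewal -> ``interevent`` (probability vector over waiting
    times 1, 2, ...); alternating_renewal -> ``runs0`` and ``runs1`` (run
    length distributions); sns -> none (canonical all-1/2 parameters).
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = {"even", "sns", "renewal", "alternating_renewal"}
        if self.name not in allowed:
            raise ValueError(f"unknown zoo process {self.name!r}; choose from {sorted(allowed)}")


def _check_pmf(v, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size == 0 or (v < 0).any() or (v > 1).any():
        raise ValueError(f"{what} must be a vector of probabilities")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError(f"{what} must sum to 1 (got {v.sum()})")
    return v


def even_process(p: float = 0.5) -> EpsilonMachine:
    """The even process with 1-branch probability ``p``.

    State A emits 0 (stay) with probability 1-p or 1 (to B) with probability
    p; state B emits 1 back to A with probability 1, which forces runs of 1s
    to even lengths.  At p = 1/2 the process has h_mu = 2/3 bits and
    C_mu = E = H(2/3, 1/3) bits.
    """
    if not 0 < p < 1:
        raise ValueError("branch probability must be in (0, 1)")
    emit = np.array([[1 - p, p], [0.0, 1.0]])
    nxt = np.array([[0, 1], [-1, 0]], dtype=np.int64)
    return EpsilonMachine(BINARY, ["A", "B"], emit, nxt)


def sns_source() -> HmmSource:
    """The simple nonunifilar source with canonical all-1/2 parameters.

    State A always emits 1, moving to A or B each with probability 1/2;
    state B emits 0 (to A) or 1 (stay) each with probability 1/2.  The 0
    symbol synchronizes the observer to state A; each further 1 walks down a
    countable chain of causal states, so the process is not finitary.
    """
    T0 = np.array([[0.0, 0.0], [0.5, 0.0]])
    T1 = np.array([[0.5, 0.5], [0.0, 0.5]])
    return HmmSource(BINARY, ["A", "B"], {0: T0, 1: T1})


def _renewal_half(interevent: np.ndarray, emit_sym: int, labels_prefix: str):
    """Chain machine states for one renewal half.

    State i means "i symbols of the current quiet run emitted"; the chain
    emits ``1 - emit_sym`` while waiting and ``emit_sym`` on the event.
    Waiting-time distribution w over {1, 2, ...}: the event at state i fires
    with the hazard  w[i] / (w[i] + w[i+1] + ...).
    """
    w = interevent
    n = len(w)
    tail = np.cumsum(w[::-1])[::-1]  # tail[i] = P(wait >= i+1)
    hazards = np.array([w[i] / tail[i] if tail[i] > 0 else 1.0 for i in range(n)])
    return hazards


def renewal_machine(interevent) -> EpsilonMachine:
    """Renewal process as a unifilar chain machine.

    ``interevent[i]`` is the probability that exactly i+1 time steps pass
    between consecutive 1s (so i zeros are emitted, then a 1).  The machine
    has one state per elapsed waiting position, a unique start state entered
    on every 1.
    """
    w = _check_pmf(interevent, "interevent distribution")
    hazards = _renewal_half(w, 1, "R")
    n = len(hazards)
    states = [f"R{i}" for i in range(n)]
    emit = np.zeros((n, 2))
    nxt = np.full((n, 2), -1, dtype=np.int64)
    for i, hz in enumerate(hazards):
        # emit 1 with the hazard (renewal; back to start), 0 otherwise
        if hz > 0:
            emit[i, 1] = hz
            nxt[i, 1] = 0
        if hz < 1:
            emit[i, 0] = 1 - hz
            nxt[i, 0] = i + 1
    if (emit.sum(axis=1) == 0).any():
        raise ValueError("malformed interevent distribution")
    return EpsilonMachine(BINARY, states, emit, nxt)


def alternating_renewal_machine(runs0, runs1) -> EpsilonMachine:
    """Alternating renewal process from run-length distributions.

    ``runs0[i]`` (resp. ``runs1[i]``) is the probability of a run of exactly
    i+1 zeros (ones).  Two chains of states, one per symbol, with unique
    start states for the first 0 and the first 1 of each run.
    """
    w0 = _check_pmf(runs0, "run-length distribution for 0s")
    w1 = _check_pmf(runs1, "run-length distribution for 1s")
    hz0 = _renewal_half(w0, 1, "Z")  # hazard of *ending* the 0-run
    hz1 = _renewal_half(w1, 0, "O")
    n0, n1 = len(hz0), len(hz1)
    states = [f"Z{i}" for i in range(n0)] + [f"O{i}" for i in range(n1)]
    emit = np.zeros((n0 + n1, 2))
    nxt = np.full((n0 + n1, 2), -1, dtype=np.int64)
    for i, hz in enumerate(hz0):
        # in the 0-run having emitted i+1 zeros; next symbol is 1 (run ends,
        # hazard) starting the 1-run, or another 0
        if hz > 0:
            emit[i, 1] = hz
            nxt[i, 1] = n0  # first 1 of a 1-run
        if hz < 1:
            emit[i, 0] = 1 - hz
            nxt[i, 0] = i + 1
    for i, hz in enumerate(hz1):
        j = n0 + i
        if hz > 0:
            emit[j, 0] = hz
            nxt[j, 0] = 0
        if hz < 1:
            emit[j, 1] = 1 - hz
            nxt[j, 1] = j + 1
    if (emit.sum(axis=1) == 0).any():
        raise ValueError("malformed run-length distribution")
    return EpsilonMachine(BINARY, states, emit, nxt)


def build_zoo_process(spec: ZooSpec) -> EpsilonMachine | HmmSource:
    """Construct the machine (or nonunifilar source) for a zoo spec."""
    if spec.name == "even":
        return even_process(float(spec.params.get("p", 0.5)))
    if spec.name == "sns":
        return sns_source()
    if spec.name == "renewal":
        return renewal_machine(spec.params["interevent"])
    if spec.name == "alternating_renewal":
        return alternating_renewal_machine(spec.params["runs0"], spec.params["runs1"])
    raise AssertionError("unreachable")


def sample_sequence(
    m: EpsilonMachine | HmmSource, T: int, seed: int
) -> tuple[SymbolSequence, np.ndarray]:
    """Sample a length-T realization with a stationary start.

    The initial hidden state is drawn from the stationary distribution; each
    step draws a symbol from the current state's emission distribution and
    moves to the successor.  A single integer seed feeds one numpy
    ``default_rng`` stream, so identical seeds give identical output.

    Returns the sequence and the hidden state path (s_0 .. s_T, length T+1).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    pi = stationary_distribution(m)
    n = m.n_states
    k = len(m.alphabet)
    if isinstance(m, EpsilonMachine):
        # cumulative emission thresholds per state for inverse-CDF draws
        cum = np.cumsum(m.emit, axis=1)
        cum[:, -1] = 1.0
        nxt = m.next
        u = rng.random(T)
        s = int(rng.choice(n, p=pi))
        path = np.empty(T + 1, dtype=np.int64)
        out = np.empty(T, dtype=np.int64)
        path[0] = s
        if k == 2:
            c0 = cum[:, 0].copy()
            n0 = nxt[:, 0].copy()
            n1 = nxt[:, 1].copy()
            c0l = c0.tolist()
            n0l = n0.tolist()
            n1l = n1.tolist()
            ol = out.tolist()
            pl = path.tolist()
            ul = u.tolist()
            for t in range(T):
                if ul[t] < c0l[s]:
                    ol[t] = 0
                    s = n0l[s]
                else:
                    ol[t] = 1
                    s = n1l[s]
                pl[t + 1] = s
            out = np.array(ol, dtype=np.int64)
            path = np.array(pl, dtype=np.int64)
        else:
            for t in range(T):
                x = int(np.searchsorted(cum[s], u[t], side="right"))
                x = min(x, k - 1)
                out[t] = x
                s = int(nxt[s, x])
                path[t + 1] = s
    else:
        # nonunifilar: draw (symbol, successor) jointly from the T matrices
        flat = np.stack([m.T[x] for x in range(k)], axis=0)  # (k, n, n)
        per_state = flat.transpose(1, 0, 2).reshape(n, k * n)  # rows sum to 1
        cums = np.cumsum(per_state, axis=1)
        cums[:, -1] = 1.0
        u = rng.random(T)
        s = int(rng.choice(n, p=pi))
        path = np.empty(T + 1, dtype=np.int64)
        out = np.empty(T, dtype=np.int64)
        path[0] = s
        for t in range(T):
            z = int(np.searchsorted(cums[s], u[t], side="right"))
            z = min(z, k * n - 1)
            out[t] = z // n
            s = z % n
            path[t + 1] = s
    return SymbolSequence(m.alphabet, out), path
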