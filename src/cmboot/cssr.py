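"""Causal State Splitting Reconstruction (CSSR).

CSSR estimates the epsilon-machine of a conditionally stationary process
from a single realization.  It starts from the simplest model — one state
holding the empty history, i.e. a Bernoulli process — and adds causal
states only when a hypothesis test shows that some history's next-symbol
distribution differs from its current state's.  Three phases:

1. *Splitting.*  For history lengths 0 .. Lh-1, every member history is
   extended one symbol into the past; the child's next-symbol counts are
   tested (two-sample chi-squared homogeneity test at level ``alpha``)
   against its parent state's pooled counts, then against every other
   state; it joins the state with the largest p-value among those not
   rejected, or founds a new state.
2. *Determinization.*  States whose longest member histories disagree about
   the successor state under symbol extension are split until every
   (state, symbol) pair has a unique successor.
3. *Transient removal.*  The recurrent communicating class is kept and the
   emission probabilities are re-estimated from its pooled counts.

Histories with fewer than ``min_count`` occurrences are not tested and
follow their parent's state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import chdtrc

from .machines import EpsilonMachine, SymbolSequence, remove_transients

__all__ = [
    "SuffixCountTable",
    "CandidateState",
    "suffix_counts",
    "test_split",
    "determinize",
    "split_histories",
    "cssr_estimate",
]

#: histories rarer than this are not tested against their state
MIN_TEST_COUNT = 5


@dataclass
class SuffixCountTable:
    """Next-symbol counts following every observed history of length <= Lh.

    ``counts[w]`` for a history ``w`` (tuple of symbol codes, most recent
    last) is the length-k vector of counts of the symbol immediately
    following an occurrence of ``w``, over a sliding window on the single
    realization.
    """

    n_symbols: int
    max_len: int
    counts: dict[tuple, np.ndarray]

    def histories_of_length(self, ell: int) -> list[tuple]:
        return [w for w in self.counts if len(w) == ell]


def suffix_counts(x: SymbolSequence, Lh: int) -> SuffixCountTable:
    """Sliding-window next-symbol counts for all histories of length <= Lh.

    Positions whose preceding context is shorter than the history length
    (the head of the sequence) are skipped.  Requires T > Lh.
    """
    T = len(x)
    if Lh < 0:
        raise ValueError("Lh must be >= 0")
    if Lh >= T:
        raise ValueError("history length must be smaller than the sequence")
    k = len(x.alphabet)
    codes = x.codes
    counts: dict[tuple, np.ndarray] = {}
    # empty history: every position has one
    counts[()] = np.bincount(codes, minlength=k).astype(np.int64)
    if Lh >= 1 and k > 1:
        # incremental base-k window codes: code(x[t..t+ell-1]) built from
        # code(x[t..t+ell-2]) in O(T) per length
        enc = codes.astype(np.int64)
        wcodes = enc.copy()  # length-1 window codes
        for ell in range(1, Lh + 1):
            if ell > 1:
                wcodes = wcodes[:-1] * k + enc[ell - 1 :]
            # history at position t of length ell is x[t-ell .. t-1] with
            # next symbol x[t]; valid t = ell .. T-1
            hist = wcodes[: T - ell]
            nxt = enc[ell:]
            flat = np.zeros(k**ell * k, dtype=np.int64)
            np.add.at(flat, hist * k + nxt, 1)
            table = flat.reshape(-1, k)
            nz = np.nonzero(table.sum(axis=1))[0]
            pw = k ** np.arange(ell - 1, -1, -1, dtype=np.int64)
            digits = ((nz[:, None] // pw[None, :]) % k).tolist()
            for h, wtup in zip(nz, digits):
                counts[tuple(wtup)] = table[h].copy()
    elif Lh >= 1:
        # single-symbol alphabet: only one history per length
        for ell in range(1, Lh + 1):
            counts[tuple([0] * ell)] = np.array([T - ell], dtype=np.int64)
    return SuffixCountTable(n_symbols=k, max_len=Lh, counts=counts)


@dataclass
class CandidateState:
    """A working CSSR state: member histories and pooled next-symbol counts."""

    histories: set = field(default_factory=set)
    pooled: np.ndarray | None = None

    def add(self, w: tuple, c: np.ndarray) -> None:
        self.histories.add(w)
        self.pooled = c.astype(float).copy() if self.pooled is None else self.pooled + c

    def remove(self, w: tuple, c: np.ndarray) -> None:
        self.histories.discard(w)
        self.pooled = self.pooled - c


def test_split(counts_a: np.ndarray, counts_b: np.ndarray, alpha: float) -> tuple[float, bool]:
    """Two-sample chi-squared homogeneity test on next-symbol counts.

    Returns (p-value, split?) with split declared iff p <= alpha.  Symbol
    cells with zero expected count are dropped from the statistic.  If
    either sample is empty the test is degenerate: p = 1, no split.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 2 and b.size == 2:
        # scalar fast path for binary alphabets
        a0, a1 = float(a[0]), float(a[1])
        b0, b1 = float(b[0]), float(b[1])
        na, nb = a0 + a1, b0 + b1
        if na == 0.0 or nb == 0.0:
            return 1.0, False
        tot = na + nb
        p0, p1 = (a0 + b0) / tot, (a1 + b1) / tot
        if p0 == 0.0 or p1 == 0.0:
            return 1.0, False
        stat = (
            (a0 - na * p0) ** 2 / (na * p0)
            + (a1 - na * p1) ** 2 / (na * p1)
            + (b0 - nb * p0) ** 2 / (nb * p0)
            + (b1 - nb * p1) ** 2 / (nb * p1)
        )
        p = float(chdtrc(1.0, stat))
        return p, p <= alpha
    na, nb = a.sum(), b.sum()
    if na == 0 or nb == 0:
        return 1.0, False
    pooled = (a + b) / (na + nb)
    keep = pooled > 0
    df = int(keep.sum()) - 1
    if df <= 0:
        return 1.0, False
    ea = na * pooled[keep]
    eb = nb * pooled[keep]
    stat = float(np.sum((a[keep] - ea) ** 2 / ea) + np.sum((b[keep] - eb) ** 2 / eb))
    p = float(chdtrc(df, stat))
    return p, p <= alpha


def _assign_child(
    w: tuple,
    c: np.ndarray,
    parent_idx: int,
    states: list[CandidateState],
    membership: dict,
    alpha: float,
) -> None:
    """Place child history w per the CSSR splitting rule."""
    parent = states[parent_idx]
    if c.sum() < MIN_TEST_COUNT:
        parent.add(w, c)
        membership[w] = parent_idx
        return
    p_parent, split = test_split(c, parent.pooled, alpha)
    if not split:
        parent.add(w, c)
        membership[w] = parent_idx
        return
    best_idx, best_p = None, -1.0
    for idx, st in enumerate(states):
        if idx == parent_idx or st.pooled is None:
            continue
        p, rej = test_split(c, st.pooled, alpha)
        if not rej and p > best_p:
            best_idx, best_p = idx, p
    if best_idx is None:
        states.append(CandidateState())
        best_idx = len(states) - 1
    states[best_idx].add(w, c)
    membership[w] = best_idx


def split_histories(table: SuffixCountTable, alpha: float) -> list[CandidateState]:
    """Splitting phase: partition all observed histories into candidate
    causal states by homogeneity testing.

    Starts from one state holding the empty history (a memoryless model)
    and extends member histories one symbol into the past, level by level.
    The number of states grows with ``alpha``: at alpha -> 0 no split is
    ever significant and one state remains; at alpha -> 1 every history
    splits into its own state (the full suffix tree).
    """
    k = table.n_symbols
    root = CandidateState()
    root.add((), table.counts[()])
    states = [root]
    membership: dict[tuple, int] = {(): 0}
    for ell in range(table.max_len):
        parents = [w for w in list(membership) if len(w) == ell]
        for w in parents:
            for a in range(k):
                child = (a,) + w  # extend into the past
                c = table.counts.get(child)
                if c is None or c.sum() == 0:
                    continue
                _assign_child(child, c, membership[w], states, membership, alpha)
    return [st for st in states if st.histories]


def determinize(
    states: list[CandidateState], table: SuffixCountTable
) -> list[CandidateState]:
    """Refine states until successor states are unique per (state, symbol).

    The successor of a member history w on symbol x is the state containing
    the extended history w + x.  Only extensions that are themselves tracked
    (length <= Lh) impose constraints: the deepest histories have untracked
    extensions and act as wildcards — truncating their extensions to a
    length-Lh suffix would conflate synchronized histories with
    unsynchronized ones and weave spurious states into the recurrent part.
    A state whose constrained members disagree is split by successor
    signature; splitting strictly refines a finite partition, so this
    terminates.
    """
    k = table.n_symbols
    hist = [w for st in states for w in sorted(st.histories)]
    hid = {w: i for i, w in enumerate(hist)}
    H = len(hist)
    # ext[i][x]: id of the extension hist[i] + (x,) when it is tracked and
    # observed; -1 means the history imposes no constraint for symbol x
    ext = np.full((H, k), -1, dtype=np.int64)
    for i, w in enumerate(hist):
        c = table.counts[w]
        for x in range(k):
            if c[x] > 0:
                j = hid.get(w + (x,))
                if j is not None:
                    ext[i, x] = j
    part = np.empty(H, dtype=np.int64)
    pos = 0
    cells: list[list[int]] = []
    for st in states:
        if st.histories:
            members = [hid[w] for w in sorted(st.histories)]
            part[members] = pos
            cells.append(members)
            pos += 1

    # Event-driven partition refinement: re-examine a cell only when the
    # cell id of some member's successor changed in the previous round.
    wild = -1
    extl = ext.tolist()
    pt = part.tolist()
    cell_members: dict[int, list[int]] = {ci: m for ci, m in enumerate(cells)}
    next_id = len(cells)
    dirty = {ci for ci, m in cell_members.items() if len(m) > 1}
    # reverse index: which histories point at history j
    pointers: dict[int, list[int]] = {}
    for i, row in enumerate(extl):
        for e in row:
            if e >= 0:
                pointers.setdefault(e, []).append(i)
    while dirty:
        moved: list[int] = []
        for ci in sorted(dirty):
            members = cell_members[ci]
            if len(members) == 1:
                continue
            groups: list[list] = []  # [signature (wild = -1), member ids]
            # wildcards merge with the first compatible group
            for i in members:
                sig = [pt[e] if e >= 0 else wild for e in extl[i]]
                for entry in groups:
                    gsig = entry[0]
                    ok = True
                    for s, g in zip(sig, gsig):
                        if s != wild and g != wild and s != g:
                            ok = False
                            break
                    if ok:
                        for xi, s in enumerate(sig):
                            if gsig[xi] == wild:
                                gsig[xi] = s
                        entry[1].append(i)
                        break
                else:
                    groups.append([sig, [i]])
            if len(groups) > 1:
                cell_members[ci] = groups[0][1]
                for entry in groups[1:]:
                    cell_members[next_id] = entry[1]
                    for i in entry[1]:
                        pt[i] = next_id
                        moved.append(i)
                    next_id += 1
        dirty = set()
        for j in moved:
            for i in pointers.get(j, ()):
                ci = pt[i]
                if len(cell_members[ci]) > 1:
                    dirty.add(ci)
    cells = [cell_members[ci] for ci in sorted(cell_members)]

    out = []
    for members in cells:
        st = CandidateState()
        for i in members:
            st.add(hist[i], table.counts[hist[i]])
        out.append(st)
    return out


def cssr_estimate(
    x: SymbolSequence, Lh: int, alpha: float = 0.001
) -> EpsilonMachine:
    """Estimate an epsilon-machine from a realization by CSSR.

    Parameters
    ----------
    x:
        The observed symbol sequence.
    Lh:
        Maximum history length considered during splitting.
    alpha:
        Significance level of the state-splitting tests (default 0.001).
    """
    table = suffix_counts(x, Lh)
    k = len(x.alphabet)
    states = split_histories(table, alpha)

    if Lh == 0:
        p = table.counts[()].astype(float)
        p /= p.sum()
        nxt = np.where(p > 0, 0, -1).astype(np.int64).reshape(1, k)
        return EpsilonMachine(x.alphabet, ["S0"], p.reshape(1, k), nxt)

    # Phase 2: determinize with full (untruncated) extension successors
    states = determinize(states, table)

    part_index = {}
    for i, st in enumerate(states):
        for w in st.histories:
            part_index[w] = i

    # pooled emission counts and successor cells per state
    n = len(states)
    counts = np.zeros((n, k))
    nxt = np.full((n, k), -1, dtype=np.int64)
    for i, st in enumerate(states):
        counts[i] = st.pooled
        for w in st.histories:
            c = table.counts[w]
            for xsym in range(k):
                if c[xsym] > 0 and nxt[i, xsym] == -1:
                    j = part_index.get(w + (xsym,))
                    if j is not None:
                        nxt[i, xsym] = j

    # Phase 3a: prune cells whose observed emissions lack a successor — the
    # structure there is not resolvable at this history depth.  Pruning can
    # orphan further cells, so iterate to a fixed point.
    alive = set(range(n))
    changed = True
    while changed:
        changed = False
        for i in list(alive):
            for xsym in range(k):
                j = nxt[i, xsym]
                if counts[i, xsym] > 0 and (j < 0 or j not in alive):
                    alive.discard(i)
                    changed = True
                    break
    if not alive:
        # no self-consistent state space at this depth: fall back to the
        # memoryless model (the starting point of the splitting phase)
        p = table.counts[()].astype(float)
        p /= p.sum()
        nxt0 = np.where(p > 0, 0, -1).astype(np.int64).reshape(1, k)
        return EpsilonMachine(x.alphabet, ["S0"], p.reshape(1, k), nxt0)

    keep = sorted(alive)
    remap = {old: new for new, old in enumerate(keep)}
    emit = np.zeros((len(keep), k))
    nxt2 = np.full((len(keep), k), -1, dtype=np.int64)
    for new_i, old_i in enumerate(keep):
        tot = counts[old_i].sum()
        emit[new_i] = counts[old_i] / tot
        for xsym in range(k):
            if emit[new_i, xsym] > 0:
                nxt2[new_i, xsym] = remap[int(nxt[old_i, xsym])]
    labels = [f"S{i}" for i in range(len(keep))]
    machine = EpsilonMachine(x.alphabet, labels, emit, nxt2)

    # Phase 3b: keep the recurrent communicating class
    machine = remove_transients(machine)
    machine.states = [f"S{i}" for i in range(machine.n_states)]
    return machine
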