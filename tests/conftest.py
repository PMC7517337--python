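"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's matrix/belief machinery: word
probabilities are computed by exhaustive enumeration over hidden state
paths, and block entropies from those word probabilities, so they provide
an independent check of the mixed-state engine.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from cmboot.machines import EpsilonMachine, HmmSource, stationary_distribution
from cmboot.zoo import (
    ZooSpec,
    build_zoo_process,
    even_process,
    sns_source,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_word_probability(m, word: tuple[int, ...]) -> float:
    """P(word) by exhaustive summation over hidden state paths."""
    pi = stationary_distribution(m)
    n = m.n_states
    if isinstance(m, EpsilonMachine):
        total = 0.0
        for s0 in range(n):
            p = pi[s0]
            s = s0
            for x in word:
                e = m.emit[s, x]
                if e == 0.0:
                    p = 0.0
                    break
                p *= e
                s = int(m.next[s, x])
            total += p
        return total
    # nonunifilar: sum over all state paths
    total = 0.0
    for path in itertools.product(range(n), repeat=len(word)):
        p = 0.0
        for s0 in range(n):
            q = pi[s0]
            prev = s0
            for x, s in zip(word, path):
                q *= m.T[x][prev, s]
                if q == 0.0:
                    break
                prev = s
            p += q
        total += p
    return total


def oracle_block_entropy(m, L: int) -> float:
    """H[X0 | X_{-L..-1}] from exhaustively enumerated word probabilities."""
    k = len(m.alphabet)
    h = 0.0
    for w in itertools.product(range(k), repeat=L):
        pw = oracle_word_probability(m, w)
        if pw <= 0:
            continue
        for x in range(k):
            pwx = oracle_word_probability(m, w + (x,))
            if pwx > 0:
                h -= pwx * math.log2(pwx / pw)
    return h


def oracle_loglik_paths(m: EpsilonMachine, codes) -> float:
    """log P(x) by exhaustive summation over start states (natural log)."""
    p = oracle_word_probability(m, tuple(int(c) for c in codes))
    return math.log(p) if p > 0 else -math.inf


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def even():
    return even_process(0.5)


@pytest.fixture(scope="session")
def sns():
    return sns_source()


@pytest.fixture(scope="session")
def zoo_machines():
    """All four study processes at representative parameters."""
    return {
        "even": build_zoo_process(ZooSpec("even", {"p": 0.5})),
        "sns": build_zoo_process(ZooSpec("sns")),
        "renewal": build_zoo_process(
            ZooSpec("renewal", {"interevent": [0.3, 0.5, 0.2]})
        ),
        "alternating_renewal": build_zoo_process(
            ZooSpec("alternating_renewal", {"runs0": [0.6, 0.4], "runs1": [0.3, 0.7]})
        ),
    }


@pytest.fixture(scope="session")
def even_study():
    """Shared Monte Carlo study of the even process with the CM bootstrap.

    S = 100 series of length T = 10000, B = 200 bootstrap replicates, fixed
    base seed.  Returns per-series percentile confidence distributions and
    the true measures; used for p-value calibration, interval coverage, and
    power checks so the expensive simulation runs once.
    """
    from cmboot.confidence import MEASURES, percentile_cd
    from cmboot.harness import ExperimentConfig, _run_bootstraps
    from cmboot.measures import measure_set

    cfg = ExperimentConfig(
        process=ZooSpec("even"),
        T=10_000,
        S=100,
        B=200,
        families=("machine",),
        cd_kinds=("percentile",),
        seed=0,
    )
    machine = build_zoo_process(cfg.process)
    truth = measure_set(machine).as_dict()
    cds = []
    n_failures = 0
    for _s_idx, _family, bs in _run_bootstraps(cfg, machine):
        if bs is None:
            n_failures += 1
            continue
        cds.append({m: percentile_cd(bs[m]) for m in MEASURES})
    return {"cds": cds, "truth": truth, "cfg": cfg, "n_failures": n_failures}
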