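"""Structural model types and exact computations on them."""

import itertools

import numpy as np
import pytest

from cmboot.machines import (
    BINARY,
    Alphabet,
    EpsilonMachine,
    MarkovChainModel,
    SymbolSequence,
    markov_to_machine,
    remove_transients,
    stationary_distribution,
    validate_machine,
    word_probability,
)
from cmboot.measures import entropy_rate

from conftest import oracle_word_probability


def two_cycle():
    """Deterministic 2-cycle: A emits 0 -> B, B emits 1 -> A."""
    emit = np.array([[1.0, 0.0], [0.0, 1.0]])
    nxt = np.array([[1, -1], [-1, 0]], dtype=np.int64)
    return EpsilonMachine(BINARY, ["A", "B"], emit, nxt)


class TestAlphabetSequence:
    def test_alphabet_invariants(self):
        with pytest.raises(ValueError):
            Alphabet(())
        with pytest.raises(ValueError):
            Alphabet(("0", "0"))
        a = Alphabet(("a", "b", "c"))
        assert a.index("c") == 2

    def test_sequence_roundtrip_and_checks(self):
        s = SymbolSequence.from_string("0110")
        assert str(s) == "0110" and len(s) == 4
        with pytest.raises(ValueError):
            SymbolSequence(BINARY, list("012"))
        with pytest.raises(ValueError):
            SymbolSequence(BINARY, [])


class TestValidateMachine:
    def test_even_process_passes(self, even):
        assert validate_machine(even).ok

    def test_violations_are_named(self, even):
        bad = EpsilonMachine(
            BINARY, ["A", "B"], np.array([[0.4, 0.5], [0.0, 1.0]]), even.next.copy()
        )
        rep = validate_machine(bad)
        assert not rep.ok and any("normalization" in v for v in rep.violations)
        # successor declared where emission is zero breaks unifilarity bookkeeping
        nxt = even.next.copy()
        nxt[1, 0] = 0
        bad2 = EpsilonMachine(BINARY, ["A", "B"], even.emit.copy(), nxt)
        rep2 = validate_machine(bad2)
        assert not rep2.ok


class TestStationary:
    def test_even_process(self, even):
        pi = stationary_distribution(even)
        assert np.allclose(pi, [2 / 3, 1 / 3], atol=1e-12)

    def test_single_state(self):
        m = EpsilonMachine(
            BINARY, ["S"], np.array([[0.5, 0.5]]), np.array([[0, 0]], dtype=np.int64)
        )
        assert np.allclose(stationary_distribution(m), [1.0])

    def test_two_cycle_symmetry(self):
        assert np.allclose(stationary_distribution(two_cycle()), [0.5, 0.5])

    def test_fixed_point(self, zoo_machines):
        for m in zoo_machines.values():
            pi = stationary_distribution(m)
            M = m.transition_matrix()
            assert np.abs(pi @ M - pi).max() < 1e-10

    def test_multiple_recurrent_classes_error(self):
        # two disconnected self-looping states
        emit = np.array([[1.0, 0.0], [0.0, 1.0]])
        nxt = np.array([[0, -1], [-1, 1]], dtype=np.int64)
        m = EpsilonMachine(BINARY, ["A", "B"], emit, nxt)
        with pytest.raises(ValueError, match="recurrent classes"):
            stationary_distribution(m)


class TestWordProbability:
    def test_even_examples(self, even):
        assert word_probability(even, "1") == pytest.approx(2 / 3, abs=1e-12)
        assert word_probability(even, "") == 1.0
        assert word_probability(even, "010") == 0.0

    @pytest.mark.parametrize("L", [1, 2, 4, 6, 8])
    def test_length_L_words_sum_to_one(self, zoo_machines, L):
        for name, m in zoo_machines.items():
            if name == "sns" and L > 6:
                continue  # exhaustive nonunifilar oracle cost grows fast
            total = sum(
                word_probability(m, SymbolSequence(m.alphabet, np.array(w)))
                for w in itertools.product(range(2), repeat=L)
            )
            assert total == pytest.approx(1.0, abs=1e-9), name

    def test_against_path_enumeration_oracle(self, zoo_machines):
        for name, m in zoo_machines.items():
            for w in itertools.product(range(2), repeat=4):
                got = word_probability(m, SymbolSequence(m.alphabet, np.array(w)))
                assert got == pytest.approx(oracle_word_probability(m, w), abs=1e-12), name

    def test_symbol_outside_alphabet(self, even):
        with pytest.raises(ValueError):
            word_probability(even, SymbolSequence(Alphabet(("a", "b")), ["a"]))


class TestRemoveTransients:
    def test_drops_unreachable_state(self, even):
        emit = np.vstack([even.emit, [0.5, 0.5]])
        nxt = np.vstack([even.next, [0, 1]])
        m = EpsilonMachine(BINARY, ["A", "B", "X"], emit, nxt)
        r = remove_transients(m)
        assert r.states == ["A", "B"]
        assert np.allclose(r.emit, even.emit)

    def test_chain_into_terminal_cycle(self):
        # A -> B -> C, with C self-looping on both symbols
        emit = np.array([[1.0, 0.0], [1.0, 0.0], [0.5, 0.5]])
        nxt = np.array([[1, -1], [2, -1], [2, 2]], dtype=np.int64)
        m = EpsilonMachine(BINARY, ["A", "B", "C"], emit, nxt)
        r = remove_transients(m)
        assert r.states == ["C"]

    def test_idempotent(self, even):
        once = remove_transients(even)
        twice = remove_transients(once)
        assert once == twice


class TestMarkovEmbedding:
    def test_order1_binary_gives_two_states(self):
        mc = MarkovChainModel(
            BINARY, 1, {(0,): np.array([0.9, 0.1]), (1,): np.array([0.3, 0.7])}
        )
        m = markov_to_machine(mc)
        assert m.n_states == 2
        assert validate_machine(m).ok

    def test_order2_binary_gives_four_states(self):
        rng = np.random.default_rng(1)
        cond = {}
        for ctx in itertools.product(range(2), repeat=2):
            p = rng.dirichlet([2, 2])
            cond[ctx] = p
        m = markov_to_machine(MarkovChainModel(BINARY, 2, cond))
        assert m.n_states == 4

    def test_entropy_rate_matches_direct_markov_computation(self):
        mc = MarkovChainModel(
            BINARY, 1, {(0,): np.array([0.9, 0.1]), (1,): np.array([0.3, 0.7])}
        )
        m = markov_to_machine(mc)
        # direct: stationary over contexts times conditional entropies
        pi = stationary_distribution(m)
        direct = 0.0
        for i, ctx in enumerate([(0,), (1,)]):
            p = mc.cond[ctx]
            pp = p[p > 0]
            direct += pi[i] * float(-(pp * np.log2(pp)).sum())
        assert entropy_rate(mc) == pytest.approx(direct, abs=1e-12)

    def test_word_probabilities_preserved(self):
        rng = np.random.default_rng(7)
        cond = {
            ctx: rng.dirichlet([3, 3]) for ctx in itertools.product(range(2), repeat=2)
        }
        mc = MarkovChainModel(BINARY, 2, cond)
        m = markov_to_machine(mc)
        # oracle: stationary context distribution, then chain rule
        pi = stationary_distribution(m)
        contexts = sorted(cond)
        for w in itertools.product(range(2), repeat=6):
            p_direct = 0.0
            for i, ctx in enumerate(contexts):
                q = pi[i]
                cur = ctx
                for x in w:
                    q *= cond[cur][x]
                    cur = cur[1:] + (x,)
                p_direct += q
            got = word_probability(m, SymbolSequence(BINARY, np.array(w)))
            assert got == pytest.approx(p_direct, abs=1e-10)
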