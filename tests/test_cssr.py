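"""CSSR: suffix statistics, splitting tests, determinization, estimation."""

import numpy as np
import pytest
from scipy import stats

from cmboot.cssr import CandidateState, cssr_estimate, determinize, suffix_counts
from cmboot.cssr import test_split as split_test
from cmboot.machines import SymbolSequence, validate_machine, word_probability
from cmboot.measures import entropy_rate
from cmboot.zoo import sample_sequence


class TestSuffixCounts:
    def test_alternating_string_by_hand(self):
        x = SymbolSequence.from_string("0101010101")
        t = suffix_counts(x, 1)
        assert t.counts[(0,)].tolist() == [0, 5]
        assert t.counts[(1,)].tolist() == [4, 0]

    def test_lh_zero_gives_symbol_counts(self):
        x = SymbolSequence.from_string("00110")
        t = suffix_counts(x, 0)
        assert t.counts[()].tolist() == [3, 2]

    def test_lh_at_least_T_rejected(self):
        x = SymbolSequence.from_string("0101")
        with pytest.raises(ValueError):
            suffix_counts(x, 4)

    def test_against_naive_counting(self):
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 2, size=300)
        x = SymbolSequence(x_alphabet(), codes)
        t = suffix_counts(x, 4)
        # naive sliding-window recount
        naive: dict = {}
        for ell in range(5):
            for i in range(ell, len(codes)):
                w = tuple(codes[i - ell : i])
                naive.setdefault(w, np.zeros(2, dtype=int))[codes[i]] += 1
        assert set(t.counts) == set(naive)
        for w, c in naive.items():
            assert t.counts[w].tolist() == c.tolist(), w


def x_alphabet():
    from cmboot.machines import BINARY

    return BINARY


class TestSplitTest:
    def test_identical_vectors_no_split(self):
        p, split = split_test(np.array([30, 70]), np.array([30, 70]), 0.001)
        assert p == pytest.approx(1.0) and not split

    def test_disjoint_vectors_split(self):
        p, split = split_test(np.array([50, 0]), np.array([0, 50]), 0.001)
        # chi-squared statistic is exactly 100 on 1 df
        assert split
        assert p == pytest.approx(float(stats.chi2.sf(100.0, 1)), rel=1e-10)

    def test_degenerate_empty_sample(self):
        p, split = split_test(np.array([5, 5]), np.array([0, 0]), 0.001)
        assert p == 1.0 and not split

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 40, size=2)
            b = rng.integers(0, 40, size=2)
            pa, _ = split_test(a, b, 0.01)
            pb, _ = split_test(b, a, 0.01)
            assert pa == pytest.approx(pb, abs=1e-12)

    def test_matches_scipy_contingency_table(self):
        a, b = np.array([37, 63]), np.array([55, 45])
        p, _ = split_test(a, b, 0.05)
        chi2, p_ref, _, _ = stats.chi2_contingency(np.vstack([a, b]), correction=False)
        assert p == pytest.approx(p_ref, rel=1e-9)


def _table_from(counts: dict):
    from cmboot.cssr import SuffixCountTable

    return SuffixCountTable(n_symbols=2, max_len=max(len(w) for w in counts), counts={
        w: np.asarray(c, dtype=np.int64) for w, c in counts.items()
    })


class TestDeterminize:
    def test_already_deterministic_partition_unchanged(self):
        counts = {
            (): [10, 10],
            (0,): [5, 5],
            (1,): [5, 5],
            (0, 0): [3, 3], (1, 0): [3, 3], (0, 1): [2, 2], (1, 1): [2, 2],
        }
        table = _table_from(counts)
        st = CandidateState()
        for w, c in counts.items():
            st.add(w, table.counts[w])
        out = determinize([st], table)
        assert len(out) == 1

    def test_successor_disagreement_splits(self):
        # histories "01" and "11" extend on symbol 1 into different states
        counts = {
            (0, 1): [0, 10],
            (1, 1): [0, 10],
            (0, 1, 1): [10, 0],
            (1, 1, 1): [0, 10],
        }
        table = _table_from(counts)
        s_pq = CandidateState()
        s_pq.add((0, 1), table.counts[(0, 1)])
        s_pq.add((1, 1), table.counts[(1, 1)])
        s_p = CandidateState()
        s_p.add((0, 1, 1), table.counts[(0, 1, 1)])
        s_q = CandidateState()
        s_q.add((1, 1, 1), table.counts[(1, 1, 1)])
        out = determinize([s_pq, s_p, s_q], table)
        parts = [sorted(st.histories) for st in out]
        assert [(0, 1)] in parts and [(1, 1)] in parts

    def test_idempotent(self):
        counts = {
            (0, 1): [0, 10], (1, 1): [0, 10],
            (0, 1, 1): [10, 0], (1, 1, 1): [0, 10],
        }
        table = _table_from(counts)
        states = []
        for w in counts:
            st = CandidateState()
            st.add(w, table.counts[w])
            states.append(st)
        once = determinize(states, table)
        twice = determinize(once, table)
        assert sorted(map(sorted, (st.histories for st in once))) == sorted(
            map(sorted, (st.histories for st in twice))
        )


class TestCssrEstimate:
    def test_bernoulli_gives_single_state(self):
        rng = np.random.default_rng(0)
        x = SymbolSequence(x_alphabet(), rng.integers(0, 2, size=10_000))
        m = cssr_estimate(x, 5, 0.001)
        assert m.n_states == 1
        assert abs(m.emit[0, 0] - 0.5) < 0.02

    def test_even_process_architecture(self, even):
        x, _ = sample_sequence(even, 10_000, 5)
        m = cssr_estimate(x, 3, 0.001)
        assert m.n_states == 2
        i_b = int(np.argmax(m.emit[:, 1]))  # the forced-1 state
        i_a = 1 - i_b
        assert m.emit[i_b, 1] == pytest.approx(1.0, abs=1e-12)
        assert abs(m.emit[i_a, 0] - 0.5) < 0.05
        assert m.next[i_b, 1] == i_a and m.next[i_a, 0] == i_a and m.next[i_a, 1] == i_b

    def test_periodic_input_two_state_deterministic(self):
        x = SymbolSequence.from_string("01" * 500)
        m = cssr_estimate(x, 3, 0.001)
        assert m.n_states == 2
        assert entropy_rate(m) == 0.0

    def test_outputs_always_validate(self, zoo_machines):
        for name, m0 in zoo_machines.items():
            if name == "sns":
                continue  # nonunifilar truth; estimate still validates below
            x, _ = sample_sequence(m0, 5000, 9)
            m = cssr_estimate(x, 3, 0.001)
            assert validate_machine(m).ok, name
        xs, _ = sample_sequence(zoo_machines["sns"], 5000, 9)
        assert validate_machine(cssr_estimate(xs, 3, 0.001)).ok

    def test_state_count_bounded_by_histories(self, even):
        x, _ = sample_sequence(even, 3000, 1)
        Lh = 4
        m = cssr_estimate(x, Lh, 0.001)
        t = suffix_counts(x, Lh)
        assert m.n_states <= len(t.histories_of_length(Lh))

    def test_alpha_monotonicity_of_splitting(self, even):
        """The splitting phase degenerates to one candidate state as alpha
        -> 0 and toward the full suffix tree as alpha -> 1 (one sample)."""
        from cmboot.cssr import split_histories

        x, _ = sample_sequence(even, 10_000, 2)
        table = suffix_counts(x, 4)
        sizes = [len(split_histories(table, a)) for a in (1e-300, 1e-3, 0.9999)]
        assert sizes[0] == 1
        assert sizes[0] < sizes[1] < sizes[2]

    def test_emission_consistency_improves_with_T(self, even):
        """Median total-variation error of the matched 2-state architecture
        decreases as the sample grows."""
        med = []
        for T in (1000, 10_000, 100_000):
            tvs = []
            for seed in range(7):
                x, _ = sample_sequence(even, T, 100 + seed)
                m = cssr_estimate(x, 3, 0.001)
                if m.n_states != 2:
                    tvs.append(1.0)
                    continue
                i_b = int(np.argmax(m.emit[:, 1]))
                tv = 0.5 * np.abs(m.emit[1 - i_b] - [0.5, 0.5]).sum()
                tv += 0.5 * np.abs(m.emit[i_b] - [0.0, 1.0]).sum()
                tvs.append(tv)
            med.append(float(np.median(tvs)))
        assert med[2] < med[1] < med[0]
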