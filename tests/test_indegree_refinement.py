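import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairgrn.data_io import ExpressionData
from pairgrn.errors import InfeasibleCountsError
from pairgrn.indegree_refinement import (
    IndegreeAssignment,
    LossTable,
    PowerLawParams,
    assign_indegrees,
    build_loss_table,
    indegree_counts,
    loss_curve,
    modify_weights,
    refine,
    regulator_ordering,
)


def brute_force_objective(losses, counts):
    """Exhaustive minimum of the count-constrained assignment."""
    n, k_max = losses.shape
    degrees = np.repeat(np.arange(1, k_max + 1), counts)
    best = np.inf
    for perm in set(itertools.permutations(degrees)):
        best = min(best, sum(losses[i, d - 1] for i, d in enumerate(perm)))
    return best


class TestRegulatorOrdering:
    def test_perfect_determiner_first(self, rng):
        m = 20
        a = rng.normal(0, 1, m)
        target = 2.0 * a + 1.0  # exactly determined by gene 0
        b = target + rng.normal(0, 1, m)  # noisy relative
        data = ExpressionData(["A", "B", "Y"], np.column_stack([a, b, target]))
        ordering = regulator_ordering(data, target=2)
        assert ordering.tolist() == [0, 1]

    def test_identical_columns_tie_break_by_index(self, rng):
        m = 15
        a = rng.normal(0, 1, m)
        y = rng.normal(0, 1, m)
        data = ExpressionData(["A", "B", "Y"], np.column_stack([a, a.copy(), y]))
        assert regulator_ordering(data, target=2).tolist() == [0, 1]

    def test_is_permutation_of_candidates(self, rng):
        data = ExpressionData(
            [f"G{i}" for i in range(7)], rng.normal(0, 1, (20, 7))
        )
        ordering = regulator_ordering(data, target=3)
        assert sorted(ordering.tolist()) == [0, 1, 2, 4, 5, 6]


class TestLossCurve:
    def test_perfect_combinatorial_fit_zero_loss(self, rng):
        m = 25
        g1, g2 = rng.normal(0, 1, m), rng.normal(0, 1, m)
        extra = rng.normal(0, 1, (m, 2))
        y = g1 + g2
        data = ExpressionData(
            ["G1", "G2", "E1", "E2", "Y"],
            np.column_stack([g1, g2, extra, y]),
        )
        ordering = regulator_ordering(data, target=4)
        L = loss_curve(data, 4, ordering, k_max=3)
        assert L[1] == 0.0
        assert np.all(L >= 0)

    def test_argmin_recovers_true_indegree(self):
        """Simulation oracle: for a 3-regulator target (m = 20, small
        additive noise) the loss minimum lands at k = 3 in a clear majority
        of replicates and 3 is the modal choice.  F-statistic-based losses
        are only weakly parsimonious, so occasional overfit to k = 4 or 5
        is expected; the frozen 30-seed run recovers k = 3 in 20 of 30."""
        picks = []
        for rep in range(30):
            rng = np.random.default_rng(900 + rep)
            m = 20
            regs = rng.normal(0, 1, (m, 3))
            distract = rng.normal(0, 1, (m, 4))
            y = regs.sum(axis=1) + rng.normal(0, 0.1, m)
            data = ExpressionData(
                [f"G{i}" for i in range(8)],
                np.column_stack([regs, distract, y]),
            )
            ordering = regulator_ordering(data, target=7)
            L = loss_curve(data, 7, ordering, k_max=5)
            picks.append(int(np.argmin(L)) + 1)
        hits = picks.count(3)
        assert hits >= 15
        assert all(picks.count(k) < hits for k in (1, 2, 4, 5))


class TestIndegreeCounts:
    def test_hand_computed_example(self):
        counts = indegree_counts(10, PowerLawParams(gamma=1.5, kbar=3.3, k_max=3))
        assert counts.tolist() == [7, 2, 1]

    def test_kmax_one_puts_everything_at_one(self):
        assert indegree_counts(12, PowerLawParams(k_max=1)).tolist() == [12]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(5, 500),
        st.floats(0.5, 3.0),
        st.floats(0.5, 10.0),
        st.integers(1, 5),
    )
    def test_counts_sum_to_n_and_track_pmf(self, n, gamma, kbar, k_max):
        k_max = min(k_max, n)
        p = PowerLawParams(gamma=gamma, kbar=kbar, k_max=k_max)
        counts = indegree_counts(n, p)
        assert counts.sum() == n
        assert np.all(counts >= 0)
        # largest-remainder rounding never strays more than one unit
        assert np.all(np.abs(counts / n - p.pmf()) <= 1.0 / n)


class TestAssignIndegrees:
    @staticmethod
    def table(losses):
        losses = np.asarray(losses, float)
        n = losses.shape[0]
        return LossTable(losses=losses, orderings=[
            np.array([j for j in range(n) if j != i]) for i in range(n)
        ])

    def test_forced_assignment(self, rng):
        L = self.table(rng.uniform(0, 1, (5, 3)))
        res = assign_indegrees(L, [5, 0, 0])
        assert res.d_hat.tolist() == [1] * 5

    def test_matches_enumeration_on_4x2(self, rng):
        losses = rng.uniform(0, 1, (4, 2))
        res = assign_indegrees(self.table(losses), [2, 2])
        assert res.objective == pytest.approx(
            brute_force_objective(losses, np.array([2, 2])), rel=1e-9
        )
        assert sorted(res.d_hat.tolist()) == [1, 1, 2, 2]

    def test_tie_symmetry(self):
        losses = np.array([[0.3, 0.1], [0.3, 0.1], [0.9, 0.2], [0.5, 0.8]])
        res = assign_indegrees(self.table(losses), [2, 2])
        # genes 0 and 1 are exchangeable; either labeling gives this optimum
        assert res.objective == pytest.approx(
            brute_force_objective(losses, np.array([2, 2])), rel=1e-9
        )

    def test_selected_sets_follow_ordering(self, rng):
        L = self.table(rng.uniform(0, 1, (4, 2)))
        res = assign_indegrees(L, [2, 2])
        for i in range(4):
            assert res.selected[i].tolist() == L.orderings[i][: res.d_hat[i]].tolist()

    def test_infeasible_counts_error(self, rng):
        L = self.table(rng.uniform(0, 1, (4, 2)))
        with pytest.raises(InfeasibleCountsError):
            assign_indegrees(L, [1, 2])


class TestModifyWeights:
    @staticmethod
    def assignment_for_column(n, target, selected, others_select_all=True):
        sel = []
        for i in range(n):
            if i == target:
                sel.append(np.asarray(selected, dtype=int))
            else:
                rest = [j for j in range(n) if j != i] if others_select_all else []
                sel.append(np.array(rest, dtype=int))
        d = np.array([len(s) if len(s) else 1 for s in sel])
        return IndegreeAssignment(d_hat=d, selected=sel, objective=0.0)

    def test_selected_entry_lifted_just_above(self):
        W = np.zeros((4, 4))
        W[[0, 1, 2], 3] = [0.2, 0.5, 0.4]
        out = modify_weights(W, self.assignment_for_column(4, 3, [2]))
        eps = 1e-6 * 0.5
        assert out[2, 3] == pytest.approx(0.5 + eps)
        assert out[0, 3] == 0.2 and out[1, 3] == 0.5
        np.testing.assert_array_equal(out[:, :3], W[:, :3])

    def test_dominating_selection_unchanged(self):
        W = np.zeros((4, 4))
        W[[0, 1, 2], 3] = [0.2, 0.5, 0.4]
        out = modify_weights(W, self.assignment_for_column(4, 3, [1, 2]))
        np.testing.assert_array_equal(out, W)

    def test_select_all_unchanged(self):
        W = np.zeros((3, 3))
        W[[0, 1], 2] = [0.3, 0.6]
        out = modify_weights(W, self.assignment_for_column(3, 2, [0, 1]))
        np.testing.assert_array_equal(out, W)

    def test_separation_and_within_group_order(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            W = rng.uniform(0, 1, (n, n))
            np.fill_diagonal(W, 0.0)
            selected = []
            for i in range(n):
                cands = [j for j in range(n) if j != i]
                k = int(rng.integers(1, n - 1))
                selected.append(rng.choice(cands, size=k, replace=False))
            asn = IndegreeAssignment(
                d_hat=np.array([len(s) for s in selected]),
                selected=selected,
                objective=0.0,
            )
            out = modify_weights(W, asn)
            for i in range(n):
                sel = selected[i]
                unsel = np.setdiff1d(np.arange(n), np.append(sel, i))
                if unsel.size:
                    assert out[sel, i].min() > out[unsel, i].max()
                    np.testing.assert_array_equal(out[unsel, i], W[unsel, i])
                assert np.argsort(W[sel, i], kind="stable").tolist() == \
                    np.argsort(out[sel, i], kind="stable").tolist()


class TestRefinePipeline:
    def test_refine_runs_and_keeps_counts(self, rng):
        import pairgrn as pg

        net = pg.sample_network(20, PowerLawParams(k_max=3), seed=3)
        data = pg.simulate_multifactorial(net, pg.SimulationConfig(m=40, seed=3))
        Wn = pg.normalize_columns(pg.weight_matrix(data))
        Wm, asn = refine(data, Wn, PowerLawParams(k_max=3))
        counts = indegree_counts(20, PowerLawParams(k_max=3))
        hist = np.bincount(asn.d_hat, minlength=4)[1:]
        assert hist.tolist() == counts.tolist()
        assert Wm.shape == Wn.shape and np.all(np.isfinite(Wm))

    def test_kmax_guardrail_lowers_not_fails(self, rng):
        data = ExpressionData(
            [f"G{i}" for i in range(10)], rng.normal(0, 1, (5, 10))
        )
        table = build_loss_table(data, PowerLawParams(k_max=8))
        assert table.k_max == 3  # m - 2
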