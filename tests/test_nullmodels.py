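"""Null models: RA3/RA2 randomization, the Pianka overlap permutation test
against exact enumeration, and the proportional-abundance prey-choice null
against binomial/multinomial oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dietlink as dl
from dietlink.dietcore import pianka_overlap
from dietlink.nullmodels import _null_counts


class TestRandomizeUtilization:
    def test_ra3_conserves_row_multisets(self):
        mat = np.array([[0.5, 0.3, 0.2, 0.0], [0.1, 0.0, 0.0, 0.9]])
        out = dl.randomize_utilization(mat, "RA3", seed=0)
        for i in range(2):
            assert sorted(out[i]) == sorted(mat[i])

    def test_ra3_deterministic_for_seed(self):
        mat = np.array([[0.5, 0.3, 0.2]])
        a = dl.randomize_utilization(mat, "RA3", seed=42)
        b = dl.randomize_utilization(mat, "RA3", seed=42)
        assert (a == b).all()

    def test_ra3_permutations_uniform(self):
        """Each of the 6 permutations of 3 distinct values appears with
        frequency 1/6 up to Monte-Carlo error over 10,000 draws."""
        mat = np.array([[0.5, 0.3, 0.2]])
        rng = np.random.default_rng(1)
        counts: dict[tuple, int] = {}
        for _ in range(10_000):
            perm = tuple(dl.randomize_utilization(mat, "RA3", seed=rng)[0])
            counts[perm] = counts.get(perm, 0) + 1
        assert len(counts) == 6
        for n in counts.values():
            lo, hi = stats.binom.ppf([0.0005, 0.9995], 10_000, 1 / 6)
            assert lo <= n <= hi

    def test_ra2_keeps_zero_structure(self):
        mat = np.array([[0.5, 0.0, 0.5, 0.0]])
        out = dl.randomize_utilization(mat, "RA2", seed=3)
        assert (out[0] > 0).tolist() == [True, False, True, False]
        assert not np.allclose(out[0], mat[0])

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            dl.randomize_utilization(np.ones((1, 3)), "RA9")


class TestOverlapNullTest:
    def test_uniform_vector_never_exceeds_null(self):
        """A uniform utilization vector is invariant under permutation, so
        the observed overlap equals every null overlap."""
        pj = pd.Series([0.2] * 5)
        pk = pd.Series([0.4, 0.3, 0.1, 0.1, 0.1])
        res = dl.overlap_null_test(pj, pk, n_iterations=500, seed=0)
        assert res.proportion_exceeded == 0.0
        assert res.proportion_geq == 1.0

    def test_identical_skewed_vectors_significant(self):
        """Two identical strongly skewed vectors over 5 taxa: the observed
        overlap (1.0) beats the null in > 95% of randomizations —
        verified against complete enumeration of all permutation pairs."""
        p = np.array([0.70, 0.15, 0.10, 0.04, 0.01])
        exact_below = np.mean(
            [
                pianka_overlap(np.array(a), np.array(b)) < 1.0 - 1e-12
                for a in itertools.permutations(p)
                for b in itertools.permutations(p)
            ]
        )
        assert exact_below > 0.95  # enumeration oracle
        res = dl.overlap_null_test(pd.Series(p), pd.Series(p), n_iterations=4000, seed=1)
        assert res.observed == pytest.approx(1.0)
        assert res.proportion_exceeded == pytest.approx(exact_below, abs=0.02)
        assert res.significant

    def test_seeded_reproducibility(self):
        pj = pd.Series([0.5, 0.3, 0.2])
        pk = pd.Series([0.2, 0.3, 0.5])
        a = dl.overlap_null_test(pj, pk, n_iterations=200, seed=9)
        b = dl.overlap_null_test(pj, pk, n_iterations=200, seed=9)
        assert a == b


class TestPreyChoiceNull:
    def test_strong_preference_detected(self):
        """10 one-item guts, two equally abundant taxa, all positives on
        taxon A: binomial(10, 0.5) 95% limits are ~(2, 8), so A is
        preferred and B avoided."""
        abundance = pd.Series({"A": 50.0, "B": 50.0})
        observed = pd.Series({"A": 10, "B": 0})
        res = dl.prey_choice_null(abundance, [1] * 10, observed=observed, n_iterations=4000, seed=0)
        t = res.table.set_index("taxon")
        lo, hi = stats.binom.ppf([0.025, 0.975], 10, 0.5)
        assert t.loc["A", "lower"] == pytest.approx(lo, abs=1)
        assert t.loc["A", "upper"] == pytest.approx(hi, abs=1)
        assert res.preferred == ["A"] and res.avoided == ["B"]

    def test_single_available_taxon_degenerate(self):
        abundance = pd.Series({"A": 10.0})
        observed = pd.Series({"A": 7})
        res = dl.prey_choice_null(abundance, [1] * 7, observed=observed, n_iterations=200, seed=1)
        t = res.table.set_index("taxon")
        assert t.loc["A", "expected"] == 7.0
        assert t.loc["A", "lower"] == 7.0 and t.loc["A", "upper"] == 7.0
        assert t.loc["A", "class"] == "neutral"

    def test_gut_larger_than_available_rejected(self):
        with pytest.raises(ValueError):
            dl.prey_choice_null(pd.Series({"A": 5.0, "B": 0.0}), [2])

    def test_expected_matches_binomial_enumeration(self):
        """1-item guts make per-taxon null counts Binomial(n, p_t); the
        Monte-Carlo expectations and limits must agree with the exact
        distribution within Monte-Carlo error."""
        abundance = pd.Series({"a": 10.0, "b": 20.0, "c": 30.0, "d": 15.0, "e": 25.0})
        p = abundance / abundance.sum()
        n = 6
        res = dl.prey_choice_null(abundance, [1] * n, n_iterations=10_000, seed=2)
        t = res.table.set_index("taxon")
        for taxon, pt in p.items():
            assert t.loc[taxon, "expected"] == pytest.approx(n * pt, abs=3 * np.sqrt(n * pt * (1 - pt) / 10_000) + 0.02)
            lo, hi = stats.binom.ppf([0.025, 0.975], n, pt)
            assert abs(t.loc[taxon, "lower"] - lo) <= 1
            assert abs(t.loc[taxon, "upper"] - hi) <= 1

    def test_expectation_monotone_in_abundance(self):
        """Raising one taxon's abundance (others fixed) never decreases
        its expected consumer count."""
        base = {"a": 10.0, "b": 30.0, "c": 40.0}
        expectations = []
        for ab_a in (5.0, 20.0, 60.0):
            abundance = pd.Series({**base, "a": ab_a})
            res = dl.prey_choice_null(abundance, [2] * 20, n_iterations=4000, seed=3)
            expectations.append(res.table.set_index("taxon").loc["a", "expected"])
        assert expectations[0] < expectations[1] < expectations[2]

    def test_full_guts_are_deterministic(self):
        """When every gut consumes all available taxa, null counts are
        degenerate at n for every taxon."""
        abundance = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        res = dl.prey_choice_null(abundance, [3] * 5, n_iterations=100, seed=4)
        assert (res.table["expected"] == 5.0).all()

    def test_null_data_classified_neutral(self, abundance_row):
        """Guts simulated with unit selection weights (the null itself)
        leave most taxa classified neutral."""
        rates = []
        for seed in range(10):
            guts = dl.simulate_guts(abundance_row, "predatorA", 40, seed=100 + seed)
            inc = dl.truth_incidence(guts).reindex(columns=abundance_row.index, fill_value=0)
            res = dl.prey_choice_null(
                abundance_row, inc.sum(axis=1).tolist(), observed=inc.sum(axis=0), n_iterations=1000, seed=seed
            )
            rates.append((res.table["class"] == "neutral").mean())
        assert np.mean(rates) >= 0.93


class TestSelectionFromDiet:
    def test_matches_manual_call(self, diet_matrix, abundance_row):
        sub = diet_matrix.subset(predator_species="predatorA")
        res = dl.selection_from_diet(sub, abundance_row, n_iterations=500, seed=5)
        manual = dl.prey_choice_null(
            abundance_row.reindex(res.table["taxon"], fill_value=0.0),
            sub.incidence.sum(axis=1).to_numpy(),
            observed=sub.positives().reindex(res.table["taxon"], fill_value=0),
            n_iterations=500,
            seed=5,
        )
        pd.testing.assert_frame_equal(res.table, manual.table)
        assert res.selection_strength == manual.selection_strength


class TestCompareSelection:
    def _result(self, classes):
        table = pd.DataFrame(
            {
                "taxon": list(classes),
                "observed": 1.0,
                "expected": 1.0,
                "lower": 0.0,
                "upper": 2.0,
                "class": list(classes.values()),
            }
        )
        return dl.SelectionResult(table=table, selection_strength=0.0, n_iterations=10, seed=0)

    def test_joint_preferences(self):
        rj = self._result({"x": "preferred", "y": "preferred", "z": "avoided"})
        rk = self._result({"x": "preferred", "y": "neutral", "z": "avoided"})
        out = dl.compare_selection(rj, rk).set_index("taxon")
        assert out.loc["x", "joint"] == "preferred"
        assert out.loc["y", "joint"] == "none"
        assert out.loc["z", "joint"] == "avoided"

    def test_identical_results_joint_everywhere(self):
        rj = self._result({"x": "preferred", "y": "avoided"})
        out = dl.compare_selection(rj, rj)
        assert (out["joint"] == out["class_j"]).all()

    def test_mismatched_support_rejected(self):
        with pytest.raises(ValueError):
            dl.compare_selection(self._result({"x": "neutral"}), self._result({"y": "neutral"}))


def test_gumbel_topk_matches_sequential_sampling():
    """The vectorized Gumbel top-k draw reproduces the inclusion
    probabilities of explicit sequential sampling without replacement."""
    probs = np.array([0.5, 0.3, 0.2])
    rng = np.random.default_rng(0)
    counts = _null_counts(probs, np.array([2] * 1), 20_000, rng).sum(axis=0) / 20_000

    seq_rng = np.random.default_rng(1)
    seq_counts = np.zeros(3)
    for _ in range(20_000):
        remaining = list(range(3))
        w = probs.copy()
        for _ in range(2):
            w_norm = w[remaining] / w[remaining].sum()
            pick = seq_rng.choice(remaining, p=w_norm)
            seq_counts[pick] += 1
            remaining.remove(pick)
    seq_counts /= 20_000
    assert np.allclose(counts, seq_counts, atol=0.015)
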