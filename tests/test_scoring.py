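"""DGES/DPES construction: delta profiles, quartile scores, pathway sums,
and tertile assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathsurv.datatypes import ValidationError
from pathsurv.genesets import GeneSetCollection
from pathsurv.scoring import (
    assign_dges,
    compute_delta_profile,
    compute_dpes,
    tertile_assign,
    tertile_table,
)


def _profile(values, genes=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    return pd.DataFrame(
        arr,
        index=pd.Index([f"S{i:03d}" for i in range(arr.shape[0])],
                       name="subject_id"),
        columns=genes or [f"G{j}" for j in range(arr.shape[1])],
    )


class TestDeltaProfile:
    def test_equal_expression_gives_zero(self, pcm_factory):
        pcm = pcm_factory([[50, 50], [10, 10]], [[50, 50], [10, 10]])
        delta = compute_delta_profile(pcm)
        # equal counts AND equal depths -> identical CPM -> delta 0
        np.testing.assert_allclose(delta.to_numpy(), 0.0, atol=1e-12)

    def test_log2_ratio_arithmetic(self, pcm_factory):
        # single gene => CPM = 1e6 for both tissues; use 2 genes to set ratio
        pcm = pcm_factory([[80, 80], [20, 20]], [[20, 20], [80, 80]])
        delta = compute_delta_profile(pcm, pseudocount=1e-9)
        # gene 0: tumor CPM 8e5 vs normal 2e5 -> log2(4) = 2
        np.testing.assert_allclose(delta["G000"], 2.0, atol=1e-6)
        np.testing.assert_allclose(delta["G001"], -2.0, atol=1e-6)

    def test_depth_invariance(self, pcm_factory):
        t = np.array([[40, 40], [60, 60]])
        n = np.array([[10, 10], [90, 90]])
        d1 = compute_delta_profile(pcm_factory(t, n), pseudocount=0.5)
        d2 = compute_delta_profile(pcm_factory(2 * t, 2 * n), pseudocount=0.5)
        # doubling both libraries' depths leaves CPM, hence deltas, unchanged
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-9)


class TestAssignDGES:
    def test_quartile_rule_with_direction(self):
        vals = np.arange(8, dtype=float)[:, None]  # 0..7, one gene
        prof = _profile(vals)
        up = pd.Series({"G0": 1})
        scores = assign_dges(prof, up)["G0"]
        # q25 = 1.75, q75 = 5.25 for 0..7
        assert list(scores) == [1, 1, 2, 2, 2, 2, 3, 3]
        down = pd.Series({"G0": -1})
        flipped = assign_dges(prof, down)["G0"]
        assert list(flipped) == list(scores[::-1])

    def test_median_subject_scores_two(self):
        prof = _profile(np.array([1.0, 2.0, 3.0, 4.0, 5.0])[:, None])
        scores = assign_dges(prof, pd.Series({"G0": 1}))["G0"]
        assert scores.iloc[2] == 2  # exactly at the median

    def test_boundary_values_fall_in_middle_bin(self):
        # value exactly at q75 must score 2, not 3 (strict inequality)
        prof = _profile(np.array([0.0, 1.0, 2.0, 3.0, 3.0])[:, None])
        q75 = np.quantile(prof["G0"], 0.75)
        scores = assign_dges(prof, pd.Series({"G0": 1}))["G0"]
        at_boundary = prof["G0"] == q75
        assert (scores[at_boundary] == 2).all()

    def test_constant_gene_scores_all_two(self):
        prof = _profile(np.full((6, 1), 1.3))
        scores = assign_dges(prof, pd.Series({"G0": 1}))["G0"]
        assert (scores == 2).all()

    def test_too_few_subjects_rejected(self):
        prof = _profile(np.zeros((3, 1)))
        with pytest.raises(ValidationError):
            assign_dges(prof, pd.Series({"G0": 1}))

    def test_string_directions_accepted(self):
        prof = _profile(np.arange(8, dtype=float)[:, None])
        a = assign_dges(prof, pd.Series({"G0": "up"}))
        b = assign_dges(prof, pd.Series({"G0": 1}))
        pd.testing.assert_frame_equal(a, b)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_occupancy_quarter_half_quarter(self, seed):
        """Continuous deltas: ~25% score 1, ~50% score 2, ~25% score 3."""
        rng = np.random.default_rng(seed)
        prof = _profile(rng.normal(size=(200, 3)))
        dirs = pd.Series({g: rng.choice([1, -1]) for g in prof.columns})
        scores = assign_dges(prof, dirs)
        for g in prof.columns:
            frac1 = (scores[g] == 1).mean()
            frac3 = (scores[g] == 3).mean()
            assert abs(frac1 - 0.25) <= 0.01 + 1 / 200
            assert abs(frac3 - 0.25) <= 0.01 + 1 / 200


class TestComputeDPES:
    def _dges(self):
        return pd.DataFrame(
            {"a": [1, 3], "b": [2, 3], "c": [3, 3], "d": [3, 1]},
            index=pd.Index(["S0", "S1"], name="subject_id"),
        )

    def test_sum_and_bounds(self):
        sets = GeneSetCollection({"P": ["a", "b", "c", "d"]})
        dpes = compute_dpes(self._dges(), sets)
        assert dpes.loc["S0", "P"] == 9
        assert dpes.loc["S1", "P"] == 10
        G = 4
        assert ((dpes["P"] >= G) & (dpes["P"] <= 3 * G)).all()

    def test_additivity_over_disjoint_pathways(self):
        sets = GeneSetCollection(
            {"P1": ["a", "b"], "P2": ["c", "d"], "U": ["a", "b", "c", "d"]}
        )
        dpes = compute_dpes(self._dges(), sets)
        np.testing.assert_array_equal(dpes["U"], dpes["P1"] + dpes["P2"])

    def test_unscored_pathway_dropped_with_warning(self):
        sets = GeneSetCollection({"P": ["a"], "Q": ["zz"]})
        with pytest.warns(UserWarning, match="no scored member"):
            dpes = compute_dpes(self._dges(), sets)
        assert list(dpes.columns) == ["P"]

    def test_subject_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        dges = pd.DataFrame(
            rng.integers(1, 4, size=(10, 4)),
            index=[f"S{i}" for i in range(10)],
            columns=["a", "b", "c", "d"],
        )
        sets = GeneSetCollection({"P": ["a", "c"]})
        base = compute_dpes(dges, sets)
        perm = rng.permutation(dges.index)
        shuffled = compute_dpes(dges.loc[perm], sets)
        pd.testing.assert_frame_equal(shuffled, base.loc[perm])


class TestTertiles:
    def test_nine_distinct_values_split_evenly(self):
        s = pd.Series(np.arange(9, dtype=float), index=[f"S{i}" for i in range(9)])
        labels = tertile_assign(s)
        assert list(labels) == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_tied_values_at_cut_points(self):
        s = pd.Series([1, 1, 1, 2, 2, 2, 3, 3, 3],
                      index=[f"S{i}" for i in range(9)])
        labels = tertile_assign(s)
        assert (labels.value_counts().sort_index() == [3, 3, 3]).all()

    def test_monotone_in_score(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.integers(4, 30, 50), index=[f"S{i}" for i in range(50)])
        labels = tertile_assign(s)
        df = pd.DataFrame({"v": s, "t": labels}).sort_values("v")
        assert (df["t"].diff().dropna() >= 0).all()

    def test_degenerate_all_equal(self):
        s = pd.Series([5, 5, 5, 5], index=list("abcd"))
        with pytest.warns(UserWarning, match="degenerate"):
            labels = tertile_assign(s)
        assert (labels == 1).all()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            tertile_assign(pd.Series([1, 2], index=["a", "b"]))

    def test_table_applies_per_pathway(self):
        dpes = pd.DataFrame(
            {"P": np.arange(9), "Q": np.arange(9)[::-1]},
            index=[f"S{i}" for i in range(9)],
        )
        table = tertile_table(dpes)
        assert list(table["P"]) == [1, 1, 1, 2, 2, 2, 3, 3, 3]
        assert list(table["Q"]) == [3, 3, 3, 2, 2, 2, 1, 1, 1]


class TestEndToEndSignal:
    def test_linked_pathway_scores_track_true_tertiles(self, small_cohort):
        """Subjects in higher true tertiles receive higher DPES for the
        survival-linked pathway (the generator's core promise)."""
        cohort = small_cohort
        truth = cohort.truth
        linked = list(truth.linked_members)[0]
        direction = truth.genes.loc[truth.genes["is_de"], "direction"]
        delta = compute_delta_profile(cohort.counts,
                                      features=list(direction.index))
        dges = assign_dges(delta, direction)
        dpes = compute_dpes(dges, GeneSetCollection(
            {linked: [g for g in cohort.gene_sets[linked]
                      if g in dges.columns]}
        ))
        means = dpes[linked].groupby(truth.subjects["true_tertile"]).mean()
        assert means[3] > means[1]
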