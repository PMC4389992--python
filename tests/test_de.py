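"""Paired DE test: thinning, signed-rank statistic, permutation null,
fold change, and the two-group selection rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pathsurv import SimulationConfig
from pathsurv.datatypes import ValidationError
from pathsurv.de import (
    ResamplingScheme,
    SelectionRule,
    _thin_matrix,
    fold_change,
    paired_de_test,
    paired_signed_rank,
    permutation_pvalue,
    select_de_features,
    selection_table,
    thin_counts,
)
from pathsurv.simulate import generate_paired_counts


def brute_force_signed_rank_null(diffs):
    """Independent oracle: standardized signed-rank statistic under all
    2^n within-pair label flips, by direct enumeration."""
    d = np.asarray(diffs, dtype=float)
    absd = np.abs(d)
    order = absd.argsort()
    ranks = np.empty(len(d))
    # mid-ranks by hand
    sorted_abs = absd[order]
    r = 1.0
    i = 0
    while i < len(d):
        j = i
        while j + 1 < len(d) and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + 1 + j + 1) / 2.0
        i = j + 1
    n_zero = int((absd == 0).sum())
    ranks = np.where(absd == 0, 0.0, ranks - n_zero)
    sigma = np.sqrt((ranks ** 2).sum())
    stats = []
    for signs in itertools.product((1, -1), repeat=len(d)):
        w = float((np.sign(d) * np.asarray(signs) * ranks).sum())
        stats.append(w / sigma)
    return np.array(stats), ranks, sigma


class TestThinning:
    def test_equal_depths_pass_through(self, pcm_factory):
        rng = np.random.default_rng(0)
        t = rng.poisson(20, size=(10, 4))
        n = t.copy()
        # equalize depths exactly
        pcm = pcm_factory(t, n)
        scheme = ResamplingScheme(n_resamples=3, seed=0)
        target = float(pcm.depths().min())
        # only columns at the minimum depth pass through; force all equal
        t_eq = np.tile(t[:, :1], (1, 4))
        pcm = pcm_factory(t_eq, t_eq)
        for res in thin_counts(pcm, ResamplingScheme(n_resamples=3, seed=0)):
            pd.testing.assert_frame_equal(res.counts, pcm.counts)
        del scheme, target

    def test_expected_total_equals_target(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(50, size=(200, 1))
        depth = float(counts.sum())
        target = depth / 2.0
        totals = [
            _thin_matrix(counts, np.array([depth]), target, rng).sum()
            for _ in range(1000)
        ]
        assert abs(np.mean(totals) - target) / target < 0.01

    def test_zero_counts_stay_zero(self):
        rng = np.random.default_rng(2)
        counts = np.zeros((5, 2), dtype=int)
        counts[0, 0] = 100  # give depth
        out = _thin_matrix(counts, np.array([100.0, 1.0]), 1.0, rng)
        assert (out[1:] == 0).all()

    def test_target_above_depth_rejected(self, pcm_factory):
        pcm = pcm_factory([[5, 5]], [[5, 5]])
        with pytest.raises(ValidationError):
            thin_counts(pcm, ResamplingScheme(target_depth=100, seed=0))


class TestSignedRank:
    def test_all_positive_attains_maximum(self):
        n = 8
        stat = paired_signed_rank(np.arange(10, 10 + n) * 2, np.arange(n))
        w_max = n * (n + 1) / 2
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 6)
        assert stat == pytest.approx(w_max / sigma)

    def test_identical_pairs_give_zero(self):
        assert paired_signed_rank([3, 7, 9], [3, 7, 9]) == 0.0

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(3)
        t = rng.poisson(30, 12)
        n = rng.poisson(30, 12)
        assert paired_signed_rank(t, n) == pytest.approx(
            -paired_signed_rank(n, t)
        )

    def test_matches_enumeration_oracle(self):
        """Exact p for differences (+5, -2, +1) against brute force."""
        diffs = np.array([5.0, -2.0, 1.0])
        null, ranks, sigma = brute_force_signed_rank_null(diffs)
        obs = float((np.sign(diffs) * ranks).sum() / sigma)
        assert paired_signed_rank(diffs, np.zeros(3)) == pytest.approx(obs)
        expected_p = float((np.abs(null) >= abs(obs) - 1e-12).mean())
        p, _ = permutation_pvalue(diffs[None, :])
        assert p[0] == pytest.approx(expected_p)
        assert expected_p == pytest.approx(6 / 8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_enumeration_matches_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(-20, 20, size=(5, 7)).astype(float)
        p, _ = permutation_pvalue(d)
        for i in range(d.shape[0]):
            null, ranks, sigma = brute_force_signed_rank_null(d[i])
            if sigma == 0:
                continue
            obs = (np.sign(d[i]) * ranks).sum() / sigma
            assert p[i] == pytest.approx(
                float((np.abs(null) >= abs(obs) - 1e-12).mean())
            )


class TestPermutationP:
    def test_sampled_path_add_one_floor(self):
        # 12 pairs -> sampled path; strongly one-sided differences give
        # the minimum attainable p under the add-one rule
        d = np.arange(1, 13, dtype=float)[None, :]
        p, _ = permutation_pvalue(d, n_perm=199, seed=0)
        assert p[0] == pytest.approx(1 / 200)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        d = rng.normal(size=(50, 15))
        p1, q1 = permutation_pvalue(d, n_perm=100, seed=9)
        p2, q2 = permutation_pvalue(d, n_perm=100, seed=9)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(q1, q2)

    def test_invalid_n_perm(self):
        with pytest.raises(ValidationError):
            permutation_pvalue(np.ones((2, 12)), n_perm=0)

    def test_null_rejection_rate_small(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=(600, 25))
        p, _ = permutation_pvalue(d, n_perm=200, seed=1)
        assert 0.02 <= (p < 0.05).mean() <= 0.09


class TestFoldChange:
    def test_ratio_of_means(self, pcm_factory):
        pcm = pcm_factory([[20, 30, 40]], [[5, 10, 15]])
        fc = fold_change(pcm, pseudocount=0.0, normalize="none")
        assert fc["fold_change"].iloc[0] == pytest.approx(3.0)
        assert fc["direction"].iloc[0] == "up"

    def test_identical_gives_unity(self, pcm_factory):
        pcm = pcm_factory([[7, 7, 7]], [[7, 7, 7]])
        fc = fold_change(pcm, pseudocount=0.0, normalize="none")
        assert fc["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_gives_reciprocal(self, pcm_factory):
        t = [[12, 24, 36], [5, 6, 7]]
        n = [[3, 6, 9], [10, 12, 14]]
        fc = fold_change(pcm_factory(t, n), pseudocount=0.0, normalize="none")
        rev = fold_change(pcm_factory(n, t), pseudocount=0.0, normalize="none")
        np.testing.assert_allclose(
            fc["fold_change"], 1.0 / rev["fold_change"]
        )

    def test_zero_normal_mean_without_pseudocount(self, pcm_factory):
        pcm = pcm_factory([[3, 3]], [[0, 0]])
        with pytest.raises(ValidationError):
            fold_change(pcm, pseudocount=0.0, normalize="none")


class TestPairedDETest:
    def test_determinism_and_antisymmetry(self, pcm_factory):
        # equal library depths (multinomial totals) so thinning is the
        # identity: label-swap antisymmetry must then hold exactly
        rng = np.random.default_rng(6)
        props = rng.dirichlet(np.ones(80))
        t = rng.multinomial(5000, props, size=15).T
        n = rng.multinomial(5000, props, size=15).T
        pcm = pcm_factory(t, n)
        scheme = ResamplingScheme(n_resamples=3, seed=2)
        r1 = paired_de_test(pcm, scheme, n_perm=50)
        r2 = paired_de_test(pcm, scheme, n_perm=50)
        pd.testing.assert_frame_equal(r1, r2)

        # swapping tissue labels negates the statistic
        swapped = pcm.samples.copy()
        swapped["tissue"] = swapped["tissue"].map(
            {"tumor": "normal", "normal": "tumor"}
        )
        from pathsurv.datatypes import PairedCountMatrix

        r3 = paired_de_test(PairedCountMatrix(pcm.counts, swapped), scheme,
                            n_perm=50)
        np.testing.assert_allclose(r3["statistic"], -r1["statistic"],
                                   atol=1e-12)

    def test_power_monotone_in_fold_change(self):
        """Rejection rate among truly DE genes is non-decreasing in the
        true fold change (one simulated cohort per fold change)."""
        rates = []
        for i, fc in enumerate([1.0, 1.5, 2.0, 4.0]):
            frac_de = 0.0 if fc == 1.0 else 0.06
            cfg = SimulationConfig(
                n_subjects=20, n_genes=1000, frac_de=frac_de,
                fc_range=(max(fc, 1.0 + 1e-9), max(fc, 1.0 + 1e-9)),
                n_pathways=0, n_linked_pathways=0, seed=70 + i,
            )
            pcm, _, truth = generate_paired_counts(cfg)
            res = paired_de_test(pcm, ResamplingScheme(n_resamples=2, seed=0),
                                 n_perm=200)
            target = truth.genes["is_de"] if frac_de else slice(None)
            rates.append((res.loc[target, "p_perm"] < 0.05).mean())
        for lo, hi in zip(rates, rates[1:]):
            assert hi >= lo - 0.02
        assert rates[-1] > 0.9

    def test_degenerate_feature_flagged(self, pcm_factory):
        t = np.vstack([np.full(6, 40), np.full(6, 10)])
        pcm = pcm_factory(t, t.copy())
        res = paired_de_test(pcm, ResamplingScheme(n_resamples=1, seed=0),
                             n_perm=10)
        assert res["degenerate"].all()
        assert (res["statistic"] == 0).all()


class TestSelection:
    def _results(self, p, fc):
        return pd.DataFrame(
            {"statistic": 0.0, "p_perm": p, "q_value": p,
             "fold_change": fc,
             "direction": np.where(np.asarray(fc) > 1, "up", "down"),
             "n_pairs": 10, "degenerate": False},
            index=[f"G{i}" for i in range(len(p))],
        )

    def test_rule_and_conservation(self):
        a = self._results([0.01, 0.01, 0.01, 0.20, 0.01],
                          [2.5, 0.3, 2.5, 3.0, 1.2])
        b = self._results([0.02, 0.04, 0.01, 0.01, 0.01],
                          [2.2, 0.4, 0.4, 3.0, 1.3])
        up, down = select_de_features(a, b, SelectionRule())
        assert up == ["G0"]        # significant + >2-fold up in both
        assert down == ["G1"]      # significant + <0.5-fold in both
        # G2 discordant direction, G3 not significant in A, G4 below fold
        assert len(up) + len(down) + 3 == len(a)

    def test_universe_mismatch_rejected(self):
        a = self._results([0.01], [3.0])
        b = self._results([0.01, 0.01], [3.0, 3.0])
        with pytest.raises(ValidationError):
            select_de_features(a, b)

    def test_selection_table_flags(self):
        a = self._results([0.01, 0.30], [2.5, 2.5])
        b = self._results([0.01, 0.01], [2.5, 2.5])
        table = selection_table(a, b)
        assert bool(table.loc["G0", "selected_both"])
        assert not bool(table.loc["G1", "selected_both"])
        assert table.loc["G0", "direction"] == "up"
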