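"""Paired nonparametric differential expression for RNA-seq counts.

The test is a reimplementation of the resampling/permutation strategy
popularised for sequencing counts by SAMseq's paired two-class mode:

1. *Depth-equalizing resampling (thinning).* Each library is binomially
   down-sampled to a common target depth (default: the minimum library
   size), removing sequencing depth as a confounder. This is repeated
   ``n_resamples`` times (default 20).
2. *Paired signed-rank statistic.* For each gene and resample, the
   Wilcoxon signed-rank statistic of the tumor-minus-normal differences
   is computed (zero differences dropped, mid-ranks for ties) and
   standardized to mean 0 / unit variance under the null; the reported
   statistic is the mean across resamples.
3. *Within-pair permutation null.* Null statistics are generated by
   independently flipping the tumor/normal labels within each pair
   (default 1,000 permutations, exact enumeration of all 2^n flips when
   n_pairs <= 10) on the SAME resample stream as the observed statistic
   (common random numbers), and the two-sided permutation p-value uses
   the add-one rule. Benjamini-Hochberg q-values are reported per batch.

Fold change is the ratio of mean tumor to mean normal expression on
depth-normalized values (counts per million) with a pseudocount, and
the two-group selection rule keeps genes significant (p below the
threshold) with a concordant >= 2-fold change in both discovery groups.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .datatypes import PairedCountMatrix, ValidationError

log = logging.getLogger(__name__)

EXACT_MAX_PAIRS = 10


@dataclass
class ResamplingScheme:
    """Depth-equalizing resampling parameters.

    target_depth defaults to the minimum library depth of the matrix it
    is applied to; it must not exceed any library's depth.
    """

    n_resamples: int = 20
    target_depth: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValidationError("n_resamples must be >= 1")

    def resolve_target(self, depths: pd.Series) -> float:
        target = self.target_depth if self.target_depth is not None else float(
            depths.min()
        )
        if target <= 0:
            raise ValidationError("target depth must be positive")
        if (depths < target - 1e-9).any():
            raise ValidationError(
                "target_depth exceeds the depth of at least one library"
            )
        return target


@dataclass
class SelectionRule:
    """Two-group gene selection: significant and >= fc_threshold-fold
    concordant change in both discovery groups."""

    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    require_both_groups: bool = True
    require_consistent_direction: bool = True

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.fc_threshold <= 0:
            raise ValidationError("selection thresholds must be positive")


def _thin_matrix(
    counts: np.ndarray, depths: np.ndarray, target: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomially thin each column to the target depth.

    Each count c in sample j is replaced by Binomial(c, target/depth_j);
    columns already at the target pass through unchanged.
    """
    p = np.minimum(target / depths, 1.0)
    at_target = np.isclose(p, 1.0)
    out = rng.binomial(counts, p[None, :])
    out[:, at_target] = counts[:, at_target]
    return out


def thin_counts(
    counts: PairedCountMatrix, scheme: ResamplingScheme
) -> list[PairedCountMatrix]:
    """Materialize the resample stream as a list of thinned matrices."""
    depths = counts.depths()
    target = scheme.resolve_target(depths)
    rng = np.random.default_rng([int(scheme.seed), 41])
    out = []
    raw = counts.counts.to_numpy()
    for _ in range(scheme.n_resamples):
        thinned = _thin_matrix(raw, depths.to_numpy(dtype=float), target, rng)
        out.append(
            PairedCountMatrix(
                pd.DataFrame(thinned, index=counts.counts.index,
                             columns=counts.counts.columns),
                counts.samples.copy(),
            )
        )
    return out


def _signed_rank_stats(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized signed-rank statistic per row of a differences matrix.

    Returns (stat, v, sigma) where v[g, i] = sign(d) * rank(|d|) with
    zero differences excluded (rank 0) and sigma = sqrt(sum of squared
    ranks), the null standard deviation. stat = sum(v) / sigma, 0 where
    every difference is zero.
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    a = np.abs(d)
    zero = a == 0
    ranks = rankdata(a, method="average", axis=1)
    # zeros are strictly the smallest |d|; shifting by the zero count
    # leaves mid-ranks of the non-zero entries exact
    ranks = np.where(zero, 0.0, ranks - zero.sum(axis=1, keepdims=True))
    v = np.sign(d) * ranks
    sigma = np.sqrt((ranks ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(sigma > 0, v.sum(axis=1) / np.where(sigma == 0, 1.0, sigma),
                        0.0)
    return stat, v, sigma


def paired_signed_rank(tumor, normal) -> float:
    """Standardized Wilcoxon signed-rank statistic for one gene.

    Positive values mean tumor expression exceeds normal. Returns 0.0
    when every within-pair difference is zero (degenerate case).
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape:
        raise ValidationError("tumor and normal vectors must align")
    if tumor.size < 2:
        raise ValidationError("need at least 2 pairs")
    stat, _, _ = _signed_rank_stats((tumor - normal)[None, :])
    return float(stat[0])


def _flip_matrix(
    n_pairs: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Within-pair label-flip signs: exact enumeration for small n."""
    if n_pairs <= EXACT_MAX_PAIRS:
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=n_pairs)))
        return flips, True
    return rng.choice([1.0, -1.0], size=(n_perm, n_pairs)), False


def permutation_pvalue(
    pair_data, n_perm: int = 1000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation p-values and BH q-values for a batch.

    Parameters
    ----------
    pair_data
        features x pairs array (or DataFrame) of within-pair
        differences; the observed statistic is the standardized
        signed-rank statistic of each row.
    n_perm
        Number of within-pair label flips; ignored when n_pairs <= 10,
        where all 2^n flips are enumerated.

    Returns (p, q): on the sampled path p = (1 + #{|null| >= |obs|}) /
    (n_perm + 1); on the exact path p = #{|null| >= |obs|} / 2^n with
    the identity flip included, so p > 0 either way.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    d = np.atleast_2d(np.asarray(pair_data, dtype=float))
    rng = np.random.default_rng([int(seed), 42])
    obs, v, sigma = _signed_rank_stats(d)
    flips, exact = _flip_matrix(d.shape[1], n_perm, rng)
    safe_sigma = np.where(sigma == 0, 1.0, sigma)
    null = (v @ flips.T) / safe_sigma[:, None]
    null[sigma == 0, :] = 0.0
    hits = (np.abs(null) >= np.abs(obs)[:, None] - 1e-12).sum(axis=1)
    if exact:
        p = hits / flips.shape[0]
    else:
        p = (1.0 + hits) / (n_perm + 1.0)
    q = bh_qvalues(p)
    return p, q


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def fold_change(
    counts: PairedCountMatrix, pseudocount: float = 0.5, normalize: str = "cpm"
) -> pd.DataFrame:
    """Per-gene fold change: mean tumor / mean normal expression.

    Means are taken over depth-normalized values (counts per million by
    default; ``normalize="none"`` uses raw counts) and a pseudocount is
    added to both means so genes silent in normal tissue stay finite.
    """
    if normalize == "cpm":
        norm = counts.cpm()
        tumor_cols = counts.sample_columns("tumor")
        normal_cols = counts.sample_columns("normal")
        mean_t = norm[tumor_cols].mean(axis=1)
        mean_n = norm[normal_cols].mean(axis=1)
    elif normalize == "none":
        mean_t = counts.matrix("tumor").mean(axis=1)
        mean_n = counts.matrix("normal").mean(axis=1)
    else:
        raise ValidationError(f"unknown normalization {normalize!r}")
    denom = mean_n + pseudocount
    if (denom == 0).any():
        raise ValidationError(
            "zero normal mean with zero pseudocount; fold change undefined"
        )
    fc = (mean_t + pseudocount) / denom
    return pd.DataFrame(
        {
            "fold_change": fc,
            "direction": np.where(fc > 1.0, "up", "down"),
        },
        index=counts.counts.index,
    )


def paired_de_test(
    counts: PairedCountMatrix,
    scheme: ResamplingScheme | None = None,
    n_perm: int = 1000,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full paired DE test for every gene of a paired count matrix.

    Returns a DataFrame indexed by feature id with columns: statistic
    (resample-averaged standardized signed-rank score), p_perm, q_value,
    fold_change, direction, n_pairs, degenerate.

    Implementation notes: the permutation flips are shared across genes
    and resamples (as in SAMseq), and null statistics are computed on
    the same resamples as the observed statistic, so resampling noise
    affects observed and null identically.
    """
    scheme = scheme or ResamplingScheme()
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if counts.n_pairs < 2:
        raise ValidationError("need at least 2 tumor/normal pairs")
    depths = counts.depths()
    target = scheme.resolve_target(depths)
    rng = np.random.default_rng([int(scheme.seed), 43])

    tumor_cols = counts.sample_columns("tumor")
    normal_cols = counts.sample_columns("normal")
    raw = counts.counts
    d_t = depths[tumor_cols].to_numpy(dtype=float)
    d_n = depths[normal_cols].to_numpy(dtype=float)
    t_raw = raw[tumor_cols].to_numpy()
    n_raw = raw[normal_cols].to_numpy()

    n_pairs = counts.n_pairs
    flips, exact = _flip_matrix(n_pairs, n_perm, rng)

    obs_sum = np.zeros(raw.shape[0])
    null_sum = np.zeros((raw.shape[0], flips.shape[0]))
    all_degenerate = np.ones(raw.shape[0], dtype=bool)
    for _ in range(scheme.n_resamples):
        t = _thin_matrix(t_raw, d_t, target, rng)
        n = _thin_matrix(n_raw, d_n, target, rng)
        stat, v, sigma = _signed_rank_stats(t - n)
        obs_sum += stat
        safe = np.where(sigma == 0, 1.0, sigma)
        contrib = (v @ flips.T) / safe[:, None]
        contrib[sigma == 0, :] = 0.0
        null_sum += contrib
        all_degenerate &= sigma == 0

    obs = obs_sum / scheme.n_resamples
    null = null_sum / scheme.n_resamples
    hits = (np.abs(null) >= np.abs(obs)[:, None] - 1e-12).sum(axis=1)
    if exact:
        p = hits / flips.shape[0]
    else:
        p = (1.0 + hits) / (flips.shape[0] + 1.0)
    q = bh_qvalues(p)

    fc = fold_change(counts, pseudocount=pseudocount)
    out = pd.DataFrame(
        {
            "statistic": obs,
            "p_perm": p,
            "q_value": q,
            "fold_change": fc["fold_change"],
            "direction": fc["direction"],
            "n_pairs": n_pairs,
            "degenerate": all_degenerate,
        },
        index=raw.index,
    )
    return out


def select_de_features(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    rule: SelectionRule | None = None,
) -> tuple[list[str], list[str]]:
    """Genes significant and concordantly >= fc_threshold-fold changed
    in both discovery groups, partitioned into (up, down) lists."""
    rule = rule or SelectionRule()
    if set(results_a.index) != set(results_b.index):
        raise ValidationError("feature universes of groups A and B differ")
    b = results_b.loc[results_a.index]
    a = results_a

    sig_a = a["p_perm"] < rule.p_threshold
    sig_b = b["p_perm"] < rule.p_threshold
    up_a = a["fold_change"] > rule.fc_threshold
    up_b = b["fold_change"] > rule.fc_threshold
    dn_a = a["fold_change"] < 1.0 / rule.fc_threshold
    dn_b = b["fold_change"] < 1.0 / rule.fc_threshold

    if rule.require_both_groups:
        sig = sig_a & sig_b
    else:
        sig = sig_a | sig_b
    if rule.require_consistent_direction:
        up = sig & up_a & up_b
        down = sig & dn_a & dn_b
    else:
        up = sig & (up_a | up_b) & ~(dn_a | dn_b)
        down = sig & (dn_a | dn_b) & ~(up_a | up_b)
    up_list = list(a.index[up])
    down_list = list(a.index[down])
    log.info("selection: %d up, %d down of %d tested",
             len(up_list), len(down_list), len(a))
    return up_list, down_list


def selection_table(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    rule: SelectionRule | None = None,
) -> pd.DataFrame:
    """Per-feature report combining both groups with selection flags."""
    rule = rule or SelectionRule()
    up, down = select_de_features(results_a, results_b, rule)
    b = results_b.loc[results_a.index]
    out = pd.DataFrame(
        {
            "statistic_A": results_a["statistic"],
            "p_perm_A": results_a["p_perm"],
            "q_value_A": results_a["q_value"],
            "fold_change_A": results_a["fold_change"],
            "statistic_B": b["statistic"],
            "p_perm_B": b["p_perm"],
            "q_value_B": b["q_value"],
            "fold_change_B": b["fold_change"],
        },
        index=results_a.index,
    )
    sel = set(up) | set(down)
    out["selected_A"] = (out["p_perm_A"] < rule.p_threshold) & (
        (out["fold_change_A"] > rule.fc_threshold)
        | (out["fold_change_A"] < 1 / rule.fc_threshold)
    )
    out["selected_B"] = (out["p_perm_B"] < rule.p_threshold) & (
        (out["fold_change_B"] > rule.fc_threshold)
        | (out["fold_change_B"] < 1 / rule.fc_threshold)
    )
    out["selected_both"] = [f in sel for f in out.index]
    out["direction"] = np.where(
        [f in set(up) for f in out.index], "up",
        np.where([f in set(down) for f in out.index], "down", ""),
    )
    return out
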