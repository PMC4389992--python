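"""Per-subject pathway de-regulation scores (DGES and DPES).

This is the study's core construct:

* **Delta profile** — for each subject and DE gene, the individual
  level of differential expression: log2 of the tumor/normal ratio of
  depth-normalized expression (counts per million) with a pseudocount.
* **DGES (differential gene expression score)** — per gene, the delta
  values are oriented by the gene's cohort-level direction (so that
  larger always means "more de-regulated", and the bottom quartile is
  "closer to normal" for down-regulated genes too) and cut at the
  cohort quartiles: score 1 below the 25th percentile, 3 above the
  75th, 2 in between (boundary values fall in the middle bin).
* **DPES (differential pathway expression score)** — the sum of DGES
  over a pathway's member genes, so a pathway of G scored genes ranges
  over [G, 3G]; higher means more of the pathway is de-regulated in
  that subject's tumor.
* **Tertiles** — per pathway, DPES values are cut at the cohort's
  33.3rd/66.7th percentiles for survival modelling; ties at a cut point
  go to the lower tertile, keeping the top tertile conservative.

The orientation step is the single most consequential convention here:
without it, strongly down-regulated genes would score "1" for the most
de-regulated subjects. It is applied as multiplication by the gene's
direction sign (+1 up, -1 down).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import PairedCountMatrix, ValidationError
from .genesets import GeneSetCollection

log = logging.getLogger(__name__)


def compute_delta_profile(
    counts: PairedCountMatrix,
    features=None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Subjects x genes matrix of per-subject differential expression.

    delta[s, g] = log2((cpm_tumor + c) / (cpm_normal + c)); the CPM
    normalization makes the value invariant to library depth.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive for log ratios")
    cpm = counts.cpm()
    t = cpm[counts.sample_columns("tumor")].to_numpy()
    n = cpm[counts.sample_columns("normal")].to_numpy()
    delta = np.log2((t + pseudocount) / (n + pseudocount))
    out = pd.DataFrame(
        delta.T,
        index=pd.Index(counts.subjects, name="subject_id"),
        columns=counts.counts.index,
    )
    if features is not None:
        missing = [f for f in features if f not in out.columns]
        if missing:
            raise ValidationError(f"features absent from counts: {missing[:10]}")
        out = out[list(features)]
    return out


def assign_dges(profile: pd.DataFrame, gene_direction: pd.Series) -> pd.DataFrame:
    """Quartile-based 1/2/3 de-regulation score per subject and gene.

    Parameters
    ----------
    profile
        Subjects x genes delta profile.
    gene_direction
        Per-gene direction sign (+1 up-regulated, -1 down-regulated) or
        the strings "up"/"down"; genes missing from it raise.

    Scores use the cohort distribution of the oriented delta
    (delta x direction): 1 strictly below the 25th percentile, 3
    strictly above the 75th, 2 otherwise. Quartiles are
    linear-interpolation sample quantiles over the full analysis
    cohort.
    """
    if len(profile) < 4:
        raise ValidationError("need at least 4 subjects for quartile scoring")
    dirs = gene_direction.replace({"up": 1, "down": -1}).astype(float)
    missing = [g for g in profile.columns if g not in dirs.index]
    if missing:
        raise ValidationError(f"no direction for genes: {missing[:10]}")
    sign = dirs.loc[profile.columns].to_numpy()
    if not np.isin(sign, (1.0, -1.0)).all():
        raise ValidationError("gene directions must be +1 or -1")
    oriented = profile.to_numpy() * sign[None, :]
    q25 = np.quantile(oriented, 0.25, axis=0)
    q75 = np.quantile(oriented, 0.75, axis=0)
    scores = 2 + (oriented > q75[None, :]).astype(int) - (
        oriented < q25[None, :]
    ).astype(int)
    return pd.DataFrame(scores, index=profile.index, columns=profile.columns)


def compute_dpes(dges: pd.DataFrame, sets: GeneSetCollection) -> pd.DataFrame:
    """Subjects x pathways sum of member-gene scores.

    Pathway members are intersected with the scored genes; pathways
    left with no scored member are dropped with a warning.
    """
    scored = set(dges.columns)
    cols = {}
    for name in sets.names:
        members = [g for g in sets[name] if g in scored]
        if not members:
            warnings.warn(
                f"pathway {name!r} has no scored member genes; dropped",
                stacklevel=2,
            )
            continue
        cols[name] = dges[members].sum(axis=1)
    return pd.DataFrame(cols, index=dges.index)


def tertile_assign(values: pd.Series) -> pd.Series:
    """Cohort tertile (1/2/3) of one pathway's DPES values.

    Cut points are the 33.3rd and 66.7th percentiles; a value equal to
    a cut point stays in the lower tertile. If all values coincide the
    assignment is degenerate (everyone in tertile 1) and a warning is
    issued.
    """
    if len(values) < 3:
        raise ValidationError("need at least 3 subjects for tertiles")
    v = np.asarray(values, dtype=float)
    if np.all(v == v[0]):
        warnings.warn("all scores identical; degenerate single tertile",
                      stacklevel=2)
        return pd.Series(1, index=values.index, dtype=int)
    c1, c2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0])
    labels = 1 + (v > c1).astype(int) + (v > c2).astype(int)
    return pd.Series(labels, index=values.index, dtype=int)


def tertile_table(dpes: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway tertile labels for every subject."""
    return pd.DataFrame(
        {name: tertile_assign(dpes[name]) for name in dpes.columns},
        index=dpes.index,
    )
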