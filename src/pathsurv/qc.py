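"""Feature filtering, subject QC, and the matched discovery-group split.

The discovery design: subjects who died of colorectal cancer are split
at random into two balanced groups (A and B); each deceased subject is
matched, where possible, to a distinct living subject of the same age
category and sex, who inherits the group label. Differential expression
is then called independently in A and B and only concordant genes are
kept, while survival and stage analyses use the whole cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import PairedCountMatrix, ValidationError

log = logging.getLogger(__name__)

FEATURE_FLAGS = ("is_coding", "has_known_function", "is_expressed")


def filter_features(features: pd.DataFrame) -> list[str]:
    """Retain features that are coding, of known function, and expressed.

    Order-preserving; raises on duplicate feature ids or missing flags.
    """
    if "feature_id" not in features.columns:
        raise ValidationError("feature manifest requires a feature_id column")
    ids = features["feature_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique()[:5])
        raise ValidationError(f"duplicate feature ids, e.g. {dupes}")
    for flag in FEATURE_FLAGS:
        if flag not in features.columns:
            raise ValidationError(f"feature manifest missing flag {flag!r}")
        if features[flag].isna().any():
            raise ValidationError(f"missing values in feature flag {flag!r}")
    mask = np.logical_and.reduce([features[f].astype(bool) for f in FEATURE_FLAGS])
    retained = list(ids[mask])
    log.info("feature filter: %d in, %d retained, %d excluded",
             len(features), len(retained), len(features) - len(retained))
    return retained


def qc_subjects(qc: pd.DataFrame) -> list[str]:
    """Retain subjects whose tumor AND normal libraries both passed QC."""
    for col in ("subject_id", "tumor_pass", "normal_pass"):
        if col not in qc.columns:
            raise ValidationError(f"subject QC table missing column {col!r}")
        if col != "subject_id" and qc[col].isna().any():
            raise ValidationError(f"missing values in QC flag {col!r}")
    if qc["subject_id"].duplicated().any():
        raise ValidationError("duplicate subject ids in QC table")
    mask = qc["tumor_pass"].astype(bool) & qc["normal_pass"].astype(bool)
    retained = list(qc.loc[mask, "subject_id"])
    log.info("subject QC: %d in, %d retained", len(qc), len(retained))
    return retained


def compute_expressed_flag(
    counts: PairedCountMatrix, cpm_threshold: float = 1.0, min_frac: float = 0.1
) -> pd.Series:
    """Expression flag when the manifest lacks one: mean-normalized count
    >= *cpm_threshold* (counts per million) in >= *min_frac* of samples."""
    cpm = counts.cpm()
    frac = (cpm >= cpm_threshold).mean(axis=1)
    return frac >= min_frac


def age_category(age, width: float = 5.0, low: float = 30.0, high: float = 80.0):
    """Epidemiologic age bins: <low, [low, low+width), ..., >=high."""
    age = np.asarray(age, dtype=float)
    edges = np.arange(low, high + width, width)
    idx = np.digitize(age, edges)  # 0 => < low, len(edges) => >= high
    labels = (
        [f"<{low:g}"]
        + [f"[{a:g},{a + width:g})" for a in edges[:-1]]
        + [f">={high:g}"]
    )
    return np.asarray(labels, dtype=object)[idx]


def split_discovery_groups(
    subjects: pd.DataFrame,
    age_bin_width: float = 5.0,
    seed: int = 0,
    deceased_statuses: tuple[str, ...] = ("crc_death",),
) -> pd.DataFrame:
    """Randomly split deceased subjects into balanced groups A and B and
    match living subjects to them on age category and sex.

    Parameters
    ----------
    subjects
        Clinical table indexed by subject_id with ``vital_status``,
        ``age`` and ``sex`` columns.
    deceased_statuses
        Statuses counted as deceased for the split (default: CRC death
        only; other-cause deaths stay on the "alive" side).

    Returns
    -------
    DataFrame with columns subject_id, group (A/B/unassigned),
    matched_to (deceased subject id or empty), age_category, sex.

    Notes
    -----
    Death counts in A and B differ by at most one. Matching is random
    without replacement within exact (age category, sex) strata, so no
    living subject is matched twice; strata with fewer living than
    deceased subjects log the shortfall. Unmatched living subjects are
    left unassigned — they still enter the full-cohort survival and
    stage analyses.
    """
    for col in ("vital_status", "age", "sex"):
        if col not in subjects.columns:
            raise ValidationError(f"clinical table missing column {col!r}")
    rng = np.random.default_rng([int(seed), 31])
    out = pd.DataFrame(
        {
            "subject_id": subjects.index,
            "group": "unassigned",
            "matched_to": "",
            "age_category": age_category(subjects["age"], width=age_bin_width),
            "sex": list(subjects["sex"]),
        }
    ).set_index("subject_id")

    deceased = subjects.index[subjects["vital_status"].isin(deceased_statuses)]
    if len(deceased) == 0:
        raise ValidationError("no deceased subjects; discovery split undefined")
    order = rng.permutation(np.asarray(deceased))
    groups = np.where(np.arange(len(order)) % 2 == 0, "A", "B")
    out.loc[order, "group"] = groups

    alive = subjects.index[~subjects["vital_status"].isin(deceased_statuses)]
    alive_by_stratum: dict[tuple, list] = {}
    for s in alive:
        key = (out.at[s, "age_category"], out.at[s, "sex"])
        alive_by_stratum.setdefault(key, []).append(s)
    for key in alive_by_stratum:
        alive_by_stratum[key] = list(rng.permutation(np.asarray(
            alive_by_stratum[key], dtype=object)))

    n_unmatched = 0
    for d in order:
        key = (out.at[d, "age_category"], out.at[d, "sex"])
        pool = alive_by_stratum.get(key, [])
        if pool:
            partner = pool.pop()
            out.at[partner, "group"] = out.at[d, "group"]
            out.at[partner, "matched_to"] = d
        else:
            n_unmatched += 1
    if n_unmatched:
        log.warning(
            "discovery split: %d deceased subjects had no same-stratum "
            "living match", n_unmatched,
        )
    return out.reset_index()


def describe_cohort(clinical: pd.DataFrame) -> dict[str, float]:
    """Descriptive percentages for the study-population table.

    Categorical percentages use the non-missing denominator for that
    variable (e.g. tumor site), as descriptive tables conventionally do.
    """
    out: dict[str, float] = {"n": float(len(clinical))}
    if "sex" in clinical:
        out["pct_male"] = 100.0 * (clinical["sex"] == "M").mean()
    if "site" in clinical:
        site = clinical["site"].dropna()
        out["pct_proximal"] = 100.0 * (site == "proximal").mean()
        out["pct_distal"] = 100.0 * (site == "distal").mean()
    for col in ("tp53", "kras", "msi", "cimp"):
        if col in clinical:
            out[f"pct_{col}"] = 100.0 * clinical[col].astype(float).mean()
    if "vital_status" in clinical:
        for status in ("alive", "crc_death", "other_death", "unknown"):
            out[f"pct_{status}"] = 100.0 * (
                clinical["vital_status"] == status
            ).mean()
    if "ajcc_stage" in clinical:
        stage = clinical["ajcc_stage"].dropna()
        for s in (1, 2, 3, 4):
            out[f"pct_stage{s}"] = 100.0 * (stage == s).mean()
    if "age" in clinical:
        out["mean_age"] = float(clinical["age"].mean())
        out["sd_age"] = float(clinical["age"].std())
    return out
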