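"""Core data containers shared across the pipeline.

The central object is :class:`PairedCountMatrix`: an integer read-count
matrix (features x samples) together with a sample sheet that pairs each
subject's tumor and adjacent-normal library. Everything downstream — the
paired differential-expression test, per-subject delta profiles and the
pathway de-regulation scores — is defined on this pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"

SAMPLE_SHEET_COLUMNS = ("sample_id", "subject_id", "tissue")


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class PairedCountMatrix:
    """Integer read counts (features x samples) with tumor/normal pairing.

    Parameters
    ----------
    counts
        DataFrame indexed by feature id, one column per sample id,
        non-negative integer values.
    samples
        Sample sheet with columns ``sample_id``, ``subject_id``,
        ``tissue`` (``tumor`` or ``normal``); exactly one tumor and one
        normal library per subject.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        sheet_ids = list(self.samples["sample_id"])
        if len(set(sheet_ids)) != len(sheet_ids):
            raise ValidationError("duplicate sample_id in sample sheet")
        if set(sheet_ids) != set(self.counts.columns):
            raise ValidationError("sample sheet and count columns disagree")
        bad_tissue = set(self.samples["tissue"]) - {TUMOR, NORMAL}
        if bad_tissue:
            raise ValidationError(f"unknown tissue labels: {sorted(bad_tissue)}")
        per_subject = self.samples.groupby("subject_id")["tissue"].apply(
            lambda t: sorted(t)
        )
        for subject, tissues in per_subject.items():
            if tissues != [NORMAL, TUMOR]:
                raise ValidationError(
                    f"subject {subject} must have exactly one tumor and one "
                    f"normal library, got {tissues}"
                )
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate feature ids in count matrix")
        if (np.asarray(self.counts.values) < 0).any():
            raise ValidationError("negative counts")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def subjects(self) -> list[str]:
        """Subject ids in sample-sheet order (first appearance)."""
        return list(dict.fromkeys(self.samples["subject_id"]))

    @property
    def n_pairs(self) -> int:
        return len(self.subjects)

    def depths(self) -> pd.Series:
        """Total read count (library size) per sample."""
        return self.counts.sum(axis=0)

    def sample_columns(self, tissue: str) -> list[str]:
        """Sample ids of one tissue, in subject order."""
        if tissue not in (TUMOR, NORMAL):
            raise ValidationError(f"tissue must be tumor/normal, got {tissue!r}")
        sheet = self.samples[self.samples["tissue"] == tissue]
        lookup = dict(zip(sheet["subject_id"], sheet["sample_id"]))
        return [lookup[s] for s in self.subjects]

    def _sample_for(self, subject: str, tissue: str) -> str:
        sheet = self.samples
        row = sheet[(sheet["subject_id"] == subject) & (sheet["tissue"] == tissue)]
        return row["sample_id"].iloc[0]

    def matrix(self, tissue: str) -> pd.DataFrame:
        """Counts for one tissue, columns relabelled to subject ids."""
        out = self.counts[self.sample_columns(tissue)].copy()
        out.columns = self.subjects
        return out

    def subset_subjects(self, subject_ids) -> "PairedCountMatrix":
        keep = [s for s in self.subjects if s in set(subject_ids)]
        sheet = self.samples[self.samples["subject_id"].isin(keep)].reset_index(
            drop=True
        )
        return PairedCountMatrix(self.counts[list(sheet["sample_id"])], sheet)

    def subset_features(self, feature_ids) -> "PairedCountMatrix":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return PairedCountMatrix(self.counts.loc[keep], self.samples.copy())

    def cpm(self, pseudo_depth: bool = False) -> pd.DataFrame:
        """Counts per million, per sample."""
        d = self.depths().astype(float)
        if (d <= 0).any():
            raise ValidationError("zero-depth library; cannot normalize")
        return self.counts.div(d, axis=1) * 1e6
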