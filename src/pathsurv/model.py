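"""Model/Results facade over the whole analysis.

:class:`PathwayDeregulationModel` holds the data of one paired
tumor/normal cohort (counts, clinical table, gene sets, optional
feature manifest); :meth:`~PathwayDeregulationModel.fit` runs the full
chain — feature filter, subject QC, matched discovery split, paired
permutation DE in both groups, concordant selection, pathway
overrepresentation, per-subject DGES/DPES scoring, tertile Cox models
and stage summaries — and returns a
:class:`PathwayDeregulationResults` carrying every intermediate and
final table, with a compact ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import de, enrichment, qc, scoring, survival
from .datatypes import PairedCountMatrix, ValidationError
from .genesets import GeneSetCollection

log = logging.getLogger(__name__)


def derive_seed(seed: int, stream: int) -> int:
    """Deterministic 31-bit substream seed for a pipeline stage."""
    return int(
        np.random.SeedSequence([int(seed), int(stream)]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class AnalysisParams:
    """Tunable analysis parameters with their conventional defaults."""

    n_resamples: int = 20
    n_perm: int = 1000
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    pseudocount: float = 0.5
    bh_alpha: float = 0.05
    age_bin_width: float = 5.0

    def __post_init__(self) -> None:
        if self.n_resamples < 1 or self.n_perm < 1:
            raise ValidationError("n_resamples and n_perm must be >= 1")
        if not 0 < self.p_threshold <= 1 or not 0 < self.bh_alpha <= 1:
            raise ValidationError("p_threshold and bh_alpha must be in (0, 1]")
        if self.fc_threshold <= 0:
            raise ValidationError("fc_threshold must be positive")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if self.age_bin_width <= 0:
            raise ValidationError("age_bin_width must be positive")


@dataclass
class PathwayDeregulationResults:
    """Fitted results; see the attribute tables.

    Attributes
    ----------
    de_a, de_b
        Per-feature DE tables for discovery groups A and B.
    up, down
        Concordantly selected up-/down-regulated gene lists.
    enrichment
        Overrepresentation table over the supplied gene sets.
    dges, dpes, tertiles
        Subjects x genes scores, subjects x pathways sums, and the
        per-pathway tertile labels (enriched pathways only).
    hazards, stages
        Tertile Cox hazard-ratio table and the per-stage score table.
    """

    params: AnalysisParams
    seed: int
    retained_features: list[str]
    retained_subjects: list[str]
    split: pd.DataFrame
    de_a: pd.DataFrame
    de_b: pd.DataFrame
    up: list[str]
    down: list[str]
    enrichment: pd.DataFrame
    dges: pd.DataFrame
    dpes: pd.DataFrame
    tertiles: pd.DataFrame
    hazards: pd.DataFrame
    stages: pd.DataFrame
    warnings_: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return list(self.up) + list(self.down)

    @property
    def enriched_pathways(self) -> list[str]:
        if len(self.enrichment) == 0:
            return []
        return list(self.enrichment.loc[self.enrichment["significant"],
                                        "set_name"])

    def summary(self) -> str:
        lines = [
            "Pathway de-regulation survival analysis",
            "=" * 46,
            f"subjects analyzed        {len(self.retained_subjects)}",
            f"features analyzed        {len(self.retained_features)}",
            (
                "discovery groups         "
                f"A n={int((self.split['group'] == 'A').sum())}, "
                f"B n={int((self.split['group'] == 'B').sum())}"
            ),
            f"DE genes (both groups)   {len(self.up)} up, {len(self.down)} down",
            f"enriched pathways        {len(self.enriched_pathways)} "
            f"(BH < {self.params.bh_alpha:g})",
            "",
        ]
        if len(self.hazards):
            lines.append("tertile hazard ratios (CRC death; T1 referent)")
            lines.append("-" * 46)
            for _, r in self.hazards.iterrows():
                if np.isnan(r["hr_t2"]):
                    lines.append(f"{r['pathway']:<24} not estimable")
                    continue
                lines.append(
                    f"{r['pathway']:<24} "
                    f"T2 {r['hr_t2']:.2f} ({r['ci_t2_low']:.2f}, "
                    f"{r['ci_t2_high']:.2f})  "
                    f"T3 {r['hr_t3']:.2f} ({r['ci_t3_low']:.2f}, "
                    f"{r['ci_t3_high']:.2f})"
                )
        return "\n".join(lines)


class PathwayDeregulationModel:
    """The full cohort analysis as a single fit-able model.

    Parameters
    ----------
    counts
        Paired tumor/normal count matrix.
    clinical
        Clinical table indexed by subject id (vital status, follow-up
        months, age, sex, AJCC stage, TP53/KRAS/MSI/CIMP, and optional
        tumor_pass/normal_pass QC flags).
    gene_sets
        Pathway collection (GMT semantics).
    features
        Optional feature manifest with coding/known-function/expressed
        flags; when omitted all features are analyzable.
    """

    def __init__(
        self,
        counts: PairedCountMatrix,
        clinical: pd.DataFrame,
        gene_sets: GeneSetCollection,
        features: pd.DataFrame | None = None,
        params: AnalysisParams | None = None,
    ) -> None:
        self.counts = counts
        self.clinical = clinical
        self.gene_sets = gene_sets
        self.features = features
        self.params = params or AnalysisParams()
        missing = [s for s in counts.subjects if s not in clinical.index]
        if missing:
            raise ValidationError(
                f"subjects missing from clinical table: {missing[:10]}"
            )

    @classmethod
    def from_cohort(cls, cohort, params: AnalysisParams | None = None):
        """Build from a :class:`~pathsurv.simulate.Cohort`."""
        return cls(
            cohort.counts,
            cohort.clinical,
            cohort.gene_sets,
            features=cohort.features,
            params=params,
        )

    def fit(self, seed: int = 0) -> PathwayDeregulationResults:
        """Run the complete analysis; deterministic given *seed*."""
        p = self.params
        notes: list[str] = []

        # 1. feature filter
        if self.features is not None:
            retained_features = qc.filter_features(self.features)
        else:
            retained_features = list(self.counts.feature_ids)
        counts = self.counts.subset_features(retained_features)
        retained_features = counts.feature_ids

        # 2. subject QC
        if {"tumor_pass", "normal_pass"} <= set(self.clinical.columns):
            qc_table = self.clinical.reset_index()[
                ["subject_id", "tumor_pass", "normal_pass"]
            ]
            retained_subjects = qc.qc_subjects(qc_table)
        else:
            retained_subjects = list(self.counts.subjects)
        counts = counts.subset_subjects(retained_subjects)
        retained_subjects = counts.subjects
        clinical = self.clinical.loc[retained_subjects]

        # 3. matched discovery split
        split = qc.split_discovery_groups(
            clinical, age_bin_width=p.age_bin_width,
            seed=derive_seed(seed, 1),
        )

        # 4. paired DE per group
        results = {}
        for i, group in enumerate(("A", "B")):
            ids = list(split.loc[split["group"] == group, "subject_id"])
            if len(ids) < 2:
                raise ValidationError(f"discovery group {group} has <2 pairs")
            scheme = de.ResamplingScheme(
                n_resamples=p.n_resamples, seed=derive_seed(seed, 10 + i)
            )
            results[group] = de.paired_de_test(
                counts.subset_subjects(ids), scheme=scheme,
                n_perm=p.n_perm, pseudocount=p.pseudocount,
            )

        # 5. concordant selection
        rule = de.SelectionRule(
            p_threshold=p.p_threshold, fc_threshold=p.fc_threshold
        )
        up, down = de.select_de_features(results["A"], results["B"], rule)

        # 6. overrepresentation over the analyzable universe
        enr = enrichment.hypergeometric_enrichment(
            up + down, retained_features, self.gene_sets,
            up=up, down=down, alpha=p.bh_alpha,
        )
        enriched = (
            list(enr.loc[enr["significant"], "set_name"]) if len(enr) else []
        )

        # 7-8. per-subject scoring of the selected genes
        empty_subj = pd.DataFrame(index=pd.Index(retained_subjects,
                                                 name="subject_id"))
        if up or down:
            direction = pd.Series(
                {**{g: 1 for g in up}, **{g: -1 for g in down}}
            )
            delta = scoring.compute_delta_profile(
                counts, features=up + down, pseudocount=p.pseudocount
            )
            dges = scoring.assign_dges(delta, direction)
        else:
            notes.append("no genes selected; scores are empty")
            dges = empty_subj.copy()
        if enriched and len(dges.columns):
            sets_enriched = GeneSetCollection(
                {n: self.gene_sets[n] for n in enriched},
                {n: self.gene_sets.descriptions.get(n, "") for n in enriched},
            ).restrict_to(set(dges.columns))
            dpes = scoring.compute_dpes(dges, sets_enriched)
        else:
            if not enriched:
                notes.append("no enriched pathways; survival tables are empty")
            dpes = empty_subj.copy()
        tertiles = (
            scoring.tertile_table(dpes) if len(dpes.columns) else empty_subj.copy()
        )

        # 9. outcome models
        if len(tertiles.columns):
            hazards = survival.hazard_table(tertiles, clinical)
            stages = survival.stage_table(dpes, clinical)
        else:
            hazards = pd.DataFrame(
                columns=["pathway", "hr_t2", "ci_t2_low", "ci_t2_high",
                         "hr_t3", "ci_t3_low", "ci_t3_high", "n", "n_events",
                         "note"]
            )
            stages = pd.DataFrame(columns=["pathway", "p_1v4"])

        return PathwayDeregulationResults(
            params=p,
            seed=seed,
            retained_features=retained_features,
            retained_subjects=retained_subjects,
            split=split,
            de_a=results["A"],
            de_b=results["B"],
            up=up,
            down=down,
            enrichment=enr,
            dges=dges,
            dpes=dpes,
            tertiles=tertiles,
            hazards=hazards,
            stages=stages,
            warnings_=notes,
        )
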