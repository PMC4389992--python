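"""Synthetic paired tumor/normal cohorts with known ground truth.

The generator emulates the structure of a population-based colon-cancer
RNA-seq cohort: per-subject paired tumor and adjacent-normal libraries
with negative-binomial counts and per-library depth variation, a
configurable fraction of >=2-fold differentially expressed (DE) genes,
pathway memberships (some "survival-linked", preferentially populated
with DE genes), clinical covariates (age, sex, AJCC stage, TP53/KRAS
mutation, MSI, CIMP), and survival outcomes from an exponential
proportional-hazards model whose log-hazard depends on the subject's
true pathway de-regulation tertile. Vital status is a four-way mixture:
alive, colorectal-cancer death, other-cause death, unknown.

Subject-level signal: for DE genes that belong to a survival-linked
pathway, each subject's tumor/normal fold change is modulated by an
exponent that depends on the subject's true tertile (default exponents
(0.6, 1.0, 1.4) for tertiles 1..3), then rescaled so the cohort-level
arithmetic-mean fold change equals the drawn gene-level fold change.
This is what makes the true tertile recoverable from expression and
gives the downstream score-and-survive pipeline a signal to find; genes
outside survival-linked pathways carry a homogeneous fold change, so
background pathways stay null with respect to survival.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import PairedCountMatrix, TUMOR, NORMAL
from .genesets import GeneSetCollection

log = logging.getLogger(__name__)

# rng stream ids: one independent substream per generation stage
_STREAM_COUNTS = 11
_STREAM_CLINICAL = 12
_STREAM_GENESETS = 13


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters.

    Defaults mirror the study population the generator emulates:
    175 subjects; ~10% DE genes with fold changes in (2, 6); 62% of DE
    genes up-regulated; stage distribution, covariate prevalences, age
    65.2 +/- 10.2 y, and the alive / CRC-death / other-death / unknown
    vital-status mixture of the descriptive cohort table; hazard ratios
    of roughly exp(-0.9) and exp(-1.1) for de-regulation tertiles 2 and
    3 versus tertile 1.
    """

    n_subjects: int = 175
    n_genes: int = 2000
    n_pathways: int = 20
    genes_per_pathway: int = 15
    n_linked_pathways: int = 2
    n_null_de_pathways: int = 0
    linked_de_weight: float = 0.9
    frac_de: float = 0.1
    frac_up: float = 0.62
    fc_range: tuple[float, float] = (2.0, 6.0)
    dispersion: float = 0.3
    depth_range: tuple[float, float] = (500_000.0, 2_000_000.0)
    mean_log_expression: float = 3.0
    sd_log_expression: float = 1.5
    tertile_lfc_scale: tuple[float, float, float] = (0.6, 1.0, 1.4)
    tertile_log_hr: tuple[float, float] = (-0.9, -1.1)
    baseline_hazard: float = 0.004
    frac_other_death: float = 0.30
    frac_unknown: float = 0.086
    censor_months: float = 120.0
    stage_probs: tuple[float, float, float, float] = (0.23, 0.32, 0.33, 0.12)
    covariate_prevalences: dict = field(
        default_factory=lambda: {
            "tp53": 0.44,
            "kras": 0.274,
            "msi": 0.183,
            "cimp": 0.257,
            "male": 0.537,
            "proximal": 0.479,
        }
    )
    age_mean_sd: tuple[float, float] = (65.2, 10.2)
    allow_pathway_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_up", "linked_de_weight", "frac_other_death",
                     "frac_unknown"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must be in [0, 1]")
        for name, v in self.covariate_prevalences.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"prevalence {name}={v} must be in [0, 1]")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ConfigurationError("stage_probs must sum to 1")
        if len(self.stage_probs) != 4 or any(p < 0 for p in self.stage_probs):
            raise ConfigurationError("stage_probs must be 4 non-negative values")
        if self.fc_range[0] <= 1.0 or self.fc_range[1] < self.fc_range[0]:
            raise ConfigurationError("fc_range lower bound must exceed 1")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ConfigurationError("depth_range must be positive and ordered")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.censor_months <= 0:
            raise ConfigurationError("censor_months must be > 0")
        if self.genes_per_pathway > self.n_genes:
            raise ConfigurationError("genes_per_pathway exceeds n_genes")
        if (not self.allow_pathway_overlap
                and self.n_pathways * self.genes_per_pathway > self.n_genes):
            raise ConfigurationError(
                "n_pathways * genes_per_pathway exceeds n_genes; "
                "set allow_pathway_overlap=True to permit shared genes"
            )
        if self.n_linked_pathways + self.n_null_de_pathways > self.n_pathways:
            raise ConfigurationError(
                "n_linked_pathways + n_null_de_pathways exceeds n_pathways"
            )

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_genes))


@dataclass
class TruthRecord:
    """Ground truth used by tests and by the survival generator.

    genes
        index gene_id; is_de (bool), direction (+1/-1, 0 for non-DE),
        fold_change (1.0 for non-DE).
    pathways
        index pathway name; is_survival_linked (bool).
    subjects
        index subject_id; true_tertile in {1, 2, 3} — the tertile used
        in hazard generation.
    linked_members
        member gene ids of each survival-linked pathway.
    null_de_members
        member gene ids of DE-enriched pathways that carry no survival
        link (matched null comparators for the end-to-end analysis).
    """

    genes: pd.DataFrame
    pathways: pd.DataFrame
    subjects: pd.DataFrame
    linked_members: dict[str, list[str]]
    null_de_members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        de = self.genes["is_de"]
        if (self.genes.loc[~de, "direction"] != 0).any():
            raise ValueError("direction defined only for DE genes")

    @property
    def n_de(self) -> int:
        return int(self.genes["is_de"].sum())

    def to_json(self, path) -> None:
        payload = {
            "genes": {
                "gene_id": list(self.genes.index),
                "is_de": [bool(v) for v in self.genes["is_de"]],
                "direction": [int(v) for v in self.genes["direction"]],
                "fold_change": [float(v) for v in self.genes["fold_change"]],
            },
            "pathways": {
                "pathway": list(self.pathways.index),
                "is_survival_linked": [
                    bool(v) for v in self.pathways["is_survival_linked"]
                ],
            },
            "subjects": {
                "subject_id": list(self.subjects.index),
                "true_tertile": [int(v) for v in self.subjects["true_tertile"]],
            },
            "linked_members": self.linked_members,
            "null_de_members": self.null_de_members,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        genes = pd.DataFrame(
            {
                "is_de": payload["genes"]["is_de"],
                "direction": payload["genes"]["direction"],
                "fold_change": payload["genes"]["fold_change"],
            },
            index=pd.Index(payload["genes"]["gene_id"], name="gene_id"),
        )
        pathways = pd.DataFrame(
            {"is_survival_linked": payload["pathways"]["is_survival_linked"]},
            index=pd.Index(payload["pathways"]["pathway"], name="pathway"),
        )
        subjects = pd.DataFrame(
            {"true_tertile": payload["subjects"]["true_tertile"]},
            index=pd.Index(payload["subjects"]["subject_id"], name="subject_id"),
        )
        return cls(
            genes, pathways, subjects,
            dict(payload["linked_members"]),
            dict(payload.get("null_de_members", {})),
        )


def _balanced_tertiles(n: int, rng: np.random.Generator) -> np.ndarray:
    base = np.tile([1, 2, 3], n // 3 + 1)[:n]
    return rng.permutation(base)


def generate_paired_counts(
    config: SimulationConfig,
) -> tuple[PairedCountMatrix, pd.DataFrame, TruthRecord]:
    """Draw one tumor and one normal library per subject.

    Normal means come from a log-normal relative-expression profile
    scaled by each library's depth (uniform in ``depth_range``); tumor
    means multiply the normal means by the gene's true fold change
    (direction-signed), with subject-tertile modulation for DE genes in
    survival-linked pathways (see module docstring). Counts are
    negative binomial with variance ``mu + dispersion * mu**2``.
    """
    rng = _rng(config.seed, _STREAM_COUNTS)
    n_g, n_s = config.n_genes, config.n_subjects
    gene_ids = [f"G{i:05d}" for i in range(n_g)]
    subject_ids = [f"S{i:04d}" for i in range(n_s)]
    pathway_ids = [f"PWY{i:03d}" for i in range(config.n_pathways)]

    # gene-level truth
    is_de = np.zeros(n_g, dtype=bool)
    de_idx = rng.choice(n_g, size=config.n_de, replace=False)
    is_de[de_idx] = True
    direction = np.zeros(n_g, dtype=int)
    direction[de_idx] = np.where(
        rng.random(config.n_de) < config.frac_up, 1, -1
    )
    fold_change = np.ones(n_g)
    fold_change[de_idx] = rng.uniform(*config.fc_range, size=config.n_de)

    # survival-linked pathway memberships, preferentially DE genes
    linked = pathway_ids[: config.n_linked_pathways]
    de_pool = list(rng.permutation(np.asarray(gene_ids)[de_idx]))
    nonde_pool = list(rng.permutation(np.asarray(gene_ids)[~is_de]))
    n_de_per_set = int(round(config.linked_de_weight * config.genes_per_pathway))

    def _preset(names: list[str]) -> dict[str, list[str]]:
        members = {}
        for name in names:
            take_de = [de_pool.pop() for _ in range(min(n_de_per_set, len(de_pool)))]
            need = config.genes_per_pathway - len(take_de)
            take_bg = [nonde_pool.pop() for _ in range(need)]
            members[name] = sorted(take_de + take_bg)
        return members

    linked_members = _preset(linked)
    null_de = pathway_ids[
        config.n_linked_pathways:
        config.n_linked_pathways + config.n_null_de_pathways
    ]
    null_de_members = _preset(null_de)

    # per-subject truth
    tertiles = _balanced_tertiles(n_s, rng)

    # expression model
    rel = rng.lognormal(config.mean_log_expression, config.sd_log_expression, n_g)
    props = rel / rel.sum()
    depth_t = rng.uniform(*config.depth_range, size=n_s)
    depth_n = rng.uniform(*config.depth_range, size=n_s)

    fc_signed = fold_change ** direction  # 1.0 for non-DE genes
    fold_matrix = np.repeat(fc_signed[:, None], n_s, axis=1)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    linked_gene_idx = sorted(
        {gene_pos[g] for members in linked_members.values() for g in members
         if is_de[gene_pos[g]]}
    )
    if linked_gene_idx:
        scale = np.asarray(config.tertile_lfc_scale)[tertiles - 1]  # per subject
        sub = fold_change[linked_gene_idx][:, None] ** (
            direction[linked_gene_idx][:, None] * scale[None, :]
        )
        # rescale so the cohort-mean fold factor equals the drawn one
        sub *= (fc_signed[linked_gene_idx][:, None] / sub.mean(axis=1, keepdims=True))
        fold_matrix[linked_gene_idx, :] = sub

    mu_normal = props[:, None] * depth_n[None, :]
    mu_tumor = props[:, None] * fold_matrix * depth_t[None, :]

    size = 1.0 / config.dispersion  # NB shape: var = mu + dispersion * mu^2
    counts_n = rng.negative_binomial(size, size / (size + mu_normal))
    counts_t = rng.negative_binomial(size, size / (size + mu_tumor))

    sample_ids = [f"{s}_T" for s in subject_ids] + [f"{s}_N" for s in subject_ids]
    counts = pd.DataFrame(
        np.hstack([counts_t, counts_n]),
        index=pd.Index(gene_ids, name="feature_id"),
        columns=sample_ids,
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": subject_ids + subject_ids,
            "tissue": [TUMOR] * n_s + [NORMAL] * n_s,
        }
    )
    truth = TruthRecord(
        genes=pd.DataFrame(
            {"is_de": is_de, "direction": direction, "fold_change": fold_change},
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        pathways=pd.DataFrame(
            {"is_survival_linked": [p in linked for p in pathway_ids]},
            index=pd.Index(pathway_ids, name="pathway"),
        ),
        subjects=pd.DataFrame(
            {"true_tertile": tertiles},
            index=pd.Index(subject_ids, name="subject_id"),
        ),
        linked_members=linked_members,
        null_de_members=null_de_members,
    )
    return PairedCountMatrix(counts, samples), samples, truth


def generate_clinical_survival(
    config: SimulationConfig, truth: TruthRecord
) -> pd.DataFrame:
    """Draw covariates and survival outcomes from the true tertiles.

    Hazard for subject i is ``baseline_hazard * exp(log_hr[tertile_i])``
    with log_hr = (0, *tertile_log_hr); survival is exponential, with
    administrative censoring at ``censor_months``. Deaths are labelled
    other-cause with probability ``frac_other_death``; a fraction
    ``frac_unknown`` of subjects instead has unknown vital status,
    censored at a uniformly drawn last-contact month.
    """
    if config.baseline_hazard <= 0:
        raise ConfigurationError("baseline_hazard must be > 0")
    rng = _rng(config.seed, _STREAM_CLINICAL)
    subjects = truth.subjects.index
    n = len(subjects)
    tert = truth.subjects["true_tertile"].to_numpy()

    mean_age, sd_age = config.age_mean_sd
    age = np.clip(rng.normal(mean_age, sd_age, n), 30.0, 99.0).round(1)
    prev = config.covariate_prevalences
    sex = np.where(rng.random(n) < prev["male"], "M", "F")
    site = np.where(rng.random(n) < prev.get("proximal", 0.5), "proximal", "distal")
    stage = rng.choice([1, 2, 3, 4], size=n, p=np.asarray(config.stage_probs))
    binaries = {
        k: (rng.random(n) < prev[k]).astype(int) for k in ("tp53", "kras", "msi", "cimp")
    }

    log_hr = np.array([0.0, *config.tertile_log_hr])
    hazard = config.baseline_hazard * np.exp(log_hr[tert - 1])
    death_time = rng.exponential(1.0 / hazard)
    is_other = rng.random(n) < config.frac_other_death
    is_unknown = rng.random(n) < config.frac_unknown
    last_contact = rng.uniform(1.0, config.censor_months, n)

    status = np.empty(n, dtype=object)
    time = np.empty(n)
    for i in range(n):
        if is_unknown[i]:
            status[i] = "unknown"
            time[i] = last_contact[i]
        elif death_time[i] <= config.censor_months:
            status[i] = "other_death" if is_other[i] else "crc_death"
            time[i] = death_time[i]
        else:
            status[i] = "alive"
            time[i] = config.censor_months

    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "site": site,
            "ajcc_stage": stage,
            **binaries,
            "vital_status": status,
            "followup_months": np.round(time, 3),
            "tumor_pass": True,
            "normal_pass": True,
        },
        index=pd.Index(subjects, name="subject_id"),
    )


def generate_gene_sets(
    config: SimulationConfig, truth: TruthRecord
) -> GeneSetCollection:
    """Assemble the pathway collection declared in the truth record.

    Survival-linked pathways reuse the memberships fixed at count
    generation (preferentially DE genes); background pathways draw
    uniformly from the remaining genes (or from all genes when
    ``allow_pathway_overlap``).
    """
    if config.genes_per_pathway > config.n_genes:
        raise ConfigurationError("genes_per_pathway exceeds n_genes")
    rng = _rng(config.seed, _STREAM_GENESETS)
    gene_ids = list(truth.genes.index)
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    used = set()
    for name, members in truth.linked_members.items():
        sets[name] = list(members)
        desc[name] = "synthetic survival-linked pathway"
        used.update(members)
    for name, members in truth.null_de_members.items():
        sets[name] = list(members)
        desc[name] = "synthetic DE-enriched null pathway"
        used.update(members)
    for name in truth.pathways.index:
        if name in sets:
            continue
        pool = gene_ids if config.allow_pathway_overlap else [
            g for g in gene_ids if g not in used
        ]
        if len(pool) < config.genes_per_pathway:
            raise ConfigurationError(
                "not enough unused genes for disjoint pathways"
            )
        members = sorted(
            rng.choice(np.asarray(pool), config.genes_per_pathway, replace=False)
        )
        sets[name] = members
        desc[name] = "synthetic background pathway"
        used.update(members)
    return GeneSetCollection(sets, desc)


@dataclass
class Cohort:
    """A fully generated synthetic study: everything the pipeline reads."""

    config: SimulationConfig
    counts: PairedCountMatrix
    clinical: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: TruthRecord
    features: pd.DataFrame

    @property
    def sample_sheet(self) -> pd.DataFrame:
        return self.counts.samples


def simulate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Generate a complete cohort (counts, clinical, gene sets, truth)."""
    config = config or SimulationConfig()
    pcm, _, truth = generate_paired_counts(config)
    clinical = generate_clinical_survival(config, truth)
    gene_sets = generate_gene_sets(config, truth)
    features = pd.DataFrame(
        {
            "feature_id": pcm.feature_ids,
            "gene_id": pcm.feature_ids,
            "is_coding": True,
            "has_known_function": True,
            "is_expressed": True,
        }
    )
    return Cohort(config, pcm, clinical, gene_sets, truth, features)


def write_fixture_bundle(cohort: Cohort, path) -> dict[str, Path]:
    """Write the cohort as plain-text fixtures; see :func:`read_fixture_bundle`."""
    out = Path(path)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    files = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.csv",
        "clinical": out / "clinical.csv",
        "gene_sets": out / "pathways.gmt",
        "features": out / "features.tsv",
        "truth": out / "truth.json",
        "config": out / "config.json",
    }
    cohort.counts.counts.to_csv(files["counts"], sep="\t")
    cohort.counts.samples.to_csv(files["samples"], index=False)
    cohort.clinical.to_csv(files["clinical"])
    cohort.gene_sets.to_gmt(files["gene_sets"])
    cohort.features.to_csv(files["features"], sep="\t", index=False)
    cohort.truth.to_json(files["truth"])
    cfg = asdict(cohort.config)
    files["config"].write_text(json.dumps(cfg, indent=1, sort_keys=True))
    return files


def read_fixture_bundle(path) -> Cohort:
    """Read a fixture bundle written by :func:`write_fixture_bundle`."""
    out = Path(path)
    cfg = json.loads((out / "config.json").read_text())
    for key in ("fc_range", "depth_range", "tertile_lfc_scale", "tertile_log_hr",
                "stage_probs", "age_mean_sd"):
        cfg[key] = tuple(cfg[key])
    config = SimulationConfig(**cfg)
    counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col="feature_id")
    samples = pd.read_csv(out / "samples.csv")
    clinical = pd.read_csv(out / "clinical.csv", index_col="subject_id")
    gene_sets = GeneSetCollection.from_gmt(out / "pathways.gmt")
    truth = TruthRecord.from_json(out / "truth.json")
    features = pd.read_csv(out / "features.tsv", sep="\t")
    return Cohort(
        config, PairedCountMatrix(counts, samples), clinical, gene_sets, truth,
        features,
    )


def synthetic_feature_manifest(
    n_total: int, n_excluded: int, seed: int = 0
) -> pd.DataFrame:
    """Feature manifest with exactly *n_excluded* rows carrying some
    exclusion flag (non-coding, unknown function, or not expressed)."""
    rng = _rng(seed, 21)
    ids = [f"F{i:06d}" for i in range(n_total)]
    flags = np.ones((n_total, 3), dtype=bool)
    excl = rng.choice(n_total, size=n_excluded, replace=False)
    which = rng.integers(0, 3, size=n_excluded)
    # a failed feature may fail on several criteria; guarantee >= 1
    flags[excl, which] = False
    extra = rng.random(n_excluded) < 0.3
    flags[excl[extra], (which[extra] + 1) % 3] = False
    return pd.DataFrame(
        {
            "feature_id": ids,
            "gene_id": ids,
            "is_coding": flags[:, 0],
            "has_known_function": flags[:, 1],
            "is_expressed": flags[:, 2],
        }
    )


def synthetic_subject_qc(
    n_subjects: int, n_fail_both: int, n_fail_one: int, seed: int = 0
) -> pd.DataFrame:
    """Subject QC table with the given failure pattern."""
    if n_fail_both + n_fail_one > n_subjects:
        raise ConfigurationError("more failures than subjects")
    rng = _rng(seed, 22)
    ids = [f"S{i:04d}" for i in range(n_subjects)]
    tumor = np.ones(n_subjects, dtype=bool)
    normal = np.ones(n_subjects, dtype=bool)
    order = rng.permutation(n_subjects)
    both = order[:n_fail_both]
    one = order[n_fail_both:n_fail_both + n_fail_one]
    tumor[both] = normal[both] = False
    pick_tumor = rng.random(n_fail_one) < 0.5
    tumor[one[pick_tumor]] = False
    normal[one[~pick_tumor]] = False
    return pd.DataFrame(
        {"subject_id": ids, "tumor_pass": tumor, "normal_pass": normal}
    )
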