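"""Configuration, orchestration and artifact bookkeeping.

A single YAML config file drives any subset of the analysis stages::

    simulate -> qc -> split -> de -> enrich -> score -> survive -> stage

Each stage reads its upstream artifacts from the output directory (or
from the configured input paths), writes plain-text result tables, and
is idempotent given identical inputs and seed. A JSON run manifest
records the config snapshot, the seed, and a checksum plus row count
for every artifact written, so exclusion bookkeeping (which features
and subjects were dropped, and why) is auditable after the fact.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import de, enrichment, qc, scoring, survival
from .datatypes import PairedCountMatrix, ValidationError
from .genesets import GeneSetCollection
from .model import AnalysisParams, derive_seed
from .simulate import SimulationConfig, simulate_cohort, write_fixture_bundle

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "split", "de", "enrich", "score", "survive", "stage")

_PARAM_KEYS = {f.name for f in dataclasses.fields(AnalysisParams)}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_INPUT_KEYS = {"counts", "samples", "clinical", "features", "gmt"}
_TOP_KEYS = {"outdir", "seed", "inputs", "simulate", "params"}


class ConfigError(ValidationError):
    """Invalid pipeline configuration."""


class DependencyError(RuntimeError):
    """A stage was requested before its upstream artifacts exist."""


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    inputs: dict[str, Path] = field(default_factory=dict)
    simulate: SimulationConfig | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)


def validate_config(path) -> PipelineConfig:
    """Load, default, and range-check a YAML pipeline config.

    Unknown keys are rejected by name; referenced input paths must
    exist unless the run simulates its own inputs.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "outdir" not in raw:
        raise ConfigError("config requires an outdir")

    params_raw = raw.get("params") or {}
    unknown = set(params_raw) - _PARAM_KEYS
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
    try:
        params = AnalysisParams(**params_raw)
    except ValidationError as exc:
        raise ConfigError(f"parameter out of range: {exc}") from exc

    sim_cfg = None
    if "simulate" in raw and raw["simulate"] is not None:
        sim_raw = dict(raw["simulate"])
        unknown = set(sim_raw) - _SIM_KEYS
        if unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
        for key in ("fc_range", "depth_range", "tertile_lfc_scale",
                    "tertile_log_hr", "stage_probs", "age_mean_sd"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim_cfg = SimulationConfig(**sim_raw)

    inputs_raw = raw.get("inputs") or {}
    unknown = set(inputs_raw) - _INPUT_KEYS
    if unknown:
        raise ConfigError(f"unknown input keys: {sorted(unknown)}")
    inputs = {k: Path(v) for k, v in inputs_raw.items()}
    if sim_cfg is None:
        required = {"counts", "samples", "clinical", "gmt"}
        missing = required - set(inputs)
        if missing:
            raise ConfigError(
                f"missing required input paths: {sorted(missing)} "
                "(or provide a simulate section)"
            )
        for k, v in inputs.items():
            if not v.exists():
                raise ConfigError(f"input path for {k!r} does not exist: {v}")

    return PipelineConfig(
        outdir=Path(raw["outdir"]),
        seed=int(raw.get("seed", 0)),
        inputs=inputs,
        simulate=sim_cfg,
        params=params,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _rows(path: Path) -> int:
    if path.suffix in {".tsv", ".csv", ".gmt", ".txt"}:
        return sum(1 for _ in path.open())
    return 0


class _Run:
    """Shared state of one pipeline invocation."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict[str, dict] = {}

    # ---- artifact helpers -------------------------------------------------
    def record(self, stage: str, path: Path) -> None:
        self.artifacts[path.name] = {
            "stage": stage,
            "path": str(path),
            "sha256": _sha256(path),
            "n_rows": _rows(path),
        }

    def path_for(self, name: str, stage: str) -> Path:
        """Resolve an artifact: produced earlier in outdir, or configured."""
        candidate = self.outdir / name
        if candidate.exists():
            return candidate
        key = {
            "counts.tsv": "counts",
            "samples.csv": "samples",
            "clinical.csv": "clinical",
            "features.tsv": "features",
            "pathways.gmt": "gmt",
        }.get(name)
        if key and key in self.config.inputs:
            return self.config.inputs[key]
        raise DependencyError(
            f"stage {stage!r} requires artifact {name!r}; run the upstream "
            "stage first or configure it as an input"
        )

    def read_counts(self, stage: str) -> PairedCountMatrix:
        counts = pd.read_csv(
            self.path_for("counts.tsv", stage), sep="\t", index_col="feature_id"
        )
        samples = pd.read_csv(self.path_for("samples.csv", stage))
        return PairedCountMatrix(counts, samples)

    def read_clinical(self, stage: str) -> pd.DataFrame:
        return pd.read_csv(
            self.path_for("clinical.csv", stage), index_col="subject_id"
        )

    def analysis_counts(self, stage: str) -> PairedCountMatrix:
        """Counts restricted to QC-retained features and subjects."""
        counts = self.read_counts(stage)
        feats = self.outdir / "retained_features.txt"
        subs = self.outdir / "retained_subjects.txt"
        for p in (feats, subs):
            if not p.exists():
                raise DependencyError(
                    f"stage {stage!r} requires {p.name}; run 'qc' first"
                )
        counts = counts.subset_features(feats.read_text().split())
        return counts.subset_subjects(subs.read_text().split())

    def analysis_clinical(self, stage: str) -> pd.DataFrame:
        subs = self.outdir / "retained_subjects.txt"
        if not subs.exists():
            raise DependencyError(
                f"stage {stage!r} requires retained_subjects.txt; run 'qc' first"
            )
        clinical = self.read_clinical(stage)
        return clinical.loc[subs.read_text().split()]


# ---- stage implementations -----------------------------------------------

def _stage_simulate(run: _Run) -> None:
    cfg = run.config.simulate
    if cfg is None:
        cfg = SimulationConfig(seed=run.config.seed)
    cohort = simulate_cohort(cfg)
    files = write_fixture_bundle(cohort, run.outdir)
    for p in files.values():
        run.record("simulate", Path(p))


def _stage_qc(run: _Run) -> None:
    features = pd.read_csv(run.path_for("features.tsv", "qc"), sep="\t")
    retained = qc.filter_features(features)
    (run.outdir / "retained_features.txt").write_text("\n".join(retained) + "\n")
    clinical = run.read_clinical("qc")
    if {"tumor_pass", "normal_pass"} <= set(clinical.columns):
        table = clinical.reset_index()[["subject_id", "tumor_pass", "normal_pass"]]
        subjects = qc.qc_subjects(table)
    else:
        subjects = list(clinical.index)
    (run.outdir / "retained_subjects.txt").write_text("\n".join(subjects) + "\n")
    run.record("qc", run.outdir / "retained_features.txt")
    run.record("qc", run.outdir / "retained_subjects.txt")
    log.info("qc: %d features, %d subjects retained", len(retained), len(subjects))


def _stage_split(run: _Run) -> None:
    clinical = run.analysis_clinical("split")
    split = qc.split_discovery_groups(
        clinical,
        age_bin_width=run.config.params.age_bin_width,
        seed=derive_seed(run.config.seed, 1),
    )
    out = run.outdir / "split.csv"
    split.to_csv(out, index=False)
    run.record("split", out)


def _stage_de(run: _Run) -> None:
    split_path = run.outdir / "split.csv"
    if not split_path.exists():
        raise DependencyError("stage 'de' requires split.csv; run 'split' first")
    split = pd.read_csv(split_path)
    counts = run.analysis_counts("de")
    p = run.config.params
    results = {}
    for i, group in enumerate(("A", "B")):
        ids = list(split.loc[split["group"] == group, "subject_id"])
        scheme = de.ResamplingScheme(
            n_resamples=p.n_resamples, seed=derive_seed(run.config.seed, 10 + i)
        )
        results[group] = de.paired_de_test(
            counts.subset_subjects(ids), scheme=scheme, n_perm=p.n_perm,
            pseudocount=p.pseudocount,
        )
        out = run.outdir / f"de_{group}.tsv"
        results[group].to_csv(out, sep="\t", index_label="feature_id")
        run.record("de", out)
    rule = de.SelectionRule(p_threshold=p.p_threshold, fc_threshold=p.fc_threshold)
    table = de.selection_table(results["A"], results["B"], rule)
    out = run.outdir / "selected.tsv"
    table.to_csv(out, sep="\t", index_label="feature_id")
    run.record("de", out)


def _stage_enrich(run: _Run) -> None:
    sel_path = run.outdir / "selected.tsv"
    if not sel_path.exists():
        raise DependencyError("stage 'enrich' requires selected.tsv; run 'de' first")
    table = pd.read_csv(sel_path, sep="\t", index_col="feature_id")
    feats = run.outdir / "retained_features.txt"
    if not feats.exists():
        raise DependencyError("stage 'enrich' requires retained_features.txt")
    universe = feats.read_text().split()
    sets = GeneSetCollection.from_gmt(run.path_for("pathways.gmt", "enrich"))
    up = list(table.index[(table["selected_both"]) & (table["direction"] == "up")])
    down = list(table.index[(table["selected_both"]) & (table["direction"] == "down")])
    enr = enrichment.hypergeometric_enrichment(
        up + down, universe, sets, up=up, down=down,
        alpha=run.config.params.bh_alpha,
    )
    out = run.outdir / "enrichment.tsv"
    enr.to_csv(out, sep="\t", index=False)
    run.record("enrich", out)


def _stage_score(run: _Run) -> None:
    for need in ("selected.tsv", "enrichment.tsv"):
        if not (run.outdir / need).exists():
            raise DependencyError(f"stage 'score' requires {need}")
    table = pd.read_csv(run.outdir / "selected.tsv", sep="\t",
                        index_col="feature_id")
    enr = pd.read_csv(run.outdir / "enrichment.tsv", sep="\t")
    counts = run.analysis_counts("score")
    p = run.config.params
    sel = table[table["selected_both"]]
    direction = pd.Series(
        {g: (1 if d == "up" else -1) for g, d in zip(sel.index, sel["direction"])}
    )
    if len(direction) == 0:
        raise DependencyError("stage 'score': no selected genes to score")
    delta = scoring.compute_delta_profile(
        counts, features=list(direction.index), pseudocount=p.pseudocount
    )
    dges = scoring.assign_dges(delta, direction)
    sets = GeneSetCollection.from_gmt(run.path_for("pathways.gmt", "score"))
    enriched = list(enr.loc[enr["significant"], "set_name"])
    if not enriched:
        raise DependencyError("stage 'score': no enriched pathways to score")
    sets = GeneSetCollection(
        {n: sets[n] for n in enriched},
        {n: sets.descriptions.get(n, "") for n in enriched},
    ).restrict_to(set(dges.columns))
    dpes = scoring.compute_dpes(dges, sets)
    tertiles = scoring.tertile_table(dpes)
    for name, frame in (("dges.tsv", dges), ("dpes.tsv", dpes),
                        ("tertiles.tsv", tertiles)):
        out = run.outdir / name
        frame.to_csv(out, sep="\t", index_label="subject_id")
        run.record("score", out)


def _stage_survive(run: _Run) -> None:
    tert_path = run.outdir / "tertiles.tsv"
    if not tert_path.exists():
        raise DependencyError(
            "stage 'survive' requires tertiles.tsv; run 'score' first"
        )
    tertiles = pd.read_csv(tert_path, sep="\t", index_col="subject_id")
    clinical = run.analysis_clinical("survive")
    hazards = survival.hazard_table(tertiles, clinical)
    out = run.outdir / "hazards.tsv"
    hazards.to_csv(out, sep="\t", index=False)
    run.record("survive", out)
    for name in list(tertiles.columns)[:3]:
        records = survival.build_survival_records(clinical, tertiles[name])
        img = run.outdir / f"km_{name}.png"
        survival.plot_km(records, img, title=name)
        run.record("survive", img)


def _stage_stage(run: _Run) -> None:
    dpes_path = run.outdir / "dpes.tsv"
    if not dpes_path.exists():
        raise DependencyError("stage 'stage' requires dpes.tsv; run 'score' first")
    dpes = pd.read_csv(dpes_path, sep="\t", index_col="subject_id")
    clinical = run.analysis_clinical("stage")
    table = survival.stage_table(dpes, clinical)
    out = run.outdir / "stage_summary.tsv"
    table.to_csv(out, sep="\t", index=False)
    run.record("stage", out)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "split": _stage_split,
    "de": _stage_de,
    "enrich": _stage_enrich,
    "score": _stage_score,
    "survive": _stage_survive,
    "stage": _stage_stage,
}


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Execute the requested stages in dependency order; returns the
    run manifest (also written to ``<outdir>/manifest.json``)."""
    if stages is None or stages == "all" or "all" in (stages or []):
        requested = list(STAGES)
    else:
        bad = set(stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        requested = [s for s in STAGES if s in set(stages)]
    run = _Run(config)
    for stage in requested:
        log.info("running stage %s", stage)
        _STAGE_FUNCS[stage](run)
    manifest = {
        "seed": config.seed,
        "stages": requested,
        "params": dataclasses.asdict(config.params),
        "simulate": (
            dataclasses.asdict(config.simulate) if config.simulate else None
        ),
        "inputs": {k: str(v) for k, v in config.inputs.items()},
        "artifacts": run.artifacts,
        "finished_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (run.outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                         sort_keys=True))
    return manifest
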