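import numpy as np
import pandas as pd
import pytest

from pathsurv import SimulationConfig, simulate_cohort
from pathsurv.datatypes import PairedCountMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_subjects=60, n_genes=200, n_pathways=4, genes_per_pathway=8,
        n_linked_pathways=1, n_null_de_pathways=1, seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def pcm_factory():
    """Build a PairedCountMatrix from genes x subjects tumor/normal arrays."""

    def make(tumor, normal, feature_ids=None):
        tumor = np.atleast_2d(np.asarray(tumor))
        normal = np.atleast_2d(np.asarray(normal))
        n_genes, n_subj = tumor.shape
        feats = feature_ids or [f"G{i:03d}" for i in range(n_genes)]
        subjects = [f"S{i:03d}" for i in range(n_subj)]
        cols_t = [f"{s}_T" for s in subjects]
        cols_n = [f"{s}_N" for s in subjects]
        counts = pd.DataFrame(
            np.hstack([tumor, normal]),
            index=pd.Index(feats, name="feature_id"),
            columns=cols_t + cols_n,
        )
        samples = pd.DataFrame(
            {
                "sample_id": cols_t + cols_n,
                "subject_id": subjects + subjects,
                "tissue": ["tumor"] * n_subj + ["normal"] * n_subj,
            }
        )
        return PairedCountMatrix(counts, samples)

    return make


@pytest.fixture
def clinical_factory():
    """Minimal clinical table for survival-model tests."""

    def make(times, events, tertiles=None, seed=0, stages=None):
        rng = np.random.default_rng(seed)
        n = len(times)
        subjects = [f"S{i:03d}" for i in range(n)]
        status = ["crc_death" if e else "alive" for e in events]
        return pd.DataFrame(
            {
                "age": rng.normal(65, 10, n).round(1),
                "sex": rng.choice(["M", "F"], n),
                "ajcc_stage": stages if stages is not None
                else rng.choice([1, 2, 3, 4], n),
                "tp53": rng.integers(0, 2, n),
                "kras": rng.integers(0, 2, n),
                "msi": rng.integers(0, 2, n),
                "cimp": rng.integers(0, 2, n),
                "vital_status": status,
                "followup_months": np.asarray(times, dtype=float),
            },
            index=pd.Index(subjects, name="subject_id"),
        )

    return make
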