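"""Cause-specific survival models for pathway de-regulation tertiles.

The endpoint is colorectal-cancer death; every other outcome (alive,
other-cause death, unknown vital status) is censored at the last
contact time. Hazard ratios for DPES tertiles 2 and 3 versus tertile 1
come from a Cox proportional-hazards model adjusted for age, sex, AJCC
stage (indicator contrasts versus stage 1) and tumor molecular
phenotype (TP53, KRAS, MSI, CIMP as 0/1), with Efron handling of tied
event times. Kaplan-Meier curves per tertile and per-stage score
summaries (Welch t-test of stage 1 versus stage 4) round out the
outcome analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .datatypes import ValidationError

log = logging.getLogger(__name__)

COVARIATES = ("age", "sex_male", "stage_2", "stage_3", "stage_4",
              "tp53", "kras", "msi", "cimp")


@dataclass
class HazardEstimate:
    """Tertile hazard ratios for one pathway (reference: tertile 1)."""

    pathway: str
    hr_t2: float
    ci_t2: tuple[float, float]
    hr_t3: float
    ci_t3: tuple[float, float]
    n: int
    n_events: int
    summary: pd.DataFrame

    def __post_init__(self) -> None:
        for hr, (lo, hi) in ((self.hr_t2, self.ci_t2), (self.hr_t3, self.ci_t3)):
            if not (lo <= hr <= hi):
                raise ValueError("confidence interval must bracket the HR")


@dataclass
class StageSummary:
    """Per-AJCC-stage mean and SD of one pathway's DPES."""

    pathway: str
    means: dict[int, float]
    sds: dict[int, float]
    ns: dict[int, int]
    p_1v4: float


def build_survival_records(
    clinical: pd.DataFrame, tertiles: pd.Series
) -> pd.DataFrame:
    """Merge clinical covariates with one pathway's tertile labels.

    CRC deaths are events at the death time; alive, other-cause deaths
    and unknown vital status are censored at last contact. Records with
    missing/non-positive follow-up or missing stage are dropped with a
    logged count.
    """
    for col in ("vital_status", "followup_months", "age", "sex", "ajcc_stage",
                "tp53", "kras", "msi", "cimp"):
        if col not in clinical.columns:
            raise ValidationError(f"clinical table missing column {col!r}")
    common = [s for s in clinical.index if s in tertiles.index]
    df = clinical.loc[common]
    time = pd.to_numeric(df["followup_months"], errors="coerce")
    ok_time = time.notna() & (time > 0)
    ok_stage = df["ajcc_stage"].isin([1, 2, 3, 4])
    dropped = int((~(ok_time & ok_stage)).sum())
    if dropped:
        log.info("survival records: dropped %d subjects with invalid "
                 "follow-up or unknown stage", dropped)
    df = df[ok_time & ok_stage]
    out = pd.DataFrame(
        {
            "time": time[df.index],
            "event": (df["vital_status"] == "crc_death").astype(int),
            "age": df["age"].astype(float),
            "sex_male": (df["sex"] == "M").astype(int),
            "stage_2": (df["ajcc_stage"] == 2).astype(int),
            "stage_3": (df["ajcc_stage"] == 3).astype(int),
            "stage_4": (df["ajcc_stage"] == 4).astype(int),
            "tp53": df["tp53"].astype(int),
            "kras": df["kras"].astype(int),
            "msi": df["msi"].astype(int),
            "cimp": df["cimp"].astype(int),
            "tertile": tertiles.loc[df.index].astype(int),
        },
        index=df.index,
    )
    return out


def fit_cox_tertiles(
    records: pd.DataFrame,
    pathway: str = "",
    adjusted: bool = True,
) -> HazardEstimate:
    """Cox proportional-hazards fit with tertile 2/3 indicator terms.

    Partial-likelihood point estimates with Wald 95% confidence
    intervals, exponentiated to the hazard-ratio scale. ``adjusted``
    includes the full covariate set; otherwise only the tertile terms
    enter (useful for simulation checks on true group labels).
    """
    if records["event"].sum() < 1:
        raise ValidationError("no events; Cox model undefined")
    levels = set(records["tertile"])
    if not levels <= {1, 2, 3}:
        raise ValidationError(f"unexpected tertile labels: {sorted(levels)}")
    if levels != {1, 2, 3}:
        raise ValidationError(
            f"degenerate tertile assignment (levels {sorted(levels)}); "
            "hazard ratios versus tertile 1 are undefined"
        )
    design = pd.DataFrame(
        {
            "time": records["time"].astype(float),
            "event": records["event"].astype(int),
            "tertile_2": (records["tertile"] == 2).astype(int),
            "tertile_3": (records["tertile"] == 3).astype(int),
        },
        index=records.index,
    )
    if adjusted:
        for c in COVARIATES:
            design[c] = records[c].astype(float)
        # drop covariates without variation (tiny simulated cohorts)
        for c in COVARIATES:
            if design[c].nunique() < 2:
                design = design.drop(columns=c)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ValidationError(
            f"Cox model failed to converge (possible separation): {exc}"
        ) from exc
    s = cph.summary
    return HazardEstimate(
        pathway=pathway,
        hr_t2=float(s.loc["tertile_2", "exp(coef)"]),
        ci_t2=(
            float(s.loc["tertile_2", "exp(coef) lower 95%"]),
            float(s.loc["tertile_2", "exp(coef) upper 95%"]),
        ),
        hr_t3=float(s.loc["tertile_3", "exp(coef)"]),
        ci_t3=(
            float(s.loc["tertile_3", "exp(coef) lower 95%"]),
            float(s.loc["tertile_3", "exp(coef) upper 95%"]),
        ),
        n=len(design),
        n_events=int(design["event"].sum()),
        summary=s,
    )


def km_by_tertile(records: pd.DataFrame) -> dict[int, KaplanMeierFitter]:
    """Product-limit survival estimate per tertile; empty tertiles are
    omitted with a warning."""
    out: dict[int, KaplanMeierFitter] = {}
    for tert in (1, 2, 3):
        sub = records[records["tertile"] == tert]
        if len(sub) == 0:
            warnings.warn(f"tertile {tert} is empty; curve omitted",
                          stacklevel=2)
            continue
        kmf = KaplanMeierFitter(label=f"T{tert}")
        kmf.fit(sub["time"], event_observed=sub["event"])
        out[tert] = kmf
    return out


def plot_km(records: pd.DataFrame, path, title: str = "") -> None:
    """Write a Kaplan-Meier plot (one curve per tertile) to *path*."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for tert, kmf in km_by_tertile(records).items():
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("months since diagnosis")
    ax.set_ylabel("CRC-specific survival")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def stage_summary(
    dpes: pd.Series, stages: pd.Series, pathway: str = ""
) -> StageSummary:
    """Mean/SD of one pathway's DPES per AJCC stage with a Welch t-test
    comparing stages 1 and 4."""
    common = [s for s in dpes.index if s in stages.index]
    v = dpes.loc[common].astype(float)
    st = stages.loc[common]
    means, sds, ns = {}, {}, {}
    for stage in (1, 2, 3, 4):
        vals = v[st == stage]
        ns[stage] = int(len(vals))
        means[stage] = float(vals.mean()) if len(vals) else float("nan")
        sds[stage] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    s1 = v[st == 1]
    s4 = v[st == 4]
    if len(s1) < 2 or len(s4) < 2:
        raise ValidationError(
            "need at least 2 subjects in stages 1 and 4 for the comparison"
        )
    if s1.std(ddof=1) == 0 and s4.std(ddof=1) == 0:
        # degenerate: both samples constant; p reflects mean equality only
        p = 1.0 if s1.mean() == s4.mean() else 0.0
    else:
        p = float(stats.ttest_ind(s1, s4, equal_var=False).pvalue)
    return StageSummary(pathway=pathway, means=means, sds=sds, ns=ns, p_1v4=p)


def hazard_table(
    tertiles: pd.DataFrame, clinical: pd.DataFrame, adjusted: bool = True
) -> pd.DataFrame:
    """Tertile hazard ratios for every pathway (Table-2-style layout).

    Pathways whose model cannot be fitted (degenerate tertiles, no
    events, separation) are reported with NaN estimates and a note.
    """
    rows = []
    for name in tertiles.columns:
        note = ""
        try:
            records = build_survival_records(clinical, tertiles[name])
            est = fit_cox_tertiles(records, pathway=name, adjusted=adjusted)
            row = {
                "pathway": name,
                "hr_t2": est.hr_t2,
                "ci_t2_low": est.ci_t2[0],
                "ci_t2_high": est.ci_t2[1],
                "hr_t3": est.hr_t3,
                "ci_t3_low": est.ci_t3[0],
                "ci_t3_high": est.ci_t3[1],
                "n": est.n,
                "n_events": est.n_events,
            }
        except ValidationError as exc:
            note = str(exc)
            log.warning("pathway %s: %s", name, note)
            row = {"pathway": name, "hr_t2": np.nan, "ci_t2_low": np.nan,
                   "ci_t2_high": np.nan, "hr_t3": np.nan, "ci_t3_low": np.nan,
                   "ci_t3_high": np.nan, "n": 0, "n_events": 0}
        row["note"] = note
        rows.append(row)
    return pd.DataFrame(rows)


def stage_table(dpes: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway, per-stage DPES means/SDs with the stage-1-vs-4 Welch
    p-value (Table-3-style layout)."""
    stages = clinical["ajcc_stage"]
    rows = []
    for name in dpes.columns:
        s = stage_summary(dpes[name], stages, pathway=name)
        row = {"pathway": name}
        for stage in (1, 2, 3, 4):
            row[f"mean_stage{stage}"] = s.means[stage]
            row[f"sd_stage{stage}"] = s.sds[stage]
        row["p_1v4"] = s.p_1v4
        rows.append(row)
    return pd.DataFrame(rows)
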