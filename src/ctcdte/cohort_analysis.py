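"""Longitudinal aggregation of per-cell MT-DTE scores.

Per-cell scores are rolled up into per-patient x timepoint summaries
(cell count, mean MT-DTE, sample SD), per-patient count statistics, and
baseline-vs-week-1 contrasts (C1D1 vs C1D8, C2D1 vs C2D8).  The 4-hour and
24-hour draws are summarized but never enter the response contrast: early
engagement reflects initial drug binding, while the week-1 change is the
response-associated signal.  No hypothesis tests are computed — with a
handful of patients the contrasts are descriptive ("increased" or not),
and a missing side yields a missing flag, never False.

The module also ships the published reference cohort of the three-patient
CRXL301 (docetaxel nanoparticle) mCRPC study — per-timepoint CTC counts
and mean (SD) MT-DTE — used as a fixture for exercising the aggregation
path against known printed values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .mt_dte_scoring import MtDteScore, score_ctc
from .synthetic_cytospin import CohortDesign, iter_cohort_cells
from .timepoints import CONTRAST_PAIRS, TIMEPOINT_LABELS


# ---------------------------------------------------------------------------
# summary types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimepointSummary:
    """One patient x timepoint row: cell count and score statistics.

    ``mean_dte``/``sd_dte`` are NaN when no cells were analyzed or the
    sample was not received; ``sd_dte`` is additionally NaN for n = 1
    (sample SD undefined).
    """

    patient_id: str
    timepoint: str
    n_ctc: int
    mean_dte: float
    sd_dte: float
    status: str = "analyzed"  # or "sample_not_received"

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINT_LABELS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r}; allowed: {TIMEPOINT_LABELS}"
            )
        if self.status not in ("analyzed", "sample_not_received"):
            raise ValidationError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class PatientCountSummary:
    """Per-patient CTC yield statistics over analyzed timepoints."""

    patient_id: str
    mean_count: float
    min_count: int
    max_count: int
    total_count: int


@dataclass(frozen=True)
class LongitudinalContrast:
    """Baseline vs week-1 comparison for one treatment cycle.

    ``increased`` is True/False when both means are present, None when
    either side is missing (never imputed).
    """

    patient_id: str
    cycle: int
    baseline_timepoint: str
    week1_timepoint: str
    baseline_mean: float
    week1_mean: float

    @property
    def delta(self) -> float:
        return self.week1_mean - self.baseline_mean

    @property
    def ratio(self) -> float:
        if np.isnan(self.baseline_mean) or np.isnan(self.week1_mean):
            return np.nan
        if self.baseline_mean == 0:
            return np.nan
        return self.week1_mean / self.baseline_mean

    @property
    def increased(self) -> bool | None:
        if np.isnan(self.baseline_mean) or np.isnan(self.week1_mean):
            return None
        return self.delta > 0


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _values(scores: Iterable) -> list[float]:
    out = []
    for s in scores:
        out.append(s.scaled_score if isinstance(s, MtDteScore) else float(s))
    return out


def _exact_mean(vals: Sequence[float]) -> float:
    """Arithmetic mean in exact rational arithmetic, rounded once.

    Summing floats and dividing can land one ulp away from the true mean
    (and is order-dependent); computing the mean over ``Fraction`` values
    makes it correctly rounded and permutation-invariant, so aggregated
    tables are reproducible digit for digit.
    """
    total = sum(Fraction(float(v)) for v in vals)
    return float(total / len(vals))


def summarize_timepoint(
    scores: Sequence,
    patient_id: str,
    timepoint: str,
    status: str = "analyzed",
) -> TimepointSummary:
    """Summarize one timepoint's per-cell scores (mean, sample SD with n-1).

    ``scores`` may be :class:`MtDteScore` objects or plain numbers.  A
    not-received sample or an empty score list yields NaN statistics.
    """
    vals = _values(scores) if status == "analyzed" else []
    n = len(vals)
    if n == 0:
        mean = sd = float("nan")
    else:
        mean = _exact_mean(vals)
        sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
    return TimepointSummary(
        patient_id=patient_id, timepoint=timepoint, n_ctc=n,
        mean_dte=mean, sd_dte=sd, status=status,
    )


def summarize_counts(
    summaries: Sequence[TimepointSummary],
) -> PatientCountSummary:
    """Per-patient CTC count statistics; not-received rows are excluded."""
    pids = {s.patient_id for s in summaries}
    if len(pids) != 1:
        raise ValidationError(f"summaries must cover exactly one patient, got {pids}")
    counts = [s.n_ctc for s in summaries if s.status == "analyzed"]
    if not counts:
        return PatientCountSummary(pids.pop(), float("nan"), 0, 0, 0)
    return PatientCountSummary(
        patient_id=pids.pop(),
        mean_count=float(np.mean(counts)),
        min_count=int(min(counts)),
        max_count=int(max(counts)),
        total_count=int(sum(counts)),
    )


def total_confirmed_ctcs(summaries: Sequence[TimepointSummary]) -> int:
    """Total analyzed CTCs across all patients and timepoints."""
    return int(sum(s.n_ctc for s in summaries if s.status == "analyzed"))


def longitudinal_contrasts(
    summaries: Sequence[TimepointSummary],
) -> list[LongitudinalContrast]:
    """Baseline vs week-1 contrasts for one patient, one per available cycle.

    A cycle contributes a contrast when both of its timepoints appear in
    the summaries; a side that is missing (not received, or no cells)
    enters as NaN and makes ``increased`` None.
    """
    pids = {s.patient_id for s in summaries}
    if len(pids) != 1:
        raise ValidationError(f"summaries must cover exactly one patient, got {pids}")
    pid = pids.pop()
    by_tp = {s.timepoint: s for s in summaries}
    out = []
    for cycle, (base, week1) in sorted(CONTRAST_PAIRS.items()):
        if base not in by_tp and week1 not in by_tp:
            continue
        b = by_tp.get(base)
        w = by_tp.get(week1)
        out.append(
            LongitudinalContrast(
                patient_id=pid,
                cycle=cycle,
                baseline_timepoint=base,
                week1_timepoint=week1,
                baseline_mean=b.mean_dte if b is not None else float("nan"),
                week1_mean=w.mean_dte if w is not None else float("nan"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def summaries_to_frame(summaries: Sequence[TimepointSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(patient_id=s.patient_id, timepoint=s.timepoint, n_ctc=s.n_ctc,
                 mean_dte=s.mean_dte, sd_dte=s.sd_dte, status=s.status)
            for s in summaries
        ],
        columns=["patient_id", "timepoint", "n_ctc", "mean_dte", "sd_dte", "status"],
    )


def contrasts_to_frame(contrasts: Sequence[LongitudinalContrast]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(patient_id=c.patient_id, cycle=c.cycle,
                 baseline_timepoint=c.baseline_timepoint,
                 week1_timepoint=c.week1_timepoint,
                 baseline_mean=c.baseline_mean, week1_mean=c.week1_mean,
                 delta=c.delta, ratio=c.ratio, increased=c.increased)
            for c in contrasts
        ],
        columns=["patient_id", "cycle", "baseline_timepoint", "week1_timepoint",
                 "baseline_mean", "week1_mean", "delta", "ratio", "increased"],
    )


def build_cohort_report(
    summaries: Sequence[TimepointSummary],
    contrasts: Sequence[LongitudinalContrast],
    output_dir: str | os.PathLike,
    clinical: pd.DataFrame | None = None,
    plot: bool = True,
) -> dict[str, str]:
    """Write the cohort table, contrasts table and a mean+/-SEM summary plot.

    ``clinical`` (optional) is merged onto the cohort table by
    ``patient_id`` and consumed as free-text metadata only.  Returns a map
    of artifact name to written path.  Empty inputs produce headers-only
    files.
    """
    output_dir = os.fspath(output_dir)
    os.makedirs(output_dir, exist_ok=True)
    table = summaries_to_frame(summaries)
    if clinical is not None and not table.empty:
        table = table.merge(clinical, on="patient_id", how="left")
    table_path = os.path.join(output_dir, "cohort_table.csv")
    table.to_csv(table_path, index=False)

    contrasts_path = os.path.join(output_dir, "contrasts.csv")
    contrasts_to_frame(contrasts).to_csv(contrasts_path, index=False)

    paths = {"cohort_table": table_path, "contrasts": contrasts_path}
    if plot:
        paths["plot"] = _plot_summary(summaries, os.path.join(output_dir, "mt_dte_summary.svg"))
    return paths


def _plot_summary(summaries: Sequence[TimepointSummary], path: str) -> str:
    """Per-patient mean +/- SEM MT-DTE at the contrast timepoints."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    focus = [tp for pair in CONTRAST_PAIRS.values() for tp in pair]
    fig, ax = plt.subplots(figsize=(6, 4))
    patients = sorted({s.patient_id for s in summaries})
    for pid in patients:
        rows = {s.timepoint: s for s in summaries if s.patient_id == pid}
        xs, ys, es = [], [], []
        for i, tp in enumerate(focus):
            s = rows.get(tp)
            if s is None or np.isnan(s.mean_dte):
                continue
            xs.append(i)
            ys.append(s.mean_dte)
            es.append(s.sd_dte / np.sqrt(s.n_ctc) if s.n_ctc > 1 else 0.0)
        if xs:
            ax.errorbar(xs, ys, yerr=es, marker="o", capsize=3, label=pid)
    ax.set_xticks(range(len(focus)))
    ax.set_xticklabels(focus)
    ax.set_ylabel("mean MT-DTE ± SEM")
    ax.set_xlabel("timepoint")
    if patients:
        ax.legend(title="patient")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# reference cohort (published three-patient CRXL301 study)
# ---------------------------------------------------------------------------

# Per-timepoint count, mean MT-DTE and SD as printed for the three mCRPC
# patients treated with the CRXL301 docetaxel nanoparticle.  None marks a
# sample that was never received.
_REFERENCE_ROWS: tuple[tuple[str, str, int | None, float | None, float | None], ...] = (
    ("Patient 1", "C1D1", 3, 0.19, 0.16),
    ("Patient 1", "C1D1+4h", 1, 0.004, None),
    ("Patient 1", "C1D2", 2, 0.34, 0.26),
    ("Patient 1", "C1D8", 6, 1.0, 0.85),
    ("Patient 1", "C2D1", 2, 0.17, 0.15),
    ("Patient 1", "C2D1+4h", 17, 8.3, 7.8),
    ("Patient 1", "C2D8", 11, 0.45, 0.32),
    ("Patient 2", "C1D1", 3, 0.33, 0.44),
    ("Patient 2", "C1D1+4h", 20, 16.39, 14.43),
    ("Patient 2", "C1D2", 5, 22.87, 18.78),
    ("Patient 2", "C1D8", 2, 0.44, 0.081),
    ("Patient 2", "C2D1", 10, 27.21, 26.79),
    ("Patient 2", "C2D1+4h", 17, 20.04, 23.58),
    ("Patient 2", "C2D8", None, None, None),
    ("Patient 3", "C1D1", 5, 14.80, 18.8),
    ("Patient 3", "C1D1+4h", 14, 5.07, 16.92),
    ("Patient 3", "C1D2", None, None, None),
    ("Patient 3", "C1D8", None, None, None),
    ("Patient 3", "C2D1", 12, 46.64, 25.67),
    ("Patient 3", "C2D1+4h", 17, 14.47, 12.14),
    ("Patient 3", "C2D8", 2, 0.1185, 0.040),
)


def reference_cohort() -> pd.DataFrame:
    """The published reference cohort as a tidy DataFrame.

    Columns: ``patient_id, timepoint, n_ctc, mean_dte, sd_dte, status``;
    not-received samples have ``status='sample_not_received'`` and NaN
    statistics.
    """
    rows = []
    for pid, tp, n, mean, sd in _REFERENCE_ROWS:
        received = n is not None
        rows.append(
            dict(
                patient_id=pid,
                timepoint=tp,
                n_ctc=n if received else 0,
                mean_dte=mean if mean is not None else np.nan,
                sd_dte=sd if sd is not None else np.nan,
                status="analyzed" if received else "sample_not_received",
            )
        )
    return pd.DataFrame(rows)


def reference_summaries() -> list[TimepointSummary]:
    """The reference cohort as :class:`TimepointSummary` objects."""
    out = []
    for row in reference_cohort().itertuples(index=False):
        out.append(
            TimepointSummary(
                patient_id=row.patient_id, timepoint=row.timepoint,
                n_ctc=int(row.n_ctc), mean_dte=float(row.mean_dte),
                sd_dte=float(row.sd_dte), status=row.status,
            )
        )
    return out


def reconstruct_scores(
    n: int,
    mean: float,
    sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Construct ``n`` per-cell scores whose sample mean equals ``mean`` exactly.

    Used to rebuild a cohort from printed (n, mean) pairs so the
    aggregation path can be exercised end to end.  The first ``n - 1``
    values carry the requested spread; the last value is solved in exact
    rational arithmetic so the correctly rounded mean (the one
    :func:`summarize_timepoint` computes) equals the target float
    bit-exactly.  For n = 2 with a target SD the construction is
    ``mean +/- sd / sqrt(2)``, exact under the n-1 denominator.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if n == 1:
        return np.array([mean], dtype=np.float64)
    rng = rng or np.random.default_rng(0)
    if n == 2 and sd is not None:
        vals = np.array([mean - sd / np.sqrt(2), mean + sd / np.sqrt(2)])
    else:
        spread = sd if sd is not None else max(abs(mean), 1.0) * 0.25
        noise = rng.normal(0.0, spread, size=n)
        noise -= noise.mean()
        vals = mean + noise
    residual = Fraction(float(mean)) * n - sum(
        Fraction(float(v)) for v in vals[:-1]
    )
    vals[-1] = float(residual)
    return vals


# ---------------------------------------------------------------------------
# synthetic-cohort scoring and the responder-recovery experiment
# ---------------------------------------------------------------------------


def score_synthetic_cohort(design: CohortDesign) -> pd.DataFrame:
    """Render and score every cell of a designed cohort, in memory.

    Returns one row per designed patient x timepoint x cell with the
    per-cell integrated density; timepoints with no cells appear with a
    NaN score so they are preserved downstream.
    """
    rows = []
    for rec in iter_cohort_cells(design):
        if rec["stack"] is None:
            rows.append(dict(patient_id=rec["patient_id"], timepoint=rec["timepoint"],
                             status=rec["status"], cell_id=None,
                             true_bundling_level=np.nan, integrated_density=np.nan))
            continue
        score = score_ctc(rec["stack"], cell_id=rec["cell_id"])
        rows.append(dict(patient_id=rec["patient_id"], timepoint=rec["timepoint"],
                         status="analyzed", cell_id=rec["cell_id"],
                         true_bundling_level=rec["bundling_level"],
                         integrated_density=score.integrated_density))
    return pd.DataFrame(rows)


def summarize_score_frame(scores: pd.DataFrame) -> list[TimepointSummary]:
    """Roll a per-cell score frame up into timepoint summaries."""
    out = []
    for (pid, tp), grp in scores.groupby(["patient_id", "timepoint"], sort=True):
        status = grp["status"].iloc[0]
        vals = grp["integrated_density"].dropna().tolist()
        out.append(summarize_timepoint(vals, pid, tp, status=status))
    return out


def responder_recovery_experiment(
    n_replicates: int = 100,
    n_cells: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Run repeated responder + stable cohorts and record contrast outcomes.

    Each replicate simulates one responder and one stable patient at the
    four contrast timepoints with ``n_cells`` CTCs each, scores every
    cell, and records whether each cycle's week-1 mean exceeded its
    baseline.  Returns one row per replicate x patient with boolean
    ``cycle1_increased``/``cycle2_increased`` columns.
    """
    from .synthetic_cytospin import recovery_design

    rows = []
    for rep in range(n_replicates):
        design = recovery_design(seed=int(base_seed) + rep, n_cells=n_cells)
        scores = score_synthetic_cohort(design)
        summaries = summarize_score_frame(scores)
        for patient in design.patients:
            pats = [s for s in summaries if s.patient_id == patient.patient_id]
            contrasts = {c.cycle: c for c in longitudinal_contrasts(pats)}
            rows.append(
                dict(
                    replicate=rep,
                    patient_id=patient.patient_id,
                    profile=patient.response_profile,
                    cycle1_increased=contrasts[1].increased,
                    cycle2_increased=contrasts[2].increased,
                )
            )
    return pd.DataFrame(rows)


__all__ = [
    "TimepointSummary",
    "PatientCountSummary",
    "LongitudinalContrast",
    "summarize_timepoint",
    "summarize_counts",
    "total_confirmed_ctcs",
    "longitudinal_contrasts",
    "summaries_to_frame",
    "contrasts_to_frame",
    "build_cohort_report",
    "reference_cohort",
    "reference_summaries",
    "reconstruct_scores",
    "score_synthetic_cohort",
    "summarize_score_frame",
    "responder_recovery_experiment",
]
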