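"""Control-referenced cohort statistics.

Small rare-disease cohorts are summarized descriptively: per metric, a
control reference band, classification of each affected tooth (or patient)
against that band, and case-versus-control fold or percent changes.  No
hypothesis tests are computed.

The reference band defaults to the 95% t-based confidence interval of the
control mean, mean ± t(0.975, n−1)·SD/√n; a population-style reference
band (mean ± 1.96·SD) is available via ``interval_mode='sd_band'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceInterval",
    "CohortTable",
    "reference_interval",
    "classify_within_limits",
    "fold_change",
    "percent_change",
    "cohort_report",
]


@dataclass(frozen=True)
class ReferenceInterval:
    metric: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    mode: str = "ci_mean"

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("reference interval requires n >= 2")
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("interval must bracket the mean")


def reference_interval(control_values, metric: str = "",
                       mode: str = "ci_mean", level: float = 0.95
                       ) -> ReferenceInterval:
    """Control reference band for one metric."""
    x = np.asarray(list(control_values), dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least two control values")
    n = int(x.size)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    q = 0.5 + level / 2.0
    if mode == "ci_mean":
        half = float(stats.t.ppf(q, n - 1)) * sd / np.sqrt(n)
    elif mode == "sd_band":
        half = float(stats.norm.ppf(q)) * sd
    else:
        raise ValueError(f"unknown interval mode {mode!r}")
    return ReferenceInterval(metric=metric, n=n, mean=mean, sd=sd,
                             ci_low=mean - half, ci_high=mean + half, mode=mode)


def classify_within_limits(value: float, interval: ReferenceInterval) -> str:
    """'below' | 'within' | 'above' against closed interval bounds."""
    if value < interval.ci_low:
        return "below"
    if value > interval.ci_high:
        return "above"
    return "within"


def fold_change(case_mean: float, control_mean: float) -> float:
    """case / control ratio; the control mean must be nonzero."""
    if control_mean == 0:
        raise ValueError(
            "control mean is zero: fold change undefined — "
            "report the absolute difference instead"
        )
    return float(case_mean) / float(control_mean)


def percent_change(case_mean: float, control_mean: float) -> float:
    """100 × (case − control) / control."""
    if control_mean == 0:
        raise ValueError("control mean must be nonzero for percent change")
    return 100.0 * (float(case_mean) - float(control_mean)) / float(control_mean)


class CohortTable:
    """Long-format cohort measurements.

    One row per tooth × metric with columns ``patient``, ``tooth``,
    ``group`` ('case' or 'control'), ``metric``, ``value``.
    """

    COLUMNS = ["patient", "tooth", "group", "metric", "value"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        bad = set(frame["group"].unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"group must be 'case' or 'control', got {sorted(bad)}")
        if frame.duplicated(subset=["tooth", "metric"]).any():
            raise ValueError("more than one value per tooth × metric")
        self.frame = frame[self.COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "CohortTable":
        return cls(pd.DataFrame(list(records)))

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def metrics(self):
        return list(pd.unique(self.frame["metric"]))


_PALETTE = [
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
    "#e6ab02", "#a6761d", "#666666",
]


def _plot_metric(sub: pd.DataFrame, interval: ReferenceInterval,
                 metric: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.0, 3.2), dpi=120)
    ax.axhspan(interval.ci_low, interval.ci_high, color="0.85", zorder=0,
               label=f"control 95% {'CI' if interval.mode == 'ci_mean' else 'band'}")
    patients = sorted(sub["patient"].unique())
    colors = {p: _PALETTE[i % len(_PALETTE)] for i, p in enumerate(patients)}
    for gi, group in enumerate(["control", "case"]):
        g = sub[sub["group"] == group]
        rng = np.random.default_rng(0)  # fixed jitter for byte-stable output
        x = gi + rng.uniform(-0.12, 0.12, len(g))
        ax.scatter(x, g["value"], s=18,
                   c=[colors[p] for p in g["patient"]], zorder=2)
        ax.errorbar(
            [gi], [g["value"].mean()], yerr=[g["value"].std(ddof=1) or 0.0],
            fmt="_", color="k", capsize=4, zorder=3,
        )
    ax.set_xticks([0, 1], ["control", "case"])
    ax.set_ylabel(metric)
    ax.set_xlim(-0.5, 1.5)
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": None})
    plt.close(fig)


def cohort_report(
    table: CohortTable,
    out_dir=None,
    interval_mode: str = "ci_mean",
    aggregate: str = "per_tooth",
    make_plots: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-metric control bands, classifications, and effect summaries.

    Returns ``(report, summary)``: *report* has one row per case
    observation (tooth by default, patient mean with
    ``aggregate='per_patient'``) with its classification against the
    control band; *summary* has one row per metric with the control
    mean ± SD and CI, case mean, fold change and percent change.  With
    ``out_dir`` the frames are written as ``report.csv``/``summary.csv``
    plus one dot plot per metric; regenerating from the same table is
    byte-identical.
    """
    if aggregate not in ("per_tooth", "per_patient"):
        raise ValueError("aggregate must be 'per_tooth' or 'per_patient'")
    out_rows, summary_rows = [], []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for metric in table.metrics:
        sub = table.frame[table.frame["metric"] == metric]
        ctrl = sub[sub["group"] == "control"]["value"]
        case = sub[sub["group"] == "case"]
        if len(ctrl) < 2 or len(case) == 0:
            warnings.warn(f"metric {metric!r} skipped: missing group data")
            continue
        interval = reference_interval(ctrl, metric=metric, mode=interval_mode)
        if aggregate == "per_patient":
            obs = case.groupby("patient", as_index=False)["value"].mean()
            obs["tooth"] = ""
        else:
            obs = case[["patient", "tooth", "value"]]
        for _, row in obs.iterrows():
            out_rows.append({
                "metric": metric,
                "patient": row["patient"],
                "tooth": row["tooth"],
                "value": row["value"],
                "control_mean": interval.mean,
                "ci_low": interval.ci_low,
                "ci_high": interval.ci_high,
                "classification": classify_within_limits(row["value"], interval),
            })
        case_mean = float(case["value"].mean())
        summary_rows.append({
            "metric": metric,
            "control_n": interval.n,
            "control_mean": interval.mean,
            "control_sd": interval.sd,
            "ci_low": interval.ci_low,
            "ci_high": interval.ci_high,
            "case_n": int(len(case)),
            "case_mean": case_mean,
            "fold_change": (fold_change(case_mean, interval.mean)
                            if interval.mean != 0 else np.nan),
            "percent_change": (percent_change(case_mean, interval.mean)
                               if interval.mean != 0 else np.nan),
        })
        if out_path is not None and make_plots:
            safe = "".join(c if c.isalnum() else "_" for c in metric)
            _plot_metric(sub, interval, metric, out_path / f"{safe}.png")

    report = pd.DataFrame(out_rows)
    summary = pd.DataFrame(summary_rows)
    if out_path is not None:
        report.to_csv(out_path / "report.csv", index=False)
        summary.to_csv(out_path / "summary.csv", index=False)
    return report, summary
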