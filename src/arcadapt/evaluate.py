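"""DVH metrics, clinical-goal checks and plan-vs-plan comparison tables.

Metric conventions are voxel-exact (no DVH interpolation): ``D_q%`` is the
largest dose d such that at least q % of the ROI's voxels receive >= d;
``D_vcc`` is the dose of the k-th hottest voxel with k = ceil(v / voxel volume
in cc).  Worst-case values are taken per metric over a scenario set: the
minimum over scenarios for goals of the form "metric > level" (coverage), the
maximum for "metric < level" (sparing).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .phantom import StructureSet

METRICS = ("D_q_percent", "D_max", "D_mean", "D_volume_cc")


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ClinicalGoal:
    roi: str
    metric: str                 # one of METRICS
    parameter: Optional[float]  # q in % for D_q_percent, v in cc for D_volume_cc
    comparator: str             # ">" or "<"
    level: float                # Gy

    def __post_init__(self):
        if self.metric not in METRICS:
            raise MetricError(f"unknown metric {self.metric!r}")
        if self.comparator not in (">", "<"):
            raise MetricError("comparator must be '>' or '<'")
        if self.level < 0:
            raise MetricError("goal level must be >= 0")
        if self.metric == "D_q_percent" and not (0.0 < (self.parameter or 0) < 100.0):
            raise MetricError("q must lie in (0, 100)")


def dose_metric(
    dose: np.ndarray,
    mask: np.ndarray,
    metric: str,
    parameter: Optional[float] = None,
    voxel_volume_cc: Optional[float] = None,
) -> float:
    """Evaluate one DVH metric of a dose grid over an ROI mask (Gy)."""
    if metric not in METRICS:
        raise MetricError(f"unknown metric {metric!r}")
    vals = np.asarray(dose)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise MetricError("ROI mask is empty")
    if metric == "D_max":
        return float(vals.max())
    if metric == "D_mean":
        return float(vals.mean())
    desc = np.sort(vals)[::-1]
    if metric == "D_q_percent":
        q = float(parameter)
        if not (0.0 < q < 100.0):
            raise MetricError("q must lie in (0, 100)")
        k = math.ceil(q / 100.0 * vals.size)
        return float(desc[k - 1])
    # D_volume_cc
    if voxel_volume_cc is None or voxel_volume_cc <= 0:
        raise MetricError("D_volume_cc requires the voxel volume in cc")
    k = min(math.ceil(float(parameter) / voxel_volume_cc), vals.size)
    return float(desc[k - 1])


def default_goals(
    structures: StructureSet,
    prescriptions: Mapping[str, float],
    oar_max_gy: float = 44.0,
    coverage_fraction: float = 0.95,
) -> List[ClinicalGoal]:
    """Prescription-relative goals: D98 > 95 % of prescription per target, plus
    an absolute max-dose cap on each serial OAR."""
    goals: List[ClinicalGoal] = []
    for name, role in structures.roles.items():
        if role in ("target_high", "target_low"):
            rx = prescriptions.get(role) or prescriptions.get(name)
            if rx:
                goals.append(
                    ClinicalGoal(name, "D_q_percent", 98.0, ">", coverage_fraction * float(rx))
                )
        elif role == "oar_serial":
            goals.append(ClinicalGoal(name, "D_max", None, "<", oar_max_gy))
    return goals


def _provenance(doses: Sequence[np.ndarray]) -> str:
    h = hashlib.sha256()
    for d in doses:
        h.update(np.ascontiguousarray(d, dtype=np.float64).tobytes())
    return h.hexdigest()[:16]


def clinical_goals_check(
    nominal_dose: np.ndarray,
    scenario_doses: Sequence[np.ndarray],
    structures: StructureSet,
    goals: Sequence[ClinicalGoal],
    voxel_volume_cc: Optional[float] = None,
    plan_id: str = "plan",
) -> pd.DataFrame:
    """Evaluate every goal on the nominal dose and the worst case over scenarios.

    ``scenario_doses`` may be empty, in which case the worst case equals the
    nominal.  Returns a long-format report with one row per goal.
    """
    if voxel_volume_cc is None:
        voxel_volume_cc = float(np.prod(structures.spacing)) / 1000.0
    all_doses = [nominal_dose] + list(scenario_doses)
    rows = []
    for goal in goals:
        if goal.roi not in structures.masks:
            raise MetricError(f"goal references unknown ROI {goal.roi!r}")
        mask = structures.masks[goal.roi]
        vals = [
            dose_metric(d, mask, goal.metric, goal.parameter, voxel_volume_cc)
            for d in all_doses
        ]
        nominal = vals[0]
        worst = min(vals) if goal.comparator == ">" else max(vals)
        passed = (nominal > goal.level) if goal.comparator == ">" else (nominal < goal.level)
        passed_worst = (worst > goal.level) if goal.comparator == ">" else (worst < goal.level)
        rows.append(
            {
                "plan": plan_id, "roi": goal.roi, "metric": goal.metric,
                "parameter": goal.parameter, "nominal": nominal, "worst": worst,
                "comparator": goal.comparator, "level": goal.level,
                "pass_nominal": bool(passed), "pass_worst": bool(passed_worst),
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["provenance"] = {"plan": plan_id, "dose_hash": _provenance(all_doses),
                                  "n_scenarios": len(scenario_doses)}
    return report


def metric_report(
    nominal_dose: np.ndarray,
    scenario_doses: Sequence[np.ndarray],
    structures: StructureSet,
    entries: Sequence[Tuple[str, str, Optional[float]]],
    voxel_volume_cc: Optional[float] = None,
    plan_id: str = "plan",
) -> pd.DataFrame:
    """Nominal and worst-case values for arbitrary (roi, metric, parameter) rows.

    Coverage-type metrics (D_q_percent) take the scenario minimum as worst
    case; max/mean/volume metrics take the maximum.
    """
    if voxel_volume_cc is None:
        voxel_volume_cc = float(np.prod(structures.spacing)) / 1000.0
    all_doses = [nominal_dose] + list(scenario_doses)
    rows = []
    for roi, metric, parameter in entries:
        mask = structures.masks[roi]
        vals = [dose_metric(d, mask, metric, parameter, voxel_volume_cc) for d in all_doses]
        worst = min(vals) if metric == "D_q_percent" else max(vals)
        rows.append(
            {"plan": plan_id, "roi": roi, "metric": metric, "parameter": parameter,
             "nominal": vals[0], "worst": worst}
        )
    return pd.DataFrame(rows)


_KEY = ["roi", "metric", "parameter"]


def compare_plans(report_a: pd.DataFrame, report_b: pd.DataFrame) -> pd.DataFrame:
    """Signed per-metric differences (a - b, Gy) on nominal and worst columns."""
    a = report_a.set_index(_KEY).sort_index()
    b = report_b.set_index(_KEY).sort_index()
    if not a.index.equals(b.index):
        only_a = a.index.difference(b.index).tolist()
        only_b = b.index.difference(a.index).tolist()
        raise MetricError(f"metric keys differ: only in a={only_a}, only in b={only_b}")
    out = pd.DataFrame(index=a.index)
    for col in ("nominal", "worst"):
        if col in a.columns and col in b.columns:
            out[f"delta_{col}"] = a[col] - b[col]
    return out.reset_index()


def summarize_differences(diffs: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Median and [min, max] range of per-case differences across a batch."""
    stacked = pd.concat(diffs, ignore_index=True)
    cols = [c for c in stacked.columns if c.startswith("delta_")]
    agg = stacked.groupby(_KEY, dropna=False)[cols].agg(["median", "min", "max"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
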