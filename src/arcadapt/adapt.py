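"""Geometric plan adaptation: move spots onto the new anatomy while preserving
the initial energy-layer pattern.

The adaptation runs in three steps.  First, each spot's Bragg-peak position is
retrieved on the initial grid ("CT1") and pushed through the displacement field
onto the anatomy of the day ("CT2").  Second, the displaced positions are
converted back to beam-eye-view coordinates and the energy required to reach
each displaced depth is recomputed by raytracing CT2.  Third, because spots of
a cluster (one energy layer at one control point of the initial plan) may now
require different energies, each cluster is forced back to a single energy: the
median of its members' updated energies, snapped to the machine list — unless
that median would introduce an energy *switch-up* (an increase between
consecutive entries of the delivery-order pattern) at a position where the
initial pattern has none, in which case the cluster inherits the previous
cluster's already-enforced energy.  The adapted pattern's switch-up positions
are therefore always a subset of the initial ones.  Spot weights are never
touched here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dose import RangeEnergyModel, beam_basis, trace_rays
from .phantom import DeformationField, VoxelGrid
from .plan import ArcPlan, ControlPoint, EnergyPattern, snap_energy, switch_up_angles

logger = logging.getLogger(__name__)


class AdaptationError(RuntimeError):
    """More than half of the spots could not be adapted cleanly."""


class ClusterOrderError(ValueError):
    """Cluster list inconsistent with the initial energy pattern."""


@dataclass
class SpotPosition:
    spot_id: int
    xyz: np.ndarray  # mm, patient system
    stage: str       # "ct1" | "ct2"

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"spot {self.spot_id}: non-finite position")


@dataclass
class ClusterEnergyUpdate:
    cluster_id: int
    spot_ids: List[int]
    updated_energies: List[float]  # per-spot raytraced energies, MeV (unsnapped)
    median_energy: float           # cluster median, MeV (snapped)
    assigned_energy: float         # after switch-up enforcement


@dataclass
class AdaptationReport:
    """Per-spot flags raised while adapting (clamped energies, lost rays...)."""

    flags: Dict[int, List[str]] = field(default_factory=dict)
    n_spots: int = 0

    def flag(self, spot_id: int, reason: str) -> None:
        self.flags.setdefault(spot_id, []).append(reason)

    @property
    def n_flagged(self) -> int:
        return len(self.flags)

    @property
    def flagged_fraction(self) -> float:
        return self.n_flagged / self.n_spots if self.n_spots else 0.0

    def to_records(self) -> List[dict]:
        return [
            {"spot_id": sid, "flags": ";".join(reasons)}
            for sid, reasons in sorted(self.flags.items())
        ]


# ---------------------------------------------------------------------------
# BEV transform
# ---------------------------------------------------------------------------

def bev_transform(
    position,
    gantry_angle_deg: float,
    isocenter,
    direction: str = "patient_to_bev",
):
    """Rotate between the patient system and beam-eye-view coordinates.

    The beam axis for gantry angle t is ``u = (sin t, cos t, 0)`` (rotation
    about the patient z axis through the isocenter); ``y_bev`` is the patient z
    axis and ``x_bev = u x z``.  ``patient_to_bev`` maps a world point to
    ``(x_bev, y_bev, depth_along_axis)``; ``bev_to_patient`` inverts it.
    """
    a = gantry_angle_deg % 360.0
    if a != gantry_angle_deg:
        logger.debug("gantry angle %s normalized to %s", gantry_angle_deg, a)
    u, ex, ez = beam_basis(a)
    iso = np.asarray(isocenter, dtype=float)
    p = np.asarray(position, dtype=float)
    if direction == "patient_to_bev":
        d = p - iso
        return float(d @ ex), float(d @ ez), float(d @ u)
    if direction == "bev_to_patient":
        x_bev, y_bev, depth = p
        return iso + x_bev * ex + y_bev * ez + depth * u
    raise ValueError(f"direction must be patient_to_bev|bev_to_patient, got {direction!r}")


# ---------------------------------------------------------------------------
# Step 1: displacement of Bragg positions
# ---------------------------------------------------------------------------

def displace_spot_bragg_positions(
    plan: ArcPlan,
    grid: VoxelGrid,
    fld: DeformationField,
    model: RangeEnergyModel = RangeEnergyModel(),
    step: Optional[float] = None,
    report: Optional[AdaptationReport] = None,
) -> Dict[int, SpotPosition]:
    """Bragg-peak positions on CT1, pushed through the field onto CT2.

    Spots whose CT1 range overshoots the grid or whose peak lies outside the
    field support are flagged in the report (position falls back to the deepest
    reachable point); spots are never dropped.
    """
    if report is None:
        report = AdaptationReport()
    report.n_spots = max(report.n_spots, len(plan.spots))
    angles = {cp.index: cp.gantry_angle_deg for cp in plan.control_points}
    positions: Dict[int, SpotPosition] = {}
    # batch rays per control point (shared direction)
    by_cp: Dict[int, List] = {}
    for s in plan.spots:
        by_cp.setdefault(s.control_point_index, []).append(s)
    for cp_idx, spots in by_cp.items():
        ang = angles[cp_idx]
        u, ex, ez = beam_basis(ang)
        origins = np.stack(
            [plan.isocenter + s.x_bev * ex + s.y_bev * ez for s in spots]
        )
        bundle = trace_rays(grid, origins, u, step)
        ranges = np.array([float(model.range_mm(s.energy)) for s in spots])
        totals = bundle.total_wepl()
        s_peak = bundle.s_at_wepl(ranges)
        for i, s in enumerate(spots):
            if not bundle.valid[i]:
                report.flag(s.id, "ray_misses_grid")
                positions[s.id] = SpotPosition(s.id, origins[i], "ct2")
                continue
            if ranges[i] > totals[i] + 1e-9:
                report.flag(s.id, "ct1_overshoot")
            p1 = bundle.point(i, float(s_peak[i]))
            if not fld.contains(p1[None, :])[0]:
                report.flag(s.id, "outside_field_support")
                disp = np.zeros(3)
            else:
                disp = fld.sample(p1)
            positions[s.id] = SpotPosition(s.id, p1 + disp, "ct2")
    return positions


# ---------------------------------------------------------------------------
# Step 2a: required energies on the new anatomy
# ---------------------------------------------------------------------------

def required_energies(
    positions: Dict[int, SpotPosition],
    grid2: VoxelGrid,
    plan: ArcPlan,
    model: RangeEnergyModel = RangeEnergyModel(),
    step: Optional[float] = None,
    report: Optional[AdaptationReport] = None,
) -> Dict[int, float]:
    """Energy needed to place each spot's Bragg peak at its displaced position.

    The spot's new central ray runs through the displaced position at its
    control point's gantry angle; the energy is the range-law inverse of the
    WEPL accumulated from the grid entry to that position.  Energies outside
    the machine interval are clamped and flagged.
    """
    if report is None:
        report = AdaptationReport()
    report.n_spots = max(report.n_spots, len(plan.spots))
    angles = {cp.index: cp.gantry_angle_deg for cp in plan.control_points}
    by_cp: Dict[int, List] = {}
    for s in plan.spots:
        by_cp.setdefault(s.control_point_index, []).append(s)
    energies: Dict[int, float] = {}
    rmin = float(model.range_mm(model.energy_min))
    rmax = float(model.range_mm(model.energy_max))
    for cp_idx, spots in by_cp.items():
        ang = angles[cp_idx]
        u, ex, ez = beam_basis(ang)
        pts = np.stack([positions[s.id].xyz for s in spots])
        rel = pts - plan.isocenter
        xb, yb = rel @ ex, rel @ ez
        origins = plan.isocenter + xb[:, None] * ex + yb[:, None] * ez
        bundle = trace_rays(grid2, origins, u, step)
        entry = bundle.entry_points()
        s_target = np.einsum("ij,j->i", pts - entry, u)
        for i, s in enumerate(spots):
            if not bundle.valid[i]:
                report.flag(s.id, "ct2_ray_misses_grid")
                energies[s.id] = float(model.energy_min)
                continue
            if s_target[i] < 0:
                report.flag(s.id, "behind_entry_surface")
                energies[s.id] = float(model.energy_min)
                continue
            w = float(np.interp(s_target[i], bundle.s[i], bundle.wepl[i]))
            if w < rmin:
                report.flag(s.id, "clamped_to_energy_min")
                energies[s.id] = float(model.energy_min)
            elif w > rmax:
                report.flag(s.id, "clamped_to_energy_max")
                energies[s.id] = float(model.energy_max)
            else:
                energies[s.id] = float(model.energy_mev(w))
    return energies


# ---------------------------------------------------------------------------
# Step 2b: cluster-median energies under the switch-up rule
# ---------------------------------------------------------------------------

def _lower_median(values: Sequence[float]) -> float:
    v = sorted(values)
    return v[(len(v) - 1) // 2]


def adapt_cluster_energies(
    cluster_energies: Sequence[Sequence[float]],
    initial_pattern: EnergyPattern,
    machine_energies: np.ndarray,
) -> Tuple[List[ClusterEnergyUpdate], EnergyPattern]:
    """Force each cluster to one energy while preserving the switch-up pattern.

    ``cluster_energies[c]`` holds the updated member energies of cluster ``c``,
    ordered exactly as the initial pattern's entries.  The cluster median (lower
    middle value for even counts) is snapped to the nearest machine energy
    (ties toward the lower energy).  Scanning clusters in delivery order, an
    energy increase relative to the previous cluster's *enforced* energy is
    only accepted where the initial pattern itself has a switch-up; elsewhere
    the cluster is flattened to the previous assignment, so a run of illegal
    increases collapses onto one plateau.
    """
    if len(cluster_energies) != len(initial_pattern):
        raise ClusterOrderError(
            f"{len(cluster_energies)} clusters vs {len(initial_pattern)} pattern entries"
        )
    for c, members in enumerate(cluster_energies):
        if len(members) == 0:
            raise ClusterOrderError(f"cluster {c} is empty")
    allowed_ups = switch_up_angles(initial_pattern)
    updates: List[ClusterEnergyUpdate] = []
    assigned_prev = None
    entries: List[Tuple[int, float]] = []
    for c, members in enumerate(cluster_energies):
        med = snap_energy(_lower_median(members), machine_energies)
        if c == 0:
            assigned = med
        elif med > assigned_prev and c not in allowed_ups:
            assigned = assigned_prev
        else:
            assigned = med
        updates.append(
            ClusterEnergyUpdate(
                cluster_id=c, spot_ids=[], updated_energies=list(members),
                median_energy=med, assigned_energy=assigned,
            )
        )
        entries.append((initial_pattern.entries[c][0], assigned))
        assigned_prev = assigned
    return updates, EnergyPattern(entries)


# ---------------------------------------------------------------------------
# full geometric adaptation
# ---------------------------------------------------------------------------

def geometric_adapt(
    plan1: ArcPlan,
    grid1: VoxelGrid,
    grid2: VoxelGrid,
    fld: DeformationField,
    model: RangeEnergyModel = RangeEnergyModel(),
    step: Optional[float] = None,
    hard_fail_fraction: float = 0.5,
    warn_fraction: float = 0.05,
) -> Tuple[ArcPlan, AdaptationReport]:
    """Steps 1-2 composed: displaced positions, refreshed BEV coordinates,
    cluster energies enforced against the initial pattern; weights untouched.
    """
    plan1.validate()
    if not grid1.same_lattice(grid2):
        logger.info("CT1 and CT2 lattices differ; adaptation proceeds in world space")
    report = AdaptationReport(n_spots=len(plan1.spots))
    positions = displace_spot_bragg_positions(plan1, grid1, fld, model, step, report)
    energies = required_energies(positions, grid2, plan1, model, step, report)

    pattern1 = plan1.energy_pattern()
    clusters = plan1.spots_by_cluster()
    if set(clusters) - set(range(len(pattern1))):
        raise ClusterOrderError("spot cluster ids exceed the initial pattern length")
    cluster_members: List[List[float]] = []
    member_ids: List[List[int]] = []
    for c in range(len(pattern1)):
        spots_c = clusters.get(c, [])
        if spots_c:
            cluster_members.append([energies[s.id] for s in spots_c])
            member_ids.append([s.id for s in spots_c])
        else:
            # layer with no spots: carry its initial energy through unchanged
            cluster_members.append([pattern1.entries[c][1]])
            member_ids.append([])
    updates, pattern2 = adapt_cluster_energies(cluster_members, pattern1, plan1.machine_energies)
    for upd, ids in zip(updates, member_ids):
        upd.spot_ids = ids

    assigned = {u.cluster_id: u.assigned_energy for u in updates}
    angles = {cp.index: cp.gantry_angle_deg for cp in plan1.control_points}
    new_spots = []
    for s in plan1.spots:
        xb, yb, _depth = bev_transform(
            positions[s.id].xyz, angles[s.control_point_index], plan1.isocenter
        )
        new_spots.append(
            replace(s, x_bev=xb, y_bev=yb, energy=assigned[s.cluster_id])
        )
    new_cps = []
    for cp in plan1.control_points:
        layers = [e for i, e in pattern2.entries if i == cp.index]
        new_cps.append(ControlPoint(index=cp.index, gantry_angle_deg=cp.gantry_angle_deg,
                                    layers=layers))
    plan2 = ArcPlan(
        control_points=new_cps, spots=new_spots, isocenter=plan1.isocenter.copy(),
        machine_energies=plan1.machine_energies.copy(),
        prescriptions=dict(plan1.prescriptions),
    )
    plan2.validate()

    frac = report.flagged_fraction
    if frac > hard_fail_fraction:
        raise AdaptationError(
            f"{report.n_flagged}/{report.n_spots} spots flagged "
            f"({frac:.0%} > {hard_fail_fraction:.0%}); adaptation aborted"
        )
    if frac > warn_fraction:
        logger.warning("geometric adaptation flagged %.1f%% of spots", 100 * frac)

    ups1, ups2 = switch_up_angles(pattern1), switch_up_angles(pattern2)
    assert ups2 <= ups1, "pattern preservation violated (internal error)"
    return plan2, report
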