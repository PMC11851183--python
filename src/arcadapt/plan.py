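"""Arc-plan data model, initial plan construction and serialization.

A proton-arc plan is an ordered list of control points (gantry angles) with
per-control-point energy layers, and a flat list of spots.  Each spot carries
the state quadruplet (x_bev, y_bev, E, w) plus the cluster it belongs to; a
"cluster" is the set of spots sharing one energy layer at one control point on
the initial plan, and clusters are indexed by their position in the flattened
delivery-order layer sequence (the *energy pattern*).

The delivery order is increasing gantry angle from 0 degrees; "consecutive
angles" in the switch-up logic means consecutive entries of the flattened
pattern.  A *switch-up* is an increase of energy between two consecutive
pattern entries — slow to deliver on real machines (magnet hysteresis), hence
budgeted at sequencing time and preserved during adaptation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .dose import RangeEnergyModel, beam_basis, trace_rays
from .phantom import StructureSet, VoxelGrid

logger = logging.getLogger(__name__)

PLAN_SCHEMA_VERSION = 1


class PlanValidationError(ValueError):
    def __init__(self, field_name: str, msg: str):
        super().__init__(f"{field_name}: {msg}")
        self.field_name = field_name


class ParameterError(ValueError):
    pass


def default_machine_energies() -> np.ndarray:
    """Machine energy list: 70-230 MeV in 2 MeV steps."""
    return np.arange(70.0, 230.0 + 1e-9, 2.0)


def snap_energy(energy: float, machine_energies: np.ndarray) -> float:
    """Nearest machine energy; ties resolved toward the lower energy."""
    me = np.asarray(machine_energies, dtype=float)
    d = np.abs(me - energy)
    best = d.min()
    return float(me[np.nonzero(d <= best + 1e-9)[0][0]])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Spot:
    id: int
    control_point_index: int
    x_bev: float
    y_bev: float
    energy: float
    weight: float
    cluster_id: int

    def __post_init__(self):
        if self.weight < 0:
            raise PlanValidationError("weight", f"spot {self.id} has weight {self.weight} < 0")


@dataclass
class ControlPoint:
    index: int
    gantry_angle_deg: float
    layers: List[float] = field(default_factory=list)  # MeV, delivery order

    def __post_init__(self):
        if not (0.0 <= self.gantry_angle_deg < 360.0):
            raise PlanValidationError(
                "gantry_angle_deg", f"angle {self.gantry_angle_deg} outside [0, 360)"
            )


@dataclass
class EnergyPattern:
    """Flattened delivery-order sequence of (control point index, layer energy)."""

    entries: List[Tuple[int, float]]

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for _, e in self.entries], dtype=float)

    @property
    def switch_up_indices(self) -> Set[int]:
        return switch_up_angles(self)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, EnergyPattern) and self.entries == other.entries


def switch_up_angles(pattern: EnergyPattern) -> Set[int]:
    """Delivery-order indices where the energy strictly increases."""
    e = pattern.energies
    return {int(i) for i in range(1, e.size) if e[i] > e[i - 1]}


@dataclass
class ArcPlan:
    control_points: List[ControlPoint]
    spots: List[Spot]
    isocenter: np.ndarray
    machine_energies: np.ndarray
    prescriptions: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.isocenter = np.asarray(self.isocenter, dtype=float).reshape(3)
        self.machine_energies = np.asarray(self.machine_energies, dtype=float)

    def validate(self) -> None:
        angles = [cp.gantry_angle_deg for cp in self.control_points]
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise PlanValidationError("gantry_angle_deg", "angles must strictly increase")
        layers_of = {cp.index: cp.layers for cp in self.control_points}
        me = self.machine_energies
        for s in self.spots:
            if s.control_point_index not in layers_of:
                raise PlanValidationError(
                    "control_point_index", f"spot {s.id} references unknown control point"
                )
            if not np.any(np.abs(me - s.energy) < 1e-6):
                raise PlanValidationError(
                    "energy", f"spot {s.id} energy {s.energy} MeV is not a machine energy"
                )
            if not any(abs(l - s.energy) < 1e-6 for l in layers_of[s.control_point_index]):
                raise PlanValidationError(
                    "energy",
                    f"spot {s.id} energy {s.energy} not among control point "
                    f"{s.control_point_index} layers",
                )
            if s.weight < 0:
                raise PlanValidationError("weight", f"spot {s.id} has negative weight")

    def energy_pattern(self) -> EnergyPattern:
        entries = [
            (cp.index, float(e)) for cp in self.control_points for e in cp.layers
        ]
        return EnergyPattern(entries)

    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.spots], dtype=float)

    def with_weights(self, w: np.ndarray) -> "ArcPlan":
        if len(w) != len(self.spots):
            raise PlanValidationError("weight", "weight vector length mismatch")
        spots = [replace(s, weight=float(wi)) for s, wi in zip(self.spots, w)]
        return ArcPlan(
            control_points=[replace(cp, layers=list(cp.layers)) for cp in self.control_points],
            spots=spots, isocenter=self.isocenter.copy(),
            machine_energies=self.machine_energies.copy(),
            prescriptions=dict(self.prescriptions),
        )

    def spots_by_cluster(self) -> Dict[int, List[Spot]]:
        out: Dict[int, List[Spot]] = {}
        for s in self.spots:
            out.setdefault(s.cluster_id, []).append(s)
        return out


# ---------------------------------------------------------------------------
# spot grid construction
# ---------------------------------------------------------------------------

def _dilated_target(structures: StructureSet, grid: VoxelGrid, margin_mm: float) -> np.ndarray:
    target = structures.target_union()
    if not target.any():
        raise PlanValidationError("target", "structure set has no target voxels")
    if margin_mm <= 0:
        return target
    dist = ndimage.distance_transform_edt(~target, sampling=grid.spacing)
    return dist <= margin_mm


def hexagonal_positions(
    points_2d: np.ndarray, spacing_mm: float, tol_mm: float
) -> np.ndarray:
    """Hexagonal lattice covering a 2-D point cloud (kept within tol of a point).

    The lattice is anchored at the BEV origin rather than at the cloud's
    bounding box, so a larger cloud (e.g. a larger target margin) always keeps
    a superset of the positions kept for a smaller one.
    """
    if points_2d.size == 0:
        return np.zeros((0, 2))
    row_h = spacing_mm * math.sqrt(3.0) / 2.0
    xmin, ymin = points_2d.min(axis=0) - spacing_mm
    xmax, ymax = points_2d.max(axis=0) + spacing_mm
    tree = cKDTree(points_2d)
    out = []
    for j in range(int(np.floor(ymin / row_h)), int(np.ceil(ymax / row_h)) + 1):
        y = j * row_h
        xoff = (abs(j) % 2) * spacing_mm / 2.0
        ks = np.arange(np.floor((xmin - xoff) / spacing_mm),
                       np.ceil((xmax - xoff) / spacing_mm) + 1)
        xs = ks * spacing_mm + xoff
        pts = np.column_stack([xs, np.full(xs.size, y)])
        d, _ = tree.query(pts)
        out.append(pts[d <= tol_mm])
    return np.concatenate(out, axis=0) if out else np.zeros((0, 2))


def _scan_control_point(
    grid: VoxelGrid,
    target_dil: np.ndarray,
    angle_deg: float,
    positions: np.ndarray,
    isocenter: np.ndarray,
    model: RangeEnergyModel,
    step: Optional[float] = None,
):
    """Trace every lateral position of a control point through the grid.

    Returns the ray bundle plus, per position, the WEPL window [w_in, w_out]
    over which the ray runs inside the dilated target (NaN when it misses) and
    the per-sample in-target flags.
    """
    u, ex, ez = beam_basis(angle_deg)
    origins = isocenter + positions[:, 0, None] * ex + positions[:, 1, None] * ez
    bundle = trace_rays(grid, origins, u, step)
    tgt = VoxelGrid(
        values=target_dil.astype(np.float32), spacing=grid.spacing, origin=grid.origin
    )
    n, m = bundle.rsp.shape
    k = (np.arange(m) + 0.5) * bundle.step
    pts = bundle.origins[:, None, :] + (
        bundle.entry_t[:, None] + k[None, :]
    )[:, :, None] * bundle.direction
    ci = tgt.world_to_index(pts.reshape(-1, 3)).T
    inside = ndimage.map_coordinates(
        tgt.values, ci, order=0, mode="constant", cval=0.0
    ).reshape(n, m) > 0.5
    w_mid = (bundle.wepl[:, :-1] + bundle.wepl[:, 1:]) / 2.0
    w_in = np.full(n, np.nan)
    w_out = np.full(n, np.nan)
    for i in range(n):
        hits = np.nonzero(inside[i])[0]
        if hits.size:
            w_in[i] = w_mid[i, hits[0]]
            w_out[i] = w_mid[i, hits[-1]]
    return bundle, w_in, w_out, inside


def candidate_energies_per_control_point(
    structures: StructureSet,
    grid: VoxelGrid,
    control_points: Sequence[ControlPoint],
    lateral_spacing_mm: float,
    margin_mm: float,
    isocenter: np.ndarray,
    model: RangeEnergyModel,
    machine_energies: np.ndarray,
    step: Optional[float] = None,
):
    """Per control point: hex positions and machine energies whose Bragg depth
    can land inside the margin-dilated target for at least one position."""
    target_dil = _dilated_target(structures, grid, margin_mm)
    vox_idx = np.argwhere(target_dil)
    vox_world = grid.index_to_world(vox_idx)
    tol = float(max(grid.spacing)) * 0.87 + 1e-9
    per_cp = []
    ranges = np.asarray([float(model.range_mm(e)) for e in machine_energies])
    for cp in control_points:
        u, ex, ez = beam_basis(cp.gantry_angle_deg)
        rel = vox_world - isocenter
        proj = np.column_stack([rel @ ex, rel @ ez])
        positions = hexagonal_positions(proj, lateral_spacing_mm, tol)
        if positions.size == 0:
            per_cp.append((positions, []))
            continue
        bundle, w_in, w_out, _ = _scan_control_point(
            grid, target_dil, cp.gantry_angle_deg, positions, isocenter, model, step
        )
        ok = np.isfinite(w_in)
        if not ok.any():
            per_cp.append((positions, []))
            continue
        cand = [
            float(machine_energies[e])
            for e in range(machine_energies.size)
            if np.any((ranges[e] >= w_in[ok]) & (ranges[e] <= w_out[ok]))
        ]
        per_cp.append((positions, cand))
    return per_cp, target_dil


def sequence_energy_layers(
    candidates_per_cp: Sequence[Sequence[float]], max_switch_ups: int
) -> EnergyPattern:
    """Sector heuristic for initial energy-layer sequencing.

    The arc is partitioned into at most ``max_switch_ups + 1`` contiguous
    angular sectors; within each sector the union of candidate energies is
    delivered in strictly descending order, distributed over the sector's
    control points.  Energy increases can therefore occur only at sector
    boundaries, so the switch-up budget holds by construction.
    """
    if max_switch_ups < 0:
        raise ParameterError("max_switch_ups must be >= 0")
    n_cp = len(candidates_per_cp)
    n_sectors = min(max_switch_ups + 1, max(n_cp, 1))
    sector_cps = np.array_split(np.arange(n_cp), n_sectors)
    entries: List[Tuple[int, float]] = []
    for cps in sector_cps:
        cps = [c for c in cps if len(candidates_per_cp[c]) > 0]
        if not cps:
            continue
        union = sorted({float(e) for c in cps for e in candidates_per_cp[c]}, reverse=True)
        n_e, n_c = len(union), len(cps)
        if n_e >= n_c:
            chunks = np.array_split(np.asarray(union), n_c)
            for c, chunk in zip(cps, chunks):
                entries.extend((int(c), float(e)) for e in chunk)
        else:
            for j, c in enumerate(cps):
                entries.append((int(c), union[(j * n_e) // n_c]))
    return EnergyPattern(entries)


def build_arc_spot_grid(
    structures: StructureSet,
    grid: VoxelGrid,
    control_points: Sequence[ControlPoint],
    lateral_spacing_mm: float,
    margin_mm: float,
    isocenter: np.ndarray,
    model: RangeEnergyModel,
    pattern: EnergyPattern,
    step: Optional[float] = None,
) -> List[Spot]:
    """One spot per (hex BEV position, energy layer) whose Bragg depth lies
    inside the margin-dilated target along the ray."""
    if lateral_spacing_mm <= 0:
        raise ParameterError("lateral spacing must be > 0")
    target_dil = _dilated_target(structures, grid, margin_mm)
    vox_world = grid.index_to_world(np.argwhere(target_dil))
    tol = float(max(grid.spacing)) * 0.87 + 1e-9
    layers_at: Dict[int, List[Tuple[int, float]]] = {}
    for cl_id, (cp_idx, e) in enumerate(pattern.entries):
        layers_at.setdefault(cp_idx, []).append((cl_id, e))
    spots: List[Spot] = []
    sid = 0
    for cp in control_points:
        if cp.index not in layers_at:
            continue
        u, ex, ez = beam_basis(cp.gantry_angle_deg)
        rel = vox_world - isocenter
        proj = np.column_stack([rel @ ex, rel @ ez])
        positions = hexagonal_positions(proj, lateral_spacing_mm, tol)
        if positions.size == 0:
            continue
        bundle, w_in, w_out, _ = _scan_control_point(
            grid, target_dil, cp.gantry_angle_deg, positions, isocenter, model, step
        )
        for cl_id, energy in layers_at[cp.index]:
            r = float(model.range_mm(energy))
            hit = np.isfinite(w_in) & (r >= w_in) & (r <= w_out)
            for i in np.nonzero(hit)[0]:
                spots.append(
                    Spot(
                        id=sid, control_point_index=cp.index,
                        x_bev=float(positions[i, 0]), y_bev=float(positions[i, 1]),
                        energy=float(energy), weight=1.0, cluster_id=cl_id,
                    )
                )
                sid += 1
    return spots


def make_initial_plan(
    structures: StructureSet,
    grid: VoxelGrid,
    n_control_points: int = 36,
    lateral_spacing_mm: float = 6.0,
    margin_mm: float = 4.0,
    max_switch_ups: int = 4,
    model: RangeEnergyModel = RangeEnergyModel(),
    machine_energies: Optional[np.ndarray] = None,
    prescriptions: Optional[Dict[str, float]] = None,
    isocenter: Optional[Sequence[float]] = None,
    step: Optional[float] = None,
) -> ArcPlan:
    """Construct a single-arc plan: hex spot grid, sector-sequenced layers,
    unit weights (to be set by the optimizer)."""
    if machine_energies is None:
        machine_energies = default_machine_energies()
    if isocenter is None:
        targets = structures.by_role("target_high")
        m = next(iter(targets.values())) if targets else structures.target_union()
        idx = np.argwhere(m)
        isocenter = grid.index_to_world(idx.mean(axis=0))
    isocenter = np.asarray(isocenter, dtype=float)
    angles = np.arange(n_control_points) * (360.0 / n_control_points)
    control_points = [ControlPoint(index=i, gantry_angle_deg=float(a)) for i, a in enumerate(angles)]
    per_cp, _ = candidate_energies_per_control_point(
        structures, grid, control_points, lateral_spacing_mm, margin_mm,
        isocenter, model, machine_energies, step,
    )
    pattern = sequence_energy_layers([c for _, c in per_cp], max_switch_ups)
    for cp in control_points:
        cp.layers = [e for i, e in pattern.entries if i == cp.index]
    spots = build_arc_spot_grid(
        structures, grid, control_points, lateral_spacing_mm, margin_mm,
        isocenter, model, pattern, step,
    )
    plan = ArcPlan(
        control_points=control_points, spots=spots, isocenter=isocenter,
        machine_energies=machine_energies,
        prescriptions=dict(prescriptions or {}),
    )
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# plan serialization
# ---------------------------------------------------------------------------

_SPOT_FIELDS = ("id", "control_point_index", "x_bev", "y_bev", "energy", "weight", "cluster_id")


def write_plan(plan: ArcPlan, path) -> None:
    plan.validate()
    doc = {
        "version": PLAN_SCHEMA_VERSION,
        "isocenter": [float(x) for x in plan.isocenter],
        "machine_energies": [float(e) for e in plan.machine_energies],
        "prescriptions": {k: float(v) for k, v in plan.prescriptions.items()},
        "control_points": [
            {
                "index": cp.index,
                "gantry_angle_deg": cp.gantry_angle_deg,
                "layers": [float(e) for e in cp.layers],
            }
            for cp in plan.control_points
        ],
        "spots": [
            {f: getattr(s, f) for f in _SPOT_FIELDS} for s in plan.spots
        ],
    }
    with open(path, "w") as f:
        json.dump(doc, f, indent=1)


def read_plan(path) -> ArcPlan:
    with open(path) as f:
        doc = json.load(f)
    if doc.get("version") != PLAN_SCHEMA_VERSION:
        raise PlanValidationError("version", f"unsupported schema version {doc.get('version')}")
    for key in ("isocenter", "machine_energies", "control_points", "spots"):
        if key not in doc:
            raise PlanValidationError(key, "missing required field")
    spots = []
    for rec in doc["spots"]:
        for f in _SPOT_FIELDS:
            if f not in rec:
                raise PlanValidationError(f, f"spot record missing field {f!r}")
        spots.append(Spot(**{f: rec[f] for f in _SPOT_FIELDS}))
    cps = [
        ControlPoint(
            index=r["index"], gantry_angle_deg=r["gantry_angle_deg"],
            layers=list(r.get("layers", [])),
        )
        for r in doc["control_points"]
    ]
    plan = ArcPlan(
        control_points=cps, spots=spots,
        isocenter=np.asarray(doc["isocenter"], dtype=float),
        machine_energies=np.asarray(doc["machine_energies"], dtype=float),
        prescriptions={k: float(v) for k, v in doc.get("prescriptions", {}).items()},
    )
    plan.validate()
    return plan
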