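"""Spot selection and restricted weight re-optimization with a frozen
background dose.

The adaptation's fourth step re-optimizes only a subset S of spot weights.  S
is chosen by two criteria applied in sequence: (1) the smallest set of spots
carrying at least a fraction ``p`` of the total initial weight (spots with tiny
weights have noisy beamlets and are poor re-optimization handles); (2) among
those, the spots whose objective-function derivative with respect to their
weight exceeds a threshold ``t``.  The remaining (discarded) spots keep their
initial weights and contribute a fixed background dose, so the optimized total
dose is  TD = w_d,1 · D_d  +  w_s · D_s  with the first term precomputed once
per scenario.

The objective is a weighted sum of one-sided quadratic dose penalties
(min/max/mean dose per ROI), each term mean-normalized over its ROI; terms
flagged robust take the worst (maximum) value over a set of setup-shift /
range-scaling scenarios.  The optimizer is projected gradient descent with an
Armijo backtracking line search and a warm-started step, which guarantees a
non-increasing objective trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy import sparse

from .dose import DoseInfluenceMatrix
from .phantom import StructureSet

logger = logging.getLogger(__name__)

TERM_KINDS = ("min_dose", "max_dose", "mean_dose")


class SelectionError(ValueError):
    pass


class ObjectiveSpecError(ValueError):
    pass


class OptimizerError(RuntimeError):
    """An accepted step increased the objective (impossible by construction)."""


# ---------------------------------------------------------------------------
# objective specification and scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObjectiveTerm:
    roi: str
    kind: str           # min_dose | max_dose | mean_dose
    dose_level: float   # Gy
    weight: float       # penalty weight lambda >= 0
    robust: bool = False

    def __post_init__(self):
        if self.kind not in TERM_KINDS:
            raise ObjectiveSpecError(f"unknown term kind {self.kind!r}")
        if self.dose_level < 0 or self.weight < 0:
            raise ObjectiveSpecError("dose_level and weight must be >= 0")


@dataclass
class ObjectiveSpec:
    terms: List[ObjectiveTerm]

    def __post_init__(self):
        if not self.terms:
            raise ObjectiveSpecError("objective needs at least one term")


@dataclass
class ScenarioSet:
    """Setup-shift / range-scaling error scenarios; scenario 0 is nominal."""

    scenarios: List[Tuple[Tuple[float, float, float], float]]

    def __post_init__(self):
        if not self.scenarios:
            raise ValueError("scenario set may not be empty")
        shift0, scale0 = self.scenarios[0]
        if any(abs(x) > 1e-12 for x in shift0) or abs(scale0 - 1.0) > 1e-12:
            raise ValueError("scenario 0 must be the nominal ((0,0,0), 1.0)")
        if any(scale <= 0 for _, scale in self.scenarios):
            raise ValueError("range scale factors must be > 0")

    def __len__(self) -> int:
        return len(self.scenarios)

    @classmethod
    def nominal_only(cls) -> "ScenarioSet":
        return cls([((0.0, 0.0, 0.0), 1.0)])

    @classmethod
    def default_robust(cls, setup_mm: float = 4.0, range_error: float = 0.026) -> "ScenarioSet":
        """Nominal + 6 single-axis setup shifts + 2 range scalings (9 scenarios)."""
        scen: List[Tuple[Tuple[float, float, float], float]] = [((0.0, 0.0, 0.0), 1.0)]
        for a in range(3):
            for sgn in (+1.0, -1.0):
                shift = [0.0, 0.0, 0.0]
                shift[a] = sgn * setup_mm
                scen.append((tuple(shift), 1.0))
        scen.append(((0.0, 0.0, 0.0), 1.0 + range_error))
        scen.append(((0.0, 0.0, 0.0), 1.0 - range_error))
        return cls(scen)


@dataclass(frozen=True)
class SelectionConfig:
    """Two-criteria selection parameters (defaults are the study's values)."""

    p_weight_fraction: float = 0.65
    t_gradient_threshold: float = 3.0
    gradient_mode: str = "magnitude"  # magnitude | signed

    def __post_init__(self):
        if not (0.0 < self.p_weight_fraction <= 1.0):
            raise ValueError("p_weight_fraction must lie in (0, 1]")
        if self.t_gradient_threshold < 0:
            raise ValueError("t_gradient_threshold must be >= 0")
        if self.gradient_mode not in ("magnitude", "signed"):
            raise ValueError("gradient_mode must be magnitude|signed")


@dataclass
class SelectionResult:
    selected: np.ndarray   # spot ids, S
    discarded: np.ndarray  # spot ids, D
    audit: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=np.int64)
        self.discarded = np.asarray(self.discarded, dtype=np.int64)
        if np.intersect1d(self.selected, self.discarded).size:
            raise SelectionError("selected and discarded sets overlap")


# ---------------------------------------------------------------------------
# objective workspace
# ---------------------------------------------------------------------------

class ObjectiveWorkspace:
    """Pre-sliced per-(scenario, ROI) influence submatrices with an optional
    frozen background dose, for fast objective/gradient evaluation.

    ``matrices`` maps scenario index -> DoseInfluenceMatrix (all sharing one
    spot ordering).  ``free_rows`` restricts the optimization variables to a
    subset of spot rows; the remaining rows times ``w_frozen`` form the
    background.
    """

    def __init__(
        self,
        matrices: Mapping[int, DoseInfluenceMatrix],
        structures: StructureSet,
        spec: ObjectiveSpec,
        free_rows: Optional[np.ndarray] = None,
        w_frozen: Optional[np.ndarray] = None,
    ):
        self.spec = spec
        self.scenario_ids = sorted(matrices)
        first = matrices[self.scenario_ids[0]]
        for sid in self.scenario_ids:
            if not np.array_equal(matrices[sid].spot_ids, first.spot_ids):
                raise SelectionError("scenario matrices index different spot sets")
        n = first.n_spots
        self.n_spots = n
        self.free_rows = (
            np.arange(n, dtype=np.int64) if free_rows is None
            else np.asarray(free_rows, dtype=np.int64)
        )
        roi_idx: Dict[str, np.ndarray] = {}
        for term in spec.terms:
            if term.roi not in structures.masks:
                raise ObjectiveSpecError(f"term references unknown ROI {term.roi!r}")
            mask = structures.masks[term.roi]
            if not mask.any():
                raise ObjectiveSpecError(f"ROI {term.roi!r} mask is empty")
            roi_idx.setdefault(term.roi, np.nonzero(mask.ravel())[0])
        # submatrices D[free_rows][:, roi] per (scenario, roi); background per pair
        self.sub: Dict[Tuple[int, str], sparse.csr_matrix] = {}
        self.bg: Dict[Tuple[int, str], np.ndarray] = {}
        for sid in self.scenario_ids:
            csc = matrices[sid].matrix.tocsc()
            for roi, idx in roi_idx.items():
                cols = csc[:, idx]
                self.sub[(sid, roi)] = cols[self.free_rows].tocsr()
                if w_frozen is not None:
                    frozen = np.setdiff1d(np.arange(n), self.free_rows)
                    self.bg[(sid, roi)] = np.asarray(
                        cols[frozen].T.dot(w_frozen[frozen])
                    ).ravel()
                else:
                    self.bg[(sid, roi)] = np.zeros(idx.size)
        self.roi_idx = roi_idx

    # -- dose of one (scenario, roi) pair at free weights wf -----------------
    def dose(self, wf: np.ndarray, sid: int, roi: str) -> np.ndarray:
        return self.bg[(sid, roi)] + self.sub[(sid, roi)].T.dot(wf)

    def _term_value(self, term: ObjectiveTerm, d: np.ndarray) -> float:
        if term.kind == "max_dose":
            v = np.maximum(d - term.dose_level, 0.0)
            return float(np.mean(v * v))
        if term.kind == "min_dose":
            v = np.maximum(term.dose_level - d, 0.0)
            return float(np.mean(v * v))
        m = float(d.mean())
        return max(0.0, m - term.dose_level) ** 2

    def _term_gradient(self, term: ObjectiveTerm, d: np.ndarray, sid: int) -> np.ndarray:
        D = self.sub[(sid, term.roi)]
        n_vox = d.size
        if term.kind == "max_dose":
            v = np.maximum(d - term.dose_level, 0.0)
            return (2.0 / n_vox) * D.dot(v)
        if term.kind == "min_dose":
            v = np.maximum(term.dose_level - d, 0.0)
            return (-2.0 / n_vox) * D.dot(v)
        m = float(d.mean())
        if m <= term.dose_level:
            return np.zeros(self.free_rows.size)
        return (2.0 * (m - term.dose_level) / n_vox) * D.dot(np.ones(n_vox))

    def value(self, wf: np.ndarray) -> float:
        total = 0.0
        for term in self.spec.terms:
            sids = self.scenario_ids if term.robust else self.scenario_ids[:1]
            vals = [self._term_value(term, self.dose(wf, sid, term.roi)) for sid in sids]
            total += term.weight * max(vals)
        return total

    def value_and_gradient(self, wf: np.ndarray) -> Tuple[float, np.ndarray]:
        total = 0.0
        grad = np.zeros(self.free_rows.size)
        for term in self.spec.terms:
            sids = self.scenario_ids if term.robust else self.scenario_ids[:1]
            doses = [self.dose(wf, sid, term.roi) for sid in sids]
            vals = [self._term_value(term, d) for d in doses]
            k = int(np.argmax(vals))  # ties -> lowest scenario index
            total += term.weight * vals[k]
            grad += term.weight * self._term_gradient(term, doses[k], sids[k])
        return total, grad


def objective_value(
    w: np.ndarray,
    matrices: Mapping[int, DoseInfluenceMatrix],
    structures: StructureSet,
    spec: ObjectiveSpec,
) -> float:
    """Robust composite objective F(w) >= 0 at the full weight vector."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    ws = ObjectiveWorkspace(matrices, structures, spec)
    return ws.value(w)


def objective_gradient(
    w: np.ndarray,
    matrices: Mapping[int, DoseInfluenceMatrix],
    structures: StructureSet,
    spec: ObjectiveSpec,
) -> np.ndarray:
    """Exact gradient dF/dw (robust terms: through their argmax scenario)."""
    w = np.asarray(w, dtype=float)
    ws = ObjectiveWorkspace(matrices, structures, spec)
    _, g = ws.value_and_gradient(w)
    return g


# ---------------------------------------------------------------------------
# spot selection
# ---------------------------------------------------------------------------

def select_by_weight(weights: np.ndarray, p: float, spot_ids=None) -> np.ndarray:
    """Smallest set of spots carrying at least a fraction p of the total weight.

    Spots are sorted by weight descending (ties broken by ascending id) and the
    shortest prefix whose cumulative weight reaches ``p * sum(w)`` is returned;
    taking the heaviest spots first makes this a minimum-cardinality feasible
    set.
    """
    w = np.asarray(weights, dtype=float)
    if not (0.0 < p <= 1.0):
        raise SelectionError(f"p must lie in (0, 1], got {p}")
    total = w.sum()
    if total <= 0:
        raise SelectionError("all spot weights are zero; nothing to select")
    ids = np.arange(w.size, dtype=np.int64) if spot_ids is None else np.asarray(spot_ids)
    order = np.lexsort((ids, -w))
    csum = np.cumsum(w[order])
    need = p * total
    k = int(np.searchsorted(csum, need - 1e-12 * total)) + 1
    return np.sort(ids[order[:k]])


def select_by_gradient(
    candidates: np.ndarray,
    gradient: np.ndarray,
    t: float,
    mode: str = "magnitude",
    spot_ids=None,
) -> np.ndarray:
    """Keep candidate spots whose objective derivative passes the threshold.

    ``magnitude`` mode (default) keeps |g_i| > t so that spots needing weight
    increases (negative derivative) remain selectable; ``signed`` keeps the
    literal g_i > t.
    """
    if t < 0:
        raise SelectionError("threshold t must be >= 0")
    g = np.asarray(gradient, dtype=float)
    ids = np.arange(g.size, dtype=np.int64) if spot_ids is None else np.asarray(spot_ids)
    if mode == "magnitude":
        passing = ids[np.abs(g) > t]
    elif mode == "signed":
        passing = ids[g > t]
    else:
        raise SelectionError(f"mode must be magnitude|signed, got {mode!r}")
    out = np.intersect1d(np.asarray(candidates, dtype=np.int64), passing)
    if out.size == 0:
        logger.info("gradient criterion removed every candidate (t=%g, mode=%s)", t, mode)
    return out


def select_spots(
    weights: np.ndarray,
    gradient: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
    spot_ids=None,
) -> SelectionResult:
    """Both criteria in sequence; returns the S/D partition with an audit."""
    ids = (
        np.arange(len(weights), dtype=np.int64) if spot_ids is None
        else np.asarray(spot_ids, dtype=np.int64)
    )
    stage1 = select_by_weight(weights, config.p_weight_fraction, ids)
    stage2 = select_by_gradient(
        stage1, gradient, config.t_gradient_threshold, config.gradient_mode, ids
    )
    return SelectionResult(
        selected=stage2,
        discarded=np.setdiff1d(ids, stage2),
        audit={"after_weight_criterion": stage1, "after_gradient_criterion": stage2},
    )


# ---------------------------------------------------------------------------
# projected-gradient optimizer
# ---------------------------------------------------------------------------

@dataclass
class OptimizationTrace:
    objective: List[float] = field(default_factory=list)
    step_size: List[float] = field(default_factory=list)

    def as_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.objective), np.asarray(self.step_size)


def _projected_gradient(
    ws: ObjectiveWorkspace,
    w0: np.ndarray,
    max_iter: int,
    tol: float,
    armijo_c: float = 1e-4,
    shrink: float = 0.5,
    tol_window: int = 10,
) -> Tuple[np.ndarray, OptimizationTrace]:
    w = np.maximum(np.asarray(w0, dtype=float).copy(), 0.0)
    trace = OptimizationTrace()
    f, g = ws.value_and_gradient(w)
    trace.objective.append(f)
    trace.step_size.append(0.0)
    alpha = 1.0 / max(np.linalg.norm(g), 1e-12)
    for it in range(max_iter):
        if f <= 0.0:
            break
        # warm-start the step from the last accepted one, allowing growth
        alpha = float(np.clip(alpha * 2.0, 1e-14, 1e14))
        accepted = False
        for _ in range(60):
            w_new = np.maximum(w - alpha * g, 0.0)
            dwn = w_new - w
            gd = float(g @ dwn)
            if gd >= 0.0 and not np.any(dwn):
                break  # stationary: projection does not move
            f_new = ws.value(w_new)
            if f_new <= f + armijo_c * gd + 1e-15 * abs(f):
                accepted = True
                break
            alpha *= shrink
        if not accepted:
            break
        if f_new > f + 1e-12 * max(abs(f), 1.0):
            raise OptimizerError(f"objective increased on an accepted step at iter {it}")
        w = w_new
        f_new2, g = ws.value_and_gradient(w)
        f = f_new2
        trace.objective.append(f)
        trace.step_size.append(alpha)
        if len(trace.objective) > tol_window:
            f_old = trace.objective[-1 - tol_window]
            if f_old - f < tol * max(f_old, 1e-30):
                break
    return w, trace


def reoptimize_weights(
    plan,
    matrices: Mapping[int, DoseInfluenceMatrix],
    structures: StructureSet,
    spec: ObjectiveSpec,
    selection: SelectionResult,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> Tuple[np.ndarray, OptimizationTrace]:
    """Re-optimize only the selected spot weights over a frozen background.

    Discarded weights are returned bit-identical to their input values; the
    dose seen by the objective is the precomputed background (discarded spots
    at initial weights) plus the selected spots' contribution.
    """
    w0 = plan.weights()
    first = matrices[sorted(matrices)[0]]
    rows = first.row_index(selection.selected)
    all_ids = set(int(i) for i in first.spot_ids)
    part = set(int(i) for i in selection.selected) | set(int(i) for i in selection.discarded)
    if part != all_ids:
        raise SelectionError("selection does not partition the plan's spots")
    w_out = w0.copy()
    if rows.size == 0:
        logger.info("empty selection: weights unchanged")
        ws = ObjectiveWorkspace(matrices, structures, spec)
        trace = OptimizationTrace(objective=[ws.value(w0)], step_size=[0.0])
        return w_out, trace
    ws = ObjectiveWorkspace(matrices, structures, spec, free_rows=rows, w_frozen=w0)
    wf, trace = _projected_gradient(ws, w0[rows], max_iter, tol)
    w_out[rows] = wf
    return w_out, trace


def full_optimize(
    plan,
    matrices: Mapping[int, DoseInfluenceMatrix],
    structures: StructureSet,
    spec: ObjectiveSpec,
    init: str = "uniform",
    max_iter: int = 500,
    tol: float = 1e-6,
) -> Tuple[np.ndarray, OptimizationTrace]:
    """Optimize every spot weight (reference-plan optimization).

    ``init='uniform'`` starts from equal weights scaled so the nominal mean
    dose of the highest-prescription target equals its prescription;
    ``init='given'`` starts from the plan's current weights.
    """
    first = matrices[sorted(matrices)[0]]
    n = first.n_spots
    if init == "uniform":
        roi, level = _primary_target(structures, spec, plan)
        idx = np.nonzero(structures.masks[roi].ravel())[0]
        csc = first.matrix.tocsc()[:, idx]
        mean_at_unit = float(np.asarray(csc.T.dot(np.ones(n))).mean())
        scale = level / mean_at_unit if mean_at_unit > 0 else 1.0
        w0 = np.full(n, scale)
    elif init == "given":
        w0 = plan.weights()
    else:
        raise ValueError(f"init must be uniform|given, got {init!r}")
    ws = ObjectiveWorkspace(matrices, structures, spec)
    return _projected_gradient(ws, w0, max_iter, tol)


def _primary_target(structures: StructureSet, spec: ObjectiveSpec, plan) -> Tuple[str, float]:
    """ROI and dose level used to scale the uniform initialization."""
    if plan is not None and getattr(plan, "prescriptions", None):
        for name, role in structures.roles.items():
            if role == "target_high" and name in structures.masks:
                level = plan.prescriptions.get(role) or plan.prescriptions.get(name)
                if level:
                    return name, float(level)
    best = None
    for term in spec.terms:
        if term.kind == "min_dose" and (best is None or term.dose_level > best[1]):
            best = (term.roi, term.dose_level)
    if best is None:
        best = (spec.terms[0].roi, max(spec.terms[0].dose_level, 1.0))
    return best
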