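"""Dwell-weight plans: symmetric and maximally asymmetric distributions,
dose asymmetry, and V150/V200 volume metrics against the RTOG limits.

The clinical planning exercise being reproduced: four reference points sit
at cardinal directions 1 cm from the balloon surface in the central
transverse plane.  A symmetric plan (equal weight on all 35 dwells,
normalized to prescription at those points) doses all four equally.  The
asymmetric plan emulates skin sparing: the central lumen and the lumen
nearest the asymmetry point are not loaded, and the remaining three lumens
are scaled — equal weights within a lumen — so the three remaining points
each receive exactly the prescription; the dose at the fourth point then
falls as far as the applicator's 0.5 cm lumen spacing allows.  The percent
difference between that point and the mean of the held points is the plan's
dose asymmetry.  RTOG 0413 constrains the hot volumes V150 <= 50 cm^3 and
V200 <= 10 cm^3; both are evaluated on the 0.25 cm dose grid excluding the
balloon interior (it is not tissue; a flag includes it for sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Applicator, reference_points
from .tg43 import DoseGrid, DoseKernel, compute_dose_grid, point_dose

PRESCRIPTION_CGY = 340.0  # per-fraction prescription of the APBI schedule
V150_LIMIT_CC = 50.0
V200_LIMIT_CC = 10.0

_LUMENS = ("central", "A", "B", "C", "D")


@dataclass(frozen=True)
class Plan:
    """35 non-negative dwell weights plus normalization metadata.

    Weights are the per-dwell weighting factors (proportional to dwell
    times), already scaled so that the plan's normalization points receive
    the prescription; ``normalization`` records that scale factor.
    """

    weights: np.ndarray
    active_lumens: tuple[str, ...]
    prescription: float = PRESCRIPTION_CGY
    normalization: float | None = None
    label: str = "plan"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (35,):
            raise ValueError("a plan carries exactly 35 dwell weights")
        if np.any(w < 0):
            raise ValueError("dwell weights must be non-negative")
        if not np.any(w > 0):
            raise ValueError("at least one dwell weight must be positive")

    def rescaled(self, factor: float) -> "Plan":
        return replace(
            self,
            weights=self.weights * factor,
            normalization=(self.normalization or 1.0) * factor,
        )


@dataclass(frozen=True)
class PlanMetrics:
    """Reference-point doses and derived plan quality metrics."""

    point_doses: dict[str, float]  # cGy, keyed by reference point label
    asymmetry_percent: float
    v150_cc: float
    v200_cc: float

    @property
    def meets_rtog(self) -> bool:
        return self.v150_cc <= V150_LIMIT_CC and self.v200_cc <= V200_LIMIT_CC


def _lumen_unit_doses(
    kernel: DoseKernel, applicator: Applicator, points: np.ndarray
) -> np.ndarray:
    """M[i, j]: dose at point i per unit weight on every dwell of lumen j."""
    m = np.zeros((len(points), len(_LUMENS)))
    for j, lum in enumerate(_LUMENS):
        w = np.zeros(35)
        w[applicator.dwell_indices(lum)] = 1.0
        for i, p in enumerate(points):
            m[i, j] = point_dose(kernel, applicator, w, p)
    return m


def make_symmetric_plan(
    applicator: Applicator,
    kernel: DoseKernel,
    prescription: float = PRESCRIPTION_CGY,
) -> Plan:
    """Equal weight on all 35 dwells, scaled so the mean cardinal-point dose
    equals the prescription; by symmetry all four points agree within the
    kernel interpolation tolerance."""
    refs = reference_points(applicator)
    unit = np.ones(35)
    doses = [point_dose(kernel, applicator, unit, p) for p in refs.points]
    scale = prescription / float(np.mean(doses))
    return Plan(
        weights=unit * scale,
        active_lumens=_LUMENS,
        prescription=prescription,
        normalization=scale,
        label="symmetric",
    )


def make_asymmetric_plan(
    applicator: Applicator,
    kernel: DoseKernel,
    prescription: float = PRESCRIPTION_CGY,
    excluded_outer: str = "A",
    method: str = "per_lumen",
) -> Plan:
    """Asymmetric (skin-sparing) plan: drop the central lumen and the outer
    lumen at the asymmetry point's azimuth, hold the three remaining
    cardinal points at the prescription, and push the fourth point's dose
    down.

    ``method='per_lumen'`` (default) keeps equal weights within each of the
    three loaded lumens and solves the 3x3 linear system exactly — the
    simplest deterministic forward plan, with all 21 remaining dwells
    active.  ``method='max_asymmetry'`` instead frees every one of the 21
    dwell weights and minimizes the asymmetry-point dose subject to the
    three held-point equalities and non-negativity (a linear program); this
    is the model's true maximum achievable dose asymmetry, emulating what a
    planner optimizing dwell times by hand is reaching for.

    Raises if the construction demands a negative weight (per-lumen) or the
    linear program is infeasible.
    """
    refs = reference_points(applicator)
    if excluded_outer not in refs.labels:
        raise ValueError(f"unknown outer lumen '{excluded_outer}'")
    asym_idx = refs.labels.index(excluded_outer)
    held_pts = np.delete(refs.points, asym_idx, axis=0)
    active = [l for l in _LUMENS if l not in ("central", excluded_outer)]
    weights = np.zeros(35)
    if method == "per_lumen":
        m_all = _lumen_unit_doses(kernel, applicator, held_pts)
        cols = [_LUMENS.index(l) for l in active]
        m = m_all[:, cols]
        scales = np.linalg.solve(
            m, np.full(len(held_pts), float(prescription))
        )
        if np.any(scales < 0):
            bad = active[int(np.argmin(scales))]
            raise ValueError(
                f"infeasible plan: lumen '{bad}' would need a negative weight"
            )
        for lum, s in zip(active, scales):
            weights[applicator.dwell_indices(lum)] = s
    elif method == "max_asymmetry":
        from scipy.optimize import linprog

        free = np.concatenate(
            [applicator.dwell_indices(l) for l in active]
        )
        m = np.zeros((len(held_pts) + 1, free.size))
        pts = np.vstack([held_pts, refs.points[asym_idx][None, :]])
        for jj, j in enumerate(free):
            w = np.zeros(35)
            w[j] = 1.0
            for i, p in enumerate(pts):
                m[i, jj] = point_dose(kernel, applicator, w, p)
        res = linprog(
            m[-1],
            A_eq=m[:-1],
            b_eq=np.full(len(held_pts), float(prescription)),
            bounds=(0, None),
            method="highs",
        )
        if not res.success:
            raise ValueError(f"asymmetry optimization infeasible: {res.message}")
        weights[free] = np.maximum(res.x, 0.0)
    else:
        raise ValueError(f"unknown method '{method}'")
    return Plan(
        weights=weights,
        active_lumens=tuple(active),
        prescription=prescription,
        normalization=1.0,
        label=f"asymmetric[{method}]" if method != "per_lumen" else "asymmetric",
    )


def dvh_volume(
    grid: DoseGrid,
    threshold_fraction: float,
    include_balloon: bool = False,
) -> float:
    """Tissue volume (cm^3) receiving at least ``threshold_fraction`` times
    the prescription, counted over node-centered voxels; balloon-interior
    voxels are excluded unless ``include_balloon``."""
    hot = grid.values >= threshold_fraction * grid.prescription
    if not include_balloon:
        hot = hot & ~grid.balloon_mask()
    return float(np.count_nonzero(hot)) * grid.voxel_volume


def plan_metrics(
    plan: Plan,
    kernel: DoseKernel,
    applicator: Applicator,
    prescription: float | None = None,
    grid: DoseGrid | None = None,
    include_balloon: bool = False,
) -> PlanMetrics:
    """Point doses by kernel superposition, the dose asymmetry, and the
    V150/V200 hot volumes from the dose grid."""
    if plan.normalization is None:
        raise ValueError("plan is not normalized")
    if prescription is None:
        prescription = plan.prescription
    refs = reference_points(applicator)
    doses = {
        lab: point_dose(kernel, applicator, plan, p)
        for lab, p in zip(refs.labels, refs.points)
    }
    d_asym = doses[refs.labels[refs.asymmetry_index]]
    held = [d for lab, d in doses.items()
            if lab != refs.labels[refs.asymmetry_index]]
    mean_held = float(np.mean(held))
    asym = 100.0 * (mean_held - d_asym) / mean_held
    if grid is None:
        grid = compute_dose_grid(kernel, applicator, plan, prescription)
    return PlanMetrics(
        point_doses=doses,
        asymmetry_percent=asym,
        v150_cc=dvh_volume(grid, 1.5, include_balloon),
        v200_cc=dvh_volume(grid, 2.0, include_balloon),
    )
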