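"""Dose modification factor (DMF) analysis.

The DMF is the ratio of the dose rate at the reference point (1 cm beyond
the balloon surface) in a homogeneous full-scatter water medium — what a
TG-43-style planning system assumes — to the dose rate with only a finite
tissue thickness beyond the prescription line.  DMF > 1 means the planning
system overestimates the delivered dose; ``underdose_percent`` =
100 x (DMF - 1) is the corresponding planned-vs-delivered deficit.

Sweeps share a single full-scatter reference run per plan, and paired
comparisons (symmetric vs asymmetric plans; steel cable on vs off) use
common random numbers: per-history seed streams depend only on (seed, dwell
index, history index), so sub-percent effects difference out history by
history and are resolvable at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import Applicator, DetectorVolume, Phantom, default_detector
from .transport import (
    EngineConfig,
    TallyResult,
    run_full_scatter_reference,
    simulate,
)


@dataclass(frozen=True)
class DMFPoint:
    """DMF at one tissue depth, with combined statistical uncertainty.

    ``batch_finite``/``batch_full`` carry the per-batch combined tallies of
    the two runs so paired (common-random-number) curve comparisons can
    propagate the batch-level correlation.
    """

    tissue_depth: float
    dmf: float
    rse: float  # relative standard error of the ratio
    batch_finite: np.ndarray | None = field(default=None, repr=False)
    batch_full: np.ndarray | None = field(default=None, repr=False)

    def _influence(self) -> np.ndarray:
        """Delta-method per-batch influence values of the ratio estimate."""
        f = float(self.batch_finite.mean())
        full = float(self.batch_full.mean())
        return self.batch_full / f - (full / f**2) * self.batch_finite

    @property
    def underdose_percent(self) -> float:
        """Planned-minus-delivered deficit, 100 x (DMF - 1)."""
        return 100.0 * (self.dmf - 1.0)

    @property
    def sigma(self) -> float:
        """Absolute one-standard-error of the DMF."""
        return self.dmf * self.rse


@dataclass(frozen=True)
class DMFCurve:
    """DMF versus tissue depth for one phantom shape and plan."""

    phantom_kind: str
    plan_label: str
    points: tuple[DMFPoint, ...]
    reference: TallyResult = field(repr=False, default=None)
    wire: bool = False

    def __post_init__(self):
        depths = self.depths
        if np.any(np.diff(depths) <= 0):
            raise ValueError("curve depths must be strictly increasing")

    @property
    def depths(self) -> np.ndarray:
        return np.array([p.tissue_depth for p in self.points])

    @property
    def dmf(self) -> np.ndarray:
        return np.array([p.dmf for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phantom": self.phantom_kind,
                "plan": self.plan_label,
                "wire": self.wire,
                "depth_cm": self.depths,
                "dmf": self.dmf,
                "rse": [p.rse for p in self.points],
                "underdose_percent": [p.underdose_percent for p in self.points],
            }
        )


def compute_dmf(finite: TallyResult, full: TallyResult) -> DMFPoint:
    """DMF = full-scatter dose / finite-geometry dose.

    Uncertainties are combined in quadrature; when the two tallies carry
    compatible batch structure, per-batch ratios are attached so paired
    curve comparisons can exploit the correlation.
    """
    if finite.dose_per_history <= 0:
        raise ValueError("finite-geometry tally is zero; DMF undefined")
    dmf = full.dose_per_history / finite.dose_per_history
    rse = math.hypot(finite.rse, full.rse)
    fb = finite.combined_batches()
    ub = full.combined_batches()
    if fb.size != ub.size:
        fb = ub = None
    return DMFPoint(
        tissue_depth=np.nan, dmf=dmf, rse=rse,
        batch_finite=fb, batch_full=ub,
    )


def dmf_sweep(
    plan,
    phantom_kind: str,
    depths,
    config: EngineConfig,
    applicator: Applicator,
    detector: DetectorVolume | None = None,
    label: str | None = None,
) -> DMFCurve:
    """DMF curve over tissue depths: one shared full-scatter reference run
    plus one finite-geometry run per depth.

    Seeds derive from ``config.seed`` and the depth value only, never from
    the plan, so sweeps of different plans at the same seed are paired
    (common random numbers) run by run.
    """
    depths = sorted(float(d) for d in depths)
    if any(d < 0 or d > 10 for d in depths):
        raise ValueError("tissue depths must lie in [0, 10] cm")
    if detector is None:
        detector = default_detector(applicator)
    full = run_full_scatter_reference(
        plan, applicator, replace(config, seed=config.seed), detector=detector
    )
    pts = []
    for d in depths:
        finite = simulate(
            plan, Phantom(phantom_kind, d), applicator, detector, config
        )
        pt = compute_dmf(finite, full)
        pts.append(replace(pt, tissue_depth=d))
    return DMFCurve(
        phantom_kind=phantom_kind,
        plan_label=label or getattr(plan, "label", "plan"),
        points=tuple(pts),
        reference=full,
        wire=config.wire,
    )


def paired_plan_sweep(
    plans: dict,
    phantom_kind: str,
    depths,
    config: EngineConfig,
    applicator: Applicator,
    detector: DetectorVolume | None = None,
) -> dict:
    """DMF curves for several plans from one set of transport runs.

    Because each dwell transports the same number of photons and weights
    enter only in the final combination, every scene is simulated once with
    unit weights on all 35 dwells and each plan's curve is recombined from
    the shared per-dwell sub-tallies.  The resulting curves are exactly
    common-random-number paired (identical underlying histories), which is
    what lets :func:`compare_curves` resolve sub-percent plan effects.

    Returns ``{label: DMFCurve}`` keyed by the keys of ``plans``.
    """
    depths = sorted(float(d) for d in depths)
    if any(d < 0 or d > 10 for d in depths):
        raise ValueError("tissue depths must lie in [0, 10] cm")
    if detector is None:
        detector = default_detector(applicator)
    base = np.ones(len(applicator.dwells))
    full = run_full_scatter_reference(base, applicator, config, detector)
    finites = [
        simulate(base, Phantom(phantom_kind, d), applicator, detector, config)
        for d in depths
    ]
    curves = {}
    for label, plan in plans.items():
        w = np.asarray(getattr(plan, "weights", plan), dtype=float)
        full_w = full.with_weights(w)
        pts = []
        for d, fin in zip(depths, finites):
            pt = compute_dmf(fin.with_weights(w), full_w)
            pts.append(replace(pt, tissue_depth=d))
        curves[label] = DMFCurve(
            phantom_kind=phantom_kind,
            plan_label=getattr(plan, "label", str(label)),
            points=tuple(pts),
            reference=full_w,
            wire=config.wire,
        )
    return curves


@dataclass(frozen=True)
class CurveComparison:
    """Per-depth DMF differences between two curves, with combined sigma."""

    depths: np.ndarray
    difference: np.ndarray  # DMF_a - DMF_b
    sigma: np.ndarray  # one standard error per depth

    @property
    def max_abs_difference(self) -> float:
        return float(np.max(np.abs(self.difference)))

    @property
    def min_signed_difference(self) -> float:
        return float(np.min(self.difference))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_cm": self.depths,
                "dmf_difference": self.difference,
                "sigma": self.sigma,
            }
        )


def compare_curves(a: DMFCurve, b: DMFCurve) -> CurveComparison:
    """Per-depth differences ``a - b`` and the maximum absolute difference.

    Requires matching phantom kinds and depth grids.  When both curves carry
    aligned per-batch ratios (paired seeds), the uncertainty of each
    difference is estimated from the spread of per-batch differences, which
    credits the common-random-number correlation; otherwise sigmas combine
    in quadrature.
    """
    if a.phantom_kind != b.phantom_kind:
        raise ValueError("curves use different phantom kinds")
    if not np.array_equal(a.depths, b.depths):
        raise ValueError("curves sampled at different depths")
    diffs, sigmas = [], []
    for pa, pb in zip(a.points, b.points):
        diffs.append(pa.dmf - pb.dmf)
        if (
            pa.batch_finite is not None
            and pb.batch_finite is not None
            and pa.batch_finite.size == pb.batch_finite.size
        ):
            # delta-method influence per batch; with paired seeds the
            # batch-level correlation between the curves is credited
            d = pa._influence() - pb._influence()
            sigmas.append(float(d.std(ddof=1)) / math.sqrt(d.size))
        else:
            sigmas.append(math.hypot(pa.sigma, pb.sigma))
    return CurveComparison(
        depths=a.depths,
        difference=np.array(diffs),
        sigma=np.array(sigmas),
    )


@dataclass(frozen=True)
class WireSpec:
    """Steel source-cable model: a type-304 cylinder along each active lumen
    path from the balloon entry to the outermost occupied dwell."""

    radius: float = 0.045  # cm
    step: float = 0.25  # arc discretization, cm


def wire_effect(
    plan,
    phantom_kind: str,
    depths,
    wire: WireSpec,
    config: EngineConfig,
    applicator: Applicator,
    detector: DetectorVolume | None = None,
) -> CurveComparison:
    """Per-depth change in DMF caused by adding the steel cable.

    Runs paired wire-on / wire-off sweeps with identical seeds (common
    random numbers), so the sub-percent cable perturbation is resolved far
    below the single-run statistical error.  Returns DMF_wire - DMF_no_wire
    per depth.
    """
    cfg_off = replace(config, wire=False)
    cfg_on = replace(config, wire=True, wire_radius=wire.radius)
    off = dmf_sweep(plan, phantom_kind, depths, cfg_off, applicator, detector)
    on = dmf_sweep(plan, phantom_kind, depths, cfg_on, applicator, detector)
    return compare_curves(on, off)
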