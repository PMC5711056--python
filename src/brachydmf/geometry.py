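"""Applicator, phantom and detector geometry, and analytic ray tracing.

Coordinate convention: balloon center at the origin, applicator axis along
+z, the asymmetry/measurement point on +y; right-handed axes, all lengths in
cm.  The multilumen balloon is modeled as a sphere of radius 2.2 cm holding
one straight central lumen and four outer lumens at cardinal azimuths.  Each
outer lumen is a circular arc in the axial plane through its azimuth, pinned
to the axis at the balloon poles and bulging to a 0.5 cm offset at the
equator (the device's maximum central-to-outer lumen separation).  Seven
0.5 cm source dwells per lumen are spaced 0.5 cm apart in arc length,
centered on the equatorial plane: 35 dwells in total.

Everything inside the phantom except (optionally) the steel source cable is
water; the balloon wall, catheters and balloon interior are not modeled as
distinct materials.  The phantom sits inside a 100 cm air cube that bounds
the simulation world.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

Vec3 = np.ndarray  # shape (3,), cm

BALLOON_RADIUS_CM = 2.2
LUMEN_OFFSET_CM = 0.5  # central-to-outer lumen separation at the equator
DWELL_HALF_LENGTH_CM = 0.25
DWELL_RADIUS_CM = 0.017
DWELL_STEP_CM = 0.5
N_DWELLS_PER_LUMEN = 7
REFERENCE_MARGIN_CM = 1.0  # reference points sit 1 cm beyond the balloon
DETECTOR_RADIUS_CM = 0.17
WORLD_HALF_SIZE_CM = 50.0
CUBOID_BACK_MARGIN_CM = 20.0  # water behind the balloon center (cuboid)
FULL_SCATTER_MARGIN_CM = 30.0  # water beyond the detector for full scatter

#: outer lumen labels and azimuths (degrees, measured from +x toward +y);
#: the asymmetry point lies on lumen A's azimuth (+y).
LUMEN_AZIMUTHS = {"A": 90.0, "B": 0.0, "C": 180.0, "D": 270.0}


@dataclass(frozen=True)
class DwellPosition:
    index: int  # 1..35
    lumen_id: str  # central, A, B, C, D
    center: Vec3
    axis: Vec3  # unit tangent of the lumen path
    half_length: float = DWELL_HALF_LENGTH_CM
    radius: float = DWELL_RADIUS_CM


@dataclass(frozen=True)
class Applicator:
    """Balloon plus the 35-dwell source geometry."""

    balloon_center: Vec3
    balloon_radius: float
    applicator_axis: Vec3
    dwells: tuple[DwellPosition, ...]
    arc_radius: float = field(repr=False, default=0.0)
    arc_center_offset: float = field(repr=False, default=0.0)

    @property
    def lumen_ids(self) -> tuple[str, ...]:
        return ("central",) + tuple(LUMEN_AZIMUTHS)

    def dwell_indices(self, lumen_id: str) -> np.ndarray:
        return np.array(
            [d.index - 1 for d in self.dwells if d.lumen_id == lumen_id]
        )

    def dwell_centers(self) -> np.ndarray:
        return np.array([d.center for d in self.dwells])

    def dwell_axes(self) -> np.ndarray:
        return np.array([d.axis for d in self.dwells])

    def lumen_point(self, lumen_id: str, s: float) -> Vec3:
        """Point on a lumen path at arc length ``s`` from the equator."""
        if lumen_id == "central":
            return np.array([0.0, 0.0, s])
        phi_az = math.radians(LUMEN_AZIMUTHS[lumen_id])
        rho_hat = np.array([math.cos(phi_az), math.sin(phi_az), 0.0])
        ang = s / self.arc_radius
        rho = self.arc_center_offset + self.arc_radius * math.cos(ang)
        z = self.arc_radius * math.sin(ang)
        return rho * rho_hat + np.array([0.0, 0.0, z])

    def wire_segments(
        self,
        active_lumens: tuple[str, ...],
        radius: float = 0.045,
        step: float = 0.25,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """Polyline cylinder segments for the steel source cable.

        The cable runs along each active lumen path from the -z balloon pole
        to the far end of the outermost dwell.  Returns ``(p0, axis, half_len)``
        arrays plus the radius; arcs are discretized at ``step`` cm.
        """
        p0s, axes, halves = [], [], []
        s_end = (N_DWELLS_PER_LUMEN // 2) * DWELL_STEP_CM + DWELL_HALF_LENGTH_CM
        for lum in active_lumens:
            if lum == "central":
                s_lo = -self.balloon_radius
            else:
                # arc length from equator to the -z pole
                s_lo = -self.arc_radius * math.asin(
                    self.balloon_radius / self.arc_radius
                )
            grid = np.arange(s_lo, s_end + 1e-9, step)
            if grid[-1] < s_end:
                grid = np.append(grid, s_end)
            pts = np.array([self.lumen_point(lum, s) for s in grid])
            for a, b in zip(pts[:-1], pts[1:]):
                seg = b - a
                length = float(np.linalg.norm(seg))
                p0s.append(0.5 * (a + b))
                axes.append(seg / length)
                # slight overlap so the polyline has no gaps at the joints
                halves.append(0.5 * length + 0.02)
        return np.array(p0s), np.array(axes), np.array(halves), radius


@dataclass(frozen=True)
class Phantom:
    """Water phantom embedded in the 100 cm air world cube.

    ``tissue_depth`` is the water thickness beyond the reference point (which
    sits 1 cm beyond the balloon surface on +y).  The cuboid phantom is
    40 x (23.2 + depth) x 40 cm with 20 cm of water behind the balloon
    center; the spherical phantom has radius 3.2 + depth, concentric with
    the balloon.
    """

    kind: str  # cuboid | spherical
    tissue_depth: float

    def __post_init__(self):
        if self.kind not in ("cuboid", "spherical"):
            raise ValueError(f"unknown phantom kind '{self.kind}'")
        if self.tissue_depth < 0:
            raise ValueError("tissue depth must be non-negative")
        # the study sweeps 0-10 cm; depths up to 45 cm exist only for the
        # full-scatter reference and its margin-convergence scan, and must
        # keep the phantom inside the 100 cm world cube
        if self.tissue_depth > 45:
            raise ValueError("tissue depth above 45 cm leaves the world cube")

    @property
    def front_extent(self) -> float:
        """Water extent beyond the balloon center on +y (cm)."""
        return BALLOON_RADIUS_CM + REFERENCE_MARGIN_CM + self.tissue_depth

    @property
    def y_extent(self) -> float:
        """Total cuboid extent along y (cm)."""
        return CUBOID_BACK_MARGIN_CM + self.front_extent

    @property
    def radius(self) -> float:
        """Spherical phantom radius (cm)."""
        return self.front_extent

    @property
    def bounds(self) -> np.ndarray:
        """Cuboid bounds [[xlo,xhi],[ylo,yhi],[zlo,zhi]]."""
        h = 20.0
        return np.array(
            [[-h, h], [-CUBOID_BACK_MARGIN_CM, self.front_extent], [-h, h]]
        )

    def contains(self, point: Vec3) -> bool:
        p = np.asarray(point, dtype=float)
        if self.kind == "spherical":
            return float(p @ p) <= self.radius**2
        b = self.bounds
        return bool(np.all(p >= b[:, 0]) and np.all(p <= b[:, 1]))


def build_phantom(kind: str, tissue_depth: float) -> Phantom:
    """Construct a water phantom: ``cuboid`` (40 x (23.2+depth) x 40 cm) or
    ``spherical`` (radius 3.2+depth cm), positioned so the balloon center is
    centered transversely with the stated water thickness beyond the
    reference point.  Negative depth raises."""
    return Phantom(kind=kind, tissue_depth=float(tissue_depth))


def full_scatter_phantom() -> Phantom:
    """Spherical water phantom with >=30 cm of water beyond the reference
    point in every direction — the homogeneous-medium (full backscatter)
    reference geometry."""
    return Phantom("spherical", FULL_SCATTER_MARGIN_CM)


@dataclass(frozen=True)
class DetectorVolume:
    """The 0.17 cm radius spherical measurement volume."""

    center: Vec3
    radius: float = DETECTOR_RADIUS_CM

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass(frozen=True)
class ReferencePointSet:
    """Four cardinal points 1 cm beyond the balloon surface in the central
    transverse plane; index 0 (+y, lumen A azimuth) is the asymmetry point."""

    points: np.ndarray  # (4, 3)
    labels: tuple[str, ...]
    asymmetry_index: int = 0

    @property
    def asymmetry_point(self) -> Vec3:
        return self.points[self.asymmetry_index]

    @property
    def held_points(self) -> np.ndarray:
        mask = np.ones(len(self.points), dtype=bool)
        mask[self.asymmetry_index] = False
        return self.points[mask]


def reference_points(applicator: Applicator) -> ReferencePointSet:
    """The four cardinal reference points for an applicator."""
    r = applicator.balloon_radius + REFERENCE_MARGIN_CM
    labels = ("A", "B", "C", "D")
    pts = []
    for lab in labels:
        az = math.radians(LUMEN_AZIMUTHS[lab])
        pts.append([r * math.cos(az), r * math.sin(az), 0.0])
    return ReferencePointSet(points=np.array(pts), labels=labels)


def default_detector(applicator: Applicator) -> DetectorVolume:
    """Detector sphere centered on the asymmetry reference point."""
    return DetectorVolume(center=reference_points(applicator).asymmetry_point)


def build_applicator(balloon_radius: float = BALLOON_RADIUS_CM) -> Applicator:
    """Construct the 5-lumen, 35-dwell balloon applicator model."""
    if not 2.0 <= balloon_radius <= 3.0:
        raise ValueError("balloon radius must lie in [2.0, 3.0] cm")
    d = LUMEN_OFFSET_CM
    arc_radius = (balloon_radius**2 + d**2) / (2.0 * d)
    arc_center = d - arc_radius  # signed rho of the arc center (negative)
    app = Applicator(
        balloon_center=np.zeros(3),
        balloon_radius=balloon_radius,
        applicator_axis=np.array([0.0, 0.0, 1.0]),
        dwells=(),
        arc_radius=arc_radius,
        arc_center_offset=arc_center,
    )
    half = N_DWELLS_PER_LUMEN // 2
    s_grid = DWELL_STEP_CM * np.arange(-half, half + 1)
    dwells = []
    idx = 1
    for lum in ("central",) + tuple(LUMEN_AZIMUTHS):
        for s in s_grid:
            center = app.lumen_point(lum, float(s))
            if lum == "central":
                axis = np.array([0.0, 0.0, 1.0])
            else:
                az = math.radians(LUMEN_AZIMUTHS[lum])
                rho_hat = np.array([math.cos(az), math.sin(az), 0.0])
                ang = s / arc_radius
                axis = -math.sin(ang) * rho_hat + np.array(
                    [0.0, 0.0, math.cos(ang)]
                )
            dwells.append(
                DwellPosition(index=idx, lumen_id=lum, center=center, axis=axis)
            )
            idx += 1
    return Applicator(
        balloon_center=app.balloon_center,
        balloon_radius=balloon_radius,
        applicator_axis=app.applicator_axis,
        dwells=tuple(dwells),
        arc_radius=arc_radius,
        arc_center_offset=arc_center,
    )


# --------------------------------------------------------------------------
# Ray tracing

_EPS = 1e-9
OUTSIDE = "outside"


def _ray_sphere_ts(p, d, radius):
    b = p @ d
    c = p @ p - radius * radius
    disc = b * b - c
    if disc <= 0:
        return ()
    s = math.sqrt(disc)
    return (-b - s, -b + s)


def _ray_box_ts(p, d, bounds):
    tmin, tmax = -math.inf, math.inf
    for i in range(3):
        if abs(d[i]) < 1e-300:
            if p[i] < bounds[i, 0] or p[i] > bounds[i, 1]:
                return ()
            continue
        t0 = (bounds[i, 0] - p[i]) / d[i]
        t1 = (bounds[i, 1] - p[i]) / d[i]
        if t0 > t1:
            t0, t1 = t1, t0
        tmin = max(tmin, t0)
        tmax = min(tmax, t1)
    if tmin > tmax:
        return ()
    return (tmin, tmax)


def _ray_cylinder_ts(p, d, c0, axis, half_len, radius):
    """Entry/exit times of a ray with a capped finite cylinder."""
    rp = p - c0
    za = rp @ axis
    zd = d @ axis
    # quadratic in the perpendicular components
    pp = rp - za * axis
    dd = d - zd * axis
    a = dd @ dd
    ts = []
    if a > 1e-20:
        b = pp @ dd
        c = pp @ pp - radius * radius
        disc = b * b - a * c
        if disc > 0:
            s = math.sqrt(disc)
            for t in ((-b - s) / a, (-b + s) / a):
                if abs(za + t * zd) <= half_len:
                    ts.append(t)
    if abs(zd) > 1e-300:
        for zcap in (-half_len, half_len):
            t = (zcap - za) / zd
            q = pp + t * dd
            if q @ q <= radius * radius:
                ts.append(t)
    return tuple(ts)


def _wire_arrays(applicator, wire):
    if wire is None:
        active = ("central",) + tuple(LUMEN_AZIMUTHS)
        return applicator.wire_segments(active)
    return wire


def material_at(
    point: Vec3,
    phantom: Phantom,
    applicator: Applicator | None = None,
    wire_enabled: bool = False,
    wire=None,
) -> str:
    """Material name at a point: water, air, steel304, or 'outside'."""
    p = np.asarray(point, dtype=float)
    if np.any(np.abs(p) > WORLD_HALF_SIZE_CM):
        return OUTSIDE
    if wire_enabled and applicator is not None:
        p0, axes, halves, radius = _wire_arrays(applicator, wire)
        if len(p0):
            rel = p - p0
            za = np.einsum("ij,ij->i", rel, axes)
            perp = rel - za[:, None] * axes
            inside = (np.abs(za) <= halves) & (
                np.einsum("ij,ij->i", perp, perp) <= radius * radius
            )
            if inside.any():
                return "steel304"
    return "water" if phantom.contains(p) else "air"


def trace(
    position: Vec3,
    direction: Vec3,
    phantom: Phantom,
    applicator: Applicator | None = None,
    wire_enabled: bool = False,
    wire=None,
) -> tuple[float, str]:
    """Distance to the next material boundary and the material beyond it.

    Exact analytic intersections with the phantom surface (sphere or box),
    the world cube, and — when ``wire_enabled`` — the steel cable cylinders.
    Crossing the world boundary returns material ``'outside'`` (the history
    terminates there).
    """
    p = np.asarray(position, dtype=float)
    d = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(d))
    if norm < 1e-12:
        raise ValueError("direction must be a non-zero unit vector")
    if abs(norm - 1.0) > 1e-9:
        raise ValueError("direction must be normalized")
    if material_at(p, phantom, applicator, wire_enabled, wire) == OUTSIDE:
        return 0.0, OUTSIDE

    candidates: list[float] = []
    world = np.array([[-WORLD_HALF_SIZE_CM, WORLD_HALF_SIZE_CM]] * 3)
    candidates.extend(_ray_box_ts(p, d, world))
    if phantom.kind == "spherical":
        candidates.extend(_ray_sphere_ts(p, d, phantom.radius))
    else:
        candidates.extend(_ray_box_ts(p, d, phantom.bounds))
    if wire_enabled and applicator is not None:
        p0, axes, halves, radius = _wire_arrays(applicator, wire)
        for i in range(len(p0)):
            candidates.extend(
                _ray_cylinder_ts(p, d, p0[i], axes[i], halves[i], radius)
            )
    positive = [t for t in candidates if t > _EPS]
    if not positive:
        return math.inf, OUTSIDE
    t = min(positive)
    ahead = material_at(
        p + (t + _EPS) * d, phantom, applicator, wire_enabled, wire
    )
    return t, ahead
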