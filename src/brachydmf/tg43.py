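"""Homogeneous-water relative dose kernel — the treatment-planning-system
surrogate — and 3-D dose-grid evaluation by superposition.

Conventional balloon-applicator plans are computed by TG-43-style systems
that superpose tabulated single-source dose-rate tables in an unbounded
water medium.  Here the equivalent object is a single 2-D kernel
``k(r, theta)``: the kerma rate around one unit-weight dwell in a
full-scatter water phantom, derived with the package's own Monte Carlo
engine and normalized to the value at r = 1 cm on the transverse axis
(theta = 90 deg).  Because every planning quantity in this study is a dose
ratio, the kernel is kept relative throughout — no air-kerma strength or
dose-rate constant enters.  Interpolation is bilinear in (log r, cos theta),
in which line-source dose varies nearly linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import _engine
from .geometry import (
    Applicator,
    BALLOON_RADIUS_CM,
    WORLD_HALF_SIZE_CM,
    full_scatter_phantom,
)
from .physics import build_transport_tables, ir192_spectrum
from .transport import EngineConfig, derive_seed

KERNEL_R_MIN = 0.25  # cm; no clinical point lies closer to a dwell
KERNEL_R_MAX = 20.0
_LOG10_STEP = 0.05
_N_COS_BINS = 41  # odd so that cos(theta) = 0 is a node

GRID_SPACING_CM = 0.25
GRID_EXTENT_CM = 40.0
GRID_NODES = int(round(GRID_EXTENT_CM / GRID_SPACING_CM)) + 1  # 161, inclusive


def kernel_grid() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(r_nodes, r_edges, cos_nodes, cos_edges) of the kernel tally grid.

    Radial nodes are log10-spaced bin centers chosen so that r = 1 cm is an
    exact node; polar nodes are uniform cos(theta) bin centers including 0.
    """
    centers_log = np.arange(-0.60, 1.30 + 1e-9, _LOG10_STEP)
    r_nodes = 10.0**centers_log
    r_edges = 10.0 ** np.concatenate(
        [[centers_log[0] - _LOG10_STEP / 2], centers_log + _LOG10_STEP / 2]
    )
    cos_edges = np.linspace(-1.0, 1.0, _N_COS_BINS + 1)
    cos_nodes = 0.5 * (cos_edges[:-1] + cos_edges[1:])
    return r_nodes, r_edges, cos_nodes, cos_edges


@dataclass(frozen=True)
class DoseKernel:
    """Relative dose-rate table around a single dwell in full-scatter water.

    ``values[i, j]`` is the relative kerma at radius ``r_nodes[i]`` and polar
    cosine ``cos_nodes[j]`` (theta measured from the dwell axis), normalized
    to 1 at (r = 1 cm, theta = 90 deg).  ``rse`` carries per-node relative
    standard errors; ``provenance`` records engine configuration, history
    count and seed, plus any nodes whose statistical error exceeded 1%.
    """

    r_nodes: np.ndarray
    cos_nodes: np.ndarray
    values: np.ndarray  # (n_r, n_cos)
    rse: np.ndarray = field(repr=False)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.values <= 0):
            raise ValueError("kernel must be positive everywhere")

    @property
    def _interp_arrays(self):
        return (
            np.log(self.r_nodes),
            self.cos_nodes,
            self.values,
        )

    def __call__(self, r, cos_theta):
        """Bilinear interpolation in (log r, cos theta), clamped at edges."""
        r = np.asarray(r, dtype=float)
        c = np.asarray(cos_theta, dtype=float)
        if np.any(r < KERNEL_R_MIN):
            raise ValueError(
                f"kernel not defined below r = {KERNEL_R_MIN} cm"
            )
        logr, cosn, vals = self._interp_arrays
        x = np.clip(np.log(r), logr[0], logr[-1])
        y = np.clip(c, cosn[0], cosn[-1])
        ix = np.clip(np.searchsorted(logr, x) - 1, 0, len(logr) - 2)
        iy = np.clip(np.searchsorted(cosn, y) - 1, 0, len(cosn) - 2)
        fx = (x - logr[ix]) / (logr[ix + 1] - logr[ix])
        fy = (y - cosn[iy]) / (cosn[iy + 1] - cosn[iy])
        v = (
            vals[ix, iy] * (1 - fx) * (1 - fy)
            + vals[ix + 1, iy] * fx * (1 - fy)
            + vals[ix, iy + 1] * (1 - fx) * fy
            + vals[ix + 1, iy + 1] * fx * fy
        )
        return float(v) if v.ndim == 0 else v

    def save(self, path):
        """Persist as a two-axis columnar text table with provenance header."""
        with open(path, "w") as f:
            f.write("# relative single-dwell dose kernel in full-scatter water\n")
            for k, v in self.provenance.items():
                f.write(f"# {k}: {v}\n")
            f.write("# columns: r_cm  cos_theta  relative_dose  rse\n")
            for i, r in enumerate(self.r_nodes):
                for j, c in enumerate(self.cos_nodes):
                    f.write(
                        f"{r:.6g}  {c:.6f}  {self.values[i, j]:.8e}  "
                        f"{self.rse[i, j]:.3e}\n"
                    )

    @classmethod
    def load(cls, path) -> "DoseKernel":
        """Load a kernel (or any user-supplied table in the same layout)."""
        prov = {}
        rows = []
        with open(path) as f:
            for line in f:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("# ")
                    if ":" in body:
                        k, _, v = body.partition(":")
                        prov[k.strip()] = v.strip()
                    continue
                rows.append([float(x) for x in line.split()])
        arr = np.asarray(rows)
        r_nodes = np.unique(arr[:, 0])
        cos_nodes = np.unique(arr[:, 1])
        nr, nc = len(r_nodes), len(cos_nodes)
        values = arr[:, 2].reshape(nr, nc)
        rse = arr[:, 3].reshape(nr, nc)
        return cls(r_nodes=r_nodes, cos_nodes=cos_nodes, values=values,
                   rse=rse, provenance=prov)


def derive_kernel(
    config: EngineConfig,
    symmetrize: bool = True,
    n_batches: int = 20,
) -> DoseKernel:
    """Derive the single-dwell kernel with the Monte Carlo engine.

    A unit-weight dwell sits at the origin with its axis along +z inside a
    full-scatter water sphere.  Track-length kerma is tallied on
    (log r, cos theta) ring bins and normalized at (1 cm, 90 deg).  With
    ``symmetrize`` the two polar halves are averaged (the source is mirror
    symmetric about its transverse plane), halving the variance.
    """
    r_nodes, r_edges, cos_nodes, cos_edges = kernel_grid()
    tables = build_transport_tables(coherent=config.coherent)
    spectrum = ir192_spectrum()
    phantom = full_scatter_phantom()
    n = int(math.ceil(config.n_histories / n_batches)) * n_batches
    if config.coherent:
        nocoh = build_transport_tables(coherent=False)
        p_coh = np.clip(1.0 - nocoh.mu_lin / tables.mu_lin, 0.0, 1.0)
    else:
        p_coh = np.zeros_like(tables.mu_lin)
    raw = _engine.run_kernel_tally(
        0.25, 0.017, phantom.radius, WORLD_HALF_SIZE_CM,
        tables.log_e0, tables.dlog, tables.mu_lin, tables.p_compton, p_coh,
        tables.muen_water, config.cutoff,
        spectrum.energies, spectrum.cdf,
        r_edges, cos_edges, 0.25,
        n, n_batches, derive_seed(config.seed, "kernel"),
    )
    # ring-bin volumes: V = 2*pi/3 (r2^3 - r1^3) * dcos
    dcos = cos_edges[1] - cos_edges[0]
    vol = (
        2.0 * math.pi / 3.0 * np.diff(r_edges**3)[:, None] * dcos
    )
    per_hist = raw / (n / n_batches)
    batches = per_hist / vol[None, :, :]
    mean = batches.mean(axis=0)
    sem = batches.std(axis=0, ddof=1) / math.sqrt(n_batches)
    if symmetrize:
        mean = 0.5 * (mean + mean[:, ::-1])
        sem = 0.5 * np.sqrt(sem**2 + sem[:, ::-1] ** 2)
    i1 = int(np.argmin(np.abs(r_nodes - 1.0)))
    j90 = int(np.argmin(np.abs(cos_nodes)))
    norm = mean[i1, j90]
    values = mean / norm
    rse = np.divide(sem, mean, out=np.ones_like(sem), where=mean > 0)
    prov = {
        "n_histories": n,
        "seed": config.seed,
        "coherent": config.coherent,
        "estimator": "track_length",
        "symmetrized": symmetrize,
        "normalization_node": f"r={r_nodes[i1]:g} cm, cos_theta={cos_nodes[j90]:g}",
    }
    bad = int(np.count_nonzero(rse > 0.01))
    if bad:
        prov["warning"] = (
            f"{bad} of {rse.size} nodes have statistical error > 1%"
        )
    values = np.where(values <= 0, 1e-12, values)
    return DoseKernel(
        r_nodes=r_nodes, cos_nodes=cos_nodes, values=values, rse=rse,
        provenance=prov,
    )


# --------------------------------------------------------------------------
# superposition


def point_dose(kernel: DoseKernel, applicator: Applicator, plan, point) -> float:
    """Relative dose at a point: sum over dwells of weight * k(r_i, theta_i)
    evaluated in each dwell's local frame.  Exactly linear in the weights."""
    w = np.asarray(getattr(plan, "weights", plan), dtype=float)
    p = np.asarray(point, dtype=float)
    centers = applicator.dwell_centers()
    axes = applicator.dwell_axes()
    rel = p[None, :] - centers
    r = np.linalg.norm(rel, axis=1)
    if np.any(r < KERNEL_R_MIN):
        raise ValueError(
            f"point lies within {KERNEL_R_MIN} cm of a dwell center"
        )
    cos_t = np.einsum("ij,ij->i", rel, axes) / r
    active = w > 0
    if not active.any():
        return 0.0
    return float(w[active] @ kernel(r[active], cos_t[active]))


@dataclass(frozen=True)
class DoseGrid:
    """Cartesian dose grid (cGy) with inclusive endpoints.

    40 cm extent per axis at 0.25 cm spacing gives 161 nodes per axis; each
    node represents a node-centered voxel of spacing^3 for DVH purposes.
    ``balloon_radius`` lets DVH extraction exclude the balloon interior.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # (n, n, n), cGy
    prescription: float
    balloon_radius: float = BALLOON_RADIUS_CM
    balloon_center: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = self.values.shape
        return tuple(
            self.origin[i] + self.spacing * np.arange(n[i]) for i in range(3)
        )

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def balloon_mask(self) -> np.ndarray:
        """Boolean mask of nodes inside the balloon sphere."""
        ax, ay, az = self.axes
        dx = ax - self.balloon_center[0]
        dy = ay - self.balloon_center[1]
        dz = az - self.balloon_center[2]
        r2 = (
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        return r2 <= self.balloon_radius**2

    def save(self, path):
        """Export as a flat binary array with a JSON sidecar describing the
        layout (origin, spacing, shape, axis order, prescription)."""
        import json
        from pathlib import Path

        path = Path(path)
        self.values.astype("<f8").tofile(path)
        sidecar = {
            "dtype": "<f8",
            "axes_order": "xyz",
            "shape": list(self.values.shape),
            "origin_cm": [float(v) for v in self.origin],
            "spacing_cm": self.spacing,
            "prescription_cgy": self.prescription,
            "balloon_radius_cm": self.balloon_radius,
            "balloon_center_cm": [float(v) for v in self.balloon_center],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )

    @classmethod
    def load(cls, path) -> "DoseGrid":
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = json.loads(
            path.with_suffix(path.suffix + ".json").read_text()
        )
        values = np.fromfile(path, dtype=sidecar["dtype"]).reshape(
            sidecar["shape"]
        )
        return cls(
            origin=np.array(sidecar["origin_cm"]),
            spacing=sidecar["spacing_cm"],
            values=values,
            prescription=sidecar["prescription_cgy"],
            balloon_radius=sidecar["balloon_radius_cm"],
            balloon_center=np.array(sidecar["balloon_center_cm"]),
        )

    def interpolate(self, point) -> float:
        """Trilinear interpolation of the grid dose at a point."""
        p = (np.asarray(point, float) - self.origin) / self.spacing
        i = np.clip(p.astype(int), 0, np.array(self.values.shape) - 2)
        f = p - i
        v = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wgt = (
                        (f[0] if dx else 1 - f[0])
                        * (f[1] if dy else 1 - f[1])
                        * (f[2] if dz else 1 - f[2])
                    )
                    v += wgt * self.values[i[0] + dx, i[1] + dy, i[2] + dz]
        return float(v)


@njit(cache=True)
def _superpose(axes_x, axes_y, axes_z, centers, daxes, weights,
               log_r0, dlogr, values, cos0, dcos, out):
    nr, nc = values.shape
    nx, ny, nz = axes_x.size, axes_y.size, axes_z.size
    for di in range(centers.shape[0]):
        w = weights[di]
        if w == 0.0:
            continue
        cx, cy, cz = centers[di, 0], centers[di, 1], centers[di, 2]
        axx, axy, axz = daxes[di, 0], daxes[di, 1], daxes[di, 2]
        for i in range(nx):
            rx = axes_x[i] - cx
            for j in range(ny):
                ry = axes_y[j] - cy
                for k in range(nz):
                    rz = axes_z[k] - cz
                    r2 = rx * rx + ry * ry + rz * rz
                    r = np.sqrt(r2) if r2 > 1e-12 else 1e-6
                    ct = (rx * axx + ry * axy + rz * axz) / r
                    x = (np.log(r) - log_r0) / dlogr
                    if x < 0.0:
                        x = 0.0
                    elif x > nr - 1.000001:
                        x = nr - 1.000001
                    y = (ct - cos0) / dcos
                    if y < 0.0:
                        y = 0.0
                    elif y > nc - 1.000001:
                        y = nc - 1.000001
                    ix = int(x)
                    iy = int(y)
                    fx = x - ix
                    fy = y - iy
                    out[i, j, k] += w * (
                        values[ix, iy] * (1 - fx) * (1 - fy)
                        + values[ix + 1, iy] * fx * (1 - fy)
                        + values[ix, iy + 1] * (1 - fx) * fy
                        + values[ix + 1, iy + 1] * fx * fy
                    )


def compute_dose_grid(
    kernel: DoseKernel,
    applicator: Applicator,
    plan,
    prescription: float | None = None,
) -> DoseGrid:
    """Superpose the kernel over the grid and scale to the prescription.

    The plan must be normalized (its weights already scaled so its
    normalization points sit at the prescription); the grid is then in cGy.
    Nodes closer than the kernel's inner radius to a dwell take the clamped
    edge value — they all lie inside the balloon and are excluded from DVH
    metrics anyway.
    """
    norm = getattr(plan, "normalization", None)
    if norm is None:
        raise ValueError("plan is not normalized to a prescription")
    if prescription is None:
        prescription = getattr(plan, "prescription")
    w = np.asarray(getattr(plan, "weights", plan), dtype=float)
    half = GRID_EXTENT_CM / 2.0
    origin = np.array([-half, -half, -half])
    ax = origin[0] + GRID_SPACING_CM * np.arange(GRID_NODES)
    out = np.zeros((GRID_NODES, GRID_NODES, GRID_NODES))
    logr = np.log(kernel.r_nodes)
    _superpose(
        ax, ax, ax,
        applicator.dwell_centers(), applicator.dwell_axes(), w,
        logr[0], logr[1] - logr[0], kernel.values,
        kernel.cos_nodes[0], kernel.cos_nodes[1] - kernel.cos_nodes[0],
        out,
    )
    return DoseGrid(
        origin=origin,
        spacing=GRID_SPACING_CM,
        values=out,
        prescription=float(prescription),
        balloon_radius=applicator.balloon_radius,
        balloon_center=np.asarray(applicator.balloon_center, float),
    )
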