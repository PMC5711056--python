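"""Physical data for photon transport: the Ir-192 emission spectrum, photon
interaction coefficients for water / air / stainless steel, and Klein-Nishina
(free-electron Compton) sampling.

All energies are in MeV, lengths in cm, mass coefficients in cm^2/g.

The interaction coefficients are shipped as plain-text columnar fixtures under
``brachydmf/data`` (see the commented header of each file for material, density
and provenance).  Public interpolation is log-log, exact at grid nodes.  The
Compton sampler draws the scattered-photon energy fraction from the exact
Klein-Nishina differential cross section on free electrons by
composition-rejection; bound-electron (incoherent scattering function)
corrections are deliberately omitted, which is accurate above ~100 keV where
almost all of the Ir-192 emission lies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import NamedTuple

import numpy as np

ELECTRON_REST_MEV = 0.51099895
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
AVOGADRO = 6.02214076e23

#: default low-energy transport cutoff (MeV); photons below it are terminated
ENERGY_CUTOFF_MEV = 0.002

MATERIALS = ("water", "air", "steel304")


class EmissionLine(NamedTuple):
    """A discrete photon emission line of the source nuclide."""

    energy: float  # MeV
    intensity: float  # photons per decay


@dataclass(frozen=True)
class EnergySpectrum:
    """Discrete emission spectrum with a normalized sampling pmf."""

    lines: tuple[EmissionLine, ...]
    pmf: np.ndarray = field(repr=False)

    @property
    def energies(self) -> np.ndarray:
        return np.array([l.energy for l in self.lines])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([l.intensity for l in self.lines])

    @property
    def total_intensity(self) -> float:
        """Total photon yield (photons per decay)."""
        return float(self.intensities.sum())

    @property
    def mean_energy(self) -> float:
        """Intensity-weighted mean photon energy (MeV)."""
        return float(self.pmf @ self.energies)

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draw emission energies according to the line intensities."""
        u = rng.random(size)
        idx = np.searchsorted(self.cdf, u, side="right")
        idx = np.minimum(idx, len(self.lines) - 1)
        return self.energies[idx]


def _read_columns(name: str) -> tuple[np.ndarray, dict[str, str]]:
    meta: dict[str, str] = {}
    rows = []
    text = resources.files("brachydmf.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        rows.append([float(x) for x in line.split()])
    return np.asarray(rows), meta


@lru_cache(maxsize=None)
def ir192_spectrum() -> EnergySpectrum:
    """The embedded Ir-192 photon emission spectrum.

    Principal gamma lines plus the K x-rays of the Pt/Os daughters, with a
    sampling pmf proportional to the per-decay intensities.
    """
    table, _ = _read_columns("ir192_spectrum.txt")
    lines = tuple(EmissionLine(float(e), float(i)) for e, i in table)
    pmf = table[:, 1] / table[:, 1].sum()
    return EnergySpectrum(lines=lines, pmf=pmf)


@dataclass(frozen=True)
class AttenuationTable:
    """Photon mass coefficients for one material on an ascending energy grid.

    ``mu_rho_nocoh`` is the total mass attenuation coefficient without coherent
    (Rayleigh) scattering — the default transport total — and ``mu_rho_coh``
    the total including it; ``muen_rho`` is the mass energy-absorption
    coefficient used for kerma scoring.
    """

    material: str
    density: float  # g/cm^3
    electrons_per_gram: float  # N_A * Z/A
    energy_grid: np.ndarray  # MeV, strictly ascending
    mu_rho_nocoh: np.ndarray  # cm^2/g
    mu_rho_coh: np.ndarray  # cm^2/g
    muen_rho: np.ndarray  # cm^2/g

    def __post_init__(self):
        e = self.energy_grid
        if not np.all(np.diff(e) > 0):
            raise ValueError(f"{self.material}: energy grid not ascending")
        for arr in (self.mu_rho_nocoh, self.mu_rho_coh, self.muen_rho):
            if np.any(arr <= 0):
                raise ValueError(f"{self.material}: non-positive coefficient")
        if np.any(self.muen_rho > self.mu_rho_nocoh * (1 + 1e-9)):
            raise ValueError(f"{self.material}: muen/rho exceeds mu/rho")

    def interpolate(self, energy, column: str) -> np.ndarray | float:
        """Log-log interpolation of one coefficient column; exact at nodes."""
        e = np.asarray(energy, dtype=float)
        lo, hi = self.energy_grid[0], self.energy_grid[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy out of range for material '{self.material}': "
                f"table covers [{lo:g}, {hi:g}] MeV"
            )
        y = getattr(self, column)
        out = np.exp(
            np.interp(np.log(e), np.log(self.energy_grid), np.log(y))
        )
        return float(out) if np.isscalar(energy) else out


@lru_cache(maxsize=None)
def load_attenuation(material: str) -> AttenuationTable:
    """Load the embedded attenuation table for ``material``."""
    if material not in MATERIALS:
        raise KeyError(f"unknown material '{material}'; known: {MATERIALS}")
    table, meta = _read_columns(f"mu_{material}.txt")
    return AttenuationTable(
        material=material,
        density=float(meta["density_g_cm3"]),
        electrons_per_gram=float(meta["electrons_per_gram_Z_over_A"]) * AVOGADRO,
        energy_grid=table[:, 0],
        mu_rho_nocoh=table[:, 1],
        mu_rho_coh=table[:, 2],
        muen_rho=table[:, 3],
    )


_KINDS = {
    "total": "mu_rho_nocoh",
    "total_with_coherent": "mu_rho_coh",
    "energy_absorption": "muen_rho",
}


def mu_over_rho(material: str, energy, kind: str = "total"):
    """Mass coefficient (cm^2/g) for ``material`` at ``energy`` (MeV).

    ``kind`` is one of ``total`` (without coherent scattering, the transport
    default), ``total_with_coherent`` or ``energy_absorption``.
    """
    try:
        column = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown kind '{kind}'; expected one of {list(_KINDS)}")
    return load_attenuation(material).interpolate(energy, column)


# --------------------------------------------------------------------------
# Klein-Nishina


def kn_total_cross_section(energy: float) -> float:
    """Total Klein-Nishina cross section per free electron (cm^2)."""
    a = energy / ELECTRON_REST_MEV
    re2 = CLASSICAL_ELECTRON_RADIUS_CM**2
    t = 1.0 + 2.0 * a
    return (
        2.0
        * np.pi
        * re2
        * (
            (1.0 + a) / a**2 * (2.0 * (1.0 + a) / t - np.log(t) / a)
            + np.log(t) / (2.0 * a)
            - (1.0 + 3.0 * a) / t**2
        )
    )


def kn_differential(energy: float, cos_theta) -> np.ndarray:
    """Klein-Nishina differential cross section dsigma/dOmega (cm^2/sr)."""
    a = energy / ELECTRON_REST_MEV
    c = np.asarray(cos_theta, dtype=float)
    eps = 1.0 / (1.0 + a * (1.0 - c))  # E'/E
    re2 = CLASSICAL_ELECTRON_RADIUS_CM**2
    return 0.5 * re2 * eps**2 * (eps + 1.0 / eps - (1.0 - c**2))


def sample_compton(
    energy: float, rng: np.random.Generator, size: int | None = None
):
    """Sample Compton scattering of a photon of ``energy`` on a free electron.

    Returns ``(scattered_energy, cos_scatter_angle)``; arrays when ``size``
    is given.  The energy fraction eps = E'/E is drawn on
    [1/(1+2a), 1] from the exact Klein-Nishina density by the standard
    composition-rejection scheme (mixture of 1/eps and eps densities with a
    [1 - eps sin^2(theta)/(1+eps^2)] acceptance factor).
    """
    if not energy > 0:
        raise ValueError("photon energy must be positive")
    a = energy / ELECTRON_REST_MEV
    n = 1 if size is None else int(size)
    eps0 = 1.0 / (1.0 + 2.0 * a)
    w1 = -np.log(eps0)
    w2 = 0.5 * (1.0 - eps0**2)
    p1 = w1 / (w1 + w2)
    out_eps = np.empty(n)
    filled = 0
    while filled < n:
        m = max(n - filled, 64)
        u1, u2, u3 = rng.random(m), rng.random(m), rng.random(m)
        eps = np.where(
            u1 < p1, eps0 * np.exp(u2 * w1), np.sqrt(eps0**2 + u2 * (1.0 - eps0**2))
        )
        t = (1.0 - eps) / (a * eps)
        sin2 = t * (2.0 - t)
        acc = u3 <= 1.0 - eps * sin2 / (1.0 + eps**2)
        take = eps[acc][: n - filled]
        out_eps[filled : filled + take.size] = take
        filled += take.size
    cos_theta = 1.0 - (1.0 - out_eps) / (a * out_eps)
    e_out = out_eps * energy
    if size is None:
        return float(e_out[0]), float(cos_theta[0])
    return e_out, cos_theta


# --------------------------------------------------------------------------
# Engine lookup tables


@dataclass(frozen=True)
class TransportTables:
    """Uniform-in-log-energy lookup arrays consumed by the transport engine.

    Linear attenuation coefficients (1/cm) per material, the Compton share of
    each total, and the water mass energy-absorption coefficient for kerma
    scoring.  Row order follows :data:`MATERIALS`.
    """

    log_e0: float
    dlog: float
    n: int
    mu_lin: np.ndarray  # (n_mat, n) total linear attenuation, 1/cm
    p_compton: np.ndarray  # (n_mat, n) Compton fraction of the total
    muen_water: np.ndarray  # (n,) cm^2/g
    densities: np.ndarray  # (n_mat,)
    coherent: bool


@lru_cache(maxsize=None)
def build_transport_tables(
    coherent: bool = False, n: int = 1024, e_min: float = ENERGY_CUTOFF_MEV,
    e_max: float = 1.5,
) -> TransportTables:
    """Precompute engine lookup tables on a uniform log-energy grid.

    With ``coherent`` False (the default) the interaction total is the
    without-coherent column; with True the with-coherent column is used and
    the non-Compton, non-absorption remainder scatters coherently.
    """
    log_e0 = np.log(e_min)
    dlog = (np.log(e_max) - log_e0) / (n - 1)
    e = np.exp(log_e0 + dlog * np.arange(n))
    e = np.clip(e, e_min, e_max)  # guard rounding at the grid ends
    mu_lin = np.empty((len(MATERIALS), n))
    p_comp = np.empty((len(MATERIALS), n))
    dens = np.empty(len(MATERIALS))
    column = "mu_rho_coh" if coherent else "mu_rho_nocoh"
    sigma_kn = np.array([kn_total_cross_section(ei) for ei in e])
    for i, mat in enumerate(MATERIALS):
        tab = load_attenuation(mat)
        dens[i] = tab.density
        mu_rho = tab.interpolate(e, column)
        mu_kn = sigma_kn * tab.electrons_per_gram
        # Compton share of the interaction total; remainder is absorbed
        # (photoelectric; pair production above 1.022 MeV is folded in).
        p_comp[i] = np.clip(mu_kn / mu_rho, 0.0, 1.0)
        mu_lin[i] = mu_rho * dens[i]
    water = load_attenuation("water")
    muen_w = water.interpolate(e, "muen_rho")
    return TransportTables(
        log_e0=log_e0, dlog=dlog, n=n, mu_lin=mu_lin, p_compton=p_comp,
        muen_water=np.asarray(muen_w), densities=dens, coherent=coherent,
    )
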