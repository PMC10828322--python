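"""Material properties: positron stopping power, CSDA range, 511 keV photons.

Four materials cover the whole study: liquid water (soft tissue), polystyrene
(the scintillating-fiber core), dry air, and an optional cortical-bone
stand-in.  The embedded tables live in :mod:`fiberaif._stopping_data`.

Note on ranges: :func:`csda_range` is the continuous-slowing-down path
length, the integral of the reciprocal linear stopping power from a 10 keV
tracking cutoff up to the given energy.  Multiple scattering makes the
actual penetration depth of a positron shorter than this path length; the
transport module provides displacement-based range statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from . import _stopping_data as _d

TRACKING_CUTOFF_KEV = 10.0
COMPTON_EDGE_511_KEV = 511.0 / (1.0 + 2.0 * 511.0 / 510.99895) * (2.0 * 511.0 / 510.99895)


@dataclass(frozen=True)
class Material:
    """A homogeneous medium with embedded interaction data.

    ``stopping_energies`` / ``stopping_values`` tabulate the mass collision
    stopping power (MeV cm^2/g) on a log grid 10 keV - 3 MeV;
    ``mass_attenuation_511`` is the 511 keV mass attenuation coefficient
    (cm^2/g, incoherent); ``radiation_length`` is X0 in g/cm^2.
    """

    name: str
    density: float  # g/cm^3
    stopping_energies: np.ndarray = field(repr=False)
    stopping_values: np.ndarray = field(repr=False)
    mass_attenuation_511: float
    radiation_length: float
    compton_fraction_511: float

    @property
    def mu_511_per_mm(self) -> float:
        """Linear 511 keV attenuation coefficient, 1/mm."""
        return self.mass_attenuation_511 * self.density / 10.0

    def stopping_table_to_csv(self, path) -> None:
        """Export the embedded stopping-power table as two-column CSV."""
        np.savetxt(
            path,
            np.column_stack([self.stopping_energies, self.stopping_values]),
            delimiter=",",
            header="energy_keV,mass_stopping_MeV_cm2_g",
            comments="",
        )

    @property
    def radiation_length_mm(self) -> float:
        return self.radiation_length / self.density * 10.0


def _make(name: str, table: np.ndarray, density: float | None = None) -> Material:
    key = "water" if name == "bone" else name
    return Material(
        name=name,
        density=_d.DENSITY[name] if density is None else density,
        stopping_energies=_d.ENERGY_GRID_KEV,
        stopping_values=table,
        mass_attenuation_511=_d.MU_RHO_511[name],
        radiation_length=_d.X0_G_CM2[name],
        compton_fraction_511=_d.COMPTON_FRACTION_511[key],
    )


#: Material registry.  "bone" reuses the water composition at cortical-bone
#: density 1.85 g/cm^3 (the study's anatomies never state a bone
#: composition); scenes may also assign plain water to bone inserts.
MATERIALS: Dict[str, Material] = {
    "water": _make("water", _d.STOPPING_WATER),
    "polystyrene": _make("polystyrene", _d.STOPPING_POLYSTYRENE),
    "air": _make("air", _d.STOPPING_AIR),
    "bone": _make("bone", _d.STOPPING_WATER),
}


def get_material(name: str) -> Material:
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; registered: {sorted(MATERIALS)}"
        ) from None


def mass_stopping_power(material: Material, energy) -> np.ndarray | float:
    """Mass collision stopping power, MeV cm^2/g (log-log interpolation)."""
    E = np.asarray(energy, dtype=float)
    lo, hi = material.stopping_energies[0], material.stopping_energies[-1]
    if np.any(E < lo) or np.any(E > hi):
        raise ValueError(f"energy outside table domain [{lo}, {hi}] keV")
    out = 10.0 ** np.interp(
        np.log10(E),
        np.log10(material.stopping_energies),
        np.log10(material.stopping_values),
    )
    return float(out) if np.isscalar(energy) else out


def stopping_power(material: Material, energy) -> np.ndarray | float:
    """Linear collision stopping power, MeV/cm."""
    out = np.asarray(mass_stopping_power(material, energy)) * material.density
    return float(out) if np.isscalar(energy) else out


def stopping_power_kev_mm(material: Material, energy) -> np.ndarray | float:
    """Linear collision stopping power in keV/mm (transport units)."""
    out = np.asarray(stopping_power(material, energy)) * 100.0
    return float(out) if np.isscalar(energy) else out


def csda_range(material: Material, energy: float) -> float:
    """CSDA path length from the 10 keV cutoff up to ``energy``, in mm.

    Strictly increasing in energy; 0 at the cutoff by convention.
    """
    E = float(energy)
    lo = TRACKING_CUTOFF_KEV
    if E < lo or E > material.stopping_energies[-1]:
        raise ValueError("energy outside table domain")
    if E == lo:
        return 0.0
    grid = np.linspace(lo, E, 2000)
    inv_s = 1.0 / stopping_power_kev_mm(material, grid)
    return float(np.trapezoid(inv_s, grid))


def photon_interaction_probability(material: Material, path_length_mm: float):
    """1 - exp(-mu * L) for a 511 keV photon crossing ``path_length_mm``."""
    L = np.asarray(path_length_mm, dtype=float)
    if np.any(L < 0.0):
        raise ValueError("path length must be >= 0")
    out = 1.0 - np.exp(-material.mu_511_per_mm * L)
    return float(out) if np.isscalar(path_length_mm) else out


def compton_edge(photon_energy_kev: float) -> float:
    """Maximum single-scatter energy transfer to an electron, keV."""
    k = photon_energy_kev / 510.99895
    return photon_energy_kev * 2.0 * k / (1.0 + 2.0 * k)


def klein_nishina_recoil_pdf(photon_energy_kev: float, T) -> np.ndarray:
    """Normalized Klein-Nishina electron recoil-energy density (1/keV).

    Used as the quadrature oracle for the sampler; derived from the
    single-differential cross-section in the scattered-photon fraction
    eps = E'/E via T = E (1 - eps).
    """
    E = float(photon_energy_kev)
    k = E / 510.99895
    T = np.asarray(T, dtype=float)
    eps = 1.0 - T / E
    eps0 = 1.0 / (1.0 + 2.0 * k)
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = 1.0 - (1.0 - eps) / (k * eps)
        sin2 = 1.0 - cost**2
        f = (1.0 / eps + eps) * (1.0 - eps * sin2 / (1.0 + eps**2))
    f = np.where((eps >= eps0) & (eps <= 1.0) & (T >= 0.0), f, 0.0)
    # normalize on a fine grid once
    eg = np.linspace(0.0, compton_edge(E), 4001)
    epsg = 1.0 - eg / E
    with np.errstate(divide="ignore", invalid="ignore"):
        cg = 1.0 - (1.0 - epsg) / (k * epsg)
        fg = (1.0 / epsg + epsg) * (1.0 - epsg * (1.0 - cg**2) / (1.0 + epsg**2))
    fg = np.where(np.isfinite(fg), fg, 0.0)
    norm = np.trapezoid(fg, eg)
    return f / norm


def sample_compton_deposit(photon_energy_kev: float, rng: np.random.Generator, n: int = 1):
    """Sample Klein-Nishina electron recoil energies (keV).

    Standard composition-rejection sampling of the scattered-photon fraction
    eps; the deposit is E(1 - eps), bounded by the Compton edge (340.7 keV
    for 511 keV photons).
    """
    E = float(photon_energy_kev)
    if E <= 0.0:
        raise ValueError("photon energy must be positive")
    k = E / 510.99895
    eps0 = 1.0 / (1.0 + 2.0 * k)
    a1 = np.log(1.0 / eps0)
    a2 = 0.5 * (1.0 - eps0**2)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = 2 * (n - filled) + 16
        u1, u2, u3 = rng.random(m), rng.random(m), rng.random(m)
        eps = np.where(
            u1 < a1 / (a1 + a2),
            eps0 * np.exp(a1 * u2),
            np.sqrt(eps0**2 + (1.0 - eps0**2) * u2),
        )
        cost = 1.0 - (1.0 - eps) / (k * eps)
        sin2 = 1.0 - cost**2
        g = 1.0 - eps * sin2 / (1.0 + eps**2)
        acc = eps[u3 <= g]
        take = min(len(acc), n - filled)
        out[filled : filled + take] = E * (1.0 - acc[:take])
        filled += take
    return float(out[0]) if n == 1 else out
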