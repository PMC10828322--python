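"""Isotope constants and positron (beta-plus) emission spectra.

The two radionuclides studied, ``F18`` and ``Ga68``, differ mainly in their
beta endpoint energy (633.5 vs 1899.1 keV) and branching fraction of decays
that emit a positron (0.9673 vs 0.8914).  The emission spectrum follows the
allowed beta shape

    N(T) dT  ~  p * E_tot * (Q - T)^2 * F(Z, T) dT

where ``T`` is the positron kinetic energy, ``Q`` the endpoint, ``p`` and
``E_tot`` the positron momentum and total energy, and ``F`` the Fermi
function for the daughter nucleus.  A nonrelativistic point-charge Fermi
function is used; for a positron the Coulomb interaction with the daughter
is repulsive so the spectrum is suppressed at low energies,

    F(Z, T) = 2*pi*eta / (1 - exp(-2*pi*eta)),   eta = -alpha * Z / beta.

Sampling is by tabulated inverse-CDF on a 1 keV grid, deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

MEC2_KEV = 510.99895  # positron rest energy, keV
_ALPHA = 1.0 / 137.035999084
_PDF_GRID_STEP_KEV = 1.0


@dataclass(frozen=True)
class Isotope:
    """Decay constants of a positron emitter.

    Parameters
    ----------
    endpoint_energy : float
        Maximum positron kinetic energy, keV.
    branching_fraction : float
        Fraction ``f`` of decays emitting a positron.
    half_life : float
        Physical half-life, seconds.
    daughter_atomic_number : int
        Z of the daughter nucleus, used by the Fermi function.
    """

    name: str
    endpoint_energy: float
    branching_fraction: float
    half_life: float
    daughter_atomic_number: int
    positron_rest_energy: float = MEC2_KEV

    def __post_init__(self) -> None:
        if not (0.0 < self.branching_fraction <= 1.0):
            raise ValueError("branching fraction must be in (0, 1]")
        if self.endpoint_energy <= 0.0:
            raise ValueError("endpoint energy must be positive")
        if self.half_life <= 0.0:
            raise ValueError("half-life must be positive")

    @property
    def decay_constant(self) -> float:
        """ln2 / half-life, 1/s."""
        return np.log(2.0) / self.half_life


#: Registry of the isotopes used in the study.  Half-lives are the standard
#: evaluated values (109.77 min for 18F, 67.71 min for 68Ga); endpoints and
#: branching fractions are the evaluated constants for the dominant
#: beta-plus branch.
ISOTOPES: Dict[str, Isotope] = {
    "F18": Isotope("F18", 633.5, 0.9673, 109.77 * 60.0, 8),
    "Ga68": Isotope("Ga68", 1899.1, 0.8914, 67.71 * 60.0, 30),
}


def get_isotope(name: str) -> Isotope:
    try:
        return ISOTOPES[name]
    except KeyError:
        raise KeyError(
            f"unknown isotope {name!r}; registered: {sorted(ISOTOPES)}"
        ) from None


def decay_constant(isotope: Isotope) -> float:
    """Decay constant lambda = ln2 / half-life, in 1/s."""
    return isotope.decay_constant


def fermi_function(Z: int, kinetic_energy: np.ndarray) -> np.ndarray:
    """Nonrelativistic point-charge Fermi function for beta-plus decay."""
    T = np.asarray(kinetic_energy, dtype=float)
    etot = T + MEC2_KEV
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.sqrt(np.clip(etot**2 - MEC2_KEV**2, 0.0, None)) / etot
        x = 2.0 * np.pi * (-_ALPHA * Z / beta)  # repulsive for positrons
        out = x / (1.0 - np.exp(-x))
    return np.where(T <= 0.0, 0.0, out)


def _unnormalized_shape(isotope: Isotope, T: np.ndarray) -> np.ndarray:
    Q = isotope.endpoint_energy
    T = np.asarray(T, dtype=float)
    etot = T + MEC2_KEV
    p = np.sqrt(np.clip(etot**2 - MEC2_KEV**2, 0.0, None))
    shape = p * etot * np.clip(Q - T, 0.0, None) ** 2
    shape = shape * fermi_function(isotope.daughter_atomic_number, T)
    return np.where((T <= 0.0) | (T >= Q), 0.0, shape)


@dataclass
class BetaSpectrum:
    """Tabulated allowed beta-plus spectrum on a uniform energy grid.

    ``pdf`` is normalized so that the trapezoidal integral over
    ``[0, endpoint]`` is 1 (to better than 1e-6); ``cdf`` supports
    inverse-CDF sampling.
    """

    isotope: Isotope
    energies: np.ndarray = field(repr=False)
    pdf: np.ndarray = field(repr=False)
    cdf: np.ndarray = field(repr=False)

    @property
    def mean_energy(self) -> float:
        """Spectrum mean kinetic energy by quadrature, keV."""
        return float(np.trapezoid(self.energies * self.pdf, self.energies))

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.energies, self.pdf]),
            delimiter=",",
            header="energy_keV,density_per_keV",
            comments="",
        )


_SPECTRUM_CACHE: Dict[str, BetaSpectrum] = {}


def build_spectrum(isotope: Isotope) -> BetaSpectrum:
    """Tabulate the normalized beta spectrum on a 1 keV grid (cached)."""
    cached = _SPECTRUM_CACHE.get(isotope.name)
    if cached is not None and cached.isotope == isotope:
        return cached
    Q = isotope.endpoint_energy
    n = int(np.ceil(Q / _PDF_GRID_STEP_KEV)) + 1
    E = np.linspace(0.0, Q, n)
    raw = _unnormalized_shape(isotope, E)
    norm = np.trapezoid(raw, E)
    pdf = raw / norm
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(E))])
    cdf /= cdf[-1]
    spec = BetaSpectrum(isotope, E, pdf, cdf)
    _SPECTRUM_CACHE[isotope.name] = spec
    return spec


def beta_pdf(isotope: Isotope, energy) -> np.ndarray | float:
    """Normalized allowed-shape density at ``energy`` (keV), in 1/keV.

    Raises for energies outside ``[0, endpoint]``.
    """
    E = np.asarray(energy, dtype=float)
    if np.any(E < 0.0) or np.any(E > isotope.endpoint_energy):
        raise ValueError("energy outside [0, endpoint]")
    spec = build_spectrum(isotope)
    out = np.interp(E, spec.energies, spec.pdf)
    return float(out) if np.isscalar(energy) else out


def sample_beta_energy(isotope: Isotope, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. positron kinetic energies (keV), inverse-CDF."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = build_spectrum(isotope)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return np.interp(u, spec.cdf, spec.energies)
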