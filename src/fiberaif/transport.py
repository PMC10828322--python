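"""Monte Carlo engine: positron and photon histories and fiber tallies.

The positron model is mixed condensed-history continuous slowing down
along the embedded stopping-power tables: Highland-style Gaussian angular
diffusion per step (the "detour" model) plus explicit Wentzel hard elastic
events beyond 30 degrees, a 10 keV tracking cutoff with local energy
deposit, and annihilation at rest into two back-to-back 511 keV photons.  Photons are traced with segment-wise exponential
attenuation and interact at most once: a Compton recoil deposit if the
sampled interaction lies in a fiber, absorption otherwise.

The angular-diffusion strength ``scatter_scale`` is calibrated once against
the printed mean/maximum positron ranges in water and against nothing else;
see ``docs/methods.md``.

Background (body) sources use forced-direction importance sampling by
default: photon directions are drawn uniformly in the cone subtending the
detector's bounding sphere and carry the cone's solid-angle fraction as a
statistical weight, which stands in for the very large analog history
counts of a full-scale run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels as K
from .geometry import Scene, Volume
from .materials import MATERIALS, csda_range, get_material
from .nuclear_data import Isotope, build_spectrum, get_isotope

#: Calibrated Highland scale; see docs/methods.md (range calibration).
DEFAULT_SCATTER_SCALE = 0.7

_MAT_ORDER = ("water", "polystyrene", "air", "bone")
_MAT_INDEX = {m: i for i, m in enumerate(_MAT_ORDER)}


@dataclass(frozen=True)
class TransportConfig:
    """Knobs of the condensed-history engine.

    ``step_fraction`` is the fractional energy loss per step (5% default);
    ``tracking_cutoff`` the energy (keV) below which the residual is
    deposited locally; ``max_step_mm`` caps geometric step length in thin
    media such as air.
    """

    n_histories: int = 10_000
    seed: int = 0
    step_fraction: float = 0.05
    tracking_cutoff: float = 10.0
    detour_model: str = "gaussian_scatter"  # or "none"
    scatter_scale: float = DEFAULT_SCATTER_SCALE
    max_step_mm: float = 200.0
    background_variance_reduction: bool = True
    energy_bin_width: float = 10.0
    energy_max: float = 2000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.step_fraction <= 0.2):
            raise ValueError("step_fraction must be in (0, 0.2]")
        if self.tracking_cutoff < 10.0:
            raise ValueError("tracking cutoff must be >= 10 keV")
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if self.detour_model not in ("none", "gaussian_scatter"):
            raise ValueError("detour_model must be 'none' or 'gaussian_scatter'")

    @property
    def effective_scatter_scale(self) -> float:
        return 0.0 if self.detour_model == "none" else self.scatter_scale


def _packed_materials():
    from . import _stopping_data as _d

    logE = np.log10(MATERIALS["water"].stopping_energies)
    logS = np.vstack([np.log10(MATERIALS[m].stopping_values) for m in _MAT_ORDER])
    s_scale = np.array([MATERIALS[m].density * 100.0 for m in _MAT_ORDER])
    x0_mm = np.array([MATERIALS[m].radiation_length_mm for m in _MAT_ORDER])
    mu_mm = np.array([MATERIALS[m].mu_511_per_mm for m in _MAT_ORDER])
    k_hard = np.array([_d.HARD_SCATTER_K_MM[m] for m in _MAT_ORDER])
    z_eff = np.array([_d.Z_EFF[m] for m in _MAT_ORDER])
    return logE, logS, s_scale, x0_mm, mu_mm, k_hard, z_eff


_PACKED_MATS = _packed_materials()


@dataclass
class PackedScene:
    """Flat-array mirror of a Scene for the numba kernels."""

    scene: Scene
    kind: np.ndarray
    params: np.ndarray
    priority: np.ndarray
    mat: np.ndarray
    is_fiber: np.ndarray
    names: List[str]

    @classmethod
    def from_scene(cls, scene: Scene) -> "PackedScene":
        n = len(scene.volumes)
        kind = np.zeros(n, dtype=np.int64)
        params = np.zeros((n, 8))
        prio = np.zeros(n, dtype=np.int64)
        mat = np.zeros(n, dtype=np.int64)
        fib = np.zeros(n, dtype=np.int64)
        for i, v in enumerate(scene.volumes):
            params[i, 0:3] = v.center
            if v.shape == "cylinder":
                kind[i] = 0
                params[i, 3:6] = v.axis
                params[i, 6] = v.radius
                params[i, 7] = v.length / 2.0
            else:
                kind[i] = 1
                params[i, 3:6] = np.asarray(v.edges) / 2.0
            prio[i] = v.priority
            mat[i] = _MAT_INDEX[v.material]
            fib[i] = 1 if v.role == "fiber" else 0
        return cls(scene, kind, params, prio, mat, fib, [v.name for v in scene.volumes])


def _derive_seed(seed: int, stream: int) -> int:
    return int((seed * 1_000_003 + 7919 * stream + 12345) % (2**31 - 1))


@dataclass
class DepositRecord:
    """Outcome of a single history."""

    origin_role: str
    particle: str
    deposited_energy: float  # keV, summed over fiber volumes
    emission_point: Tuple[float, float, float]
    terminus: str  # stopped_in_fiber | escaped | annihilated_in_tissue


@dataclass
class RoleResult:
    """Raw per-history tallies for one source role of one scene.

    ``e_dep``/``g_dep`` are the fiber deposits of the positron track and of
    its two annihilation photons (summed), per history.  ``dep_matrix``
    holds deposits per volume for energy-bookkeeping checks.
    """

    scene_name: str
    isotope: str
    role: str
    n_histories: int
    energies: np.ndarray
    e_dep: np.ndarray
    g_dep: np.ndarray
    dep_matrix: np.ndarray
    escaped_energy: np.ndarray
    terminus: np.ndarray  # 0 annihilated, 1 escaped world
    annihilation_points: np.ndarray
    volume_names: List[str]

    def efficiency(self, threshold_kev: float = 0.0) -> float:
        """Detected positrons (fiber deposit > threshold) per emitted positron."""
        return float(np.mean(self.e_dep > threshold_kev))

    def efficiency_stderr(self, threshold_kev: float = 0.0) -> float:
        p = self.efficiency(threshold_kev)
        return float(np.sqrt(p * (1.0 - p) / self.n_histories))

    def gamma_detected_fraction(self, threshold_kev: float = 0.0) -> float:
        """Histories detected only through annihilation photons."""
        mask = (self.e_dep <= threshold_kev) & (self.g_dep > threshold_kev)
        return float(np.mean(mask))


@dataclass
class BackgroundResult:
    """Weighted photon tallies for a body-background source.

    Each sampled decay contributes one traced photon direction carrying
    weight ``2 * cone_fraction`` (two annihilation photons per positron,
    each isotropic); in analog mode both photons are traced with weight 1.
    """

    scene_name: str
    isotope: str
    n_decays: int
    weights: np.ndarray
    deposits: np.ndarray
    variance_reduced: bool

    def detections_per_decay(self, threshold_kev: float = 0.0) -> float:
        return float(np.sum(self.weights * (self.deposits > threshold_kev)) / self.n_decays)

    def detections_per_decay_stderr(self, threshold_kev: float = 0.0) -> float:
        x = self.weights * (self.deposits > threshold_kev)
        return float(np.std(x) / np.sqrt(self.n_decays))

    def count_rate(self, activity_bq: float, branching_fraction: float,
                   threshold_kev: float = 0.0) -> float:
        """Background count rate (cps) for a given total source activity."""
        return activity_bq * branching_fraction * self.detections_per_decay(threshold_kev)


@dataclass
class EnergySpectrum:
    """Histogram of fiber deposits per origin role and particle."""

    scene_name: str
    bin_edges: np.ndarray
    counts: Dict[Tuple[str, str], np.ndarray]
    n_histories: Dict[str, float]

    def role_counts(self, role: str, particle: Optional[str] = None) -> np.ndarray:
        if particle is not None:
            return self.counts.get((role, particle), np.zeros(len(self.bin_edges) - 1))
        out = np.zeros(len(self.bin_edges) - 1)
        for (r, _p), c in self.counts.items():
            if r == role:
                out = out + c
        return out

    def normalized(self, role: str) -> np.ndarray:
        c = self.role_counts(role)
        tot = c.sum()
        return c / tot if tot > 0 else c

    def to_frame(self):
        import pandas as pd

        data = {"bin_lo_keV": self.bin_edges[:-1], "bin_hi_keV": self.bin_edges[1:]}
        for (role, particle), c in sorted(self.counts.items()):
            data[f"{role}:{particle}"] = c
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def histogram_intersection(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap of two normalized histograms, in [0, 1]."""
    return float(np.minimum(a, b).sum())


def _emission_length_mm(scene: Scene, volume: Volume) -> float:
    """Axial extent of the vessel section whose decays are tallied.

    Decays are simulated over the vessel section the detector subtends
    (the axial overlap with the fiber, which is centered on the vessel):
    positrons from beyond the fiber ends have sub-millimetre ranges and
    cannot reach it, and the sensitivity definition divides by the same
    subtended volume, keeping the efficiency/volume bookkeeping
    consistent.
    """
    full = volume.length if volume.shape == "cylinder" else volume.edges[2]
    if volume.role in ("source_artery", "source_vein"):
        overlap = scene.meta.get("fiber_overlap_mm", full)
        return float(min(full, overlap))
    return float(full)


def _sample_emissions(
    scene: Scene, volumes: Sequence[Volume], isotope: Isotope, n: int, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    lengths = np.array([_emission_length_mm(scene, v) for v in volumes])
    full_lengths = np.array(
        [v.length if v.shape == "cylinder" else v.edges[2] for v in volumes])
    vols_mm3 = np.array([v.volume_mm3() for v in volumes]) * lengths / full_lengths
    counts = rng.multinomial(n, vols_mm3 / vols_mm3.sum())
    chunks = []
    for v, c, lz in zip(volumes, counts, lengths):
        if c == 0:
            continue
        p = scene.sample_in_volume(v, c, rng)
        if lz < (v.length if v.shape == "cylinder" else v.edges[2]):
            # resample the axial coordinate uniformly over the subtended span
            p[:, 2] = v.center[2] + rng.uniform(-lz / 2.0, lz / 2.0, c)
        chunks.append(p)
    pts = np.vstack(chunks)
    rng.shuffle(pts, axis=0)
    spec = build_spectrum(isotope)
    energies = np.interp(rng.random(n), spec.cdf, spec.energies)
    return pts, energies


def simulate_positron_source(
    scene: Scene,
    isotope: Isotope | str,
    source_role: str,
    config: TransportConfig,
    track_photons: bool = True,
) -> RoleResult:
    """Transport ``config.n_histories`` positrons emitted uniformly in the
    volumes of ``source_role`` and tally fiber deposits per history."""
    iso = get_isotope(isotope) if isinstance(isotope, str) else isotope
    volumes = scene.volumes_by_role(source_role)
    if not volumes:
        raise ValueError(f"scene has no volumes with role {source_role!r}")
    packed = PackedScene.from_scene(scene)
    pts, energies = _sample_emissions(
        scene, volumes, iso, config.n_histories, _derive_seed(config.seed, 1)
    )
    logE, logS, s_scale, x0_mm, mu_mm, k_hard, z_eff = _PACKED_MATS
    e_dep, g_dep, dep, esc, term, annih = K.positron_batch(
        packed.kind, packed.params, packed.priority, packed.mat, packed.is_fiber,
        logE, logS, s_scale, x0_mm, mu_mm, k_hard, z_eff,
        pts, energies,
        config.step_fraction, config.tracking_cutoff,
        config.effective_scatter_scale, config.max_step_mm,
        _derive_seed(config.seed, 2), 1 if track_photons else 0,
    )
    return RoleResult(
        scene_name=scene.name, isotope=iso.name, role=source_role,
        n_histories=config.n_histories, energies=energies,
        e_dep=e_dep, g_dep=g_dep, dep_matrix=dep, escaped_energy=esc,
        terminus=term, annihilation_points=annih, volume_names=packed.names,
    )


def run_positron_history(
    scene: Scene, isotope: Isotope | str, source_volume: str,
    config: TransportConfig,
) -> DepositRecord:
    """Single positron history emitted in the named source volume."""
    vol = scene.volume(source_volume)
    if not vol.role.startswith("source_"):
        raise ValueError(f"volume {source_volume!r} is not a source volume")
    sub = Scene(
        name=scene.name, volumes=scene.volumes,
        activity=scene.activity, activity_kind=scene.activity_kind,
        meta=scene.meta,
    )
    one = replace(config, n_histories=1)
    # restrict emission to the named volume by a single-volume role query
    iso = get_isotope(isotope) if isinstance(isotope, str) else isotope
    packed = PackedScene.from_scene(sub)
    pts, energies = _sample_emissions(sub, [vol], iso, 1, _derive_seed(one.seed, 1))
    logE, logS, s_scale, x0_mm, mu_mm, k_hard, z_eff = _PACKED_MATS
    e_dep, g_dep, dep, esc, term, annih = K.positron_batch(
        packed.kind, packed.params, packed.priority, packed.mat, packed.is_fiber,
        logE, logS, s_scale, x0_mm, mu_mm, k_hard, z_eff, pts, energies,
        one.step_fraction, one.tracking_cutoff,
        one.effective_scatter_scale, one.max_step_mm,
        _derive_seed(one.seed, 2), 1,
    )
    if term[0] == 1:
        terminus = "escaped"
    else:
        stop_vol = sub.locate(annih[0])
        terminus = "stopped_in_fiber" if stop_vol.role == "fiber" else "annihilated_in_tissue"
    return DepositRecord(
        origin_role=vol.role, particle="positron",
        deposited_energy=float(e_dep[0]),
        emission_point=tuple(pts[0]), terminus=terminus,
    )


def run_photon_history(
    scene: Scene, emission_point: Sequence[float], direction: Sequence[float],
    config: TransportConfig, energy_kev: float = 511.0,
) -> DepositRecord:
    """Trace one photon; deposit is nonzero only for a Compton in a fiber."""
    if energy_kev <= 0.0:
        raise ValueError("photon energy must be positive")
    packed = PackedScene.from_scene(scene)
    mu_mm = _PACKED_MATS[4]
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    dep = K.photon_batch(
        packed.kind, packed.params, packed.priority, packed.mat, packed.is_fiber,
        mu_mm, np.asarray([emission_point], dtype=float), d[None, :],
        float(energy_kev), _derive_seed(config.seed, 3),
    )
    return DepositRecord(
        origin_role="air", particle="photon", deposited_energy=float(dep[0]),
        emission_point=tuple(np.asarray(emission_point, dtype=float)),
        terminus="escaped" if dep[0] == 0.0 else "stopped_in_fiber",
    )


def trace_photons(
    scene: Scene,
    points: np.ndarray,
    directions: np.ndarray,
    config: TransportConfig,
    energy_kev: float = 511.0,
) -> np.ndarray:
    """Trace a batch of photons; returns the fiber deposit per photon (keV)."""
    packed = PackedScene.from_scene(scene)
    mu_mm = _PACKED_MATS[4]
    d = np.asarray(directions, dtype=float)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    return K.photon_batch(
        packed.kind, packed.params, packed.priority, packed.mat, packed.is_fiber,
        mu_mm, np.asarray(points, dtype=float), d, float(energy_kev),
        _derive_seed(config.seed, 3),
    )


def _fiber_bounding_sphere(scene: Scene) -> Tuple[np.ndarray, float]:
    fibers = scene.volumes_by_role("fiber")
    centers = np.array([f.center for f in fibers])
    c = centers.mean(axis=0)
    r = 0.0
    for f in fibers:
        if f.shape == "cylinder":
            br = float(np.hypot(f.radius, f.length / 2.0))
        else:
            br = float(np.linalg.norm(np.asarray(f.edges) / 2.0))
        r = max(r, float(np.linalg.norm(np.asarray(f.center) - c)) + br)
    return c, r


def simulate_background_photons(
    scene: Scene,
    isotope: Isotope | str,
    config: TransportConfig,
    n_decays: Optional[int] = None,
) -> BackgroundResult:
    """Photon-only simulation of a ``source_body`` volume.

    Each sampled decay annihilates at its emission point (the positron
    range is negligible on the body scale) and emits two isotropic
    back-to-back 511 keV photons.  With variance reduction enabled, one
    direction per decay is drawn in the cone subtending the detector
    bounding sphere, weighted by twice the cone solid-angle fraction.
    """
    iso = get_isotope(isotope) if isinstance(isotope, str) else isotope
    bodies = scene.volumes_by_role("source_body")
    if not bodies:
        raise ValueError("scene has no source_body volume")
    n = int(n_decays if n_decays is not None else config.n_histories)
    packed = PackedScene.from_scene(scene)
    rng = np.random.default_rng(_derive_seed(config.seed, 4))
    pts = scene.sample_in_volume(bodies[0], n, rng)
    mu_mm = _PACKED_MATS[4]
    if config.background_variance_reduction:
        c, R = _fiber_bounding_sphere(scene)
        to_c = c[None, :] - pts
        dist = np.linalg.norm(to_c, axis=1)
        w_axis = to_c / dist[:, None]
        sin_a = np.clip(R / dist, 0.0, 1.0)
        cos_a = np.sqrt(1.0 - sin_a**2)
        omega = 0.5 * (1.0 - cos_a)  # cone solid-angle fraction
        u = rng.random(n)
        ct = 1.0 - u * (1.0 - cos_a)
        st = np.sqrt(np.clip(1.0 - ct**2, 0.0, None))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        # frame around each axis
        t = np.where(np.abs(w_axis[:, [0]]) < 0.9,
                     np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]))
        uvec = np.cross(w_axis, t)
        uvec /= np.linalg.norm(uvec, axis=1, keepdims=True)
        wvec = np.cross(w_axis, uvec)
        dirs = (ct[:, None] * w_axis
                + (st * np.cos(phi))[:, None] * uvec
                + (st * np.sin(phi))[:, None] * wvec)
        weights = 2.0 * omega
        deposits = K.photon_batch(
            packed.kind, packed.params, packed.priority, packed.mat,
            packed.is_fiber, mu_mm, pts, dirs, 511.0,
            _derive_seed(config.seed, 5),
        )
    else:
        ct = rng.uniform(-1.0, 1.0, n)
        st = np.sqrt(1.0 - ct**2)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        d1 = np.column_stack([st * np.cos(phi), st * np.sin(phi), ct])
        pts2 = np.vstack([pts, pts])
        dirs = np.vstack([d1, -d1])
        weights = np.ones(2 * n)
        deposits = K.photon_batch(
            packed.kind, packed.params, packed.priority, packed.mat,
            packed.is_fiber, mu_mm, pts2, dirs, 511.0,
            _derive_seed(config.seed, 5),
        )
    return BackgroundResult(
        scene_name=scene.name, isotope=iso.name, n_decays=n,
        weights=np.asarray(weights), deposits=deposits,
        variance_reduced=config.background_variance_reduction,
    )


@dataclass
class SceneResult:
    """Per-role tallies plus the binned spectrum for one scene run."""

    scene: Scene
    isotope: str
    config: TransportConfig
    roles: Dict[str, RoleResult]
    background: Optional[BackgroundResult] = None

    def spectrum(self) -> EnergySpectrum:
        edges = np.arange(0.0, self.config.energy_max + self.config.energy_bin_width,
                          self.config.energy_bin_width)
        counts: Dict[Tuple[str, str], np.ndarray] = {}
        n_hist: Dict[str, float] = {}
        for role, rr in self.roles.items():
            pos = rr.e_dep[rr.e_dep > 0.0]
            gam = rr.g_dep[rr.g_dep > 0.0]
            counts[(role, "positron")] = np.histogram(pos, bins=edges)[0].astype(float)
            counts[(role, "photon")] = np.histogram(gam, bins=edges)[0].astype(float)
            n_hist[role] = float(rr.n_histories)
        if self.background is not None:
            b = self.background
            sel = b.deposits > 0.0
            counts[("source_body", "photon")] = np.histogram(
                b.deposits[sel], bins=edges, weights=b.weights[sel]
            )[0]
            n_hist["source_body"] = float(b.n_decays)
        return EnergySpectrum(self.scene.name, edges, counts, n_hist)


def simulate_scene(
    scene: Scene,
    isotope: Isotope | str,
    config: TransportConfig,
    include_background: bool = True,
    n_background_decays: Optional[int] = None,
) -> SceneResult:
    """Independent tallies per source role of a scene (vessels as positron
    histories, body backgrounds as weighted photon histories)."""
    iso = get_isotope(isotope) if isinstance(isotope, str) else isotope
    roles: Dict[str, RoleResult] = {}
    for k, role in enumerate(("source_artery", "source_vein")):
        if scene.volumes_by_role(role):
            cfg = replace(config, seed=_derive_seed(config.seed, 10 + k))
            roles[role] = simulate_positron_source(scene, iso, role, cfg)
    background = None
    if include_background and scene.volumes_by_role("source_body"):
        cfg = replace(config, seed=_derive_seed(config.seed, 20))
        background = simulate_background_photons(scene, iso, cfg, n_background_decays)
    return SceneResult(scene, iso.name, config, roles, background)


def detection_efficiency(
    spectrum: EnergySpectrum, threshold_kev: float, origin_role: str
) -> float:
    """Detected-positron fraction above a lower energy threshold.

    Computed from the binned spectrum: counts in bins whose lower edge is
    at or above the threshold, over the number of emitted positrons.
    """
    if threshold_kev < 0.0:
        raise ValueError("threshold must be >= 0")
    c = spectrum.counts.get((origin_role, "positron"))
    if c is None:
        raise KeyError(f"no positron tally for role {origin_role!r}")
    sel = spectrum.bin_edges[:-1] >= threshold_kev
    return float(c[sel].sum() / spectrum.n_histories[origin_role])


@dataclass
class RangeStatistics:
    """Positron range summary in an infinite homogeneous medium."""

    material: str
    isotope: str
    mean_displacement_mm: float
    max_displacement_mm: float
    csda_endpoint_mm: float
    n_histories: int


def positron_range_statistics(
    material: str,
    isotope: Isotope | str,
    n: int,
    seed: int,
    config: Optional[TransportConfig] = None,
    n_endpoint: Optional[int] = None,
) -> RangeStatistics:
    """Mean and maximum positron range under transport, plus the CSDA
    path length at the endpoint.

    The mean is the average emission-to-annihilation displacement of
    ``n`` spectrum-sampled positrons.  The maximum range is the deepest
    penetration of endpoint-energy positrons, estimated as the 99.9th
    percentile of the displacement distribution over ``n_endpoint``
    histories (default ``min(n, 20000)``; a fixed quantile, unlike the
    ensemble maximum, is stable in the ensemble size): scattering makes it
    shorter than the CSDA path length.
    """
    iso = get_isotope(isotope) if isinstance(isotope, str) else isotope
    mat = get_material(material)
    cfg = config or TransportConfig(n_histories=n, seed=seed)
    spec = build_spectrum(iso)
    rng = np.random.default_rng(_derive_seed(seed, 6))
    energies = np.interp(rng.random(n), spec.cdf, spec.energies)
    logE, logS, s_scale, x0_mm, _, k_hard, z_eff = _PACKED_MATS
    mi = _MAT_INDEX[material]
    disp = K.range_batch(
        logE, logS, s_scale, x0_mm, k_hard, z_eff, mi, energies,
        cfg.step_fraction, cfg.tracking_cutoff,
        cfg.effective_scatter_scale, cfg.max_step_mm, _derive_seed(seed, 7),
    )
    n_ep = int(n_endpoint if n_endpoint is not None else min(n, 20_000))
    ep = np.full(n_ep, iso.endpoint_energy)
    disp_ep = K.range_batch(
        logE, logS, s_scale, x0_mm, k_hard, z_eff, mi, ep,
        cfg.step_fraction, cfg.tracking_cutoff,
        cfg.effective_scatter_scale, cfg.max_step_mm, _derive_seed(seed, 8),
    )
    return RangeStatistics(
        material=material, isotope=iso.name,
        mean_displacement_mm=float(disp.mean()),
        max_displacement_mm=float(np.quantile(disp_ep, 0.999)),
        csda_endpoint_mm=csda_range(mat, iso.endpoint_energy),
        n_histories=n,
    )
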