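"""Monte Carlo engine: tallies, conservation laws, reproducibility."""

import numpy as np
import pytest

from fiberaif import (
    Scene,
    TransportConfig,
    Volume,
    build_human_wrist_scene,
    build_mouse_tail_scene,
    detection_efficiency,
    get_material,
    positron_range_statistics,
    run_photon_history,
    run_positron_history,
    simulate_background_photons,
    simulate_positron_source,
    simulate_scene,
    trace_photons,
)
from fiberaif.materials import COMPTON_EDGE_511_KEV, stopping_power_kev_mm
from fiberaif.nuclear_data import build_spectrum, get_isotope
from fiberaif.transport import histogram_intersection


def _world():
    return Volume("world_air", "cylinder", (0.0, 0.0, 0.0), "air", "air", 0,
                  radius=500.0, length=1000.0)


@pytest.fixture(scope="module")
def wire_in_fiber_scene():
    """A hair-thin source wire embedded in a large fiber block."""
    return Scene(
        name="wire_in_fiber",
        volumes=[
            _world(),
            Volume("block", "box", (0, 0, 0), "polystyrene", "fiber", 1,
                   edges=(10.0, 10.0, 10.0)),
            Volume("wire", "cylinder", (0, 0, 0), "water", "source_artery", 2,
                   radius=0.005, length=8.0),
        ],
        activity={"wire": 1.0},
        activity_kind={"wire": "concentration_kBq_mL"},
    )


class TestPositronHistories:
    def test_source_inside_fiber_detects_everything(self, wire_in_fiber_scene):
        cfg = TransportConfig(n_histories=2_000, seed=1)
        rr = simulate_positron_source(wire_in_fiber_scene, "F18",
                                      "source_artery", cfg)
        # the only undetected histories are near/below the tracking cutoff,
        # which stop inside the hair-thin water wire itself
        assert rr.efficiency(0.0) > 0.99
        energetic = rr.energies > 50.0
        assert np.all(rr.e_dep[energetic] > 0.0)

    def test_energy_conservation_per_history(self, mouse_f18):
        """Deposits + escaping energy account for the initial energy."""
        rr = mouse_f18.roles["source_artery"]
        balance = rr.dep_matrix.sum(axis=1) + rr.escaped_energy - rr.energies
        assert np.max(np.abs(balance)) < 0.1  # keV

    def test_deposits_bounded_by_initial_energy(self, mouse_f18):
        rr = mouse_f18.roles["source_artery"]
        assert np.all(rr.e_dep <= rr.energies + 1e-9)
        assert np.all(rr.e_dep >= 0.0)

    def test_fixed_seed_reproducible(self):
        cfg = TransportConfig(n_histories=1_000, seed=5)
        scene = build_mouse_tail_scene("F18")
        a = simulate_positron_source(scene, "F18", "source_artery", cfg)
        b = simulate_positron_source(scene, "F18", "source_artery", cfg)
        assert np.array_equal(a.e_dep, b.e_dep)
        assert np.array_equal(a.g_dep, b.g_dep)
        assert np.array_equal(a.dep_matrix, b.dep_matrix)

    def test_single_history_record(self):
        cfg = TransportConfig(n_histories=1, seed=2)
        scene = build_mouse_tail_scene("F18")
        rec = run_positron_history(scene, "F18", "artery", cfg)
        assert rec.origin_role == "source_artery"
        assert rec.deposited_energy >= 0.0
        assert rec.terminus in ("stopped_in_fiber", "escaped",
                                "annihilated_in_tissue")
        with pytest.raises(ValueError):
            run_positron_history(scene, "F18", "tail", cfg)

    def test_mouse_artery_efficiency_regression(self):
        """Pinned no-cut artery efficiency for the reference configuration."""
        cfg = TransportConfig(n_histories=20_000, seed=1)
        rr = simulate_positron_source(build_mouse_tail_scene("F18"), "F18",
                                      "source_artery", cfg)
        assert rr.efficiency(0.0) == pytest.approx(0.188, abs=0.012)


class TestPhotonHistories:
    def test_photon_missing_everything_deposits_nothing(self):
        scene = build_mouse_tail_scene("F18")
        cfg = TransportConfig(seed=1)
        rec = run_photon_history(scene, (0.0, -50.0, 0.0), (0.0, -1.0, 0.0), cfg)
        assert rec.deposited_energy == 0.0

    def test_interaction_fraction_closed_form(self):
        """Fraction interacting in a 1 mm fiber slab matches 1-exp(-mu L)."""
        scene = Scene(
            name="slab",
            volumes=[
                _world(),
                Volume("slab", "box", (0, 0, 0), "polystyrene", "fiber", 1,
                       edges=(1.0, 50.0, 50.0)),
            ],
        )
        cfg = TransportConfig(seed=3)
        n = 200_000
        pts = np.tile([-5.0, 0.0, 0.0], (n, 1))
        dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
        dep = trace_photons(scene, pts, dirs, cfg)
        p = get_material("polystyrene")
        expect = 1.0 - np.exp(-p.mu_511_per_mm * 1.0)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(np.mean(dep > 0) - expect) < 3.0 * se
        assert np.all(dep <= COMPTON_EDGE_511_KEV + 1e-9)

    def test_variance_reduction_agrees_with_analog(self):
        """Weighted cone sampling reproduces the analog detection rate."""
        scene = Scene(
            name="toy_bg",
            volumes=[
                _world(),
                Volume("det", "box", (0, 0, 0), "polystyrene", "fiber", 1,
                       edges=(20.0, 20.0, 40.0)),
                Volume("body", "cylinder", (0.0, -60.0, 0.0), "water",
                       "source_body", 1, radius=10.0, length=30.0),
            ],
        )
        vr = simulate_background_photons(
            scene, "F18", TransportConfig(seed=4, background_variance_reduction=True),
            n_decays=60_000)
        an = simulate_background_photons(
            scene, "F18", TransportConfig(seed=5, background_variance_reduction=False),
            n_decays=60_000)
        d_vr, d_an = vr.detections_per_decay(0.0), an.detections_per_decay(0.0)
        s_vr = vr.detections_per_decay_stderr(0.0)
        s_an = an.detections_per_decay_stderr(0.0)
        assert abs(d_vr - d_an) < 3.0 * np.hypot(s_vr, s_an)


class TestSpectraAndEfficiency:
    def test_threshold_monotonicity(self, mouse_f18):
        spec = mouse_f18.spectrum()
        effs = [detection_efficiency(spec, t, "source_artery")
                for t in np.arange(0.0, 700.0, 25.0)]
        assert np.all(np.diff(effs) <= 1e-12)
        assert effs[0] == mouse_f18.roles["source_artery"].efficiency(0.0)

    def test_threshold_above_spectrum_gives_zero(self, mouse_f18):
        spec = mouse_f18.spectrum()
        assert detection_efficiency(spec, 1900.0, "source_artery") == 0.0

    def test_spectra_of_both_isotopes_overlap(self, mouse_f18, mouse_ga68):
        """Thin-fiber transmission spectra look alike for F18 and Ga68."""
        a = mouse_f18.spectrum().normalized("source_artery")
        b = mouse_ga68.spectrum().normalized("source_artery")
        assert histogram_intersection(a, b) >= 0.7

    def test_efficiency_decreases_with_depth(self):
        cfg = TransportConfig(n_histories=10_000, seed=6)
        effs = []
        for depth in (0.0, 1.0, 2.0):
            scene = build_human_wrist_scene("Ga68", vessel_depth_mm=depth,
                                            n_fibers=1, fiber_shape="square")
            effs.append(simulate_positron_source(
                scene, "Ga68", "source_artery", cfg).efficiency(0.0))
        assert effs[0] > effs[1] > effs[2]

    def test_wrist_f18_negligible_at_2mm(self):
        """Hardly any F18 positron crosses 2 mm of tissue (max range 2.16)."""
        cfg = TransportConfig(n_histories=10_000, seed=7)
        rr = simulate_positron_source(
            build_human_wrist_scene("F18", 2.0, 1, "round"), "F18",
            "source_artery", cfg)
        assert rr.efficiency(0.0) < 1e-3

    def test_gamma_share_small_for_vessels(self, mouse_f18):
        rr = mouse_f18.roles["source_artery"]
        share = rr.gamma_detected_fraction(0.0) / (
            rr.efficiency(0.0) + rr.gamma_detected_fraction(0.0))
        assert 0.005 < share < 0.05


class TestRangeStatistics:
    def test_straight_tracks_equal_csda_mean(self):
        """With the detour model off, displacement = CSDA path length."""
        iso = get_isotope("F18")
        spec = build_spectrum(iso)
        cfg = TransportConfig(n_histories=5_000, seed=8, detour_model="none")
        rs = positron_range_statistics("water", "F18", 5_000, 8, cfg)
        # quadrature oracle: spectrum-averaged CSDA path length
        w = get_material("water")
        E = spec.energies[1:]
        grid = np.linspace(10.0, iso.endpoint_energy, 4000)
        inv_s = 1.0 / stopping_power_kev_mm(w, grid)
        cum = np.concatenate([[0.0], np.cumsum(
            (inv_s[1:] + inv_s[:-1]) / 2.0 * np.diff(grid))])
        R = np.interp(np.clip(E, 10.0, None), grid, cum)
        mean_oracle = np.trapezoid(R * spec.pdf[1:], E)
        assert rs.mean_displacement_mm == pytest.approx(mean_oracle, rel=0.02)
        # scattering shortens the displacement
        rs_scatter = positron_range_statistics("water", "F18", 5_000, 8)
        assert rs_scatter.mean_displacement_mm < rs.mean_displacement_mm

    def test_scattered_max_below_csda(self):
        rs = positron_range_statistics("water", "Ga68", 5_000, 9)
        assert rs.max_displacement_mm < rs.csda_endpoint_mm


def test_config_validation():
    with pytest.raises(ValueError):
        TransportConfig(step_fraction=0.5)
    with pytest.raises(ValueError):
        TransportConfig(tracking_cutoff=1.0)
    with pytest.raises(ValueError):
        TransportConfig(n_histories=0)
    with pytest.raises(ValueError):
        TransportConfig(detour_model="banana")
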