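"""Pathway classification and channel-profile observables."""

import numpy as np
import pytest

import permkit as pk
from permkit.event_detection import BT, TB
from permkit.pathways_profiles import DEFAULT_VDW_RADII
from permkit.synthetic_data import AVOGADRO
from conftest import make_trace

GEOM = pk.ChannelGeometry(z_top=18.0, z_bottom=-18.0, cylinder_radius=17.3)


class TestPathwayClassification:
    def test_axial_descent_is_never_lateral(self):
        spec = pk.SyntheticSpec(duration=60.0, seed=2, n_bulk=0, lateral_fraction=0.0)
        bundle, _ = pk.generate_run(spec)
        led = pk.detect_crossings(bundle)
        rep = pk.classify_pathways(led, bundle)
        assert rep.lateral_count == 0
        assert rep.lateral_fraction_tb_k == 0.0

    def test_generator_lateral_fraction_recovered(self):
        frac = 0.2
        lat, tot = 0, 0
        for seed in range(4):
            spec = pk.SyntheticSpec(duration=120.0, seed=seed, n_bulk=0,
                                    lateral_fraction=frac)
            bundle, truth = pk.generate_run(spec)
            led = pk.detect_crossings(bundle)
            rep = pk.classify_pathways(led, bundle)
            lat += rep.lateral.get(("K+", TB), 0)
            tot += rep.total(("K+", TB))
        assert tot > 60
        # early entries are forced axial; allow that bias inside 3 sigma
        sigma = np.sqrt(frac * (1 - frac) / tot)
        assert abs(lat / tot - frac) < 3 * sigma + 10.0 / 120.0 * frac

    def test_partition_is_exact(self, small_run):
        _, bundle, _ = small_run
        led = pk.detect_crossings(bundle)
        rep = pk.classify_pathways(led, bundle)
        for key, n in led.counts().items():
            assert rep.total(key) == n
        assert rep.lateral_count + sum(rep.axial.values()) == len(led)

    def test_truncated_lookback_warns_and_labels_axial(self):
        tr = make_trace([30, 10, -30], dt=0.5)
        bundle = pk.TrajectoryBundle(
            [tr], GEOM,
            pk.SystemMetadata(box_height=160, duration=1.0, membrane_voltage=-102.0),
        )
        led = pk.detect_crossings(bundle)
        with pytest.warns(UserWarning, match="look-back"):
            rep = pk.classify_pathways(led, bundle)
        assert rep.axial.get(("K+", TB)) == 1

    def test_rate_and_fraction_arithmetic(self):
        rep = pk.PathwayReport(
            lateral={("K+", TB): 5}, axial={("K+", TB): 789, ("K+", BT): 295},
            pooled_time_ns=3600.0,
        )
        assert rep.lateral_rate_per_us == pytest.approx(5 / 3.6)
        assert rep.lateral_fraction_tb_k == pytest.approx(5 / 794)
        assert rep.lateral_fraction_all_k == pytest.approx(5 / 1089)


class TestIonDensityProfile:
    @pytest.fixture(scope="class")
    def ideal_gas_bundle(self):
        # iid uniform ions each frame: a 150-mM ideal gas filling the box
        rng = np.random.default_rng(7)
        box = (40.0, 40.0, 60.0)
        vol_l = box[0] * box[1] * box[2] * 1e-27
        n_ions = 120
        conc_mM = n_ions / (AVOGADRO * vol_l) * 1e3
        n_frames = 400
        times = 0.1 * np.arange(n_frames)
        traces = [
            pk.IonTrace(
                f"g{i}", "K+", times,
                rng.uniform([-20, -20, -30], [20, 20, 30], size=(n_frames, 3)),
            )
            for i in range(n_ions)
        ]
        geom = pk.ChannelGeometry(z_top=10.0, z_bottom=-10.0, cylinder_radius=12.0)
        md = pk.SystemMetadata(
            box_height=box[2], duration=times[-1], frame_interval=100.0,
            bulk_concentration=conc_mM, box_x=box[0], box_y=box[1],
            membrane_voltage=-102.0,
        )
        return pk.TrajectoryBundle(traces, geom, md)

    def test_uniform_ions_give_unit_density(self, ideal_gas_bundle):
        grid = pk.ion_density_profile(
            ideal_gas_bundle, stride_ps=100.0, z_range=(-25.0, 25.0)
        )
        dens = grid.columns["density_K+"]
        counts = grid.columns["count_K+"]
        assert dens.mean() == pytest.approx(1.0, abs=0.02)
        # per-bin Poisson counting noise, 4 sigma
        n_frames = 400
        expected = counts.mean() * n_frames
        sigma = np.sqrt(expected) / expected
        assert np.all(np.abs(dens - 1.0) < 4 * sigma + 0.02)

    def test_bulk_disk_expectation_constant(self, ideal_gas_bundle):
        # closed form: c * N_A * pi * r^2 * dz, computed independently
        grid = pk.ion_density_profile(ideal_gas_bundle, z_range=(-5.0, 5.0))
        c = ideal_gas_bundle.metadata.bulk_concentration
        r = ideal_gas_bundle.geometry.cylinder_radius
        expected_per_disk = c * 1e-3 * AVOGADRO * np.pi * r**2 * 0.5 * 1e-27
        implied = grid.columns["count_K+"] / grid.columns["density_K+"]
        np.testing.assert_allclose(implied, expected_per_disk, rtol=1e-9)

    def test_standard_concentration_disk_count(self):
        # at 150 mM in a 17.3-Å disk of 0.5 Å: ~0.0425 ions expected
        expected = 150 * 1e-3 * AVOGADRO * np.pi * 17.3**2 * 0.5 * 1e-27
        assert expected == pytest.approx(0.04246, abs=2e-4)

    def test_empty_bin_is_zero(self):
        tr = make_trace([30.0, 30.0, 30.0])
        md = pk.SystemMetadata(box_height=160, duration=0.2, frame_interval=100.0,
                               membrane_voltage=-102.0)
        bundle = pk.TrajectoryBundle([tr], GEOM, md)
        grid = pk.ion_density_profile(bundle, z_range=(-10, 10))
        assert np.all(grid.columns["density_K+"] == 0.0)


def ring_coords(radius, n=5, z=0.0, center=(0.0, 0.0)):
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang),
         np.full(n, z)]
    )


def brute_force_pore_radius(atoms, radii, z, extent=4.0, step=0.05):
    """Independent oracle: exhaustive 2-D grid search for the widest sphere."""
    best = -np.inf
    for cx in np.arange(-extent, extent + step / 2, step):
        for cy in np.arange(-extent, extent + step / 2, step):
            d = atoms - np.array([cx, cy, z])
            r = np.min(np.sqrt(np.einsum("ij,ij->i", d, d)) - radii)
            best = max(best, r)
    return best


class TestPoreRadius:
    def test_centered_ring_gives_ring_radius_minus_vdw(self):
        prot = pk.ProteinCoordinates(ring_coords(5.0), elements=["C"] * 5)
        grid = pk.pore_radius_profile(prot, z_range=(-0.25, 0.25))
        assert grid.columns["pore_radius"][0] == pytest.approx(5.0 - 1.7, abs=1e-6)

    def test_offset_ring_center_search_recovers_full_radius(self):
        prot = pk.ProteinCoordinates(
            ring_coords(5.0, center=(1.0, 0.0)), elements=["C"] * 5
        )
        grid = pk.pore_radius_profile(prot, z_range=(-0.25, 0.25))
        found = grid.columns["pore_radius"][0]
        assert found == pytest.approx(3.3, abs=0.05)
        # a fixed-axis estimate (no center search) is strictly smaller
        fixed = pk.pore_radius_profile(
            prot, z_range=(-0.25, 0.25), max_steps=0
        ).columns["pore_radius"][0]
        assert fixed < found - 0.5

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        coords = np.concatenate(
            [ring_coords(5.0, center=(0.7, -0.4)), ring_coords(7.5, z=3.0),
             rng.uniform(-8, 8, (10, 3)) + [0, 0, -3.0]]
        )
        far = np.sqrt(coords[:, 0] ** 2 + coords[:, 1] ** 2) > 3.5
        coords = coords[far]  # keep the pore open
        elements = ["C"] * len(coords)
        radii = np.full(len(coords), DEFAULT_VDW_RADII["C"])
        grid = pk.pore_radius_profile(prot := pk.ProteinCoordinates(coords, elements),
                                      z_range=(-1.0, 3.5))
        for zc, val in zip(grid.z_centers, grid.columns["pore_radius"]):
            oracle = brute_force_pore_radius(coords, radii, zc)
            assert val == pytest.approx(oracle, abs=0.05)

    def test_stacked_rings_interpolate_monotonically(self):
        coords = np.concatenate([ring_coords(4.0, z=0.0), ring_coords(8.0, z=6.0)])
        prot = pk.ProteinCoordinates(coords, ["C"] * len(coords))
        grid = pk.pore_radius_profile(prot, z_range=(0.0, 6.0))
        vals = grid.columns["pore_radius"]
        assert np.all(np.diff(vals) > -1e-9)

    def test_empty_slab_marked_unbounded(self):
        prot = pk.ProteinCoordinates(ring_coords(5.0, z=0.0), ["C"] * 5)
        grid = pk.pore_radius_profile(prot, z_range=(40.0, 41.0))
        assert np.all(np.isnan(grid.columns["pore_radius"]))


class TestHydration:
    def make_bundle(self, waters, protein=None):
        tr = make_trace([0.0, 0.0], dt=0.1)
        md = pk.SystemMetadata(box_height=160, duration=0.1, frame_interval=100.0,
                               membrane_voltage=-102.0)
        wat = np.broadcast_to(np.asarray(waters, float), (2, len(waters), 3)).copy()
        prot = None
        if protein is not None:
            coords = np.broadcast_to(np.asarray(protein, float),
                                     (2, len(protein), 3)).copy()
            prot = pk.ProteinCoordinates(coords, ["O"] * len(protein))
        return pk.TrajectoryBundle([tr], GEOM, md, water_oxygens=wat,
                                   protein_atoms=prot)

    def octahedron(self, d):
        return d * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                             [0, 0, 1], [0, 0, -1]], dtype=float)

    def test_six_waters_in_shell(self):
        bundle = self.make_bundle(self.octahedron(3.0))
        grid = pk.hydration_profile(bundle, z_range=(-1.0, 1.0))
        b = np.flatnonzero(grid.columns["n_observations"])[0]
        assert grid.columns["hydration"][b] == pytest.approx(6.0)
        assert grid.columns["replacement"][b] == pytest.approx(0.0)

    def test_protein_oxygens_count_as_replacements(self):
        shell = self.octahedron(3.0)
        bundle = self.make_bundle(shell[:4], protein=shell[4:])
        grid = pk.hydration_profile(bundle, z_range=(-1.0, 1.0))
        b = np.flatnonzero(grid.columns["n_observations"])[0]
        assert grid.columns["hydration"][b] == pytest.approx(4.0)
        assert grid.columns["replacement"][b] == pytest.approx(2.0)

    def test_shell_boundary_is_strictly_exclusive(self):
        bundle = self.make_bundle(self.octahedron(3.52))
        grid = pk.hydration_profile(bundle, z_range=(-1.0, 1.0))
        b = np.flatnonzero(grid.columns["n_observations"])[0]
        assert grid.columns["hydration"][b] == pytest.approx(0.0)

    def test_invariant_under_rotation_about_axis(self):
        shell = self.octahedron(3.0)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        g1 = pk.hydration_profile(self.make_bundle(shell), z_range=(-1, 1))
        g2 = pk.hydration_profile(self.make_bundle(shell @ rot.T), z_range=(-1, 1))
        np.testing.assert_allclose(
            np.nan_to_num(g1.columns["hydration"]),
            np.nan_to_num(g2.columns["hydration"]),
        )

    def test_missing_solvent_stream_errors(self):
        tr = make_trace([0.0, 0.0])
        md = pk.SystemMetadata(box_height=160, duration=0.1, membrane_voltage=-102.0)
        bundle = pk.TrajectoryBundle([tr], GEOM, md)
        with pytest.raises(ValueError, match="water"):
            pk.hydration_profile(bundle)


class TestResidueDensity:
    def test_delta_distribution_integrates_to_one(self):
        coords = np.zeros((1, 25, 3))
        coords[..., 2] = 5.1
        prot = pk.ProteinCoordinates(coords, ["C"] * 25, ["GLU"] * 25)
        grid = pk.residue_position_density(prot, ["GLU"], z_range=(0.0, 10.0))
        dens = grid.columns["P_GLU"]
        assert np.count_nonzero(dens) == 1
        assert dens.sum() * grid.bin_width == pytest.approx(1.0)

    def test_uniform_spread_is_flat_and_types_normalize_independently(self):
        n = 10_000
        rng = np.random.default_rng(1)
        z_glu = np.linspace(0.0, 5.0, n, endpoint=False) + 0.00025
        z_lys = rng.uniform(2.0, 4.0, n)
        coords = np.zeros((1, 2 * n, 3))
        coords[0, :n, 2] = z_glu
        coords[0, n:, 2] = z_lys
        prot = pk.ProteinCoordinates(
            coords, ["C"] * 2 * n, ["GLU"] * n + ["LYS"] * n
        )
        grid = pk.residue_position_density(prot, ["GLU", "LYS"], z_range=(0.0, 5.0))
        for res in ("GLU", "LYS"):
            total = grid.columns[f"P_{res}"].sum() * grid.bin_width
            assert total == pytest.approx(1.0)
        np.testing.assert_allclose(grid.columns["P_GLU"], 0.2, rtol=0.01)

    def test_empty_selection_errors(self):
        prot = pk.ProteinCoordinates(np.zeros((1, 3, 3)), ["C"] * 3, ["GLU"] * 3)
        with pytest.raises(ValueError, match="matches no atoms"):
            pk.residue_position_density(prot, ["ARG"])


class TestAxialDiffusion:
    def make_walk_bundle(self, d_target, n_steps=10_000, seed=0):
        rng = np.random.default_rng(seed)
        dt_ns = 0.01
        sigma = np.sqrt(2 * d_target * dt_ns)
        z = np.cumsum(rng.normal(0, sigma, n_steps))
        z -= z.mean()
        geom = pk.ChannelGeometry(z_top=np.inf, z_bottom=-np.inf, cylinder_radius=1e6)
        times = dt_ns * np.arange(n_steps)
        pos = np.column_stack([np.zeros(n_steps), np.zeros(n_steps), z])
        tr = pk.IonTrace("w", "K+", times, pos)
        md = pk.SystemMetadata(box_height=1e3, duration=times[-1],
                               membrane_voltage=-102.0)
        return pk.TrajectoryBundle([tr], geom, md)

    def test_random_walk_diffusion_recovered_within_10_percent(self):
        d_true = 40.0  # Å²/ns, ~0.2x free K+ diffusion
        bundle = self.make_walk_bundle(d_true)
        out = pk.axial_diffusion(bundle, region=(-1e6, 1e6))
        assert out["D_A2_per_ns"] == pytest.approx(d_true, rel=0.10)
        assert out["D_1e-9_m2_per_s"] == pytest.approx(d_true * 0.01, rel=0.10)

    def test_ballistic_drift_is_flagged(self):
        n = 2000
        times = 0.01 * np.arange(n)
        pos = np.column_stack([np.zeros(n), np.zeros(n), 5.0 * times])
        tr = pk.IonTrace("d", "K+", times, pos)
        geom = pk.ChannelGeometry(z_top=np.inf, z_bottom=-np.inf, cylinder_radius=1e6)
        md = pk.SystemMetadata(box_height=1e3, duration=times[-1],
                               membrane_voltage=-102.0)
        bundle = pk.TrajectoryBundle([tr], geom, md)
        with pytest.raises(ValueError, match="ballistic"):
            pk.axial_diffusion(bundle, region=(-1e6, 1e6))

    def test_empty_region_errors(self, small_run):
        _, bundle, _ = small_run
        with pytest.raises(ValueError, match="resides"):
            pk.axial_diffusion(bundle, region=(500.0, 600.0))
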