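import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from splitmem.analysis import (
    MSDSeries,
    area_per_lipid,
    density_profile,
    diffusion_time,
    fit_diffusion,
    lateral_msd,
    order_parameters,
    pn_angle,
    rdf,
    select_atoms,
    speedup,
    thickness,
)
from splitmem.core import AtomTable, SystemFrame, Trajectory
from splitmem.fixtures import default_chain_definitions, ideal_chain


def _single_particle_traj(velocity, n_frames=50, dt=0.1, box=(100.0, 100.0, 10.0)):
    table = AtomTable(names=["C"], resnames=["BRW"], resids=[1],
                      masses=[12.0])
    frames = []
    for i in range(n_frames):
        pos = np.array([[50.0 + velocity[0] * i * dt,
                         50.0 + velocity[1] * i * dt, 5.0]])
        frames.append(SystemFrame(table, pos, box, time=i * dt))
    return Trajectory(frames)


class TestLateralMsd:
    def test_ballistic_closed_form(self):
        v = np.array([0.3, -0.4])
        traj = _single_particle_traj(v)
        series = lateral_msd(traj)
        expected = (v @ v) * series.lag_times**2
        np.testing.assert_allclose(series.msd, expected, atol=1e-9)

    def test_stationary(self):
        traj = _single_particle_traj(np.zeros(2))
        series = lateral_msd(traj)
        np.testing.assert_allclose(series.msd, 0.0, atol=1e-8)

    def test_msd_zero_at_zero_lag(self, brownian_fit):
        traj = _single_particle_traj(np.array([0.1, 0.1]))
        series = lateral_msd(traj)
        assert series.msd[0] == 0.0
        assert np.all(np.diff(series.lag_times) > 0)

    def test_brownian_recovery(self, brownian_fit):
        assert brownian_fit.D == pytest.approx(0.05, rel=0.10)

    def test_empty_selection_error(self):
        traj = _single_particle_traj(np.zeros(2))
        with pytest.raises(ValueError, match="no molecules"):
            lateral_msd(traj, selection=set())

    def test_rotation_about_z_invariance(self):
        v = np.array([0.3, -0.4])
        traj = _single_particle_traj(v)
        base = lateral_msd(traj).msd
        c, s = np.cos(0.7), np.sin(0.7)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        table = traj.table
        frames = []
        center = np.array([50.0, 50.0, 5.0])
        for f in traj:
            pos = (f.positions - center) @ rot.T + center
            frames.append(SystemFrame(table, pos, f.box, time=f.time))
        rotated = lateral_msd(Trajectory(frames)).msd
        np.testing.assert_allclose(rotated, base, atol=1e-9)


class TestFitDiffusion:
    def test_exact_line(self):
        lags = np.linspace(0, 10, 101)
        series = MSDSeries(lag_times=lags, msd=0.4 * lags,
                           n_origins=np.full(101, 100))
        result = fit_diffusion(series, (1.0, 9.0))
        assert result.D == pytest.approx(0.1)

    def test_constant_msd(self):
        lags = np.linspace(0, 10, 101)
        series = MSDSeries(lag_times=lags, msd=np.full(101, 2.0),
                           n_origins=np.full(101, 100))
        assert fit_diffusion(series, (1.0, 9.0)).D == pytest.approx(0.0)

    def test_window_outside_data(self):
        lags = np.linspace(0, 10, 11)
        series = MSDSeries(lag_times=lags, msd=lags, n_origins=lags + 1)
        with pytest.raises(ValueError, match="window"):
            fit_diffusion(series, (50.0, 400.0))


class TestDiffusionArithmetic:
    def test_closed_form(self):
        assert diffusion_time(1.0, 2.0) == pytest.approx(0.001)

    def test_nonpositive_d_rejected(self):
        with pytest.raises(ValueError):
            diffusion_time(0.0)

    def test_speedup_identity(self):
        assert speedup(0.05, 0.05) == pytest.approx(1.0)

    def test_speedup_zero_denominator(self):
        with pytest.raises(ValueError):
            speedup(1.0, 0.0)


class TestDensityProfile:
    def test_single_atom_unit_conversion(self):
        # hand oracle: m amu in a 1 x 1 x 1 nm bin -> m * 1.66054 kg/m^3
        mass = 18.0
        table = AtomTable(names=["P"], resnames=["POPC"], resids=[1],
                          masses=[mass])
        frame = SystemFrame(table, np.array([[0.5, 0.5, 5.2]]),
                            (1.0, 1.0, 10.0))
        profile = density_profile(frame, bin_width=1.0)
        dens = profile.densities["all"]
        assert dens.sum() == pytest.approx(mass * 1.66053906660, rel=1e-9)
        assert (dens > 0).sum() == 1

    def test_mass_closure(self, popc_system):
        frame, _ = popc_system
        profile = density_profile(frame, bin_width=0.2)
        area = frame.box[0] * frame.box[1]
        integral = profile.densities["all"].sum() * profile.bin_width * area
        total = frame.table.masses.sum() * 1.66053906660
        assert integral == pytest.approx(total, rel=0.01)

    def test_uniform_slab_flat(self):
        rng = np.random.default_rng(3)
        n = 20000
        table = AtomTable(names=["OW"] * n, resnames=["SOL"] * n,
                          resids=list(range(1, n + 1)), masses=[18.0] * n)
        pos = rng.uniform(0, 10, size=(n, 3))
        pos[:, 2] = rng.uniform(0, 10, n)
        frame = SystemFrame(table, pos, (10.0, 10.0, 10.0))
        # membrane COM defaults to lipid atoms; call with water-only system
        profile = density_profile(frame, selections={
            "w": np.ones(n, dtype=bool)}, bin_width=1.0)
        dens = profile.densities["w"]
        inner = dens[dens > 0]
        expected = n / 10.0  # atoms per bin
        sigma = np.sqrt(expected)
        counts = inner / (18.0 * 1.66053906660 / (10 * 10 * 1.0))
        assert np.all(np.abs(counts - expected) < 3 * sigma)

    def test_symmetric_fixture(self, popc_system):
        frame, _ = popc_system
        mask = select_atoms(frame.table, species={"POPC"})
        profile = density_profile(frame, {"lipid": mask}, bin_width=0.4)
        dens = profile.densities["lipid"]
        flipped = dens[::-1]
        scale = dens.max()
        assert np.all(np.abs(dens - flipped) <= 0.05 * scale + 1e-9)

    def test_empty_selection_error(self, popc_system):
        frame, _ = popc_system
        with pytest.raises(ValueError, match="empty"):
            density_profile(frame, {"x": np.zeros(frame.n_atoms, bool)})

    def test_bad_bin_width(self, popc_system):
        frame, _ = popc_system
        with pytest.raises(ValueError, match="bin_width"):
            density_profile(frame, bin_width=0.0)


def _chain_frame(carbons, resname="LIP"):
    n = len(carbons)
    table = AtomTable(names=[f"C{i + 1}A" for i in range(n)],
                      resnames=[resname] * n, resids=[1] * n,
                      masses=[12.011] * n)
    return SystemFrame(table, carbons + 5.0, (20.0, 20.0, 20.0)), table


class TestOrderParameters:
    def test_all_trans_z_aligned(self):
        chain = ideal_chain(10)
        frame, _ = _chain_frame(chain.carbons)
        defs = {"LIP": {"SN1": [f"C{i + 1}A" for i in range(10)]}}
        profile = order_parameters(frame, defs)["SN1"]
        for value in profile.s_cd.values():
            assert value == pytest.approx(-0.5, abs=1e-6)

    def test_explicit_ch_along_z(self):
        # three carbons in the xy plane, explicit hydrogens straight up
        carbons = np.array([[0.0, 0, 0], [0.1, 0.1, 0], [0.2, 0.0, 0]])
        names = ["C1A", "C2A", "C3A", "H1", "H2"]
        h = np.array([[0.1, 0.1, 0.109], [0.1, 0.1, -0.109]])
        table = AtomTable(names=names, resnames=["LIP"] * 5, resids=[1] * 5,
                          masses=[12.011] * 3 + [1.008] * 2)
        pos = np.vstack([carbons, h]) + 5.0
        frame = SystemFrame(table, pos, (20.0, 20.0, 20.0))
        defs = {"LIP": {"SN1": ["C1A", "C2A", "C3A"]}}
        profile = order_parameters(frame, defs, hydrogen_mode="explicit")
        assert profile["SN1"].s_cd[2] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_orientations_average_to_zero(self):
        # Monte-Carlo oracle of the orientational average
        chain = ideal_chain(8)
        rots = Rotation.random(10_000, random_state=7).as_matrix()
        ch = chain.hydrogens - chain.carbons[1:-1, None, :]
        ch = ch.reshape(-1, 3)
        ch /= np.linalg.norm(ch, axis=1)[:, None]
        cos_t = np.einsum("rj,kj->rk", rots[:, 2, :], ch)
        s = 1.5 * cos_t**2 - 0.5
        per_rotation = s.mean(axis=1)
        sem = per_rotation.std(ddof=1) / np.sqrt(len(per_rotation))
        assert abs(per_rotation.mean()) < 3 * sem

    def test_missing_carbon_error(self):
        chain = ideal_chain(5)
        frame, _ = _chain_frame(chain.carbons)
        defs = {"LIP": {"SN1": ["C1A", "C9A"]}}
        with pytest.raises(ValueError, match="C9A"):
            order_parameters(frame, defs)

    def test_fixture_bilayer_ordered_tails(self, popc_system):
        frame, _ = popc_system
        defs = default_chain_definitions(["POPC"])
        profiles = order_parameters(frame, defs)
        for profile in profiles.values():
            for value in profile.s_cd.values():
                assert value == pytest.approx(-0.5, abs=1e-6)


class TestPnAngle:
    def _frame(self, pn_vectors, leaflet="upper"):
        n = len(pn_vectors)
        names, resnames, resids, masses, pos = [], [], [], [], []
        for i, v in enumerate(pn_vectors):
            p = np.array([1.0 + i, 1.0, 6.0 if leaflet == "upper" else 2.0])
            names += ["P", "N", "C1A"]
            resnames += ["POPC"] * 3
            resids += [i + 1] * 3
            masses += [30.974, 14.007, 12.011]
            # ballast carbon keeps the lipid COM on the right side
            pos += [p, p + v, p + np.array([0, 0, -2.0 if leaflet == "upper"
                                            else 2.0])]
        table = AtomTable(names=names, resnames=resnames, resids=resids,
                          masses=masses)
        return SystemFrame(table, np.array(pos), (20.0, 20.0, 8.0))

    def test_vector_along_normal(self):
        frame = self._frame([np.array([0, 0, 1.0]), np.array([0, 0, 1.0])])
        result = pn_angle(frame)
        assert result.mean == pytest.approx(0.0, abs=1e-9)

    def test_vector_in_plane(self):
        frame = self._frame([np.array([1.0, 0, 0]), np.array([0, 1.0, 0])])
        assert pn_angle(frame).mean == pytest.approx(90.0, abs=1e-9)

    def test_fixture_in_plane_vectors(self, popc_system):
        frame, _ = popc_system
        assert pn_angle(frame).mean == pytest.approx(90.0, abs=1e-6)

    def test_species_without_nitrogen_skipped(self, mixed_system):
        frame, _ = mixed_system
        with pytest.warns(UserWarning, match="POPA"):
            result = pn_angle(frame)
        assert np.isfinite(result.mean)


class TestAreaPerLipid:
    def test_simple(self):
        table = AtomTable(names=["P"], resnames=["POPC"], resids=[1],
                          masses=[30.974])
        frame = SystemFrame(table, np.zeros((1, 3)) + 1, (8.0, 8.0, 8.0))
        assert area_per_lipid(frame, 64).mean == pytest.approx(1.0)

    def test_fixture_value(self):
        table = AtomTable(names=["P"], resnames=["POPC"], resids=[1],
                          masses=[30.974])
        frame = SystemFrame(table, np.zeros((1, 3)) + 1,
                            (6.4912, 6.4912, 8.0))
        assert area_per_lipid(frame, 64).mean == pytest.approx(
            6.4912**2 / 64
        )

    def test_constant_box_zero_variance(self):
        table = AtomTable(names=["P"], resnames=["POPC"], resids=[1],
                          masses=[30.974])
        frames = [
            SystemFrame(table, np.zeros((1, 3)) + 1, (8.0, 8.0, 8.0), time=i)
            for i in range(5)
        ]
        result = area_per_lipid(Trajectory(frames), 64)
        assert result.sem == 0.0

    def test_invalid_count(self, popc_system):
        frame, _ = popc_system
        with pytest.raises(ValueError):
            area_per_lipid(frame, 0)


class TestThickness:
    def _frame(self, z_up, z_lo):
        table = AtomTable(names=["P", "P"], resnames=["POPC", "POPC"],
                          resids=[1, 2], masses=[30.974, 30.974])
        pos = np.array([[1.0, 1.0, 5.0 + z_up], [1.0, 1.0, 5.0 + z_lo]])
        return SystemFrame(table, pos, (10.0, 10.0, 10.0))

    def test_simple(self):
        assert thickness(self._frame(2.0, -2.0), {"P"})[0] == pytest.approx(4.0)

    def test_translation_invariance(self):
        frame = self._frame(1.5, -1.5)
        base = thickness(frame, {"P"})[0]
        shifted = frame.copy()
        shifted.positions[:, 2] += 1.0
        assert thickness(shifted, {"P"})[0] == pytest.approx(base)

    def test_fixture_head_planes(self, popc_system):
        frame, _ = popc_system
        assert thickness(frame, {"P"})[0] == pytest.approx(3.8, abs=1e-6)

    def test_single_leaflet_error(self):
        table = AtomTable(names=["P"], resnames=["POPC"], resids=[1],
                          masses=[30.974])
        frame = SystemFrame(table, np.array([[1.0, 1.0, 7.0]]),
                            (10.0, 10.0, 10.0))
        with pytest.raises(ValueError, match="one leaflet"):
            thickness(frame, {"P"})


class TestRdf:
    def test_ideal_gas_flat(self):
        rng = np.random.default_rng(11)
        n = 2000
        table = AtomTable(names=["C"] * n, resnames=["GAS"] * n,
                          resids=list(range(1, n + 1)), masses=[12.0] * n)
        frame = SystemFrame(table, rng.uniform(0, 10, (n, 3)),
                            (10.0, 10.0, 10.0))
        mask = np.ones(n, dtype=bool)
        result = rdf(frame, mask, mask, r_max=4.0, dr=0.2)
        far = result.g[result.r_centers > 1.0]
        assert np.all(np.abs(far - 1.0) < 0.15)
        assert abs(far.mean() - 1.0) < 0.01

    def test_two_particles_single_peak(self):
        table = AtomTable(names=["A", "B"], resnames=["X", "Y"],
                          resids=[1, 2], masses=[1.0, 1.0])
        frame = SystemFrame(table, np.array([[1.0, 1, 1], [1.0, 1, 2.33]]),
                            (10.0, 10.0, 10.0))
        a = np.array([True, False])
        b = np.array([False, True])
        result = rdf(frame, a, b, r_max=4.0, dr=0.1)
        peak_bins = np.nonzero(result.g)[0]
        assert len(peak_bins) == 1
        assert result.r_centers[peak_bins[0]] == pytest.approx(1.35, abs=0.06)

    def test_pair_count_conserved_across_dr(self):
        rng = np.random.default_rng(2)
        n = 300
        table = AtomTable(names=["C"] * n, resnames=["GAS"] * n,
                          resids=list(range(1, n + 1)), masses=[12.0] * n)
        frame = SystemFrame(table, rng.uniform(0, 8, (n, 3)),
                            (8.0, 8.0, 8.0))
        mask = np.ones(n, dtype=bool)
        counts = []
        for dr in (0.1, 0.2):
            result = rdf(frame, mask, mask, r_max=3.0, dr=dr)
            vol = 8.0**3
            shell = (4 / 3) * np.pi * (
                (result.r_centers + dr / 2) ** 3
                - (result.r_centers - dr / 2) ** 3
            )
            counts.append((result.g * n * (n - 1) / vol * shell).sum())
        assert counts[0] == pytest.approx(counts[1], rel=1e-9)

    def test_lateral_mode_flat_for_uniform(self):
        rng = np.random.default_rng(4)
        n = 3000
        table = AtomTable(names=["C"] * n, resnames=["GAS"] * n,
                          resids=list(range(1, n + 1)), masses=[12.0] * n)
        pos = rng.uniform(0, 12, (n, 3))
        frame = SystemFrame(table, pos, (12.0, 12.0, 12.0))
        mask = np.ones(n, dtype=bool)
        result = rdf(frame, mask, mask, r_max=5.0, dr=0.25, mode="lateral_2D")
        far = result.g[result.r_centers > 1.0]
        assert abs(far.mean() - 1.0) < 0.02

    def test_r_max_too_large(self, popc_system):
        frame, _ = popc_system
        mask = select_atoms(frame.table, names={"P"})
        with pytest.raises(ValueError, match="half"):
            rdf(frame, mask, mask, r_max=100.0, dr=0.1)

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        n = 200
        table = AtomTable(names=["C"] * n, resnames=["GAS"] * n,
                          resids=list(range(1, n + 1)), masses=[12.0] * n)
        pos = rng.uniform(0, 8, (n, 3))
        frame = SystemFrame(table, pos, (8.0, 8.0, 8.0))
        mask = np.ones(n, dtype=bool)
        base = rdf(frame, mask, mask, r_max=3.0, dr=0.1).g
        shifted_pos = (pos + np.array([1.1, 2.2, 3.3])) % 8.0
        shifted = SystemFrame(table, shifted_pos, (8.0, 8.0, 8.0))
        moved = rdf(shifted, mask, mask, r_max=3.0, dr=0.1).g
        np.testing.assert_allclose(moved, base, atol=1e-9)
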