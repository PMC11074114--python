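"""Dipolar-noise estimation: closed-form oracles and invariance properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_frame
from spinatmos.constants import molar_to_per_nm3
from spinatmos.dipolar import (MN2P, NVSite, autocorrelation_tau_c,
                               coverage_extrapolation, frame_field_variance,
                               noise_vs_distance, spin_prefactor,
                               trajectory_noise, transverse_variance)
from spinatmos.synthetic import (OUFieldParams, SurrogateSystem,
                                 generate_ou_field, plant_accumulation,
                                 sample_static_ions)
from spinatmos.trajectory import SlabGeometry, Trajectory

CS = MN2P.C_S


class TestSpinPrefactor:
    def test_mn2p_value(self):
        # closed formula with CODATA constants, printed value 1.00574e-5
        assert spin_prefactor(2.5) == pytest.approx(1.00574e-5, rel=1e-3)

    def test_diamagnetic_zero(self):
        assert spin_prefactor(0.0) == 0.0

    def test_spin_half(self):
        # hand evaluation: C_S(1/2) = C_S(5/2) * (3/4)/(35/4) = 8.62e-7 nm^6 T^2
        assert spin_prefactor(0.5) == pytest.approx(8.62e-7, rel=2e-3)

    @pytest.mark.parametrize("bad", [-0.5, 0.3, 1.2])
    def test_invalid_spin_rejected(self, bad):
        with pytest.raises(ValueError):
            spin_prefactor(bad)


class TestFrameFieldVariance:
    nv = NVSite(position=(500.0, 500.0, 0.0))
    smap = {"Mn": MN2P, "Na": "diamagnetic"}

    def test_single_ion_on_axis(self):
        # ion straight above: khat = (0,0,1) so Bz2 = 4 C_S/r^6, Bx2 = By2 = C_S/r^6
        f = make_frame([[500.0, 500.0, 7.0]])
        bx2, by2, bz2 = frame_field_variance(f, self.nv, self.smap)
        assert bz2 == pytest.approx(4 * CS / 7**6, rel=1e-12)
        assert bx2 == pytest.approx(CS / 7**6, rel=1e-12)
        assert by2 == pytest.approx(CS / 7**6, rel=1e-12)

    def test_empty_frame(self):
        f = make_frame(np.empty((0, 3)))
        assert frame_field_variance(f, self.nv, self.smap) == (0.0, 0.0, 0.0)

    def test_component_sum_is_isotropic(self):
        # sum of direction cosines squared is 1, so the sum is 6 C_S/r^6
        f = make_frame([[500.0 + 3.0, 500.0 + 4.0, np.sqrt(49 - 25)]])
        comps = frame_field_variance(f, self.nv, self.smap)
        assert sum(comps) == pytest.approx(6 * CS / 7**6, rel=1e-12)
        assert sum(comps) == pytest.approx(5.13e-10, rel=1e-2)

    def test_diamagnetic_species_skipped(self):
        f = make_frame([[500, 500, 7.0], [500, 500, 3.0]], species=["Mn", "Na"])
        comps = frame_field_variance(f, self.nv, self.smap)
        assert sum(comps) == pytest.approx(6 * CS / 7**6, rel=1e-12)

    def test_guard_names_offending_ion(self):
        f = make_frame([[500.0, 500.0, 0.1]])
        with pytest.raises(ValueError, match=r"\[0\]"):
            frame_field_variance(f, self.nv, self.smap)


@given(st.floats(0.0, np.pi), st.floats(0.0, 2 * np.pi), st.floats(1.0, 30.0))
def test_single_ion_isotropy_identities(theta, phi, r):
    """For any direction, sum = 6 C_S/r^6 and Bperp2 = 4 C_S/r^6 to 1e-12."""
    nv = NVSite(position=(500.0, 500.0, 0.0))
    offset = r * np.array([np.sin(theta) * np.cos(phi),
                           np.sin(theta) * np.sin(phi), np.cos(theta)])
    f = make_frame([np.array([500.0, 500.0, 0.0]) + offset])
    comps = frame_field_variance(f, nv, {"Mn": MN2P}, periodic=False)
    assert sum(comps) == pytest.approx(6 * CS / r**6, rel=1e-12)
    assert transverse_variance(comps) == pytest.approx(4 * CS / r**6, rel=1e-12)


class TestTransverseVariance:
    def test_two_thirds_of_sum(self):
        assert transverse_variance((1.0, 1.0, 1.0)) == pytest.approx(2.0)

    def test_zero(self):
        assert transverse_variance((0.0, 0.0, 0.0)) == 0.0

    def test_single_ion_at_7nm(self):
        assert 4 * CS / 7**6 == pytest.approx(3.42e-10, rel=1e-2)


class TestTrajectoryNoise:
    def test_single_frame_equals_frame_variance(self):
        nv = NVSite(position=(5.0, 5.0, -7.0))
        f = make_frame([[5.0, 5.0, 2.0]], box=(10, 10, 20))
        traj = Trajectory(frames=[f], dt=1.0, species_map={"Mn": MN2P})
        est = trajectory_noise(traj, nv)
        comps = frame_field_variance(f, nv, traj.species_map)
        assert est.bperp2 == pytest.approx(transverse_variance(comps), rel=1e-14)
        assert est.n_frames == 1

    def test_static_configuration_has_zero_std(self):
        nv = NVSite(position=(5.0, 5.0, -7.0))
        f0 = make_frame([[5.0, 5.0, 2.0]], box=(10, 10, 20))
        frames = [make_frame([[5.0, 5.0, 2.0]], box=(10, 10, 20), time=float(k))
                  for k in range(100)]
        traj = Trajectory(frames=frames, dt=1.0, species_map={"Mn": MN2P})
        est = trajectory_noise(traj, nv)
        single = transverse_variance(frame_field_variance(f0, nv, traj.species_map))
        assert est.bperp2 == pytest.approx(single, rel=1e-14)
        assert est.bperp2_std <= 1e-12 * est.bperp2  # numerically zero

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            trajectory_noise(Trajectory(frames=[], dt=1.0), NVSite(position=(0, 0, 0)))

    def test_half_space_monte_carlo_matches_closed_form(self):
        # (2 pi / 3) C_S rho / d^3 for a uniform half-space at 5 mM, d = 7 nm
        rho = molar_to_per_nm3(5.0)
        traj = sample_static_ions(rho, box=(140.0, 140.0, 70.0), n_frames=60, seed=42)
        nv = NVSite(position=(70.0, 70.0, -7.0))
        est = trajectory_noise(traj, nv, keep_series=False)
        closed = 2 * np.pi / 3 * CS * rho / 7**3
        assert closed == pytest.approx(1.85e-10, rel=1e-2)
        # ~2.5e5 samples: expect agreement within a few MC sigma (~8%)
        assert est.bperp2 == pytest.approx(closed, rel=0.25)

    def test_lateral_translation_invariance(self):
        rng = np.random.default_rng(7)
        xyz = rng.uniform(0, 1, (50, 3)) * np.array([10, 10, 15]) + [0, 0, 2]
        nv = NVSite(position=(5.0, 5.0, -7.0))
        smap = {"Mn": MN2P}
        base = frame_field_variance(make_frame(xyz, box=(10, 10, 20)), nv, smap)
        shifted = frame_field_variance(
            make_frame(xyz + np.array([10.0, 20.0, 0.0]), box=(10, 10, 20)), nv, smap)
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_vectorized_sum_matches_naive_double_loop(self):
        rng = np.random.default_rng(11)
        xyz = rng.uniform(0, 1, (100, 3)) * np.array([10, 10, 15]) + [0, 0, 1]
        f = make_frame(xyz, box=(10, 10, 20))
        nv = NVSite(position=(5.0, 5.0, -7.0))
        fast = frame_field_variance(f, nv, {"Mn": MN2P})
        naive = np.zeros(3)
        for p in xyz:
            d = p - np.array(nv.position)
            d[0] -= 10 * round(d[0] / 10)
            d[1] -= 10 * round(d[1] / 10)
            r2 = d @ d
            naive += CS * (1 + 3 * d**2 / r2) / r2**3
        assert fast == pytest.approx(tuple(naive), rel=1e-12)


class TestNoiseVsDistance:
    geom = SlabGeometry(bottom_zero=0.5, top_zero=19.5)

    def _planted(self, height, rng):
        """Rigid ion cloud + molecule blob at the given height above the bottom."""
        cloud = rng.uniform(-1, 1, (20, 3)) * np.array([2, 2, 0.8])
        beads = rng.uniform(-1, 1, (5, 3)) * 0.4
        beads -= beads.mean(axis=0)  # COM sits exactly at the planted height
        frames = []
        for k in range(3):
            centre = np.array([5.0, 5.0, self.geom.bottom_zero + height])
            xyz = np.vstack([centre + beads, centre + cloud])
            frames.append(make_frame(xyz, species=["P"] * 5 + ["Mn"] * 20,
                                     box=(10, 10, 20), time=float(k)))
        return Trajectory(frames=frames, dt=1.0,
                          species_map={"Mn": MN2P, "P": "diamagnetic"})

    def test_rigid_translation_decays_monotonically(self, rng):
        ens = [(self._planted(h, np.random.default_rng(0)), {"species": "P"})
               for h in (1.0, 5.0, 9.0)]
        table = noise_vs_distance(ens, self.geom)
        assert len(table) == 3
        assert table["com_distance"].tolist() == pytest.approx([1.0, 5.0, 9.0], abs=1e-9)
        assert table["bperp2"].is_monotonic_decreasing

    def test_single_replica_single_row(self, rng):
        table = noise_vs_distance([(self._planted(3.0, rng), {"species": "P"})], self.geom)
        assert len(table) == 1

    def test_bottom_top_symmetry(self):
        # mirror-symmetric system: both NV sites see the same noise
        rng = np.random.default_rng(3)
        cloud = rng.uniform(-1, 1, (15, 3))
        mirrored = cloud * np.array([1, 1, -1])
        z_mid = 10.0
        xyz = np.vstack([[5, 5, z_mid - 7], [5, 5, z_mid + 7],
                         np.array([5, 5, z_mid - 7]) + cloud,
                         np.array([5, 5, z_mid + 7]) + mirrored])
        f = make_frame(xyz, species=["P", "P"] + ["Mn"] * 30, box=(10, 10, 20))
        traj = Trajectory(frames=[f], dt=1.0, species_map={"Mn": MN2P, "P": "diamagnetic"})
        bot = noise_vs_distance([(traj, {"species": "P"})], self.geom, side="bottom")
        top = noise_vs_distance([(traj, {"species": "P"})], self.geom, side="top")
        assert bot["bperp2"][0] == pytest.approx(top["bperp2"][0], rel=1e-12)

    def test_missing_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="selection"):
            noise_vs_distance([(self._planted(3.0, rng), {})], self.geom)


class TestCoverageExtrapolation:
    def test_single_image_limit(self):
        # footprint so large that the neighbours are negligible
        out = coverage_extrapolation(1e-9, footprint_area=1e8, nv_depth=7.0)
        assert out == pytest.approx(1e-9, rel=1e-6)

    def test_denser_coverage_increases_noise(self):
        loose = coverage_extrapolation(1e-9, footprint_area=16.0)
        dense = coverage_extrapolation(1e-9, footprint_area=4.0)
        assert dense > loose > 1e-9

    def test_full_coverage_order_of_magnitude(self):
        # per-molecule increments around 1.35e-9 T^2 at 3-4 nm pitch land near 1e-8 T^2
        out = coverage_extrapolation(1.35e-9, footprint_area=3.5**2, nv_depth=7.0)
        assert 1e-8 / 3 < out < 1e-8 * 3

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError):
            coverage_extrapolation(1e-9, footprint_area=0.0)


class TestAutocorrelationTauC:
    def test_recovers_ou_ground_truth(self):
        p = OUFieldParams(variance=1e-9, tau_c=0.1, dt=0.01, n_steps=1_000_000, seed=5)
        series = generate_ou_field(p)
        var, tc, diag = autocorrelation_tau_c(series, p.dt)
        assert tc == pytest.approx(0.1, rel=0.05)
        assert var == pytest.approx(1e-9, rel=0.05)
        assert not diag["flags"]

    def test_white_noise_flagged_as_unresolved(self, rng):
        var, tc, diag = autocorrelation_tau_c(rng.standard_normal(20000), dt=0.01)
        assert tc <= 0.01
        assert "tau_c_below_dt" in diag["flags"]

    def test_constant_series_flagged(self):
        var, tc, diag = autocorrelation_tau_c(np.ones(100), dt=0.1)
        assert var == 0.0
        assert np.isnan(tc)
        assert "constant_series" in diag["flags"]
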