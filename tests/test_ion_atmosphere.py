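"""Density profiles, region integration, excess accumulation, adsorption."""

import numpy as np
import pytest

from conftest import make_frame
from spinatmos.atmosphere import (adsorption_statistics, detect_adsorption,
                                  excess_accumulation, integrate_regions,
                                  z_density_profile)
from spinatmos.synthetic import SurrogateSystem, plant_accumulation
from spinatmos.trajectory import SlabGeometry, Trajectory

GEOM = SlabGeometry(bottom_zero=0.5, top_zero=19.5)
REGIONS = ((0.0, 4.0), (4.0, 9.5), (9.5, 15.0), (15.0, 19.0))


def _traj(frames):
    return Trajectory(frames=frames, dt=1.0, species_map={"Mn": "diamagnetic"})


class TestDensityProfile:
    def test_fixed_ions_occupy_single_bin(self):
        xyz = np.column_stack([np.linspace(1, 9, 10), np.full(10, 5.0),
                               np.full(10, GEOM.bottom_zero + 2.0)])
        traj = _traj([make_frame(xyz, box=(10, 10, 20))])
        prof = z_density_profile(traj, "Mn", GEOM, bin_width=0.1)
        occupied = np.nonzero(prof.density["Mn"])[0]
        assert len(occupied) == 1
        assert prof.bin_edges[occupied[0]] == pytest.approx(2.0, abs=0.1)
        assert prof.integral("Mn") == pytest.approx(10.0)

    def test_uniform_placement_is_flat_within_poisson_error(self, rng):
        frames = []
        n = 200
        for k in range(100):
            xyz = rng.uniform(0, 1, (n, 3)) * np.array([10, 10, 19]) + [0, 0, 0.5]
            frames.append(make_frame(xyz, box=(10, 10, 20), time=float(k)))
        prof = z_density_profile(_traj(frames), "Mn", GEOM, bin_width=1.0)
        counts = prof.counts_per_frame["Mn"].sum(axis=0)
        expected = 100 * n / 19
        # chi-square-ish bound: each 1-nm bin holds ~1050 counts, sigma ~ 32
        assert np.abs(counts - expected).max() < 5 * np.sqrt(expected)

    def test_profile_integral_conserves_count_every_frame(self, rng):
        frames = [make_frame(rng.uniform(0, 1, (37, 3)) * np.array([10, 10, 19])
                             + [0, 0, 0.5], box=(10, 10, 20), time=float(k))
                  for k in range(5)]
        prof = z_density_profile(_traj(frames), "Mn", GEOM, bin_width=0.5)
        per_frame = prof.counts_per_frame["Mn"].sum(axis=1)
        assert np.all(per_frame == 37)

    def test_absent_species_rejected(self, rng):
        traj = _traj([make_frame([[5, 5, 3]], box=(10, 10, 20))])
        with pytest.raises(ValueError, match="absent"):
            z_density_profile(traj, "Gd", GEOM)


class TestIntegrateRegions:
    def _uniform_profile(self, rng, n=500, n_frames=50):
        frames = [make_frame(rng.uniform(0, 1, (n, 3)) * np.array([10, 10, 19])
                             + [0, 0, 0.5], box=(10, 10, 20), time=float(k))
                  for k in range(n_frames)]
        return z_density_profile(_traj(frames), "Mn", GEOM, bin_width=0.1)

    def test_uniform_density_region_analytic(self, rng):
        prof = self._uniform_profile(rng)
        counts = integrate_regions(prof, [(0.0, 4.0)])
        assert counts.mean["Mn"][0] == pytest.approx(500 * 4 / 19, rel=0.05)

    def test_full_support_recovers_total(self, rng):
        prof = self._uniform_profile(rng, n=123, n_frames=5)
        counts = integrate_regions(prof, [(0.0, 19.0)])
        assert counts.mean["Mn"][0] == pytest.approx(123.0, abs=1e-9)
        assert counts.std["Mn"][0] == pytest.approx(0.0, abs=1e-9)

    def test_additive_under_refinement(self, rng):
        prof = self._uniform_profile(rng, n=200, n_frames=10)
        whole = integrate_regions(prof, [(2.0, 8.0)]).mean["Mn"][0]
        split = integrate_regions(prof, [(2.0, 4.3), (4.3, 8.0)]).mean["Mn"]
        assert split.sum() == pytest.approx(whole, abs=1e-9)

    def test_partial_bins_pro_rata(self, rng):
        # region boundary inside a bin: 0.25-width slice of a 0.1-binned profile
        prof = self._uniform_profile(rng, n=500, n_frames=20)
        a = integrate_regions(prof, [(0.0, 19.0)]).mean["Mn"][0]
        b = integrate_regions(prof, [(0.0, 7.35), (7.35, 19.0)]).mean["Mn"].sum()
        assert b == pytest.approx(a, abs=1e-9)

    def test_region_outside_support_rejected(self, rng):
        prof = self._uniform_profile(rng, n=10, n_frames=2)
        with pytest.raises(ValueError, match="outside"):
            integrate_regions(prof, [(18.0, 25.0)])


class TestExcessAccumulation:
    def test_identical_regions_give_zero(self, rng):
        frames = [make_frame(rng.uniform(0, 1, (50, 3)) * np.array([10, 10, 19])
                             + [0, 0, 0.5], box=(10, 10, 20), time=float(k))
                  for k in range(20)]
        prof = z_density_profile(_traj(frames), "Mn", GEOM)
        counts = integrate_regions(prof, [(5.0, 8.0)])
        est = excess_accumulation(counts, 0, 0)  # region compared with itself
        assert est.mean == 0.0

    def test_planted_excess_recovered(self):
        traj = plant_accumulation(SurrogateSystem(), n_excess=8, n_frames=200, seed=1)
        prof = z_density_profile(traj, "Mn", GEOM)
        counts = integrate_regions(prof, REGIONS)
        est = excess_accumulation(counts, 0, 3)
        assert est.mean == pytest.approx(8.0, abs=4 * est.std_err)

    def test_null_excess_within_two_sigma_for_most_seeds(self):
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            traj = plant_accumulation(SurrogateSystem(), n_excess=0, n_frames=100,
                                      seed=500 + s)
            prof = z_density_profile(traj, "Mn", GEOM)
            est = excess_accumulation(integrate_regions(prof, REGIONS), 0, 3)
            if abs(est.mean) < 2 * est.std_err:
                hits += 1
        assert hits >= int(0.8 * n_seeds)  # nominal 95%, binomial slack at n=20

    def test_unequal_widths_rejected(self, rng):
        frames = [make_frame(rng.uniform(0, 1, (10, 3)) * np.array([10, 10, 19])
                             + [0, 0, 0.5], box=(10, 10, 20))]
        prof = z_density_profile(_traj(frames), "Mn", GEOM)
        counts = integrate_regions(prof, [(0.0, 4.0), (10.0, 19.0)])
        with pytest.raises(ValueError, match="unequal"):
            excess_accumulation(counts, 0, 1)


def _molecule_traj(z_series, dt=0.1):
    frames = [make_frame([[5.0, 5.0, z]], species="P", box=(10, 10, 20), time=k * dt)
              for k, z in enumerate(z_series)]
    return Trajectory(frames=frames, dt=dt, species_map={"P": "diamagnetic"})


class TestDetectAdsorption:
    def test_held_at_surface_adsorbs_immediately(self):
        traj = _molecule_traj([GEOM.bottom_zero + 0.2] * 30)
        rec = detect_adsorption(traj, {"species": "P"}, GEOM, persistence=1.0)
        assert rec.adsorbed and rec.side == "bottom" and rec.onset_ns == 0.0

    def test_mid_box_molecule_never_adsorbs(self):
        traj = _molecule_traj([10.0] * 30)
        rec = detect_adsorption(traj, {"species": "P"}, GEOM)
        assert not rec.adsorbed and rec.onset_ns is None and rec.side is None

    def test_top_surface_detected(self):
        traj = _molecule_traj([GEOM.top_zero - 0.1] * 30)
        rec = detect_adsorption(traj, {"species": "P"}, GEOM)
        assert rec.adsorbed and rec.side == "top"

    def test_short_excursion_before_persistence_postpones_onset(self):
        # approach at t=5.0, excursion above cutoff at t=5.5-5.9 (0.5 ns),
        # then settled: the first window shorter than persistence is discarded
        z = [10.0] * 50 + [0.7] * 5 + [1.5] * 5 + [0.7] * 40
        traj = _molecule_traj(z)  # cutoff 0.35 on distance: 0.7-0.5 = 0.2 < 0.35
        rec = detect_adsorption(traj, {"species": "P"}, GEOM,
                                contact_cutoff=0.35, persistence=1.0)
        assert rec.adsorbed
        assert rec.onset_ns == pytest.approx(6.0, abs=1e-9)

    def test_excursion_after_persistence_is_ignored(self):
        # window 5.0-7.0 already satisfies persistence=1.0 before the excursion
        z = [10.0] * 50 + [0.7] * 20 + [1.5] * 5 + [0.7] * 25
        traj = _molecule_traj(z)
        rec = detect_adsorption(traj, {"species": "P"}, GEOM, persistence=1.0)
        assert rec.onset_ns == pytest.approx(5.0, abs=1e-9)

    def test_persistence_below_dt_rejected(self):
        traj = _molecule_traj([10.0] * 10)
        with pytest.raises(ValueError, match="persistence"):
            detect_adsorption(traj, {"species": "P"}, GEOM, persistence=0.01)


class TestAdsorptionStatistics:
    def _records(self, n_ads, n_total):
        recs = []
        for i in range(n_total):
            ads = i < n_ads
            traj = _molecule_traj([GEOM.bottom_zero + 0.2 if ads else 10.0] * 15)
            rec = detect_adsorption(traj, {"species": "P"}, GEOM, replica_id=i)
            recs.append(rec)
        return recs

    def test_fraction_38_of_48(self):
        stats = adsorption_statistics(self._records(38, 48))
        assert stats.fraction == pytest.approx(0.792, abs=5e-4)
        assert stats.n_adsorbed == 38

    def test_all_adsorbed(self):
        stats = adsorption_statistics(self._records(5, 5))
        assert stats.fraction == 1.0
        assert stats.onset_quartiles_ns is not None

    def test_none_adsorbed(self):
        stats = adsorption_statistics(self._records(0, 6))
        assert stats.fraction == 0.0
        assert stats.onset_quartiles_ns is None
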