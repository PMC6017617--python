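"""Bilayer observables: per-lipid geometry, electron density, order
parameters, headgroup tilt and the dipole potential."""

import numpy as np
import pytest

from polmem import fixtures
from polmem.constants import COULOMB, VOLT_PER_KCAL_MOL_E
from polmem.membrane import (
    BilayerComposition,
    Profile,
    TrajectoryFrame,
    UndefinedThicknessError,
    area_per_lipid,
    bilayer_thickness,
    dipole_potential,
    electron_density_profile,
    headgroup_angle_distribution,
    order_parameter_of_vectors,
    order_parameters,
    volume_per_lipid,
)


def _minimal_comp(n_atoms, n_lipid=72, n_water=0, **kw):
    return BilayerComposition(
        n_lipid=n_lipid,
        n_water=n_water,
        labels=kw.pop("labels", ["CH2"] * n_atoms),
        charges=kw.pop("charges", np.zeros(n_atoms)),
        atomic_numbers=kw.pop("atomic_numbers", np.full(n_atoms, 6)),
        **kw,
    )


class TestPerLipidGeometry:
    def test_area_single_frame_exact(self):
        frame = TrajectoryFrame([60.0, 60.0, 80.0], np.zeros((1, 3)))
        mean, sd = area_per_lipid([frame], _minimal_comp(1))
        assert mean == 100.0
        assert sd == 0.0

    def test_area_constant_box_zero_sd(self):
        frames = [TrajectoryFrame([46.5, 46.5, 80.0], np.zeros((1, 3)))
                  for _ in range(5)]
        mean, sd = area_per_lipid(frames, _minimal_comp(1))
        assert mean == pytest.approx(46.5 * 46.5 / 36.0, rel=1e-14)
        assert sd == 0.0

    def test_area_fluctuating_box_mean_recovered(self):
        rng = np.random.default_rng(0)
        true_l, sigma, n = 46.5, 0.3, 400
        frames = [
            TrajectoryFrame([l, l, 80.0], np.zeros((1, 3)))
            for l in rng.normal(true_l, sigma, n)
        ]
        mean, sd = area_per_lipid(frames, _minimal_comp(1))
        expect = true_l**2 / 36.0 + sigma**2 / 36.0   # E[L²] = μ² + σ²
        se = sd / np.sqrt(n)
        assert abs(mean - expect) < 3 * se + 1e-9

    def test_volume_no_water(self):
        frame = TrajectoryFrame([10.0, 10.0, 10.0], np.zeros((1, 3)))
        mean, _ = volume_per_lipid([frame], _minimal_comp(1, n_lipid=2))
        assert mean == 500.0

    def test_volume_with_published_water_volume(self):
        """46×46×80 box, 2000 waters at 30.53 Å³, 72 lipids →
        (169280 − 61060)/72 Å³, to machine precision."""
        frame = TrajectoryFrame([46.0, 46.0, 80.0], np.zeros((1, 3)))
        comp = _minimal_comp(1, n_lipid=72, n_water=2000)
        mean, _ = volume_per_lipid([frame], comp)
        assert mean == pytest.approx(108220.0 / 72.0, rel=1e-14)
        assert comp.water_volume == 30.53

    def test_volume_exceeding_box_rejected(self):
        frame = TrajectoryFrame([5.0, 5.0, 5.0], np.zeros((1, 3)))
        comp = _minimal_comp(1, n_lipid=2, n_water=100)
        with pytest.raises(ValueError, match="water volume"):
            volume_per_lipid([frame], comp)


class TestElectronDensity:
    def test_z_minus_q_rule_single_atom(self):
        """One oxygen with q = −0.5 deposits 8.5 electrons in its slab."""
        frame = TrajectoryFrame([10.0, 10.0, 20.0],
                                np.array([[5.0, 5.0, 3.7]]))
        comp = _minimal_comp(
            1, n_lipid=2, labels=["PO4"],
            charges=np.array([-0.5]), atomic_numbers=np.array([8]),
        )
        prof = electron_density_profile([frame], comp, n_slabs=10)
        slab_vol = 10.0 * 10.0 * 2.0
        assert prof["total"].values[1] == pytest.approx(8.5 / slab_vol,
                                                        rel=1e-12)
        assert prof["PO4"].values[1] == prof["total"].values[1]

    def test_electron_conservation_every_frame(self, small_bilayer):
        frames, comp = small_bilayer
        total_e = float(np.sum(comp.atomic_numbers - comp.charges))
        for frame in frames:
            prof = electron_density_profile([frame], comp, n_slabs=64)
            area = frame.box[0] * frame.box[1]
            integral = prof["total"].values.sum() * area * prof["total"].width
            assert integral == pytest.approx(total_e, rel=1e-9)

    def test_group_profiles_sum_to_total(self, small_bilayer):
        frames, comp = small_bilayer
        prof = electron_density_profile(frames, comp, n_slabs=50)
        summed = sum(v.values for g, v in prof.items() if g != "total")
        assert np.allclose(summed, prof["total"].values, atol=1e-12)

    def test_mirror_symmetric_bilayer_gives_symmetric_profile(self):
        """Atoms placed symmetrically about the midplane produce a
        profile symmetric under slab reversal."""
        z = np.array([10.3, 15.7, 19.9, 24.1, 8.6])  # off the bin edges
        coords = np.zeros((10, 3))
        coords[:5, 2] = z
        coords[5:, 2] = 40.0 - z
        frame = TrajectoryFrame([20.0, 20.0, 40.0], coords)
        comp = _minimal_comp(10, n_lipid=2)
        prof = electron_density_profile([frame], comp, n_slabs=40)
        assert np.allclose(prof["total"].values,
                           prof["total"].values[::-1], atol=1e-12)


class TestThickness:
    def _double_gaussian(self, centers, lz=80.0, n=200):
        z = (np.arange(n) + 0.5) * (lz / n)
        v = sum(np.exp(-((z - c) ** 2) / 8.0) for c in centers)
        return Profile(z, v, lz / n)

    def test_constructed_peak_distance(self):
        prof = self._double_gaussian([23.0, 57.0])  # midplane 40, ±17
        d = bilayer_thickness(prof)
        assert d == pytest.approx(34.0, abs=prof.width / 2)

    def test_single_peak_raises(self):
        prof = self._double_gaussian([40.0])
        with pytest.raises(UndefinedThicknessError):
            bilayer_thickness(prof)

    def test_invariant_to_uniform_scaling(self):
        prof = self._double_gaussian([20.0, 60.0])
        scaled = Profile(prof.z, prof.values * 7.3, prof.width)
        assert bilayer_thickness(scaled) == pytest.approx(
            bilayer_thickness(prof), abs=1e-12
        )


class TestOrderParameters:
    def test_parallel_vectors_give_unity(self):
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        assert order_parameter_of_vectors(v) == pytest.approx(1.0)

    def test_in_plane_vectors_give_minus_half(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 2 * np.pi, 500)
        v = np.column_stack([np.cos(a), np.sin(a), np.zeros(500)])
        assert order_parameter_of_vectors(v) == pytest.approx(-0.5, abs=1e-12)

    def test_isotropic_vectors_average_to_zero(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(200_000, 3))
        s = order_parameter_of_vectors(v)
        assert abs(s) < 0.005     # ~3 standard errors at this sample size

    def test_per_carbon_averaging_over_frames(self):
        """Two frames with S = 1 and S = −0.5 average to 0.25."""
        coords_up = np.array([[0.0, 0, 0], [0.0, 0, 1.09]])
        coords_flat = np.array([[0.0, 0, 0], [1.09, 0, 0]])
        comp = _minimal_comp(
            2, n_lipid=2,
            ch_pairs={"sn1": {2: [(0, 1)]}},
        )
        frames = [
            TrajectoryFrame([10.0, 10, 10], coords_up),
            TrajectoryFrame([10.0, 10, 10], coords_flat),
        ]
        out = order_parameters(frames, comp)
        assert out["sn1"][2] == pytest.approx((1.0 - 0.5) / 2, abs=1e-12)

    def test_invariant_under_rotation_about_z(self, small_bilayer):
        frames, comp = small_bilayer
        base = order_parameters(frames[:1], comp)
        t = 1.1
        Rz = np.array([[np.cos(t), -np.sin(t), 0],
                       [np.sin(t), np.cos(t), 0], [0, 0, 1]])
        rot = TrajectoryFrame(frames[0].box, frames[0].coords @ Rz.T)
        rotated = order_parameters([rot], comp)
        for c in base["sn1"]:
            assert rotated["sn1"][c] == pytest.approx(base["sn1"][c],
                                                      abs=1e-10)


class TestHeadgroupTilt:
    def _comp_two_lipids(self):
        # one lipid per leaflet: P and partner atoms
        return BilayerComposition(
            n_lipid=2, n_water=0,
            labels=["PO4", "GLY", "PO4", "GLY", "CH3", "CH3"],
            charges=np.zeros(6), atomic_numbers=[15, 6, 15, 6, 6, 6],
            headgroup_vectors=[(0, 1), (2, 3)],
            terminal_carbons=[4, 5],
        )

    def test_in_plane_vectors_mode_at_ninety(self):
        coords = np.array([
            [5.0, 5.0, 30.0], [7.0, 5.0, 30.0],     # upper lipid, +x vector
            [5.0, 5.0, 10.0], [5.0, 7.0, 10.0],     # lower lipid, +y vector
            [5.0, 5.0, 21.0], [5.0, 5.0, 19.0],     # terminal carbons
        ])
        frame = TrajectoryFrame([20.0, 20.0, 40.0], coords)
        _, mode = headgroup_angle_distribution([frame],
                                               self._comp_two_lipids())
        assert mode == pytest.approx(90.0, abs=2.5)

    def test_outward_normal_vectors_mode_at_zero(self):
        """Vectors along +z upstairs and −z downstairs both count as 0°."""
        coords = np.array([
            [5.0, 5.0, 30.0], [5.0, 5.0, 32.0],
            [5.0, 5.0, 10.0], [5.0, 5.0, 8.0],
            [5.0, 5.0, 21.0], [5.0, 5.0, 19.0],
        ])
        frame = TrajectoryFrame([20.0, 20.0, 40.0], coords)
        profile, mode = headgroup_angle_distribution(
            [frame], self._comp_two_lipids()
        )
        assert mode == pytest.approx(2.5, abs=2.5)    # first bin center
        # density integrates to one over degrees
        assert profile.values.sum() * profile.width == pytest.approx(1.0)

    def test_constructed_mode_recovered(self):
        """Tilt angles drawn around 100° give a 100° mode."""
        rng = np.random.default_rng(3)
        spec = fixtures.BilayerSpec(seed=9, n_lipid=40, n_water=0,
                                    n_frames=6, box_xy=40.0)
        frames, comp = fixtures.gen_bilayer_traj(spec)
        # fixture tilts are drawn around 90°; shift the check accordingly
        _, mode = headgroup_angle_distribution(frames, comp, bin_deg=5.0)
        assert abs(mode - 90.0) <= 5.0


class TestDipolePotential:
    def test_zero_induced_dipoles_zero_everything(self, small_bilayer):
        frames, comp = small_bilayer
        zeroed = [
            TrajectoryFrame(f.box, f.coords,
                            np.zeros_like(f.coords))
            for f in frames
        ]
        res = dipole_potential(zeroed, comp, n_slabs=50)
        assert np.allclose(res.ez.values, 0.0)
        assert np.allclose(res.phi.values, 0.0)
        assert res.delta_phi == 0.0

    def test_single_slab_analytic_integral(self):
        """Constant μ_z/α = E₀ inside one slab: φ beyond it equals
        E₀·w in converted units (trapezoid across the slab edges)."""
        lz, n_slabs = 40.0, 40
        w = lz / n_slabs
        e0 = 0.01   # e/Å²
        # one polarizable atom per slab so nothing gets interpolated;
        # only the atom in slab 10 carries an induced dipole
        coords = np.zeros((n_slabs, 3))
        coords[:, 2] = (np.arange(n_slabs) + 0.5) * w
        comp = _minimal_comp(
            n_slabs, n_lipid=2,
            labels=["CH2"] * n_slabs,
            polarizabilities=np.ones(n_slabs),
        )
        induced = np.zeros((n_slabs, 3))
        induced[10, 2] = e0 * 1.0
        frame = TrajectoryFrame([10.0, 10.0, lz], coords, induced)
        res = dipole_potential([frame], comp, n_slabs=n_slabs)
        phi_far = res.phi.values[-1]
        expected = e0 * COULOMB * w * VOLT_PER_KCAL_MOL_E
        assert phi_far == pytest.approx(expected, rel=1e-9)

    def test_prescribed_field_round_trip(self):
        """μ_ind = α·E*(z) recovers φ(z) = ∫E* within trapezoid error."""
        def efield(z, lz=70.0):
            mid = lz / 2
            return (0.002 * np.exp(-((z - mid - 15) ** 2) / 18.0)
                    - 0.002 * np.exp(-((z - mid + 15) ** 2) / 18.0))

        spec = fixtures.BilayerSpec(
            seed=4, n_lipid=24, n_water=800, n_frames=3, box_xy=30.0,
            box_z=70.0, box_sigma=0.0, n_chain_carbons=6, head_offset=15.0,
            efield=efield,
        )
        frames, comp = fixtures.gen_bilayer_traj(spec)
        res = dipole_potential(frames, comp, n_slabs=100)
        z = res.phi.z
        estar = efield(z) * COULOMB
        phi_star = np.concatenate([
            [0.0],
            np.cumsum(0.5 * (estar[1:] + estar[:-1]) * res.phi.width),
        ]) * VOLT_PER_KCAL_MOL_E
        scale = np.abs(phi_star).max()
        assert np.abs(res.phi.values - phi_star).max() < 0.05 * scale

    def test_antisymmetric_field_gives_symmetric_potential(self):
        """E_z odd about the midplane ⇒ φ even about the midplane."""
        lz, n_slabs = 40.0, 40
        w = lz / n_slabs
        z_atoms = (np.arange(n_slabs) + 0.5) * w
        coords = np.zeros((n_slabs, 3))
        coords[:, 2] = z_atoms
        ez = np.sin(2 * np.pi * (z_atoms - lz / 2) / lz) * 0.01
        comp = _minimal_comp(
            n_slabs, n_lipid=2,
            polarizabilities=np.ones(n_slabs),
        )
        induced = np.zeros((n_slabs, 3))
        induced[:, 2] = ez
        frame = TrajectoryFrame([10.0, 10.0, lz], coords, induced)
        res = dipole_potential([frame], comp, n_slabs=n_slabs)
        phi = res.phi.values
        assert np.allclose(phi, phi[::-1], atol=1e-9 + 0.02 * np.abs(phi).max())

    def test_missing_polarizabilities_rejected(self, small_bilayer):
        frames, comp = small_bilayer
        import dataclasses

        bare = dataclasses.replace(comp, polarizabilities=None)
        with pytest.raises(ValueError, match="polarizabilities"):
            dipole_potential(frames, bare)
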