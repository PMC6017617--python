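"""ESP evaluation, molecular dipoles, staged multipole fitting,
fragment merging and quadrupole scaling."""

import numpy as np
import pytest

from polmem import fixtures
from polmem.esp import (
    ESPGrid,
    ExclusionShellError,
    FitSpec,
    RankDeficientFitError,
    esp_at_points,
    fit_multipoles_to_esp,
    merge_fragments,
    molecular_dipole,
    scale_quadrupoles,
)
from polmem.mpole import Multipole, MultipoleSet, rotate_to_global

from conftest import random_multipole
from oracles import esp_oracle

K = 332.0637


def _global_set(mpoles):
    return MultipoleSet(mpoles, "global")


class TestEspAtPoints:
    def test_unit_charge_at_one_angstrom(self):
        coords = np.zeros((1, 3))
        phi = esp_at_points(
            coords, _global_set([Multipole(1.0)]), np.array([[1.0, 0, 0]])
        )
        assert phi[0] == pytest.approx(K, rel=1e-12)

    def test_superposition(self):
        rng = np.random.default_rng(2)
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        m1, m2 = random_multipole(rng), random_multipole(rng)
        pts = np.array([[2.0, 3.0, 1.0], [-1.5, 2.0, -2.0]])
        both = esp_at_points(coords, _global_set([m1, m2]), pts)
        first = esp_at_points(coords[:1], _global_set([m1]), pts)
        second = esp_at_points(coords[1:], _global_set([m2]), pts)
        assert np.allclose(both, first + second, atol=1e-12)

    def test_dipole_against_two_charge_limit(self):
        """A point dipole is the h → 0 limit of ±q/h charges at spacing h."""
        mu = np.array([0.1, -0.05, 0.2])
        coords = np.zeros((1, 3))
        pt = np.array([[2.0, 1.0, -1.5]])
        exact = esp_at_points(coords, _global_set([Multipole(0.0, mu)]), pt)[0]
        errs = []
        for h in (1e-2, 1e-3, 1e-4):
            d = mu / np.linalg.norm(mu)
            pos = np.array([d * h / 2, -d * h / 2])
            q = np.linalg.norm(mu) / h
            phi = K * (
                q / np.linalg.norm(pt[0] - pos[0])
                - q / np.linalg.norm(pt[0] - pos[1])
            )
            errs.append(abs(phi - exact) / abs(exact))
        assert errs[1] < errs[0] / 3
        assert errs[2] < 1e-6

    def test_full_multipole_against_cluster_oracle(self):
        rng = np.random.default_rng(5)
        coords = np.array([[0.0, 0, 0], [3.5, 0.5, -1.0]])
        mset = _global_set([random_multipole(rng), random_multipole(rng)])
        pts = np.array([[2.0, 4.0, 2.0], [-3.0, -1.0, 3.0]])
        exact = esp_at_points(coords, mset, pts)
        approx = esp_oracle(coords, mset, pts, h=1e-3)
        assert np.allclose(approx, exact, rtol=1e-4)

    def test_exclusion_shell_enforced(self):
        coords = np.zeros((1, 3))
        with pytest.raises(ExclusionShellError):
            esp_at_points(
                coords, _global_set([Multipole(1.0)]),
                np.array([[0.5, 0, 0]]),
            )


class TestMolecularDipole:
    def test_neutral_pair_magnitude_in_debye(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        mset = _global_set([Multipole(1.0), Multipole(-1.0)])
        d = molecular_dipole(coords, mset)
        assert d.magnitude == pytest.approx(4.803205, rel=1e-9)
        # origin independence for neutral species
        d2 = molecular_dipole(coords, mset, origin=np.array([5.0, 5, 5]))
        assert np.allclose(d.dipole, d2.dipole, atol=1e-12)

    def test_origin_shift_identity_for_ions(self):
        """Shifting the origin by t changes D by −q_tot·t (in Debye)."""
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        mset = _global_set([Multipole(-0.7), Multipole(-0.3)])
        t = np.array([1.0, -2.0, 0.5])
        d0 = molecular_dipole(coords, mset, origin=np.zeros(3))
        d1 = molecular_dipole(coords, mset, origin=t)
        assert np.allclose(
            d1.dipole - d0.dipole, -(-1.0) * t * 4.803205, atol=1e-10
        )

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(8)
        n = 4
        coords = rng.normal(0, 3, (n, 3))
        mset = _global_set([random_multipole(rng) for _ in range(n)])
        qtot = mset.total_charge
        origin = coords.mean(axis=0)
        expected = sum(
            m.charge * (coords[i] - origin) + m.dipole
            for i, m in enumerate(mset.multipoles)
        ) * 4.803205
        got = molecular_dipole(coords, mset)
        assert np.allclose(got.dipole, expected, atol=1e-10)


class TestEspFit:
    """Parameter recovery on synthetic multi-conformer grids."""

    @pytest.fixture
    def truth_setup(self):
        system = fixtures.gen_toy_molecule(
            fixtures.ToyMoleculeSpec(seed=21, n_sites=5, net_charge=-1)
        )
        conf = fixtures.gen_conformers(system, [25.0, -40.0])
        grids = []
        for cid, coords in conf.items():
            pts = fixtures.gen_esp_grid_points(
                coords, [s.element for s in system.sites], seed=77,
                density_per_a2=0.35,
            )
            gset = rotate_to_global(
                system.local_multipoles, system.frames, coords
            )
            ref = esp_at_points(coords, gset, pts)
            grids.append(ESPGrid(cid, pts, ref))
        return system, conf, grids

    def _perturbed(self, local, rng):
        out = local.copy()
        for m in out.multipoles:
            m.charge *= 1.2
            m.dipole = m.dipole * 0.8 + rng.normal(0, 0.01, 3)
            m.quadrupole = m.quadrupole * 1.2
        # keep the net charge consistent with the declared total
        shift = (local.total_charge - out.total_charge) / len(out)
        for m in out.multipoles:
            m.charge += shift
        return out

    def test_recovery_from_noise_free_grids(self, truth_setup):
        """A 20 %-perturbed start recovers charges within 1e-3 e and
        dipoles within 1e-3 e·Å at the tight 0.01 kcal/mol/e² stage."""
        system, conf, grids = truth_setup
        rng = np.random.default_rng(0)
        n = len(system.sites)
        spec = FitSpec(
            conformers=grids,
            free_charges=frozenset(range(n)),
            free_dipoles=frozenset(range(n)),
            free_quadrupoles=frozenset(range(n)),
            convergence=0.01,
            net_charge=-1.0,
        )
        initial = self._perturbed(system.local_multipoles, rng)
        result = fit_multipoles_to_esp(spec, initial, system.frames, conf)
        for m_fit, m_true in zip(
            result.multipoles.multipoles, system.local_multipoles.multipoles
        ):
            assert abs(m_fit.charge - m_true.charge) < 1e-3
            assert np.abs(m_fit.dipole - m_true.dipole).max() < 1e-3
            assert np.abs(m_fit.quadrupole - m_true.quadrupole).max() < 5e-3
        assert all(r < 1e-6 for r in result.rmse.values())
        assert result.multipoles.total_charge == pytest.approx(-1.0,
                                                               abs=1e-12)

    def test_initial_truth_returns_unchanged(self, truth_setup):
        system, conf, grids = truth_setup
        n = len(system.sites)
        spec = FitSpec(
            conformers=grids,
            free_charges=frozenset(range(n)),
            free_dipoles=frozenset(range(n)),
            convergence=0.01,
            net_charge=-1.0,
        )
        result = fit_multipoles_to_esp(
            spec, system.local_multipoles, system.frames, conf
        )
        assert result.iterations == 0
        for m_fit, m_true in zip(
            result.multipoles.multipoles, system.local_multipoles.multipoles
        ):
            assert m_fit.charge == m_true.charge
            assert np.array_equal(m_fit.dipole, m_true.dipole)

    def test_stage_two_freezes_charges_bit_identical(self, truth_setup):
        """Dipole/quadrupole refinement with charges frozen at (wrong)
        values must not touch the charges while reducing the RMSE."""
        system, conf, grids = truth_setup
        rng = np.random.default_rng(1)
        initial = self._perturbed(system.local_multipoles, rng)
        frozen_charges = [m.charge for m in initial.multipoles]
        n = len(system.sites)
        spec = FitSpec(
            conformers=grids,
            free_dipoles=frozenset(range(n)),
            free_quadrupoles=frozenset(range(n)),
            convergence=0.01,
        )
        rmse_before = {
            g.conformer: float(np.sqrt(np.mean((
                esp_at_points(
                    conf[g.conformer],
                    rotate_to_global(initial, system.frames,
                                     conf[g.conformer]),
                    g.points,
                ) - g.reference) ** 2)))
            for g in grids
        }
        result = fit_multipoles_to_esp(spec, initial, system.frames, conf)
        for m, q in zip(result.multipoles.multipoles, frozen_charges):
            assert m.charge == q           # bit-identical, not approx
        for cid in rmse_before:
            assert result.rmse[cid] <= rmse_before[cid]

    def test_rank_deficient_design_reports_null_space(self, truth_setup):
        system, conf, grids = truth_setup
        n = len(system.sites)
        tiny = ESPGrid(
            grids[0].conformer, grids[0].points[:3], grids[0].reference[:3]
        )
        spec = FitSpec(
            conformers=[tiny],
            free_charges=frozenset(range(n)),
            free_dipoles=frozenset(range(n)),
            free_quadrupoles=frozenset(range(n)),
            convergence=1e-12,
        )
        with pytest.raises(RankDeficientFitError) as exc:
            fit_multipoles_to_esp(
                spec, self._perturbed(system.local_multipoles,
                                      np.random.default_rng(4)),
                system.frames, conf,
            )
        assert exc.value.null_space.shape[0] >= 1


class TestMergeAndScale:
    def test_residual_spread_equally_over_heavy_atoms(self):
        frag = MultipoleSet([Multipole(-0.35), Multipole(0.1),
                             Multipole(0.2)], "local")
        merged = merge_fragments(
            [frag], [{0: 0, 1: 1, 2: 2}], n_sites=5, net_charge=0.0,
            heavy_atoms=[0, 1, 2, 3, 4],
        )
        # residual = 0 − (−0.05) = +0.05 over 5 heavy atoms → +0.01 each
        assert merged[0].charge == pytest.approx(-0.34, abs=1e-12)
        assert merged[3].charge == pytest.approx(0.01, abs=1e-12)
        assert merged.total_charge == pytest.approx(0.0, abs=1e-12)

    def test_already_consistent_fragments_unchanged(self):
        frag = MultipoleSet([Multipole(0.4), Multipole(-0.4)], "local")
        merged = merge_fragments(
            [frag], [{0: 0, 1: 1}], n_sites=2, net_charge=0.0,
            heavy_atoms=[0, 1],
        )
        assert merged[0].charge == 0.4
        assert merged[1].charge == -0.4

    def test_unmapped_merged_sites_are_zero_caps(self):
        frag = MultipoleSet([Multipole(0.3, [0.1, 0, 0])], "local")
        merged = merge_fragments(
            [frag], [{0: 0}], n_sites=2, net_charge=0.3, heavy_atoms=[0]
        )
        assert merged[1].charge == 0.0
        assert np.allclose(merged[1].dipole, 0.0)

    def test_overlapping_correspondence_rejected(self):
        f1 = MultipoleSet([Multipole(0.1)], "local")
        f2 = MultipoleSet([Multipole(0.2)], "local")
        with pytest.raises(ValueError, match="covered more than once"):
            merge_fragments([f1, f2], [{0: 0}, {0: 0}], n_sites=1,
                            net_charge=0.3, heavy_atoms=[0])

    def test_residual_without_heavy_atoms_rejected(self):
        frag = MultipoleSet([Multipole(0.1)], "local")
        with pytest.raises(ValueError, match="no heavy atoms"):
            merge_fragments([frag], [{0: 0}], n_sites=1, net_charge=0.0,
                            heavy_atoms=[])

    def test_scale_quadrupoles_hydroxyl_convention(self):
        q = np.diag([0.10, -0.04, -0.06])
        mset = MultipoleSet(
            [Multipole(0.2, [0.1, 0, 0], q), Multipole(-0.2)], "local"
        )
        out = scale_quadrupoles(mset, [0], 0.6)
        assert out[0].quadrupole[0, 0] == pytest.approx(0.06, abs=1e-12)
        assert abs(np.trace(out[0].quadrupole)) < 1e-12
        assert out[0].charge == 0.2
        assert np.allclose(out[0].dipole, [0.1, 0, 0])
        assert np.allclose(out[1].quadrupole, 0.0)
        # factor 1 is the identity
        ident = scale_quadrupoles(mset, [0, 1], 1.0)
        assert np.allclose(ident[0].quadrupole, q - np.trace(q) / 3 * np.eye(3))

    def test_bad_factor_rejected(self):
        mset = MultipoleSet([Multipole()], "local")
        with pytest.raises(ValueError):
            scale_quadrupoles(mset, [0], 0.0)
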