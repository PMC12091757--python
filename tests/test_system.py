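"""Total-energy assembly: continuum wall terms plus discrete drug-drug sums."""

import math

import numpy as np
import pytest

import nanocap as nc
from nanocap.system import PENALTY_SCALE, WALL_MARGIN, PopulationEvaluator


def rotz(phi):
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestMoleculeTubeEnergy:
    def test_single_atom_reduces_to_point_energy(self, ff, single_atom):
        for a in (5.0, 10.0):
            tube = nc.TubeModel(a)
            e = nc.molecule_tube_energy([[0.0, 0.0, 0.0]], ["C"], tube, ff)
            assert e == pytest.approx(
                nc.point_cylinder_energy(ff.pair("C", "C"), tube, 0.0), rel=1e-12)

    def test_axial_translation_invariance(self, ff, fluorouracil):
        tube = nc.TubeModel(8.0)
        w = nc.apply_pose(fluorouracil, nc.Pose(1.0, 2.0, 0.0, 0.4, 0.9))
        e0 = nc.molecule_tube_energy(w, fluorouracil.elements, tube, ff)
        e1 = nc.molecule_tube_energy(w + [0, 0, 7.3], fluorouracil.elements, tube, ff)
        assert abs(e1 - e0) < 1e-9

    def test_axial_rotation_invariance(self, ff, fluorouracil):
        tube = nc.TubeModel(8.0)
        w = nc.apply_pose(fluorouracil, nc.Pose(1.0, 2.0, -3.0, 0.4, 0.9))
        e0 = nc.molecule_tube_energy(w, fluorouracil.elements, tube, ff)
        e1 = nc.molecule_tube_energy(w @ rotz(1.234).T, fluorouracil.elements, tube, ff)
        assert abs(e1 - e0) < 1e-9

    def test_atom_outside_wall_raises(self, ff):
        with pytest.raises(nc.WallDomainError):
            nc.molecule_tube_energy([[5.0, 0, 0]], ["C"], nc.TubeModel(5.0), ff)


class TestPairwiseDrugEnergy:
    def test_two_atoms_at_sigma_give_minus_epsilon(self, ff):
        pp = ff.pair("C", "C")
        e = nc.pairwise_drug_energy([[0, 0, 0]], ["C"], [[pp.sigma, 0, 0]], ["C"], ff)
        assert e == pytest.approx(-pp.epsilon, rel=1e-12)

    def test_symmetric_under_swap(self, ff, hexagon, fluorouracil):
        wi = nc.apply_pose(hexagon, nc.Pose(0, 0, 0))
        wj = nc.apply_pose(fluorouracil, nc.Pose(0, 0, 4.0))
        a = nc.pairwise_drug_energy(wi, hexagon.elements, wj, fluorouracil.elements, ff)
        b = nc.pairwise_drug_energy(wj, fluorouracil.elements, wi, hexagon.elements, ff)
        assert a == pytest.approx(b, rel=1e-15)

    def test_decay_with_separation(self, ff, hexagon):
        els = hexagon.elements
        near = nc.pairwise_drug_energy(hexagon.coords_body, els,
                                       hexagon.coords_body + [0, 0, 3.4], els, ff)
        far = nc.pairwise_drug_energy(hexagon.coords_body, els,
                                      hexagon.coords_body + [0, 0, 10.0], els, ff)
        assert abs(far) < 0.05 * abs(near)

    def test_coincident_atoms_rejected(self, ff):
        with pytest.raises(ValueError):
            nc.pairwise_drug_energy([[0, 0, 0]], ["C"], [[0, 0, 0]], ["C"], ff)


class TestTotalEnergy:
    def test_single_molecule_has_no_pair_terms(self, ff, fluorouracil):
        cfg = nc.Configuration([fluorouracil], [nc.Pose(1, 0, 0, 0.2, 0.3)],
                               nc.TubeModel(8.0))
        bd = nc.total_energy(cfg, ff)
        assert bd.drug_drug == {}
        assert bd.total == pytest.approx(bd.drug_tube[0])

    def test_distant_molecules_are_additive(self, ff, fluorouracil):
        tube = nc.TubeModel(8.0)
        p1, p2 = nc.Pose(3.0, 0, -15.0), nc.Pose(3.0, 0, 15.0)
        both = nc.total_energy(nc.Configuration([fluorouracil] * 2, [p1, p2], tube), ff)
        singles = sum(
            nc.total_energy(nc.Configuration([fluorouracil], [p], tube), ff).total
            for p in (p1, p2))
        assert both.total == pytest.approx(singles, abs=0.5)

    def test_breakdown_conserves_total(self, ff, fluorouracil, hexagon):
        cfg = nc.Configuration(
            [fluorouracil, hexagon], [nc.Pose(1, 0, 0), nc.Pose(-1, 0, 4)],
            nc.TubeModel(9.0))
        bd = nc.total_energy(cfg, ff)
        assert bd.total == pytest.approx(
            sum(bd.drug_tube) + sum(bd.drug_drug.values()), abs=1e-9)

    def test_swap_of_identical_molecules(self, ff, fluorouracil):
        tube = nc.TubeModel(8.0)
        p1, p2 = nc.Pose(1.5, 0.5, -2, 0.3, 0.7), nc.Pose(-1, 1, 2, -0.2, 0.1)
        e12 = nc.total_energy(nc.Configuration([fluorouracil] * 2, [p1, p2], tube), ff)
        e21 = nc.total_energy(nc.Configuration([fluorouracil] * 2, [p2, p1], tube), ff)
        assert e12.total == pytest.approx(e21.total, abs=1e-9)

    def test_global_symmetry_invariance_over_random_configs(self, ff, rng, hexagon):
        # total energy must not drift under global z-shift or axial rotation
        tube = nc.TubeModel(9.0)
        mols = [hexagon, hexagon]
        for _ in range(100):
            world = []
            for k, _m in enumerate(mols):
                # keep molecules apart so energies stay O(10) and the
                # 1e-9 kcal/mol drift bound is meaningful
                pose = nc.Pose(*rng.uniform(-2, 2, 2),
                               rng.uniform(-6, -3) if k == 0 else rng.uniform(3, 6),
                               *rng.uniform(-math.pi, math.pi, 2))
                world.append(nc.apply_pose(hexagon, pose))
            phi, dz = rng.uniform(0, 2 * math.pi), rng.uniform(-10, 10)
            moved = [w @ rotz(phi).T + [0, 0, dz] for w in world]
            def total(ws):
                e = sum(nc.molecule_tube_energy(w, hexagon.elements, tube, ff)
                        for w in ws)
                e += nc.pairwise_drug_energy(ws[0], hexagon.elements, ws[1],
                                             hexagon.elements, ff)
                return e
            assert abs(total(moved) - total(world)) < 1e-9


class TestConfigurationVector:
    def test_roundtrip(self, ff, fluorouracil, hexagon):
        cfg = nc.Configuration(
            [fluorouracil, hexagon],
            [nc.Pose(1, 2, 3, 0.1, -0.2), nc.Pose(-1, 0, 2, 1.0, 0.5)],
            nc.TubeModel(10.0))
        v = cfg.to_vector()
        assert v.shape == (10,)
        back = nc.Configuration.from_vector(v, cfg.molecules, cfg.tube)
        assert back.to_vector() == pytest.approx(v)

    def test_wrong_length_rejected(self, fluorouracil):
        with pytest.raises(ValueError):
            nc.Configuration.from_vector(np.zeros(7), [fluorouracil], nc.TubeModel(5))


class TestPopulationEvaluator:
    def test_matches_exact_total_energy_on_feasible_configs(self, ff, rng,
                                                            fluorouracil, hexagon):
        tube = nc.TubeModel(9.0)
        mols = [fluorouracil, hexagon]
        ev = PopulationEvaluator(mols, tube, ff)
        X = np.column_stack([
            rng.uniform(-2, 2, 40), rng.uniform(-2, 2, 40), rng.uniform(-6, 6, 40),
            rng.uniform(-math.pi, math.pi, 40), rng.uniform(-math.pi, math.pi, 40),
            rng.uniform(-2, 2, 40), rng.uniform(-2, 2, 40), rng.uniform(-6, 6, 40),
            rng.uniform(-math.pi, math.pi, 40), rng.uniform(-math.pi, math.pi, 40),
        ])
        F = ev.evaluate(X)
        for x, f in zip(X, F):
            exact = nc.total_energy(
                nc.Configuration.from_vector(x, mols, tube), ff).total
            assert f == pytest.approx(exact, rel=1e-12, abs=1e-9)

    def test_wall_violation_gets_finite_penalty(self, ff, single_atom):
        tube = nc.TubeModel(5.0)
        ev = PopulationEvaluator([single_atom], tube, ff)
        x = np.array([[4.99, 0, 0, 0, 0]])  # inside margin band
        f = ev.evaluate(x)[0]
        assert f >= PENALTY_SCALE
        worse = ev.evaluate(np.array([[8.0, 0, 0, 0, 0]]))[0]
        assert np.isfinite(worse) and worse > f  # penalty grows with violation
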