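import numpy as np
import pytest
from scipy.stats import chisquare

from pocketdiff.chem import (AtomRecord, ComplexRecord, LigandStructure,
                             PocketStructure, lookup_radii, pair_threshold)
from pocketdiff.collisions import CollisionConfig, colliding_pairs_of, plcr
from pocketdiff.geometry import (CollidingPair, CorrectionOutcome, IntersectionCircle,
                                 TangentPoint, correct_complex, correct_pair,
                                 line_sphere_second_intersection,
                                 nearest_ligand_neighbor, sample_on_circle,
                                 sphere_sphere_intersection)
from pocketdiff.synth import SynthConfig, inject_collisions, make_training_set


class TestNearestNeighbor:
    def test_line_fixture(self):
        C = lookup_radii("C")
        lig = LigandStructure([C] * 3, np.array([[0.0, 0, 0], [1.6, 0, 0], [4.8, 0, 0]]))
        assert nearest_ligand_neighbor(lig, 0) == 1

    def test_tie_lowest_index(self):
        C = lookup_radii("C")
        lig = LigandStructure([C] * 3, np.array([[0.0, 0, 0], [0, 0, 2.0], [0, 0, -2.0]]))
        assert nearest_ligand_neighbor(lig, 0) == 1

    def test_single_atom_errors(self):
        C = lookup_radii("C")
        lig = LigandStructure([C], np.zeros((1, 3)))
        with pytest.raises(ValueError):
            nearest_ligand_neighbor(lig, 0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        C = lookup_radii("C")
        coords = rng.uniform(-5, 5, (20, 3)) * 2
        lig = LigandStructure([C] * 20, coords)
        for b in range(20):
            d = np.linalg.norm(coords - coords[b], axis=1)
            d[b] = np.inf
            assert nearest_ligand_neighbor(lig, b) == int(np.argmin(d))


class TestLineSphere:
    def test_collinear_worked_example(self):
        out = line_sphere_second_intersection(
            np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0]), 1.0)
        assert out.status == "corrected"
        np.testing.assert_allclose(out.new_position, [3.0, 0, 0], atol=1e-12)

    def test_defining_properties_random(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            center = rng.normal(0, 3, 3)
            r = rng.uniform(0.5, 3.0)
            u = rng.normal(size=3)
            b = center + r * u / np.linalg.norm(u)
            a = rng.normal(0, 3, 3)
            if np.allclose(a, b):
                continue
            out = line_sphere_second_intersection(a, b, center, r)
            bp = out.new_position
            # on the sphere
            assert abs(np.linalg.norm(bp - center) - r) < 1e-9
            # collinear with a, b
            cross = np.cross(b - a, bp - a)
            assert np.linalg.norm(cross) < 1e-6 * max(1, np.linalg.norm(bp - a))

    def test_root_matches_dense_line_scan(self):
        rng = np.random.default_rng(2)
        center = np.array([1.0, 1.0, 0.0])
        r = 2.0
        b = center + np.array([r, 0, 0])
        a = np.array([-3.0, 0.5, 0.2])
        out = line_sphere_second_intersection(a, b, center, r)
        ts = np.linspace(-5, 5, 2000001)
        pts = a[None, :] + ts[:, None] * (b - a)[None, :]
        resid = np.abs(np.linalg.norm(pts - center, axis=1) - r)
        # the two local minima of the residual bracket the analytic roots
        t_hit = ts[resid < 5e-6]
        t2 = float(np.dot(out.new_position - a, b - a) / np.dot(b - a, b - a))
        assert np.min(np.abs(t_hit - t2)) < 1e-5
        assert np.min(np.abs(t_hit - 1.0)) < 1e-5

    def test_degenerate_direction_errors(self):
        with pytest.raises(ValueError):
            line_sphere_second_intersection(np.ones(3), np.ones(3), np.zeros(3), 1.0)


class TestSphereSphere:
    def test_closed_form_example(self):
        out = sphere_sphere_intersection(np.zeros(3), 2.0, np.array([3.0, 0, 0]), 2.0)
        assert isinstance(out, IntersectionCircle)
        np.testing.assert_allclose(out.center, [1.5, 0, 0])
        assert out.radius == pytest.approx(np.sqrt(1.75))
        np.testing.assert_allclose(out.normal, [1, 0, 0])

    def test_external_tangency(self):
        out = sphere_sphere_intersection(np.zeros(3), 1.0, np.array([3.0, 0, 0]), 2.0)
        assert isinstance(out, TangentPoint)
        np.testing.assert_allclose(out.point, [1.0, 0, 0], atol=1e-9)

    def test_disjoint_returns_none(self):
        assert sphere_sphere_intersection(np.zeros(3), 1.0, np.array([10.0, 0, 0]), 2.0) is None
        # contained without touching
        assert sphere_sphere_intersection(np.zeros(3), 5.0, np.array([0.5, 0, 0]), 1.0) is None

    def test_concentric_errors(self):
        with pytest.raises(ValueError):
            sphere_sphere_intersection(np.zeros(3), 1.0, np.zeros(3), 2.0)

    def test_circle_points_satisfy_both_spheres(self):
        rng = np.random.default_rng(3)
        for trial in range(100):
            a = rng.normal(0, 2, 3)
            c = rng.normal(0, 2, 3)
            if np.linalg.norm(a - c) < 1e-3:
                continue
            d = np.linalg.norm(a - c)
            ra = rng.uniform(0.6 * d, 1.2 * d)
            rc = rng.uniform(abs(d - ra) + 0.1 * d, d + ra - 0.1 * d)
            out = sphere_sphere_intersection(a, ra, c, rc)
            assert isinstance(out, IntersectionCircle)
            for seed in (0, 1):
                p = sample_on_circle(out, seed=seed + trial)
                assert abs(np.linalg.norm(p - a) - ra) < 1e-9
                assert abs(np.linalg.norm(p - c) - rc) < 1e-9


class TestSampleOnCircle:
    CIRCLE = IntersectionCircle(np.array([1.0, 2.0, 3.0]), 1.5,
                                np.array([0.0, 0.0, 1.0]))

    def test_seed_42_bit_reproducible(self):
        a = sample_on_circle(self.CIRCLE, seed=42)
        b = sample_on_circle(self.CIRCLE, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_membership(self):
        p = sample_on_circle(self.CIRCLE, seed=42)
        assert abs(np.linalg.norm(p - self.CIRCLE.center) - 1.5) < 1e-9
        assert abs(np.dot(p - self.CIRCLE.center, self.CIRCLE.normal)) < 1e-9

    def test_angular_uniformity_chi_square(self):
        angles = []
        for seed in range(10000):
            p = sample_on_circle(self.CIRCLE, seed=seed)
            v = p - self.CIRCLE.center
            angles.append(np.arctan2(v[1], v[0]))
        hist, _ = np.histogram(angles, bins=20, range=(-np.pi, np.pi))
        _, pval = chisquare(hist)
        assert pval > 0.01


def _make_pair(ligand, pocket, i, j):
    thr = pair_threshold(ligand.elements[i], pocket.elements[j])
    return CollidingPair(AtomRecord(pocket.elements[j], pocket.coords[j]),
                         AtomRecord(ligand.elements[i], ligand.coords[i]), i, thr)


class TestCorrectPair:
    def collinear_fixture(self):
        C = lookup_radii("C")
        # ligand atom b at (1,0,0) collides with pocket atom a at origin;
        # neighbor c at (3,0,0)
        ligand = LigandStructure([C, C], np.array([[1.0, 0, 0], [3.0, 0, 0]]))
        pocket = PocketStructure([C], np.zeros((1, 3)))
        return ComplexRecord(ligand, pocket)

    def test_parallelogram_collinear(self):
        rec = self.collinear_fixture()
        pair = _make_pair(rec.ligand, rec.pocket, 0, 0)
        out = correct_pair(rec, pair, "parallelogram")
        np.testing.assert_allclose(out.new_position, [5.0, 0, 0], atol=1e-9)
        assert np.linalg.norm(out.new_position - rec.pocket.coords[0]) > pair.threshold

    def test_circle_worked_example(self):
        rec = self.collinear_fixture()
        pair = _make_pair(rec.ligand, rec.pocket, 0, 0)
        out = correct_pair(rec, pair, "circle", seed=42)
        assert out.status == "corrected"
        a = rec.pocket.coords[0]
        c = rec.ligand.coords[1]
        # corrected pair distance is the clash threshold; b-c distance kept
        assert np.linalg.norm(out.new_position - a) == pytest.approx(pair.threshold, abs=1e-9)
        assert np.linalg.norm(out.new_position - c) == pytest.approx(2.0, abs=1e-9)

    def test_both_methods_preserve_neighbor_distance(self, small_benchmark):
        complexes, _ = small_benchmark
        rng_seed = 0
        for method in ("parallelogram", "circle"):
            for k, rec in enumerate(complexes[:5]):
                clashed = inject_collisions(rec, 0.3, seed=k)
                pairs = colliding_pairs_of(clashed)
                assert pairs
                i, j = pairs[0]
                pair = _make_pair(clashed.ligand, clashed.pocket, i, j)
                out = correct_pair(clashed, pair, method, seed=rng_seed)
                if out.new_position is None:
                    continue
                b = clashed.ligand.coords[i]
                # distance to the sphere-center neighbor is preserved: find it
                mask = np.arange(len(clashed.ligand)) != i
                d_before = np.linalg.norm(clashed.ligand.coords[mask] - b, axis=1)
                d_after = np.linalg.norm(clashed.ligand.coords[mask] - out.new_position, axis=1)
                assert np.min(np.abs(d_after - d_before)) < 1e-9

    def test_circle_always_resolves_collision(self, small_benchmark):
        complexes, _ = small_benchmark
        cfg = CollisionConfig()
        resolved = 0
        total = 0
        for k, rec in enumerate(complexes):
            for rep in range(20):
                clashed = inject_collisions(rec, 0.4, seed=1000 * k + rep)
                for i, j in colliding_pairs_of(clashed, cfg):
                    pair = _make_pair(clashed.ligand, clashed.pocket, i, j)
                    try:
                        out = correct_pair(clashed, pair, "circle", seed=rep)
                    except ValueError:
                        continue
                    if out.new_position is None:
                        continue
                    total += 1
                    d = np.linalg.norm(out.new_position - clashed.pocket.coords[j])
                    resolved += bool(d >= pair.threshold)
        assert total >= 200
        assert resolved == total  # 100% of circle outcomes clear the strict clash


class TestCorrectComplex:
    def test_clash_free_input_is_fixpoint(self, small_benchmark):
        rec = small_benchmark[0][0]
        fixed, outcomes, valid = correct_complex(rec, method="circle")
        assert valid and outcomes == []
        np.testing.assert_array_equal(fixed.ligand.coords, rec.ligand.coords)

    @pytest.mark.parametrize("method", ["parallelogram", "circle"])
    def test_eliminates_injected_collisions(self, small_benchmark, method):
        complexes, _ = small_benchmark
        clashed = [inject_collisions(c, 0.3, seed=i) for i, c in enumerate(complexes)]
        fixed = [correct_complex(c, method=method)[0] for c in clashed]
        assert plcr(fixed, CollisionConfig(K=10)).colliding_pairs == 0

    def test_idempotent_on_valid_output(self, small_benchmark):
        rec = inject_collisions(small_benchmark[0][0], 0.3, seed=5)
        fixed, _, valid = correct_complex(rec, method="circle", seed=42)
        again, outcomes, _ = correct_complex(fixed, method="circle", seed=42)
        if valid:
            assert outcomes == []
            np.testing.assert_array_equal(again.ligand.coords, fixed.ligand.coords)

    def test_protein_atoms_never_move(self, small_benchmark):
        rec = inject_collisions(small_benchmark[0][1], 0.5, seed=2)
        fixed, _, _ = correct_complex(rec, method="parallelogram")
        np.testing.assert_array_equal(fixed.pocket.coords, rec.pocket.coords)

    def test_intra_ligand_clash_flags_invalid(self):
        C = lookup_radii("C")
        # b collides with pocket atom; the only admissible correction sphere
        # (around neighbor at distance 1.6) passes through another atom site
        ligand = LigandStructure([C, C, C], np.array([
            [1.0, 0.0, 0.0],    # b: collides with pocket atom at origin
            [2.6, 0.0, 0.0],    # c: nearest neighbor
            [4.2, 0.0, 0.0],    # parallelogram target region
        ]))
        pocket = PocketStructure([C], np.zeros((1, 3)))
        rec = ComplexRecord(ligand, pocket)
        fixed, outcomes, valid = correct_complex(rec, CollisionConfig(K=1),
                                                 method="parallelogram")
        # b' lands at (4.2, 0, 0) = exactly on atom 2 -> intra-ligand clash
        assert not valid
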