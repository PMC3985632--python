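import numpy as np
import pytest

from chromo3d import (
    Ensemble,
    ModelParameters,
    OptimizerOptions,
    Structure,
    compare_ensembles,
    gdt_ha,
    pairwise_similarity,
    robustness_test,
    score_structure,
    select_representative,
    superimpose,
)
from chromo3d.normalize import ConstraintSet


def chiral_structure():
    """Four non-planar points with a handedness (no proper rotation maps
    them onto their mirror image)."""
    return Structure(
        points=np.array(
            [[0, 0, 0], [3, 0, 0], [3, 3, 0], [2, 1, 4]], dtype=float
        )
    )


def simple_cs(n=4, contacts=((0, 2),), weights=(1.0,), noncontacts=((1, 3),)):
    return ConstraintSet(
        n=n, cutoff=0.0,
        contacts=np.array(contacts).reshape(-1, 2),
        contact_weights=np.array(weights, dtype=float),
        noncontacts=np.array(noncontacts).reshape(-1, 2),
        adjacent=np.array([(i, i + 1) for i in range(n - 1)]),
    )


def make_ensemble(structures):
    return Ensemble(
        structures=structures,
        seeds=list(range(len(structures))),
        final_scores=[0.0] * len(structures),
    )


class TestScoreStructure:
    def test_fully_satisfied(self):
        # contact pair close, non-contact pair far
        S = Structure(
            points=np.array([[0, 0, 0], [0, 0, 9], [1, 0, 0], [9, 9, 9]], dtype=float)
        )
        r = score_structure(S, simple_cs())
        assert r.contact_score == 1.0
        assert r.noncontact_score == 1.0
        assert r.satisfied_if_pct == 100.0
        assert r.avg_sq_dist_unsat_contacts is None

    def test_coincident_points_degenerate(self):
        S = Structure(points=np.zeros((4, 3)))
        r = score_structure(S, simple_cs())
        assert r.contact_score == 1.0
        assert r.noncontact_score == 0.0
        assert r.avg_sq_dist_unsat_noncontacts == 0.0

    def test_if_weighted_percentage(self):
        # contacts weighted 9 and 1; only the heavy one (0,2) is satisfied
        CS = ConstraintSet(
            n=4, cutoff=0.0,
            contacts=np.array([[0, 2], [1, 3]]),
            contact_weights=np.array([9.0, 1.0]),
            noncontacts=np.empty((0, 2), dtype=int),
            adjacent=np.array([[0, 1], [1, 2], [2, 3]]),
        )
        S = Structure(
            points=np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [9, 0, 0]], dtype=float)
        )
        r = score_structure(S, CS)
        assert r.contact_score == pytest.approx(0.5)
        assert r.satisfied_if_pct == pytest.approx(90.0)
        assert r.avg_if_unsat_contacts == pytest.approx(1.0)
        assert r.avg_if_all == pytest.approx(5.0)

    def test_count_conservation(self, binary_constraints, reconstructed):
        r = score_structure(reconstructed.structure, binary_constraints)
        n_sat = round(r.contact_score * r.n_contacts)
        assert 0 <= n_sat <= r.n_contacts

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="points"):
            score_structure(Structure(points=np.zeros((3, 3))), simple_cs())


class TestSuperimpose:
    def test_rotated_translated_copy_rmsd_zero(self, rng):
        from scipy.spatial.transform import Rotation

        A = Structure(points=rng.normal(size=(8, 3)))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        B = Structure(points=A.points @ R.T + [2, 3, 4])
        _, rmsd = superimpose(A, B)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_identity(self, rng):
        A = Structure(points=rng.normal(size=(6, 3)))
        fitted, rmsd = superimpose(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fitted, A.points, atol=1e-9)

    def test_mirror_keeps_positive_rmsd(self):
        A = chiral_structure()
        B = Structure(points=A.points * [-1, 1, 1])
        _, rmsd = superimpose(A, B)
        assert rmsd > 0.1

    def test_too_few_points_rejected(self):
        A = Structure(points=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="3 points"):
            superimpose(A, A)

    def test_collinear_points_flagged(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        A = Structure(points=pts)
        with pytest.warns(UserWarning, match="collinear"):
            superimpose(A, A)


class TestGdtHa:
    def test_identical_structures_score_one(self, rng):
        A = Structure(points=rng.normal(size=(10, 3)))
        assert gdt_ha(A, A) == 1.0

    def test_rigid_copy_scores_one(self, rng):
        from scipy.spatial.transform import Rotation

        A = Structure(points=rng.normal(size=(10, 3)))
        R = Rotation.random(random_state=0).as_matrix()
        B = Structure(points=A.points @ R.T - [1, 5, 2])
        assert gdt_ha(A, B) == pytest.approx(1.0)

    def test_mirror_resolved_only_when_mirror_aware(self):
        A = chiral_structure()
        B = Structure(points=A.points * [-1, 1, 1])
        assert gdt_ha(A, B, mirror_aware=True) == pytest.approx(1.0)
        assert gdt_ha(A, B, mirror_aware=False) < 1.0

    def test_symmetry(self, rng):
        A = Structure(points=rng.normal(scale=2, size=(12, 3)))
        B = Structure(points=rng.normal(scale=2, size=(12, 3)))
        assert gdt_ha(A, B) == pytest.approx(gdt_ha(B, A), abs=1e-9)


class TestPairwiseSimilarity:
    def test_identical_ensemble_all_ones(self, rng):
        S = Structure(points=rng.normal(size=(8, 3)))
        sim = pairwise_similarity(make_ensemble([S.copy() for _ in range(3)]))
        np.testing.assert_allclose(sim.values, 1.0)
        assert sim.mean_offdiagonal == pytest.approx(1.0)

    def test_mean_permutation_invariant(self, rng):
        structures = [Structure(points=rng.normal(size=(8, 3))) for _ in range(4)]
        m1 = pairwise_similarity(make_ensemble(structures)).mean_offdiagonal
        m2 = pairwise_similarity(make_ensemble(structures[::-1])).mean_offdiagonal
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_mean_matches_direct_enumeration(self, rng):
        structures = [Structure(points=rng.normal(size=(7, 3))) for _ in range(3)]
        sim = pairwise_similarity(make_ensemble(structures))
        direct = np.mean(
            [
                gdt_ha(structures[a], structures[b])
                for a in range(3)
                for b in range(a + 1, 3)
            ]
        )
        assert sim.mean_offdiagonal == pytest.approx(direct)

    def test_singleton_rejected(self, rng):
        E = make_ensemble([Structure(points=rng.normal(size=(5, 3)))])
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_similarity(E)


class TestSelectRepresentative:
    def test_duplicate_pair_beats_outlier(self, rng):
        X = Structure(points=rng.normal(size=(8, 3)))
        Y = Structure(points=rng.normal(size=(8, 3)))
        idx = select_representative(make_ensemble([X, X.copy(), Y]))
        assert idx == 0  # lowest-index copy of the majority structure

    def test_singleton(self, rng):
        assert select_representative(
            make_ensemble([Structure(points=rng.normal(size=(5, 3)))])
        ) == 0

    def test_agrees_with_exhaustive_search(self, rng):
        for _ in range(10):
            m = int(rng.integers(2, 9))
            base = rng.normal(size=(6, 3))
            structures = [
                Structure(points=base + rng.normal(scale=rng.uniform(0.05, 1.0), size=(6, 3)))
                for _ in range(m)
            ]
            E = make_ensemble(structures)
            sim = pairwise_similarity(E)
            D = 1.0 / np.clip(sim.values, 1e-6, None)
            np.fill_diagonal(D, 0.0)
            brute = int(np.argmin(D.sum(axis=1)))
            assert select_representative(E, sim) == brute


class TestCompareEnsembles:
    def test_singletons_equal_gdt(self, rng):
        A = Structure(points=rng.normal(size=(6, 3)))
        B = Structure(points=rng.normal(size=(6, 3)))
        assert compare_ensembles(
            make_ensemble([A]), make_ensemble([B])
        ) == pytest.approx(gdt_ha(A, B))

    def test_rigid_transform_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        E1 = make_ensemble([Structure(points=rng.normal(size=(6, 3))) for _ in range(2)])
        R = Rotation.random(random_state=1).as_matrix()
        E2 = make_ensemble(
            [Structure(points=s.points @ R.T + [3, 1, -2]) for s in E1.structures]
        )
        assert compare_ensembles(E1, E2) == pytest.approx(
            compare_ensembles(E1, E1), abs=1e-9
        )

    def test_point_count_mismatch_rejected(self, rng):
        E1 = make_ensemble([Structure(points=rng.normal(size=(6, 3)))])
        E2 = make_ensemble([Structure(points=rng.normal(size=(7, 3)))])
        with pytest.raises(ValueError, match="point counts"):
            compare_ensembles(E1, E2)


class TestRobustnessTest:
    def test_same_seed_same_split_and_recovery(self, binary_constraints):
        opts = OptimizerOptions(seed=5, max_iterations=300)
        r1 = robustness_test(binary_constraints, 0.7, opts=opts)
        r2 = robustness_test(binary_constraints, 0.7, opts=opts)
        assert r1.recovery_pct == r2.recovery_pct
        assert r1.table.equals(r2.table)

    def test_degenerate_split_rejected(self, binary_constraints):
        with pytest.raises(ValueError, match="degenerate"):
            robustness_test(binary_constraints, 0.9999)

    def test_split_sizes(self, binary_constraints):
        r = robustness_test(
            binary_constraints, 0.7, opts=OptimizerOptions(seed=1, max_iterations=100)
        )
        assert r.kept + r.withheld == binary_constraints.n_contacts
        assert len(r.table) == r.withheld

    def test_table_sorted_by_if(self, binary_constraints):
        r = robustness_test(
            binary_constraints, 0.7, opts=OptimizerOptions(seed=1, max_iterations=100)
        )
        ifs = r.table.normalized_if.values
        assert np.all(np.diff(ifs) <= 0)
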