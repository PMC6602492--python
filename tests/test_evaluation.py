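import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from nucdock.errors import ContractViolation
from nucdock.evaluation import (
    EvaluationResult,
    evaluate_models,
    first_hit_rank,
    interface_residues,
    irmsd,
    success_rate,
    superpose,
)
from nucdock.fixtures import make_decoys
from nucdock.structures import RigidTransform, apply_transform
from tests.conftest import random_rotation


class TestInterfaceResidues:
    def test_fixture_duplex_all_interfacial(self, partners):
        receptor, ligand = partners
        iface_r, iface_l = interface_residues(receptor, ligand, cutoff=10.0)
        assert len(iface_r) == receptor.n_residues
        assert len(iface_l) == ligand.n_residues

    def test_far_partners_empty(self, partners):
        receptor, ligand = partners
        far = apply_transform(
            ligand, RigidTransform(np.eye(3), np.array([100.0, 0.0, 0.0]))
        )
        iface_r, iface_l = interface_residues(receptor, far, cutoff=10.0)
        assert iface_r == set() and iface_l == set()

    def test_zero_cutoff_empty(self, partners):
        receptor, ligand = partners
        iface_r, iface_l = interface_residues(receptor, ligand, cutoff=0.0)
        assert iface_r == set() and iface_l == set()


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        transform, rmsd = superpose(pts, pts)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert rmsd < 1e-12

    def test_recovers_known_transform(self, rng):
        pts = rng.normal(size=(12, 3)) * 5
        R = random_rotation(rng)
        t = rng.normal(size=3) * 10
        target = pts @ R.T + t
        transform, rmsd = superpose(pts, target)
        np.testing.assert_allclose(transform.rotation, R, atol=1e-6)
        np.testing.assert_allclose(transform.translation, t, atol=1e-6)
        assert rmsd < 1e-9

    def test_reflection_rejected(self):
        # non-planar tetrad and its mirror image
        pts = np.array(
            [[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0], [0.5, 0.5, 3.0]]
        )
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        _, rmsd = superpose(pts, mirrored)
        # unconstrained oracle (allows improper rotations) via plain SVD
        X = pts - pts.mean(0)
        Y = mirrored - mirrored.mean(0)
        U, S, Vt = np.linalg.svd(X.T @ Y)
        improper_rmsd = np.sqrt(
            max(0.0, (np.sum(X**2) + np.sum(Y**2) - 2 * S.sum()))
            / len(pts)
        )
        assert improper_rmsd < 1e-9
        assert rmsd > 0.5

    def test_too_few_points(self):
        with pytest.raises(ContractViolation):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ContractViolation):
            superpose(pts, pts + 1.0)

    def test_three_point_closed_form(self):
        mobile = np.array([[0.0, 0, 0], [4.0, 0, 0], [0, 4.0, 0]])
        target = mobile.copy()
        _, rmsd = superpose(mobile, target)
        assert rmsd == pytest.approx(0.0, abs=1e-9)


class TestIrmsd:
    def test_self_is_zero(self, partners):
        value = irmsd(partners, partners)
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_global_rigid_motion(self, partners, rng):
        receptor, ligand = partners
        decoy, _ = make_decoys(ligand, 1, 3.0, 10.0, seed=7)[0]
        base = irmsd((receptor, decoy), partners)
        t = RigidTransform(random_rotation(rng), rng.normal(size=3) * 20)
        moved = (apply_transform(receptor, t), apply_transform(decoy, t))
        assert irmsd(moved, partners) == pytest.approx(base, abs=1e-6)

    def test_matches_minimizer_oracle(self, partners):
        """Ligand rotated 10 degrees about the interface centroid: compare
        against direct numerical minimisation over all superpositions."""
        receptor, ligand = partners
        axis = np.array([0.0, 0.0, 1.0])
        R10 = Rotation.from_rotvec(np.deg2rad(10.0) * axis).as_matrix()
        center = np.vstack([receptor.coords(), ligand.coords()]).mean(0)
        rotated = apply_transform(
            ligand, RigidTransform(R10, np.zeros(3)), center
        )
        ours = irmsd((receptor, rotated), partners)

        iface_r, iface_l = interface_residues(receptor, ligand, 10.0)
        nat, pred = [], []
        for s, pred_s, iface in (
            (receptor, receptor, iface_r),
            (ligand, rotated, iface_l),
        ):
            for res_nat, res_pred in zip(s.residues(), pred_s.residues()):
                if res_nat.key in iface:
                    nat.append(res_nat.atom("C4'").coord)
                    pred.append(res_pred.atom("C4'").coord)
        nat, pred = np.array(nat), np.array(pred)

        def objective(params):
            R = Rotation.from_rotvec(params[:3]).as_matrix()
            moved = pred @ R.T + params[3:]
            return np.sqrt(np.mean(np.sum((moved - nat) ** 2, axis=1)))

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12,
                              "maxiter": 20000}).fun
            for x0 in (np.zeros(6), np.array([0.05, -0.05, 0.1, 1.0, -1.0, 0.5]))
        )
        assert ours == pytest.approx(best, abs=1e-4)

    def test_noise_grows_irmsd(self, partners):
        receptor, ligand = partners
        rng = np.random.default_rng(0)
        values = []
        for sigma in (0.1, 0.5, 1.5, 3.0):
            noisy = ligand.with_coords(
                ligand.coords() + rng.normal(scale=sigma,
                                             size=(ligand.n_atoms, 3))
            )
            values.append(irmsd((receptor, noisy), partners))
        assert values == sorted(values)

    def test_too_few_interface_atoms(self, partners):
        receptor, ligand = partners
        far = apply_transform(
            ligand, RigidTransform(np.eye(3), np.array([200.0, 0, 0]))
        )
        with pytest.raises(ContractViolation):
            irmsd((receptor, ligand), (receptor, far))

    def test_superpose_on_all_variant(self, partners):
        value = irmsd(partners, partners, superpose_on="all")
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_chain_map(self, partners):
        receptor, ligand = partners
        renamed_chains = [("X", [r for r in ligand.chain("B")])]
        from nucdock.structures import Structure

        renamed = Structure(renamed_chains)
        value = irmsd(
            (receptor, renamed), partners, chain_map={"X": "B"}
        )
        assert value == pytest.approx(0.0, abs=1e-9)


class TestHitsAndSuccessRate:
    def test_hit_boundary(self):
        result = EvaluationResult(
            per_model_irmsd=[4.9, 5.1], first_hit_rank=1, hit_threshold=5.0
        )
        assert result.hits == [True, False]
        assert first_hit_rank([5.1, 4.9]) == 2
        assert first_hit_rank([5.0]) is None  # strict "< 5.0"

    def test_all_hits_rank_one(self):
        assert success_rate([1, 1, 1], top_n=1) == 1.0
        assert success_rate([1, 1, 1], top_n=50) == 1.0

    def test_mixed_ranks(self):
        assert success_rate([1, 4, None, 12], top_n=10) == 0.5

    def test_empty_cases_rejected(self):
        with pytest.raises(ContractViolation):
            success_rate([], top_n=10)

    def test_monotone_in_top_n(self, rng):
        for _ in range(100):
            ranks = [
                None if rng.random() < 0.3 else int(rng.integers(1, 100))
                for _ in range(10)
            ]
            curve = [success_rate(ranks, n) for n in range(1, 101)]
            assert all(a <= b for a, b in zip(curve, curve[1:]))

    def test_evaluate_models(self, partners):
        receptor, ligand = partners
        decoys = make_decoys(ligand, 3, 8.0, 30.0, seed=3)
        models = [(receptor, pose) for pose, _ in decoys]
        models.insert(1, (receptor, ligand))
        result = evaluate_models(models, partners)
        assert result.per_model_irmsd[1] == pytest.approx(0.0, abs=1e-9)
        assert result.first_hit_rank is not None
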