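import numpy as np
import pytest

from nucdock.errors import ContractViolation
from nucdock.fixtures import DuplexSpec, duplex_partners, make_decoys
from nucdock.potential import (
    AtomTypeScheme,
    PotentialTable,
    TypedAtoms,
    assign_atom_types,
    default_potential,
    derive_potential,
    inverse_boltzmann,
    score_pair_arrays,
    score_pose,
    uniform_density_reference,
)
from nucdock.structures import Atom, Residue, RigidTransform, Structure
from tests.conftest import random_rotation

G_HEAVY_ATOMS = [
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'",
    "O2'", "C1'", "N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2",
    "N3", "C4",
]
U_BASE_ATOMS = ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"]


def single_atom_structure(coord, name="C4'", element="C", res_name="G"):
    atom = Atom(name, element, np.asarray(coord, dtype=float))
    return Structure([("A", [Residue(res_name, "A", 1, [atom])])])


def simple_table(energy_value=0.0, n_types=None):
    scheme = AtomTypeScheme.default()
    n = n_types or scheme.n_types
    edges = np.arange(0.0, 10.5, 0.5)
    E = np.full((n, n, len(edges) - 1), energy_value)
    return PotentialTable(bin_edges=edges, energies=E)


class TestAtomTypeScheme:
    def test_standard_g_fully_mapped(self):
        scheme = AtomTypeScheme.default()
        for name in G_HEAVY_ATOMS:
            element = name.lstrip("0123456789")[0]
            assert scheme.type_of("G", name, element) != scheme.catch_all

    def test_dt_matches_u_except_methyl(self):
        scheme = AtomTypeScheme.default()
        for name in U_BASE_ATOMS:
            element = name[0]
            assert scheme.type_of("DT", name, element) == scheme.type_of(
                "U", name, element
            )
        assert scheme.type_of("DT", "C7", "C") == scheme.catch_all
        assert scheme.type_of("DT", "C5M", "C") == scheme.catch_all

    def test_unknown_residue_falls_to_catch_all(self):
        scheme = AtomTypeScheme.default()
        assert scheme.type_of("XYZ", "C1'", "C") == scheme.catch_all

    def test_assign_on_empty_structure(self):
        typed = assign_atom_types(Structure([("A", [])]))
        assert len(typed.coords) == 0

    def test_assign_counts_unmapped(self, duplex):
        typed = assign_atom_types(duplex)
        assert len(typed.coords) == duplex.n_atoms
        assert typed.n_unmapped <= duplex.n_atoms


class TestScorePose:
    def test_distant_partners_score_zero(self):
        a = assign_atom_types(single_atom_structure([0, 0, 0]))
        b = assign_atom_types(single_atom_structure([100, 0, 0]))
        assert score_pose(a, b, simple_table(1.0)) == 0.0

    def test_single_pair_closed_form(self):
        scheme = AtomTypeScheme.default()
        table = simple_table(0.0)
        ti = scheme.type_of("G", "C4'", "C")
        d = 3.7
        table.energies[ti, ti, int(d / 0.5)] = -1.25
        a = assign_atom_types(single_atom_structure([0, 0, 0]))
        b = assign_atom_types(single_atom_structure([d, 0, 0]))
        assert score_pose(a, b, table) == pytest.approx(-1.25)

    def test_clash_overrides_table(self):
        table = simple_table(-5.0)
        a = assign_atom_types(single_atom_structure([0, 0, 0]))
        b = assign_atom_types(single_atom_structure([1.0, 0, 0]))
        assert score_pose(a, b, table) == pytest.approx(10.0)

    def test_joint_transform_invariance(self, partners, rng):
        receptor, ligand = partners
        table = default_potential()
        tr = assign_atom_types(receptor)
        tl = assign_atom_types(ligand)
        # jitter away from exact bin-edge distances of the ideal helix
        tr = TypedAtoms(tr.coords + rng.normal(scale=0.01, size=tr.coords.shape),
                        tr.types)
        tl = TypedAtoms(tl.coords + rng.normal(scale=0.01, size=tl.coords.shape),
                        tl.types)
        base = score_pair_arrays(tr, tl.coords, tl.types, table)
        R = random_rotation(rng)
        t = rng.normal(size=3) * 7
        moved_r = TypedAtoms(tr.coords @ R.T + t, tr.types)
        moved_l_coords = tl.coords @ R.T + t
        moved = score_pair_arrays(moved_r, moved_l_coords, tl.types, table)
        assert moved == pytest.approx(base, abs=1e-9)

    def test_symmetry(self, partners):
        receptor, ligand = partners
        table = default_potential()
        tr = assign_atom_types(receptor)
        tl = assign_atom_types(ligand)
        ab = score_pair_arrays(tr, tl.coords, tl.types, table)
        ba = score_pair_arrays(tl, tr.coords, tr.types, table)
        assert ab == ba

    def test_additivity_of_disjoint_ligands(self, partners):
        receptor, ligand = partners
        table = default_potential()
        tr = assign_atom_types(receptor)
        tl = assign_atom_types(ligand)
        far = tl.coords + np.array([500.0, 0.0, 0.0])
        both_coords = np.vstack([tl.coords, far])
        both_types = np.concatenate([tl.types, tl.types])
        combined = score_pair_arrays(tr, both_coords, both_types, table)
        near = score_pair_arrays(tr, tl.coords, tl.types, table)
        assert combined == pytest.approx(near, abs=1e-9)

    def test_locality_of_small_perturbation(self, partners):
        """Moving one ligand atom by less than a bin width only changes that
        atom's own pair terms."""
        receptor, ligand = partners
        table = default_potential()
        tr = assign_atom_types(receptor)
        tl = assign_atom_types(ligand)
        moved = tl.coords.copy()
        moved[5] += np.array([0.2, 0.0, 0.0])
        delta_full = (
            score_pair_arrays(tr, moved, tl.types, table)
            - score_pair_arrays(tr, tl.coords, tl.types, table)
        )
        one_before = score_pair_arrays(
            tr, tl.coords[5:6], tl.types[5:6], table
        )
        one_after = score_pair_arrays(tr, moved[5:6], tl.types[5:6], table)
        assert delta_full == pytest.approx(one_after - one_before, abs=1e-9)

    def test_transform_argument(self, partners):
        receptor, ligand = partners
        table = default_potential()
        tr = assign_atom_types(receptor)
        tl = assign_atom_types(ligand)
        t = RigidTransform(np.eye(3), np.array([100.0, 0.0, 0.0]))
        assert score_pose(tr, tl, table, transform=t) == 0.0


class TestDerivePotential:
    def test_inverse_boltzmann_reference_equals_observed(self):
        obs = np.full((2, 2, 4), 7.0)
        energies = inverse_boltzmann(obs, obs, epsilon=0.5)
        np.testing.assert_allclose(energies, 0.0)

    def test_inverse_boltzmann_twofold_enrichment(self):
        ref = np.full((1, 1, 1), 100.0)
        obs = 2.0 * ref
        e = inverse_boltzmann(obs, ref, epsilon=1e-12)
        assert e[0, 0, 0] == pytest.approx(-np.log(2.0), abs=1e-6)

    def test_uniform_density_reference_shell_weights(self):
        edges = np.array([0.0, 1.0, 2.0])
        obs = np.zeros((1, 1, 2))
        obs[0, 0, 0] = obs[0, 0, 1] = 4.0
        ref = uniform_density_reference(obs, edges)
        # shells scale as r^3 differences: 1 : 7
        assert ref[0, 0, 0] == pytest.approx(8.0 * 1.0 / 8.0)
        assert ref[0, 0, 1] == pytest.approx(8.0 * 7.0 / 8.0)

    def test_empty_training_set(self):
        with pytest.raises(ContractViolation):
            derive_potential([])

    def test_deterministic(self):
        complexes = [duplex_partners(DuplexSpec("GGCC"))]
        a = derive_potential(complexes)
        b = derive_potential(complexes)
        np.testing.assert_array_equal(a.energies, b.energies)

    def test_discriminates_natives_from_decoys(self):
        """Derived table scores natives better than 5 A-shifted decoys in
        >= 90% of 20 fixture complexes."""
        table = default_potential()
        sequences = [
            "GGGGCCCC", "AUAUAUAU", "GACUGACU", "CCGGAAUU", "UGCAUGCA",
            "GGCCGGCC", "AAUUGGCC", "CGCGAUAU", "GGAACCUU", "ACGUACGU",
            "GCGCGCGC", "UUAACCGG", "AGCUAGCU", "CAGUCAGU", "GUCAGUCA",
            "CCCCGGGG", "AAAAUUUU", "GAGACUCU", "UGUGACAC", "CUCUGAGA",
        ]
        wins = 0
        for k, seq in enumerate(sequences):
            rec, lig = duplex_partners(DuplexSpec(seq))
            tr = assign_atom_types(rec)
            tl = assign_atom_types(lig)
            native = score_pair_arrays(tr, tl.coords, tl.types, table)
            decoy, _ = make_decoys(lig, 1, 5.0, 0.0, seed=900 + k)[0]
            td = assign_atom_types(decoy)
            if native < score_pair_arrays(tr, td.coords, td.types, table):
                wins += 1
        assert wins >= 18

    def test_iterative_refinement_runs(self):
        complexes = [duplex_partners(DuplexSpec("GGGGCCCC"))]
        decoys = [[pose for pose, _ in make_decoys(complexes[0][1], 3, 6.0,
                                                   20.0, seed=5)]]
        t1 = derive_potential(complexes, iterations=1)
        t3 = derive_potential(complexes, iterations=3, decoys=decoys)
        assert t3.metadata["iterations"] == 3
        assert t1.energies.shape == t3.energies.shape


class TestTableSerialization:
    def test_text_roundtrip_bit_exact(self):
        table = derive_potential([duplex_partners(DuplexSpec("GGCC"))])
        again = PotentialTable.from_text(table.to_text())
        np.testing.assert_array_equal(again.energies, table.energies)
        np.testing.assert_array_equal(again.bin_edges, table.bin_edges)

    def test_symmetry_enforced(self):
        edges = np.array([0.0, 1.0])
        E = np.zeros((2, 2, 1))
        E[0, 1, 0] = 1.0  # asymmetric
        with pytest.raises(ContractViolation):
            PotentialTable(bin_edges=edges, energies=E)

    def test_non_finite_rejected(self):
        edges = np.array([0.0, 1.0])
        E = np.full((1, 1, 1), np.nan)
        with pytest.raises(ContractViolation):
            PotentialTable(bin_edges=edges, energies=E)
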