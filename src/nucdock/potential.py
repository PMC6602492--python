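"""Distance-dependent knowledge-based atom-pair potential.

Atom typing collapses (residue, atom name) to base-specific chemical classes
(phosphate, sugar, base N/O/C per base identity) plus a catch-all; DNA
residues are aliased onto the RNA classes with thymine treated as uracil and
its methyl carbon falling to the catch-all.  The potential is an
inverse-Boltzmann table over uniform distance bins, optionally refined by an
iterative native-vs-decoy reweighting; scoring sums table energies over all
inter-molecular heavy-atom pairs inside the distance range, with a flat
repulsive clash term below 2 A.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from nucdock.errors import ContractViolation
from nucdock.structures import RigidTransform, Structure, canonical_residue_name

_PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P",
                              "O5'", "O3'"})
_SUGAR_ATOMS = frozenset({"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'"})
_THYMINE_METHYL = frozenset({"C7", "C5M"})

_BASES = ("A", "C", "G", "U")
_CLASSES = ("phos", "sugar", "baseN", "baseO", "baseC")


@dataclass(frozen=True)
class AtomTypeScheme:
    """(residue name, atom name) -> integer type id; last id is catch-all."""

    type_names: tuple[str, ...]

    @classmethod
    def default(cls) -> "AtomTypeScheme":
        names = tuple(f"{b}_{c}" for b in _BASES for c in _CLASSES) + ("other",)
        return cls(type_names=names)

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    @property
    def catch_all(self) -> int:
        return self.n_types - 1

    def type_of(self, residue_name: str, atom_name: str, element: str) -> int:
        try:
            base = canonical_residue_name(residue_name)
        except Exception:
            return self.catch_all
        if base.startswith("D"):
            base = base[1:]
        if base == "T":
            base = "U"
        if base not in _BASES:
            return self.catch_all
        if atom_name in _THYMINE_METHYL:
            return self.catch_all
        if atom_name in _PHOSPHATE_ATOMS:
            cls_name = "phos"
        elif atom_name in _SUGAR_ATOMS:
            cls_name = "sugar"
        elif element == "N":
            cls_name = "baseN"
        elif element == "O":
            cls_name = "baseO"
        elif element == "C":
            cls_name = "baseC"
        else:
            return self.catch_all
        return self.type_names.index(f"{base}_{cls_name}")


@dataclass
class TypedAtoms:
    """Heavy atoms of one molecule, ready for pair scoring."""

    coords: np.ndarray  # (n, 3)
    types: np.ndarray  # (n,) int
    n_unmapped: int = 0


def assign_atom_types(s: Structure, scheme: AtomTypeScheme | None = None) -> TypedAtoms:
    """Type every heavy atom; unknowns fall to the catch-all (counted)."""
    scheme = scheme or AtomTypeScheme.default()
    coords = []
    types = []
    unmapped = 0
    for res in s.residues():
        for atom in res.atoms:
            t = scheme.type_of(res.name, atom.name, atom.element)
            if t == scheme.catch_all:
                unmapped += 1
            coords.append(atom.coord)
            types.append(t)
    if not coords:
        return TypedAtoms(np.zeros((0, 3)), np.zeros(0, dtype=int), 0)
    return TypedAtoms(np.array(coords), np.array(types, dtype=int), unmapped)


@dataclass
class PotentialTable:
    """type-pair x distance-bin energies; symmetric; zero beyond r_max."""

    bin_edges: np.ndarray  # (n_bins + 1,), uniform, starting at 0
    energies: np.ndarray  # (n_types, n_types, n_bins)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        E = np.asarray(self.energies, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or edges[0] != 0.0:
            raise ContractViolation("bin_edges must be 1D starting at 0")
        widths = np.diff(edges)
        if not np.allclose(widths, widths[0]):
            raise ContractViolation("bin_edges must be uniform")
        if E.shape[2] != len(edges) - 1 or E.shape[0] != E.shape[1]:
            raise ContractViolation(
                f"energies shape {E.shape} inconsistent with {len(edges)-1} bins"
            )
        if not np.all(np.isfinite(E)):
            raise ContractViolation("energies must be finite")
        if not np.allclose(E, E.transpose(1, 0, 2)):
            raise ContractViolation("energies must be symmetric in the type pair")
        self.bin_edges = edges
        self.energies = E

    @property
    def r_max(self) -> float:
        return float(self.bin_edges[-1])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_types(self) -> int:
        return self.energies.shape[0]

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("# nucdock pair potential\n")
        buf.write(f"n_types {self.n_types}\n")
        buf.write(f"n_bins {self.energies.shape[2]}\n")
        buf.write(f"bin_width {self.bin_width!r}\n")
        for i in range(self.n_types):
            for j in range(i, self.n_types):
                for b in range(self.energies.shape[2]):
                    lo = float(self.bin_edges[b])
                    hi = float(self.bin_edges[b + 1])
                    e = float(self.energies[i, j, b])
                    buf.write(f"{i} {j} {lo!r} {hi!r} {e!r}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "PotentialTable":
        header: dict[str, str] = {}
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2 and not parts[0].lstrip("-").isdigit():
                header[parts[0]] = parts[1]
            elif len(parts) == 5:
                rows.append(parts)
            else:
                raise ContractViolation(f"malformed potential line: {line!r}")
        n_types = int(header["n_types"])
        n_bins = int(header["n_bins"])
        bw = float(header["bin_width"])
        edges = np.arange(n_bins + 1) * bw
        E = np.zeros((n_types, n_types, n_bins))
        for i_s, j_s, lo_s, _hi_s, e_s in rows:
            i, j = int(i_s), int(j_s)
            b = int(round(float(lo_s) / bw))
            E[i, j, b] = E[j, i, b] = float(e_s)
        return cls(bin_edges=edges, energies=E)


def score_pair_arrays(
    receptor: TypedAtoms,
    ligand_coords: np.ndarray,
    ligand_types: np.ndarray,
    table: PotentialTable,
    clash_distance: float = 2.0,
    clash_energy: float = 10.0,
) -> float:
    """Core pair-sum; ligand coordinates given explicitly (already posed)."""
    n_r = len(receptor.coords)
    n_l = len(ligand_coords)
    if n_r == 0 or n_l == 0:
        return 0.0
    r_max = table.r_max
    if n_r * n_l <= 250_000:
        D = cdist(receptor.coords, ligand_coords)
        ri, li = np.nonzero(D < r_max)
        d = D[ri, li]
    else:
        tree_r = cKDTree(receptor.coords)
        tree_l = cKDTree(ligand_coords)
        pairs = tree_r.query_ball_tree(tree_l, r_max)
        ri = np.fromiter(
            (i for i, js in enumerate(pairs) for _ in js), dtype=int
        )
        li = np.fromiter(
            (j for js in pairs for j in js), dtype=int
        )
        if len(ri) == 0:
            return 0.0
        d = np.linalg.norm(receptor.coords[ri] - ligand_coords[li], axis=1)
        keep = d < r_max
        ri, li, d = ri[keep], li[keep], d[keep]
    if len(d) == 0:
        return 0.0
    bins = np.minimum(
        (d / table.bin_width).astype(int), table.energies.shape[2] - 1
    )
    e = table.energies[receptor.types[ri], ligand_types[li], bins]
    e = np.where(d < clash_distance, clash_energy, e)
    return float(e.sum())


def score_pose(
    receptor: TypedAtoms,
    ligand: TypedAtoms,
    table: PotentialTable,
    transform: RigidTransform | None = None,
    center: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
    clash_distance: float = 2.0,
    clash_energy: float = 10.0,
) -> float:
    """Energy of a ligand pose against the receptor (lower is better)."""
    coords = ligand.coords
    if transform is not None:
        c = np.asarray(center, dtype=float)
        coords = (coords - c) @ transform.rotation.T + c + transform.translation
    return score_pair_arrays(
        receptor, coords, ligand.types, table, clash_distance, clash_energy
    )


def _pair_counts(
    rec: TypedAtoms,
    lig_coords: np.ndarray,
    lig_types: np.ndarray,
    n_types: int,
    bin_edges: np.ndarray,
) -> np.ndarray:
    counts = np.zeros((n_types, n_types, len(bin_edges) - 1))
    if len(rec.coords) == 0 or len(lig_coords) == 0:
        return counts
    r_max = bin_edges[-1]
    bw = bin_edges[1] - bin_edges[0]
    D = cdist(rec.coords, lig_coords)
    ri, li = np.nonzero(D < r_max)
    if len(ri) == 0:
        return counts
    bins = np.minimum((D[ri, li] / bw).astype(int), len(bin_edges) - 2)
    np.add.at(counts, (rec.types[ri], lig_types[li], bins), 1.0)
    # symmetrize so the table never depends on partner order
    return counts + counts.transpose(1, 0, 2) - np.where(
        np.eye(counts.shape[0], dtype=bool)[:, :, None], counts, 0.0
    )


def uniform_density_reference(
    observed: np.ndarray, bin_edges: np.ndarray
) -> np.ndarray:
    """Reference counts: per type pair, total observed pairs spread over bins
    in proportion to shell volume (distance-uniform density)."""
    shells = np.diff(bin_edges**3)
    shells = shells / shells.sum()
    totals = observed.sum(axis=2, keepdims=True)
    return totals * shells[None, None, :]


def inverse_boltzmann(
    observed: np.ndarray, reference: np.ndarray, epsilon: float = 0.5
) -> np.ndarray:
    """E = -ln((N_obs + eps) / (N_ref + eps)), elementwise."""
    return -np.log((observed + epsilon) / (reference + epsilon))


def derive_potential(
    training_complexes: Sequence[tuple[Structure, Structure]],
    scheme: AtomTypeScheme | None = None,
    bin_edges: np.ndarray | None = None,
    iterations: int = 1,
    decoys: Sequence[Sequence[Structure]] | None = None,
    epsilon: float = 0.5,
    learning_rate: float = 1.0,
) -> PotentialTable:
    """Derive a pair potential from native complexes.

    Iteration 0 is the inverse-Boltzmann step
    ``E = -ln((N_obs + eps) / (N_ref + eps))`` against a distance-uniform
    density reference.  Further iterations reweight the table toward
    discriminating each native pose from caller-supplied decoy poses of the
    same ligand: for every decoy scored at least as well as its native, the
    normalized decoy-minus-native contact histogram is added to the energies.
    Deterministic given inputs.
    """
    if not training_complexes:
        raise ContractViolation("training set must contain at least one complex")
    scheme = scheme or AtomTypeScheme.default()
    if bin_edges is None:
        bin_edges = np.arange(0.0, 10.0 + 0.25, 0.5)
    bin_edges = np.asarray(bin_edges, dtype=float)
    n_types = scheme.n_types

    typed = [
        (assign_atom_types(rec, scheme), assign_atom_types(lig, scheme))
        for rec, lig in training_complexes
    ]
    observed = np.zeros((n_types, n_types, len(bin_edges) - 1))
    any_contact = False
    for rec_t, lig_t in typed:
        c = _pair_counts(rec_t, lig_t.coords, lig_t.types, n_types, bin_edges)
        if c.sum() > 0:
            any_contact = True
        observed += c
    if not any_contact:
        raise ContractViolation("no inter-molecular contacts in training set")

    reference = uniform_density_reference(observed, bin_edges)
    energies = inverse_boltzmann(observed, reference, epsilon)
    table = PotentialTable(
        bin_edges=bin_edges,
        energies=energies,
        metadata={"iterations": 0, "epsilon": epsilon},
    )

    if iterations <= 1 or decoys is None:
        table.metadata["iterations"] = max(iterations, 1)
        return table

    for _ in range(1, iterations):
        delta = np.zeros_like(energies)
        n_misranked = 0
        for (rec_t, lig_t), decoy_list in zip(typed, decoys):
            native_score = score_pair_arrays(
                rec_t, lig_t.coords, lig_t.types, table
            )
            native_counts = _pair_counts(
                rec_t, lig_t.coords, lig_t.types, n_types, bin_edges
            )
            n_native = max(native_counts.sum(), 1.0)
            for decoy in decoy_list:
                decoy_t = assign_atom_types(decoy, scheme)
                decoy_score = score_pair_arrays(
                    rec_t, decoy_t.coords, decoy_t.types, table
                )
                if decoy_score <= native_score:
                    n_misranked += 1
                    decoy_counts = _pair_counts(
                        rec_t, decoy_t.coords, decoy_t.types, n_types, bin_edges
                    )
                    n_decoy = max(decoy_counts.sum(), 1.0)
                    delta += (
                        decoy_counts / n_decoy - native_counts / n_native
                    )
        if n_misranked == 0:
            break
        energies = energies + learning_rate * delta
        table = PotentialTable(
            bin_edges=bin_edges, energies=energies, metadata=table.metadata
        )
    table.metadata["iterations"] = iterations
    return table


@lru_cache(maxsize=1)
def default_potential() -> PotentialTable:
    """Small built-in table derived from fixture duplexes (pipeline default)."""
    from nucdock.fixtures import DuplexSpec, duplex_partners, make_decoys

    sequences = ["GGGGCCCC", "AUAUAUAU", "GACUGACU", "CCGGAAUU", "UGCAUGCA"]
    complexes = []
    decoys = []
    for k, seq in enumerate(sequences):
        rec, lig = duplex_partners(DuplexSpec(seq))
        complexes.append((rec, lig))
        decoys.append(
            [pose for pose, _ in make_decoys(lig, 6, 6.0, 25.0, seed=100 + k)]
        )
    table = derive_potential(complexes, iterations=3, decoys=decoys)
    table.metadata["source"] = "fixture-duplex-default"
    return table
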