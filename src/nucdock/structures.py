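"""Nucleic-acid structure model: parsing, selection, rigid motion, PDB output.

The structure hierarchy is chains -> residues -> heavy atoms.  Hydrogens,
waters and common ions are stripped at parse time; only the first MODEL of an
ensemble is kept; altloc 'A' (or blank) wins.  Residue identity is the triple
``(chain_id, seq_id, icode)`` with the original PDB numbering preserved.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from nucdock.errors import (
    ContractViolation,
    MissingChainError,
    PDBParseError,
    UnknownResidueError,
)

#: Canonical nucleotide names (RNA + DNA).
STANDARD_RESIDUES = frozenset({"A", "C", "G", "U", "DA", "DC", "DG", "DT"})

#: Modified / alternative residue names mapped onto the canonical alphabet.
RESIDUE_ALIASES = {
    "RA": "A", "RC": "C", "RG": "G", "RU": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U",
    "THY": "DT", "T": "DT",
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "OMU": "U", "DHU": "U",
    "1MA": "A", "MA6": "A", "6MA": "A", "A2M": "A", "OMA": "A",
    "5MC": "C", "OMC": "C", "CCC": "C", "4OC": "C",
    "1MG": "G", "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "YG": "G",
    "I": "G", "INO": "G",
}

#: Solvent / ion residue names dropped silently during parsing.
_SOLVENT = frozenset({
    "HOH", "WAT", "DOD", "NA", "K", "MG", "CA", "CL", "ZN", "MN", "SR", "BA",
    "CS", "BR", "IOD", "SO4", "PO4", "NH4", "SPD", "SPM", "EDO", "GOL",
})

_CHAIN_ID_POOL = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def canonical_residue_name(name: str) -> str:
    """Map a PDB residue name onto the canonical nucleic alphabet.

    Raises :class:`UnknownResidueError` for names that are neither standard
    nucleotides nor known aliases.
    """
    name = name.strip().upper()
    if name in STANDARD_RESIDUES:
        return name
    if name in RESIDUE_ALIASES:
        return RESIDUE_ALIASES[name]
    raise UnknownResidueError(f"residue name {name!r} is not a known nucleotide")


def is_purine(residue_name: str) -> bool:
    return canonical_residue_name(residue_name) in {"A", "G", "DA", "DG"}


@dataclass(frozen=True)
class Atom:
    """A single heavy atom."""

    name: str
    element: str
    coord: np.ndarray
    residue_index: int = 0
    serial: int = 0

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ContractViolation(f"atom {self.name}: invalid coordinates {coord}")
        if not self.element:
            raise ContractViolation(f"atom {self.name}: empty element")
        object.__setattr__(self, "coord", coord)


@dataclass
class Residue:
    """One nucleotide with its heavy atoms."""

    name: str
    chain_id: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Structure:
    """An ordered collection of chains of nucleotides."""

    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.chains]
        if len(ids) != len(set(ids)):
            raise ContractViolation(f"duplicate chain ids in {self.label!r}: {ids}")

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise MissingChainError(f"chain {chain_id!r} not in {self.chain_ids}")

    def residues(self) -> Iterator[Residue]:
        for _, residues in self.chains:
            yield from residues

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    def residue(self, key: tuple[str, int, str]) -> Residue:
        chain_id, seq_id, icode = key
        for res in self.chain(chain_id):
            if res.seq_id == seq_id and res.icode == icode:
                return res
        raise KeyError(f"residue {key} not found")

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of all heavy-atom coordinates, file order."""
        arr = [a.coord for a in self.atoms()]
        if not arr:
            return np.zeros((0, 3))
        return np.array(arr, dtype=float)

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    @property
    def n_residues(self) -> int:
        return sum(1 for _ in self.residues())

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with all atom coordinates replaced (file order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ContractViolation(
                f"coordinate array shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        out_chains: list[tuple[str, list[Residue]]] = []
        i = 0
        for cid, residues in self.chains:
            new_residues = []
            for res in residues:
                new_atoms = []
                for a in res.atoms:
                    new_atoms.append(
                        Atom(a.name, a.element, coords[i], a.residue_index, a.serial)
                    )
                    i += 1
                new_residues.append(
                    Residue(res.name, res.chain_id, res.seq_id, new_atoms, res.icode)
                )
            out_chains.append((cid, new_residues))
        return Structure(out_chains, label=self.label)

    def subset(self, chain_ids: Iterable[str]) -> "Structure":
        wanted = list(chain_ids)
        missing = [c for c in wanted if c not in self.chain_ids]
        if missing:
            raise MissingChainError(
                f"chain(s) {missing} not present; available: {self.chain_ids}"
            )
        chains = [(cid, res) for cid, res in self.chains if cid in wanted]
        return Structure(chains, label=self.label)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ContractViolation("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ContractViolation("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ContractViolation("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


# ---------------------------------------------------------------------------
# Parsing

def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_structure(
    pdb_text: str | io.TextIOBase,
    chains: set[str] | None = None,
    label: str = "",
) -> Structure:
    """Parse PDB text into a heavy-atom :class:`Structure`.

    Only the first MODEL is read; altloc blank/'A' atoms are kept; hydrogens,
    waters and common ions are dropped.  Unknown residue names raise
    :class:`UnknownResidueError`.
    """
    if hasattr(pdb_text, "read"):
        pdb_text = pdb_text.read()

    chain_order: list[str] = []
    by_chain: dict[str, list[Residue]] = {}
    current_key: tuple[str, int, str] | None = None
    current_res: Residue | None = None
    saw_record = False
    in_first_model = True

    for line in pdb_text.splitlines():
        record = line[:6]
        if record == "MODEL ":
            # first MODEL only
            if saw_record:
                break
            continue
        if record == "ENDMDL":
            if saw_record:
                break
            continue
        if record not in ("ATOM  ", "HETATM"):
            continue
        if not in_first_model:
            continue
        line = line.ljust(80)
        res_name_raw = line[17:20].strip()
        if record == "HETATM" and res_name_raw.upper() in _SOLVENT:
            continue
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        element = line[76:78].strip().upper()
        atom_name = line[12:16].strip()
        if not element:
            element = _infer_element(atom_name)
        if element in ("H", "D"):
            continue
        saw_record = True
        res_name = canonical_residue_name(res_name_raw)
        chain_id = line[21]
        try:
            seq_id = int(line[22:26])
            serial = int(line[6:11]) if line[6:11].strip() else 0
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"malformed ATOM record: {line.rstrip()!r}") from exc
        icode = line[26].strip()
        key = (chain_id, seq_id, icode)
        if key != current_key:
            if chain_id not in by_chain:
                by_chain[chain_id] = []
                chain_order.append(chain_id)
            current_res = Residue(res_name, chain_id, seq_id, [], icode)
            by_chain[chain_id].append(current_res)
            current_key = key
        assert current_res is not None
        current_res.atoms.append(
            Atom(
                name=atom_name,
                element=element,
                coord=np.array([x, y, z]),
                residue_index=len(by_chain[chain_id]) - 1,
                serial=serial,
            )
        )

    if not saw_record:
        raise PDBParseError("no ATOM/HETATM records found")

    structure = Structure(
        [(cid, by_chain[cid]) for cid in chain_order], label=label
    )
    if chains is not None:
        missing = sorted(set(chains) - set(structure.chain_ids))
        if missing:
            raise MissingChainError(
                f"chain(s) {missing} not present; available: {structure.chain_ids}"
            )
        structure = structure.subset(
            [c for c in structure.chain_ids if c in chains]
        )
    return structure


def select_atoms(
    s: Structure, atom_name: str
) -> tuple[list[tuple[tuple[str, int, str], np.ndarray]], int]:
    """Per-residue selection of a named atom.

    Returns ``(entries, n_skipped)`` where entries are ``(residue_key, coord)``
    in residue order and ``n_skipped`` counts residues lacking the atom.
    """
    entries: list[tuple[tuple[str, int, str], np.ndarray]] = []
    skipped = 0
    for res in s.residues():
        atom = res.atom(atom_name)
        if atom is None:
            skipped += 1
        else:
            entries.append((res.key, atom.coord))
    return entries, skipped


def apply_transform(
    s: Structure, t: RigidTransform, center: np.ndarray | Sequence[float] = (0, 0, 0)
) -> Structure:
    """Rigidly move a structure: x -> R (x - center) + center + translation."""
    center = np.asarray(center, dtype=float)
    coords = s.coords()
    moved = (coords - center) @ t.rotation.T + center + t.translation
    return s.with_coords(moved)


# ---------------------------------------------------------------------------
# Writing

def _format_atom_name(name: str, element: str) -> str:
    # standard PDB alignment: 1-char elements start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(
    serial: int, atom: Atom, res: Residue, chain_id: str
) -> str:
    x, y, z = atom.coord
    return (
        f"ATOM  {serial:>5d} {_format_atom_name(atom.name, atom.element)} "
        f"{res.name:>3s} {chain_id}{res.seq_id:>4d}{res.icode or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{atom.element:>2s}"
    )


def write_structure(s: Structure) -> str:
    """Serialize a structure to PDB text (ATOM/TER/END)."""
    lines: list[str] = []
    serial = 0
    for cid, residues in s.chains:
        for res in residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_atom_line(serial, atom, res, cid))
        serial += 1
        lines.append(f"TER   {serial:>5d}      {residues[-1].name:>3s} "
                     f"{cid}{residues[-1].seq_id:>4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_model(
    receptor: Structure,
    ligand_pose: Structure,
    rank: int,
    scores: tuple[float, float],
) -> str:
    """One docked model as PDB text: receptor chains then ligand chains.

    ``scores`` is ``(shape_score, energy_score)``; both are echoed on REMARK 3
    lines along with the rank.  Ligand chains colliding with receptor chain
    ids are renamed from an A-Z/a-z/0-9 pool.
    """
    if rank < 1:
        raise ContractViolation(f"rank must be >= 1, got {rank}")
    shape_score, energy_score = scores
    used = set(receptor.chain_ids)
    renamed: list[tuple[str, list[Residue]]] = []
    for cid, residues in ligand_pose.chains:
        new_cid = cid
        if new_cid in used:
            for candidate in _CHAIN_ID_POOL:
                if candidate not in used:
                    new_cid = candidate
                    break
            else:
                raise ContractViolation("chain-id pool exhausted (>62 chains)")
        used.add(new_cid)
        renamed.append((new_cid, residues))

    header = (
        f"REMARK 3 RANK {rank}\n"
        f"REMARK 3 SHAPE_SCORE {shape_score:.6f}\n"
        f"REMARK 3 ENERGY_SCORE {energy_score:.6f}\n"
    )
    body_receptor = write_structure(receptor).replace("END\n", "")
    lig = Structure(renamed, label=ligand_pose.label)
    body_ligand = write_structure(lig)
    return header + body_receptor + body_ligand


def read_model_scores(pdb_text: str) -> dict[str, float]:
    """Recover rank/shape/energy from a model's REMARK 3 lines."""
    out: dict[str, float] = {}
    for line in pdb_text.splitlines():
        if not line.startswith("REMARK 3 "):
            continue
        parts = line.split()
        if len(parts) == 4 and parts[2] in ("RANK", "SHAPE_SCORE", "ENERGY_SCORE"):
            out[parts[2].lower()] = float(parts[3])
    return out
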