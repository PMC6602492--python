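"""Synthetic test data: ideal duplex complexes, decoy poses, toy grids.

The duplex builder places a coarse heavy-atom set (P, C4', C1', N1/N9) on an
ideal double helix so that every pipeline stage can run without external
structure files.  Helix constants default to textbook A-form values (twist
32.7 deg/bp, rise 2.81 A/bp, backbone radius 9.4 A); they are fixture
constants chosen for geometric realism, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nucdock.errors import ContractViolation
from nucdock.grids import GridMap
from nucdock.structures import (
    Atom,
    Residue,
    RigidTransform,
    Structure,
    apply_transform,
    select_atoms,
)

_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_PAIR_PHASE = 140.0  # angular offset of the partner strand

# Per-residue heavy-atom layout as (name, param offset, radius, angular
# offset, z offset): param offset advances along the helix (in base-pair
# units, sign-flipped on the antiparallel strand), angular offsets are
# mirrored on strand B.  The sugar/backbone region is filled with a small
# 3D lattice of atoms so that the digitized strand has a solid interior —
# a sparser bead model never produces grid core cells and would make every
# interpenetrating pose look shape-complementary.
_PHOSPHATE_GROUP = (
    ("P", -0.65, 9.6, 0.0, 0.0),
    ("OP1", -0.65, 10.3, 5.0, 0.8),
    ("OP2", -0.70, 9.9, -6.0, -0.8),
)
_FILLER_NAMES = (
    "O3'", "C3'", "C2'", "O2'", "O4'", "C8", "N7", "C5", "C6",
    "N3", "C4", "O2", "N4", "O6", "N2", "C7", "N6", "O4",
)
_FILLER_RADII = (9.9, 8.7, 7.5)
_FILLER_ANGLES = (-6.0, 6.0, 18.0)
_FILLER_DZ = (-0.9, 0.9)
_CORE_ATOMS = (
    ("O5'", -0.35, 9.5, 0.0, 0.2),
    ("C5'", -0.15, 9.35, 0.0, 0.1),
    ("C4'", 0.0, None, 0.0, 0.0),  # radius from the spec
    ("C1'", 0.0, 7.2, 12.0, 0.2),
    ("C6", 0.0, 6.4, 22.0, 0.1),
    ("C2", 0.0, 5.2, 30.0, -0.1),
    ("C3", 0.0, 3.0, 40.0, 0.0),
)
_N_RADIUS = 4.0
_N_OFFSET = 42.0


@dataclass(frozen=True)
class DuplexSpec:
    """Parameters of an ideal duplex fixture."""

    sequence: str
    rise: float = 2.81
    twist: float = 32.7
    radius: float = 9.4
    seed: int = 0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 2:
            raise ContractViolation("duplex sequence must have length >= 2")
        if "T" in seq and "U" in seq:
            raise ContractViolation("sequence mixes T and U")
        alphabet = set("ACGT") if "T" in seq else set("ACGU")
        bad = set(seq) - alphabet
        if bad:
            raise ContractViolation(f"invalid bases in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def is_dna(self) -> bool:
        return "T" in self.sequence


def _cyl(radius: float, angle_deg: float, z: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([radius * np.cos(a), radius * np.sin(a), z])


def _residue_name(base: str, dna: bool) -> str:
    return f"D{base}" if dna else base


def _build_residue(
    base: str,
    param: float,
    spec: DuplexSpec,
    phase: float,
    mirror: float,
    has_p: bool,
) -> list[Atom]:
    """Atom set for one residue at helix parameter ``param`` (bp index).

    ``mirror`` flips the base angular offsets on strand B; ``has_p`` is
    False for the 5'-terminal residue (no phosphate linkage); linkage atoms
    step toward the previous residue at ``param - mirror-independent``
    fractional offsets scaled by the strand direction.
    """

    def place(p_off: float, radius: float, ang_off: float, dz: float) -> np.ndarray:
        p = param + mirror * p_off  # strand B advances -param per step
        theta = p * spec.twist + phase + mirror * ang_off
        return _cyl(radius, theta, p * spec.rise + dz)

    def element_of(name: str) -> str:
        return name.lstrip("0123456789")[0]

    atoms: list[Atom] = []
    if has_p:
        for name, p_off, radius, ang_off, dz in _PHOSPHATE_GROUP:
            atoms.append(
                Atom(name, element_of(name), place(p_off, radius, ang_off, dz))
            )
    for name, p_off, radius, ang_off, dz in _CORE_ATOMS:
        r = spec.radius if radius is None else radius
        atoms.append(Atom(name, element_of(name), place(p_off, r, ang_off, dz)))
    k = 0
    for radius in _FILLER_RADII:
        for ang_off in _FILLER_ANGLES:
            for dz in _FILLER_DZ:
                name = _FILLER_NAMES[k]
                atoms.append(
                    Atom(name, element_of(name), place(0.0, radius, ang_off, dz))
                )
                k += 1
    n_name = "N9" if base in ("A", "G") else "N1"
    atoms.append(Atom(n_name, "N", place(0.0, _N_RADIUS, _N_OFFSET, 0.0)))
    return atoms


def build_aform_duplex(spec: DuplexSpec) -> Structure:
    """Two antiparallel chains (A: given sequence 5'->3', B: reverse
    complement) on an ideal helix.  The 5'-terminal residue of each chain
    carries no phosphate.  Deterministic given the spec."""
    seq = spec.sequence
    L = len(seq)
    comp = _DNA_COMPLEMENT if spec.is_dna else _RNA_COMPLEMENT

    chain_a: list[Residue] = []
    for i, base in enumerate(seq):
        atoms = _build_residue(
            base, float(i), spec, 0.0, +1.0, has_p=i > 0,
        )
        chain_a.append(Residue(_residue_name(base, spec.is_dna), "A", i + 1, atoms))

    chain_b: list[Residue] = []
    for j in range(L):
        i_pair = L - 1 - j
        base = comp[seq[i_pair]]
        atoms = _build_residue(
            base, float(i_pair), spec, _PAIR_PHASE, -1.0, has_p=j > 0,
        )
        chain_b.append(Residue(_residue_name(base, spec.is_dna), "B", j + 1, atoms))

    return Structure([("A", chain_a), ("B", chain_b)],
                     label=f"duplex:{seq}")


def duplex_partners(spec: DuplexSpec) -> tuple[Structure, Structure]:
    """The two chains of a fixture duplex as separate structures."""
    duplex = build_aform_duplex(spec)
    return duplex.subset(["A"]), duplex.subset(["B"])


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _axis_angle_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(a) * K + (1.0 - np.cos(a)) * (K @ K)


def make_decoys(
    ligand: Structure,
    n: int,
    translation_mag: float = 5.0,
    rotation_deg: float = 0.0,
    seed: int = 0,
) -> list[tuple[Structure, float]]:
    """Rigidly perturbed ligand poses tagged with their exact C4' RMSD.

    Each decoy is rotated by exactly ``rotation_deg`` about a random axis
    through the ligand centroid, then translated by exactly
    ``translation_mag`` along a random direction.  Reproducible per seed.
    """
    if n < 1:
        raise ContractViolation("n must be >= 1")
    rng = np.random.default_rng(seed)
    center = ligand.centroid()
    entries, _ = select_atoms(ligand, "C4'")
    native_c4 = np.array([c for _, c in entries])
    out: list[tuple[Structure, float]] = []
    for _ in range(n):
        R = _axis_angle_matrix(_random_unit_vector(rng), rotation_deg)
        t = _random_unit_vector(rng) * translation_mag
        transform = RigidTransform(R, t)
        pose = apply_transform(ligand, transform, center)
        pose_c4 = (native_c4 - center) @ R.T + center + t
        rmsd = float(np.sqrt(np.mean(np.sum((pose_c4 - native_c4) ** 2, axis=1))))
        out.append((pose, rmsd))
    return out


# ---------------------------------------------------------------------------
# Toy grids for FFT oracle tests


def toy_grid(pattern: str, dims: tuple[int, int, int] = (12, 12, 12)):
    """Deterministic analytically-known grids.

    ``point``: one occupied cell at the box center (binary, ligand role).
    ``slab``: a 1-cell-thick occupied z-slab at mid-height (binary).
    ``pocket_plug``: returns ``(receptor GridMap, plug GridMap, offset,
    score)`` — a solid block whose interior is core penalty, with a cavity
    whose one-cell lining is +1, and a plug that covers exactly the lining
    at integer offset ``offset`` with correlation score ``score``.
    """
    dims = tuple(int(d) for d in dims)
    if pattern == "point":
        values = np.zeros(dims)
        c = tuple(d // 2 for d in dims)
        values[c] = 1.0
        return GridMap(origin=np.zeros(3), spacing=1.2, values=values, role="ligand")
    if pattern == "slab":
        values = np.zeros(dims)
        values[:, :, dims[2] // 2] = 1.0
        return GridMap(origin=np.zeros(3), spacing=1.2, values=values, role="ligand")
    if pattern == "pocket_plug":
        if any(d < 12 for d in dims):
            raise ContractViolation("pocket_plug needs dims >= 12 per axis")
        rec = np.zeros(dims)
        # solid block, interior treated as core
        rec[1:11, 1:11, 1:7] = -15.0
        # cavity open at the block top (z = 6)
        cavity = (slice(4, 8), slice(4, 8), slice(3, 7))
        rec[cavity] = 0.0
        # one-cell lining of the cavity inside the solid
        lining_count = 0
        for ix in range(3, 9):
            for iy in range(3, 9):
                for iz in range(2, 7):
                    in_cavity = 4 <= ix < 8 and 4 <= iy < 8 and 3 <= iz < 7
                    if not in_cavity:
                        rec[ix, iy, iz] = 1.0
                        lining_count += 1
        receptor = GridMap(np.zeros(3), 1.2, rec, role="receptor")
        plug = np.ones((6, 6, 5))
        ligand = GridMap(np.zeros(3), 1.2, plug, role="ligand")
        return receptor, ligand, (3, 3, 2), float(lining_count)
    raise ContractViolation(f"unknown toy grid pattern {pattern!r}")
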