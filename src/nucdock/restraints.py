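"""Binding-site and distance restraints: parsing, evaluation, filtering.

Grammar (one restraint per line, '#' comments):

    site <R|L> chain:seqid[,chain:seqid...]
    dist chain:seqid chain:seqid <max distance A>

A site residue is satisfied when its minimum heavy-atom distance to the
partner molecule is within the interface cutoff; a distance pair when the
minimum heavy-atom distance between the two residues is within its bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from nucdock.errors import RestraintError
from nucdock.structures import Structure

logger = logging.getLogger(__name__)

ResidueRef = tuple[str, int]  # (chain_id, seq_id); insertion codes not addressable


@dataclass
class RestraintSet:
    site_residues: list[tuple[str, str, int]] = field(default_factory=list)
    # (partner "receptor"|"ligand", chain_id, seq_id)
    distance_pairs: list[tuple[ResidueRef, ResidueRef, float]] = field(
        default_factory=list
    )
    mode: str = "filter"

    def __len__(self) -> int:
        return len(self.site_residues) + len(self.distance_pairs)

    def resolve(self, receptor: Structure, ligand: Structure) -> None:
        """Check every residue key against the input structures (pre-dock)."""
        for partner, chain_id, seq_id in self.site_residues:
            s = receptor if partner == "receptor" else ligand
            _find_residue(s, (chain_id, seq_id), partner)
        for rec_ref, lig_ref, _ in self.distance_pairs:
            _find_residue(receptor, rec_ref, "receptor")
            _find_residue(ligand, lig_ref, "ligand")


def _find_residue(s: Structure, ref: ResidueRef, partner: str):
    chain_id, seq_id = ref
    for res in s.residues():
        if res.chain_id == chain_id and res.seq_id == seq_id:
            return res
    raise RestraintError(
        f"restraint residue {chain_id}:{seq_id} not found in {partner}"
    )


def _parse_residue_ref(token: str) -> ResidueRef:
    if ":" not in token:
        raise RestraintError(f"malformed residue reference {token!r}")
    chain_id, _, seq = token.partition(":")
    if not chain_id or len(chain_id) != 1:
        raise RestraintError(f"malformed chain id in {token!r}")
    try:
        return (chain_id, int(seq))
    except ValueError as exc:
        raise RestraintError(f"malformed residue number in {token!r}") from exc


def parse_restraints(text: str, mode: str = "filter") -> RestraintSet:
    """Parse restraint lines; empty text gives an empty (always-satisfied) set."""
    rset = RestraintSet(mode=mode)
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "site":
            if len(parts) != 3 or parts[1] not in ("R", "L"):
                raise RestraintError(f"malformed site restraint: {raw.rstrip()!r}")
            partner = "receptor" if parts[1] == "R" else "ligand"
            for token in parts[2].split(","):
                chain_id, seq_id = _parse_residue_ref(token)
                rset.site_residues.append((partner, chain_id, seq_id))
        elif parts[0] == "dist":
            if len(parts) != 4:
                raise RestraintError(f"malformed dist restraint: {raw.rstrip()!r}")
            rec_ref = _parse_residue_ref(parts[1])
            lig_ref = _parse_residue_ref(parts[2])
            try:
                max_d = float(parts[3])
            except ValueError as exc:
                raise RestraintError(
                    f"malformed distance in {raw.rstrip()!r}"
                ) from exc
            if max_d <= 0:
                raise RestraintError(f"distance must be > 0 in {raw.rstrip()!r}")
            rset.distance_pairs.append((rec_ref, lig_ref, max_d))
        else:
            raise RestraintError(f"unknown restraint keyword {parts[0]!r}")
    return rset


def _min_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    if len(coords_a) * len(coords_b) <= 1_000_000:
        return float(cdist(coords_a, coords_b).min())
    tree = cKDTree(coords_b)
    d, _ = tree.query(coords_a, k=1)
    return float(d.min())


def evaluate_restraints(
    receptor: Structure,
    ligand_pose: Structure,
    r: RestraintSet,
    interface_cutoff: float = 10.0,
) -> tuple[bool, int]:
    """(all satisfied, violation count) for one ligand pose."""
    violations = 0
    rec_coords = receptor.coords()
    lig_coords = ligand_pose.coords()
    for partner, chain_id, seq_id in r.site_residues:
        if partner == "receptor":
            res = _find_residue(receptor, (chain_id, seq_id), partner)
            other = lig_coords
        else:
            res = _find_residue(ligand_pose, (chain_id, seq_id), partner)
            other = rec_coords
        if _min_distance(res.coords(), other) > interface_cutoff:
            violations += 1
    for rec_ref, lig_ref, max_d in r.distance_pairs:
        rec_res = _find_residue(receptor, rec_ref, "receptor")
        lig_res = _find_residue(ligand_pose, lig_ref, "ligand")
        if _min_distance(rec_res.coords(), lig_res.coords()) > max_d:
            violations += 1
    return violations == 0, violations


def apply_restraint_filter(
    modes: Sequence,
    r: RestraintSet,
    violations_of: Callable[[object], int],
    penalty_weight: float = 100.0,
):
    """Filter or re-rank a ranked mode list against a restraint set.

    ``violations_of(mode)`` must return the mode's violation count.  In
    ``filter`` mode violating modes are dropped; if every mode violates, the
    full list is kept but re-ordered by (violations, energy) with a warning.
    In ``penalty`` mode the list is re-ranked by
    ``energy + penalty_weight * violations``.
    """
    modes = list(modes)
    if len(r) == 0 or not modes:
        return modes
    counts = [violations_of(m) for m in modes]
    if r.mode == "penalty":
        order = sorted(
            range(len(modes)),
            key=lambda i: (modes[i].energy + penalty_weight * counts[i], i),
        )
        return [modes[i] for i in order]
    surviving = [m for m, c in zip(modes, counts) if c == 0]
    if surviving:
        return surviving
    logger.warning(
        "all %d modes violate the restraints; falling back to "
        "(violations, energy) ordering", len(modes)
    )
    order = sorted(range(len(modes)), key=lambda i: (counts[i], modes[i].energy, i))
    return [modes[i] for i in order]
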