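"""Mode ranking, greedy ligand-RMSD clustering, model emission.

Clustering metric: RMSD over the ligand's cached C4' coordinates in the
common receptor frame, with no superposition.  Greedy procedure: the best
remaining mode seeds a cluster that absorbs every remaining mode within the
cutoff; repeat until exhaustion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nucdock.errors import ContractViolation
from nucdock.structures import (
    RigidTransform,
    Structure,
    apply_transform,
    write_model,
)


@dataclass
class BindingMode:
    """One candidate pose: rotation index + grid offset + scores."""

    rotation_index: int
    offset: tuple[int, int, int]
    shape_score: float
    energy: float
    transform: RigidTransform | None = None
    center: np.ndarray | None = None
    ligand_c4_coords: np.ndarray | None = None
    violations: int = 0

    def pose(self, ligand: Structure) -> Structure:
        if self.transform is None:
            raise ContractViolation("mode has no transform attached")
        return apply_transform(ligand, self.transform, self.center)


@dataclass
class Cluster:
    representative: BindingMode
    members: list[BindingMode]
    rank: int  # 1-based creation order


def rank_modes(modes: list[BindingMode]) -> list[BindingMode]:
    """Ascending energy; ties by rotation index, then lexicographic offset."""
    return sorted(modes, key=lambda m: (m.energy, m.rotation_index, m.offset))


def ligand_rmsd_between(a: BindingMode, b: BindingMode) -> float:
    """C4' RMSD between two poses of the same ligand, no superposition."""
    ca, cb = a.ligand_c4_coords, b.ligand_c4_coords
    if ca is None or cb is None:
        raise ContractViolation("modes lack cached C4' coordinates")
    if ca.shape != cb.shape:
        raise ContractViolation(
            f"C4' count mismatch: {ca.shape[0]} vs {cb.shape[0]}"
        )
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def cluster_modes(
    ranked: list[BindingMode],
    cutoff: float = 5.0,
    max_clusters: int | None = None,
) -> list[Cluster]:
    """Greedy clustering of an energy-sorted mode list."""
    energies = [m.energy for m in ranked]
    if energies != sorted(energies):
        raise ContractViolation("cluster_modes requires energy-sorted input")
    if not ranked:
        return []
    coords = np.array([m.ligand_c4_coords for m in ranked])  # (n, m, 3)
    remaining = np.ones(len(ranked), dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        if max_clusters is not None and len(clusters) >= max_clusters:
            break
        seed = int(np.argmax(remaining))  # best remaining (list is sorted)
        diffs = coords[remaining] - coords[seed]
        rmsds = np.sqrt(np.mean(np.sum(diffs**2, axis=2), axis=1))
        idx_remaining = np.nonzero(remaining)[0]
        member_idx = idx_remaining[rmsds <= cutoff]
        members = [ranked[i] for i in member_idx]
        clusters.append(
            Cluster(representative=ranked[seed], members=members,
                    rank=len(clusters) + 1)
        )
        remaining[member_idx] = False
    return clusters


def score_table(clusters: list[Cluster], n: int = 100) -> str:
    """TSV summary of cluster representatives: rank, scores, pose indices."""
    lines = ["rank\tenergy\tshape_score\trotation_index\toffset"]
    for cluster in clusters[:n]:
        m = cluster.representative
        lines.append(
            f"{cluster.rank}\t{m.energy:.6f}\t{m.shape_score:.6f}\t"
            f"{m.rotation_index}\t{m.offset[0]},{m.offset[1]},{m.offset[2]}"
        )
    return "\n".join(lines) + "\n"


def emit_top_models(
    clusters: list[Cluster],
    receptor: Structure,
    ligand: Structure,
    n: int = 100,
) -> tuple[list[tuple[str, str]], str]:
    """PDB text for up to n cluster representatives, plus the score table.

    Returns ``([(filename, pdb_text), ...], score_table_text)``.
    """
    if not clusters:
        raise ContractViolation("no clusters to emit")
    models: list[tuple[str, str]] = []
    for cluster in clusters[:n]:
        m = cluster.representative
        pose = m.pose(ligand)
        text = write_model(receptor, pose, cluster.rank,
                           (m.shape_score, m.energy))
        models.append((f"model_{cluster.rank}.pdb", text))
    return models, score_table(clusters, n)
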