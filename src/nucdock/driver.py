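"""Full docking pipeline: digitize -> rotate -> FFT scan -> rescore ->
retain one mode per rotation -> restraint filter -> rank -> cluster -> emit.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from nucdock.config import DockConfig
from nucdock.errors import ContractViolation
from nucdock.evaluation import evaluate_models, success_rate
from nucdock.grids import (
    TranslationScanner,
    digitize_coords,
    top_translations,
)
from nucdock.postprocess import (
    BindingMode,
    Cluster,
    cluster_modes,
    emit_top_models,
    rank_modes,
)
from nucdock.potential import (
    AtomTypeScheme,
    PotentialTable,
    assign_atom_types,
    default_potential,
    score_pair_arrays,
)
from nucdock.restraints import (
    RestraintSet,
    apply_restraint_filter,
    evaluate_restraints,
)
from nucdock.rotations import generate_rotations
from nucdock.structures import RigidTransform, Structure, apply_transform

logger = logging.getLogger(__name__)


@dataclass
class DockResult:
    receptor: Structure
    ligand: Structure
    config: DockConfig
    modes: list[BindingMode]  # one per rotation, pre-filter order
    filtered: list[BindingMode]
    ranked: list[BindingMode]
    clusters: list[Cluster]
    swapped: bool = False
    timings: dict = field(default_factory=dict)

    def emit(self, n: int | None = None):
        n = n if n is not None else self.config.n_models
        return emit_top_models(self.clusters, self.receptor, self.ligand, n)

    def top_model_pairs(self, n: int = 10) -> list[tuple[Structure, Structure]]:
        """(receptor, posed ligand) pairs for the top n cluster representatives."""
        return [
            (self.receptor, c.representative.pose(self.ligand))
            for c in self.clusters[:n]
        ]


def _swap_restraints(restraints: RestraintSet) -> RestraintSet:
    flipped = RestraintSet(mode=restraints.mode)
    swap = {"receptor": "ligand", "ligand": "receptor"}
    flipped.site_residues = [
        (swap[p], c, s) for p, c, s in restraints.site_residues
    ]
    flipped.distance_pairs = [
        (lig_ref, rec_ref, d) for rec_ref, lig_ref, d in restraints.distance_pairs
    ]
    return flipped


def dock(
    receptor: Structure,
    ligand: Structure,
    config: DockConfig | None = None,
    restraints: RestraintSet | None = None,
    table: PotentialTable | None = None,
    scheme: AtomTypeScheme | None = None,
) -> DockResult:
    """Global rigid-body docking of ligand onto receptor.

    For each rotation of the deterministic rotation set the ligand is rotated
    about its centroid and FFT-scanned over all in-box translations; the top
    shape-complementarity translations are rescored with the pair potential
    and the best one is retained, giving exactly one binding mode per
    rotation.  Modes are then restraint-filtered, ranked by energy, clustered
    by ligand C4' RMSD, and the cluster representatives become the models.
    """
    config = config or DockConfig()
    scheme = scheme or AtomTypeScheme.default()
    table = table or default_potential()

    swapped = False
    if ligand.n_atoms > receptor.n_atoms:
        logger.info(
            "ligand (%d atoms) larger than receptor (%d): swapping roles",
            ligand.n_atoms, receptor.n_atoms,
        )
        receptor, ligand = ligand, receptor
        swapped = True
        if restraints is not None:
            restraints = _swap_restraints(restraints)
    if restraints is not None:
        restraints.resolve(receptor, ligand)

    t0 = time.perf_counter()
    lig_coords = ligand.coords()
    center = lig_coords.mean(axis=0)
    lig_radius = float(np.linalg.norm(lig_coords - center, axis=1).max())
    padding = lig_radius + 2.0

    grid_kwargs = dict(
        spacing=config.spacing,
        r_occ=config.occupancy_radius,
        core_penalty=config.core_penalty,
        kernel=config.kernel,
        kernel_cutoff=config.kernel_cutoff,
        max_cells=config.max_grid_cells,
    )
    receptor_grid = digitize_coords(
        receptor.coords(), padding=padding, role="receptor", **grid_kwargs
    )
    max_lig_dim = (
        int(np.ceil(2.0 * (lig_radius + config.occupancy_radius)
                    / config.spacing)) + 3
    )
    scanner = TranslationScanner(receptor_grid, max_lig_dim)
    t_grid = time.perf_counter()

    typed_r = assign_atom_types(receptor, scheme)
    typed_l = assign_atom_types(ligand, scheme)
    c4_idx = np.array(
        [i for i, a in enumerate(ligand.atoms()) if a.name == "C4'"], dtype=int
    )
    if len(c4_idx) == 0:
        raise ContractViolation("ligand has no C4' atoms for clustering")

    rotation_set = generate_rotations(config.angle_interval)
    modes: list[BindingMode] = []
    for rot_index in range(len(rotation_set)):
        R = rotation_set[rot_index]
        rotated = (lig_coords - center) @ R.T + center
        lig_grid = digitize_coords(rotated, role="ligand", **grid_kwargs)
        field_ = scanner.scan(lig_grid)
        hits = top_translations(field_, config.top_translations)
        best = None
        for hit in hits:
            delta = (
                receptor_grid.origin
                + np.array(hit.offset, dtype=float) * config.spacing
                - lig_grid.origin
            )
            posed = rotated + delta
            energy = score_pair_arrays(typed_r, posed, typed_l.types, table)
            if best is None or energy < best[0]:
                best = (energy, hit, delta, posed)
        energy, hit, delta, posed = best  # type: ignore[misc]
        modes.append(
            BindingMode(
                rotation_index=rot_index,
                offset=hit.offset,
                shape_score=hit.shape_score,
                energy=energy,
                transform=RigidTransform(R, delta),
                center=center,
                ligand_c4_coords=posed[c4_idx],
            )
        )
    t_sample = time.perf_counter()
    logger.info("retained %d modes (one per rotation)", len(modes))

    if restraints is not None and len(restraints) > 0:

        def violations_of(mode: BindingMode) -> int:
            pose = apply_transform(ligand, mode.transform, mode.center)
            _, count = evaluate_restraints(
                receptor, pose, restraints, config.interface_cutoff
            )
            mode.violations = count
            return count

        filtered = apply_restraint_filter(
            modes, restraints, violations_of, config.restraint_penalty
        )
    else:
        filtered = list(modes)

    ranked = rank_modes(filtered)
    clusters = cluster_modes(
        ranked, config.cluster_cutoff,
        max_clusters=max(config.n_models, 100),
    )
    t_end = time.perf_counter()
    timings = {
        "grids_s": t_grid - t0,
        "sampling_s": t_sample - t_grid,
        "postprocess_s": t_end - t_sample,
        "total_s": t_end - t0,
    }
    logger.info(
        "docking finished: %d clusters in %.1f s", len(clusters),
        timings["total_s"],
    )
    return DockResult(
        receptor=receptor,
        ligand=ligand,
        config=config,
        modes=modes,
        filtered=filtered,
        ranked=ranked,
        clusters=clusters,
        swapped=swapped,
        timings=timings,
    )


def run_benchmark(
    cases: list[tuple[Structure, Structure, tuple[Structure, Structure]]],
    config: DockConfig | None = None,
    top_n_values: list[int] | None = None,
) -> dict:
    """Redock a list of (receptor, ligand, native pair) cases.

    Returns per-case first-hit ranks and the success-rate curve over top-N.
    """
    if not cases:
        raise ContractViolation("benchmark needs at least one case")
    config = config or DockConfig()
    top_n_values = top_n_values or list(range(1, 101))
    ranks: list[int | None] = []
    for receptor, ligand, native in cases:
        result = dock(receptor, ligand, config)
        models = result.top_model_pairs(n=config.n_models)
        evaluation = evaluate_models(
            models, native,
            interface_cutoff=config.interface_cutoff,
            hit_threshold=config.hit_threshold,
        )
        ranks.append(evaluation.first_hit_rank)
    curve = {n: success_rate(ranks, n) for n in top_n_values}
    return {"first_hit_ranks": ranks, "success_rate": curve}
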