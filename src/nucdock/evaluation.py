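"""Prediction quality against a native complex: interfaces, IRMSD, hits.

IRMSD convention: interface residues are taken from the native complex (any
heavy atom within the cutoff of the partner); the predicted complex is
superposed onto the native over the C4' atoms of those interface residues of
both partners jointly, and the IRMSD is the residual RMSD over the same
atoms.  A model is a hit when IRMSD < the threshold (default 5.0 A).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from nucdock.errors import ContractViolation
from nucdock.structures import RigidTransform, Structure

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]


@dataclass
class EvaluationResult:
    per_model_irmsd: list[float]
    first_hit_rank: int | None
    hit_threshold: float = 5.0
    interface_cutoff: float = 10.0

    @property
    def hits(self) -> list[bool]:
        return [x < self.hit_threshold for x in self.per_model_irmsd]


def interface_residues(
    native_receptor: Structure,
    native_ligand: Structure,
    cutoff: float = 10.0,
) -> tuple[set[ResidueKey], set[ResidueKey]]:
    """Residues of each partner with any heavy atom within cutoff of the other."""
    if native_receptor.n_atoms == 0 or native_ligand.n_atoms == 0:
        raise ContractViolation("both partners must be non-empty")
    out: list[set[ResidueKey]] = []
    for s, other in (
        (native_receptor, native_ligand),
        (native_ligand, native_receptor),
    ):
        if cutoff <= 0:
            out.append(set())
            continue
        tree = cKDTree(other.coords())
        keys: set[ResidueKey] = set()
        for res in s.residues():
            d, _ = tree.query(res.coords(), k=1)
            if np.min(d) <= cutoff:
                keys.add(res.key)
        out.append(keys)
    if not out[0]:
        logger.warning("empty interface at cutoff %.1f A", cutoff)
    return out[0], out[1]


def superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of mobile onto target (Kabsch).

    Proper rotations only (reflections rejected).  Returns the transform
    ``x -> R x + t`` and the residual RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ContractViolation("point sets must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ContractViolation("superposition needs at least 3 points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    X = mobile - mc
    Y = target - tc
    if np.linalg.matrix_rank(X, tol=1e-9) < 2:
        raise ContractViolation("degenerate (collinear) point set")
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def _c4_map(s: Structure) -> dict[ResidueKey, np.ndarray]:
    out = {}
    for res in s.residues():
        atom = res.atom("C4'")
        if atom is not None:
            out[res.key] = atom.coord
    return out


def irmsd(
    predicted: tuple[Structure, Structure],
    native: tuple[Structure, Structure],
    interface_cutoff: float = 10.0,
    superpose_on: str = "interface",
    chain_map: dict[str, str] | None = None,
) -> float:
    """Interface RMSD of a predicted complex against the native one.

    ``superpose_on``: "interface" (default) superposes on interface C4'
    atoms; "all" superposes on every matched C4' atom, the residual is still
    measured over the interface atoms.  ``chain_map`` renames predicted
    chain ids onto native ones before matching by (chain, seq_id, icode).
    """
    if superpose_on not in ("interface", "all"):
        raise ContractViolation("superpose_on must be 'interface' or 'all'")
    pred_r, pred_l = predicted
    nat_r, nat_l = native
    iface_r, iface_l = interface_residues(nat_r, nat_l, interface_cutoff)

    def mapped_key(key: ResidueKey) -> ResidueKey:
        if chain_map and key[0] in chain_map:
            return (chain_map[key[0]], key[1], key[2])
        return key

    pairs_iface: list[tuple[np.ndarray, np.ndarray]] = []
    pairs_all: list[tuple[np.ndarray, np.ndarray]] = []
    for pred_s, nat_s, iface in (
        (pred_r, nat_r, iface_r),
        (pred_l, nat_l, iface_l),
    ):
        nat_c4 = _c4_map(nat_s)
        pred_c4 = {mapped_key(k): v for k, v in _c4_map(pred_s).items()}
        for key, nat_coord in nat_c4.items():
            if key not in pred_c4:
                continue
            pairs_all.append((pred_c4[key], nat_coord))
            if key in iface:
                pairs_iface.append((pred_c4[key], nat_coord))
    if len(pairs_iface) < 3:
        raise ContractViolation(
            f"only {len(pairs_iface)} interface C4' atoms matched (need >= 3)"
        )
    iface_mobile = np.array([p for p, _ in pairs_iface])
    iface_target = np.array([q for _, q in pairs_iface])
    if superpose_on == "interface":
        _, residual = superpose(iface_mobile, iface_target)
        return residual
    all_mobile = np.array([p for p, _ in pairs_all])
    all_target = np.array([q for _, q in pairs_all])
    transform, _ = superpose(all_mobile, all_target)
    moved = transform.apply(iface_mobile)
    return float(np.sqrt(np.mean(np.sum((moved - iface_target) ** 2, axis=1))))


def first_hit_rank(
    irmsds: list[float], threshold: float = 5.0
) -> int | None:
    for i, x in enumerate(irmsds, start=1):
        if x < threshold:
            return i
    return None


def success_rate(per_case_first_hit_ranks: list[int | None], top_n: int) -> float:
    """Fraction of cases whose first hit falls within the top_n predictions."""
    if not per_case_first_hit_ranks:
        raise ContractViolation("empty case list")
    n_hit = sum(
        1 for r in per_case_first_hit_ranks if r is not None and r <= top_n
    )
    return n_hit / len(per_case_first_hit_ranks)


def evaluate_models(
    models: list[tuple[Structure, Structure]],
    native: tuple[Structure, Structure],
    interface_cutoff: float = 10.0,
    hit_threshold: float = 5.0,
    chain_map: dict[str, str] | None = None,
) -> EvaluationResult:
    """IRMSD of every (receptor, ligand) model against the native complex."""
    values = [
        irmsd(model, native, interface_cutoff, chain_map=chain_map)
        for model in models
    ]
    return EvaluationResult(
        per_model_irmsd=values,
        first_hit_rank=first_hit_rank(values, hit_threshold),
        hit_threshold=hit_threshold,
        interface_cutoff=interface_cutoff,
    )
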