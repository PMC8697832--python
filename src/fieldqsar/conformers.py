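"""Conformer ensemble generation with energy-window and duplicate pruning.

Raw conformer pools come from distance-geometry embedding with torsion
sampling (ETKDG). Each raw conformer is MMFF94-minimized; the ensemble is
then pruned by (a) an energy window above the global minimum and (b) a
duplicate cutoff on best-fit heavy-atom RMSD, keeping at most
``max_conformers`` members sorted by energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem import rdMolAlign

from .chemio import Molecule3D, _mmff_minimize

__all__ = ["EnsembleConfig", "ConformerEnsemble", "enumerate_conformers",
           "best_fit_rmsd", "kabsch"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Limits for the conformational search.

    Defaults: at most 500 conformers, duplicates merged below 0.5 A
    heavy-atom RMSD, members within 2.5 kcal/mol of the minimized global
    minimum, minimizer gradient cutoff 0.1 kcal/(mol*A).
    """

    max_conformers: int = 500
    duplicate_rmsd: float = 0.5
    energy_window: float = 2.5
    gradient_tol: float = 0.1
    seed: int = 2021
    pool_factor: int = 4
    pool_cap: int = 2000

    def __post_init__(self):
        for name in ("max_conformers", "duplicate_rmsd", "energy_window",
                     "gradient_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ConformerEnsemble:
    """Pruned conformer set for one molecule, sorted by energy ascending."""

    mol_id: str
    mol: Chem.Mol            # template topology (with Hs); conformers stored here
    energies: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return self.mol.GetNumConformers()

    @property
    def reference_energy(self) -> float:
        return min(self.energies)

    def conformer_coords(self, i: int) -> np.ndarray:
        return np.asarray(self.mol.GetConformer(i).GetPositions(), dtype=float)

    def as_molecule3d(self, i: int = 0) -> Molecule3D:
        """Extract conformer ``i`` as a standalone single-conformer molecule."""
        single = Chem.Mol(self.mol)
        single.RemoveAllConformers()
        conf = Chem.Conformer(self.mol.GetConformer(i))
        conf.SetId(0)
        single.AddConformer(conf, assignId=False)
        return Molecule3D(self.mol_id, single, energy=self.energies[i])


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t superposing P onto Q.

    Returns (R, t) with det(R) = +1 minimizing ||(P @ R.T + t) - Q||.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def best_fit_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    mapping: list[tuple[int, int]] | None = None,
) -> float:
    """Minimal RMSD (A) between two coordinate sets over rigid superposition.

    ``mapping`` pairs indices (i in a, j in b); identity if omitted.
    Symmetric in its arguments. Requires >= 2 mapped atoms (with exactly 2
    the superposition is the degenerate 1-D case and still well defined).
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if mapping is not None:
        ia = [i for i, _ in mapping]
        ib = [j for _, j in mapping]
        A, B = A[ia], B[ib]
    if A.shape != B.shape:
        raise ValueError("mapped coordinate sets differ in size")
    if len(A) < 2:
        raise ValueError(f"need >= 2 mapped atoms, got {len(A)}")
    R, t = kabsch(A, B)
    diff = (A @ R.T + t) - B
    return float(np.sqrt((diff * diff).sum() / len(A)))


def _symmetry_aware_rmsd(mol: Chem.Mol, ci: int, cj: int) -> float:
    """Best-fit heavy-atom RMSD between two conformers of the same molecule,
    minimized over graph automorphisms (so e.g. phenyl flips count as copies).
    """
    probe = Chem.Mol(mol)
    ref = Chem.Mol(mol)
    return float(rdMolAlign.GetBestRMS(
        Chem.RemoveHs(probe), Chem.RemoveHs(ref), prbId=ci, refId=cj))


def enumerate_conformers(mol3d: Molecule3D, cfg: EnsembleConfig | None = None,
                         ) -> ConformerEnsemble:
    """Enumerate, minimize and prune a conformer ensemble.

    The minimized input conformer is always part of the raw pool, so the
    result is never empty. Pruning keeps, in energy order, conformers that
    are inside ``cfg.energy_window`` of the pool minimum and at least
    ``cfg.duplicate_rmsd`` (heavy-atom best-fit RMSD) away from every
    already-kept conformer; for an equal-energy duplicate pair the
    earlier-generated conformer wins. Deterministic given ``cfg.seed``.
    """
    cfg = cfg or EnsembleConfig()
    work = Chem.Mol(mol3d.mol)  # keeps the input conformer at id 0
    n_rot = AllChem.CalcNumRotatableBonds(work) if hasattr(AllChem, "CalcNumRotatableBonds") else 0
    pool_target = min(cfg.pool_factor * cfg.max_conformers, cfg.pool_cap)
    # rigid molecules need no large pool
    pool_target = min(pool_target, max(1, 3 ** max(n_rot, 0)))

    params = AllChem.ETKDGv3()
    params.randomSeed = cfg.seed
    params.clearConfs = False
    params.pruneRmsThresh = -1.0
    if pool_target > 1:
        AllChem.EmbedMultipleConfs(work, numConfs=pool_target - 1, params=params)

    conf_ids = [c.GetId() for c in work.GetConformers()]
    energies = []
    for cid in conf_ids:
        energies.append(_mmff_minimize(work, cid, cfg.gradient_tol))
    energies = np.asarray(energies)
    e_min = energies.min()

    # energy window on minimized energies, then dedup in energy order
    order = np.lexsort((np.arange(len(conf_ids)), energies))
    kept: list[int] = []
    kept_energies: list[float] = []
    for pos in order:
        if energies[pos] - e_min > cfg.energy_window:
            continue
        cid = conf_ids[pos]
        dup = False
        for kcid in kept:
            if _symmetry_aware_rmsd(work, cid, kcid) < cfg.duplicate_rmsd:
                dup = True
                break
        if not dup:
            kept.append(cid)
            kept_energies.append(float(energies[pos]))
        if len(kept) >= cfg.max_conformers:
            break

    out = Chem.Mol(work)
    out.RemoveAllConformers()
    for i, cid in enumerate(kept):
        conf = Chem.Conformer(work.GetConformer(cid))
        conf.SetId(i)
        out.AddConformer(conf, assignId=False)
    ens = ConformerEnsemble(mol3d.id, out, kept_energies)
    # carry partial charges over (topology unchanged)
    try:
        q = mol3d.partial_charges
        for atom, qi in zip(out.GetAtoms(), q):
            atom.SetDoubleProp("_partial_charge", float(qi))
    except KeyError:
        pass
    return ens


def write_ensemble_sdf(ens: ConformerEnsemble, path) -> None:
    """Serialize an ensemble as multi-record SDF with energy SD tags."""
    writer = Chem.SDWriter(str(path))
    try:
        for i in range(len(ens)):
            m = ens.as_molecule3d(i)
            out = Chem.Mol(m.mol)
            out.SetProp("_Name", f"{ens.mol_id}_conf{i}")
            out.SetProp("FQ_ENERGY_KCAL_MOL", repr(float(ens.energies[i])))
            writer.write(out)
    finally:
        writer.close()
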