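"""Structure and activity I/O, protonation, 3D embedding and minimization.

This module owns the boundary between file formats (CSV activity tables,
SMILES lists, SDF structure files) and the in-memory objects the rest of
the pipeline consumes.  Affinities are handled as pKi = -log10(Ki in M);
3D geometry is produced by distance-geometry embedding followed by MMFF94
minimization to a configurable gradient cutoff, with Gasteiger (PEOE,
iterative partial equalization of orbital electronegativity) partial
charges as the default empirical charge scheme.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "ActivityRecord",
    "Molecule3D",
    "ActivityTableError",
    "EmbeddingError",
    "ki_to_pki",
    "pki_to_ki",
    "load_activity_table",
    "protonate_ph7",
    "embed_minimize",
    "assign_gasteiger_charges",
    "write_sdf",
    "read_sdf",
    "read_smiles_file",
]

PKI_CONSISTENCY_TOL = 1e-6


class ActivityTableError(ValueError):
    """Raised for malformed activity tables (missing columns, bad rows)."""

    def __init__(self, message: str, row_errors: list[str] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


class EmbeddingError(RuntimeError):
    """Raised when 3D embedding fails for a molecule; carries its id."""

    def __init__(self, mol_id: str, message: str):
        super().__init__(f"{mol_id}: {message}")
        self.mol_id = mol_id


def ki_to_pki(ki: float) -> float:
    """Convert an inhibition constant Ki (molar) to pKi = -log10(Ki).

    Parameters
    ----------
    ki : float
        Equilibrium inhibition constant in molar units. Must be > 0.
    """
    if not ki > 0:
        raise ValueError(f"Ki must be positive (molar), got {ki!r}")
    return -math.log10(ki)


def pki_to_ki(pki: float) -> float:
    """Inverse of :func:`ki_to_pki`: Ki in molar from pKi."""
    return 10.0 ** (-pki)


@dataclass(frozen=True)
class ActivityRecord:
    """One ligand with its binding affinity.

    At least one of ``ki`` (molar) or ``pki`` must be given; when both are
    present they must agree (pki == -log10 ki) to within 1e-6.
    """

    id: str
    smiles: str
    ki: float | None = None
    pki: float | None = None

    def __post_init__(self):
        if self.ki is None and self.pki is None:
            raise ValueError(f"record {self.id}: need ki or pki")
        if self.ki is not None:
            if not self.ki > 0:
                raise ValueError(f"record {self.id}: Ki must be > 0")
            derived = ki_to_pki(self.ki)
            if self.pki is not None:
                if abs(self.pki - derived) > PKI_CONSISTENCY_TOL:
                    raise ValueError(
                        f"record {self.id}: inconsistent ki/pki pair "
                        f"(-log10(ki)={derived:.6f} != pki={self.pki:.6f})"
                    )
            else:
                object.__setattr__(self, "pki", derived)


@dataclass
class Molecule3D:
    """An embedded, protonated, minimized small molecule.

    Wraps an RDKit molecule holding exactly one conformer, plus the
    molecular-mechanics energy (kcal/mol) of that conformer and per-atom
    partial charges (e). Coordinates are in Angstrom.
    """

    id: str
    mol: Chem.Mol
    energy: float | None = None

    def __post_init__(self):
        if self.mol.GetNumConformers() < 1:
            raise ValueError(f"{self.id}: Molecule3D requires a conformer")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) positions in Angstrom."""
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    @coords.setter
    def coords(self, xyz: np.ndarray) -> None:
        conf = self.mol.GetConformer()
        for i, p in enumerate(np.asarray(xyz, dtype=float)):
            conf.SetAtomPosition(i, p.tolist())

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @property
    def formal_charges(self) -> np.ndarray:
        return np.array([a.GetFormalCharge() for a in self.mol.GetAtoms()], dtype=int)

    @property
    def partial_charges(self) -> np.ndarray:
        return np.array(
            [a.GetDoubleProp("_partial_charge") for a in self.mol.GetAtoms()],
            dtype=float,
        )

    @partial_charges.setter
    def partial_charges(self, q: Sequence[float]) -> None:
        for atom, qi in zip(self.mol.GetAtoms(), q):
            atom.SetDoubleProp("_partial_charge", float(qi))

    @property
    def total_formal_charge(self) -> int:
        return int(self.formal_charges.sum())

    def heavy_atom_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    def copy(self) -> "Molecule3D":
        return Molecule3D(self.id, Chem.Mol(self.mol), self.energy)


# --------------------------------------------------------------------------
# Activity tables
# --------------------------------------------------------------------------

def load_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Read a CSV activity table into validated records.

    The header must declare ``id``, ``smiles`` and at least one of ``ki``
    (molar) / ``pki``. Rows that fail to parse (bad SMILES, inconsistent
    ki/pki pair, missing affinity) are collected and reported together in
    an :class:`ActivityTableError` rather than silently dropped.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ActivityTableError(f"{path}: empty file")
        cols = {c.strip().lower() for c in reader.fieldnames}
        if "id" not in cols or "smiles" not in cols:
            raise ActivityTableError(f"{path}: header must declare id and smiles")
        if not ({"ki", "pki"} & cols):
            raise ActivityTableError(f"{path}: header must declare ki and/or pki")
        records: list[ActivityRecord] = []
        errors: list[str] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            row = {k.strip().lower(): (v or "").strip() for k, v in row.items() if k}
            rid = row.get("id", "")
            try:
                if not rid:
                    raise ValueError("missing id")
                if rid in seen:
                    raise ValueError(f"duplicate id {rid!r}")
                smiles = row.get("smiles", "")
                if Chem.MolFromSmiles(smiles) is None:
                    raise ValueError(f"unparsable SMILES {smiles!r}")
                ki = float(row["ki"]) if row.get("ki") else None
                pki = float(row["pki"]) if row.get("pki") else None
                records.append(ActivityRecord(id=rid, smiles=smiles, ki=ki, pki=pki))
                seen.add(rid)
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
        if errors:
            raise ActivityTableError(
                f"{path}: {len(errors)} bad row(s):\n" + "\n".join(errors),
                row_errors=errors,
            )
    return records


def write_activity_table(records: Iterable[ActivityRecord], path: str | Path) -> None:
    """Write standardized records (id, smiles, ki, pki) as CSV."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "ki", "pki"])
        for r in records:
            ki = r.ki if r.ki is not None else pki_to_ki(r.pki)
            writer.writerow([r.id, r.smiles, repr(float(ki)), repr(float(r.pki))])


# --------------------------------------------------------------------------
# Protonation at pH 7
# --------------------------------------------------------------------------

# Fixed rule table for the dominant microspecies at pH 7.0.  Each rule is a
# SMARTS for the *neutral* form of the group, the index (within the match) of
# the atom whose charge changes, the charge delta, and the pKa rationale.
# Groups whose pKa sits close to 7 (anilines, amides, pyridines, imidazoles)
# are deliberately left untouched; borderline groups are reported by
# `flag_borderline_groups` instead of guessed at.
PH7_RULES: list[tuple[str, str, int, int, str]] = [
    # (name, SMARTS for the neutral group, charged-atom index in match, dq, rationale)
    (
        "aliphatic_amine",
        "[NX3;H2,H1,H0;+0;!$(N-[a]);!$(N-C=[O,N,S]);!$(N-[S,P]=O);!$(N=*);!$(N#*);!$(N-O)]",
        0,
        +1,
        "aliphatic/alicyclic amines, pKa ~ 9-11 > 7 -> protonated",
    ),
    (
        "amidine",
        "[NX2;+0]=[CX3]([NX3;+0])",
        0,
        +1,
        "amidines/guanidines, pKa ~ 11-13 > 7 -> protonated on the imine N",
    ),
    (
        "carboxylic_acid",
        "[CX3](=O)[OX2H1]",
        2,
        -1,
        "carboxylic acids, pKa ~ 4-5 < 7 -> deprotonated",
    ),
    (
        "sulfonic_acid",
        "[SX4](=O)(=O)[OX2H1]",
        3,
        -1,
        "sulfonic acids, pKa ~ -1 < 7 -> deprotonated",
    ),
    (
        "phosphonic_acid",
        "[PX4;!$(P~[O-])](=O)[OX2H1]",
        2,
        -1,
        "phosphonic acids, first pKa ~ 2 < 7 -> deprotonated once",
    ),
]

# Groups with pKa near 7 where the dominant species is genuinely ambiguous.
BORDERLINE_SMARTS: list[tuple[str, str]] = [
    ("imidazole", "c1cnc[nH]1"),
    ("morpholine_n_aryl", "[NX3;+0]([a])([CX4])[CX4]"),
]

_PH7_PATTERNS = [
    (name, Chem.MolFromSmarts(smarts), idx, dq, why)
    for name, smarts, idx, dq, why in PH7_RULES
]
_BORDERLINE_PATTERNS = [
    (name, Chem.MolFromSmarts(s)) for name, s in BORDERLINE_SMARTS
]


def protonate_ph7(mol: Chem.Mol) -> Chem.Mol:
    """Apply the fixed pH-7 protonation rule table to a molecular graph.

    Returns a new molecule with formal charges and hydrogen counts adjusted
    so that basic amines/amidines carry +1 and strong oxyacids carry -1.
    The rules match only neutral groups, so the operation is idempotent.
    Molecules with no ionizable group pass through unchanged.
    """
    out = Chem.RWMol(Chem.Mol(mol))
    touched: set[int] = set()
    for _name, patt, idx, dq, _why in _PH7_PATTERNS:
        for match in out.GetSubstructMatches(patt):
            ai = match[idx]
            # one charge change per matched group: the anchor atom (first in
            # the SMARTS, e.g. the P of a phosphonic acid) blocks re-matching
            if ai in touched or match[0] in touched:
                continue
            atom = out.GetAtomWithIdx(ai)
            if atom.GetFormalCharge() != 0:
                continue
            atom.SetFormalCharge(dq)
            h = atom.GetTotalNumHs()
            atom.SetNoImplicit(True)
            atom.SetNumExplicitHs(max(0, h + dq))
            touched.add(ai)
            touched.add(match[0])
    result = out.GetMol()
    Chem.SanitizeMol(result)
    return result


def flag_borderline_groups(mol: Chem.Mol) -> list[str]:
    """Names of near-pKa-7 groups present, for the protonation log."""
    return [name for name, patt in _BORDERLINE_PATTERNS if mol.HasSubstructMatch(patt)]


# --------------------------------------------------------------------------
# Charges and 3D geometry
# --------------------------------------------------------------------------

def assign_gasteiger_charges(mol3d: Molecule3D) -> Molecule3D:
    """Attach Gasteiger (PEOE) partial charges to a molecule, in place."""
    AllChem.ComputeGasteigerCharges(mol3d.mol)
    q = [
        float(a.GetDoubleProp("_GasteigerCharge")) for a in mol3d.mol.GetAtoms()
    ]
    q = [0.0 if not math.isfinite(v) else v for v in q]
    mol3d.partial_charges = q
    return mol3d


ChargeScheme = Callable[[Molecule3D], Molecule3D]


def molecule_seed(mol_or_smiles) -> int:
    """Deterministic embedding seed derived from the canonical SMILES.

    Using a molecule-identity seed makes 3D geometry a pure function of the
    molecule, so the same compound gets the same conformer whether it is
    met during training, screening or scaffold hopping.
    """
    import zlib
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        smiles = Chem.MolToSmiles(mol) if mol is not None else mol_or_smiles
    else:
        smiles = Chem.MolToSmiles(mol_or_smiles)
    return zlib.crc32(smiles.encode()) % (2 ** 31 - 1)


def _mmff_minimize(mol: Chem.Mol, conf_id: int, gradient_tol: float,
                   max_iters: int = 2000) -> float:
    """Minimize one conformer with MMFF94 to the given gradient cutoff.

    Returns the final energy in kcal/mol. Falls back to UFF when MMFF has
    no parameters for the molecule.
    """
    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is not None:
        ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=conf_id)
    else:
        ff = AllChem.UFFGetMoleculeForceField(mol, confId=conf_id)
    ff.Initialize()
    ff.Minimize(maxIts=max_iters, forceTol=gradient_tol)
    return float(ff.CalcEnergy())


def embed_minimize(
    mol: Chem.Mol,
    mol_id: str = "mol",
    gradient_tol: float = 0.1,
    seed: int = 2021,
    charge_scheme: ChargeScheme = assign_gasteiger_charges,
    n_attempts: int = 3,
) -> Molecule3D:
    """Embed one 3D conformer and minimize it with MMFF94.

    Parameters
    ----------
    gradient_tol : float
        Force-norm convergence cutoff for the minimizer, kcal/(mol*A).
        Default 0.1.
    seed : int
        Distance-geometry random seed, making geometry reproducible.
    charge_scheme : callable
        Assigns partial charges to the minimized molecule; Gasteiger by
        default, pluggable so alternative schemes can be swapped in.
    """
    work = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    conf_id = -1
    for attempt in range(n_attempts):
        params.randomSeed = seed + 7919 * attempt
        conf_id = AllChem.EmbedMolecule(work, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        params.useRandomCoords = True
        params.randomSeed = seed
        conf_id = AllChem.EmbedMolecule(work, params)
    if conf_id < 0:
        raise EmbeddingError(mol_id, "3D embedding failed")
    energy = _mmff_minimize(work, conf_id, gradient_tol)
    result = Molecule3D(mol_id, work, energy=energy)
    charge_scheme(result)
    return result


# --------------------------------------------------------------------------
# SDF serialization
# --------------------------------------------------------------------------

_ENERGY_TAG = "FQ_ENERGY_KCAL_MOL"
_CHARGES_TAG = "FQ_PARTIAL_CHARGES"


def write_sdf(molecules: Iterable[Molecule3D], path: str | Path) -> None:
    """Write molecules to SDF with energy and partial charges as SD tags."""
    writer = Chem.SDWriter(str(path))
    try:
        for m in molecules:
            out = Chem.Mol(m.mol)
            out.SetProp("_Name", m.id)
            if m.energy is not None:
                out.SetProp(_ENERGY_TAG, repr(float(m.energy)))
            try:
                q = m.partial_charges
                out.SetProp(_CHARGES_TAG, " ".join(repr(float(v)) for v in q))
            except KeyError:
                pass
            writer.write(out)
    finally:
        writer.close()


def read_sdf(path: str | Path) -> list[Molecule3D]:
    """Read an SDF written by :func:`write_sdf` (or any V2000 SDF)."""
    out: list[Molecule3D] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: unparsable record #{i}")
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        energy = float(mol.GetProp(_ENERGY_TAG)) if mol.HasProp(_ENERGY_TAG) else None
        m3d = Molecule3D(mol_id or f"mol{i}", mol, energy=energy)
        if mol.HasProp(_CHARGES_TAG):
            m3d.partial_charges = [float(v) for v in mol.GetProp(_CHARGES_TAG).split()]
        out.append(m3d)
    return out


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated id.

    Returns (id, smiles) pairs; ids default to mol<line index>.
    """
    pairs: list[tuple[str, str]] = []
    with Path(path).open(encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            pairs.append((mol_id, smiles))
    return pairs
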