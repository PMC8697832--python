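"""Template alignment by maximum common substructure refined by field overlap.

Every ligand is placed into the fixed frame of one of a small set of
template ligands (bioactive-conformation references). Candidate poses are
(conformer x template x MCS atom mapping) triples; each is superposed by
the mapped heavy atoms (Kabsch) and scored as

    score = w_sub * (mapped heavy-atom fraction) + w_field * field_similarity

where the field similarity is a Gaussian-overlap (Carbo-type) similarity of
the two molecules' field-point values, normalized to [0, 1]. The maximizer
wins, with a deterministic tie-break (template order, then conformer index,
then mapping index). Molecules whose best score falls below a configurable
gate are flagged for review in the alignment report, mirroring a manual
alignment check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chemio import Molecule3D
from .conformers import ConformerEnsemble, kabsch
from .fieldspace import FieldConfig, FieldPoint, compute_field_points

__all__ = ["Template", "AlignmentResult", "AlignmentConfig", "mcs_map",
           "align_ensemble", "UnalignableError", "load_templates_sdf"]

_MAX_MATCHES_PER_SIDE = 8


class UnalignableError(RuntimeError):
    """No scoreable pose exists for a molecule against any template."""

    def __init__(self, mol_id: str, reason: str):
        super().__init__(f"{mol_id}: unalignable ({reason})")
        self.mol_id = mol_id
        self.reason = reason


@dataclass(frozen=True)
class AlignmentConfig:
    w_sub: float = 0.5
    w_field: float = 0.5
    min_score: float = 0.3     # poses below this are flagged, not dropped
    field_sigma: float = 1.0   # A, Gaussian overlap width
    mcs_timeout: int = 5       # seconds per MCS call


class Template:
    """A reference ligand in its fixed bioactive frame.

    Coordinates are immutable once loaded: every other molecule is aligned
    *into* this frame. Field points are computed once and cached.
    """

    def __init__(self, id: str, mol3d: Molecule3D,
                 field_cfg: FieldConfig | None = None):
        self.id = id
        self.mol3d = mol3d
        self._coords = mol3d.coords.copy()
        self._coords.setflags(write=False)
        self._field_cfg = field_cfg or FieldConfig()
        self._field_points: list[FieldPoint] | None = None

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    @property
    def field_points(self) -> list[FieldPoint]:
        if self._field_points is None:
            self._field_points = compute_field_points(self.mol3d, self._field_cfg)
        return self._field_points


@dataclass
class AlignmentResult:
    """Winning pose of one molecule in the template frame."""

    mol_id: str
    template_id: str
    conformer_index: int
    mapping: list[tuple[int, int]]          # molecule atom -> template atom
    rotation: np.ndarray                    # (3,3), proper orthogonal
    translation: np.ndarray                 # (3,)
    score: float                            # in [0, 1]
    substructure_rmsd: float                # A over mapped atoms
    flagged: bool = False                   # below the minimum-score gate

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper orthogonal (det=+1)")
        ja = [i for i, _ in self.mapping]
        jb = [j for _, j in self.mapping]
        if len(set(ja)) != len(ja) or len(set(jb)) != len(jb):
            raise ValueError("mapping must be injective")

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _heavy_frame(mol: Chem.Mol) -> tuple[Chem.Mol, list[int]]:
    """Hydrogen-free copy plus heavy-index -> original-index lookup."""
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    noh = Chem.RemoveHs(Chem.Mol(mol), sanitize=False)
    Chem.SanitizeMol(noh, catchErrors=True)
    return noh, heavy


def mcs_map(mol: Chem.Mol, template: Chem.Mol,
            timeout: int = 5) -> list[list[tuple[int, int]]]:
    """Candidate atom mappings of the maximum common substructure.

    Heavy atoms only, element and bond-order matched, connected subgraph.
    Returns mappings as lists of (mol atom index, template atom index); all
    automorphic placements (capped) are returned so the caller can score
    each. Empty when the MCS has fewer than 3 atoms.
    """
    mol_noh, mol_heavy = _heavy_frame(mol)
    tpl_noh, tpl_heavy = _heavy_frame(template)

    # fast path: one graph contained in the other (common for R-group series)
    query = None
    if tpl_noh.GetNumAtoms() <= mol_noh.GetNumAtoms() and \
            mol_noh.HasSubstructMatch(tpl_noh):
        query = tpl_noh
    elif mol_noh.GetNumAtoms() < tpl_noh.GetNumAtoms() and \
            tpl_noh.HasSubstructMatch(mol_noh):
        query = mol_noh
    if query is None:
        res = rdFMCS.FindMCS(
            [mol_noh, tpl_noh],
            atomCompare=rdFMCS.AtomCompare.CompareElements,
            bondCompare=rdFMCS.BondCompare.CompareOrder,
            timeout=timeout,
        )
        if res.canceled and res.numAtoms < 3:
            return []
        query = Chem.MolFromSmarts(res.smartsString) if res.numAtoms else None
    if query is None or query.GetNumAtoms() < 3:
        return []

    mol_matches = mol_noh.GetSubstructMatches(
        query, uniquify=False, maxMatches=_MAX_MATCHES_PER_SIDE)
    tpl_matches = tpl_noh.GetSubstructMatches(
        query, uniquify=False, maxMatches=_MAX_MATCHES_PER_SIDE)
    mappings: list[list[tuple[int, int]]] = []
    seen: set[tuple] = set()
    for mm in mol_matches:
        for tm in tpl_matches:
            pairs = tuple(sorted(
                (mol_heavy[mi], tpl_heavy[ti]) for mi, ti in zip(mm, tm)))
            if pairs in seen:
                continue
            seen.add(pairs)
            mappings.append(list(pairs))
    return mappings


def _gaussian_overlap(pts_a: np.ndarray, val_a: np.ndarray,
                      pts_b: np.ndarray, val_b: np.ndarray,
                      sigma: float) -> float:
    d2 = ((pts_a[:, None, :] - pts_b[None, :, :]) ** 2).sum(axis=2)
    return float((val_a[:, None] * val_b[None, :]
                  * np.exp(-d2 / (2.0 * sigma * sigma))).sum())


def field_similarity(fps_a: Sequence[FieldPoint], fps_b: Sequence[FieldPoint],
                     sigma: float = 1.0) -> float:
    """Carbo-type Gaussian-overlap similarity of two field-point sets in [0,1].

    Channels are compared like-with-like; identical sets score exactly 1.
    Empty sets score 0 against anything.
    """
    channels = {fp.channel for fp in fps_a} | {fp.channel for fp in fps_b}
    s_ab = s_aa = s_bb = 0.0
    for ch in channels:
        a = [fp for fp in fps_a if fp.channel == ch]
        b = [fp for fp in fps_b if fp.channel == ch]
        if a:
            pa = np.array([fp.position for fp in a])
            va = np.array([fp.magnitude for fp in a])
            s_aa += _gaussian_overlap(pa, va, pa, va, sigma)
        if b:
            pb = np.array([fp.position for fp in b])
            vb = np.array([fp.magnitude for fp in b])
            s_bb += _gaussian_overlap(pb, vb, pb, vb, sigma)
        if a and b:
            s_ab += _gaussian_overlap(pa, va, pb, vb, sigma)
    if s_aa <= 0 or s_bb <= 0:
        return 0.0
    return float(np.clip(s_ab / np.sqrt(s_aa * s_bb), 0.0, 1.0))


def _transform_field_points(fps: Sequence[FieldPoint], R: np.ndarray,
                            t: np.ndarray) -> list[FieldPoint]:
    out = []
    for fp in fps:
        p = R @ np.asarray(fp.position) + t
        out.append(FieldPoint(tuple(p.tolist()), fp.channel, fp.magnitude))
    return out


def align_ensemble(
    ensemble: ConformerEnsemble,
    templates: Sequence[Template],
    cfg: AlignmentConfig | None = None,
    field_cfg: FieldConfig | None = None,
) -> AlignmentResult:
    """Best pose of a conformer ensemble over all templates and MCS mappings.

    Raises :class:`UnalignableError` when no template shares a >=3-atom
    common substructure with the molecule.
    """
    cfg = cfg or AlignmentConfig()
    field_cfg = field_cfg or FieldConfig()
    if not templates:
        raise ValueError("need at least one template")
    if len(ensemble) == 0:
        raise ValueError(f"{ensemble.mol_id}: empty ensemble")

    n_heavy = len([a for a in ensemble.mol.GetAtoms() if a.GetAtomicNum() > 1])
    mappings_by_template = []
    for tpl in templates:
        mappings_by_template.append(
            mcs_map(ensemble.mol, tpl.mol3d.mol, timeout=cfg.mcs_timeout))
    if all(not m for m in mappings_by_template):
        raise UnalignableError(ensemble.mol_id,
                               "no >=3-atom common substructure with any template")

    conf_field_points: dict[int, list[FieldPoint]] = {}
    best = None  # (-score, t_idx, c_idx, m_idx, result fields)
    for t_idx, tpl in enumerate(templates):
        tpl_coords = tpl.coords
        for m_idx, mapping in enumerate(mappings_by_template[t_idx]):
            mi = [i for i, _ in mapping]
            ti = [j for _, j in mapping]
            frac = len(mapping) / n_heavy
            for c_idx in range(len(ensemble)):
                coords = ensemble.conformer_coords(c_idx)
                R, tr = kabsch(coords[mi], tpl_coords[ti])
                moved = coords[mi] @ R.T + tr
                rmsd = float(np.sqrt(((moved - tpl_coords[ti]) ** 2).sum()
                                     / len(mapping)))
                if c_idx not in conf_field_points:
                    conf_field_points[c_idx] = compute_field_points(
                        ensemble.as_molecule3d(c_idx), field_cfg)
                fps = _transform_field_points(conf_field_points[c_idx], R, tr)
                fsim = field_similarity(fps, tpl.field_points, cfg.field_sigma)
                score = cfg.w_sub * frac + cfg.w_field * fsim
                key = (-score, t_idx, c_idx, m_idx)
                if best is None or key < best[0]:
                    best = (key, AlignmentResult(
                        mol_id=ensemble.mol_id, template_id=tpl.id,
                        conformer_index=c_idx, mapping=mapping,
                        rotation=R, translation=tr, score=score,
                        substructure_rmsd=rmsd))
    result = best[1]
    result.flagged = result.score < cfg.min_score
    return result


def apply_alignment(ensemble: ConformerEnsemble, res: AlignmentResult
                    ) -> Molecule3D:
    """The chosen conformer as a Molecule3D in the template frame."""
    m = ensemble.as_molecule3d(res.conformer_index)
    m.coords = res.transform(m.coords)
    return m


def write_alignment_report(results: Sequence[AlignmentResult],
                           path: str | Path) -> None:
    """Per-molecule TSV report replacing the interactive alignment check."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("id\ttemplate\tconformer\tscore\tsubstructure_rmsd\tflagged\n")
        for r in results:
            fh.write(f"{r.mol_id}\t{r.template_id}\t{r.conformer_index}\t"
                     f"{r.score:.4f}\t{r.substructure_rmsd:.4f}\t"
                     f"{str(r.flagged).lower()}\n")


def load_templates_sdf(path: str | Path,
                       field_cfg: FieldConfig | None = None) -> list[Template]:
    """Load template ligands from an SDF file, coordinates respected verbatim."""
    from .chemio import read_sdf, assign_gasteiger_charges
    templates = []
    for m in read_sdf(path):
        try:
            m.partial_charges
        except KeyError:
            assign_gasteiger_charges(m)
        templates.append(Template(m.id, m, field_cfg))
    return templates
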