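"""Pharmacophore filtering, consensus-QSAR library ranking, scaffold hopping.

The screening funnel has two stages: a geometric pharmacophore pre-filter
(features derived from the template ligands; candidate conformers must
place matching feature centers within an RMSD gate, default 0.75 A, of the
query features) and a QSAR scoring stage (survivors are aligned into the
template frame and scored by each fitted model plus their consensus).

Scaffold hopping cuts a parent molecule at designated acyclic bonds into
parts, substitutes library fragments for each non-frozen part, and rescores
the valence-valid products through the same embed -> align -> predict path.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from scipy.optimize import linear_sum_assignment

from . import chemio
from .alignment import AlignmentConfig, Template, align_ensemble, apply_alignment
from .chemio import Molecule3D
from .conformers import ConformerEnsemble, EnsembleConfig, enumerate_conformers, kabsch
from .fieldspace import FieldConfig, SamplePointSet, descriptor_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PharmacophoreFeature", "PharmacophoreModel", "ScreeningHit",
    "derive_pharmacophore", "extract_features", "match_pharmacophore",
    "screen_library", "scaffold_hop", "FEATURE_SMARTS",
]

# Documented SMARTS feature dictionary. Feature centers are the centroid of
# the matched atoms.
FEATURE_SMARTS: dict[str, tuple[str, ...]] = {
    "aromatic": ("a1aaaaa1", "a1aaaa1"),
    "hbond_donor": ("[N!H0;!$([N+0]);!$(N=*)]", "[O!H0]", "[N+!H0]"),
    "hbond_acceptor": ("[O;!$([OX2H0]([#6])[#6r])]",
                       "[N;!$([N+]);!$([nX3]);!$(N=*);X3;H0;!$(NC=O)]",
                       "[nX2]"),
    "positive_ionizable": ("[+;!$([+]~[-])]",),
    "hydrophobic": ("[CX4;!$(C~[!#6;!#1])]~[CX4;!$(C~[!#6;!#1])]",
                    "[F,Cl,Br,I;$(*-[#6])]"),
}

_FEATURE_PATTERNS = {
    ftype: [Chem.MolFromSmarts(s) for s in patterns]
    for ftype, patterns in FEATURE_SMARTS.items()
}


@dataclass(frozen=True)
class PharmacophoreFeature:
    type: str
    center: tuple[float, float, float]
    tolerance: float = 1.0     # A
    required: bool = False


@dataclass
class PharmacophoreModel:
    """Typed 3D feature centers in the template frame, with match radii."""

    features: list[PharmacophoreFeature]

    def __post_init__(self):
        if len(self.features) < 3:
            raise ValueError("pharmacophore needs >= 3 features")
        if any(f.tolerance <= 0 for f in self.features):
            raise ValueError("tolerance radii must be > 0")

    def required_features(self) -> list[PharmacophoreFeature]:
        return [f for f in self.features if f.required]

    def to_json(self) -> str:
        return json.dumps({"features": [
            {"type": f.type, "center": list(f.center),
             "tolerance": f.tolerance, "required": f.required}
            for f in self.features]})

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreModel":
        d = json.loads(text)
        return cls([PharmacophoreFeature(f["type"], tuple(f["center"]),
                                         f["tolerance"], f["required"])
                    for f in d["features"]])


def extract_features(mol3d: Molecule3D, tolerance: float = 1.0
                     ) -> list[PharmacophoreFeature]:
    """Feature centers of one molecule from the SMARTS dictionary.

    Overlapping matches of the same type within 0.5 A are merged to avoid
    double counting (e.g. fused-ring aromatic SMARTS).
    """
    coords = mol3d.coords
    feats: list[PharmacophoreFeature] = []
    for ftype, patterns in _FEATURE_PATTERNS.items():
        centers: list[np.ndarray] = []
        for patt in patterns:
            for match in mol3d.mol.GetSubstructMatches(patt):
                c = coords[list(match)].mean(axis=0)
                if all(np.linalg.norm(c - prev) > 0.5 for prev in centers):
                    centers.append(c)
        for c in centers:
            feats.append(PharmacophoreFeature(ftype, tuple(c.tolist()),
                                              tolerance))
    return feats


def derive_pharmacophore(templates: Sequence[Template], tolerance: float = 1.0,
                         merged: bool = True) -> PharmacophoreModel:
    """Build the screening pharmacophore from template ligands.

    Per-template features come from the SMARTS dictionary; with ``merged``
    (default) features of the same type co-located (< tolerance) across at
    least two templates are collapsed to their centroid and marked required.
    Deterministic; duplicate templates add nothing.
    """
    if not templates:
        raise ValueError("need >= 1 template")
    per_template = []
    seen_ids = set()
    for t in templates:
        if t.id in seen_ids:
            continue
        seen_ids.add(t.id)
        per_template.append((t.id, extract_features(t.mol3d, tolerance)))
    all_feats = [(tid, f) for tid, feats in per_template for f in feats]
    if not merged or len(per_template) == 1:
        feats = [f for _tid, f in all_feats]
        if len(feats) < 3:
            raise ValueError(f"only {len(feats)} features found; need >= 3")
        return PharmacophoreModel(feats)

    used = [False] * len(all_feats)
    out: list[PharmacophoreFeature] = []
    for i, (tid_i, fi) in enumerate(all_feats):
        if used[i]:
            continue
        group = [(tid_i, fi)]
        used[i] = True
        for j in range(i + 1, len(all_feats)):
            tid_j, fj = all_feats[j]
            if used[j] or fj.type != fi.type or tid_j == tid_i:
                continue
            if np.linalg.norm(np.array(fi.center) - np.array(fj.center)) \
                    < tolerance:
                group.append((tid_j, fj))
                used[j] = True
        centroid = np.mean([f.center for _t, f in group], axis=0)
        out.append(PharmacophoreFeature(
            fi.type, tuple(centroid.tolist()), tolerance,
            required=len({t for t, _f in group}) >= 2))
    if len(out) < 3:
        raise ValueError(f"only {len(out)} features found; need >= 3")
    return PharmacophoreModel(out)


def _assign_features(lig_centers: np.ndarray, model_centers: np.ndarray,
                     max_exact: int = 8) -> list[tuple[int, int]]:
    """Assign model features to distinct ligand features minimizing total
    squared distance: exhaustive for small sets, Hungarian otherwise."""
    n_m, n_l = len(model_centers), len(lig_centers)
    d2 = ((model_centers[:, None, :] - lig_centers[None, :, :]) ** 2).sum(axis=2)
    if n_m <= max_exact and n_l <= max_exact:
        best = None
        for perm in itertools.permutations(range(n_l), n_m):
            cost = d2[range(n_m), list(perm)].sum()
            if best is None or cost < best[0]:
                best = (cost, perm)
        return [(mi, li) for mi, li in enumerate(best[1])]
    rows, cols = linear_sum_assignment(d2)
    return list(zip(rows.tolist(), cols.tolist()))


def match_pharmacophore(ensemble: ConformerEnsemble, model: PharmacophoreModel,
                        tolerance: float = 1.0
                        ) -> tuple[float, int, list[tuple[int, int]]] | None:
    """Best pharmacophore RMSD of a conformer ensemble against a model.

    For each conformer, ligand features are extracted, model features are
    assigned to distinct same-type ligand features, matched pairs are
    superposed optimally (Kabsch), and the RMSD of the matched center
    distances is computed. Returns (min RMSD, conformer index, matching)
    over conformers, or None when some required feature has no same-type
    ligand feature (no-match is a value, not an error).
    """
    best: tuple[float, int, list[tuple[int, int]]] | None = None
    model_by_type: dict[str, list[int]] = {}
    for k, f in enumerate(model.features):
        model_by_type.setdefault(f.type, []).append(k)

    for ci in range(len(ensemble)):
        m3d = ensemble.as_molecule3d(ci)
        lig_feats = extract_features(m3d, tolerance)
        lig_by_type: dict[str, list[int]] = {}
        for k, f in enumerate(lig_feats):
            lig_by_type.setdefault(f.type, []).append(k)
        # required features must be matchable by type
        ok = True
        for f in model.features:
            if f.required and f.type not in lig_by_type:
                ok = False
                break
        if not ok:
            continue
        pairs: list[tuple[int, int]] = []
        for ftype, midx in model_by_type.items():
            lidx = lig_by_type.get(ftype, [])
            if not lidx:
                continue
            # required model features claim ligand features first, so a
            # scarce ligand feature is never spent on an optional one
            req = [k for k in midx if model.features[k].required]
            opt = [k for k in midx if not model.features[k].required]
            remaining = list(lidx)
            for group in (req, opt):
                if not group or not remaining:
                    continue
                mc = np.array([model.features[k].center for k in group])
                lc = np.array([lig_feats[k].center for k in remaining])
                if len(remaining) >= len(group):
                    assign = _assign_features(lc, mc)
                    chosen = [(group[mi], remaining[li]) for mi, li in assign]
                else:
                    assign = _assign_features(mc, lc)
                    chosen = [(group[mi], remaining[li]) for li, mi in assign]
                pairs.extend(chosen)
                used = {li for _mi, li in chosen}
                remaining = [li for li in remaining if li not in used]
        required_ids = {k for k, f in enumerate(model.features) if f.required}
        if not required_ids <= {mi for mi, _li in pairs}:
            continue
        if len(pairs) < 2:
            continue
        P = np.array([lig_feats[li].center for _mi, li in pairs])
        Q = np.array([model.features[mi].center for mi, _li in pairs])
        R, t = kabsch(P, Q)
        diff = (P @ R.T + t) - Q
        rmsd = float(np.sqrt((diff * diff).sum() / len(pairs)))
        if rmsd < 1e-9:   # exact overlay up to round-off
            rmsd = 0.0
        if best is None or rmsd < best[0]:
            best = (rmsd, ci, pairs)
    return best


@dataclass
class ScreeningHit:
    mol_id: str
    rmsd: float
    conformer_index: int
    predicted: dict[str, float]
    consensus: float
    rank: int = 0


def screen_library(
    library: Sequence[tuple[str, str]],
    pharmacophore: PharmacophoreModel,
    models: dict,
    templates: Sequence[Template],
    sample_points: SamplePointSet,
    rmsd_cut: float = 0.75,
    ensemble_cfg: EnsembleConfig | None = None,
    field_cfg: FieldConfig | None = None,
    align_cfg: AlignmentConfig | None = None,
    seed: int = 2021,
) -> tuple[list[ScreeningHit], dict]:
    """Two-stage virtual screen of (id, SMILES) pairs.

    Stage 1 keeps molecules whose best pharmacophore RMSD over the conformer
    ensemble is below ``rmsd_cut``; stage 2 aligns survivors into the
    template frame, evaluates their descriptors on the model sample points
    and predicts pKi with every model plus the (field + SVM style) consensus
    mean. Hits are sorted by consensus descending, ties by RMSD ascending
    then id. The run manifest records counts at each stage. Stage-1 survival
    is per molecule, hence independent of library order.
    """
    ensemble_cfg = ensemble_cfg or EnsembleConfig(max_conformers=20, seed=seed)
    field_cfg = field_cfg or FieldConfig()
    manifest = {"input": len(library), "parsed": 0, "filtered": 0,
                "aligned": 0, "rmsd_cut": rmsd_cut, "errors": []}
    stage1: list[tuple[str, float, ConformerEnsemble, int]] = []
    for mol_id, smi in library:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            manifest["errors"].append(f"{mol_id}: unparsable SMILES")
            continue
        manifest["parsed"] += 1
        try:
            m3d = chemio.embed_minimize(chemio.protonate_ph7(mol), mol_id,
                                        gradient_tol=ensemble_cfg.gradient_tol,
                                        seed=chemio.molecule_seed(mol))
            ens = enumerate_conformers(m3d, ensemble_cfg)
        except chemio.EmbeddingError as exc:
            manifest["errors"].append(str(exc))
            continue
        match = match_pharmacophore(ens, pharmacophore)
        # strict RMSD gate; an exact overlay (rmsd 0) always survives, which
        # keeps the rmsd_cut=0 boundary meaningful
        if match is None or not (match[0] < rmsd_cut or match[0] == 0.0):
            continue
        stage1.append((mol_id, match[0], ens, match[1]))
    manifest["filtered"] = len(stage1)
    if not stage1:
        logger.warning("no molecules pass the pharmacophore filter")
        return [], manifest

    hits: list[ScreeningHit] = []
    for mol_id, rmsd, ens, conf_idx in stage1:
        try:
            res = align_ensemble(ens, templates, align_cfg, field_cfg)
        except Exception as exc:
            manifest["errors"].append(f"{mol_id}: alignment failed ({exc})")
            continue
        aligned = apply_alignment(ens, res)
        X = descriptor_matrix([aligned], sample_points, field_cfg).values
        preds = {name: float(np.asarray(m.predict(X)).ravel()[0])
                 for name, m in models.items()}
        hits.append(ScreeningHit(mol_id, rmsd, conf_idx, preds,
                                 consensus=float(np.mean(list(preds.values())))))
    manifest["aligned"] = len(hits)
    hits.sort(key=lambda h: (-h.consensus, h.rmsd, h.mol_id))
    for rank, h in enumerate(hits, start=1):
        h.rank = rank
    return hits, manifest


def write_hits_tsv(hits: Sequence[ScreeningHit], path: str | Path) -> None:
    model_names = sorted({k for h in hits for k in h.predicted}) if hits else []
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("rank\tid\trmsd\t" + "\t".join(f"pki_{m}" for m in model_names)
                 + "\tconsensus\n")
        for h in hits:
            fh.write(f"{h.rank}\t{h.mol_id}\t{h.rmsd:.4f}\t"
                     + "\t".join(f"{h.predicted[m]:.4f}" for m in model_names)
                     + f"\t{h.consensus:.4f}\n")


# --------------------------------------------------------------------------
# Scaffold hopping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CutSpec:
    """Bonds (atom-index pairs in the parent) partitioning it into parts.

    ``frozen_parts`` are part indices that are never replaced (e.g. a core
    whose receptor salt bridge must be preserved).
    """

    cut_bonds: tuple[tuple[int, int], ...]
    frozen_parts: tuple[int, ...] = ()


def _fragment_parent(parent: Chem.Mol, spec: CutSpec
                     ) -> list[Chem.Mol]:
    """Split the parent on the cut bonds; dummy atoms labelled per cut."""
    bond_ids = []
    for (i, j) in spec.cut_bonds:
        bond = parent.GetBondBetweenAtoms(i, j)
        if bond is None:
            raise ValueError(f"no bond between atoms {i} and {j}")
        if bond.IsInRing():
            raise ValueError(f"cut bond ({i},{j}) is in a ring")
        bond_ids.append(bond.GetIdx())
    labels = [(k + 1, k + 1) for k in range(len(bond_ids))]
    frag = Chem.FragmentOnBonds(parent, bond_ids, addDummies=True,
                                dummyLabels=labels)
    parts = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
    return list(parts)


def _part_labels(part: Chem.Mol) -> list[int]:
    return sorted(a.GetIsotope() for a in part.GetAtoms()
                  if a.GetAtomicNum() == 0)


def _relabel_fragment(fragment: Chem.Mol, labels: Sequence[int]) -> Chem.Mol:
    """Give the fragment's dummy atoms the replaced part's cut labels."""
    frag = Chem.Mol(fragment)
    dummies = [a for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != len(labels):
        raise ValueError(
            f"fragment has {len(dummies)} attachment point(s), part needs "
            f"{len(labels)}")
    for a, lab in zip(dummies, labels):
        a.SetIsotope(lab)
        a.SetAtomMapNum(lab)
    return frag


def _zip_parts(parts: Sequence[Chem.Mol]) -> Chem.Mol | None:
    combo = parts[0]
    for p in parts[1:]:
        combo = Chem.CombineMols(combo, p)
    combo = Chem.Mol(combo)
    for a in combo.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomMapNum(a.GetIsotope())
    try:
        out = Chem.molzip(combo)
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


@dataclass
class HopCandidate:
    mol_id: str
    smiles: str
    part_index: int
    fragment_smiles: str
    consensus_pki: float


def scaffold_hop(
    parent_smiles: str,
    cut_spec: CutSpec,
    fragment_library: Sequence[str],
    models: dict,
    templates: Sequence[Template],
    sample_points: SamplePointSet,
    field_cfg: FieldConfig | None = None,
    align_cfg: AlignmentConfig | None = None,
    seed: int = 2021,
) -> list[HopCandidate]:
    """Replace each non-frozen part of the parent with library fragments.

    For every designated part and every fragment with matching attachment
    arity, a candidate molecule is assembled (parent's preserved parts
    unchanged), embedded, aligned and scored by the consensus of the given
    models. Valence-invalid or unassemblable candidates are skipped and
    logged. Results are sorted by predicted consensus pKi descending.
    """
    parent = Chem.MolFromSmiles(parent_smiles)
    if parent is None:
        raise ValueError("unparsable parent SMILES")
    parts = _fragment_parent(parent, cut_spec)
    field_cfg = field_cfg or FieldConfig()
    out: list[HopCandidate] = []
    n = 0
    for pi, part in enumerate(parts):
        if pi in cut_spec.frozen_parts:
            continue
        labels = _part_labels(part)
        others = [p for k, p in enumerate(parts) if k != pi]
        for frag_smi in fragment_library:
            frag = Chem.MolFromSmiles(frag_smi)
            if frag is None:
                logger.warning("skipping unparsable fragment %s", frag_smi)
                continue
            try:
                frag_rl = _relabel_fragment(frag, labels)
            except ValueError as exc:
                logger.info("fragment %s skipped: %s", frag_smi, exc)
                continue
            product = _zip_parts([frag_rl] + others)
            if product is None:
                logger.info("fragment %s: assembly/valence failure", frag_smi)
                continue
            smi = Chem.MolToSmiles(product)
            mol_id = f"hop_p{pi}_{n}"
            n += 1
            try:
                from .synthdata import prepare_molecule
                # molecule-identity embedding seed: identical candidates get
                # identical poses, and identity replacement reproduces the
                # parent's training-time geometry
                aligned = prepare_molecule(smi, mol_id, templates,
                                           field_cfg=field_cfg,
                                           align_cfg=align_cfg)
            except Exception as exc:
                logger.info("candidate %s skipped: %s", smi, exc)
                continue
            X = descriptor_matrix([aligned], sample_points, field_cfg).values
            preds = [float(np.asarray(m.predict(X)).ravel()[0])
                     for m in models.values()]
            out.append(HopCandidate(mol_id, smi, pi, frag_smi,
                                    float(np.mean(preds))))
    out.sort(key=lambda c: (-c.consensus_pki, c.mol_id))
    return out
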