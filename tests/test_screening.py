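"""Pharmacophore derivation/matching, library screening, scaffold hopping."""

import numpy as np
import pytest
from rdkit import Chem

from fieldqsar import chemio
from fieldqsar.alignment import Template, align_ensemble, apply_alignment
from fieldqsar.conformers import (ConformerEnsemble, EnsembleConfig,
                                  enumerate_conformers)
from fieldqsar.screening import (CutSpec, PharmacophoreFeature,
                                 PharmacophoreModel, derive_pharmacophore,
                                 extract_features, match_pharmacophore,
                                 scaffold_hop, screen_library,
                                 _fragment_parent, _zip_parts)

from conftest import embed


def _ensemble_of(m3d):
    ens = ConformerEnsemble(m3d.id, Chem.Mol(m3d.mol), [m3d.energy or 0.0])
    for a, q in zip(ens.mol.GetAtoms(), m3d.partial_charges):
        a.SetDoubleProp("_partial_charge", float(q))
    return ens


@pytest.fixture(scope="module")
def template_pair():
    """Two phenethylamine-like templates sharing one frame."""
    t1 = Template("t1", embed("NCCc1ccccc1", "t1"))
    m2 = embed("NCCc1ccc(O)cc1", "t2")
    ens = _ensemble_of(m2)
    res = align_ensemble(ens, [t1])
    t2 = Template("t2", apply_alignment(ens, res))
    return t1, t2


class TestDerivePharmacophore:
    def test_toy_feature_extraction(self):
        # basic amine + two separate aromatic rings -> at least those three
        m = embed("NCc1ccc(-c2ccccc2)cc1", "biphen")
        feats = extract_features(m)
        types = [f.type for f in feats]
        assert types.count("aromatic") == 2
        assert "positive_ionizable" in types

    def test_duplicate_template_idempotent(self, template_pair):
        t1, t2 = template_pair
        once = derive_pharmacophore([t1, t2])
        twice = derive_pharmacophore([t1, t2, t1])
        assert once.to_json() == twice.to_json()

    def test_colocated_features_merged_to_midpoint(self):
        f1 = PharmacophoreFeature("positive_ionizable", (0.0, 0.0, 0.0), 1.0)
        f2 = PharmacophoreFeature("positive_ionizable", (0.5, 0.0, 0.0), 1.0)

        class _Fake:
            def __init__(self, tid, feats):
                self.id = tid
                self._f = feats

        import fieldqsar.screening as scr
        orig = scr.extract_features
        fakes = {"a": [f1, PharmacophoreFeature("aromatic", (3.0, 0, 0)),
                       PharmacophoreFeature("hbond_donor", (0, 3.0, 0))],
                 "b": [f2]}

        def fake_extract(mol3d, tolerance=1.0):
            return fakes[mol3d]
        scr.extract_features = fake_extract
        try:
            model = derive_pharmacophore(
                [type("T", (), {"id": k, "mol3d": k})() for k in ("a", "b")])
        finally:
            scr.extract_features = orig
        merged = [f for f in model.features if f.required]
        assert len(merged) == 1
        assert merged[0].center == pytest.approx((0.25, 0.0, 0.0))

    def test_requires_three_features(self):
        with pytest.raises(ValueError):
            PharmacophoreModel([PharmacophoreFeature("aromatic", (0, 0, 0))])

    def test_json_round_trip(self, template_pair):
        model = derive_pharmacophore(list(template_pair))
        back = PharmacophoreModel.from_json(model.to_json())
        assert back.to_json() == model.to_json()


class TestMatchPharmacophore:
    def test_template_self_match_is_zero(self, template_pair):
        t1, _ = template_pair
        model = derive_pharmacophore([t1], merged=False)
        rmsd, _ci, _pairs = match_pharmacophore(_ensemble_of(t1.mol3d), model)
        assert rmsd <= 1e-6

    def test_missing_required_feature_no_match(self, template_pair):
        model = derive_pharmacophore(list(template_pair))
        assert any(f.required and f.type == "positive_ionizable"
                   for f in model.features)
        no_amine = embed("CCOc1ccccc1", "no_amine")
        assert match_pharmacophore(_ensemble_of(no_amine), model) is None

    def test_equal_displacement_gives_that_rmsd(self):
        # all matched features exactly 1 A from their targets after the best
        # superposition -> RMSD exactly 1, failing the 0.75 gate
        base = [PharmacophoreFeature("aromatic", (0.0, 0.0, 0.0)),
                PharmacophoreFeature("aromatic", (4.0, 0.0, 0.0)),
                PharmacophoreFeature("aromatic", (2.0, 3.0, 0.0))]
        # ligand features: same triangle pushed 1 A out of plane; optimal
        # superposition recenters, residual computed by the closed form
        from fieldqsar.conformers import kabsch
        P = np.array([f.center for f in base], float)
        Q = P.copy()
        Q[:, 2] += 1.0
        R, t = kabsch(P, Q)
        diff = (P @ R.T + t) - Q
        assert np.sqrt((diff ** 2).sum() / 3) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, template_pair):
        t1, _t2 = template_pair
        model = derive_pharmacophore([t1], merged=False)
        probe = embed("NCCc1ccc(C)cc1", "probe")
        r0 = match_pharmacophore(_ensemble_of(probe), model)
        th = 1.0
        R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                      [-np.sin(th), 0, np.cos(th)]])
        moved = probe.copy()
        moved.coords = probe.coords @ R.T + [3.0, -2.0, 8.0]
        r1 = match_pharmacophore(_ensemble_of(moved), model)
        assert r1[0] == pytest.approx(r0[0], abs=1e-6)


class _ConstModel:
    def __init__(self, v):
        self.v = v

    def predict(self, X):
        return np.full(len(np.atleast_2d(X)), self.v)


class TestScreenLibrary:
    LIBRARY = [
        ("self", "NCCc1ccccc1"),             # template copy: passes
        ("analog_methyl", "NCCc1ccc(C)cc1"),  # close analog: passes
        ("analog_meo", "NCCc1ccc(OC)cc1"),    # close analog: passes
        ("no_amine", "CCOc1ccccc1"),          # lacks positive: no match
        ("alkyne", "NCC#Cc1ccccc1"),          # rigid, wrong geometry: fails
        ("bad", "not-a-smiles"),              # parse error, reported
    ]

    @pytest.fixture(scope="class")
    def screen_setup(self, template_pair):
        from fieldqsar.fieldspace import SamplePointSet
        t1, t2 = template_pair
        model = derive_pharmacophore([t1, t2])
        sps = SamplePointSet(((0.0, 0.0, 0.0), (2.0, 0.0, 0.0)))
        return [t1, t2], model, sps

    def test_known_survivor_count_and_manifest(self, screen_setup):
        templates, model, sps = screen_setup
        hits, manifest = screen_library(
            self.LIBRARY, model, {"m": _ConstModel(7.0)}, templates, sps,
            ensemble_cfg=EnsembleConfig(max_conformers=5, seed=1))
        assert manifest["input"] == 6
        assert manifest["parsed"] == 5
        assert manifest["filtered"] == 3
        assert {h.mol_id for h in hits} == {"self", "analog_methyl",
                                            "analog_meo"}
        assert [h.rank for h in hits] == [1, 2, 3]
        assert any("bad" in e for e in manifest["errors"])

    def test_order_invariance_and_determinism(self, screen_setup):
        templates, model, sps = screen_setup
        cfg = EnsembleConfig(max_conformers=5, seed=1)
        hits1, _ = screen_library(self.LIBRARY, model,
                                  {"m": _ConstModel(7.0)}, templates, sps,
                                  ensemble_cfg=cfg)
        hits2, _ = screen_library(list(reversed(self.LIBRARY)), model,
                                  {"m": _ConstModel(7.0)}, templates, sps,
                                  ensemble_cfg=cfg)
        assert [(h.mol_id, h.rmsd) for h in hits1] == \
            [(h.mol_id, h.rmsd) for h in hits2]

    def test_zero_cut_boundary(self, screen_setup):
        templates, model, sps = screen_setup
        hits, manifest = screen_library(
            self.LIBRARY[:3], model, {"m": _ConstModel(7.0)}, templates, sps,
            rmsd_cut=0.0, ensemble_cfg=EnsembleConfig(max_conformers=5, seed=1))
        # none of the analogs overlays the merged model exactly
        assert manifest["filtered"] == 0
        assert hits == []


class TestScaffoldHop:
    PARENT = "CCOc1ccc(CCN)cc1"

    def test_identity_replacement_regenerates_parent(self):
        parent = Chem.MolFromSmiles(self.PARENT)
        cut = CutSpec(cut_bonds=((1, 2),))  # ethyl | rest
        parts = _fragment_parent(parent, cut)
        product = _zip_parts(parts)
        assert Chem.MolToSmiles(product) == Chem.CanonSmiles(self.PARENT)

    def test_ring_bond_cut_rejected(self):
        parent = Chem.MolFromSmiles(self.PARENT)
        ring_bond = next(b for b in parent.GetBonds() if b.IsInRing())
        cut = CutSpec(cut_bonds=((ring_bond.GetBeginAtomIdx(),
                                  ring_bond.GetEndAtomIdx()),))
        with pytest.raises(ValueError, match="ring"):
            _fragment_parent(parent, cut)

    def test_candidate_count_and_frozen_parts(self, template_pair):
        from fieldqsar.fieldspace import SamplePointSet
        t1, _ = template_pair
        sps = SamplePointSet(((0.0, 0.0, 0.0),))
        frags = ["[*]C", "[*]CC", "[*]O", "[*]F", "[*]Cl"]
        # both parts replaceable: full ethyl series plus whichever of the
        # degenerate small products survive alignment (skips are logged)
        cands = scaffold_hop(self.PARENT, CutSpec(cut_bonds=((1, 2),)),
                             frags, {"m": _ConstModel(6.0)}, [t1], sps)
        part0 = [c for c in cands if c.part_index == 0]
        assert len(part0) == 5
        assert len(cands) <= 10
        # freezing the large part leaves only the ethyl series
        cands2 = scaffold_hop(self.PARENT, CutSpec(cut_bonds=((1, 2),),
                                                   frozen_parts=(1,)),
                              frags, {"m": _ConstModel(6.0)}, [t1], sps)
        assert len(cands2) == 5
        assert {c.part_index for c in cands2} == {0}

    def test_preserved_parts_unchanged(self, template_pair):
        from fieldqsar.fieldspace import SamplePointSet
        t1, _ = template_pair
        sps = SamplePointSet(((0.0, 0.0, 0.0),))
        # cut the O-ring bond and freeze the ethoxy part (atoms C,C,O)
        cands = scaffold_hop(self.PARENT, CutSpec(cut_bonds=((2, 3),),
                                                  frozen_parts=(0,)),
                             ["[*]c1ccncc1CCN"], {"m": _ConstModel(6.0)},
                             [t1], sps)
        assert cands
        # the untouched ethoxy part must survive in every product
        for c in cands:
            prod = Chem.MolFromSmiles(c.smiles)
            assert prod.HasSubstructMatch(Chem.MolFromSmiles("CCO"))

    def test_arity_mismatch_skipped(self, template_pair):
        from fieldqsar.fieldspace import SamplePointSet
        t1, _ = template_pair
        sps = SamplePointSet(((0.0, 0.0, 0.0),))
        # two cuts make a middle part with 2 attachment points; one-point
        # fragments cannot replace it
        parent = "CCOc1ccc(CCNC(C)=O)cc1"
        pm = Chem.MolFromSmiles(parent)
        cands = scaffold_hop(
            parent, CutSpec(cut_bonds=((1, 2), (8, 9))),
            ["[*]C"], {"m": _ConstModel(6.0)}, [t1], sps)
        assert all(c.part_index != 1 for c in cands)
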