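"""Shared fixtures: small molecules and the default synthetic benchmark.

The benchmark and fitted pipeline are session-scoped because generating
3D structures for 200 molecules is the dominant cost of the suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from fieldqsar import chemio
from fieldqsar.alignment import Template
from fieldqsar.cli import build_pipeline
from fieldqsar.config import PipelineConfig
from fieldqsar.synthdata import BenchmarkSpec, make_benchmark


def embed(smiles: str, mol_id: str = "mol", seed: int = 2021,
          protonate: bool = True) -> chemio.Molecule3D:
    mol = Chem.MolFromSmiles(smiles)
    if protonate:
        mol = chemio.protonate_ph7(mol)
    return chemio.embed_minimize(mol, mol_id, seed=seed)


@pytest.fixture(scope="session")
def phenethylamine_template() -> Template:
    return Template("tpl", embed("NCCc1ccccc1", "tpl"))


@pytest.fixture(scope="session")
def benchmark200():
    """The default synthetic benchmark: n=200, sigma=0.4 pKi, fixed seed."""
    return make_benchmark(BenchmarkSpec())


@pytest.fixture(scope="session")
def pipeline200(benchmark200):
    """Field, SVM and kNN models fitted on the default benchmark."""
    return build_pipeline(benchmark200, PipelineConfig(),
                          kinds=("field", "svm", "knn"))


@pytest.fixture(scope="session")
def multiseed_results():
    """Field/SVM/kNN test performance over 20 regenerated benchmarks.

    Each seed regenerates the full study: library, 3D preparation,
    alignment, planted activity, split, sample points and model fits.
    Returns one record per seed with test r2 values, the field model's
    5-fold cross-validated q2, its training r2, and the noise ceiling
    1 - sigma^2 / var(pKi).
    """
    from fieldqsar import qsar, validation as V

    records = []
    for seed in range(1, 21):
        spec = BenchmarkSpec(seed=seed)
        bench = make_benchmark(spec)
        res = build_pipeline(bench, PipelineConfig(seed=seed),
                             kinds=("field", "svm", "knn"))
        factory = lambda X, y: qsar.simpls_fit(X, y, 5)
        records.append({
            "seed": seed,
            "field_r2_train": V.r2(res.y_train,
                                   res.models["field"].predict(res.X_train)),
            "field_q2_cv5": V.q2_kfold(factory, res.X_train, res.y_train,
                                       k=5, seed=seed),
            "field_r2_test": V.r2(res.y_test,
                                  res.models["field"].predict(res.X_test)),
            "svm_r2_test": V.r2(res.y_test,
                                res.models["svm"].predict(res.X_test)),
            "knn_r2_test": V.r2(res.y_test,
                                res.models["knn"].predict(res.X_test)),
            "ceiling": 1.0 - spec.noise_sd ** 2 / float(np.var(bench.pki)),
        })
    return records
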