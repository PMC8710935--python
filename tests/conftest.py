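import numpy as np
import pandas as pd
import pytest

from famscore import fam_scores, fm_scores, ac_scores
from famscore.synthetic import GeneratorSpec, generate
from famscore.types import (
    DiseaseSignature,
    DrugTargetTable,
    GeneAssociationTable,
    p_to_z,
)


def make_assoc(genes, pvals, phenotype="toy"):
    p = np.asarray(pvals, dtype=float)
    return GeneAssociationTable(
        phenotype, pd.DataFrame({"gene_id": genes, "p_value": p, "z_stat": p_to_z(p)})
    )


def make_targets(rows):
    """rows: iterable of (drug_id, gene_id, affinity_weight)."""
    return DrugTargetTable(
        pd.DataFrame(rows, columns=["drug_id", "gene_id", "affinity_weight"])
    )


def make_disease(genes, effects, phenotype="toy"):
    return DiseaseSignature(phenotype, pd.DataFrame({"gene_id": genes, "effect": effects}))


@pytest.fixture(scope="session")
def small_spec():
    return GeneratorSpec(
        n_genes=300, n_drugs=60, n_effective=8, target_count_range=(1, 30),
        effect_strength=3.0, seed=1, phenotype="signal",
    )


@pytest.fixture(scope="session")
def small_signal(small_spec):
    """Planted-signal synthetic dataset, small enough for fast tests."""
    return generate(small_spec)


@pytest.fixture(scope="session")
def small_null():
    """Null synthetic dataset: effect_strength 0, truth drugs are unremarkable."""
    return generate(
        GeneratorSpec(
            n_genes=300, n_drugs=60, n_effective=8, target_count_range=(1, 30),
            effect_strength=0.0, seed=2, phenotype="null",
        )
    )


@pytest.fixture(scope="session")
def small_signal_scores(small_signal):
    """Ranked FAM score table for the planted-signal dataset."""
    d = small_signal
    fm = fm_scores(d.drug_targets, d.assoc, n_perm=500, seed=11)
    ac = ac_scores(d.disease, d.signatures)
    return fam_scores(fm, ac, phenotype="signal")
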