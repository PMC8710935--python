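"""Seeded synthetic inputs with planted structure.

The generator emulates the statistical shape of the real inputs: a gene-level
association table whose p-values are mostly uniform with a small strongly
associated tail (Beta(0.1, 20) for planted genes, so only a handful reach
genome-wide significance), a signed disease signature whose magnitudes track
association strength, a sparse drug-target table with per-drug target counts
spanning a configurable range, and a drug-signature matrix in which planted
"effective" drugs anti-correlate with the disease signature.

``effect_strength`` scales every planted difference — target preference for
planted genes, the affinity boost on them, and the signature reversal — so
``effect_strength = 0`` is an exact null in which the "effective" drugs are
statistically indistinguishable from the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    DiseaseSignature,
    DrugSetAnnotation,
    DrugSignatureMatrix,
    DrugTargetTable,
    GeneAssociationTable,
    p_to_z,
)

__all__ = ["GeneratorSpec", "SyntheticData", "generate", "write_fixture_dir"]


@dataclass
class GeneratorSpec:
    """Parameters of the planted-signal generator.

    Defaults are the benchmark conditions used throughout the test-suite:
    2000 genes, 300 drugs, 20 effective drugs, target counts 1-100.
    """

    n_genes: int = 2000
    n_drugs: int = 300
    n_effective: int = 20
    target_count_range: tuple[int, int] = (1, 100)
    effect_strength: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0
    phenotype: str = "synthetic"
    #: fraction of non-effective drugs absent from the signature matrix
    missing_signature_fraction: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.target_count_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("target_count_range must lie within [1, n_genes]")
        if not 0 <= self.n_effective <= self.n_drugs:
            raise ValueError("n_effective must lie in [0, n_drugs]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.effect_strength < 0:
            raise ValueError("effect_strength must be >= 0")
        if not 0 <= self.missing_signature_fraction < 1:
            raise ValueError("missing_signature_fraction must be in [0, 1)")


@dataclass
class SyntheticData:
    assoc: GeneAssociationTable
    disease: DiseaseSignature
    drug_targets: DrugTargetTable
    signatures: DrugSignatureMatrix
    annotation: DrugSetAnnotation
    truth: list[str] = field(default_factory=list)
    planted_genes: list[str] = field(default_factory=list)


def generate(spec: GeneratorSpec) -> SyntheticData:
    """Generate one phenotype's worth of inputs; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    drugs = [f"drug{j:04d}" for j in range(spec.n_drugs)]

    # --- gene-level association p-values: uniform null + planted low-p tail
    n_planted = min(max(10, round(0.025 * spec.n_genes)), spec.n_genes)
    planted_idx = rng.choice(spec.n_genes, size=n_planted, replace=False)
    p = rng.uniform(size=spec.n_genes)
    p[planted_idx] = rng.beta(0.1, 20.0, size=n_planted)
    p = np.clip(p, 1e-300, 1.0)
    z = p_to_z(p)
    assoc = GeneAssociationTable(
        spec.phenotype, pd.DataFrame({"gene_id": genes, "p_value": p, "z_stat": z})
    )

    # --- disease signature: |effect| tracks association strength, random sign
    signs = rng.choice([-1.0, 1.0], size=spec.n_genes)
    effect = signs * np.abs(z) + rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
    disease = DiseaseSignature(
        spec.phenotype, pd.DataFrame({"gene_id": genes, "effect": effect})
    )

    # --- effective drugs and drug-target structure
    effective = sorted(rng.choice(drugs, size=spec.n_effective, replace=False).tolist())
    eff_set = set(effective)
    planted_mask = np.zeros(spec.n_genes, dtype=bool)
    planted_mask[planted_idx] = True
    lo, hi = spec.target_count_range
    # planted genes are preferentially targeted by effective drugs, with a
    # preference that vanishes at effect_strength = 0
    weights_eff = np.where(planted_mask, 1.0 + 10.0 * spec.effect_strength, 1.0)
    weights_eff = weights_eff / weights_eff.sum()
    rows = []
    for drug in drugs:
        k = int(rng.integers(lo, hi + 1))
        if drug in eff_set:
            t_idx = rng.choice(spec.n_genes, size=k, replace=False, p=weights_eff)
        else:
            t_idx = rng.choice(spec.n_genes, size=k, replace=False)
        affinity = rng.uniform(4.0, 9.0, size=k)
        if drug in eff_set:
            affinity = affinity + spec.effect_strength * planted_mask[t_idx]
        for i, a in zip(t_idx, affinity):
            rows.append((drug, genes[int(i)], float(a)))
    drug_targets = DrugTargetTable(
        pd.DataFrame(rows, columns=["drug_id", "gene_id", "affinity_weight"])
    )

    # --- drug-induced signatures: effective drugs reverse the disease vector
    non_eff = [d for d in drugs if d not in eff_set]
    n_missing = round(spec.missing_signature_fraction * len(non_eff))
    missing = set(rng.choice(non_eff, size=n_missing, replace=False).tolist())
    sig_drugs = [d for d in drugs if d not in missing]
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, len(sig_drugs)))
    for j, d in enumerate(sig_drugs):
        if d in eff_set:
            values[:, j] -= spec.effect_strength * effect
    signatures = DrugSignatureMatrix(genes, sig_drugs, values)

    half = len(effective) // 2
    annotation = DrugSetAnnotation(
        {
            "ASM": list(effective),
            "more_effective": effective[:half],
            "less_effective": effective[half:],
        }
    )
    return SyntheticData(
        assoc,
        disease,
        drug_targets,
        signatures,
        annotation,
        truth=list(effective),
        planted_genes=[genes[int(i)] for i in sorted(planted_idx)],
    )


def write_fixture_dir(data: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    """Write the standard input files for one phenotype into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_associations": outdir / "gene_associations.tsv",
        "disease_signature": outdir / "disease_signature.tsv",
        "drug_targets": outdir / "drug_targets.tsv",
        "drug_signatures": outdir / "drug_signatures.tsv",
        "drug_sets": outdir / "drug_sets.yaml",
        "truth": outdir / "truth.txt",
    }
    data.assoc.records[["gene_id", "p_value"]].to_csv(
        paths["gene_associations"], sep="\t", index=False, float_format="%.12g"
    )
    data.disease.records.to_csv(
        paths["disease_signature"], sep="\t", index=False, float_format="%.12g"
    )
    data.drug_targets.records.rename(columns={"affinity_weight": "affinity"}).to_csv(
        paths["drug_targets"], sep="\t", index=False, float_format="%.12g"
    )
    wide = data.signatures.to_frame()
    wide.index.name = "gene_id"
    wide.to_csv(paths["drug_signatures"], sep="\t", float_format="%.12g")
    with open(paths["drug_sets"], "w") as fh:
        yaml.safe_dump({k: list(v) for k, v in data.annotation.sets.items()}, fh)
    paths["truth"].write_text("\n".join(data.truth) + "\n")
    return paths
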