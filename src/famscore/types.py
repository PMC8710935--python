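"""Core data containers shared across the scoring pipeline.

Each container wraps a validated :class:`pandas.DataFrame` (or ndarray) with
the identifier conventions used throughout the package:

* gene identifiers are uppercased symbols (or stable IDs), joined across
  sources by exact string match after normalization;
* drug identifiers are lowercased names with punctuation and whitespace
  stripped.

Validation happens at construction so downstream scoring code can assume
clean inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_gene_id",
    "normalize_drug_id",
    "p_to_z",
    "GeneAssociationTable",
    "DiseaseSignature",
    "DrugTargetTable",
    "DrugSignatureMatrix",
    "DrugSetAnnotation",
    "DrugScoreTable",
    "ValidationError",
    "FormatError",
]

#: p-values below this are clamped before the inverse-normal transform so the
#: resulting z-statistic stays finite.
P_FLOOR = 1e-300

_DRUG_PUNCT = re.compile(r"[^a-z0-9]+")


class ValidationError(ValueError):
    """Raised when input values violate a container invariant."""


class FormatError(ValueError):
    """Raised when an input file lacks required structure (columns, labels)."""


def normalize_gene_id(gene: str) -> str:
    """Uppercase and strip a gene symbol/ID. Idempotent."""
    return str(gene).strip().upper()


def normalize_drug_id(drug: str) -> str:
    """Lowercase a drug name and strip punctuation/whitespace. Idempotent."""
    return _DRUG_PUNCT.sub("", str(drug).strip().lower())


def p_to_z(p: np.ndarray | float, convention: str = "one_sided") -> np.ndarray | float:
    """Convert association p-values to z-statistics.

    ``one_sided`` (the package convention) maps p to ``Phi^{-1}(1 - p)`` so a
    larger z means stronger disease association; p = 0.5 maps to z = 0.
    p-values below :data:`P_FLOOR` are clamped first.
    """
    if convention != "one_sided":
        raise ValueError(f"unknown p-to-z convention: {convention!r}")
    p = np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0)
    out = stats.norm.isf(p)  # isf(p) == ppf(1 - p), accurate for tiny p
    return float(out) if out.ndim == 0 else out


@dataclass
class GeneAssociationTable:
    """Per-gene disease-association p-values and z-statistics for a phenotype.

    ``records`` columns: ``gene_id`` (normalized, unique), ``p_value`` in
    (0, 1], ``z_stat`` under the table's declared p-to-z convention.
    """

    phenotype: str
    records: pd.DataFrame
    convention: str = "one_sided"

    def __post_init__(self) -> None:
        df = self.records
        required = {"gene_id", "p_value", "z_stat"}
        if not required.issubset(df.columns):
            raise FormatError(f"gene association table needs columns {sorted(required)}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id {dup!r}")
        p = df["p_value"].to_numpy(dtype=float)
        if np.isnan(p).any():
            raise ValidationError("missing p_value")
        bad = np.flatnonzero((p <= 0) | (p > 1))
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"p_value out of (0, 1] at row {i} (gene {df['gene_id'].iloc[i]!r}): {p[i]}"
            )
        self.records = df.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return self.records["gene_id"].tolist()

    def z_by_gene(self) -> pd.Series:
        return self.records.set_index("gene_id")["z_stat"]

    def drop_genes(self, genes: set[str]) -> "GeneAssociationTable":
        keep = ~self.records["gene_id"].isin(genes)
        return GeneAssociationTable(
            self.phenotype, self.records.loc[keep].reset_index(drop=True), self.convention
        )


@dataclass
class DiseaseSignature:
    """Signed per-gene abundance-change statistics for a phenotype.

    Positive effect = abundance increased in disease; negative = decreased.
    """

    phenotype: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        if not {"gene_id", "effect"}.issubset(df.columns):
            raise FormatError("disease signature needs columns ['gene_id', 'effect']")
        if len(df) == 0:
            raise ValidationError("empty signature")
        if df["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in disease signature")
        eff = df["effect"].to_numpy(dtype=float)
        if not np.isfinite(eff).all():
            raise ValidationError("non-finite effect in disease signature")
        if not np.any(eff != 0):
            raise ValidationError("disease signature has no nonzero effect")
        self.records = df.reset_index(drop=True)

    def effect_by_gene(self) -> pd.Series:
        return self.records.set_index("gene_id")["effect"]

    def drop_genes(self, genes: set[str]) -> "DiseaseSignature":
        keep = ~self.records["gene_id"].isin(genes)
        return DiseaseSignature(self.phenotype, self.records.loc[keep].reset_index(drop=True))


@dataclass
class DrugTargetTable:
    """Sparse drug -> (target gene, affinity weight) mapping.

    ``affinity_weight`` is nonnegative on a declared potency scale (e.g.
    pAffinity); (drug, gene) pairs are unique; every drug has >= 1 target.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        if not {"drug_id", "gene_id", "affinity_weight"}.issubset(df.columns):
            raise FormatError(
                "drug-target table needs columns ['drug_id', 'gene_id', 'affinity_weight']"
            )
        if df.duplicated(["drug_id", "gene_id"]).any():
            raise ValidationError("duplicate (drug_id, gene_id) pair")
        w = df["affinity_weight"].to_numpy(dtype=float)
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValidationError("affinity_weight must be finite and >= 0")
        self.records = df.reset_index(drop=True)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.records["drug_id"].unique())

    def targets_of(self, drug_id: str) -> pd.DataFrame:
        return self.records[self.records["drug_id"] == drug_id]

    def drop_genes(self, genes: set[str]) -> "DrugTargetTable":
        keep = ~self.records["gene_id"].isin(genes)
        out = self.records.loc[keep].reset_index(drop=True)
        if len(out) == 0:
            raise ValidationError("gene exclusion removed every drug-target row")
        return DrugTargetTable(out)


@dataclass
class DrugSignatureMatrix:
    """Genes x drugs matrix of signed expression-change statistics.

    Cells may be NaN (gene not measured for that drug); NaN cells are excluded
    from overlap computations. Drugs never assayed are simply absent.
    """

    genes: list[str]
    drugs: list[str]
    values: np.ndarray  # shape (n_genes, n_drugs), float, NaN = missing

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene row label in signature matrix")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValidationError("duplicate drug column label in signature matrix")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.drugs)):
            raise ValidationError(
                f"signature matrix shape {self.values.shape} does not match labels "
                f"({len(self.genes)}, {len(self.drugs)})"
            )
        if np.isinf(self.values).any():
            raise ValidationError("infinite value in signature matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.drugs)

    def drop_genes(self, genes: set[str]) -> "DrugSignatureMatrix":
        keep = [i for i, g in enumerate(self.genes) if g not in genes]
        return DrugSignatureMatrix(
            [self.genes[i] for i in keep], list(self.drugs), self.values[keep, :]
        )


@dataclass
class DrugSetAnnotation:
    """Named drug-sets (e.g. "ASM", "more_effective") used for evaluation.

    Drug ids are normalized at construction; sets may overlap.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {
            name: [normalize_drug_id(d) for d in drugs] for name, drugs in self.sets.items()
        }

    def resolve(self, name: str, universe: set[str]) -> list[str]:
        """Members of set ``name`` present in ``universe`` (scored drugs)."""
        if name not in self.sets:
            raise KeyError(f"unknown drug-set {name!r}")
        return [d for d in self.sets[name] if d in universe]


@dataclass
class DrugScoreTable:
    """Ranked per-drug FM/AC/FAM z-scores with percentile ranks.

    ``fam`` is present iff both ``fm_z`` and ``ac_z`` are present; rank 1 is
    best; percentile 100 means ranked above every other scored drug.
    """

    phenotype: str
    rows: pd.DataFrame

    COLUMNS = ["drug_id", "fm_z", "ac_z", "fam", "rank", "percentile"]

    def __post_init__(self) -> None:
        df = self.rows
        if not set(self.COLUMNS).issubset(df.columns):
            raise FormatError(f"drug score table needs columns {self.COLUMNS}")
        if df["drug_id"].duplicated().any():
            raise ValidationError("duplicate drug_id in score table")
        fam_present = df["fam"].notna()
        both = df["fm_z"].notna() & df["ac_z"].notna()
        if not (fam_present == both).all():
            raise ValidationError("fam must be present iff both fm_z and ac_z are present")
        scored = df.loc[fam_present]
        if len(scored):
            ranks = np.sort(scored["rank"].to_numpy(dtype=float))
            if not np.array_equal(ranks, np.arange(1, len(scored) + 1)):
                raise ValidationError("ranks must be a permutation of 1..n over scored drugs")
        self.rows = df[self.COLUMNS].reset_index(drop=True)

    @property
    def scored(self) -> pd.DataFrame:
        """Rows carrying a FAM score, sorted by rank."""
        return self.rows[self.rows["fam"].notna()].sort_values("rank").reset_index(drop=True)

    def percentile_by_drug(self) -> pd.Series:
        return self.scored.set_index("drug_id")["percentile"]

    def rank_by_drug(self) -> pd.Series:
        return self.scored.set_index("drug_id")["rank"]
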