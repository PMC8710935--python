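"""Readers and writers for the tabular/matrix inputs and ranked outputs.

All tabular inputs are TSV/CSV with headers (separator sniffed from the file).
Drug signatures may be a wide matrix (first column genes, remaining columns
drugs) or a long triplet file (gene, drug, value). Values round-trip at 12
significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DiseaseSignature,
    DrugScoreTable,
    DrugSignatureMatrix,
    DrugTargetTable,
    FormatError,
    GeneAssociationTable,
    ValidationError,
    normalize_drug_id,
    normalize_gene_id,
    p_to_z,
)

log = logging.getLogger(__name__)

_GENE_COLS = ("gene_id", "gene", "symbol", "gene_symbol", "id")
_P_COLS = ("p_value", "pvalue", "p", "pval", "p.value")
_EFFECT_COLS = ("effect", "z", "zscore", "z_score", "twas_z", "stat", "beta")
_DRUG_COLS = ("drug_id", "drug", "compound", "name")
_TARGET_COLS = ("gene_id", "target", "gene", "symbol")
_AFFINITY_COLS = ("affinity", "affinity_weight", "paffinity", "ki", "kd", "ic50", "value")

#: raw-affinity -> nonnegative weight transforms, keyed by tag
AFFINITY_TRANSFORMS = {
    "identity": lambda x: x,
    # raw value in nanomolar concentration -> pAffinity = -log10(molar)
    "neglog10_nanomolar": lambda x: -np.log10(x * 1e-9),
    # raw value already in molar
    "neglog10_molar": lambda x: -np.log10(x),
}


def _read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _find_column(df: pd.DataFrame, candidates: tuple[str, ...], what: str) -> str:
    lower = {str(c).strip().lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise FormatError(f"no {what} column found (looked for one of {list(candidates)})")


def read_gene_associations(
    path: str | Path, convention: str = "one_sided", phenotype: str = ""
) -> GeneAssociationTable:
    """Read a gene-level association table (gene, p-value) and derive z-stats.

    Duplicate gene rows are collapsed to the smallest p-value; z-statistics
    are populated under ``convention`` (default ``one_sided``:
    z = Phi^{-1}(1-p), larger z = stronger association).
    """
    df = _read_table(path)
    gcol = _find_column(df, _GENE_COLS, "gene")
    pcol = _find_column(df, _P_COLS, "p-value")
    out = pd.DataFrame(
        {
            "gene_id": df[gcol].map(normalize_gene_id),
            "p_value": pd.to_numeric(df[pcol], errors="raise"),
        }
    )
    p = out["p_value"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.isnan(p) | (p <= 0) | (p > 1))
    if bad.size:
        i = int(bad[0])
        raise ValidationError(
            f"invalid p_value at input row {i} (gene {out['gene_id'].iloc[i]!r}): {p[i]}"
        )
    # min-p collapse for duplicated genes, order-independent
    out = out.sort_values(["gene_id", "p_value"], kind="stable").drop_duplicates(
        "gene_id", keep="first"
    )
    out = out.sort_values("gene_id", kind="stable").reset_index(drop=True)
    out["z_stat"] = p_to_z(out["p_value"].to_numpy(), convention)
    return GeneAssociationTable(phenotype or Path(path).stem, out, convention)


def read_disease_signature(path: str | Path, phenotype: str = "") -> DiseaseSignature:
    """Read a signed per-gene disease signature (gene, effect)."""
    df = _read_table(path)
    if len(df) == 0:
        raise ValidationError("empty signature")
    gcol = _find_column(df, _GENE_COLS, "gene")
    ecol = _find_column(df, _EFFECT_COLS, "effect")
    try:
        effect = pd.to_numeric(df[ecol], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric effect in {path}: {exc}") from exc
    out = pd.DataFrame({"gene_id": df[gcol].map(normalize_gene_id), "effect": effect})
    out = out.drop_duplicates("gene_id").sort_values("gene_id", kind="stable")
    return DiseaseSignature(phenotype or Path(path).stem, out.reset_index(drop=True))


def read_drug_targets(
    path: str | Path,
    affinity_transform: str = "identity",
    synonyms: dict[str, str] | None = None,
) -> DrugTargetTable:
    """Read a long-format drug-target table and map affinities to weights.

    ``affinity_transform`` is a tag from :data:`AFFINITY_TRANSFORMS`.
    Duplicate (drug, target) rows collapse to the maximum weight. An optional
    ``synonyms`` mapping is applied to drug names before normalization.
    """
    if affinity_transform not in AFFINITY_TRANSFORMS:
        raise ValueError(f"unknown affinity transform {affinity_transform!r}")
    transform = AFFINITY_TRANSFORMS[affinity_transform]
    df = _read_table(path)
    dcol = _find_column(df, _DRUG_COLS, "drug")
    tcol = _find_column(df, _TARGET_COLS, "target")
    acol = _find_column(df, _AFFINITY_COLS, "affinity")
    raw = pd.to_numeric(df[acol], errors="raise").to_numpy(dtype=float)
    if affinity_transform.startswith("neglog10") and (raw <= 0).any():
        raise ValidationError("non-positive raw affinity under a log transform")
    names = df[dcol].astype(str)
    if synonyms:
        names = names.map(lambda n: synonyms.get(n, n))
    out = pd.DataFrame(
        {
            "drug_id": names.map(normalize_drug_id),
            "gene_id": df[tcol].map(normalize_gene_id),
            "affinity_weight": transform(raw),
        }
    )
    if (out["affinity_weight"] < 0).any():
        raise ValidationError("negative affinity_weight after transform")
    # max-weight collapse for duplicated pairs, order-independent
    out = (
        out.groupby(["drug_id", "gene_id"], as_index=False)["affinity_weight"]
        .max()
        .sort_values(["drug_id", "gene_id"], kind="stable")
        .reset_index(drop=True)
    )
    return DrugTargetTable(out)


def read_signature_matrix(path: str | Path) -> DrugSignatureMatrix:
    """Read a drug-signature matrix, wide (genes x drugs) or long triplets.

    A long file has exactly the columns (gene, drug, value) recognizable by
    name; anything else is treated as wide with genes in the first column.
    Cells absent from a long file become NaN (missing). All-zero drug columns
    are retained but logged.
    """
    df = _read_table(path)
    lower = [str(c).strip().lower() for c in df.columns]
    is_long = (
        len(df.columns) == 3
        and any(c in _GENE_COLS for c in lower)
        and any(c in _DRUG_COLS for c in lower)
    )
    if is_long:
        gcol = _find_column(df, _GENE_COLS, "gene")
        dcol = _find_column(df, _DRUG_COLS, "drug")
        vcol = next(c for c in df.columns if c not in (gcol, dcol))
        long = pd.DataFrame(
            {
                "gene_id": df[gcol].map(normalize_gene_id),
                "drug_id": df[dcol].map(normalize_drug_id),
                "value": pd.to_numeric(df[vcol], errors="raise"),
            }
        )
        if long.duplicated(["gene_id", "drug_id"]).any():
            raise FormatError("duplicated (gene, drug) cell in long signature file")
        wide = long.pivot(index="gene_id", columns="drug_id", values="value")
    else:
        gene_col = df.columns[0]
        drug_cols = list(df.columns[1:])
        norm_drugs = [normalize_drug_id(c) for c in drug_cols]
        if len(set(norm_drugs)) != len(norm_drugs):
            raise FormatError("duplicated drug column in signature matrix")
        wide = df.set_index(gene_col)
        wide.index = wide.index.map(normalize_gene_id)
        wide.columns = norm_drugs
        wide = wide.astype(float)
        if wide.index.duplicated().any():
            raise FormatError("duplicated gene row in signature matrix")
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    values = wide.to_numpy(dtype=float)
    zero_cols = [d for j, d in enumerate(wide.columns) if np.nansum(np.abs(values[:, j])) == 0]
    if zero_cols:
        log.warning("signature matrix: all-zero columns retained: %s", zero_cols)
    return DrugSignatureMatrix(list(wide.index), list(wide.columns), values)


def write_score_table(table: DrugScoreTable, path: str | Path) -> None:
    """Write a ranked drug-score table as TSV (rank-sorted, 12 sig digits)."""
    df = table.rows.copy()
    order = df["rank"].fillna(np.inf)
    df = (
        df.assign(_o=order)
        .sort_values(["_o", "drug_id"], kind="stable")
        .drop(columns="_o")
        .reset_index(drop=True)
    )
    with open(path, "w") as fh:
        fh.write("# phenotype=" + table.phenotype + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_score_table(path: str | Path) -> DrugScoreTable:
    """Read a table written by :func:`write_score_table`."""
    phenotype = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# phenotype="):
            phenotype = first[len("# phenotype=") :].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    if len(df) and df["rank"].notna().any():
        df["rank"] = df["rank"].astype("float")
    df["drug_id"] = df["drug_id"].astype(str)
    return DrugScoreTable(phenotype, df)
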