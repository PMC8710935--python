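"""Abundance Correction (AC) score.

A drug's AC score measures how well its induced transcriptomic signature
reverses the disease's signed abundance-change signature. For each drug the
cosine distance

    d = 1 - (u . v) / (||u|| ||v||)   in [0, 2]

is computed between the disease vector u and the drug vector v over their
shared genes; d = 2 means perfect reversal. Distances are standardized across
drugs into ac_z, oriented so that higher = more corrective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import DiseaseSignature, DrugSignatureMatrix

log = logging.getLogger(__name__)

__all__ = ["AcResult", "cosine_distance", "ac_scores"]

DEFAULT_MIN_OVERLAP = 10


@dataclass
class AcResult:
    """Per-drug cosine distance to the disease signature and its z-score.

    ``table`` columns: drug_id, cosine_distance, n_overlap, ac_z.
    """

    table: pd.DataFrame

    def ac_z_by_drug(self) -> pd.Series:
        return self.table.set_index("drug_id")["ac_z"]


def cosine_distance(disease_vec: np.ndarray, drug_vec: np.ndarray) -> float:
    """Cosine distance 1 - cos(u, v) in [0, 2] between two signed vectors."""
    u = np.asarray(disease_vec, dtype=float)
    v = np.asarray(drug_vec, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must share support")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate vector: zero norm")
    return float(np.clip(1.0 - (u @ v) / (nu * nv), 0.0, 2.0))


def _collapse_replicates(signatures: DrugSignatureMatrix) -> pd.DataFrame:
    """Per-gene median over replicate columns sharing a drug id (robust collapse)."""
    df = signatures.to_frame()
    if df.columns.duplicated().any():
        df = df.T.groupby(level=0).median().T
    return df


def ac_scores(
    disease: DiseaseSignature,
    signatures: DrugSignatureMatrix,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> AcResult:
    """Cosine distance of every drug signature to the disease signature.

    Each drug is scored over the genes present (non-missing) in both its
    signature column and the disease signature; drugs with fewer than
    ``min_overlap`` shared genes are excluded and logged. The distances are
    z-scored across scored drugs (larger distance = more anti-correlated =
    more corrective = higher ac_z).
    """
    eff = disease.effect_by_gene()
    mat = _collapse_replicates(signatures)
    shared_genes = mat.index.intersection(eff.index)
    mat = mat.loc[shared_genes]
    u_all = eff.loc[shared_genes].to_numpy(dtype=float)

    records = []
    dropped = []
    for drug_id in mat.columns:
        v = mat[drug_id].to_numpy(dtype=float)
        mask = ~np.isnan(v)
        n_overlap = int(mask.sum())
        if n_overlap < min_overlap:
            dropped.append(drug_id)
            continue
        u = u_all[mask]
        vv = v[mask]
        if np.linalg.norm(u) == 0 or np.linalg.norm(vv) == 0:
            dropped.append(drug_id)
            continue
        records.append((drug_id, cosine_distance(u, vv), n_overlap))
    if dropped:
        log.info("ac_scores: %d drugs below min_overlap=%d or degenerate: %s",
                 len(dropped), min_overlap, dropped[:20])
    if len(records) < 2:
        raise ValueError(
            f"fewer than 2 drugs pass min_overlap={min_overlap}; cannot standardize"
        )
    table = pd.DataFrame(records, columns=["drug_id", "cosine_distance", "n_overlap"])
    d = table["cosine_distance"].to_numpy()
    sd = d.std(ddof=0)
    if sd == 0:
        log.warning("zero variance in cosine distances; ac_z set to 0 for all drugs")
        table["ac_z"] = 0.0
    else:
        table["ac_z"] = (d - d.mean()) / sd
    return AcResult(table.reset_index(drop=True))
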