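"""Function Modulation (FM) score.

A drug's FM score aggregates the disease association of each protein whose
function the drug modulates, weighted by how strongly the drug binds it:

    raw_fm(d) = (1/k_d) * sum_{t in targets(d)} w_t * z_t

where w_t is the drug-target affinity weight normalized by the largest weight
in the whole table, z_t the gene-level association z-statistic, and k_d the
number of the drug's targets present in the association table. Because drugs
with many targets accumulate signal by size alone, raw scores are standardized
against a size-matched permutation null (random target-sets of size k_d drawn
from all association genes, reusing the drug's own weights), then z-scored
across drugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import DrugTargetTable, GeneAssociationTable

log = logging.getLogger(__name__)

__all__ = ["FmResult", "UNSCOREABLE", "raw_fm", "size_adjust", "fm_scores"]

#: sentinel for drugs with no scoreable target
UNSCOREABLE = None

DEFAULT_N_PERM = 10_000


@dataclass
class FmResult:
    """Per-drug raw, size-adjusted and standardized FM scores.

    ``table`` columns: drug_id, raw_fm, size_adjusted_fm, fm_z,
    n_targets_scored. fm_z has mean 0 / unit variance over scored drugs.
    """

    table: pd.DataFrame

    def fm_z_by_drug(self) -> pd.Series:
        return self.table.set_index("drug_id")["fm_z"]


def _normalized_weights(drug_targets: DrugTargetTable) -> pd.DataFrame:
    df = drug_targets.records.copy()
    wmax = df["affinity_weight"].max()
    if wmax <= 0:
        # all-zero affinities: every target contributes equally
        df["w_norm"] = 1.0
        return df
    df["w_norm"] = df["affinity_weight"] / wmax
    return df


def _scoreable(
    drug_targets: DrugTargetTable, assoc: GeneAssociationTable
) -> tuple[pd.DataFrame, pd.Series]:
    """Target rows restricted to association genes, with normalized weights."""
    z = assoc.z_by_gene()
    df = _normalized_weights(drug_targets)
    in_assoc = df["gene_id"].isin(z.index)
    skipped = df.loc[~in_assoc].groupby("drug_id").size()
    if len(skipped):
        log.info("targets absent from association table, per drug: %s", skipped.to_dict())
    return df.loc[in_assoc].reset_index(drop=True), z


def raw_fm(drug_targets: DrugTargetTable, assoc: GeneAssociationTable, drug_id: str):
    """Raw FM score for one drug, or the unscoreable sentinel.

    Mean over the drug's scoreable targets of normalized affinity weight times
    the gene z-statistic.
    """
    rows, z = _scoreable(drug_targets, assoc)
    rows = rows[rows["drug_id"] == drug_id]
    if len(rows) == 0:
        return UNSCOREABLE
    return float(
        (rows["w_norm"].to_numpy() * z.loc[rows["gene_id"]].to_numpy()).sum() / len(rows)
    )


def _null_permutation_matrix(
    rng: np.random.Generator, n_genes: int, max_k: int, n_perm: int
) -> np.ndarray:
    """n_perm random permutations of gene indices, truncated to max_k columns.

    The first k columns of a uniform random permutation are a uniform random
    k-subset, so one matrix serves every target-set size.
    """
    perm = np.argsort(rng.random((n_perm, n_genes)), axis=1)
    return perm[:, :max_k].astype(np.int32)


def size_adjust(
    raw_scores: dict[str, float],
    assoc: GeneAssociationTable,
    drug_targets: DrugTargetTable,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> dict[str, float]:
    """Standardize each raw FM score against its size-matched permutation null.

    For a drug with k scoreable targets the null draws ``n_perm`` target-sets
    of size k uniformly without replacement from all association genes, scores
    them with the drug's own normalized weights, and returns
    (raw - null_mean) / null_sd. The null permutation draws are shared across
    drugs (valid per drug; deterministic given ``seed``). A degenerate null
    (sd = 0, e.g. k equals the gene universe) maps to 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rows, z = _scoreable(drug_targets, assoc)
    z_arr = z.to_numpy(dtype=float)
    n_genes = len(z_arr)
    groups = {d: g for d, g in rows.groupby("drug_id") if d in raw_scores}
    if not groups:
        return {}
    max_k = min(max(len(g) for g in groups.values()), n_genes)
    rng = np.random.default_rng(seed)
    perm = _null_permutation_matrix(rng, n_genes, max_k, n_perm)
    null_z = z_arr[perm]  # (n_perm, max_k)
    adjusted: dict[str, float] = {}
    for drug_id, g in groups.items():
        w = g["w_norm"].to_numpy(dtype=float)
        k = len(w)
        null_vals = null_z[:, :k] @ w / k
        mu = float(null_vals.mean())
        sd = float(null_vals.std(ddof=1))
        r = raw_scores[drug_id]
        # degenerate null (k = whole gene universe): sd is 0 up to rounding
        degenerate = sd <= 1e-12 * max(1.0, abs(mu))
        adjusted[drug_id] = 0.0 if degenerate else (r - mu) / sd
    return adjusted


def fm_scores(
    drug_targets: DrugTargetTable,
    assoc: GeneAssociationTable,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> FmResult:
    """Compute raw, size-adjusted and across-drug standardized FM scores."""
    rows, z = _scoreable(drug_targets, assoc)
    z_vals = z.loc[rows["gene_id"]].to_numpy()
    contrib = rows["w_norm"].to_numpy() * z_vals
    per_drug = pd.DataFrame({"drug_id": rows["drug_id"], "contrib": contrib}).groupby("drug_id")
    raw = per_drug["contrib"].mean()
    n_scored = per_drug.size()
    if len(raw) < 2:
        raise ValueError("insufficient drugs: need >= 2 scoreable drugs")
    adjusted = size_adjust(raw.to_dict(), assoc, drug_targets, n_perm=n_perm, seed=seed)
    adj = pd.Series(adjusted).loc[raw.index]
    sd = adj.std(ddof=0)
    if sd == 0:
        log.warning("zero variance in size-adjusted FM scores; fm_z set to 0 for all drugs")
        fm_z = pd.Series(0.0, index=adj.index)
    else:
        fm_z = (adj - adj.mean()) / sd
    out = pd.DataFrame(
        {
            "drug_id": raw.index,
            "raw_fm": raw.to_numpy(),
            "size_adjusted_fm": adj.to_numpy(),
            "fm_z": fm_z.to_numpy(),
            "n_targets_scored": n_scored.to_numpy(),
        }
    ).reset_index(drop=True)
    return FmResult(out)
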