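"""FAM score: integration of the FM and AC z-scores into a drug ranking.

fam = (fm_z + ac_z) / 2 for drugs carrying both scores. Drugs are ranked by
descending fam (rank 1 = best, ties broken lexicographically by drug id) and
ranks converted to percentiles: percentile = 100 * (n - rank) / (n - 1), so
the top drug of n scored drugs sits at 100 and the bottom at 0, and a drug at
percentile 90 is ranked above 90% of all scored drugs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ac import AcResult
from .fm import FmResult
from .types import DrugScoreTable, normalize_drug_id

__all__ = ["fam_scores", "top_candidates", "TopCandidates"]


def fam_scores(fm: FmResult, ac: AcResult, phenotype: str = "") -> DrugScoreTable:
    """Average FM and AC z-scores into FAM and build the ranked score table.

    Drugs present in only one of the two inputs are retained with the score
    they have but carry no FAM, no rank and no percentile.
    """
    fm_z = fm.fm_z_by_drug()
    ac_z = ac.ac_z_by_drug()
    drugs = sorted(set(fm_z.index) | set(ac_z.index))
    df = pd.DataFrame({"drug_id": drugs})
    df["fm_z"] = df["drug_id"].map(fm_z)
    df["ac_z"] = df["drug_id"].map(ac_z)
    both = df["fm_z"].notna() & df["ac_z"].notna()
    if not both.any():
        raise ValueError("no drug carries both an FM and an AC score")
    df["fam"] = np.where(both, (df["fm_z"] + df["ac_z"]) / 2.0, np.nan)
    scored = df.loc[both].sort_values(
        ["fam", "drug_id"], ascending=[False, True], kind="stable"
    )
    n = len(scored)
    ranks = pd.Series(np.arange(1, n + 1, dtype=float), index=scored.index)
    df["rank"] = ranks.reindex(df.index)
    if n > 1:
        df["percentile"] = 100.0 * (n - df["rank"]) / (n - 1)
    else:
        df["percentile"] = np.where(df["rank"].notna(), 100.0, np.nan)
    return DrugScoreTable(phenotype, df)


@dataclass
class TopCandidates:
    """Demarcation of the top predictions by effective-drug enrichment.

    ``k`` is the ranked-list cutoff minimizing the one-sided hypergeometric
    enrichment p-value of the effective set among the top k; ``drugs`` are the
    top-k drugs; ``significant`` is False when even the best cutoff shows no
    enrichment at BH-adjusted p < 0.05.
    """

    k: int
    p_value: float
    p_adjusted: float
    drugs: list[str]
    significant: bool


def top_candidates(
    table: DrugScoreTable, effective_set: list[str], alpha: float = 0.05
) -> TopCandidates:
    """Find the ranked-list cutoff with the greatest effective-drug enrichment.

    Scans every cutoff k = 1..n of the FAM ranking, computes the one-sided
    hypergeometric tail P(X >= x) for x effective drugs among the top k, and
    returns the k with the smallest p (smallest k on ties). The minimal p is
    BH-corrected for the n cutoffs scanned.
    """
    scored = table.scored
    n = len(scored)
    eff = {normalize_drug_id(d) for d in effective_set}
    if not eff:
        raise ValueError("effective_set empty after normalization")
    member = scored["drug_id"].isin(eff).to_numpy()
    m = int(member.sum())
    if m == 0:
        raise ValueError("no member of effective_set is scored")
    cum = np.cumsum(member)
    ks = np.arange(1, n + 1)
    # P(X >= x) with X ~ Hypergeom(N=n, K=m, draws=k)
    pvals = stats.hypergeom.sf(cum - 1, n, m, ks)
    best = int(np.argmin(pvals))  # argmin returns the first (smallest k) on ties
    p_best = float(pvals[best])
    from .evaluation import bh_correct

    p_adj = float(bh_correct(list(pvals))[best])
    return TopCandidates(
        k=best + 1,
        p_value=p_best,
        p_adjusted=p_adj,
        drugs=scored["drug_id"].iloc[: best + 1].tolist(),
        significant=bool(p_adj < alpha),
    )
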