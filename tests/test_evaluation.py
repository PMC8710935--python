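"""Validation machinery: AUROC, under-sampling, permutation p-values, BH,
baseline methods."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famscore.evaluation import (
    auroc,
    bh_correct,
    gene_set_ttest,
    median_percentile,
    permutation_pvalue,
    rank_drugs_by_gene_set_ttest,
    standard_method_baseline,
    undersampled_auroc,
)
from famscore.fam import fam_scores

from .conftest import make_assoc, make_targets
from .test_fam import _ac, _fm


def brute_force_auroc(pos, neg):
    """Concordant-pair counting oracle: ties count 1/2."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        s = {"p1": 3.0, "p2": 2.5, "n1": 1.0, "n2": 0.5}
        assert auroc(s, ["p1", "p2"], ["n1", "n2"]) == 1.0

    def test_all_ties(self):
        s = {d: 1.0 for d in "abcdef"}
        assert auroc(s, list("abc"), list("def")) == 0.5

    @given(st.data())
    @settings(max_examples=60, derandomize=True)
    def test_matches_pair_counting_oracle(self, data):
        npos = data.draw(st.integers(1, 5))
        nneg = data.draw(st.integers(1, 5))
        vals = data.draw(
            st.lists(
                st.integers(0, 6).map(float), min_size=npos + nneg, max_size=npos + nneg
            )
        )
        scores = {f"d{i}": v for i, v in enumerate(vals)}
        pos = [f"d{i}" for i in range(npos)]
        neg = [f"d{i}" for i in range(npos, npos + nneg)]
        expected = brute_force_auroc(vals[:npos], vals[npos:])
        assert auroc(scores, pos, neg) == pytest.approx(expected, abs=1e-12)

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=12)
        scores = pd.Series(vals, index=[f"d{i}" for i in range(12)])
        pos, neg = [f"d{i}" for i in range(5)], [f"d{i}" for i in range(5, 12)]
        assert auroc(scores, pos, neg) + auroc(-scores, pos, neg) == pytest.approx(1.0)

    def test_overlapping_sets_error(self):
        s = {"a": 1.0, "b": 2.0}
        with pytest.raises(ValueError, match="overlap"):
            auroc(s, ["a"], ["a", "b"])


class TestUndersampledAuroc:
    def test_perfect_positives(self):
        scores = {f"p{i}": 100.0 + i for i in range(4)}
        scores.update({f"n{i}": float(i) for i in range(20)})
        res = undersampled_auroc(scores, [f"p{i}" for i in range(4)], list(scores), n_reps=50, seed=0)
        assert res.mean_auroc == 1.0 and res.sd_auroc == 0.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=200), index=[f"d{i}" for i in range(200)])
        pos = [f"d{i}" for i in range(15)]
        res = undersampled_auroc(scores, pos, list(scores.index), n_reps=400, seed=1)
        assert res.mean_auroc == pytest.approx(0.5, abs=0.15)

    def test_mean_matches_full_cohort_auroc(self, small_signal_scores, small_signal):
        """Undersampled mean converges to the full tie-corrected AUROC."""
        scores = small_signal_scores.scored.set_index("drug_id")["fam"]
        pos = [d for d in small_signal.truth if d in scores.index]
        neg = [d for d in scores.index if d not in set(pos)]
        full = auroc(scores, pos, neg)
        res = undersampled_auroc(scores, pos, list(scores.index), n_reps=1000, seed=2)
        assert res.mean_auroc == pytest.approx(full, abs=0.02)

    def test_insufficient_negatives_error(self):
        scores = {"a": 1.0, "b": 2.0, "c": 3.0}
        with pytest.raises(ValueError, match="insufficient"):
            undersampled_auroc(scores, ["a", "b"], list(scores), n_reps=10, seed=0)


class TestMedianPercentile:
    def test_single_drug(self, small_signal_scores):
        pct = small_signal_scores.percentile_by_drug()
        d = pct.index[0]
        assert median_percentile(small_signal_scores, [d]) == pct[d]

    def test_even_set_midpoint(self):
        zs = {f"d{i}": float(100 - i) for i in range(101)}
        t = fam_scores(_fm(zs), _ac(zs))
        pct = t.percentile_by_drug()
        two = [pct.index[k] for k in (27, 73)]
        expected = (pct[two[0]] + pct[two[1]]) / 2
        assert median_percentile(t, two) == pytest.approx(expected)

    def test_whole_cohort_is_fifty(self, small_signal_scores):
        all_drugs = list(small_signal_scores.scored["drug_id"])
        assert median_percentile(small_signal_scores, all_drugs) == pytest.approx(50.0, abs=1.0)

    def test_unscored_set_errors(self, small_signal_scores):
        with pytest.raises(ValueError):
            median_percentile(small_signal_scores, ["nope"])


class TestPermutationPvalue:
    def test_add_one_floor(self):
        scores = pd.Series(np.arange(20, dtype=float), index=[f"d{i}" for i in range(20)])
        # statistic maximal under the identity assignment: score of d19
        res = permutation_pvalue(
            100.0, lambda s: float(s.iloc[0]), scores, n_perm=200, seed=0, direction="greater"
        )
        assert res.p_value == pytest.approx(1 / 201)

    def test_observed_at_null_center_gives_half(self):
        # subset-mean statistic: its permutation null is symmetric around the
        # grand mean, so an observation right there has p ~ 0.5
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=50), index=[f"d{i}" for i in range(50)])
        obs = float(scores.to_numpy().mean())
        res = permutation_pvalue(
            obs,
            lambda s: float(s.to_numpy()[:10].mean()),
            scores,
            n_perm=400,
            seed=2,
            direction="greater",
        )
        assert res.p_value == pytest.approx(0.5, abs=0.15)

    def test_converges_to_exhaustive_enumeration(self):
        # 4 drugs, statistic = score assigned to drug 'a'; exact p from 4! relabelings
        vals = np.array([0.1, 0.7, 0.4, 0.9])
        scores = pd.Series(vals, index=list("abcd"))
        obs = 0.7
        exact_ge = np.mean(
            [perm[0] >= obs for perm in itertools.permutations(vals)]
        )
        res = permutation_pvalue(
            obs, lambda s: float(s.iloc[0]), scores, n_perm=20_000, seed=3, direction="greater"
        )
        se = np.sqrt(exact_ge * (1 - exact_ge) / 20_000)
        assert res.p_value == pytest.approx(exact_ge, abs=4 * se + 1e-4)

    def test_exchangeability(self):
        """Relabeling drugs leaves the null distribution invariant."""
        rng = np.random.default_rng(4)
        vals = rng.normal(size=12)
        idx = [f"d{i}" for i in range(12)]
        scores = pd.Series(vals, index=idx)
        relabeled = pd.Series(vals, index=list(np.roll(idx, 3)))
        stat = lambda s: float(s.max() - s.min())  # label-free statistic
        r1 = permutation_pvalue(1.0, stat, scores, n_perm=300, seed=5)
        r2 = permutation_pvalue(1.0, stat, relabeled, n_perm=300, seed=5)
        assert r1.p_value == r2.p_value


class TestBhCorrect:
    def test_hand_example(self):
        assert bh_correct([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_correct([0.2]) == [0.2]

    def test_all_ones(self):
        assert bh_correct([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    @settings(max_examples=60, derandomize=True)
    def test_matches_step_up_oracle(self, ps):
        """Independent step-up computation: p_(i) * n/i, cummin from the top, cap 1."""
        p = np.asarray(ps)
        n = len(p)
        order = np.argsort(p)
        scaled = p[order] * n / np.arange(1, n + 1)
        adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj_sorted, 1.0)
        assert bh_correct(ps) == pytest.approx(list(expected), rel=1e-9)

    def test_monotone_on_sorted_inputs(self):
        adj = bh_correct([0.001, 0.01, 0.04, 0.2, 0.9])
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))


class TestStandardMethodBaseline:
    def _data(self):
        # 1 genome-wide significant gene (G0) targeted by some drugs
        genes = [f"G{i}" for i in range(6)]
        assoc = make_assoc(genes, [1e-9, 0.2, 0.4, 0.6, 0.8, 0.9])
        rows = [("asm1", "G0", 1.0), ("asm2", "G0", 1.0), ("other1", "G0", 1.0),
                ("asm3", "G1", 1.0), ("other2", "G2", 1.0)]
        return assoc, make_targets(rows)

    def test_recall_precision_f(self):
        assoc, targets = self._data()
        res = standard_method_baseline(assoc, targets, 5e-8, ["asm1", "asm2", "asm3"])
        assert res.recall == pytest.approx(2 / 3)
        assert res.precision == pytest.approx(2 / 3)
        assert res.f_score == pytest.approx(2 / 3)
        assert set(res.predicted_set) == {"asm1", "asm2", "other1"}

    def test_empty_prediction_flagged(self):
        assoc, targets = self._data()
        res = standard_method_baseline(assoc, targets, 1e-12, ["asm1"])
        assert res.empty_prediction and res.recall == 0.0 and res.f_score == 0.0

    def test_perfect_prediction(self):
        genes = ["G0"]
        assoc = make_assoc(genes, [1e-9])
        targets = make_targets([("a", "G0", 1.0), ("b", "G0", 1.0)])
        res = standard_method_baseline(assoc, targets, 5e-8, ["a", "b"])
        assert res.recall == res.precision == res.f_score == 1.0


class TestGeneSetTtest:
    def test_matches_welch_formula(self):
        """Hand Welch computation on a 6-gene toy."""
        genes = [f"G{i}" for i in range(6)]
        pvals = [0.001, 0.01, 0.3, 0.5, 0.7, 0.9]
        assoc = make_assoc(genes, pvals)
        targets = make_targets([("d1", "G0", 1.0), ("d1", "G1", 1.0), ("d2", "G2", 1.0)])
        t_obs, p_obs = gene_set_ttest(assoc, targets, "d1")
        z = assoc.z_by_gene()
        a = z.loc[["G0", "G1"]].to_numpy()
        b = z.loc[["G2", "G3", "G4", "G5"]].to_numpy()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va / len(a) + vb / len(b))
        assert t_obs == pytest.approx(t_hand, rel=1e-9)
        # Welch-Satterthwaite df, one-sided upper tail
        df = (va / 2 + vb / 4) ** 2 / ((va / 2) ** 2 / 1 + (vb / 4) ** 2 / 3)
        from scipy import stats as sps

        assert p_obs == pytest.approx(float(sps.t.sf(t_hand, df)), rel=1e-9)

    def test_no_separation_gives_half(self):
        genes = [f"G{i}" for i in range(8)]
        assoc = make_assoc(genes, [0.3, 0.7] * 4)
        targets = make_targets([("d1", "G0", 1.0), ("d1", "G1", 1.0)])
        _, p = gene_set_ttest(assoc, targets, "d1")
        assert p == pytest.approx(0.5, abs=0.05)

    def test_ranking_recovers_planted_drugs(self, small_signal):
        d = small_signal
        df = rank_drugs_by_gene_set_ttest(d.assoc, d.drug_targets)
        scores = df.set_index("drug_id")["score"]
        pos = [x for x in d.truth if x in scores.index]
        neg = [x for x in scores.index if x not in set(pos)]
        assert auroc(scores, pos, neg) > 0.8
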