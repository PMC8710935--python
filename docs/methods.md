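# Methods

## The scoring model

`famscore` predicts the relative efficacy of licensed drugs against a complex
disease from three data layers: gene-level GWAS association statistics,
drug–target affinity data, and signed transcriptomic signatures (a disease
signature and one per-drug induced signature). Two complementary drug-level
scores are computed and averaged.

### Function Modulation (FM)

For drug *d* with targets *t* present in the association table,

    raw_fm(d) = (1 / k_d) * Σ_t  w_t · z_t

where `z_t = Φ⁻¹(1 − p_t)` is the gene-level association z-statistic
(one-sided convention: larger z = stronger association; p below 1e−300 is
clamped so z stays finite), `w_t` is the drug–target affinity weight divided
by the largest weight in the whole table, and `k_d` is the number of
scoreable targets. Targets absent from the association table are skipped and
logged; a drug with no scoreable target is unscoreable and excluded
downstream.

Drugs differ enormously in target-set size (1–100+ targets), and a raw mean
over targets still drifts with k through its sampling variance. The score is
therefore standardized against a **size-matched permutation null**: for each
drug, `n_perm` random target-sets of size `k_d` are drawn uniformly without
replacement from all association genes, scored with the drug's own
normalized weights, and the drug's standardized score is
`(raw − null_mean) / null_sd`. The adjusted scores are then z-scored across
drugs into `fm_z`.

Implementation notes:

* One matrix of `n_perm` random gene permutations is drawn per call; the
  first *k* columns of a uniform permutation are a uniform *k*-subset, so a
  single matrix serves every target-set size. Nulls for different drugs
  share these draws — each drug's null is still exact, only the (irrelevant)
  cross-drug correlation of the Monte-Carlo error is affected.
* A degenerate null (k equal to the whole gene universe, sd = 0 up to
  floating-point rounding, detected at `sd ≤ 1e-12·max(1, |mean|)`) maps to
  an adjusted score of 0.
* Because the null universe is "all genes in the association table",
  removing even an untargeted gene from that table perturbs the null
  slightly; rankings are insensitive to this (tau > 0.9 in the test), but it
  is the reason a fully excluded inert gene does not reproduce the original
  ranking bit-for-bit.
* FM deliberately ignores direction of drug action (agonist/antagonist):
  only the strength of functional modulation enters.
* `n_perm` defaults to 10 000 (config `n_perm_fm`). The test-suite and the
  acceptance script use 300–2000 draws; the Monte-Carlo standard error of
  the adjustment at 2000 draws (≈ 0.02 on a z scale) is far below the
  between-drug score spread the rankings depend on.

### Abundance Correction (AC)

For each drug, the cosine distance

    d = 1 − (u · v) / (‖u‖‖v‖)  ∈ [0, 2]

is computed between the disease signature *u* and the drug signature *v*
over the genes measured in both (missing cells excluded). Distance 2 means
the drug's induced expression changes exactly oppose the disease's — the
ideal corrective profile — so distances are z-scored across drugs with
higher = better (`ac_z`). Unlike FM, AC is directional: it distinguishes
reversing from mimicking the disease state.

* Drugs with fewer than `min_overlap` shared genes (default 10; cosine in
  fewer dimensions is noise-dominated) are excluded and logged.
* Replicate signature columns for one drug (cell lines, doses) are collapsed
  by per-gene median before scoring.
* The full disease signature is used, not only genome-wide-significant
  genes: sub-threshold association signal carries information.

### FAM integration

`fam = (fm_z + ac_z) / 2` for drugs carrying both scores. A drug missing
either score (e.g. never assayed transcriptomically) gets no FAM score and
is excluded from the ranking but retained in FM-only output. Ranks are
assigned by descending FAM, ties broken lexicographically by drug id, and
converted to percentiles by `100·(n − rank)/(n − 1)` — the top drug of *n*
sits at 100, the bottom at 0, and a drug at percentile 90 outranks 90% of
scored drugs.

`top_candidates` demarcates the head of the ranking by scanning every cutoff
k, computing the one-sided hypergeometric enrichment of a known-effective
drug-set among the top k, and reporting the cutoff with the smallest p
(smallest k on ties), Benjamini–Hochberg-corrected over the scanned cutoffs.

## Validation machinery

* **AUROC** is computed by the tie-corrected rank-sum identity
  (Mann–Whitney U / (n_pos·n_neg)); a brute-force concordant-pair oracle
  backs it in the tests. Because effective drugs are a tiny minority of all
  drugs, AUROC is estimated under **random under-sampling**: all positives
  versus an equal-size negative sample, repeated (default 1000×), reported
  as mean ± sd. The under-sampled mean is an unbiased estimate of the
  full-cohort AUROC; the tests require agreement within 0.02.
* **Prioritization** is the median percentile rank of a drug-set (median,
  not mean, to resist outliers).
* **Permutation p-values** shuffle the score-to-drug assignment and use the
  add-one estimator `p = (1 + #extreme)/(1 + n_perm)`, which never returns 0
  and bottoms out at `1/(1+n_perm)`. Arbitrary statistics of the assignment
  are supported, including compound order-and-threshold hypotheses ("these
  drugs all above percentile X, in this order") via
  `pipeline.ordered_high_rank_stat`. Note that a statistic must actually
  depend on the assignment (the median of *all* scores is
  permutation-invariant and has no null).
* **BH correction** is standard step-up (via statsmodels), hand-verified in
  tests. Step-up adjustment is not idempotent in general, and no such
  property is relied on.
* **Comparators**: (i) the genome-wide-significance baseline predicts every
  drug with at least one target among genes below a p-value threshold and
  is scored by recall/precision/F (it yields an unranked set, so no AUROC);
  (ii) a competitive gene-set Welch t-test per drug asks one-sidedly whether
  the drug's target genes have a higher mean association z than the rest of
  the genome, ranking drugs by p. Under a p-derived z convention oriented
  the opposite way this same test reads "lower mean z"; the package stores
  association-strength z, so "greater" is the correct direction here.
* **Stability**: the top-k (default 10) most strongly associated genes that
  contribute to the score (targeted by ≥ 1 drug or present in the disease
  signature) are excluded one at a time from every input, the pipeline is
  re-run, and Kendall's tau-b (tie-corrected; exact p for n ≤ 8 tie-free
  rankings, normal approximation otherwise) compares the new ranking with
  the original over their common drugs. Exclusion is applied to both FM and
  AC inputs.

## Synthetic data generator

The generator emulates the statistical shape of the real inputs rather than
their biology:

* gene-level p-values: Uniform(0,1) null with 2.5% of genes (minimum 10)
  planted from Beta(0.1, 20) — a heavy low-p tail in which only a handful of
  genes reach genome-wide significance, matching the regime where the
  significance-threshold baseline starves;
* disease signature: `effect = sign · |z| + N(0, noise_sd)` with random
  signs, so effect magnitude tracks association strength;
* drug–target structure: per-drug target counts uniform on
  `target_count_range` (default 1–100); *effective* drugs select planted
  genes with selection weight `1 + 10·effect_strength` and receive an
  affinity bonus of `effect_strength` on planted targets;
* drug signatures: noise `N(0, noise_sd)` for inert drugs,
  `−effect_strength · disease_vector + noise` for effective drugs.

Every planted difference scales with `effect_strength`, so
`effect_strength = 0` is an exact null: the labelled "effective" drugs are
then exchangeable with the rest, which is what the calibration tests check
(under-sampled AUROC ≈ 0.5 averaged over fixtures; permutation p-values
uniform by KS). The defaults (2000 genes, 300 drugs, 20 effective drugs,
effect strength 3, noise sd 1, seed-deterministic output) are the benchmark
conditions used by the acceptance checks. At small fixture sizes recovery
saturates quickly — AUROC is ≈ 1 by effect strength 0.5 — so the
monotonicity-of-recovery test samples the unsaturated region
(0, 0.05, 0.3).

What the generator does **not** emulate: linkage disequilibrium among genes,
tissue-specific expression structure, correlated drug signatures within
pharmacological classes, and incomplete/biased target annotation. Passing
the recovery benchmarks therefore demonstrates that the statistical
machinery is correct and well-calibrated, not that real GWAS/affinity/
signature data carry this much signal.

## Numerical and design choices

* p-to-z: `z = Φ⁻¹(1 − p)` via `scipy.stats.norm.isf`, accurate in the far
  tail; p clamped at 1e−300.
* Identifier harmonization: genes uppercased, drugs lowercased with
  punctuation stripped; both idempotent. Cross-source joins are exact string
  matches; a synonym table can be supplied to the drug-target reader. No
  gene-ID translation is attempted.
* Duplicate-row collapse is order-independent: min-p for repeated genes,
  max-weight for repeated drug–target pairs.
* All randomness flows from explicit seeds; the pipeline derives stage seeds
  from one global config seed by hashing, so stage-wise and monolithic runs
  produce byte-identical outputs.
* Zero-variance standardization (all drugs identical) maps scores to 0 with
  a logged warning rather than failing.
* Scores round-trip through TSV at 12 significant digits.

## Known limitations

* The FM/AC composition (mean over targets; direct z-scoring of cosine
  distances) is one defensible choice among close variants (sum vs mean,
  rank-transform vs z); rankings are insensitive to affine variants by
  construction (max-normalization makes FM scale-invariant in affinities).
* FM inherits the incompleteness of target annotation: sparsely annotated
  drugs are systematically under-scored, and no deorphanization is
  attempted.
* The permutation engine evaluates the statistic in Python per draw; at 10⁶
  permutations a cheap statistic takes minutes. Configurable `n_perm`
  (default 10⁵ for evaluation) trades floor depth against runtime.
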