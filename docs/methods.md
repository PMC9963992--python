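# Methods

## Problem and model

`ictosig` scores the seizure liability (ictogenicity) of a test compound
from its transcriptomic response in neuronal culture. The premise is that
seizure-prone compounds perturb overlapping transcriptional programs, so a
test compound whose differentially expressed (DE) genes resemble those of
established ictogens ("tool" compounds) is likely ictogenic itself. Three
compound categories are used throughout: tool compounds (reference
ictogens), FAERS-positive compounds (many seizure adverse-event reports;
the test set) and FAERS-negative compounds (few or none; used to define
transcriptomic noise).

The unit of input is a per-compound DE table versus vehicle — per gene a
log2 fold-change, nominal p-value and Benjamini–Hochberg FDR — as produced
by any standard DE caller. A gene is DE when FDR < 0.05 and |log2FC| > 1.5.
The fold-change criterion is applied to the *magnitude* of the log2
fold-change; applying it to the signed value would exclude every
downregulated gene, which is inconsistent with the analyses the thresholds
feed (shared downregulated-gene sets are a core signal).

All three scoring procedures first subtract noise: the union of all
FAERS-negative compounds' DE genes is removed from every gene set,
direction-agnostically. A narrower variant that removes only noise genes
also regulated by a tool/positive compound is available
(`restrict_noise=True`); the blunt full-union subtraction is the default
because it is the stronger and simpler reading, and because it guarantees
that a FAERS-negative compound's own post-subtraction set is empty, which
is what gives the shared-signature classifier its perfect specificity on
negatives.

### Alikeness-%

For test compound *x* and tool compound *t* (both noise-subtracted):

    alikeness(x, t) = |up_x ∩ up_t| + |down_x ∩ down_t|
                      ─────────────────────────────────  × 100
                              |up_t| + |down_t|

The denominator is the tool compound's DE count *after* noise subtraction;
a pre-subtraction denominator would make 100% unattainable even for
self-comparison. An empty post-subtraction tool set scores 0 with a
warning, never a division error. The per-compound score is the sum of
alikeness-% over all tool compounds, and a compound is called positive
when the sum strictly exceeds the cutoff (default 10).

### GSEA score

Each tool compound defines a signed ranked list: gene score
−log10(p) × sign(log2FC), p floored at 1e−300, sorted descending, ties
broken by larger |log2FC| then gene id (so the ranking is independent of
input row order). Each test compound defines up to two gene sets — its
upregulated and downregulated DE genes — eligible when they hold at least
`min_size` genes (default 3; smaller sets make the running-sum walk
meaningless, matching the screen's "no score calculable" outcomes).

Enrichment of a set in a list uses the weighted Kolmogorov–Smirnov running
sum: hits increment by |score|^weight normalized over hits (weight 1 by
default), misses decrement by 1/(N − n_hits); the enrichment score (ES) is
the extremum of the walk by absolute value, in [−1, 1]. The null is gene
permutation: `n_perm` random same-size sets drawn from the ranked list
(default 1000). NES = ES / mean(|null ES| of matching sign); the nominal p
is (1 + #{null at least as extreme, same sign}) / (1 + #{null same sign}),
so p ≥ 1/(1+n_perm). For one test compound, BH adjustment is applied
across all set×list pairs, and the GSEA score is Σ|NES| over pairs with
adjusted p < 0.05. The adjustment scope (per test compound) and the
plain Monte-Carlo null are package choices; the Monte-Carlo p-floor means
significance after BH requires n_perm large relative to the number of
pairs (with 22 pairs, n_perm = 1000 is about the practical minimum —
fewer permutations silently zero the score).

For efficiency the null ES is computed in closed form from sorted hit
positions (the walk between hits is linear, so its extrema occur
immediately before or after hits); a test asserts exact agreement with the
explicit step-by-step walk, and another asserts agreement of the walk with
the `fgsea` reference implementation.

### Shared-signature classification

The scalar feature of a compound is the number of tool compounds with
which it shares at least one *upregulated* DE gene after noise
subtraction. A logistic regression with intercept (effectively
unpenalized, C = 1e6) on this feature is evaluated by leave-one-out
cross-validation over the combined FAERS-positive/negative set; the
held-out compound is called positive when its predicted probability
exceeds 0.5 (standard default). Pooled probabilities give the AUC by
all-pairs concordance with ties counted 0.5 (asserted equal to the
trapezoidal ROC integral); accuracy is tested against the no-information
rate (the larger class proportion) with an exact one-sided binomial test.
Because the noise union contains every negative compound's genes, each
negative's feature is 0 by construction; the evaluation's information
content lies in how many positives rise above it.

### One-vs-rest count classification

Where replicate normalized count matrices are available, compounds are
classified one-vs-rest by category. Genes with fewer than 5 normalized
counts in at least 50% of samples (inclusive boundary) are removed. Each
sample's counts are rank-transformed (average ranks), the per-gene median
over the replicates is taken per compound, and features are z-scored over
compounds (zero-variance genes dropped). Feature screening uses the ratio
Var(group means) / mean(within-group variances) with sample variances —
deliberately *not* the df-scaled ANOVA F; the two orderings differ only
under unbalanced groups. The classifier (logistic regression with l1/l2
regularization, or SVM with linear/RBF kernel, plus the screening k) is
chosen by an inner leave-one-out loop on training compounds only, inside
an outer loop where each target-group compound is tested together with
3–4 randomly drawn non-target compounds. By default standardization is
fit within each training fold; `global_standardize=True` standardizes once
over the whole dataset before splitting, a leaky variant provided for
comparison with analyses that preprocess globally. The default
hyperparameter grid is small (LR l1/l2 × C ∈ {0.1, 1}; linear/RBF SVM at
C = 1; k ∈ {50, all}) to keep nested LOOCV desk-scale; the grid is an
argument.

### Score comparison and summary

Alikeness sums and GSEA scores are compared by tie-corrected Spearman
correlation (average ranks, t-approximation p), with not-calculable GSEA
scores entered as 0 — this pairing is what the concordance of the two
scores is defined over. The categorization summary excludes compounds
with ≤ 3 DE genes (they cannot express a signature), reports per-method
correct counts, and derives whole-percent figures by rounding the ratio
of counts (9/11 → 82%, 10/11 → 91%), never storing a percentage
independently of its counts.

## Synthetic panels

The generator emulates the structure of a 34-compound screen: a
10,000-gene universe, 11 tool / 13 positive / 10 negative compounds, DE-set
sizes drawn log-uniformly per category (tool 21–2,700; positive 40–3,700;
negative 7–2,300), mirroring the heavy-tailed spread of real per-compound
DE counts. Each positive copies `share_fraction` (default 0.3) of its DE
genes, with direction, from 1–3 randomly chosen tool donors; the rest are
drawn uniformly, so residual overlap sits at hypergeometric chance level.
Negative compounds draw from genes untouched by tool/positive signatures
except for a `noise_overlap` (default 0.05) collision rate. Planted genes
receive |log2FC| ≥ 1.6 centred on `planted_lfc` = 2.5 and FDR < 0.05;
all other genes are guaranteed non-significant, so thresholding recovers
the planted truth exactly.

The positive size floor of 40 is a contract, not an accident: the
generator's job is to produce panels on which a correct pipeline
demonstrably separates categories (median AUC ≥ 0.95 over seeds at the
default sharing level), and a planted positive with a handful of DE genes
often shares zero upregulated genes with every tool, making it
unrecoverable in principle — the same failure the real screen reported
for its 0- and 3-gene test compounds. Such degenerate compounds remain
expressible through `de_size_range` when the failure mode itself is under
study.

Counts, when requested, are negative-binomial with per-gene baseline
log2 means uniform on (2, 10), dispersion 0.1 (variance = μ + 0.1 μ²),
four replicates, and one shared pseudo-vehicle condition per panel;
treated means shift by each gene's tabulated log2FC. The DE tables are
the primary artifact — downstream stages never require counts — because
the pipeline consumes DE-caller output, not raw counts. The companion
`simple_de_test` (Welch's t on log2(count+1) with BH adjustment and a
pseudocount-1 fold-change) is a deliberately simple two-group screen for
simulator output only; real experiments should ingest proper DE tables.

What the synthetic panels do **not** emulate: library-size and
gene-length effects, batch structure, correlated gene modules,
dispersion–mean trends, and partially-overlapping tool signatures.
Passing recovery tests therefore demonstrates the correctness of the
scoring and classification machinery under the planted model, not
clinical predictive performance on real screens.

## Cytotoxicity screen

Cytotoxicity-% of a treated well is
(A_treated − mean A_low) / (mean A_high − mean A_low) × 100, where low
controls are vehicle wells and high controls maximal-release wells; the
quantity is affine-invariant in absorbance and may leave [0, 100]. Group
differences use a Kruskal–Wallis omnibus test gatekeeping pairwise
vehicle-vs-group Mann–Whitney U tests (two-sided, reported unadjusted by
default, Bonferroni optional); all-tied input returns p = 1 with a
degenerate flag.

## Numerical choices and reproducibility

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-compound and per-(tool, set) streams are
  derived via CRC32 of the identifier so results are independent of
  iteration order. Identical configuration reproduces byte-identical
  output files.
- BH adjustment is `statsmodels`' `fdr_bh`; rank tests and Spearman come
  from `scipy.stats`; logistic/SVM engines from scikit-learn. The scoring
  procedures themselves (alikeness, GSEA walk and NES, F-ratio, nested CV
  protocol) are implemented in-package.
- Floats are written to 12 significant digits; TSV/GMT/JSON round-trip
  losslessly at that precision.
- Problem sizes in the test-suite and acceptance computations (panels of
  up to 10,000 genes, 20 seeds, 200–1,000 permutations) were chosen as
  the smallest scales at which the statistical assertions are stable.

## Known limitations

- The Monte-Carlo GSEA null cannot produce p-values below 1/(1+n_perm);
  an adaptive multilevel null (as in `fgsea`) would sharpen small p but is
  not implemented.
- The shared-signature LOOCV pools probabilities from per-fold models;
  at tied feature values the fold-dependence of the fitted intercept can
  order tied compounds systematically, a known pessimistic quirk of
  pooled LOOCV.
- `simple_de_test` is not a negative-binomial DE model and will be
  underpowered at low counts.
- One-vs-rest results depend on the supplied hyperparameter grid; the
  default grid is intentionally small.
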