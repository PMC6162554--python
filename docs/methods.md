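# Methods

## Model and procedure

The package detects k-way SNP combinations associated with a binary
case-control phenotype in two stages.

**Information measures.** All quantities are maximum-likelihood plug-in
estimates from contingency tables of genotype counts (values 0/1/2)
against the phenotype (control = 0, case = 1), in nats, with
0·log 0 = 0. Natural logarithms are used throughout: the G-test is
defined with ln, and the remaining quantities that drive the search
(symmetrical uncertainty, interaction weight factor) are ratios of
entropies and therefore base-invariant. No pseudocounts or estimator
bias corrections (Miller–Madow and similar) are applied; empty cells
simply contribute nothing to entropy sums. Mutual-information values in
(−1e−12, 0) arising from float cancellation are clamped to 0; anything
more negative raises, as it would indicate a bug rather than noise.

The search's per-SNP score is the *modified* symmetrical uncertainty
2·I(X;C)/H(X,C). Because H(X,C) ≤ H(X)+H(C), it is never smaller than
the standard form 2·I(X;C)/(H(X)+H(C)) and stretches weak associations;
its range is [0, 2]. A constant SNP scores 0 by convention; a constant
phenotype is rejected as an input error.

The interaction weight factor is read as IWF = 1 + IG/(H(X)+H(Y)). With
exact plug-in estimates the identities I(X;C) ≤ H(X) and
I([X,Y];C) ≤ H(X)+H(Y) bound it to [0, 2], with 1 the neutral point
(IG = 0). When both SNPs are constant the denominator vanishes; the
factor is then defined as the neutral 1 and the event is logged, since
no interaction evidence exists either way.

**Search stage.** Seeds are chosen by maximum SU×W with W the per-SNP
multiplicative weight coefficient (initially 1). A combination grows
from its seed by evaluating IWF of every pool SNP against the *most
recently added* member, folding the factor into that SNP's persistent
weight, and selecting the maximum relevance R = W·(1+SU). Three
behaviours deserve emphasis because they are easy to miss:

* selected SNPs are consumed — they leave the pool for the remainder of
  the entire run and their weight drops to 0, so candidate combinations
  are disjoint in their member SNPs;
* weight updates persist across combinations and seed groups, making
  later selections history-dependent by design;
* within a seed group of K combinations, the default `literal` policy
  starts the m-th combination (m > 1) from the last SNP selected into
  the (m−1)-th; the alternative `reselect` policy re-runs seed selection
  instead. Both are deterministic.

All argmax operations break ties toward the lowest SNP index, which
(together with the absence of any randomness in the search) makes
results bit-reproducible. Candidates are deduplicated on sorted index
tuples; duplicates do not count toward the candidate budget T. If the
pool empties before T candidates exist, the search returns short with a
warning rather than failing. An internal counter verifies that the
number of IWF evaluations stays within the nominal O(N·k!·K) budget
under the study conventions K = k, T = 2k.

**Testing stage.** Each candidate is tested with the gated
likelihood-ratio statistic G = 2 Σ O·ln(O/E) over its 3^k × 2 table. A
genotype row whose total count is ≤ ξ is excluded from the sum *and*
removes one degree of freedom from the nominal (I−1)(J−1); the single
predicate "row total ≤ ξ" governs both effects, which keeps the
statistic and its reference distribution consistent at the boundary.
The df is floored at 0, in which case p := 1 and the combination can
never be declared significant. ξ defaults to 5, its maximum sensible
value for a 2-column table. Under row gating the partial sum can in
rare cases go negative; G is floored at 0, its value when the data fit
the null at least as well as the alternative.

Expected counts default to independence margins (row total × column
total / n), the classical G-test null. An `hwe` mode is available that
builds genotype-row probabilities from per-locus Hardy–Weinberg
frequencies (1−q)², 2q(1−q), q² at the pooled-sample allele-2 frequency,
multiplied across loci and renormalised to the observed column totals.
Pooling cases and controls for q is this package's choice; a
case-control design distorts genotype frequencies at true disease loci,
so the `hwe` null is stricter there and independence margins remain the
default.

**Significance threshold.** θ defaults to the adaptive
0.01·MAF/C(N,k), computed in log space so very large binomial
coefficients underflow to 0 rather than overflow. The MAF entering the
formula is the smallest sample minor-allele frequency among the
combination's members — the most conservative per-combination choice.
A fixed θ can be supplied instead.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| k | combination order | 2 | smallest epistatic order |
| K | combinations per seed | k | simulation-study convention |
| T | candidate-set size | 2k | simulation-study convention |
| θ | G-test p-value threshold | adaptive (above) | Bonferroni-type control over C(N,k) implicit tests |
| ξ | small-cell gate | 5 | upper end of the sensible range; protects the chi-square approximation |
| k_max | largest joint-table order | 6 | 3^k cells must stay small |
| kNN k | imputation neighbours | 5 | standard for categorical genotype panels |

## Synthetic data

The simulator draws disease-locus genotypes under Hardy–Weinberg
equilibrium at stated MAFs, assigns case status with probability equal
to the penetrance of the drawn joint genotype, and rejection-samples
until the case and control quotas are filled exactly. Null SNPs are
independent of status with MAFs uniform on [0.05, 0.5] (our choice; no
published value governs it). Columns are independent — no linkage
disequilibrium — and there is no population stratification, genotyping
error or covariate structure. Passing tests on these data therefore
demonstrate correctness of the algorithmic pipeline and its calibration
under idealised sampling, not robustness to the confounders of real
GWAS panels.

The shipped model catalogue (`builtin_models`) contains four synthetic
fixtures written for this package — a multiplicative model
(penetrance 0.07·1.9^(g₁+g₂), MAF 0.3), a strong threshold model (0.62
when both loci carry a minor allele, 0.05 otherwise, MAF 0.3), a pure
parity/XOR model (0.7 for odd g₁+g₂, 0.3 otherwise, MAF 0.5, flat
single-locus marginals), and a nested three-locus model (base 0.04,
×5 for the two-locus core, ×2 more with the third locus). They span the
archetypes of the published disease-model families but are **not** any
published catalogue's tables. The parity model documents the method's
known weak spot: with no marginal signal, SU-guided seeding has nothing
to grab, so pure strict epistasis is found only by luck — the search is
designed for *nested* epistasis where at least one locus shows a
marginal or lower-order effect.

Because sampling is case-control (ascertained), genotype frequencies at
disease loci deviate from their population HWE values; the simulator
fidelity test checks empirical genotype-stratified case rates against
the analytic ascertained mixture, not against raw penetrance.

## Preprocessing

Missing genotypes are filled by k-nearest-neighbour majority vote with
normalised Hamming distance over mutually observed columns, ties to the
lower genotype value, deterministically. On the package's own simulated
data the achievable accuracy is capped near E[max genotype
probability] ≈ 0.6, because columns are independent (no LD) with MAFs
up to 0.5 — an imputer cannot beat the majority genotype without
between-marker correlation. Measured kNN accuracy is ≈ 0.55; on real
panels with LD it would be substantially higher. Class imbalance is
addressed by bootstrap-resampling the minority class up to the majority
size with a seeded generator, recording the drawn indices in
provenance.

## Evaluation

Per replicate with one planted combination: TP if the planted sorted
tuple is among the candidates and passes θ; FN if it was found by the
search but failed the test; FP/TN for non-planted candidates that
pass/fail. Power is the TP count over the number of replicate datasets
(model detected or not, per dataset); recall, precision and the
F-measure (harmonic mean) summarise the testing stage. Although power
and recall coincide numerically when every replicate contributes at
most one planted combination, they answer different questions and the
report keeps both. Percentages are rounded half-up to two decimals for
display only.

The per-combination AUC scores each sample with the plug-in case
fraction of its joint genotype cell and computes the tie-corrected
Mann–Whitney statistic. It is resubstitution (training-set) AUC — an
optimistic, exploratory summary used for ranking nested combinations,
deliberately not cross-validated.

## Problem sizes in the shipped checks

The planted-model study uses 20 replicates of the small published
design (100 SNPs, 800 cases + 800 controls); G-test null calibration
uses 5000 phenotype permutations at n = 2000 in the test suite and 2000
in the acceptance script; the simulator fidelity check uses 50,000
samples; oracle equivalence uses 200 random datasets with n ≤ 200 and
N ≤ 10. These sizes keep every check comfortably on one CPU while
leaving the statistical assertions sharp (binomial or KS bounds at the
stated levels).

## Known limitations

* Pure strict epistasis (flat marginals, e.g. parity models at MAF 0.5)
  defeats the SU-guided seeding by construction.
* The candidate sets of one run are disjoint in their SNPs; a locus
  participating in two distinct true interactions can surface in only
  one of them per run.
* The chi-square reference for G is asymptotic; ξ-gating protects the
  approximation but discards rare-genotype information.
* J = 2 phenotype classes only; no continuous traits.
* The simulator has no LD, stratification or genotyping error.
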