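# Methods

## Scope and data model

splicemark quantifies alternative splicing from junction-spanning reads
and carries candidate events through discovery (paired cohorts),
validation-style contrasts (a junction-usage matrix), classification and
survival association. Internal coordinates are 0-based half-open
everywhere; GTF and STAR `SJ.out.tab` (both 1-based inclusive) convert at
the file boundary, refFlat is consumed as-is. Splice sites are
transcript-oriented: the donor (5′ splice site) is the last base of the
upstream exon, so on the minus strand the donor is the genomically
rightmost site and 5′ site groups on minus-strand genes key on that site.
A junction is uniquely keyed by (chromosome, intron interval, strand);
rows of undetermined strand (SJ strand code 0) are retained and flagged
ambiguous, and catalog lookups fall back to the ambiguous key.

## Read filter and counting

A read is used when it is a primary alignment with MAPQ > 10 and
mismatches (edit-distance tag) strictly below 5% of its aligned (matched)
length. The aligned length is the denominator deliberately: it is robust
to soft-clipping, and "read length" is otherwise ill-defined for clipped
alignments. "Uniquely mapped" is operationalized as this MAPQ rule plus
the exclusion of secondary/supplementary records. A missing mismatch tag
passes by default (with a warning); this is configurable. Each skipped
region (CIGAR `N`) of a passing read increments one junction, so a read
spanning two introns increments two junctions. Exon-block counting
flattens each gene's exons into disjoint blocks and increments every block
a read's aligned segments overlap by ≥ 1 base, once per (read, block)
pair — junction reads therefore do count toward the exon blocks they
touch. RPM normalization divides by the per-sample count of passing reads,
not raw reads.

## PSI estimators

* `PSI_exon = (a + b)/(a + b + 2c)` — algebraically the mean inclusion
  junction against the skip junction, ((a+b)/2) / ((a+b)/2 + c). This is
  the standard junction-read estimator for cassette exons: an inclusion
  molecule exposes two countable junctions, a skipping molecule one.
* `PSI_junc` — one junction's share of all junction reads at its shared
  donor (5′) or acceptor (3′) site. Site groups are built from annotation
  plus any observed junctions at the site, so unannotated competitors
  correctly depress the usage of annotated ones.
* The minimum-informative-reads rule (default 10) applies to the full
  event denominator: a + b + c for cassette events, the group read sum for
  site groups. Below it the value is missing, not zero.
* Junction usage divides a junction's quantification by the mean
  quantification of its gene's junctions in the same person; a person with
  zero gene mean is missing for that gene. By construction the per-(gene,
  person) mean of usage is exactly 1, asserted to 1e-12 in the tests.

Cassette events require direct annotation evidence of both inclusion and
skipping; junctions discovered only in reads may join site groups but
never create cassette events. Catalogs are built per gene; junctions of
overlapping genes are not disambiguated (each gene sees its own).

## Differential splicing

Groups are compared with the two-sided Wilcoxon rank-sum test — unpaired,
although cohorts are patient-paired, trading power for an assumption-free
comparison. The implementation uses the exact null distribution when the
combined sample size is ≤ 25 with no ties, otherwise the normal
approximation with midranks, tie correction and continuity correction;
the test suite checks it against an exhaustive rank-assignment
enumeration. ΔPSI is the difference of group means (medians are reported
descriptively). Samples missing an event's PSI are dropped per event, and
each group needs ≥ 3 non-missing values or the test is refused with a
reason. Discovery cutoffs are p < 0.05 and |ΔPSI| > 0.20, intersected
across cohorts with matching ΔPSI sign. Discovery p-values are left
unadjusted; Bonferroni (min(1, p·m)) is applied only in the
validation-stage usage contrasts — a two-stage design in which the
independent validation cohort, not multiplicity correction, controls the
discovery error.

The metastasis filter keeps events with |ΔPSI(MC−NC)| > 0.20 and
p < 0.001, the same ΔPSI sign in every supplied contrast, and a further
shift |mean(MC) − mean(CRC)| ≥ 0.15 in that direction. "Consistent trend"
is implemented as sign agreement only — the primary-tumor contrasts need
not individually reach significance — and the per-criterion pass flags are
emitted so the stricter reading can be applied downstream. Stromal
confounding is screened by Spearman correlation of usage with stromal
percentage, Bonferroni-adjusted over the tested junctions.

## Predictor search

Predictors are clustered by average-linkage hierarchical clustering on
1 − Spearman ρ, cut into three groups; groups are numbered by ascending
mean between-cluster correlation so group 1 is the most distinct. The
clustering method is a design choice (only the grouping, not the method,
matters downstream), and an explicit grouping can be supplied to bypass
it. Candidate sets are all singletons, all pairs of a group-1 member with
a group-2∪3 member, and all one-per-group triples: n + g₁(g₂+g₃) + g₁g₂g₃
sets, 41 for sizes (3, 2, 3). Each set is scored by 5 repetitions of a
random 50/50 split: unregularized maximum-likelihood logistic regression
(lbfgs, iteration-capped; a quasi-separated capped fit still ranks test
samples correctly) fitted on the training half, AUC measured on the test
half only. Splits are stratified by class — with 382 tumors against 51
normals an unstratified half can lose the minority class — and degenerate
single-class halves are resampled with a logged retry. Repetition seeds
derive from one explicit seed. The best set is the highest mean AUC, ties
broken toward fewer predictors then lexicographically; the final model is
the top-AUC repetition within that set. AUC is the Mann–Whitney
probability P(score⁺ > score⁻) + ½P(tie), verified against brute-force
pair counting.

## Survival

Patients are median-split on a junction's usage with ties going low (an
exactly equal split can be impossible, e.g. with 357 patients; realized
group sizes are reported). Curves use the product-limit estimator with
Greenwood variance; deaths precede censorings at tied times. Group
comparison is the standard log-rank test (observed − expected with
hypergeometric variance, χ² with 1 df), delegated to lifelines and
verified against a hand-computed oracle. Duplicate person ids collapse to
the first record and the collision count is reported.

## Synthetic data

The generators emulate the study conditions and carry their ground truth:

* **Cassette cohorts** — paired groups of 18 patients (10 for the
  replication cohort), event depth T ~ NegBin(mean 200, dispersion 10).
  Each read is inclusion-type with probability 2ψ/(1+ψ) — the
  junction-read model under which an inclusion molecule exposes two
  junctions — then inclusion reads split Binomial(½) between the upstream
  and downstream junctions, the rest are skip reads. Under this model
  `PSI_exon` is consistent for the planted ψ; mean absolute ΔPSI recovery
  error at depth 200, n = 18 is ≤ 0.05. Planted effects default to
  0.50→0.85 and 0.10→0.45, the magnitude of the strongest recurrent
  cassette changes the pipeline targets; null events share one
  Uniform(0.1, 0.9) ψ. An optional beta-binomial knob adds biological
  overdispersion the estimator does not model — useful for stress tests,
  off by default.
* **Site groups** — multinomial reads over a donor-sharing group
  (CD44-like topology), with a planted proportion shift (0.2→0.8 on the
  first member by default) and Dirichlet-drawn null groups.
* **Trio cohorts** — NC/CRC/MC per patient plus a shared-catalog NC/CRC
  replication cohort; planted metastasis events (default 0.6→0.4→0.2)
  satisfy the filter criteria in expectation, distractors
  (0.65→0.40→0.40) shift only NC→CRC.
* **Usage matrix** — 382 tumors vs 51 normals, 8 predictors in blocks
  (3, 2, 3) sharing latent factors (within-block correlation ≈ 0.8), a
  3-SD tumor shift on one predictor per block.
* **Survival** — exponential event times with hazard λ·HR^{high} tied to
  the usage median split (HR = 3 default), independent exponential
  censoring calibrated to the target censoring fraction (0.4).
* **Toy SAM** — a minimal single-sample SAM over a three-exon gene with
  hand-computed expected junction and exon-block counts, for the counting
  stage.

All generators are bit-reproducible under a fixed seed. What passing tests
show is recovery under the estimator's own sampling assumptions at the
study's depth and sample sizes; real data add overdispersion, depth
variation across events, mappability artifacts and annotation errors that
these generators deliberately do not model (beyond the optional
beta-binomial switch).

## Numerical choices and problem sizes

Missing PSI is NaN end-to-end and written as `NA`. The exact Wilcoxon
path switches to the corrected normal approximation at combined n > 25 or
any tie. Bonferroni caps at 1. Logistic fits cap at 1000 lbfgs
iterations. KM variance terms where the curve reaches zero contribute 0.
The statistical guarantees in the test suite use: 100 seeds × 100 null
events (n = 18 pairs, depth 200) for selection size and power; 200
survival simulations for HR = 3 power and 400 for null uniformity
(Kolmogorov–Smirnov against Uniform(0,1)), n = 350 each — sizes chosen so
binomial error on the tested rates is small while the suite stays quick.

## Known limitations

DEXSeq-style exon-usage model fitting is out of scope; only the published
adjusted-p/fold-change thresholds are applied to an externally supplied
results table. No isoform-level EM, no read-level sequence simulation, no
transcript assembly or novel-exon discovery, no Cox regression or
multivariable survival adjustment. The rank-sum test ignores patient
pairing. Whether upstream analyses recomputed junction usage or consumed
precomputed values cannot be distinguished here: the normalization is
implemented from its definition and precomputed usage is accepted as-is.
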