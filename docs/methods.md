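# Methods

`pairedspc` implements the downstream statistics of a paired label-free
secretome study: human monocytes from two age groups (newborn, adult), one
control and several adjuvant stimulations per subject, quantified by
spectral counts (SpC), then compared against an independent paired
multi-timepoint PBMC transcriptome. This note documents the models, the
numerical choices, and what the synthetic studies do and do not show.

## Preprocessing (cluster-analysis arm)

Missing counts mean "protein not reported in that run". They are imputed
at **half the data set's minimum observed positive SpC** (0.5 when the
minimum is 1), which keeps every later ratio finite and avoids
overstating fold changes for borderline proteins. A cell that is an
explicit 0 is kept as 0 on input; when such a cell would enter a
fold-change ratio it is floored at the same imputation value (scaled by
the sample's normalization factor), with a warning — otherwise the
treated/control ratio would be undefined for matrices that distinguish
"searched but zero" from "absent".

Samples are scaled so every column total equals the maximum column total
(factor = max total / sample total); the operation is idempotent.
Per-subject fold change is treated/control within the same subject; the
per-condition summary is the arithmetic mean of log2 fold changes across
that condition's paired subjects. Unpaired subjects contribute to
imputation and normalization but not to fold changes. Rows are z-scored
with the sample (n−1) standard deviation; constant rows map to zero and
are excluded from clustering by the inclusion filter anyway.

## Inclusion/exclusion rules

* Exclusion: a protein whose entire evidence is a single count of exactly
  1 (one sample, hence one condition) is removed before any analysis.
* Cluster inclusion, per (age, treatment) condition: total spectra ≥ 2
  and detection in ≥ 2 biological samples (scope: the age group's samples
  by default, the condition's own samples via a flag), and per-subject
  fold change ≥ 2 in **strictly more than half** of the condition's
  paired replicates (4 of 7 passes; 3 of 6 fails — a literal reading of
  "more than half").
* "Detected" always means an observed non-zero raw count; imputed cells
  never count.
* Condition-overlap accounting reports, per age group: the nonredundant
  total, the all-condition intersection with its percentage, and
  per-condition unique counts with their mean. Percentages round half-up
  to integer percent, which reproduces the published 41% (617/1519), 33%
  (565/1717), 5% (75/1519) and 4% (67/1717).

## Two-way clustering

Distance is Pearson: d = 1 − r. For z-scored rows this equals (up to the
constant 1/(2(n−1))) a squared Euclidean distance, so Ward's
minimum-variance criterion is well defined on it. `ward_cluster` is a
greedy Lance–Williams implementation in squared-distance semantics:
merge heights are the Ward dissimilarities themselves (twice the
within-cluster SSE increase on the embedded points), monotone
non-decreasing, and ties break on the lexicographically smallest cluster
label pair, labels in creation order — so output is bit-reproducible.
Leaf order places the subtree containing the smaller minimal original
index first; no optimal-leaf-ordering is applied. The implementation is
pinned by a from-scratch greedy SSE oracle in the tests (and cross-checked
against `scipy.cluster.hierarchy` on tie-free instances, whose Ward
heights are the square roots of ours).

## Paired count-model differential abundance

For protein *g*, subject *s*, condition *c* ∈ {control, treated}:

    y_gsc ~ Poisson(mu_gsc),  log mu_gsc = log offset_sc + alpha_gs + beta_g·1[c = treated]

Conditioning on the pair total n_gs = y_gs,ctrl + y_gs,trt eliminates the
subject effect: y_gs,trt | n_gs ~ Binomial(n_gs, sigmoid(r_s + beta_g)),
r_s = log(offset_trt/offset_ctrl). beta_g (the natural-log fold change,
reported as log2) is the conditional MLE via Newton iteration; separated
proteins (all evidence on one side) get a Haldane-style bounded estimate
and a `boundary` flag. A per-protein length constant multiplies both
offsets of a pair and therefore cancels; it is accepted for interface
completeness.

**Offsets.** The classic choice (`offset_method="total"`) is each
sample's total SpC. Spectral counting is compositional: when a sizeable
responsive fraction moves in one direction, the total shifts with it and
every null protein appears to move the other way. The default
(`offset_method="robust"`) therefore estimates the per-pair depth ratio
from the data: the half-sample mode of protein log-ratios (pair total
≥ 8) locates the non-changing bulk — the mode, unlike the median or any
precision-weighted mean, is not dragged by a 20% one-sided responsive
contingent — and proteins within 2.5 standardized residuals of the mode
are pooled into the closed-form aggregate MLE log(ΣT/ΣC). The estimator's
sampling variance is propagated into each protein's score variance by
the delta method; with fewer than ~20 usable proteins the method falls
back to totals. On mixed simulations this changes the measured false
discovery proportion from 0.57 (totals) to 0.06.

**Inference.** The reported Z is the conditional score statistic at
beta = 0 divided by a moderated dispersion, not a Wald statistic at the
MLE — the Wald form degenerates for near-separated counts
(Hauck–Donner) and misses the exact conditional reference by a factor
of ~2.5 on the canonical 4×(2 vs 8) example, while the score form is
within 20%. Dispersion moderation is quasi-likelihood: the per-protein
Pearson dispersion phi (df = informative pairs − 1) is shrunk toward an
**abundance-trended** prior (trimmed mean of phi within total-count
bins; prior df 4) and floored at 1. The trend matters because
negative-binomial overdispersion grows with the mean, and a single
global prior under-corrects abundant proteins. p-values use a Student-t
reference with Satterthwaite df (prior+resid)²/resid; where the floor
binds, or no residual df exists, the model is plain conditional Poisson
and the p-value is the exact doubled-tail probability of the
Poisson-binomial pair sum. FDR is Benjamini–Hochberg (statsmodels);
significance is FDR < 0.05. Age-specificity labels each protein
newborn_only / adult_only / both / neither by the two contrasts' calls.

Measured operating characteristics under the default study conditions
(500 proteins, 6 pairs, 200 replicates; recomputed by
`scripts/acceptance.py` and the acceptance tests): null raw p<0.05
fraction ≈ 0.04, null BH-5% false-discovery proportion ≈ 0.05–0.07,
mixed-simulation FDR ≈ 0.05, sensitivity ≈ 0.83.

## Exact test kernel

Signed-rank and rank-sum use subset-sum dynamic programming on doubled
mid-ranks (exact for ties) within their exact regimes (n ≤ 25 and pooled
n ≤ 20), with tie-corrected, continuity-corrected normal approximations
beyond; two-sided p doubles the smaller tail. Fisher's exact test sums
hypergeometric point probabilities ≤ the observed one, decided in exact
integer arithmetic (no floating tie tolerance); the odds ratio is the
sample cross-product a·d/(b·c), ±inf/0 with zero cells. Kendall tau-b is
computed from the contingency table of unique values (cheap for ternary
vectors of any length), with permutation enumeration for n ≤ 8 and the
standard tie-corrected normal variance otherwise. Zero differences are
dropped before signed-ranking (Wilcoxon's original convention). Every
exact path equals a brute-force enumeration oracle bit-for-bit in the
tests; the approximate paths agree with the exact ones to ≤ 0.01 at the
regime boundaries.

## Cross-omics concordance

The transcriptome arm quantile-normalizes the probe × sample matrix
(column ranks mapped to the mean order-statistic; ties share the mean of
their reference values; idempotent and rank-preserving), calls per-probe
changes between two timepoints with the exact paired signed-rank test,
takes the minimum-p probe per gene (ties by probe id), and sets
direction by the sign of the median paired difference. Genes join
secretome proteins through a many-to-many id map (each pair kept once);
measured genes without a protein partner can be retained as
transcriptome-only background. Both layers are encoded ternary
(−1/0/+1 = significant down / not significant / significant up) over a
fixed background of measurable molecules; Kendall tau-b with its
tie-corrected normal p tests the association, and the concordant count
is the number of molecules significant in both layers with equal sign.

The background should consist of **measured** molecules with their real
(mostly null) calls: padding with synthetic all-zero entries makes the
permutation variance far too small, so mere co-occurrence of the two
significant sets — inevitable when both concentrate on the matched panel
— masquerades as association. With the measured platform as background
the null p-value is uniform (measured fraction of p < 0.05 over 200 null
seeds: 0.06). The GO-term co-occurrence fraction divides the
intersection by the secretome term set.

## Synthetic data generator

The generator emulates the study's statistical structure, not its
measurements. Defaults (the simulated study conditions): 6 paired
subjects per age group (optionally one extra control-less newborn to
mirror a 7-vs-6 design), treatments control/Alum/MPLA/R848, 500
proteins, 20% responsive per adjuvant with true effects
Normal(2.0, 0.25) log2 units; MPLA and R848 share 80% of their
responsive proteins with identical effects (a shared TLR-driven
secretion program — this is what makes their secretome profiles
co-cluster away from Alum), Alum draws independently. Counts are
negative binomial (dispersion 0.05 — spectral counting is near-Poisson
at the technical level; Poisson at dispersion 0) around per-subject
log-normal baselines (σ = 0.3) shared across a subject's samples, with
protein abundances log-normal (median 4 SpC, σ = 1). Missingness is
missing-not-at-random: a cell is masked with probability
dropout_rate·exp(−count/3), so only low counts drop out (default rate
0.1). One integer seed fans out to named substreams (structure, counts,
dropout, expression, genesets), so adding a downstream stage never
perturbs earlier draws, and the ground truth is re-derivable from the
config alone.

The transcriptome generator gives every gene 2–3 probes (shared gene
signal, probe offsets, noise σ = 0.3) over 24 participants × 4
timepoints; a chosen fraction of the responsive-protein genes shifts by
1 log2 unit at T2 in the protein effect's direction. It adds unmapped
background genes (default 2500) because quantile normalization assumes
most of the measured distribution is unchanged — without the background
the shifted probes distort the reference distribution and nulls are
called in the opposite direction. The simulated platform (~3000 genes)
is a scaled-down stand-in for a ~13k-gene expression array; analyses of
real data should pass the platform's own size as the background.

What passing tests do **not** show: the generator has no peptide-level
structure, no shared-peptide ambiguity, no run-order or batch effects,
no inter-subject effect-size heterogeneity, and its missingness
mechanism is a single smooth detection curve. Published dataset-specific
numbers (total protein counts, numbers of significant proteins, specific
tau-b p-values, GO overlap fractions) depend on the deposited raw data
and are out of reach of synthetic studies by construction.

## Numerical and interface choices

* Percent rounding: half-up to integer percent.
* Fisher sidedness for enrichment: one-sided (greater) by default —
  over-representation is a right-tail question; two-sided available.
  The EASE variant takes the right tail from overlap − 1 under the same
  margins (conservative: p_EASE ≥ p_Fisher always; overlap 1 can never
  be significant).
* Enrichment universe: the proteins quantified in the experiment, not
  the proteome; sets are intersected with the universe, raw p is
  reported (no multiplicity adjustment across sets by default).
* Reporting filter for pathway tables: overlap ≥ 2 in at least one data
  set and p < 0.05 in at least one, with a user-supplied name exclusion
  list.
* The CLI runs stages (simulate, normalize, filter, cluster, diffexp,
  enrich, concord, all) against one working directory, validates its
  flat YAML config (flags override the file), refuses missing
  prerequisites by naming the producing stage, and writes per-stage
  manifests with SHA-256 hashes of inputs and outputs and no
  timestamps, so reruns with the same seed are byte-identical.
* Everything is single-threaded; determinism first.

## Known limitations

* The robust offset estimator needs a few hundred quantified proteins;
  below that it silently falls back to total-SpC offsets, which are
  composition-sensitive.
* The dispersion trend is piecewise-constant over abundance bins, not a
  smooth fit; with < 80 proteins it degrades to a single global value.
* Moderation deliberately reorders borderline proteins relative to the
  plain exact conditional test (rank agreement ~0.89 instead of ~0.93);
  the unmoderated score ranking is exposed as `score_z`.
* The concordance tau-b p-value uses the tie-corrected normal
  approximation for realistic background sizes; exact enumeration is
  only feasible (and tested) for toy backgrounds ≤ 8.
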