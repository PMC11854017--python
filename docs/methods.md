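# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `stpscore`, in the order the pipeline runs them.

## Pathway activity model

Each signal transduction pathway (STP) is represented by a three-layer
Bayesian network: a binary root `T` for the transcription complex
(active/inactive), one binary node per target gene (transcriptionally
up/down) and one binary node per probe (observed intensity above/below a
threshold). Probes are conditionally independent given their gene's state
and genes are conditionally independent given `T`, so the posterior odds
factorize over genes and the per-sample pathway activity score (PAS) is
the log2 posterior odds of the active state. A brute-force enumerator of
the full joint (`brute_force_pas`, feasible up to 12 genes) is kept as an
independent oracle; for this tree-shaped network the factorization is
exact, and the test suite verifies agreement to 1e-9 on randomized models.

Assumptions worth stating plainly:

* **Hard probe evidence.** Observations enter as threshold indicators,
  not as continuous likelihoods. This is the simplest scheme consistent
  with a discretized network; a soft-evidence observation layer would be
  a natural extension but is not implemented.
* **Tie-break.** A value exactly equal to the threshold counts as
  "high". This is arbitrary but deterministic and documented.
* **Conditional independence.** Probes of one gene and genes of one
  pathway are treated as independent given their parent. Real target
  genes are co-regulated by other factors; the score is therefore best
  read as a calibrated evidence aggregate, not a generative fit.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| π | prior P(pathway active) | 0.5 | uniform prior makes PAS = 0 the indifference point |
| α | P(gene up \| active), direction +1 | 0.95 | strong but not deterministic TF→target link |
| β | P(gene up \| inactive), direction +1 | 0.05 | mirror of α; swapped roles for direction −1 targets |
| κ | Laplace pseudocount in calibration | 1 | keeps every CPT entry strictly inside (0,1) |
| clamp | |PAS| ceiling | 64 | keeps downstream statistics finite under degenerate CPTs |

Calibration estimates the probe layer from labeled reference samples: the
threshold is the midpoint between label-conditional means, and exceedance
probabilities are smoothed counts `(c + κ)/(n + 2κ)`. For down-regulated
targets the label roles swap, so the gene-layer invariant (α > β for
up-targets, α < β for down-targets) holds by construction. Probes constant
across training samples carry no information and are dropped with a
warning; a gene whose probes are all missing at scoring time is dropped
and counted, which for this network equals exact marginalization. No
imputation is performed anywhere.

### Score semantics

PAS values are log2 odds on a per-pathway scale: every calibrated model
has its own attainable range, so scores are comparable between samples
within one pathway, never across pathways, and a negative score does not
by itself mean the pathway is off. The library exposes no cross-pathway
normalization, and the pipeline's summary output carries this disclaimer
in its header. Reproducing any published absolute PAS values is explicitly
a non-goal: those depend on proprietary calibrated models and curated
target-gene lists; the bundled definitions are synthetic placeholders that
exercise the machinery only.

## Quality control

QC operates on the summarized log2 matrix plus a feature annotation that
flags control features. Per sample it computes: mean probe intensity,
median ("center of intensity"), counts of negative and saturated values
(saturation at log2(2^16) = 16, the 16-bit scanner ceiling), 3′/5′ ratios
for housekeeping probe pairs (GAPDH, ACTB) computed as `2^(log2 3′ − log2
5′)` and reported on the linear scale as is conventional, spike-in
presence for poly-A (sample preparation) and hybridization (cRNA) spike
classes, border-control means, and a degradation slope proxy over features
ordered by an annotation-supplied 5′→3′ index when one is available.
Checks that lack the needed control features are reported "not evaluable",
never as a pass. True probe-level degradation statistics require CEL-file
data and are out of scope.

No community-agreed matrix-level pass thresholds exist, so the defaults —
mean intensity within [4, 12] log2, 3′/5′ ratio ≤ 3.0, no negative and no
saturated values — are this package's documented, config-overridable
defaults, not literature values.

## Group statistics

* **Unpaired designs**: two-sided Mann-Whitney U with Bonferroni
  correction. The exact null distribution is used when the combined
  sample size is ≤ 12 and tie-free; otherwise the tie-corrected normal
  approximation (scipy). The Bonferroni family defaults to the contrasts
  within one pathway — matching per-panel annotation practice — with an
  across-pathways option.
* **Paired designs**: two-sided paired t-test on within-pair
  differences. All-zero differences give p = 1 by convention; a constant
  non-zero difference is degenerate and raises.
* **Time courses**: linear mixed-effects model with categorical time and
  a random intercept per subject (statsmodels MixedLM, REML). Each
  post-baseline time is contrasted against baseline on the paired subset.
  The per-contrast p-value is a Wald t-test of the time coefficient
  against a t reference with `n_subjects − 1` degrees of freedom. The
  asymptotic chi-squared likelihood-ratio reference was evaluated first
  and rejected: at 8 subjects it rejected ~3.4% of null contrasts at
  nominal 1%, while the between-within t reference is exactly calibrated
  for the balanced paired subset (it reduces to the paired t-test there)
  and stays inside the binomial Monte-Carlo band in the test suite. When
  the subject variance estimate sits on the zero boundary and the REML
  Hessian is singular, the fallback is the complete-pair difference
  statistic — the boundary limit of the same quantity.
* **Annotation**: `****` p < 0.0001, `***` p < 0.001, `**` p < 0.01,
  `ns` otherwise; p < 0.01 is the significance cut throughout.

## Synthetic cohorts

The generator produces log2 expression values under an additive model:
feature baseline `μ ~ Uniform(5, 10)`, pathway effect `d·δ·a` on target
probes (direction `d`, effect size `δ`, programmed activity `a ∈ [0,1]`),
subject random intercept `u ~ N(0, τ²)`, and Gaussian noise
`ε ~ N(0, σ²)`. Nuisance features (default 500) carry no activity term;
AFFX-style control features sit at fixed intensities (3′/5′ pairs at 10.0
each, hence ratio 1; spikes at 11–12; border positives at 13, negatives
at 2) so QC has material to work on. Corruptions — negative values,
saturated values, extreme 3′ bias (+4 log2 on 3′ controls, ratio 16) —
are applied last and are exactly the failure modes QC must catch.

Defaults δ = 1.5 log2, σ = 0.5, τ = 0.3 are this package's choices: a
three-standard-deviation target-gene shift is a strong but realistic
stimulation response for immune target genes, and τ < σ reflects that
technical-plus-sampling noise usually dominates stable subject offsets in
short stimulation designs. No distributional parameters for real LPS
responses were available to copy; these values were fixed once for
testability and realism, not tuned.

Four templates mirror common sepsis/LPS study shapes and their published
sample sizes: a two-group PBMC sepsis cohort (16 healthy vs 54 septic,
split 16/18/6/14 across Gram-positive/Gram-negative/mixed/unidentified
subgroups; only AR raised, only in the Gram-positive subgroup), a
primed/unprimed PBMC LPS design (6 donors × 3 arms, all null — PBMC LPS
stimulation does not move these pathway scores), a paired whole-blood
vehicle/LPS design (4 subjects; NFκB, JAK-STAT1/2, JAK-STAT3 respond), and
an in vivo endotoxemia time course (8 subjects at 0/2/6 h; NFκB, AR, TGFβ,
JAK-STAT3 on from 2 h, JAK-STAT1/2 only at 6 h, plus an always-inactive
CONTROL pathway for null checks). Activity is encoded at the condition
level; cell-mixture composition shifts, gene-gene correlation beyond
pathway structure, and probe-level array physics are deliberately not
modeled — so passing tests demonstrate the statistical machinery works
under its stated assumptions, not that it is robust to real-data artifacts
like batch effects or cell-type deconvolution.

## Pipeline

`run_study` chains QC → calibration (or model loading) → scoring → the
design-appropriate statistics, writing TSV tables, a QC report and a JSON
manifest with a content hash per output file. Runs are deterministic given
config and seed (verified byte-for-byte in tests). Group summary SDs use
the n−1 denominator; single-sample groups get an NA marker. A contrast
whose groups fall below two usable samples after QC is reported "not
evaluable" while the run still succeeds.

## Problem sizes used in the checks

The verification suite runs at sizes chosen to make each property sharp at
desk scale: 1000 random ≤4-gene models for the inference oracle,
20/20-sample calibration sets with 25/25 held out per pathway, full
permutation enumeration for all Mann-Whitney group sizes with n+m ≤ 10,
2000-replicate null simulations for the rejection-rate checks (300 for the
mixed-model calibration, whose fits dominate runtime), and single cohorts
of the published template sizes for the end-to-end checks.

## Known limitations

* Hard-threshold evidence discards within-bin intensity information.
* Placeholder target-gene lists carry no biology; real analyses need
  curated lists and reference samples for calibration.
* The matrix-level QC analogs cannot reproduce probe-level (CEL) QC
  statistics; degradation is a proxy slope, evaluable only with a 5′→3′
  feature index.
* The mixed model fits a random intercept only; random slopes are not
  supported.
* No normalization is applied or validated; matrices are scored as given,
  with only a scale-tag heuristic (log2 vs linear) guarding unit errors.
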