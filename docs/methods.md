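# Methods

## The subtyping procedure and its assumptions

`omnisub` treats molecular subtyping as a survival-guided model-selection
problem. For one platform the cohort is a feature-by-sample matrix X and a
right-censored survival table (event ∈ {0, 1}, time in days, both per
patient; one primary-tumor sample per patient is assumed — when several
map to a patient the lexicographically first sample id is kept and
logged).

**Feature screen.** Each feature is standardized (z-score) and fit alone in
a Cox proportional-hazards model by Newton–Raphson on the Breslow partial
likelihood. The Wald test supplies the per-feature p-value; features with
p < α (default 0.05) are retained *without multiple-testing correction* —
the screen is a deliberate high-recall filter, and a Benjamini–Hochberg
option (`bh_correct=True`) exists for users who want FDR control instead.
Zero-variance features and non-converged fits (monotone likelihood, |β|
drifting beyond 50 on the standardized scale) are excluded, never
selected. Count-like platforms (mRNA, miRNA) are log2(x+1)-transformed
before screening and clustering; methylation (already bounded) and protein
(already roughly symmetric) are used as-is. Features with more than 20 %
missing values are dropped; remaining missing values are median-imputed
per feature.

**Cluster sweep.** Three algorithms run for every N in 2…9:

- *PAM* — k-medoids on Euclidean distances between samples over
  standardized features; greedy BUILD seeding followed by steepest-descent
  SWAP to a local optimum. A sub-measurement-precision (≤1e-9) symmetric
  jitter seeded by the run seed breaks exact distance ties
  deterministically.
- *HC* — scipy agglomerative clustering (average linkage by default;
  complete and Ward available, correlation distance optional), cut to
  exactly N groups.
- *NMF* — Frobenius-error multiplicative updates, best of 10 random
  restarts (uniform init scaled to the data mean), tolerance 1e-5 on the
  relative objective decrease, 500 iterations max. Samples are assigned to
  the argmax component of their H column; restarts whose assignment leaves
  an empty cluster are discarded. Real-valued input is first min-shifted
  per feature to be non-negative; rows constant after the shift carry no
  information and are dropped.

**Model selection.** Every candidate partition is evaluated by the
k-sample log-rank test (hypergeometric observed-minus-expected events,
chi-square with N−1 df) and scored

    score = −log10(p) − λ·(N − 2),   λ ≥ 0, default 1.

The score rises as the survival separation sharpens and falls linearly in
the cluster count, with N = 2 unpenalized; λ = 0 reduces selection to
minimum-p. Ties break toward the smaller N, then PAM < HC < NMF. p = 0
underflow is clamped to the smallest positive float with a warning rather
than propagating infinities. The raw (method, N, p) sweep table is always
emitted so any alternative penalty can be recomputed externally.

A known behavior of this criterion, visible in the validation runs: when
the subtype hazards are close on the log scale, merging the two closest
hazard groups costs only a fraction of a decade of log-rank p while saving
a whole penalty unit, so the selected N can sit below the planted number
of subtypes even when the clustering itself recovers the planted labels
essentially perfectly. The per-cluster Kaplan–Meier medians and the sweep
table make this visible in any concrete run. Singleton clusters produced
by HC chaining can also carry extreme log-rank statistics; inspecting the
emitted cluster sizes is advised before interpreting a selected model.

**Pathway activity.** Gene-level change for a sample is
logFC(g, s) = log2((x(g,s)+ε)/(mean_s' x(g,s')+ε)) with pseudocount ε = 1
on count-like expression (configurable; ε enters numerator and
denominator alike). Changes propagate through a signed, weighted topology:
PF(g) = ΔE(g) + Σ_j β_{j→g}·PF(j)/n_downstream(j), a linear system
(I − M)·PF = ΔE solved per pathway for all samples at once; the pathway's
per-sample activity is tA = Σ_g (PF(g) − ΔE(g)). All measured pathway
genes contribute (no differential-expression cutoff), because activity is
computed per sample for survival binding rather than for a two-group
contrast. Pathways whose system is numerically singular (condition number
above 1e12, e.g. an unbroken positive feedback cycle) are marked
unavailable and excluded with a report. Genes absent from the expression
matrix enter with ΔE = 0 and their fraction is reported. Topologies are
consumed as user-supplied edge lists (`pathway_id, source_gene,
target_gene, beta`); nothing is fetched from KEGG.

**Characterization.** Subtype gene sets use the linear-scale one-vs-rest
ratio (mean in cluster + ε)/(mean in all other clusters + ε) with ε
defaulting to the smallest positive matrix value; thresholds 2.0 (up) and
0.5 (down). Heatmap rows group by the cluster of maximal up-regulation
(descending ratio within a block, not-up features appended last in input
order). Enrichment is a one-sided hypergeometric upper tail against GMT
terms intersected with the user-declared universe, significant at raw
p < 0.05. Clinical association uses one-way ANOVA for declared
quantitative variables and the two-way chi-square independence test
(cluster × category) for categorical ones — the independence test is the
coherent reading of "association with the subtypes" even where a one-way
table test might be quoted; variables with a single observed level are
skipped with a note, and tables with >20 % expected cells below 5 are
flagged `low-count` but still reported.

**Integration.** Two partitions are compared on their shared samples: an
overall chi-square independence test on the k_A × k_B table (empty
rows/columns dropped) plus, per cluster pair, a 2×2 chi-square without
continuity correction on (in a vs not) × (in b vs not), star-coded at
0.05/0.01/0.001. Stars are assigned from the p-value alone; a separate
`pair_enriched` flag records whether the pair co-occurs above expectation,
and the "matched starred pairs" summary counts Hungarian-matched,
positively associated, starred pairs — the label-free analogue of a
starred diagonal.

## The synthetic cohort generator

The generator emulates the structure of a TCGA-style SOC cohort and is the
package's test bed. Per platform a latent Gaussian matrix z ~ N(μ_p, 1) is
drawn; each informative feature (fraction `frac_informative`, default 0.1
— a minority of features) receives a random non-empty proper subset of the
k_true subtypes in which its latent mean is shifted by `effect_size`
(default 1.5 within-group standard deviations). Subset patterns rather
than single-subtype bumps are used so that informative features separate
every pair of subtypes and so that features for hazard-middle subtypes
still carry marginal survival signal. The latent matrix is pushed through
a platform link: logistic for methylation (beta values in (0,1)),
exponential for mRNA/miRNA (non-negative, right-skewed, count-like),
identity for protein. Survival is exponential per subtype
(default hazards 0.004, 0.0023, 0.0013, 0.0008 events/day — log-spaced
spanning 5×, the arrangement that maximizes the minimum survival contrast
lost by merging any two subtypes); censoring is an independent exponential
whose rate is calibrated by bisection so the expected censored fraction
matches `censor_rate` (default 0.47, matching the cohort the package
models). Times are reported as whole days (≥1). Partial platform coverage
drops a seeded random patient subset per platform, mirroring differing
per-platform case counts. The clinical table carries one quantitative and
one categorical variable correlated with subtype plus one null variable of
each kind, giving the clinical-association test known positives and
negatives.

What the generator does **not** emulate: batch effects or
platform-specific noise models, copy number or mutation data,
non-proportional hazards, feature–feature correlation beyond the shared
subtype structure, or realistic marginal distributions of any real
platform (no public distributional description exists for the cohorts the
package models, so all generative choices are declared stand-ins). Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the statistics under a clean planted model — not performance on real
tumor data.

## Numerical choices

- Cox Newton steps are clipped to ±2 per iteration; convergence at
  |step| < 1e-9, at most 50 iterations. Tied event times share a Breslow
  risk-set denominator.
- The Cox score test at β = 0 is exposed separately; for a binary
  covariate with no tied event times it equals the classical two-group
  log-rank chi-square (verified to ~1e-15 in the validation suite).
- NMF denominators carry a 1e-12 guard; the objective trace is recorded
  every iteration and is monotone non-increasing up to float rounding.
- Percentages in clinical summaries round half-up to one decimal, with
  missing values as their own category, so published cohort tables
  reproduce digit-for-digit from their counts.
- Cluster labels are canonicalized to 1..k in order of first appearance,
  making partitions invariant (up to that relabeling) to sample order.

## Validation experiments (scripts/acceptance.py)

Problem sizes were chosen to exercise each property at desk scale: 20
random instances of 6–8 samples for the PAM-versus-exhaustive oracle; 20
null cohorts of 500 features × 300 patients for screen calibration; 20
random 15×10 matrices plus one exact rank-3 factorization for the NMF
properties; 20 random DAG topologies for tA linearity; 50 random sweep
tables for selection behavior; and 10 planted 4-subtype cohorts of 600
patients (mRNA 2000 features, methylation 500) for end-to-end recovery and
cross-platform overlap. All randomness derives from the single `--seed`
argument.

## Known limitations

- The complexity penalty is linear with λ = 1 by default; as noted above
  it can select a merged model when subtype hazards are close. λ is a
  config knob and the sweep table is always written.
- The screen's raw-p selection inflates the selected-feature count at high
  dimension by design (≈α of null features); use `bh_correct` when a
  controlled FDR matters.
- Per-pair overlap tests use the asymptotic 2×2 chi-square by default; a
  hypergeometric (Fisher) exact alternative (`exact=True`) is recommended
  when `low_count` is flagged on small shared-sample sets.
- The pipeline assumes sample ids equal patient ids after cohort
  filtering; multi-sample patients must be resolved upstream.
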