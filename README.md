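# omnisub

Survival-guided multi-omics subtyping of serous ovarian cancer (SOC)
cohorts.

Morphologic classification of SOC carries little prognostic information, so
molecular subtyping works directly from multi-platform cohort data — DNA
methylation beta values, reverse-phase protein array abundances, miRNA and
mRNA expression — together with right-censored overall survival. `omnisub`
implements that workflow as a tested, reusable library for computational
biologists who want to subtype a cohort per platform and ask whether the
subtypings agree across platforms:

1. **Cox screening.** Every molecular feature is fit in a univariate Cox
   proportional-hazards model against overall survival (Breslow ties,
   standardized covariate); features with Wald *p* < 0.05 form the
   clustering feature set.
2. **Cluster sweep.** Three unsupervised algorithms — Partitioning Around
   Medoids (PAM, BUILD + SWAP), agglomerative hierarchical clustering (HC)
   and non-negative matrix factorization (NMF, multiplicative updates with
   restarts) — are each run for every cluster count *N* = 2…9.
3. **Model selection.** Each candidate partition is scored by the k-sample
   log-rank test of its survival split, penalized for complexity:

   `score(N) = −log₁₀(p_logrank) − λ·(N − 2)`,  λ = 1 by default.

   The highest-scoring (method, N) is the subtyping model; per-cluster
   Kaplan–Meier medians describe the subtypes.
4. **Pathway activity.** Expression can be converted to per-sample pathway
   features: per-gene log₂ fold change against the cohort mean, propagated
   through signed KEGG-style topologies to a net accumulated perturbation
   (tA) per pathway, in the style of signaling pathway impact analysis.
   The pathway-by-sample matrix then flows through the same pipeline.
5. **Characterization & integration.** Subtype-specific gene sets
   (≥2-fold up / ≤0.5-fold down versus the rest of the cohort),
   heatmap row ordering, hypergeometric enrichment against GMT gene sets,
   one-way ANOVA / chi-square clinical association, and cross-platform
   subtype overlap tests with 0.05/0.01/0.001 star coding.

A first-class synthetic-cohort generator (`omnisub.simulate`) plants known
subtypes, prognostic features and censored exponential survival so every
stage is testable end to end without access to patient data.

## Worked example

```python
from omnisub import SimulationConfig, simulate_cohort, subtype_platform

cfg = SimulationConfig(n_patients=240, k_true=3,
                       platform_dims={"mrna": 500},
                       hazard_per_subtype=(0.004, 0.0015, 0.0008),
                       frac_informative=0.15, effect_size=1.5,
                       censor_rate=0.47, seed=42)
cohort = simulate_cohort(cfg)
result = subtype_platform(cohort.matrices["mrna"], cohort.survival, seed=42)
print(f"selected: {result.selected.method} with N={result.selected.N} "
      f"(log-rank p = {result.selected.logrank_p:.3g}, "
      f"score = {result.selected.score:.2f})")
print(result.medians.to_string(index=False))
```

prints

```
selected: PAM with N=3 (log-rank p = 8.91e-21, score = 19.05)
 cluster  n  median_days
       1 62        135.0
       2 80        975.0
       3 98        457.0
```

The pipeline screens the 500 genes down to the prognostic subset, sweeps
PAM/HC/NMF over N = 2…9 and selects PAM with three subtypes — matching the
three planted subtypes (adjusted Rand index 0.79 against the planted
labels for this seed) — whose Kaplan–Meier median survivals (135, 975 and
457 days) reflect the three planted hazard rates.

The same workflow is available from the shell:

```sh
omnisub simulate --config sim.yaml --out cohort/ --seed 7
omnisub screen  --matrix cohort/mrna.tsv --platform mrna \
                --survival cohort/survival.tsv --out screen.tsv
omnisub cluster --matrix cohort/mrna.tsv --platform mrna \
                --survival cohort/survival.tsv --kmin 2 --kmax 9 \
                --seed 7 --out out/
omnisub run --config pipeline.yaml     # all platforms + integration
```

## Layout

- `src/omnisub/containers.py` — matrix/survival/clinical/partition types
- `src/omnisub/simulate.py` — synthetic cohorts with planted subtypes
- `src/omnisub/io.py` — TSV dialects, cohort filtering, clinical summaries
- `src/omnisub/survival.py` — Cox screen, Kaplan–Meier, log-rank
- `src/omnisub/cluster.py` — PAM, HC, NMF, k-sweep
- `src/omnisub/select.py` — penalized score and model choice
- `src/omnisub/pathway.py` — logFC and tA pathway activity
- `src/omnisub/characterize.py` — gene sets, enrichment, overlap, clinical
- `src/omnisub/pipeline.py` — per-platform driver and integration
- `docs/methods.md` — model assumptions, defaults and limitations
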