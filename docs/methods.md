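# Methods

This note documents the models and procedures implemented in `adsubpop`,
the defaults and why they were chosen, what the synthetic cohort generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Preprocessing

The pipeline consumes a visit-level clinical table (one row per patient
clinic visit) and runs a fixed, logged sequence:

1. **Diagnosis filter** — analysis restricted to the AD arm by default.
2. **High-missingness drop** — features missing in strictly more than 20%
   of rows are removed (`missingness_threshold`, configurable); the digit
   span score is the canonical casualty in this data dialect.
3. **Censored strings** — assay values reported against detection limits
   (`"<200"`, `">1700"`) are converted to the limit value. This is lossy by
   design and counted in the `PreprocessReport`.
4. **Categorical coding** — levels map to integers 0..L−1 in lexicographic
   order (no ordering is clinically meaningful; lexicographic is
   deterministic and round-trips through the stored code book).
5. **Deskewing** — per continuous feature, the transform among
   {identity, log(x − min + 1), cube root} minimizing the bias-corrected
   |sample skewness| is applied. A rank-based piecewise linearization to
   uniform scores ((rank − ½)/n) exists as a last resort, used only when
   the best parametric candidate leaves |skew| > 2: rank scores have
   *exactly* zero skewness for distinct values, so admitting them to an
   unconditional argmin would select them always while destroying all
   spacing information. The threshold 2 corresponds to the conventional
   notion of severe skew.
6. **Standardization** — z-scores with the **population** standard
   deviation (divide by n). Any fixed convention satisfies the pipeline's
   invariants; population sd makes the output column sd exactly 1 and the
   test fixtures exact. Constant columns are centered only and flagged.
7. **KNN imputation** (k = 5) — missing cells are replaced by the mean of
   the k nearest rows that observe the feature, with Euclidean distance
   over mutually observed standardized features rescaled by
   √(d/n_shared) so that rows sharing few features are not artificially
   close. Observed cells are never altered (bitwise). Imputation follows
   standardization so distances are scale-free; the reverse order is a
   known sensitivity-analysis axis.

The pipeline is fully deterministic: identical input and options produce a
byte-identical analysis matrix.

## Embedding and clustering

**PCA** is plain SVD of the centered matrix with component signs fixed
(largest-magnitude loading positive) for determinism.

**t-SNE** is the exact O(n²) algorithm, appropriate at cohort scale
(hundreds of rows): per-row Gaussian bandwidths found by bisection until
each conditional distribution's entropy is within 1e−4 nats of
log(perplexity); symmetrized joint affinities P; Student-t (1 df)
low-dimensional kernel; gradient descent with early exaggeration ×12 for
250 iterations, learning rate 200, momentum 0.5 → 0.8 at iteration 250,
adaptive per-parameter gains, 1000 iterations total. These are the
canonical defaults of the original algorithm; all are configurable.
Perplexities ≥ (n−1)/3 are shrunk with a warning. The per-iteration KL
divergence (against the un-exaggerated P) is recorded; it can rise while
exaggeration is active and must descend afterwards.

**k-means** is Lloyd's algorithm with k-means++ seeding, 10 restarts (best
inertia wins), tolerance 1e−6 on centroid movement, ties in assignment to
the lowest centroid index, and empty-cluster repair by reseeding at the
farthest point. Within-run inertia monotonicity is asserted on every run.
**DBSCAN** uses the standard core/border/noise labeling with discovery-order
cluster ids (defaults eps 0.5 on standardized embeddings, min_samples 5).
All distances everywhere are Euclidean.

**Choosing k.** "Where the scores fluctuate most" is not an algorithm, so
the implemented rule is: sweep k over [2, 12], average silhouette and
Calinski–Harabasz over seeds, select the silhouette argmax (ties → smaller
k), and return the full score table so the fluctuation pattern can be read
alongside the automatic choice. Silhouette follows the convention that
singleton-cluster points contribute 0 and noise points are excluded.

## Cluster profiling

Each cluster is compared against **its complement**, not against the full
cohort: a subset-vs-superset comparison would correlate the two samples
and invalidate the t-test's independence assumption; the complement
comparison preserves the intent ("is this cluster's mean different from
everyone else's?") and is statistically defensible. The literal reading is
available via `include_self=True`. Continuous features get a Welch t-test
(Welch–Satterthwaite df), categoricals a Pearson χ² against expected
counts scaled from the overall relative frequencies.

Family-wise control at α = 0.05: within a feature, the k cluster
comparisons get a Tukey-HSD-style adjustment through the studentized range
(q = |t|·√2 with k groups at the Welch df); χ² comparisons get Bonferroni
within the feature (no studentized-range analogue exists); Bonferroni
across features then sets the family threshold. Raw p, adjusted p and the
threshold are all retained.

**Fold changes** are computed on the original (pre-z-score) feature scale
— the percent change of a z-scored feature is ill-defined near mean zero —
as 100·(x̄_c − x̄)/|x̄|, and direction-standardized: deficit-direction
features (ADAS scales, trail-making time, percent forgetting, CDR sum of
boxes, FAQ) are sign-flipped so that positive always means less severe
disease. The severity summary averages the standardized fold changes over
a brain-volume axis (7 regional/whole-brain volume features) and a
cognitive-performance axis (the remaining 15 profiled features), with the
population sd as the error bar.

Severity **ranking** deliberately emits two orderings instead of choosing:
the unweighted mean of the two axes, and the volume-first ordering implied
by the brain-reserve hypothesis (larger volumes tolerate more pathology
before cognitive decline shows). On the built-in reference profile these
genuinely disagree — combined mean gives (least→most severe) 1, 3, 0, 2;
volume-weighted gives 1, 0, 3, 2 — and the choice between them is a
scientific judgment, not an arithmetic one.

The built-in reference profile (`REFERENCE_PROFILE`) is the published
per-feature percent fold-change table of the four clinical AD
sub-populations identified in the ADNI AD cohort. One entry (cluster 2,
mPACCdigit_bl, +15.752) is positive as published although the surrounding
pattern for that most-severe cluster suggests a sign error in the source;
it is kept as published, and consequently the cluster-2 cognition axis
recomputes to ≈ −16.3 rather than the −18.4 summary figure quoted
alongside the table. The other seven axis aggregates reproduce exactly to
one decimal.

## Association rule mining

Each patient visit is one transaction; items are normalized drug tokens,
their pharmacologic class tokens, a diagnosis token and a cluster token.
Brand and generic names are intentionally **not** merged (Aricept ≠
donepezil) so brand-level patterns stay visible; the class layer
(cholinesterase inhibitors, NMDA receptor antagonists, serotonin reuptake
inhibitors, HMG-CoA reductase inhibitors, antioxidant vitamins, ...)
provides the merged view. The bundled lexicon covers ~40 spellings; users
can extend it from CSV.

Apriori is capped at two joined singletons — appropriate to a cohort of
hundreds of patients, where 3-itemsets are too sparse to support — with
exact integer counting, min support 0.001, and rule thresholds confidence
≥ 0.7 and lift strictly > 1 (lift exactly 1 is independence, not
association; the strictness is configurable). Conviction at confidence 1
is serialized as the string `"inf"` to keep files parseable. Transactions
are visit-level but coverage reporting deduplicates to distinct patients;
both counts are kept. Cluster overlay reports, for every cluster, the
drug/class antecedents of passing rules with that cluster as consequent —
explicitly including clusters with no passing rule, which is itself a
finding (the least-severe sub-population characteristically has none).

## Synthetic cohort generator

The generator emulates the study population the pipeline targets: 424 AD
patients (one baseline visit each by default; multi-visit behind a flag)
in four equally likely latent sub-populations. Feature values are

    value = base_mean + (offset_pct/100)·|base_mean| + N(0, noise_sd),

so the expected percent fold change of a sub-population equals its planted
offset for every feature — including the negative-mean mPACC composites,
which a multiplicative form would sign-flip. The default effect matrix is
the reference profile above (plus small severity-consistent offsets for
CDR sum of boxes and FAQ); categorical sociodemographics follow the
published cohort proportions; printed cohort means/sds are used where
available and plausible clinical values elsewhere.

`noise_scale` (default 0.5) sets the within-subpopulation sd as a fraction
of the cohort-level sd, splitting cohort variance roughly evenly between
within- and between-subpopulation components. The value was fixed
analytically before any end-to-end run: it yields a minimum pairwise
centroid separation of ≈ 6.3 within-cluster sds across the four planted
sub-populations (≈ 0.08% nearest-pair misassignment), i.e., clearly
separable sub-populations — the regime the analysis is designed for.

Realism injections: one feature (digit span analog) missing in ~25% of
rows to exercise the drop rule, 2–4% missingness on several cognitive
scores to exercise imputation, assay-floor censoring on the CSF
amyloid-beta column (values below 200 pg/mL emitted as `"<200"`), and
medication names emitted in mixed spelling dialects. Medication baskets
are drawn independently per drug and visit with group-conditional
probabilities; the default enrichments plant the pattern the overlay
should find (statins in sub-population 0, Zoloft in 2, antioxidant
vitamins in 3, nothing sub-population-specific in 1, AD-wide symptomatic
therapies, vitamin D in the cognitively normal arm only).

**What the generator does not emulate** — and hence what passing tests do
not establish about real registry data: between-feature correlation within
patients (real cognitive scores are strongly correlated; here noise is
independent per feature), visit schedules and dropout, informative
missingness, label noise in the diagnosis, and polypharmacy correlation
between drugs. Recovery results on this generator demonstrate the
pipeline's correctness, not the clinical validity of any particular
clustering of real cohorts.

## Statistical resolvability of planted signs

Sign recovery of a planted fold change is a power question: a cell
(feature × sub-population) is reliably sign-identifiable only when its
planted mean shift is large relative to the standard error of the
sub-population mean, |Δ| ≥ z·σ_noise/√(n·π). The acceptance checks use
z = 4.5 (per-cell flip probability ≈ 3×10⁻⁶), which covers all volumetric
cells and most cognitive ones; small offsets on high-variability features
(e.g., a 3.4% shift on trail-making time, CV ≈ 0.45) are excluded because
no correct implementation could recover them consistently at this cohort
size.

## Problem sizes and tolerances

Stochastic recovery checks run the full pipeline at the study's cohort
size (n = 424) over 10 seeds for k selection and adjusted Rand index, and
20 seeds for sign recovery and the medication overlay pattern; property
checks use 500 random transaction databases (Apriori vs brute-force
enumeration, exact), 200 random small instances (k-means vs exhaustive
optimum, ≥95% within 1e−9), and reference-implementation agreement within
1e−9 for silhouette, Calinski–Harabasz, Welch t and χ². Perplexity
calibration is verified to 1e−4 in log-space. Degenerate inputs
(constant vectors, single-level categoricals, empty clusters, zero
within-cluster variance, confidence-1 rules) have defined, tested
behavior rather than errors wherever a sensible value exists.

## Known limitations

- Exact t-SNE is quadratic in n; the implementation targets cohorts of
  hundreds, not tens of thousands (no Barnes–Hut/FFT variant).
- The deskew transform set is fixed and univariate; no Box–Cox/Yeo–Johnson.
- Rule mining is cross-sectional: medication start dates are not modeled,
  so no temporal or causal claims attach to any rule.
- The severity axes weight all member features equally; a variance- or
  reliability-weighted composite is a possible refinement.
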