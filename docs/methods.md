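# Methods

## Problem and data model

The unit of analysis is a clinical note reduced to a bag of normalized
problem concepts (CUI-like identifiers) plus a practice-setting label.
Raw institutional labels ("Family Medicine BA", "Ped Neonatology-I") are
merged into general settings through a user-supplied two-column mapping
table; concepts may be restricted to an allow-list (e.g. a problem-list
subset of a clinical terminology); and a fixed number of notes per setting
(default 1000) is sampled for the analysis so that large settings do not
dominate. Concepts are multisets: repeated mentions count, because the
frequency term of the TF-IDF score is an occurrence count.

## Representative-concept selection

**χ² stage.** Association between a concept and a setting is tested on the
2×2 *document-level presence* table (a: docs in the setting containing the
concept, b: in-setting lacking it, c: out-of-setting containing it, d:
neither) with the Pearson statistic n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), no
continuity correction, defined as 0 when a margin is empty. Presence
rather than token counts is the standard text-categorization usage and
matches the 1-df cutoff. The cutoff 6.64 is the conventional printed
χ²(1) value for P < 0.01 (the exact 0.99 quantile is 6.6349, so a strict
χ² > 6.64 comparison guarantees P < 0.01). All three filter comparisons
are strict.

**TF-IDF stage.** Survivors are scored with TFIDF = F_{c,s}/log(1+N/n_c),
natural log. F_{c,s} defaults to the concept's occurrence count in the
setting's documents (`tf_mode="doc_frequency"` switches to distinct
documents), N counts all settings in the corpus. This exact form *divides*
by the inverse-document-frequency factor, so it grows for concepts present
in many settings — the opposite of the conventional weighting; because the
stated purpose of the stage is to demote ubiquitous concepts, a
`tfidf_variant="conventional"` switch multiplies instead of dividing. The
division form is the default because it is the form as printed in the
method this package operationalises. Pairs with scores strictly above 1
are kept; the cutoff is only meaningful relative to the chosen `tf_mode`.

**Enrichment stage.** Against a symmetric concept-pair co-occurrence
database (absent pair ⇒ count 0, no self-pairs): ProbExpSet averages the
counts over all C(n,2) pairs of the global concept collection — by default
the union of concepts surviving χ²+TF-IDF (`global_collection=
"full_vocabulary"` uses the whole corpus vocabulary) — and ProbObsSet
averages over one setting's pairs; EnrichFold is their ratio. The default
scope `"both"` first gates settings (a setting with fold ≤ 1 contributes
nothing) and then prunes individual concepts whose anchored fold — pairs
(c, other) within the setting's candidate set — is ≤ 1. Concept-level
pruning matters: with sparse per-setting counts the χ² approximation is
anti-conservative, and roughly 2% of background (concept, setting) pairs
slip through the first two stages; their anchored folds sit near the
background rate and well below 1, so they are removed, while genuine
signature concepts have anchored folds far above 1. Pure `"per_setting"`
and `"per_concept"` scopes are available. Folds are scale-free: Poisson
noise aside, multiplying every database count by a constant changes no
fold.

## Topic model

LDA is fitted by collapsed Gibbs sampling — a single chain, token-level
resampling from p(z_i=k|·) ∝ (n_dk+α)(n_kw+β)/(n_k+Vβ) — with φ and θ read
off the final state using the same Dirichlet smoothing. Defaults α = 50/K
and β = 0.1 (the long-standing defaults of the Gibbs LDA ecosystem),
burn-in 1000 sweeps; all configurable. Note that α = 50/K is a strong
smoother for small K: with K = 2 and 15-token documents θ cannot exceed
~0.6, so recovery experiments that assert sharp document mixtures set α
explicitly (≈0.1).

Model selection fits one model per candidate K (default grid 5–150 by 5)
and keeps the argmax of the collapsed log-likelihood
log p(w|z,β) = K[lnΓ(Vβ) − VlnΓ(β)] + Σ_k[Σ_w lnΓ(n_kw+β) − lnΓ(n_k+Vβ)]
at the final state, ties to the smaller K. This final-state criterion is a
goodness-of-fit, not a marginal likelihood: it keeps improving (weakly)
past the true K unless documents are strongly single-topic, so on weakly
separated corpora it should be read as an elbow plot; the full (K,
log-likelihood) table is always returned. Training-state likelihood is
used throughout (no held-out estimator).

Held-out documents are folded in by Gibbs sampling with the topic–term
counts frozen at training values; out-of-vocabulary tokens are skipped
with a warning, a document left empty receives the uniform mixture 1/K.
Topic assignments are accumulated over 200 post-burn-in sweeps (burn-in
1000 by default), yielding both smoothed θ and per-term topic counts.

## Profiles, similarity, prediction

p(topic|term) is the φ column for the term normalized under a uniform
topic prior (a corpus-mean-θ weighting is available); terms unseen in
training are flagged and set exactly uniform. A setting's profile is the
unweighted mean of its representative terms' rows — a mean of simplex
vectors, hence a distribution over topics. Held-out profiles mirror this:
the mean of the normalized per-term topic-count rows over the terms
observed in the setting's held-out documents (the held-out setting's
representative set is unknown by construction).

Profiles are compared by Pearson correlation. Zero-variance (uniform)
profiles have undefined correlations and are recorded as missing with a
warning; the clustered image map refuses missing entries. The map applies
average-linkage (configurable: complete, single) agglomerative clustering
on distance 1 − r identically to rows and columns, orders leaves by the
dendrogram, and assigns colors by decile bins computed over off-diagonal
entries only (the unit diagonal would distort the quantiles; it is drawn
in the top bin). The canonical output is data (ordering, binned matrix,
linkage); rendering a PNG is optional so tests stay image-free.

Prediction ranks every training-setting profile by correlation with the
held-out profile, ties broken lexicographically. @k counts follow the
unique-union reading of false positives, FP@k = U@k − TP@k, which uniquely
yields the observed identity precision = recall = F1 whenever every gold
setting appears in some top-k list (U = S); a `list_slots` strategy
(FP = k·|predictions| − TP) is provided for comparison. k cannot exceed
the ranked-list length; with S settings, k = S forces all three rates
to 1.

Cross-validation is stratified by setting (shuffle within setting,
round-robin deal across 5 folds) and leakage-safe: representative-concept
selection and the topic model are re-run on every training split. A
fixed-holdout mode (n notes per setting) is also provided. The gold
setting count for FN@k is the number of settings in the full corpus.

## Synthetic data

`SyntheticConfig` defaults define the study conditions: S = 8 settings,
m = 20 signature concepts each (pairwise disjoint), B = 200 shared
background concepts, D = 100 documents per setting, document length
Poisson(λ = 15) floored at one token, each token drawn from the setting's
signature with probability π = 0.8 else uniformly from the background, and
a co-occurrence database with Poisson(μ1 = 10) counts for within-signature
pairs versus Poisson(μ0 = 1) elsewhere. These sizes keep the full pipeline
(including 5-fold cross-validation) within minutes on one CPU while
leaving every stage statistically non-trivial: background concepts are
frequent enough to produce χ² false positives, and μ1/μ0 = 10 matches the
order of enrichment observed between clinically related concepts in
literature-scale databases. A Zipf-popularity option exists for stress
tests. What the generator does **not** emulate: overlapping or correlated
setting signatures, per-document topic mixtures across settings, negation
or temporal structure, and realistic long-tailed setting sizes — so
perfect recovery here bounds, rather than predicts, performance on real
corpora, where the same pipeline reports curves that rise with k rather
than saturating.

The LDA benchmark generator is separate: topics with disjoint uniform
vocabulary blocks, document mixtures Dirichlet(0.3) (0.02 in the
model-selection experiment, which needs near-single-topic documents for
the final-state likelihood to peak at the true K), used to measure φ
recovery as the mean total-variation distance under optimal topic
matching (Hungarian assignment).

## Numerical and reproducibility choices

All randomness descends from one root seed; stage seeds are
SHA-256-derived from (root, stage label), per-setting draws from (root,
stage, setting), so adding a stage or setting never perturbs the others.
The Gibbs kernels are numba-compiled sequential sweeps with an internal
seeded RNG; two runs with identical config and seed produce byte-identical
artifacts, including the metrics JSON (sorted keys, fixed layout). Every
pipeline stage writes atomically (temp file, rename) plus a manifest with
the config hash, seed, input digests and package version. Simplex rows are
validated to 1e-9; correlations are clipped to [−1, 1] against float
drift.

The evaluation in the acceptance script fixes K = S = 8 topics for the
synthetic study — the natural choice for a corpus with S planted,
disjoint themes — rather than re-running grid selection inside every
fold; grid selection remains available (`choose-k`, `LDAConfig(grid=…)`).

## Known limitations

- The final-state collapsed likelihood is a weak model-selection criterion
  on corpora with mixed documents (see above); treat the grid table as an
  elbow plot.
- The as-printed TF-IDF form does not demote ubiquitous concepts; the χ²
  and enrichment stages carry that burden unless the conventional variant
  is enabled.
- Single-chain Gibbs with a final-state read-out carries Monte-Carlo
  noise; no chain averaging or convergence diagnostics are implemented.
- Enrichment requires ≥ 2 surviving concepts per setting and a non-empty
  global expectation; degenerate inputs raise rather than guess.
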