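# Methods

## Scope and model

`snfomics` implements an unsupervised molecular-subtyping pipeline for
multi-modal omics cohorts. The statistical object is a set of
sample-similarity networks, one per modality, merged by similarity
network fusion (SNF) — an iterative cross-diffusion in which each
modality's transition matrix is propagated through its own sparse
K-nearest-neighbour kernel while averaging in the other modalities'
global structure. The fusion assumes that (i) a meaningful subtype
structure expresses itself as block structure in at least some
modalities' similarity graphs, and (ii) modality-specific noise is not
reinforced across modalities, so diffusion amplifies shared structure and
washes out idiosyncratic edges.

### Kernel dialect

The affinity kernel evaluates a Gaussian *density* on the squared
Euclidean distance with a locally adaptive scale
`eps(i,j) = (mu_i + mu_j + D(i,j))/3`, where `mu_i` is the mean squared
distance from i to its K nearest neighbours, floored at machine epsilon,
and SD `alpha*eps`. This dialect is adopted so that the conventional
parameter values K=40, alpha=0.5, T=50 carry their usual meaning; under
it, the worked 1-D example — points (0, 1, 4), K=1, alpha=0.5 — gives
W(1,2) = N(1; 0, 0.5) ≈ 0.1080, which the tests assert against a direct
density evaluation.

### Fusion update and numerical conventions

- Full kernel: `P(i,j) = W(i,j)/(2*sum_{k≠i} W(i,k))` off-diagonal,
  `P(i,i) = 1/2`. This halving bounds the self-transition and makes the
  update a strict average between self and neighbours.
- Local kernel: row-normalized over the K largest off-diagonal entries;
  ties at the K-th neighbour are broken by sample order (stable sort), so
  output is deterministic.
- After every iteration each matrix is re-normalized (full-kernel
  convention) and symmetrized by averaging with its transpose; the final
  output is the average of the m matrices, re-normalized and symmetrized
  the same way. These per-iteration projections keep rows stochastic and
  the matrix symmetric in finite precision.
- T is a fixed iteration count — there is no early-stopping tolerance.
  The per-iteration Frobenius change of the transition matrices is
  recorded on the result (`AffinityMatrix.convergence`) purely as a
  diagnostic.
- When a subsample is so small that `n <= K` (sweep configurations,
  stability draws), K is capped at `floor((n-1)/2)` with a logged
  warning instead of failing, so exhaustive sweeps can run at small n.
- Fusing a single network reduces to its (symmetrized) full kernel, so
  single-modality sweep configurations flow through the same code path.

### Spectral clustering and cluster-number election

Clustering takes the c eigenvectors of the smallest eigenvalues of the
symmetric-normalized Laplacian, row-normalizes them to the unit sphere,
and discretizes by iterative rotation toward a discrete indicator matrix
(SVD-based, deterministically initialized from fixed data rows). If the
rotation leaves a cluster empty, a seeded k-means with 20 restarts is the
fallback; both paths are deterministic under the seed. Labels are
canonicalized by decreasing cluster size, ties by smallest member ID, so
output files are reproducible.

Two cluster-number criteria are computed over candidates 2..8 (defaults):

- *eigen-gap*: the difference between the (c+1)-th and c-th smallest
  Laplacian eigenvalues, maximized;
- *rotation cost*: the Zelnik-Manor/Perona-style alignment cost
  `sum_i sum_j M_ij / max_j M_ij` of the squared rotated eigenvector
  matrix M, minimized (n for a perfect indicator fit).

Rows that are numerically zero in the candidate eigenspace (possible for
exactly disconnected graphs when c is below the number of components)
are mapped to the uniform direction, i.e. counted as maximally ambiguous;
without this convention a too-small c could score spuriously well simply
by leaving whole blocks unrepresented. Both per-candidate curves are
always reported; when the two criteria disagree the pipeline evaluates
both elected solutions rather than privileging either.

NMI between partitions uses arithmetic-mean entropy normalization
(sqrt/max variants behind a flag); the exact normalization used by
upstream tooling is not documented, so the choice is stated rather than
asserted. ARI and the chi-square independence test use their standard
contingency-table forms.

## Stability (APN / ADM)

Internal validity follows the resampling protocol: 80% of participants
drawn without replacement, 300 draws by default, full re-run of
affinity → fusion → clustering at the same c per draw. The cluster number
is fixed from the full-data run rather than re-elected per draw (a flagged
alternative would re-elect); this matches the reporting of per-solution
stability histograms. APN is the mean proportion of a sample's full-data
co-cluster (restricted to the draw) lost in the resampled clustering; it
is deliberately asymmetric and needs no label alignment. ADM is the mean
distance between full-data and resampled cluster centroids; centroids
live in the concatenation of all fused modalities' standardized features
(per-modality centroids are available by passing a single matrix). ARI
between the restricted full partition and each draw is reported
alongside for transparency.

## Association models

Outcomes are tested by nested-model omnibus comparisons: F for linear
outcomes, likelihood-ratio chi-square for logistic, with c−1 subtype
dummies against baseline subtype 1. The neuropathology model adjusts for
age at death, sex, education, PMI, study, and APOE ε4; cognitive models
additionally adjust for measurement latency. The 4-level ordinal
pathologies (TDP-43, atherosclerosis, arteriolosclerosis, CAA, Lewy body
stage) are modelled with the linear family on scores 0–3 — the simplest
member of the "linear or logistic" family pair; an ordinal-logit could be
substituted but is out of scope here. Missing covariates/outcomes are
handled by listwise deletion with logged counts. Logistic separation is
caught and reported with a missing p rather than a spurious one.
Cognitive slopes are per-person OLS slopes of the z-scored global
composite on years; residual cognition is the OLS residual of last-visit
cognition on the eleven observed pathologies, with aliased columns
dropped. Tukey HSD post hocs use the studentized-range distribution;
groups with fewer than two members are skipped with a warning. Per-feature
subtype discrimination is ranked by one-way ANOVA p; features with zero
within-group variance but distinct group means are ranked first with
F = ∞ (perfect separation), overall-constant features last with a flag.

Bonferroni correction defaults to the 16-outcome battery (raw threshold
0.05/16 ≈ 3.1e-3) and 32 when two clustering solutions are jointly
evaluated (≈ 1.6e-3). A five-domain cognitive follow-up battery
(corrected within the 5 domains) triggers when a global cognition test
survives correction.

## Sensitivity sweep

A configuration is (d, d′, c) with ∅ ≠ d ⊆ d′: d′ fixes the sample (the
participants non-missing on all of d′) and d the modalities actually
fused, which separates "which data" from "how many samples". For five
modalities there are Σ_{d′}(2^{|d′|}−1) = 211 (d, d′) pairs; with c in
2..5 this is 844 configurations, a count the tests verify against
brute-force enumeration. Per-configuration seeds are derived from the
master seed and a CRC of the configuration identity, so results are
independent of execution order and resumable. By default the sweep
slices precomputed processed matrices (deterministic and fast); a flag
re-normalizes within each subsample. Configurations whose overlap is
below max(c+2, 10) are recorded as skipped. Meta-regressions relate
−log10(p) (base 10, matching the figure scale convention) for one
outcome to one design parameter at a time — m, n, c by OLS, cf by
one-way ANOVA across c levels — never jointly.

## Synthetic cohorts

The generator emulates the data structure the pipeline is designed for,
not any particular dataset's marginals:

- **Subtype signal**: per modality, cluster centers are drawn once per
  (seed, modality) from a standard Gaussian and scaled by
  `signal_strength`, so signal is expressed in within-cluster SD units
  per feature. Unit Gaussian noise (configurable SD) is added on top.
- **Covariates**: age at death ~ N(89, 6.6²) yr, sex ~ Bernoulli(0.33),
  education ~ N(16, 3.5²) yr, PMI ~ N(8.3, 6.1²) h truncated at 0,
  study ~ Bernoulli(0.5), APOE ε4 ~ Bernoulli(0.25), latency
  ~ |N(1, 0.8²)| yr — moments chosen to resemble an elderly
  community-based brain-donation cohort; they are not fit-critical.
  Covariate confounding of features is linear with random per-feature
  loadings scaled by the requested effect.
- **Missingness**: whole-modality dropout is independent Bernoulli per
  modality by default; the `nested` option draws one latent availability
  score per sample and observes a modality iff the score exceeds its
  missing fraction, producing exactly nested sample sets — a small
  full-overlap core under a large single-modality set, the ordering seen
  in real multi-assay cohorts. Entry-level missingness is MCAR on top.
- **Phenotypes**: the 16-outcome battery is generated from a shared
  latent linear predictor (subtype means z-scored across subtypes so the
  effect size is the realized between-subtype SD, plus a mild age effect
  and unit noise): continuous pathologies use the latent directly,
  ordinal ones cut it at quartiles, binary ones pass it through a
  logistic link. Cognition is realized longitudinally — per-subtype
  slopes around a base decline of −0.05/yr, 8 annual visits, visit noise
  SD 0.15 — and last-visit score, per-person OLS slope and residual
  cognition are derived from the trajectories by the package's own
  operations.

What the generator does *not* emulate: realistic feature correlation
structure within a modality, heavy-tailed or count-valued measurement
distributions, batch effects beyond linear covariates, informative
(outcome-dependent) missingness, and practice effects in repeated
cognitive testing. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under the planted model, not performance on
any real cohort.

## Problem sizes and numerical choices

Simulated checks use cohort sizes chosen to make the studied effects
measurable at interactive runtimes: planted-recovery runs use n = 90 with
two modalities of 40/30 features over 25 seeds at 0.5 SD signal (a regime
where fusion visibly outperforms the best single modality); the
modality-ranking check uses n = 150 and three modalities over 20 seeds;
stability uses 50 draws of the 80% protocol; calibration checks use 200
replicate cohorts. Sample-SD conventions are n−1 throughout; kNN
imputation distances use the standard nan-Euclidean scaling over
mutually observed features; variance-filter ties are broken by feature-ID
lexicographic order; z-normalization drops zero-variance features (within
1e-12 relative tolerance) with a warning. The per-modality processing
order is missing-rate filter → imputation → variance filter →
residualization → z-normalization; whether variance filtering should
precede residualization is genuinely open, and the fixed order is flagged
here. Residualization covers age/sex/PMI/study by default with a
per-modality skip flag (some upstream pipelines deliver already
residualized data).

## Known limitations

- The rotation-cost functional and NMI normalization are reasonable,
  documented choices among several variants in circulation; electing a
  different variant can change the elected c on borderline networks.
- APN/ADM are computed against the full-data partition restricted to the
  draw; with very unbalanced clusters APN can be optimistically low (a
  single-cluster resample scores APN = 0 by construction — the measure's
  documented asymmetry).
- Logistic omnibus tests rely on asymptotic chi-square calibration;
  at small n with rare outcomes the LRT is conservative/anticonservative
  in the usual ways and separation is reported, not repaired.
- The sweep's default matrix-slicing means imputation/residualization
  are not re-estimated within each subsample; the full-reprocess flag
  trades determinism-speed for strictness.
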