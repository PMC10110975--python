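# snfomics

Molecular subtyping of multi-omic cohorts by **similarity network fusion
(SNF)**, with the full downstream battery needed to decide whether the
subtypes mean anything: spectral clustering with dual cluster-number
criteria, modality-contribution ranking, resampling-based internal
stability, covariate-adjusted outcome associations, and an exhaustive
sensitivity sweep over the analysis design space.

The package is aimed at studies of brain ageing and dementia that profile
the same post-mortem samples on several omic layers (e.g. RNA abundance,
DNA methylation, histone acetylation, proteomics, metabolomics) and ask
whether data-driven subtypes relate to neuropathology and cognitive
decline. Because such cohort data are typically restricted-access, the
package ships a first-class synthetic-cohort generator that emulates the
relevant structure — modality-heterogeneous subtype signal, nested
modality missingness, covariate confounding, and subtype-linked
longitudinal cognition — so every stage is testable end to end.

## Method

For each modality, samples×features measurements `X_v` are filtered,
imputed, residualized on covariates, z-scored, and turned into an affinity
network with a locally scaled Gaussian kernel on squared Euclidean
distances:

    eps(i,j) = ( mu_i + mu_j + D(i,j) ) / 3,      mu_i = mean D over i's K nearest neighbours
    W_v(i,j) = N( D(i,j); 0, (alpha * eps(i,j))^2 )

Each network yields a row-stochastic *full kernel* `P_v` (off-diagonal
mass halved, diagonal 1/2) and a K-nearest-neighbour *local kernel* `S_v`.
Fusion is T rounds of cross-diffusion,

    P_v  <-  S_v ( sum_{k != v} P_k / (m-1) ) S_v^T ,

re-normalizing and symmetrizing each round; the fused network is the
average of the final matrices. Defaults are the conventional K=40,
alpha=0.5, T=50.

Subtypes come from spectral clustering of the fused network (normalized
Laplacian, eigenvector rotation to discrete indicators); the cluster
number is elected over candidates 2..8 by both the **eigen-gap** (larger
is better) and the **rotation cost** (smaller is better), and both curves
are reported so disagreement is visible. Each modality's contribution to
the fused structure is the NMI between its own spectral partition and the
fused one. Internal stability is measured by APN and ADM over repeated
80% subsampling (300 draws by default) with full pipeline re-runs.
External validity uses omnibus F / likelihood-ratio tests of subtype
membership (dummy coded, c−1 indicators) against 16 outcomes — 13
neuropathologies plus last-visit cognition, cognitive slope and residual
cognition — adjusting for age at death, sex, education, post-mortem
interval, study and APOE ε4 (plus measurement latency for cognitive
outcomes), Bonferroni corrected for 16 tests (32 when two solutions are
evaluated jointly). The sensitivity sweep enumerates every
(modality subset d, sample-defining superset d′, cluster number c)
configuration — 844 for five modalities with c in 2..5 — and
meta-regresses −log10 p on each design parameter separately.

## Worked example

```python
import snfomics as sf
from snfomics.preprocess import standard_normalize

spec = sf.CohortSpec(
    n_samples=90, n_subtypes_true=3,
    modalities=(sf.ModalitySpec("rna", 40, signal_strength=1.0),
                sf.ModalitySpec("methyl", 30, signal_strength=1.0)),
    seed=3,
)
cohort = sf.generate_cohort(spec)
mats = [standard_normalize(m) for m in cohort.matrices.values()]
affinities = [sf.affinity_from_matrix(m, sf.SNFParams()) for m in mats]
fused = sf.fuse(affinities)

part = sf.spectral_cluster(fused, 3, seed=0)
print("ARI vs truth:", sf.ari(part, cohort.true_labels))
est = sf.estimate_cluster_number(fused, range(2, 9))
print("eigen-gap elects:", est.eigen_gap_best,
      "| rotation cost elects:", est.rotation_cost_best)
```

prints

```
ARI vs truth: 1.0
eigen-gap elects: 3 | rotation cost elects: 3
```

i.e. the fused network recovers the three planted subtypes exactly and
both cluster-number criteria elect c = 3.

The same flow is available from a shell via the `snfomics` CLI
(`simulate`, `preprocess`, `fuse`, `cluster`, `stability`, `associate`,
`sweep`, `two-stage`); `snfomics two-stage --config pipeline.yaml` runs
the full two-stage design: fuse all modalities on the common core, rank
modalities by NMI, re-fuse the top three on their larger overlap, and
evaluate every elected solution.

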