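"""Synthetic multi-modal cohorts with planted subtypes.

Cohorts emulate the structure of an elderly brain multi-omics study:
several modalities with very different feature counts, modality-wise
sample missingness producing a small full-overlap core and a large
single-modality set, modality-heterogeneous subtype signal, covariate
confounding of features, and subtype-linked phenotypes (13 neuropathology
outcomes plus longitudinal cognition).  Every generator is fully
determined by its seed.

Feature model per modality: each subtype has a Gaussian cluster center
(drawn once per seed x modality, scaled by ``signal_strength``, so signal
is expressed in within-cluster SD units); features additionally receive
linear covariate effects and Gaussian noise.  Whole-modality dropout is
sampled per sample (independent across modalities by default, or nested
via a shared latent availability score), and entry-level missingness is
applied on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association
from .clustering import Partition
from .containers import OmicsMatrix

_SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class ModalitySpec:
    """One modality's size, signal-to-noise and missingness structure."""

    name: str
    n_features: int
    signal_strength: float = 1.0  # between-subtype mean shift, in SD units
    noise_sd: float = 1.0
    missing_fraction: float = 0.0  # whole-modality sample dropout
    feature_missing_rate: float = 0.0  # entry-level missingness

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for r in (self.missing_fraction, self.feature_missing_rate):
            if not 0 <= r < 1:
                raise ValueError("missing rates must lie in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; the seed determines everything."""

    n_samples: int
    n_subtypes_true: int
    modalities: tuple[ModalitySpec, ...]
    subtype_proportions: tuple[float, ...] | None = None  # default uniform
    #: per-modality covariate effect sizes for age/sex/pmi/study (scalar or dict)
    covariate_effects: dict[str, float | dict[str, float]] = field(default_factory=dict)
    #: per-outcome effect size of subtype membership (0 where absent)
    outcome_effects: dict[str, float] = field(default_factory=dict)
    missingness: str = "independent"  # or "nested"
    n_visits: int = 8
    visit_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subtypes_true < 2:
            raise ValueError("n_subtypes_true must be >= 2")
        if self.n_subtypes_true > self.n_samples:
            raise ValueError("n_subtypes_true > n_samples")
        names = [m.name for m in self.modalities]
        if len(set(names)) != len(names):
            raise ValueError("modality names must be distinct")
        if self.missingness not in ("independent", "nested"):
            raise ValueError("missingness must be 'independent' or 'nested'")
        props = self.proportions()
        if len(props) != self.n_subtypes_true:
            raise ValueError("subtype_proportions length must equal n_subtypes_true")
        if abs(sum(props) - 1.0) > _SIMPLEX_TOL or min(props) <= 0:
            raise ValueError("subtype_proportions must lie on the simplex")

    def proportions(self) -> tuple[float, ...]:
        if self.subtype_proportions is None:
            return tuple([1.0 / self.n_subtypes_true] * self.n_subtypes_true)
        return tuple(float(p) for p in self.subtype_proportions)


@dataclass
class SyntheticCohort:
    matrices: dict[str, OmicsMatrix]
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame
    true_labels: Partition
    visits: pd.DataFrame | None = None  # long-format cognition trajectories

    def __post_init__(self) -> None:
        cov_ids = set(self.covariates.index)
        for name, mat in self.matrices.items():
            if not set(mat.sample_ids) <= cov_ids:
                raise ValueError(f"modality {name!r} has samples outside the covariate table")
        if set(self.true_labels.sample_ids) != cov_ids:
            raise ValueError("true labels must cover exactly the covariate samples")


def _allocate_labels(n: int, proportions, rng) -> np.ndarray:
    """Largest-remainder allocation of cluster sizes, then a random shuffle."""
    props = np.asarray(proportions, float)
    counts = np.floor(props * n).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > n:
        counts[int(np.argmax(counts))] -= 1
    remainders = props * n - counts
    while counts.sum() < n:
        j = int(np.argmax(remainders))
        counts[j] += 1
        remainders[j] = -np.inf
    labels = np.repeat(np.arange(1, len(props) + 1), counts)
    return rng.permutation(labels)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_covariates(n: int, rng: np.random.Generator, sample_ids) -> pd.DataFrame:
    """Demographics with realistic elderly-cohort moments.

    Age at death ~ N(89, 6.6^2) years, sex ~ Bernoulli(0.33) (male),
    education ~ N(16, 3.5^2) years, post-mortem interval ~ N(8.3, 6.1^2)
    hours truncated at 0, study ~ Bernoulli(0.5), APOE-e4 carrier
    ~ Bernoulli(0.25), latency ~ |N(1, 0.8^2)| years.
    """
    return pd.DataFrame(
        {
            "age_death": rng.normal(89.0, 6.6, n),
            "sex": rng.binomial(1, 0.33, n).astype(float),
            "education": np.clip(rng.normal(16.0, 3.5, n), 5.0, None),
            "pmi": np.maximum(rng.normal(8.3, 6.1, n), 0.0),
            "study": rng.binomial(1, 0.5, n).astype(float),
            "apoe4": rng.binomial(1, 0.25, n).astype(float),
            "latency": np.abs(rng.normal(1.0, 0.8, n)),
        },
        index=sample_ids,
    )


def generate_longitudinal_cognition(
    labels: Partition,
    n_visits: int,
    slope_by_subtype,
    noise_sd: float,
    seed: int,
    visit_interval: float = 1.0,
    intercepts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-sample cognition trajectories: intercept + subtype slope x years + noise.

    Returns a long-format table with columns ``sample``, ``time``, ``score``.
    """
    if n_visits < 2:
        raise ValueError("n_visits must be >= 2")
    slopes = np.asarray(slope_by_subtype, float)
    if len(slopes) != labels.c:
        raise ValueError("one slope per subtype required")
    rng = np.random.default_rng(seed)
    n = len(labels.sample_ids)
    if intercepts is None:
        intercepts = rng.normal(0.0, 0.5, n)
    times = np.arange(n_visits) * visit_interval
    rows = []
    for i, sample in enumerate(labels.sample_ids):
        slope = slopes[labels.labels[i] - 1]
        scores = intercepts[i] + slope * times + rng.normal(0.0, noise_sd, n_visits)
        for t, s in zip(times, scores):
            rows.append({"sample": sample, "time": float(t), "score": float(s)})
    return pd.DataFrame(rows)


def _modality_matrix(
    spec: CohortSpec,
    mod: ModalitySpec,
    mod_index: int,
    labels: np.ndarray,
    covariates: pd.DataFrame,
    availability: np.ndarray,
    sample_ids,
) -> OmicsMatrix:
    rng = np.random.default_rng([spec.seed % (2**31), 1000 + mod_index])
    n, p, k = spec.n_samples, mod.n_features, spec.n_subtypes_true
    centers = rng.standard_normal((k, p)) * mod.signal_strength
    X = centers[labels - 1].copy()

    effects = spec.covariate_effects.get(mod.name, {})
    if np.isscalar(effects):
        effects = {c: float(effects) for c in ("age_death", "sex", "pmi", "study")}
    for cov, eff in effects.items():
        loading = rng.standard_normal(p)
        X += float(eff) * _zscore(covariates[cov].to_numpy())[:, None] * loading[None, :]

    X += rng.standard_normal((n, p)) * mod.noise_sd

    if spec.missingness == "nested":
        observed = availability >= mod.missing_fraction
    else:
        observed = rng.random(n) >= mod.missing_fraction
    if not observed.any():
        raise ValueError(f"modality {mod.name!r} has no observed samples")

    if mod.feature_missing_rate > 0:
        mask = rng.random((n, p)) < mod.feature_missing_rate
        X = np.where(mask, np.nan, X)

    frame = pd.DataFrame(
        X[observed],
        index=[s for s, o in zip(sample_ids, observed) if o],
        columns=[f"{mod.name}_f{j}" for j in range(p)],
    )
    return OmicsMatrix(mod.name, frame)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _generate_phenotypes(
    spec: CohortSpec, labels: np.ndarray, covariates: pd.DataFrame, sample_ids
):
    rng = np.random.default_rng([spec.seed % (2**31), 77])
    n, k = spec.n_samples, spec.n_subtypes_true
    z_age = _zscore(covariates["age_death"].to_numpy())
    pheno = pd.DataFrame(index=pd.Index(sample_ids))

    pathology_specs = {
        name: (fam,)
        for name, (fam, model) in association.OUTCOME_MANIFEST.items()
        if model == "A"
    }
    ordinal = {"tdp43", "atherosclerosis", "arteriolosclerosis", "caa", "lewy_body"}
    def subtype_means(effect: float) -> np.ndarray:
        # z-score the k draws so `effect` is the realized between-subtype SD
        draws = rng.standard_normal(k)
        return effect * _zscore(draws) if effect != 0 else np.zeros(k)

    for name, (family,) in pathology_specs.items():
        effect = float(spec.outcome_effects.get(name, 0.0))
        mu = subtype_means(effect)
        latent = mu[labels - 1] + 0.3 * z_age + rng.standard_normal(n)
        if family == "logistic":
            pheno[name] = rng.binomial(1, _sigmoid(latent - latent.mean())).astype(float)
        elif name in ordinal:
            cuts = np.quantile(latent, [0.25, 0.5, 0.75])
            pheno[name] = np.digitize(latent, cuts).astype(float)
        else:
            pheno[name] = latent

    # cognition: subtype-linked intercepts and slopes, realized longitudinally
    slope_effect = float(spec.outcome_effects.get("cognition_slope", 0.0))
    base_slopes = -0.05 + subtype_means(slope_effect)
    last_effect = float(spec.outcome_effects.get("cognition_last", 0.0))
    resil_effect = float(spec.outcome_effects.get("residual_cognition", 0.0))
    intercept_mu = subtype_means(last_effect) + subtype_means(resil_effect)
    intercepts = intercept_mu[labels - 1] + rng.normal(0.0, 0.5, n)
    part = Partition(list(sample_ids), labels)
    visits = generate_longitudinal_cognition(
        part,
        spec.n_visits,
        base_slopes,
        noise_sd=0.15,
        seed=int(rng.integers(2**31)),
        visit_interval=spec.visit_interval,
        intercepts=intercepts,
    )
    last = visits.loc[visits.groupby("sample")["time"].idxmax()].set_index("sample")
    pheno["cognition_last"] = last["score"].loc[pheno.index]
    pheno["cognition_slope"] = association.cognitive_slope(visits).loc[pheno.index]
    pheno["residual_cognition"] = association.residual_cognition(
        pheno["cognition_last"], pheno
    )
    return pheno, visits


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a complete synthetic cohort from a :class:`CohortSpec`."""
    rng = np.random.default_rng(spec.seed % (2**31))
    n = spec.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]
    labels = _allocate_labels(n, spec.proportions(), rng)
    covariates = generate_covariates(n, rng, sample_ids)
    availability = rng.random(n)  # shared latent score for nested dropout

    matrices = {}
    for idx, mod in enumerate(spec.modalities):
        matrices[mod.name] = _modality_matrix(
            spec, mod, idx, labels, covariates, availability, sample_ids
        )
    phenotypes, visits = _generate_phenotypes(spec, labels, covariates, sample_ids)
    return SyntheticCohort(
        matrices=matrices,
        covariates=covariates,
        phenotypes=phenotypes,
        true_labels=Partition(sample_ids, labels),
        visits=visits,
    )


def overlap_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Sample counts per modality combination (upset-plot style).

    One row per nonempty modality subset with two counts: samples observed
    in *exactly* that subset and in *at least* that subset.  The exact
    counts partition the cohort, so at-least counts follow by
    inclusion of supersets.
    """
    names = list(cohort.matrices)
    if not names:
        raise ValueError("cohort has no modalities")
    observed = {m: set(cohort.matrices[m].sample_ids) for m in names}
    all_ids = list(cohort.true_labels.sample_ids)
    membership = {
        s: frozenset(m for m in names if s in observed[m]) for s in all_ids
    }
    rows = []
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            cset = frozenset(combo)
            exact = sum(1 for s in all_ids if membership[s] == cset)
            at_least = sum(1 for s in all_ids if cset <= membership[s])
            rows.append(
                {
                    "modalities": "+".join(combo),
                    "size": r,
                    "exact": exact,
                    "at_least": at_least,
                }
            )
    return pd.DataFrame(rows)


def nested_five_modality_spec(seed: int = 0, scale: float = 1.0) -> CohortSpec:
    """A five-modality cohort with a realistic nested overlap ordering.

    Feature counts are scaled-down stand-ins for RNA abundance, DNA
    methylation, histone acetylation, proteomics and metabolomics; the
    nested dropout pattern yields a small full-overlap core and a large
    single-modality (RNA) set, the overlap ordering typical of
    multi-assay brain banks.  ``scale`` multiplies the cohort size.
    """
    n = int(round(1092 * scale))
    return CohortSpec(
        n_samples=n,
        n_subtypes_true=3,
        modalities=(
            ModalitySpec("rnaseq", 120, signal_strength=1.2, missing_fraction=0.0),
            ModalitySpec("methylation", 100, signal_strength=1.2, missing_fraction=0.33),
            ModalitySpec("acetylation", 80, signal_strength=1.5, missing_fraction=0.5),
            ModalitySpec("proteomics", 60, signal_strength=0.0, missing_fraction=0.65),
            ModalitySpec("metabolomics", 40, signal_strength=0.0, missing_fraction=0.9),
        ),
        missingness="nested",
        seed=seed,
    )
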