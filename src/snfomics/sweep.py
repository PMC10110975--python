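"""Exhaustive sensitivity sweep over modality sets, sample subsets and c.

Each configuration is a triple (d, d', c): the modalities ``d`` actually
fused, a superset ``d'`` defining the analysis sample (participants
non-missing on every modality of d'), and the cluster number ``c``.  The
d'-superset construction makes it possible to cluster a modality set on an
artificially restricted sample, separating the effect of which data are
fused from the effect of how many participants are available.  For five
modalities and c in 2..5 this yields sum over nonempty d' of (2^|d'| - 1)
= 211 (d, d') pairs x 4 cluster numbers = 844 configurations.

Second-level meta-regressions relate each configuration's omnibus
-log10 p for an outcome j to single design parameters:

    -log10(p_j) ~ m     (number of modalities fused)
    -log10(p_j) ~ n     (sample size)
    -log10(p_j) ~ c     (cluster number, continuous)
    -log10(p_j) ~ cf    (cluster number as categorical, one-way ANOVA)
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import association
from .clustering import spectral_cluster
from .cohort import SyntheticCohort
from .containers import align_samples
from .snf import SNFParams, affinity_from_matrix, fuse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepConfig:
    d: tuple[str, ...]  # modalities fused
    d_prime: tuple[str, ...]  # modalities defining the sample overlap
    c: int

    def __post_init__(self) -> None:
        if not self.d:
            raise ValueError("d must be nonempty")
        if not set(self.d) <= set(self.d_prime):
            raise ValueError("d must be a subset of d_prime")

    @property
    def m(self) -> int:
        return len(self.d)

    def key(self) -> str:
        return f"d={'+'.join(self.d)};dp={'+'.join(self.d_prime)};c={self.c}"


@dataclass
class MetaRegressionResult:
    outcome: str
    predictor: str  # one of m | n | c | cf
    slope: float  # ANOVA F for cf
    p: float
    n_configs: int


def enumerate_configurations(modalities, c_range) -> list[SweepConfig]:
    """All (d, d', c) with nonempty d subset of d' subset of the modalities.

    Deterministic lexicographic ordering.  For k modalities the count is
    [sum over nonempty d' of (2^|d'| - 1)] x |c_range|.
    """
    modalities = list(modalities)
    c_values = sorted(int(c) for c in c_range)
    if not modalities:
        raise ValueError("need at least one modality")
    if not c_values:
        raise ValueError("empty cluster-number range")
    configs = []
    for r_prime in range(1, len(modalities) + 1):
        for d_prime in combinations(modalities, r_prime):
            for r in range(1, r_prime + 1):
                for d in combinations(d_prime, r):
                    for c in c_values:
                        configs.append(SweepConfig(d=d, d_prime=d_prime, c=c))
    configs.sort(key=lambda cfg: (cfg.d_prime, cfg.d, cfg.c))
    return configs


def config_seed(master_seed: int, config: SweepConfig) -> int:
    """Per-configuration seed derived from the master seed and identity."""
    digest = zlib.crc32(config.key().encode())
    return int((master_seed * 1_000_003 + digest) % (2**31))


def run_sweep(
    cohort: SyntheticCohort,
    configs: list[SweepConfig],
    snf_params: SNFParams = SNFParams(),
    manifest: dict | None = None,
    seed: int = 0,
    preprocessed: dict | None = None,
) -> pd.DataFrame:
    """Execute each configuration and collect per-outcome omnibus p-values.

    Precomputed processed matrices may be supplied via ``preprocessed``
    (modality -> OmicsMatrix); otherwise raw cohort matrices are z-scored
    per subsample.  Configurations whose overlap is smaller than c (plus a
    small margin) are recorded as skipped.  Results are a tidy table with
    one row per configuration x outcome.
    """
    from .preprocess import standard_normalize

    manifest = dict(association.OUTCOME_MANIFEST if manifest is None else manifest)
    matrices = preprocessed if preprocessed is not None else cohort.matrices
    missing = [m for cfg in configs for m in cfg.d_prime if m not in matrices]
    if missing:
        raise ValueError(f"cohort lacks modalities: {sorted(set(missing))}")

    rows = []
    for cfg in configs:
        samples = align_samples(*[matrices[m].sample_ids for m in cfg.d_prime])
        n = len(samples)
        if n < max(cfg.c + 2, 10):
            logger.warning("config %s skipped: overlap n=%d too small", cfg.key(), n)
            rows.append(
                {
                    "d": "+".join(cfg.d),
                    "d_prime": "+".join(cfg.d_prime),
                    "m": cfg.m,
                    "n": n,
                    "c": cfg.c,
                    "outcome": None,
                    "p_raw": np.nan,
                    "neg_log10_p": np.nan,
                    "status": "skipped",
                }
            )
            continue
        local_seed = config_seed(seed, cfg)
        mats = [matrices[m].restrict_samples(samples) for m in cfg.d]
        if preprocessed is None:
            mats = [standard_normalize(m) for m in mats]
        affinities = [affinity_from_matrix(m, snf_params) for m in mats]
        fused = fuse(affinities, affinities[0].params)
        part = spectral_cluster(fused, cfg.c, seed=local_seed)
        checksum = zlib.crc32(part.labels.tobytes())
        results = association.run_association_battery(
            part, cohort.phenotypes, cohort.covariates, manifest=manifest
        )
        for res in results:
            rows.append(
                {
                    "d": "+".join(cfg.d),
                    "d_prime": "+".join(cfg.d_prime),
                    "m": cfg.m,
                    "n": n,
                    "c": cfg.c,
                    "outcome": res.outcome,
                    "p_raw": res.p_raw,
                    "neg_log10_p": -np.log10(res.p_raw) if res.p_raw > 0 else np.inf,
                    "status": "ok",
                    "membership_checksum": checksum,
                }
            )
    return pd.DataFrame(rows)


def meta_regression(
    results: pd.DataFrame, predictor: str, outcome: str
) -> MetaRegressionResult:
    """Relate -log10(p) for one outcome to a single design parameter.

    Predictors m, n, c use simple OLS; cf treats the cluster number as
    categorical and reports a one-way ANOVA F across its levels.
    Predictors are tested independently, never jointly.
    """
    if predictor not in ("m", "n", "c", "cf"):
        raise ValueError("predictor must be one of m | n | c | cf")
    sub = results[(results["outcome"] == outcome) & (results["status"] == "ok")]
    sub = sub[np.isfinite(sub["neg_log10_p"])]
    y = sub["neg_log10_p"].to_numpy(float)
    if predictor == "cf":
        groups = [y[sub["c"] == level] for level in sorted(sub["c"].unique())]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            raise ValueError("need >= 2 cluster-number levels")
        F, p = stats.f_oneway(*groups)
        return MetaRegressionResult(outcome, predictor, float(F), float(p), len(y))
    x = sub[predictor].to_numpy(float)
    if len(np.unique(x)) < 2:
        raise ValueError(f"predictor {predictor!r} is constant")
    if np.allclose(y, y[0]):
        return MetaRegressionResult(outcome, predictor, 0.0, 1.0, len(y))
    res = stats.linregress(x, y)
    return MetaRegressionResult(outcome, predictor, float(res.slope), float(res.pvalue), len(y))
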