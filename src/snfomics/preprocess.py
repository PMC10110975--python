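"""Uniform per-modality post-processing ahead of network fusion.

The per-modality pipeline is: missing-rate filtering -> imputation (kNN or
iterative forest-based) -> variance-based feature selection -> covariate
residualization -> z-normalization.  A PCA screen quantifies how strongly
technical/demographic covariates drive each modality's leading components,
which is the empirical justification for residualizing before fusion.

All operations take and return :class:`~snfomics.containers.OmicsMatrix`
and never mutate their input.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, KNNImputer

from .containers import OmicsMatrix, validate_covariates

logger = logging.getLogger(__name__)

DEFAULT_RESIDUAL_COVARIATES = ("age_death", "sex", "pmi", "study")


def select_top_variance_features(X: OmicsMatrix, k: int) -> OmicsMatrix:
    """Keep the min(k, n_features) features with largest sample variance.

    Original feature order is preserved among the selected features.  Ties
    in variance at the cutoff are resolved by feature-ID lexicographic
    order (smaller ID wins), so the selection is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if X.n_features == 0 or X.n_samples == 0:
        raise ValueError("empty matrix")
    variances = X.data.var(axis=0, ddof=1, skipna=True)
    order = sorted(X.data.columns, key=lambda f: (-variances[f], str(f)))
    keep = set(order[: min(k, X.n_features)])
    selected = [f for f in X.data.columns if f in keep]
    return X.with_data(X.data[selected])


def knn_impute(X: OmicsMatrix, k: int = 100) -> OmicsMatrix:
    """Replace missing entries by the feature mean over the k nearest samples.

    Distances are Euclidean over mutually observed features (scaled to the
    full feature count, as in the standard nan-Euclidean convention).
    Observed entries are never modified.  Default k = 100.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if X.data.isna().all(axis=1).any():
        raise ValueError("a sample has no observed features")
    if X.data.isna().all(axis=0).any():
        bad = X.data.columns[X.data.isna().all(axis=0)].tolist()
        raise ValueError(f"features missing in all samples: {bad}")
    if not X.has_missing():
        return X.with_data(X.data.copy())
    k_eff = min(k, X.n_samples - 1)
    imputer = KNNImputer(n_neighbors=k_eff, weights="uniform")
    filled = imputer.fit_transform(X.values)
    out = pd.DataFrame(filled, index=X.data.index, columns=X.data.columns)
    out = out.where(X.data.isna(), X.data)  # observed entries bit-identical
    return X.with_data(out)


def iterative_impute(X: OmicsMatrix, max_iter: int = 10, seed: int = 0) -> OmicsMatrix:
    """missForest-style chained imputation with a random-forest regressor.

    Incomplete features are initialized at their means and then cyclically
    regressed on all other features with a nonparametric ensemble until the
    change in imputed values stops decreasing or ``max_iter`` is reached.
    Deterministic under ``seed``.
    """
    if X.data.isna().all(axis=1).any():
        raise ValueError("a sample has no observed features")
    if X.data.isna().all(axis=0).any():
        raise ValueError("a feature is missing in all samples")
    if not X.has_missing():
        return X.with_data(X.data.copy())
    estimator = RandomForestRegressor(n_estimators=30, random_state=seed, n_jobs=1)
    imputer = IterativeImputer(
        estimator=estimator,
        max_iter=max_iter,
        random_state=seed,
        sample_posterior=False,
        initial_strategy="mean",
    )
    with np.errstate(all="ignore"):
        filled = imputer.fit_transform(X.values)
    if imputer.n_iter_ >= max_iter:
        logger.warning(
            "iterative imputation did not converge in %d iterations; returning best iterate",
            max_iter,
        )
    out = pd.DataFrame(filled, index=X.data.index, columns=X.data.columns)
    out = out.where(X.data.isna(), X.data)
    return X.with_data(out)


def missing_rate_filter(
    X: OmicsMatrix, max_feature_rate: float = 0.2, max_sample_rate: float = 0.4
) -> tuple[OmicsMatrix, dict[str, int]]:
    """Drop features, then samples, whose missing rates exceed the thresholds.

    Feature filtering is applied first and sample missingness is
    re-evaluated on the surviving features, mirroring typical omics QC
    (e.g. <20% per feature, <40% per sample).  Returns the filtered matrix
    and the counts dropped.
    """
    for r in (max_feature_rate, max_sample_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    feat_rate = X.data.isna().mean(axis=0)
    keep_features = feat_rate[feat_rate <= max_feature_rate].index
    if len(keep_features) == 0:
        raise ValueError("all features exceed the missing-rate threshold")
    trimmed = X.data[keep_features]
    sample_rate = trimmed.isna().mean(axis=1)
    keep_samples = sample_rate[sample_rate <= max_sample_rate].index
    out = trimmed.loc[keep_samples]
    report = {
        "features_dropped": X.n_features - len(keep_features),
        "samples_dropped": X.n_samples - len(keep_samples),
    }
    if any(report.values()):
        logger.info(
            "missing-rate filter on %s: dropped %d features, %d samples",
            X.modality,
            report["features_dropped"],
            report["samples_dropped"],
        )
    return X.with_data(out), report


def residualize(
    X: OmicsMatrix,
    covariates: pd.DataFrame,
    covariate_names=DEFAULT_RESIDUAL_COVARIATES,
) -> OmicsMatrix:
    """Replace every feature by its OLS residual on the given covariates.

    Residuals have (numerically) zero sample correlation with each included
    covariate.  The default covariate set is age at death, sex, post-mortem
    interval and study cohort.
    """
    if X.has_missing():
        raise ValueError("residualize requires fully imputed data")
    validate_covariates(covariates, required=covariate_names)
    C = covariates.loc[X.data.index, list(covariate_names)].to_numpy(dtype=float)
    if np.isnan(C).any():
        raise ValueError("missing covariate values among matrix samples")
    design = np.column_stack([np.ones(len(C)), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    coef, *_ = np.linalg.lstsq(design, X.values, rcond=None)
    resid = X.values - design @ coef
    return X.with_data(pd.DataFrame(resid, index=X.data.index, columns=X.data.columns))


def standard_normalize(X: OmicsMatrix) -> OmicsMatrix:
    """Z-score each feature to mean 0, SD 1 (n-1 convention).

    Zero-variance features cannot be standardized and are dropped with a
    warning.
    """
    if X.has_missing():
        raise ValueError("normalization requires fully imputed data")
    mu = X.data.mean(axis=0)
    sd = X.data.std(axis=0, ddof=1)
    # constant columns: std is zero up to float rounding of the mean
    tol = 1e-12 * (mu.abs() + 1.0)
    degenerate = sd[(sd <= tol) | sd.isna()].index
    if len(degenerate):
        logger.warning(
            "dropping %d zero-variance features from %s", len(degenerate), X.modality
        )
    keep = [f for f in X.data.columns if f not in set(degenerate)]
    if not keep:
        raise ValueError("no feature with non-zero variance")
    out = (X.data[keep] - mu[keep]) / sd[keep]
    return X.with_data(out)


def pca_covariate_screen(
    X: OmicsMatrix,
    covariates: pd.DataFrame,
    n_pc: int = 20,
    covariate_names=DEFAULT_RESIDUAL_COVARIATES,
) -> pd.DataFrame:
    """Associate each leading principal component with each covariate.

    For each of the top ``n_pc`` components (default 20): the fraction of
    variance explained, and per covariate the slope and p-value of a simple
    linear model PC ~ covariate.  Large associations indicate that
    technical/demographic structure dominates the modality and motivates
    residualization.
    """
    n_pc = min(n_pc, X.n_samples - 1, X.n_features)
    if n_pc < 1:
        raise ValueError("degenerate matrix: cannot extract components")
    if X.has_missing():
        raise ValueError("PCA requires fully imputed data")
    validate_covariates(covariates, required=covariate_names)
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(X.values)
    rows = []
    for i in range(n_pc):
        for cov in covariate_names:
            cvals = covariates.loc[X.data.index, cov].to_numpy(dtype=float)
            if np.std(cvals) == 0 or np.std(scores[:, i]) == 0:
                slope, p = 0.0, 1.0
            else:
                res = stats.linregress(cvals, scores[:, i])
                slope, p = float(res.slope), float(res.pvalue)
            rows.append(
                {
                    "pc": i + 1,
                    "variance_explained": float(pca.explained_variance_ratio_[i]),
                    "covariate": cov,
                    "statistic": slope,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def preprocess_modality(
    X: OmicsMatrix,
    covariates: pd.DataFrame | None = None,
    top_k: int | None = None,
    knn_k: int = 100,
    max_feature_missing: float = 0.2,
    max_sample_missing: float = 0.4,
    imputer: str = "knn",
    residualize_covariates: bool = True,
    seed: int = 0,
) -> OmicsMatrix:
    """Full per-modality pipeline: filter -> impute -> select -> residualize -> z-score."""
    out, _ = missing_rate_filter(X, max_feature_missing, max_sample_missing)
    if out.has_missing():
        if imputer == "knn":
            out = knn_impute(out, knn_k)
        elif imputer == "iterative":
            out = iterative_impute(out, seed=seed)
        else:
            raise ValueError(f"unknown imputer {imputer!r}")
    if top_k is not None:
        out = select_top_variance_features(out, top_k)
    if residualize_covariates and covariates is not None:
        out = residualize(out, covariates)
    return standard_normalize(out)
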