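"""External validity: subtype-phenotype association models.

Subtype membership (dummy coded against subtype 1) is related to 13
neuropathological outcomes and three cognitive measures with linear or
logistic regression, adjusting for age at death, sex, education,
post-mortem interval, study cohort and APOE epsilon-4 status; cognitive
models additionally adjust for measurement latency (years between last
cognitive visit and death):

    model A:  pathology ~ subtype + age_death + sex + education + pmi + study + apoe4
    model B:  cognition ~ subtype + latency + age_death + sex + education + pmi + study + apoe4

Significance of subtype membership is the omnibus test of the joint null
that all subtype coefficients are zero: an F-test comparing the full
against the covariate-only model for linear outcomes, a likelihood-ratio
chi-square for logistic ones.  P-values are Bonferroni corrected for the
16 tested outcomes by default, or 32 when two clustering solutions are
evaluated jointly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .clustering import Partition

logger = logging.getLogger(__name__)

#: the 16 tested outcomes: name -> (family, model)
#: continuous pathologies and 0-3 ordinal scores use the linear family
#: (model A); presence/absence pathologies and the neuropathological
#: diagnosis use logistic (model A); cognitive measures use model B.
OUTCOME_MANIFEST: dict[str, tuple[str, str]] = {
    "amyloid": ("linear", "A"),
    "plaques_diffuse": ("linear", "A"),
    "plaques_neuritic": ("linear", "A"),
    "tau_phf": ("linear", "A"),
    "tangles": ("linear", "A"),
    "tdp43": ("linear", "A"),
    "atherosclerosis": ("linear", "A"),
    "arteriolosclerosis": ("linear", "A"),
    "caa": ("linear", "A"),
    "lewy_body": ("linear", "A"),
    "gross_infarcts": ("logistic", "A"),
    "microinfarcts": ("logistic", "A"),
    "nia_reagan": ("logistic", "A"),
    "cognition_last": ("linear", "B"),
    "cognition_slope": ("linear", "B"),
    "residual_cognition": ("linear", "B"),
}

#: the eleven observed neuropathologies regressed out of last-visit global
#: cognition to define residual cognition (cognitive resilience)
RESIDUAL_PATHOLOGIES = (
    "amyloid",
    "tangles",
    "plaques_neuritic",
    "plaques_diffuse",
    "lewy_body",
    "gross_infarcts",
    "microinfarcts",
    "atherosclerosis",
    "arteriolosclerosis",
    "tdp43",
    "caa",
)

#: five cognitive subdomains followed up when global cognition is significant
COGNITIVE_DOMAINS = (
    "episodic_memory",
    "semantic_memory",
    "working_memory",
    "perceptual_speed",
    "perceptual_orientation",
)

MODEL_A_COVARIATES = ("age_death", "sex", "education", "pmi", "study", "apoe4")
MODEL_B_COVARIATES = ("latency",) + MODEL_A_COVARIATES


@dataclass
class AssociationResult:
    outcome: str
    family: str
    omnibus_statistic: float
    df: int
    p_raw: float
    p_bonf: float
    n_used: int
    coefficients: pd.DataFrame | None = None  # per-subtype vs baseline subtype 1
    note: str = ""


def bonferroni(p_raw, n_tests: int):
    """Bonferroni adjustment: min(1, p * n_tests); threshold form alpha/n."""
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.minimum(1.0, p * n_tests)
    return float(adjusted) if np.ndim(p_raw) == 0 else adjusted


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Raw p-value threshold equivalent to family-wise alpha over n tests."""
    return alpha / n_tests


def global_cognition_composite(domain_scores: pd.DataFrame) -> pd.DataFrame:
    """Average z-scored cognitive domains into a per-visit global composite.

    ``domain_scores`` is long format with columns ``sample``, ``time`` and
    one column per domain.  Each domain is z-scored against the cohort's
    baseline-visit (earliest time) mean/SD; the composite is the mean of
    the available domains at each visit.
    """
    required = {"sample", "time"}
    if not required <= set(domain_scores.columns):
        raise ValueError("domain table needs 'sample' and 'time' columns")
    domains = [c for c in domain_scores.columns if c not in required]
    if not domains:
        raise ValueError("no domain columns")
    baseline_time = domain_scores["time"].min()
    base = domain_scores[domain_scores["time"] == baseline_time]
    z = domain_scores[domains].copy()
    for d in domains:
        mu = base[d].mean()
        sd = base[d].std(ddof=1)
        z[d] = (domain_scores[d] - mu) / (sd if sd > 0 else 1.0)
    composite = z.mean(axis=1, skipna=True)
    if composite.isna().any():
        raise ValueError("a visit has all domains missing")
    return pd.DataFrame(
        {"sample": domain_scores["sample"], "time": domain_scores["time"], "score": composite}
    )


def cognitive_slope(visits: pd.DataFrame) -> pd.Series:
    """Per-sample OLS slope of the global composite on time (per year).

    ``visits`` is long format with columns ``sample``, ``time``, ``score``.
    Samples with fewer than two visits get a missing slope with a warning.
    """
    slopes = {}
    for sample, grp in visits.groupby("sample", sort=False):
        if len(grp) < 2 or grp["time"].nunique() < 2:
            logger.warning("sample %s has <2 visits; slope set missing", sample)
            slopes[sample] = np.nan
            continue
        slope = np.polyfit(grp["time"].to_numpy(float), grp["score"].to_numpy(float), 1)[0]
        slopes[sample] = float(slope)
    return pd.Series(slopes, name="cognition_slope")


def residual_cognition(
    cognition_last: pd.Series, pathologies: pd.DataFrame, columns=RESIDUAL_PATHOLOGIES
) -> pd.Series:
    """Residuals of last-visit global cognition on observed neuropathologies.

    Positive residuals indicate better-than-expected cognition given the
    measured pathology burden (cognitive resilience).  Aliased (collinear)
    pathology columns are dropped with a warning.
    """
    cols = [c for c in columns if c in pathologies.columns]
    missing = set(columns) - set(cols)
    if missing:
        raise ValueError(f"pathology columns missing: {sorted(missing)}")
    frame = pathologies.loc[cognition_last.index, cols].astype(float)
    if frame.isna().any().any() or cognition_last.isna().any():
        raise ValueError("residual cognition requires complete cases")
    design = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy() for c in cols])
    kept = ["const"] + cols
    # drop aliased columns until full rank
    while np.linalg.matrix_rank(design) < design.shape[1]:
        for j in range(design.shape[1] - 1, 0, -1):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
                logger.warning("dropping aliased pathology column %s", kept[j])
                design = reduced
                kept.pop(j)
                break
    coef, *_ = np.linalg.lstsq(design, cognition_last.to_numpy(float), rcond=None)
    resid = cognition_last.to_numpy(float) - design @ coef
    return pd.Series(resid, index=cognition_last.index, name="residual_cognition")


def _design_frames(
    outcome: pd.Series,
    subtypes: Partition,
    covariates: pd.DataFrame,
    covariate_names,
):
    """Listwise-complete aligned outcome, subtype dummies, covariate block."""
    memb = subtypes.to_series()
    ids = [s for s in memb.index if s in outcome.index and s in covariates.index]
    frame = pd.DataFrame(
        {"outcome": outcome.loc[ids], "subtype": memb.loc[ids]}
    ).join(covariates.loc[ids, list(covariate_names)])
    frame = frame.dropna()
    if frame.empty:
        raise ValueError("no complete cases")
    dropped = len(ids) - len(frame)
    if dropped:
        logger.info("listwise deletion removed %d samples for %s", dropped, outcome.name)
    present = sorted(frame["subtype"].unique())
    if len(present) < 2:
        raise ValueError("fewer than two subtypes after listwise deletion")
    # dummy coding: n_subtypes - 1 indicators, baseline = subtype 1
    dummies = pd.DataFrame(
        {f"subtype_{s}": (frame["subtype"] == s).astype(float) for s in present[1:]},
        index=frame.index,
    )
    cov_block = frame[list(covariate_names)].astype(float)
    return frame["outcome"].astype(float), dummies, cov_block


def fit_outcome_model(
    outcome: pd.Series,
    subtypes: Partition,
    covariates: pd.DataFrame,
    family: str = "linear",
    with_latency: bool = False,
    n_tests: int = 1,
    standardized: bool = False,
) -> AssociationResult:
    """Fit model A (pathology) or model B (cognition) and test subtype omnibus.

    ``with_latency`` selects model B's covariate set.  For the linear
    family the omnibus statistic is the F of the full vs covariate-only
    comparison; for logistic it is the likelihood-ratio chi-square.  With
    ``standardized`` the outcome and continuous predictors are z-scored so
    the per-subtype coefficients are standardized betas.
    """
    covariate_names = MODEL_B_COVARIATES if with_latency else MODEL_A_COVARIATES
    covariate_names = [c for c in covariate_names if c in covariates.columns]
    y, dummies, cov_block = _design_frames(outcome, subtypes, covariates, covariate_names)
    if standardized and family == "linear":
        y = (y - y.mean()) / (y.std(ddof=1) or 1.0)
        for c in cov_block.columns:
            sd = cov_block[c].std(ddof=1)
            if cov_block[c].nunique() > 2 and sd > 0:
                cov_block[c] = (cov_block[c] - cov_block[c].mean()) / sd

    X_full = sm.add_constant(pd.concat([dummies, cov_block], axis=1), has_constant="add")
    X_red = sm.add_constant(cov_block, has_constant="add")
    q = dummies.shape[1]
    note = ""

    if family == "linear":
        full = sm.OLS(y, X_full).fit()
        red = sm.OLS(y, X_red).fit()
        f_stat, p_raw, _ = full.compare_f_test(red)
        stat, p_raw = float(f_stat), float(p_raw)
    elif family == "logistic":
        vals = set(y.unique())
        if not vals <= {0.0, 1.0}:
            raise ValueError(f"logistic outcome must be binary, got {sorted(vals)}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
                red = sm.Logit(y, X_red).fit(disp=0, maxiter=200)
            stat = float(2.0 * (full.llf - red.llf))
            stat = max(stat, 0.0)
            p_raw = float(stats.chi2.sf(stat, q))
            if not (np.isfinite(full.llf) and np.isfinite(red.llf)):
                raise PerfectSeparationError("non-finite likelihood")
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            logger.warning("logistic fit failed for %s: %s", outcome.name, exc)
            return AssociationResult(
                outcome=str(outcome.name), family=family, omnibus_statistic=np.nan,
                df=q, p_raw=np.nan, p_bonf=np.nan, n_used=len(y),
                note=f"fit failed: {exc}",
            )
    else:
        raise ValueError(f"unknown family {family!r}")

    coef_rows = []
    for name in dummies.columns:
        coef_rows.append(
            {
                "term": name,
                "estimate": float(full.params[name]),
                "se": float(full.bse[name]),
                "p": float(full.pvalues[name]),
            }
        )
    return AssociationResult(
        outcome=str(outcome.name),
        family=family,
        omnibus_statistic=stat,
        df=q,
        p_raw=p_raw,
        p_bonf=bonferroni(p_raw, n_tests) if np.isfinite(p_raw) else np.nan,
        n_used=len(y),
        coefficients=pd.DataFrame(coef_rows),
        note=note,
    )


def tukey_hsd(outcome: pd.Series, subtypes: Partition, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise subtype mean differences with studentized-range adjustment.

    Subtypes with fewer than two members are excluded with a warning (their
    pairs are skipped).
    """
    memb = subtypes.to_series()
    ids = [s for s in memb.index if s in outcome.index]
    frame = pd.DataFrame({"y": outcome.loc[ids], "g": memb.loc[ids]}).dropna()
    sizes = frame["g"].value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("skipping singleton subtypes in Tukey HSD: %s", small)
        frame = frame[~frame["g"].isin(small)]
    if frame["g"].nunique() < 2:
        raise ValueError("need >= 2 subtypes with >= 2 members each")
    res = pairwise_tukeyhsd(frame["y"].to_numpy(float), frame["g"].to_numpy(), alpha=alpha)
    table = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return table.astype(
        {"meandiff": float, "p-adj": float, "lower": float, "upper": float}, errors="ignore"
    )


def rank_features_anova(X, subtypes: Partition) -> pd.DataFrame:
    """Rank features by one-way ANOVA across subtypes (ascending p).

    Zero-variance features have an undefined F; they are flagged and ranked
    last.  Supports top-k extraction via ``.head(k)`` on the result.
    """
    data = X.data if hasattr(X, "data") else pd.DataFrame(X)
    memb = subtypes.to_series().loc[data.index]
    groups = [data[memb == g].to_numpy(float) for g in sorted(memb.unique())]
    if len(groups) < 2:
        raise ValueError("need >= 2 subtypes")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*groups, axis=0)
    F = np.atleast_1d(np.asarray(F, float))
    p = np.atleast_1d(np.asarray(p, float))
    # zero within-group variance with distinct group means: perfect
    # separation, F diverges and p underflows to 0 (ranked first)
    means = np.stack([g.mean(axis=0) for g in groups])
    separated = ~np.isfinite(F) & (means.std(axis=0) > 0)
    F[separated] = np.inf
    p[separated] = 0.0
    degenerate = ~np.isfinite(F) & ~separated
    table = pd.DataFrame(
        {"feature": list(data.columns), "F": F, "p": p, "degenerate": degenerate}
    )
    # constant-across-groups features: F = 0, p = 1 by convention
    within_const = data.std(axis=0, ddof=1).to_numpy() == 0
    table.loc[within_const, ["F", "p", "degenerate"]] = [0.0, 1.0, True]
    table.loc[table["degenerate"] & table["F"].isna(), ["F", "p"]] = [0.0, 1.0]
    table = table.sort_values(
        by=["degenerate", "p", "feature"], ascending=[True, True, True]
    ).reset_index(drop=True)
    return table


def run_association_battery(
    subtypes: Partition,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    manifest: dict[str, tuple[str, str]] | None = None,
    n_tests: int | None = None,
    domain_scores: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Run the full outcome battery for one clustering solution.

    One association per manifest outcome (default: the 16-outcome set),
    Bonferroni corrected for ``n_tests`` (defaults to the manifest size; 32
    when two solutions are jointly evaluated).  If a global cognition test
    (last visit or slope) survives correction and per-domain last-visit
    scores are supplied, a five-domain follow-up battery (model B,
    corrected within the domain set) is appended.
    """
    manifest = dict(OUTCOME_MANIFEST if manifest is None else manifest)
    n_tests = len(manifest) if n_tests is None else n_tests
    results = []
    for name, (family, model) in manifest.items():
        if name not in phenotypes.columns:
            raise ValueError(f"phenotype table lacks outcome {name!r}")
        res = fit_outcome_model(
            phenotypes[name],
            subtypes,
            covariates,
            family=family,
            with_latency=(model == "B"),
            n_tests=n_tests,
        )
        results.append(res)

    cognition_hit = any(
        r.outcome in ("cognition_last", "cognition_slope")
        and np.isfinite(r.p_bonf)
        and r.p_bonf < alpha
        for r in results
    )
    if cognition_hit and domain_scores is not None:
        for domain in COGNITIVE_DOMAINS:
            if domain not in domain_scores.columns:
                continue
            res = fit_outcome_model(
                domain_scores[domain],
                subtypes,
                covariates,
                family="linear",
                with_latency=True,
                n_tests=len(COGNITIVE_DOMAINS),
            )
            res.note = "subdomain follow-up"
            results.append(res)
    return results


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    rows = [
        {
            "outcome": r.outcome,
            "family": r.family,
            "statistic": r.omnibus_statistic,
            "df": r.df,
            "p_raw": r.p_raw,
            "p_bonf": r.p_bonf,
            "n": r.n_used,
            "note": r.note,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
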