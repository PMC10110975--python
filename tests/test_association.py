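"""Outcome models: omnibus tests, corrections, post hocs, feature ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import snfomics as sf
from snfomics import association as assoc
from snfomics.clustering import Partition


def _covariates(n, seed=0, with_latency=True):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "age_death": rng.normal(89, 6.6, n),
            "sex": rng.binomial(1, 0.33, n).astype(float),
            "education": rng.normal(16, 3.5, n),
            "pmi": np.maximum(rng.normal(8.3, 6.1, n), 0.0),
            "study": rng.binomial(1, 0.5, n).astype(float),
            "apoe4": rng.binomial(1, 0.25, n).astype(float),
        },
        index=[f"s{i}" for i in range(n)],
    )
    if with_latency:
        frame["latency"] = np.abs(rng.normal(1, 0.8, n))
    return frame


def _random_partition(n, c, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.arange(1, c + 1), rng.integers(1, c + 1, n - c)])
    return Partition([f"s{i}" for i in range(n)], rng.permutation(labels))


# ---------------------------------------------------------- composites
def test_global_composite_simple_cases():
    base = pd.DataFrame(
        {
            "sample": ["a", "b", "c", "d"],
            "time": [0.0] * 4,
            "d1": [1.0, 2.0, 3.0, 4.0],
            "d2": [0.0, 1.0, 2.0, 3.0],
        }
    )
    comp = assoc.global_cognition_composite(base)
    # at-baseline z-scores average to 0 across the cohort
    assert comp["score"].mean() == pytest.approx(0.0, abs=1e-12)
    # one domain only -> composite equals that domain's z
    single = base.drop(columns="d2")
    comp1 = assoc.global_cognition_composite(single)
    z = (base["d1"] - base["d1"].mean()) / base["d1"].std(ddof=1)
    assert np.allclose(comp1["score"], z)


def test_cognitive_slope_exact_line_and_constant():
    visits = pd.DataFrame(
        {
            "sample": ["a"] * 4 + ["b"] * 4,
            "time": [0, 1, 2, 3] * 2,
            "score": [1.0, 0.9, 0.8, 0.7] + [2.0] * 4,
        }
    )
    slopes = assoc.cognitive_slope(visits)
    assert slopes["a"] == pytest.approx(-0.1, abs=1e-12)
    assert slopes["b"] == pytest.approx(0.0, abs=1e-12)


def test_cognitive_slope_noisy_recovery(rng):
    n, n_visits = 500, 8
    truth = rng.normal(-0.1, 0.05, n)
    rows = []
    for i in range(n):
        for t in range(n_visits):
            rows.append(
                {"sample": f"s{i}", "time": float(t), "score": truth[i] * t + rng.normal(0, 0.2)}
            )
    slopes = assoc.cognitive_slope(pd.DataFrame(rows))
    err = slopes.to_numpy() - truth
    # per-sample OLS sampling SD with 8 unit-spaced visits
    se = 0.2 / np.sqrt(((np.arange(n_visits) - n_visits / 2 + 0.5) ** 2).sum())
    assert np.abs(err).mean() < 2 * se


# ------------------------------------------------------ residual cognition
def test_residual_cognition_exact_and_orthogonal(rng):
    n = 80
    ids = [f"s{i}" for i in range(n)]
    paths = pd.DataFrame(
        {name: rng.standard_normal(n) for name in assoc.RESIDUAL_PATHOLOGIES}, index=ids
    )
    exact = pd.Series(
        2.0 * paths["amyloid"] - paths["tangles"] + 0.5, index=ids, name="cog"
    )
    res = assoc.residual_cognition(exact, paths)
    assert np.max(np.abs(res)) < 1e-8
    design = np.column_stack([np.ones(n), paths.to_numpy()])
    raw = rng.standard_normal(n)
    ortho = raw - design @ np.linalg.lstsq(design, raw, rcond=None)[0]
    res2 = assoc.residual_cognition(pd.Series(ortho + 3.0, index=ids), paths)
    assert np.allclose(res2, ortho - ortho.mean(), atol=1e-8)
    for c in paths.columns:
        assert abs(np.corrcoef(res2, paths[c])[0, 1]) < 1e-10


def test_residual_cognition_recovers_planted_resilience(rng):
    n = 400
    ids = [f"s{i}" for i in range(n)]
    paths = pd.DataFrame(
        {name: rng.standard_normal(n) for name in assoc.RESIDUAL_PATHOLOGIES}, index=ids
    )
    resilience = rng.standard_normal(n) * 3.0
    cog = pd.Series(
        paths.to_numpy() @ rng.standard_normal(len(paths.columns)) + resilience
        + rng.standard_normal(n),
        index=ids,
    )
    res = assoc.residual_cognition(cog, paths)
    assert np.corrcoef(res, resilience)[0, 1] > 0.9


def test_residual_cognition_drops_aliased_column(rng):
    n = 50
    ids = [f"s{i}" for i in range(n)]
    paths = pd.DataFrame(
        {name: rng.standard_normal(n) for name in assoc.RESIDUAL_PATHOLOGIES}, index=ids
    )
    paths["caa"] = 2 * paths["amyloid"]  # aliased
    cog = pd.Series(rng.standard_normal(n), index=ids)
    res = assoc.residual_cognition(cog, paths)
    assert np.isfinite(res).all()


# --------------------------------------------------------------- omnibus
def _brute_force_ancova_f(y, dummies, covs):
    """Independent RSS-based one-way ANCOVA F."""
    n = len(y)
    X_full = np.column_stack([np.ones(n), dummies, covs])
    X_red = np.column_stack([np.ones(n), covs])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    q = dummies.shape[1]
    df_full = n - X_full.shape[1]
    return ((rss(X_red) - rss(X_full)) / q) / (rss(X_full) / df_full)


def test_omnibus_f_matches_brute_force_rss_oracle(rng):
    n = 50
    covs = _covariates(n, seed=1)
    part = _random_partition(n, 3, seed=2)
    y = pd.Series(rng.standard_normal(n), index=covs.index, name="y")
    res = assoc.fit_outcome_model(y, part, covs, family="linear")
    dummies = np.column_stack(
        [(part.labels == g).astype(float) for g in (2, 3)]
    )
    cov_arr = covs[list(assoc.MODEL_A_COVARIATES)].to_numpy()
    f_oracle = _brute_force_ancova_f(y.to_numpy(), dummies, cov_arr)
    assert res.omnibus_statistic == pytest.approx(f_oracle, abs=1e-8)
    assert res.df == 2


def test_omnibus_null_calibration_uniform():
    """Outcome independent of subtype: omnibus p uniform over 200 seeds."""
    pvals = []
    for seed in range(200):
        rng = np.random.default_rng(50_000 + seed)
        n = 200
        covs = _covariates(n, seed=seed)
        part = _random_partition(n, 3, seed=seed)
        y = pd.Series(
            0.5 * covs["age_death"] + rng.standard_normal(n) * 3, index=covs.index, name="y"
        )
        pvals.append(assoc.fit_outcome_model(y, part, covs, family="linear").p_raw)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_omnibus_confounding_controlled():
    """Outcome a pure age effect, subtypes independent of age: p uniform."""
    pvals = []
    for seed in range(100):
        rng = np.random.default_rng(10_000 + seed)
        n = 200
        covs = _covariates(n, seed=seed)
        part = _random_partition(n, 3, seed=seed + 1)
        y = pd.Series(2.0 * covs["age_death"] + rng.standard_normal(n), index=covs.index)
        pvals.append(assoc.fit_outcome_model(y, part, covs, family="linear").p_raw)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_logistic_lrt_type_i_error():
    """Null logistic omnibus is asymptotically chi-square(c-1): type-I
    error near nominal 0.05 at n = 2000."""
    rejections = 0
    n_sims = 200
    for seed in range(n_sims):
        rng = np.random.default_rng(20_000 + seed)
        n = 2000
        covs = _covariates(n, seed=seed)
        part = _random_partition(n, 3, seed=seed)
        y = pd.Series(rng.binomial(1, 0.4, n).astype(float), index=covs.index)
        res = assoc.fit_outcome_model(y, part, covs, family="logistic")
        rejections += res.p_raw < 0.05
    assert 0.03 <= rejections / n_sims <= 0.07


def test_planted_slope_shift_detected():
    """One of five subtypes with cognition slope shifted by -0.15/yr is
    detected after Bonferroni in nearly all repetitions (n = 500)."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(30_000 + seed)
        n = 500
        covs = _covariates(n, seed=seed)
        part = _random_partition(n, 5, seed=seed)
        shift = np.where(part.labels == 5, -0.15, 0.0)
        y = pd.Series(shift + rng.normal(0, 0.15, n), index=covs.index)
        res = assoc.fit_outcome_model(y, part, covs, family="linear",
                                      with_latency=True, n_tests=16)
        hits += res.p_bonf < 0.05
    assert hits >= 0.9 * n_seeds


def test_dummy_coding_has_c_minus_1_indicators():
    n = 60
    covs = _covariates(n)
    part = _random_partition(n, 4, seed=3)
    y = pd.Series(np.random.default_rng(0).standard_normal(n), index=covs.index)
    res = assoc.fit_outcome_model(y, part, covs, family="linear")
    assert res.df == 3
    assert list(res.coefficients["term"]) == ["subtype_2", "subtype_3", "subtype_4"]


# ------------------------------------------------------------- bonferroni
def test_bonferroni_thresholds_and_cap():
    assert assoc.bonferroni_threshold(0.05, 16) == pytest.approx(3.1e-3, rel=0.02)
    assert assoc.bonferroni_threshold(0.05, 32) == pytest.approx(1.6e-3, rel=0.03)
    assert assoc.bonferroni(0.2, 16) == 1.0
    assert assoc.bonferroni(0.001, 16) == pytest.approx(0.016)


# -------------------------------------------------------------- Tukey HSD
def test_tukey_two_groups_equals_pooled_t():
    rng = np.random.default_rng(5)
    n = 40
    y = pd.Series(rng.standard_normal(n), index=[f"s{i}" for i in range(n)])
    part = Partition(list(y.index), np.repeat([1, 2], n // 2))
    table = assoc.tukey_hsd(y, part)
    t_p = stats.ttest_ind(y[part.labels == 1], y[part.labels == 2]).pvalue
    assert float(table["p-adj"].iloc[0]) == pytest.approx(t_p, abs=1e-4)


def test_tukey_equal_means_cover_zero(rng):
    n = 60
    y = pd.Series(rng.standard_normal(n), index=[f"s{i}" for i in range(n)])
    part = Partition(list(y.index), np.repeat([1, 2, 3], n // 3))
    table = assoc.tukey_hsd(y, part)
    assert (table["lower"] < 0).all() and (table["upper"] > 0).all()


def test_tukey_detects_shifted_group(rng):
    n = 150
    part = Partition([f"s{i}" for i in range(n)], np.repeat([1, 2, 3], 50))
    y = pd.Series(
        rng.standard_normal(n) + np.where(part.labels == 3, 3.0, 0.0),
        index=part.sample_ids,
    )
    table = assoc.tukey_hsd(y, part)
    involving3 = table[(table["group1"] == 3) | (table["group2"] == 3)]
    others = table[(table["group1"] != 3) & (table["group2"] != 3)]
    assert (involving3["p-adj"] < 0.001).all()
    assert (others["p-adj"] > 0.05).all()


# -------------------------------------------------------- feature ranking
def test_rank_features_anova_edge_cases(rng):
    n = 60
    part = Partition([f"s{i}" for i in range(n)], np.repeat([1, 2, 3], 20))
    X = pd.DataFrame(
        {
            "constant": np.ones(n),
            "labels_exact": part.labels.astype(float),
            "noise": rng.standard_normal(n),
        },
        index=part.sample_ids,
    )
    table = assoc.rank_features_anova(X, part).set_index("feature")
    assert table.index[0] == "labels_exact"  # perfect separation ranks first
    assert table.loc["labels_exact", "p"] < 1e-30
    assert table.index[-1] == "constant"  # degenerate ranked last
    assert bool(table.loc["constant", "degenerate"])
    assert table.loc["constant", "F"] == 0.0 and table.loc["constant", "p"] == 1.0


def test_rank_features_anova_null_uniform(rng):
    n = 90
    part = Partition([f"s{i}" for i in range(n)], np.repeat([1, 2, 3], 30))
    X = pd.DataFrame(
        rng.standard_normal((n, 1000)),
        index=part.sample_ids,
        columns=[f"f{j}" for j in range(1000)],
    )
    table = assoc.rank_features_anova(X, part)
    assert stats.kstest(table["p"], "uniform").pvalue > 0.01


# ----------------------------------------------------------- battery
def test_battery_bookkeeping_and_corrections(two_modal_cohort):
    part = two_modal_cohort.true_labels
    results = assoc.run_association_battery(
        part, two_modal_cohort.phenotypes, two_modal_cohort.covariates
    )
    main = [r for r in results if r.note != "subdomain follow-up"]
    assert len(main) == 16
    for r in main:
        if np.isfinite(r.p_raw):
            assert r.p_bonf == pytest.approx(min(1.0, r.p_raw * 16))
    # joint two-solution mode: correction factor 32
    joint = assoc.run_association_battery(
        part, two_modal_cohort.phenotypes, two_modal_cohort.covariates, n_tests=32
    )
    for r in joint:
        if np.isfinite(r.p_raw):
            assert r.p_bonf == pytest.approx(min(1.0, r.p_raw * 32))
    # planted amyloid effect survives
    amyloid = next(r for r in results if r.outcome == "amyloid")
    assert amyloid.p_bonf < 0.05


def test_battery_null_false_positive_rate():
    """Null cohorts: about 5% of the 16 raw p-values fall below 0.05."""
    count, total = 0, 0
    for seed in range(12):
        spec = sf.CohortSpec(
            n_samples=150,
            n_subtypes_true=3,
            modalities=(sf.ModalitySpec("a", 10, signal_strength=0.0),),
            seed=600 + seed,
        )
        cohort = sf.generate_cohort(spec)
        results = assoc.run_association_battery(
            cohort.true_labels, cohort.phenotypes, cohort.covariates
        )
        ps = [r.p_raw for r in results if np.isfinite(r.p_raw)]
        count += sum(p < 0.05 for p in ps)
        total += len(ps)
    assert count / total < 0.12  # ~0.05 expected; generous binomial margin
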