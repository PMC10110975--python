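"""End-to-end two-stage subtyping driver.

Stage 1 fuses all configured modalities on the full-overlap sample,
elects the cluster number by both criteria, clusters, measures resampling
stability, and ranks each modality's contribution to the fused network by
NMI.  Stage 2 re-fuses the top-k (default 3) NMI-ranked modalities on
their (larger) overlap, evaluates every elected solution — both of them
when the eigen-gap and rotation-cost criteria disagree — runs the
association batteries with 16-test (single solution) or combined 32-test
correction, and cross-tabulates the solutions (ARI, chi-square).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association
from .clustering import (
    Partition,
    ari,
    chi_square_independence,
    estimate_cluster_number,
    modality_contribution,
    spectral_cluster,
)
from .cohort import SyntheticCohort
from .containers import OmicsMatrix, align_samples
from .preprocess import standard_normalize
from .snf import SNFParams, affinity_from_matrix, fuse

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Structured configuration for the two-stage driver (YAML-loadable)."""

    modality_paths: dict[str, str] = field(default_factory=dict)
    covariates_path: str | None = None
    phenotypes_path: str | None = None
    snf: SNFParams = field(default_factory=SNFParams)
    candidate_range: tuple[int, int] = (2, 8)
    stability_fraction: float = 0.8
    stability_draws: int = 300
    top_k_modalities: int = 3
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        snf_raw = raw.pop("snf", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.snf = SNFParams(**snf_raw)
        cfg.candidate_range = tuple(raw.get("candidate_range", cfg.candidate_range))
        for name, p in cfg.modality_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"modality {name!r}: {p}")
        return cfg

    def validate(self) -> None:
        lo, hi = self.candidate_range
        if lo < 2 or hi < lo:
            raise ValueError("invalid candidate range")


def _fuse_set(matrices: list[OmicsMatrix], params: SNFParams):
    affinities = {m.modality: affinity_from_matrix(m, params) for m in matrices}
    fused = fuse(list(affinities.values()), next(iter(affinities.values())).params)
    return fused, affinities


def _solution_block(fused, c, seed, phenotypes, covariates, n_tests):
    part = spectral_cluster(fused, c, seed=seed)
    results = association.run_association_battery(
        part, phenotypes, covariates, n_tests=n_tests
    )
    return part, association.results_table(results)


def run_two_stage(
    matrices: dict[str, OmicsMatrix],
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    params: SNFParams = SNFParams(),
    candidate_range=range(2, 9),
    top_k: int = 3,
    stability_draws: int = 50,
    stability_fraction: float = 0.8,
    normalize: bool = True,
    seed: int = 0,
    output_dir=None,
) -> dict:
    """Run the two-stage design on processed (or raw, z-scored) matrices."""
    from .stability import resample_stability

    if len(matrices) < 3:
        raise ValueError("two-stage design requires >= 3 modalities")
    report: dict = {"seed": seed, "params": {"K": params.K, "alpha": params.alpha, "T": params.T}}

    # ---- stage 1: full fusion on the all-modality overlap --------------
    overlap = align_samples(*[m.sample_ids for m in matrices.values()])
    if len(overlap) < 10:
        raise ValueError(f"full overlap too small: n={len(overlap)}")
    stage1_mats = [m.restrict_samples(overlap) for m in matrices.values()]
    if normalize:
        stage1_mats = [standard_normalize(m) for m in stage1_mats]
    fused1, affinities1 = _fuse_set(stage1_mats, params)
    candidates = [c for c in candidate_range if c < len(overlap)]
    est1 = estimate_cluster_number(fused1, candidates)
    c1 = est1.eigen_gap_best
    part1 = spectral_cluster(fused1, c1, seed=seed)
    nmi_ranking = modality_contribution(fused1, affinities1, c1, seed=seed)
    stab1 = resample_stability(
        stage1_mats, params, c1,
        fraction=stability_fraction, draws=stability_draws, seed=seed,
        full_partition=part1,
    )
    report["stage1"] = {
        "n": len(overlap),
        "elected": est1.elected(),
        "eigen_gap_best": est1.eigen_gap_best,
        "rotation_cost_best": est1.rotation_cost_best,
        "subtype_sizes": part1.sizes(),
        "nmi_ranking": nmi_ranking,
        "stability": stab1.summary(),
    }

    # ---- stage 2: refuse the top-k contributing modalities -------------
    top_modalities = list(nmi_ranking)[:top_k]
    overlap2 = align_samples(*[matrices[m].sample_ids for m in top_modalities])
    stage2_mats = [matrices[m].restrict_samples(overlap2) for m in top_modalities]
    if normalize:
        stage2_mats = [standard_normalize(m) for m in stage2_mats]
    fused2, _ = _fuse_set(stage2_mats, params)
    candidates2 = [c for c in candidate_range if c < len(overlap2)]
    est2 = estimate_cluster_number(fused2, candidates2)
    elected = est2.elected()
    n_tests = 16 * len(elected)

    solutions = {}
    parts: dict[int, Partition] = {}
    for c in elected:
        part, table = _solution_block(fused2, c, seed, phenotypes, covariates, n_tests)
        parts[c] = part
        solutions[c] = {
            "subtype_sizes": part.sizes(),
            "associations": table,
            "stability": resample_stability(
                stage2_mats, params, c,
                fraction=stability_fraction, draws=stability_draws, seed=seed,
                full_partition=part,
            ).summary(),
        }
    report["stage2"] = {
        "modalities": top_modalities,
        "n": len(overlap2),
        "elected": elected,
        "eigen_gap_best": est2.eigen_gap_best,
        "rotation_cost_best": est2.rotation_cost_best,
        "criteria_agree": est2.agree(),
        "n_tests": n_tests,
        "solutions": solutions,
    }
    if len(elected) == 2:
        a, b = (parts[c] for c in elected)
        stat, df, p = chi_square_independence(a, b)
        report["stage2"]["cross_tabulation"] = {
            "ari": ari(a, b),
            "chi2": stat,
            "df": df,
            "p": p,
        }

    if output_dir is not None:
        _write_report(report, parts, fused1, fused2, output_dir)
    return report


def run_two_stage_on_cohort(cohort: SyntheticCohort, **kwargs) -> dict:
    return run_two_stage(cohort.matrices, cohort.phenotypes, cohort.covariates, **kwargs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.replace({np.nan: None}).to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_report(report, parts, fused1, fused2, output_dir) -> None:
    from .io import save_affinity, save_partition

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    save_affinity(fused1, out / "fused_stage1.tsv")
    save_affinity(fused2, out / "fused_stage2.tsv")
    for c, part in parts.items():
        save_partition(part, out / f"membership_stage2_c{c}.tsv")
    for c, block in report["stage2"]["solutions"].items():
        block["associations"].to_csv(out / f"associations_c{c}.tsv", sep="\t", index=False)
    logger.info("two-stage report written to %s", out)
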