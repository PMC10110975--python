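"""Internal cluster validity by resampling.

Repeatedly subsample a fraction of participants (default 80%, 300 draws),
re-run the affinity -> fusion -> spectral clustering pipeline at the same
cluster number, and compare each draw's partition with the full-data
partition restricted to the drawn samples, using two adapted measures:

* APN (average proportion of non-overlap): for each retained sample, the
  proportion of its full-data co-cluster (within the draw) that is no
  longer in its resampled cluster; 0 for perfectly stable clusters.
* ADM (average distance between means): the mean Euclidean distance
  between the centroids (in feature space) of each sample's full-data
  cluster and resampled cluster; 0 for perfectly stable clusters.

Both are set-overlap/centroid based, so no label alignment between draws
is required; the adjusted Rand index per draw is reported additionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import Partition, ari, spectral_cluster
from .containers import OmicsMatrix
from .snf import SNFParams, affinity_from_matrix, fuse

logger = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    draws: int
    fraction: float
    per_draw: pd.DataFrame  # columns: draw, apn, adm, ari
    full_partition: Partition

    @property
    def apn_values(self) -> np.ndarray:
        return self.per_draw["apn"].to_numpy()

    @property
    def adm_values(self) -> np.ndarray:
        return self.per_draw["adm"].to_numpy()

    def summary(self) -> dict[str, float]:
        return {
            "apn_mean": float(self.per_draw["apn"].mean()),
            "apn_sd": float(self.per_draw["apn"].std(ddof=1)),
            "adm_mean": float(self.per_draw["adm"].mean()),
            "adm_sd": float(self.per_draw["adm"].std(ddof=1)),
            "ari_mean": float(self.per_draw["ari"].mean()),
        }


def apn(full: Partition, sub: Partition) -> float:
    """Average proportion of non-overlap of a subsample clustering.

    For each sample i in the subsample, let C0(i) be the subsample members
    sharing i's full-data cluster and Cl(i) those sharing i's subsample
    cluster; i contributes 1 - |C0(i) & Cl(i)| / |C0(i)|.  APN is the mean
    contribution, in [0, 1]; note it is asymmetric in its arguments.
    """
    if not sub.sample_ids:
        raise ValueError("empty subsample")
    if not set(sub.sample_ids) <= set(full.sample_ids):
        raise ValueError("subsample contains samples outside the full partition")
    full_series = full.to_series()
    sub_ids = np.array(sub.sample_ids, dtype=object)
    full_labels = full_series.loc[sub.sample_ids].to_numpy()
    sub_labels = sub.labels
    contributions = []
    for i in range(len(sub_ids)):
        c0 = full_labels == full_labels[i]
        cl = sub_labels == sub_labels[i]
        contributions.append(1.0 - (c0 & cl).sum() / c0.sum())
    return float(np.mean(contributions))


def adm(full: Partition, sub: Partition, X) -> float:
    """Average distance between full-data and subsample cluster centroids.

    For each retained sample, the Euclidean distance between the centroid
    (in the feature matrix ``X``, rows indexed by sample ID) of its
    full-data cluster and of its subsample cluster, restricted to the
    subsample; averaged over retained samples.  Scales linearly with X.
    """
    data = X.data if isinstance(X, OmicsMatrix) else pd.DataFrame(X)
    missing = set(sub.sample_ids) - set(data.index)
    if missing:
        raise ValueError(f"feature matrix lacks subsample samples: {sorted(missing)[:5]}")
    sub_X = data.loc[sub.sample_ids].to_numpy(float)
    full_labels = full.to_series().loc[sub.sample_ids].to_numpy()
    sub_labels = sub.labels

    def centroid(mask):
        return sub_X[mask].mean(axis=0)

    full_centroids = {g: centroid(full_labels == g) for g in np.unique(full_labels)}
    sub_centroids = {g: centroid(sub_labels == g) for g in np.unique(sub_labels)}
    dists = [
        float(np.linalg.norm(full_centroids[full_labels[i]] - sub_centroids[sub_labels[i]]))
        for i in range(len(sub_labels))
    ]
    return float(np.mean(dists))


def resample_stability(
    matrices: list[OmicsMatrix],
    params: SNFParams,
    c: int,
    fraction: float = 0.8,
    draws: int = 300,
    seed: int = 0,
    full_partition: Partition | None = None,
) -> StabilityReport:
    """APN/ADM distributions under repeated subsampling with full re-runs.

    The processed (imputed, residualized, z-scored) per-modality matrices
    must share the same sample set.  The full-data pipeline is run once to
    fix the reference partition (or a precomputed one can be supplied);
    each draw subsamples ``floor(fraction * n)`` participants without
    replacement, rebuilds affinities, refuses, and re-clusters at the same
    c.  ADM centroids live in the concatenation of all modalities'
    features.  Deterministic under ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    ids = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != ids:
            raise ValueError("matrices must share the identical sample set and order")
    n = len(ids)
    n_sub = int(np.floor(fraction * n))
    if n_sub < c + 2:
        raise ValueError(f"subsample size {n_sub} too small for c={c}")

    def cluster_set(mats: list[OmicsMatrix]) -> Partition:
        affinities = [affinity_from_matrix(m, params) for m in mats]
        fused = fuse(affinities, affinities[0].params)
        return spectral_cluster(fused, c, seed=seed)

    if full_partition is None:
        full_partition = cluster_set(matrices)
    concat = pd.concat([m.data for m in matrices], axis=1)

    rng = np.random.default_rng(seed)
    rows = []
    for d in range(draws):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        keep = [ids[i] for i in idx]
        sub_mats = [m.restrict_samples(keep) for m in matrices]
        sub_part = cluster_set(sub_mats)
        ref = full_partition.restrict(keep)
        rows.append(
            {
                "draw": d,
                "apn": apn(full_partition, sub_part),
                "adm": adm(full_partition, sub_part, concat),
                "ari": ari(ref, sub_part),
            }
        )
    report = StabilityReport(
        draws=draws,
        fraction=fraction,
        per_draw=pd.DataFrame(rows),
        full_partition=full_partition,
    )
    return report
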