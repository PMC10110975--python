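"""Shared data containers: per-modality omics matrices and sample tables.

An :class:`OmicsMatrix` is a thin, validated wrapper around a pandas
DataFrame holding one modality's samples x features measurements.  Sample
and feature identifiers must be unique; entries may be missing (NaN) prior
to imputation.  Covariate and phenotype tables are plain DataFrames indexed
by sample identifier, validated by the helpers below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: covariates used throughout the association models: age at death (years),
#: biological sex (binary), educational attainment (years), post-mortem
#: interval (hours), study cohort (binary), APOE epsilon-4 carrier status
#: (binary) and measurement latency (years between last visit and death).
COVARIATE_COLUMNS = (
    "age_death",
    "sex",
    "education",
    "pmi",
    "study",
    "apoe4",
    "latency",
)


@dataclass
class OmicsMatrix:
    """One modality's samples x features real matrix with identifiers."""

    modality: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def has_missing(self) -> bool:
        return bool(self.data.isna().to_numpy().any())

    def with_data(self, data: pd.DataFrame) -> "OmicsMatrix":
        """Return a new matrix for the same modality with replaced data."""
        return OmicsMatrix(self.modality, data)

    def restrict_samples(self, sample_ids) -> "OmicsMatrix":
        """Subset (and reorder) rows to the given sample identifiers."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from modality {self.modality!r}: {missing[:5]}")
        return self.with_data(self.data.loc[list(sample_ids)])


def validate_covariates(table: pd.DataFrame, required=("age_death", "sex", "pmi", "study")) -> pd.DataFrame:
    """Check a covariate table: unique sample index, required columns, latency >= 0."""
    if table.index.has_duplicates:
        raise ValueError("duplicate sample IDs in covariate table")
    absent = [c for c in required if c not in table.columns]
    if absent:
        raise ValueError(f"covariate table missing columns: {absent}")
    if "latency" in table.columns and (table["latency"].dropna() < 0).any():
        raise ValueError("latency must be non-negative")
    return table


def align_samples(*id_lists) -> list[str]:
    """Intersection of sample-ID collections, in the order of the first."""
    if not id_lists:
        return []
    common = set(id_lists[0])
    for ids in id_lists[1:]:
        common &= set(ids)
    return [s for s in id_lists[0] if s in common]
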