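"""Reading and writing the pipeline's tab-delimited file formats.

Matrices are tab- or comma-delimited with sample IDs in the first column
and feature IDs in the header row; "NA" or empty cells denote missing
values.  Memberships are two-column (sample, subtype) tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import Partition
from .containers import OmicsMatrix

_NA_VALUES = ["NA", "NaN", "nan", ""]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False)
    frame.index = frame.index.astype(str)
    return frame


def load_matrix(path, modality: str | None = None) -> OmicsMatrix:
    """Read one modality's samples x features matrix."""
    path = Path(path)
    frame = _read_table(path)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        line = int(np.where(frame.index == dup)[0][-1]) + 2  # header is line 1
        raise ValueError(f"duplicate sample ID {dup!r} at line {line} of {path}")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return OmicsMatrix(modality or path.stem, frame)


def save_matrix(X: OmicsMatrix, path) -> None:
    X.data.to_csv(path, sep="\t", na_rep="NA")


def load_samples_table(path) -> pd.DataFrame:
    """Read a per-sample covariate or phenotype table."""
    frame = _read_table(path)
    if frame.index.has_duplicates:
        raise ValueError(f"duplicate sample IDs in {path}")
    return frame


def save_samples_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", na_rep="NA")


def load_partition(path) -> Partition:
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.shape[1] < 2:
        raise ValueError("membership file needs two columns (sample, subtype)")
    return Partition.from_labels(frame.iloc[:, 0].tolist(), frame.iloc[:, 1].tolist())


def save_partition(partition: Partition, path) -> None:
    partition.to_series().rename_axis("sample").reset_index().to_csv(
        path, sep="\t", index=False
    )


def load_affinity(path):
    from .snf import AffinityMatrix, SNFParams

    frame = _read_table(path)
    return AffinityMatrix(
        sample_ids=[str(s) for s in frame.index],
        W=frame.to_numpy(float),
        params=SNFParams(),
    )


def save_affinity(W, path) -> None:
    pd.DataFrame(W.W, index=W.sample_ids, columns=W.sample_ids).to_csv(path, sep="\t")
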