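"""Reading, writing and summarising the matrices the pipeline consumes.

Two binary matrices drive everything:

* an interaction matrix ``Y`` (drugs x targets, entries in {0, 1}), stored
  as a tab-delimited table with target identifiers in the header row and
  drug identifiers in the first column;
* a fingerprint matrix ``Z`` (fingerprint bits x drugs, entries in {0, 1})
  in the same dialect.

Some mirrors of the interaction benchmark ship the transpose (targets as
rows), so :func:`read_interaction_matrix` takes an explicit ``orientation``
flag instead of guessing.  Identifiers are opaque strings; matrices are kept
dense (benchmark scale tops out around 445 x 664).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InteractionMatrix",
    "FingerprintMatrix",
    "DatasetStats",
    "read_interaction_matrix",
    "read_fingerprint_matrix",
    "dataset_statistics",
    "write_interaction_matrix",
    "write_fingerprint_matrix",
    "write_score_matrix",
    "read_score_matrix",
]


def _check_ids(ids: Sequence[str], axis: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {axis} identifiers")
    return ids


def _check_binary(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
        raise ValueError(f"{name} must be a non-empty 2-D matrix")
    as_float = values.astype(float, copy=False)
    if not np.isin(as_float, (0.0, 1.0)).all():
        bad = as_float[~np.isin(as_float, (0.0, 1.0))].flat[0]
        raise ValueError(f"{name} contains a non-binary cell value: {bad!r}")
    return as_float.astype(np.int8)


@dataclass(frozen=True)
class InteractionMatrix:
    """Binary drug x target adjacency with row/column identifiers."""

    values: np.ndarray
    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = _check_binary(self.values, "interaction matrix")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "drug_ids", _check_ids(self.drug_ids, "drug"))
        object.__setattr__(self, "target_ids", _check_ids(self.target_ids, "target"))
        n, m = values.shape
        if n != len(self.drug_ids) or m != len(self.target_ids):
            raise ValueError(
                f"shape {values.shape} inconsistent with "
                f"{len(self.drug_ids)} drugs / {len(self.target_ids)} targets"
            )

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_targets(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FingerprintMatrix:
    """Binary fingerprint-bit x drug matrix.

    Bit semantics are opaque here; the conventional fingerprint length is
    800 bits but ``f`` is whatever the file (or generator) provides.
    """

    values: np.ndarray
    bit_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = _check_binary(self.values, "fingerprint matrix")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "bit_ids", _check_ids(self.bit_ids, "bit"))
        object.__setattr__(self, "drug_ids", _check_ids(self.drug_ids, "drug"))
        f, n = values.shape
        if f != len(self.bit_ids) or n != len(self.drug_ids):
            raise ValueError(
                f"shape {values.shape} inconsistent with "
                f"{len(self.bit_ids)} bits / {len(self.drug_ids)} drugs"
            )

    @property
    def n_bits(self) -> int:
        return self.values.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DatasetStats:
    """Interaction-count summary of an :class:`InteractionMatrix`."""

    n_drugs: int
    n_targets: int
    n_interactions: int
    sparsity: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.n_drugs * self.n_targets
        if self.n_interactions > total:
            raise ValueError("more interactions than drug-target pairs")
        object.__setattr__(self, "sparsity", self.n_interactions / total)


def _read_table(path: str | Path, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{name} file not found: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise ValueError(f"malformed {name} file {path}: {exc}") from exc
    if frame.index.has_duplicates or frame.columns.has_duplicates:
        raise ValueError(f"duplicate identifiers in {name} file {path}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {name} file {path}: {exc}") from exc
    if np.isnan(values).any():
        raise ValueError(f"missing cell in {name} file {path}")
    frame = frame.astype(float)
    return frame


def read_interaction_matrix(
    path: str | Path, orientation: str = "drugs-as-rows"
) -> InteractionMatrix:
    """Read a tab-delimited binary adjacency table.

    Parameters
    ----------
    path:
        Tab-delimited file; first column holds row identifiers, header row
        holds column identifiers.
    orientation:
        ``"drugs-as-rows"`` (default) or ``"targets-as-rows"``; the latter
        transposes the file so the returned matrix is always drugs x targets.
    """
    if orientation not in ("drugs-as-rows", "targets-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = _read_table(path, "interaction")
    if orientation == "targets-as-rows":
        frame = frame.T
    return InteractionMatrix(
        values=frame.to_numpy(),
        drug_ids=tuple(frame.index),
        target_ids=tuple(frame.columns),
    )


def read_fingerprint_matrix(path: str | Path) -> FingerprintMatrix:
    """Read a tab-delimited binary bits x drugs table."""
    frame = _read_table(path, "fingerprint")
    return FingerprintMatrix(
        values=frame.to_numpy(),
        bit_ids=tuple(frame.index),
        drug_ids=tuple(frame.columns),
    )


def dataset_statistics(Y: InteractionMatrix) -> DatasetStats:
    """Counts and sparsity (known interactions over all possible pairs).

    Sparsity is returned unrounded; rounding to any table precision is the
    caller's concern.
    """
    return DatasetStats(
        n_drugs=Y.n_drugs,
        n_targets=Y.n_targets,
        n_interactions=int(Y.values.sum()),
    )


def _write_table(
    values: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
) -> None:
    values = np.asarray(values)
    if values.shape != (len(row_ids), len(col_ids)):
        raise ValueError(
            f"matrix shape {values.shape} does not match "
            f"{len(row_ids)} row / {len(col_ids)} column identifiers"
        )
    if not np.isfinite(values.astype(float)).all():
        raise ValueError("matrix contains non-finite values")
    frame = pd.DataFrame(values, index=list(row_ids), columns=list(col_ids))
    frame.to_csv(path, sep="\t")


def write_interaction_matrix(Y: InteractionMatrix, path: str | Path) -> None:
    _write_table(Y.values, Y.drug_ids, Y.target_ids, path)


def write_fingerprint_matrix(Z: FingerprintMatrix, path: str | Path) -> None:
    _write_table(Z.values, Z.bit_ids, Z.drug_ids, path)


def write_score_matrix(
    scores: np.ndarray,
    drug_ids: Sequence[str],
    target_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write a real-valued score matrix; read-back reproduces full precision."""
    _write_table(np.asarray(scores, dtype=float), drug_ids, target_ids, path)


def read_score_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    frame = _read_table(path, "score")
    return frame.to_numpy(dtype=float), tuple(frame.index), tuple(frame.columns)
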