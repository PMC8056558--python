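"""Densify the interaction matrix through fingerprints.

The sparse drug-target adjacency ``Y`` is lifted onto the fingerprint axis
by the product ``W = Z @ Y`` (bits x targets): entry (k, t) counts the drugs
that both carry bit k and hit target t.  The counts are min-max normalised
and then binarised (any strictly positive value becomes 1), producing a much
denser binary matrix that serves as the autoencoder's training input.

Normalisation uses a single global min/max over the whole matrix.  The
subsequent ``> 0`` binarisation is scale-invariant, so the scope of the
min-max makes no difference downstream; the normalised intermediate is kept
only for fidelity and inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_io import FingerprintMatrix, InteractionMatrix, _read_table, _write_table

__all__ = [
    "FingerprintTargetMatrix",
    "fingerprint_target_product",
    "minmax_normalize",
    "binarize",
    "preprocess",
    "read_binary_fingerprint_target_matrix",
    "write_fingerprint_target_matrix",
]

_STAGES = ("raw", "normalized", "binary")


@dataclass(frozen=True)
class FingerprintTargetMatrix:
    """Bits x targets matrix at one of three pipeline stages.

    raw        -- nonnegative integer co-occurrence counts (Z @ Y)
    normalized -- counts min-max scaled into [0, 1]
    binary     -- 1 wherever the raw count was positive
    """

    values: np.ndarray
    bit_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("fingerprint-target matrix must be 2-D")
        if self.stage == "raw":
            if (values < 0).any() or not np.equal(values, np.round(values)).all():
                raise ValueError("raw stage requires nonnegative integer counts")
        elif self.stage == "normalized":
            if (values < 0).any() or (values > 1).any():
                raise ValueError("normalized stage requires entries in [0, 1]")
        else:
            if not np.isin(values, (0.0, 1.0)).all():
                raise ValueError("binary stage requires entries in {0, 1}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "bit_ids", tuple(self.bit_ids))
        object.__setattr__(self, "target_ids", tuple(self.target_ids))

    @property
    def density(self) -> float:
        return float((self.values > 0).mean())


def fingerprint_target_product(
    Z: FingerprintMatrix, Y: InteractionMatrix
) -> FingerprintTargetMatrix:
    """Raw bits x targets co-occurrence counts, ``Z @ Y``.

    The drug axes of ``Z`` and ``Y`` must agree in both content and order.
    """
    if Z.drug_ids != Y.drug_ids:
        raise ValueError(
            "drug identifiers of fingerprint and interaction matrices "
            "do not match (count or order)"
        )
    counts = Z.values.astype(np.int64) @ Y.values.astype(np.int64)
    return FingerprintTargetMatrix(
        values=counts, bit_ids=Z.bit_ids, target_ids=Y.target_ids, stage="raw"
    )


def minmax_normalize(W: FingerprintTargetMatrix) -> FingerprintTargetMatrix:
    """Scale a raw count matrix into [0, 1] with one global min/max.

    The minimum of the scaling range is the natural floor of co-occurrence
    counts (zero), not the observed minimum: scaling a strictly positive
    count down to 0 would let the downstream "> 0 becomes 1" binarisation
    erase a known association.  An all-zero matrix maps to all zeros
    (avoids 0/0 on degenerate input).
    """
    if W.stage != "raw":
        raise ValueError(f"expected raw stage, got {W.stage!r}")
    hi = W.values.max()
    if hi == 0:
        scaled = np.zeros_like(W.values, dtype=float)
    else:
        scaled = W.values / hi
    return FingerprintTargetMatrix(
        values=scaled, bit_ids=W.bit_ids, target_ids=W.target_ids, stage="normalized"
    )


def binarize(W: FingerprintTargetMatrix) -> FingerprintTargetMatrix:
    """Replace every strictly positive entry by 1."""
    if W.stage not in ("normalized", "raw"):
        raise ValueError(f"expected normalized (or raw) stage, got {W.stage!r}")
    return FingerprintTargetMatrix(
        values=(W.values > 0).astype(np.int8),
        bit_ids=W.bit_ids,
        target_ids=W.target_ids,
        stage="binary",
    )


def preprocess(Z: FingerprintMatrix, Y: InteractionMatrix) -> FingerprintTargetMatrix:
    """product -> min-max normalise -> binarise, in that order."""
    return binarize(minmax_normalize(fingerprint_target_product(Z, Y)))


def write_fingerprint_target_matrix(W: FingerprintTargetMatrix, path) -> None:
    _write_table(W.values, W.bit_ids, W.target_ids, path)


def read_binary_fingerprint_target_matrix(path) -> FingerprintTargetMatrix:
    frame = _read_table(path, "fingerprint-target")
    return FingerprintTargetMatrix(
        values=frame.to_numpy(),
        bit_ids=tuple(frame.index),
        target_ids=tuple(frame.columns),
        stage="binary",
    )
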