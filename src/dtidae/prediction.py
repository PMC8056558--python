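"""Map reconstructed fingerprint-target profiles back to drug-target scores.

The reconstructed matrix ``W_hat`` lives on the fingerprint axis; projecting
through the fingerprint matrix, ``Y_hat = Z.T @ W_hat``, gives every drug a
score for every target: the dot product of the drug's fingerprint bits with
the target's reconstructed profile.  Scores are unnormalised dot products
(bounded by the drug's bit count); ranking metrics are unaffected, and an
optional per-drug division by bit count is available for display purposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autoencoder import TrainingConfig, reconstruct, train
from .matrix_io import FingerprintMatrix, InteractionMatrix
from .preprocessing import preprocess

__all__ = ["ScoreMatrix", "RankedPair", "predict_interactions", "rank_novel", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreMatrix:
    values: np.ndarray
    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("score matrix contains non-finite entries")
        if values.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError("score matrix shape inconsistent with identifiers")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(self, "target_ids", tuple(self.target_ids))


@dataclass(frozen=True)
class RankedPair:
    drug_id: str
    target_id: str
    score: float
    rank: int


def predict_interactions(Z: FingerprintMatrix, W_hat: np.ndarray) -> ScoreMatrix:
    """``Y_hat = Z.T @ W_hat`` (drugs x targets)."""
    W_hat = np.asarray(W_hat, dtype=float)
    if W_hat.ndim != 2 or W_hat.shape[0] != Z.n_bits:
        raise ValueError(
            f"reconstructed matrix has {W_hat.shape} but fingerprints have {Z.n_bits} bits"
        )
    target_ids = tuple(f"t{j}" for j in range(W_hat.shape[1]))
    return ScoreMatrix(
        values=Z.values.T.astype(float) @ W_hat,
        drug_ids=Z.drug_ids,
        target_ids=target_ids,
    )


def rank_novel(
    scores: ScoreMatrix, Y: InteractionMatrix, top_k: int
) -> list[RankedPair]:
    """Top-scoring pairs among those unknown in ``Y`` (descending score).

    Ties are broken by (drug_id, target_id) lexicographic order for
    determinism.  If fewer than ``top_k`` unknown pairs exist, all are
    returned.
    """
    if scores.drug_ids != Y.drug_ids:
        raise ValueError("drug identifiers of scores and interactions differ")
    if len(scores.target_ids) != len(Y.target_ids):
        raise ValueError("target axes of scores and interactions differ")
    if top_k < 0:
        raise ValueError("top_k must be nonnegative")
    di, ti = np.nonzero(Y.values == 0)
    pairs = sorted(
        zip(scores.values[di, ti], di, ti),
        key=lambda p: (-p[0], Y.drug_ids[p[1]], Y.target_ids[p[2]]),
    )
    return [
        RankedPair(
            drug_id=Y.drug_ids[d], target_id=Y.target_ids[t], score=float(s), rank=r + 1
        )
        for r, (s, d, t) in enumerate(pairs[:top_k])
    ]


def run_pipeline(
    Z: FingerprintMatrix, Y: InteractionMatrix, config: TrainingConfig
) -> ScoreMatrix:
    """preprocess -> train -> reconstruct -> project back to drug-target scores."""
    W = preprocess(Z, Y)
    if not W.values.any() and not config.zeros_are_observed:
        raise ValueError(
            "no observed interactions: the densified fingerprint-target matrix is all zero"
        )
    result = train(W, config)
    logger.info(
        "training finished: loss %.6f -> %.6f",
        result.epoch_losses[0],
        result.epoch_losses[-1],
    )
    W_hat = reconstruct(W, result.params)
    scores = predict_interactions(Z, W_hat)
    return ScoreMatrix(values=scores.values, drug_ids=Z.drug_ids, target_ids=Y.target_ids)
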