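"""Cross-validation under pairwise / drug-wise / target-wise hold-out.

Three scenarios: random drug-target pairs left out ("pairwise"), whole drug
interaction profiles left out ("drugwise", the new-drug cold start) and
whole target profiles left out ("targetwise").  The default protocol is
5 repeats of 10-fold CV; per fold the held-out information is zeroed in the
training matrix, the entire pipeline is re-run from scratch (densification
included, so held-out profiles cannot leak through the fingerprint product)
and the held-out entries are scored with AUC and AUPR.

Pairwise folding partitions ALL n*m pairs by default, so held-out zeros act
as test negatives; ``positives_only=True`` folds only the known interactions
and scores each fold's held-out positives against every pair that is zero in
the full matrix.

AUC is the Mann-Whitney probability that a random positive outranks a random
negative (ties count 1/2).  AUPR is the non-interpolated step summation
``sum (R_i - R_{i-1}) * P_i`` over descending score thresholds with tied
scores grouped, so a constant predictor scores exactly the positive
prevalence.  Both are implemented directly (not via a metrics library) so
the test suite can check them against brute-force oracles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .autoencoder import TrainingConfig
from .matrix_io import InteractionMatrix
from .prediction import run_pipeline
from .matrix_io import FingerprintMatrix
from .seeding import derive_seed

__all__ = [
    "SCENARIOS",
    "CVPlan",
    "EvalResult",
    "make_cv_plan",
    "mask_training_matrix",
    "held_out_pair_labels",
    "auc_score",
    "aupr_score",
    "run_cv",
]

logger = logging.getLogger(__name__)

SCENARIOS = ("pairwise", "drugwise", "targetwise")


@dataclass(frozen=True)
class CVPlan:
    """Fold assignments for every repeat.

    ``fold_assignment`` has shape (n_repeats, n_units); units are flattened
    pairs (drug * m + target), drugs, or targets depending on the scenario.
    With ``positives_only`` (pairwise only) the units are the positive pairs
    and ``unit_pairs`` maps unit index -> flattened pair index.
    """

    scenario: str
    n_folds: int
    n_repeats: int
    seed: int
    fold_assignment: np.ndarray
    n_drugs: int
    n_targets: int
    positives_only: bool = False
    unit_pairs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        fa = np.asarray(self.fold_assignment)
        if fa.shape[0] != self.n_repeats:
            raise ValueError("fold assignment repeat axis mismatch")
        for rep in range(self.n_repeats):
            counts = np.bincount(fa[rep], minlength=self.n_folds)
            if counts.max() - counts.min() > 1:
                raise ValueError("fold sizes differ by more than 1")


def make_cv_plan(
    Y: InteractionMatrix,
    scenario: str,
    n_folds: int = 10,
    n_repeats: int = 5,
    seed: int = 0,
    positives_only: bool = False,
) -> CVPlan:
    """Seeded balanced fold assignments for each repeat."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    n, m = Y.n_drugs, Y.n_targets
    unit_pairs = None
    if scenario == "pairwise":
        if positives_only:
            unit_pairs = np.flatnonzero(Y.values.ravel())
            n_units = unit_pairs.size
        else:
            n_units = n * m
    elif scenario == "drugwise":
        if positives_only:
            raise ValueError("positives_only applies to the pairwise scenario only")
        n_units = n
    else:
        if positives_only:
            raise ValueError("positives_only applies to the pairwise scenario only")
        n_units = m
    if n_units < n_folds:
        raise ValueError(f"{n_units} units cannot fill {n_folds} folds")

    assignment = np.empty((n_repeats, n_units), dtype=np.int64)
    for rep in range(n_repeats):
        rng = np.random.default_rng(derive_seed(seed, "cv-plan", scenario, rep))
        perm = rng.permutation(n_units)
        folds = np.empty(n_units, dtype=np.int64)
        folds[perm] = np.arange(n_units) % n_folds
        assignment[rep] = folds
    return CVPlan(
        scenario=scenario,
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
        fold_assignment=assignment,
        n_drugs=n,
        n_targets=m,
        positives_only=positives_only,
        unit_pairs=unit_pairs,
    )


def _held_out_units(plan: CVPlan, fold: int, repeat: int) -> np.ndarray:
    if not (0 <= fold < plan.n_folds and 0 <= repeat < plan.n_repeats):
        raise IndexError("fold or repeat index out of range")
    return np.flatnonzero(plan.fold_assignment[repeat] == fold)


def mask_training_matrix(
    Y: InteractionMatrix, plan: CVPlan, fold: int, repeat: int
) -> InteractionMatrix:
    """Copy of Y with the held-out information zeroed."""
    values = Y.values.copy()
    units = _held_out_units(plan, fold, repeat)
    if plan.scenario == "pairwise":
        pairs = plan.unit_pairs[units] if plan.positives_only else units
        flat = values.ravel()
        flat[pairs] = 0
    elif plan.scenario == "drugwise":
        values[units, :] = 0
    else:
        values[:, units] = 0
    return InteractionMatrix(values=values, drug_ids=Y.drug_ids, target_ids=Y.target_ids)


def held_out_pair_labels(
    Y: InteractionMatrix, plan: CVPlan, fold: int, repeat: int
) -> tuple[np.ndarray, np.ndarray]:
    """Flattened pair indices and labels scored for one fold."""
    units = _held_out_units(plan, fold, repeat)
    flat_Y = Y.values.ravel()
    if plan.scenario == "pairwise":
        if plan.positives_only:
            held_pos = plan.unit_pairs[units]
            negatives = np.flatnonzero(flat_Y == 0)
            pairs = np.concatenate([held_pos, negatives])
        else:
            pairs = units
    elif plan.scenario == "drugwise":
        m = plan.n_targets
        pairs = (units[:, None] * m + np.arange(m)[None, :]).ravel()
    else:
        m = plan.n_targets
        pairs = (np.arange(plan.n_drugs)[:, None] * m + units[None, :]).ravel()
    return pairs, flat_Y[pairs]


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 1/2."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-D of equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined with a single class")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aupr_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Non-interpolated area under the precision-recall curve.

    Thresholds sweep the distinct scores in descending order; tied scores
    enter together.  Area = sum over thresholds of (R_i - R_{i-1}) * P_i.
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-D of equal length")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPR is undefined without positives")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # indices where a threshold group (tied scores) ends
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.concatenate([distinct, [s_sorted.size - 1]])
    tp = np.cumsum(l_sorted)[ends]
    predicted = ends + 1.0
    precision = tp / predicted
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev_recall) * precision).sum())


@dataclass
class EvalResult:
    """Per-fold scores plus the aggregation used for reporting."""

    fold_scores: pd.DataFrame  # columns: repeat, fold, auc, aupr
    repeat_means: pd.DataFrame  # columns: repeat, auc, aupr

    @property
    def mean_auc(self) -> float:
        return float(self.repeat_means["auc"].mean())

    @property
    def mean_aupr(self) -> float:
        return float(self.repeat_means["aupr"].mean())

    @property
    def std_auc(self) -> float:
        return float(self.repeat_means["auc"].std(ddof=0))

    @property
    def std_aupr(self) -> float:
        return float(self.repeat_means["aupr"].std(ddof=0))

    def summary(self) -> dict[str, float]:
        return {
            "mean_auc": self.mean_auc,
            "std_auc": self.std_auc,
            "mean_aupr": self.mean_aupr,
            "std_aupr": self.std_aupr,
        }


def _assert_no_leakage(
    Y_train: InteractionMatrix, plan: CVPlan, fold: int, repeat: int
) -> None:
    units = _held_out_units(plan, fold, repeat)
    if plan.scenario == "drugwise":
        assert not Y_train.values[units, :].any(), "held-out drug rows leak into training"
    elif plan.scenario == "targetwise":
        assert not Y_train.values[:, units].any(), "held-out target columns leak into training"


def run_cv(
    Z: FingerprintMatrix,
    Y: InteractionMatrix,
    config: TrainingConfig,
    plan: CVPlan,
) -> EvalResult:
    """Train and score every (repeat, fold); fresh model and fold-derived seed
    each time.  Folds whose test set is single-class are recorded as missing
    and excluded from the means with a warning."""
    rows = []
    for repeat in range(plan.n_repeats):
        for fold in range(plan.n_folds):
            Y_train = mask_training_matrix(Y, plan, fold, repeat)
            _assert_no_leakage(Y_train, plan, fold, repeat)
            fold_config = replace(
                config, seed=derive_seed(config.seed, "cv-fold", repeat, fold)
            )
            scores = run_pipeline(Z, Y_train, fold_config)
            pairs, labels = held_out_pair_labels(Y, plan, fold, repeat)
            pred = scores.values.ravel()[pairs]
            if labels.min() == labels.max():
                warnings.warn(
                    f"repeat {repeat} fold {fold}: single-class test set, fold skipped",
                    stacklevel=2,
                )
                auc = aupr = float("nan")
            else:
                auc = auc_score(labels, pred)
                aupr = aupr_score(labels, pred)
            logger.info(
                "repeat %d fold %d: auc=%.4f aupr=%.4f", repeat, fold, auc, aupr
            )
            rows.append({"repeat": repeat, "fold": fold, "auc": auc, "aupr": aupr})
    fold_scores = pd.DataFrame(rows)
    repeat_means = (
        fold_scores.groupby("repeat")[["auc", "aupr"]].mean().reset_index()
    )
    return EvalResult(fold_scores=fold_scores, repeat_means=repeat_means)
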