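"""Naive-Bayes-style classification of ligand specificity from positional scores.

The procedure is a modification of the PASS (Prediction of Activity
Spectra for Substances) algorithm.  Each training sequence k carries
binary weights for a ligand class C: a_k = 1 if it is a class member,
b_k = 1 - a_k if it belongs to the complement.  Given the stack of
positional scores S_pk of a query against n training sequences:

* integrated positional score
      t_p = sum_k S_pk (a_k - b_k) / sum_k S_pk (a_k + b_k),
  the evidence balance at position p, in [-1, 1]; a position with no
  evidence at all (all S_pk = 0) is indefinite and scores t_p = 0;

* arcsine average over the m query positions
      t = sin( (1/m) sum_p arcsin(t_p) ),
  a variance-stabilising mean on [-1, 1];

* a priori score
      t0 = sum_k (a_k - b_k) / sum_k (a_k + b_k),
  the dataset-level class/complement imbalance;

* classification statistic
      B(C) = (t - t0) / (1 - t * t0),
  ranging from -1 (complement) to +1 (class member), with values near 0
  indefinite.  When t and t0 sit at the same pole (t * t0 = 1) the
  statistic is taken as 0: the query is exactly as extreme as the prior,
  so there is no signal either way.

Weights are binary in this version; real-valued weights are accepted by
the low-level functions but validated to be binary by `predict`.
Substitution-matrix similarity can produce negative S_pk, which would push
t_p outside [-1, 1]; scores are clamped at 0 (and the clamping logged)
before entering the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .scoring import FragmentConfig, ScoreStack, score_stack
from .seqio import InteractionTable, SequenceRecord

logger = logging.getLogger("posim")

#: relative tolerance for detecting t * t0 at the pole in classify()
POLE_EPS = 1e-12

__all__ = [
    "PredictionResult",
    "integrated_position_score",
    "arcsine_average",
    "prior_score",
    "classify",
    "predict",
    "predict_from_stack",
]


@dataclass(frozen=True)
class PredictionResult:
    """Classification of one query against one ligand class."""

    query_id: str
    class_id: str
    t_p: np.ndarray
    t: float
    t0: float
    B: float
    n_class: int
    n_complement: int


def _check_weights(a: np.ndarray, b: np.ndarray, n: int) -> None:
    if len(a) != n or len(b) != n:
        raise ValueError(
            f"weight length mismatch: {len(a)} class / {len(b)} complement "
            f"weights for {n} scores"
        )
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("class weights must be binary (0 or 1)")
    if not np.array_equal(a + b, np.ones(n)):
        raise ValueError("weights must satisfy a_k + b_k = 1 for every k")


def integrated_position_score(
    S_row: Sequence[float], a: Sequence[int], b: Sequence[int]
) -> float:
    """Integrated score t_p for one query position.

    ``S_row`` holds the n positional scores of this position against the
    training sequences; ``a``/``b`` are the binary class/complement
    weights.  All-zero evidence gives the indefinite value 0.
    """
    S_row = np.asarray(S_row, dtype=float)
    a = np.asarray(a)
    b = np.asarray(b)
    _check_weights(a, b, len(S_row))
    denom = float(S_row @ (a + b))
    if denom == 0.0:
        return 0.0
    return float(S_row @ (a - b)) / denom


def arcsine_average(t_vector: Sequence[float]) -> float:
    """Variance-stabilised mean of per-position scores: sin(mean(arcsin(t_p)))."""
    t_vector = np.asarray(t_vector, dtype=float)
    if t_vector.size == 0:
        raise ValueError("cannot average an empty score vector")
    if (np.abs(t_vector) > 1).any():
        raise ValueError("positional scores must lie in [-1, 1]")
    return float(np.sin(np.mean(np.arcsin(t_vector))))


def prior_score(a: Sequence[int], b: Sequence[int]) -> float:
    """A priori score t0 = (|class| - |complement|) / n."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) == 0:
        raise ValueError("prior score undefined for an empty training set")
    _check_weights(a, b, len(a))
    return float(np.sum(a) - np.sum(b)) / float(len(a))


def classify(t: float, t0: float) -> float:
    """Classification statistic B = (t - t0) / (1 - t*t0), clamped to [-1, 1].

    At the pole t*t0 = 1 (query exactly as extreme as the prior, same
    side) the result is defined as 0.
    """
    if not (-1 <= t <= 1 and -1 <= t0 <= 1):
        raise ValueError(f"t and t0 must lie in [-1, 1], got t={t}, t0={t0}")
    denom = 1.0 - t * t0
    if abs(denom) < POLE_EPS:
        return 0.0
    return float(np.clip((t - t0) / denom, -1.0, 1.0))


def _clamped(S: np.ndarray, query_id: str) -> np.ndarray:
    if (S < 0).any():
        logger.warning(
            "query %r: %d negative positional score(s) clamped to 0 before "
            "classification",
            query_id,
            int((S < 0).sum()),
        )
        return np.maximum(S, 0.0)
    return S


def predict_from_stack(
    stack: ScoreStack,
    table: InteractionTable,
    classes: Sequence[str] | None = None,
) -> list[PredictionResult]:
    """Classify a precomputed score stack against each requested ligand class.

    The stack's training order must match the table's protein order.  A
    class with no member or no complement protein among the training
    sequences is skipped with a warning -- both sides are needed to form
    the evidence balance.
    """
    if list(stack.training_ids) != list(table.protein_ids):
        raise ValueError(
            "score stack training order does not match interaction table"
        )
    if classes is None:
        classes = table.ligand_ids
    S = _clamped(stack.S, stack.query_id)
    results: list[PredictionResult] = []
    for class_id in classes:
        a = table.class_weights(class_id)
        b = 1 - a
        n_class = int(a.sum())
        n_complement = int(b.sum())
        if n_class == 0 or n_complement == 0:
            logger.warning(
                "query %r: class %r skipped (%d member(s), %d complement) -- "
                "both sides required",
                stack.query_id,
                class_id,
                n_class,
                n_complement,
            )
            continue
        diff = S @ (a - b).astype(float)
        total = S @ (a + b).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_p = np.where(total > 0, diff / np.where(total > 0, total, 1.0), 0.0)
        t_p = np.clip(t_p, -1.0, 1.0)  # guard rounding overshoot at +/-1
        t = arcsine_average(t_p)
        t0 = prior_score(a, b)
        results.append(
            PredictionResult(
                stack.query_id,
                class_id,
                t_p,
                t,
                t0,
                classify(t, t0),
                n_class,
                n_complement,
            )
        )
    return results


def predict(
    Q: SequenceRecord,
    training: list[SequenceRecord],
    table: InteractionTable,
    cfg: FragmentConfig,
    classes: Sequence[str] | None = None,
) -> list[PredictionResult]:
    """Score Q against the training set once, then classify every ligand class.

    Q must not itself be among the training sequences (remove it first for
    cross-validation).
    """
    ids = [r.id for r in training]
    if Q.id in ids:
        raise ValueError(
            f"query {Q.id!r} appears in the training set; remove it first"
        )
    if ids != list(table.protein_ids):
        raise ValueError("training sequence order does not match interaction table")
    stack = score_stack(Q, training, cfg)
    return predict_from_stack(stack, table, classes)
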