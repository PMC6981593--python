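"""Leave-one-out cross-validation and pooled ROC analysis.

Each protein in turn is removed from the dataset entirely -- its sequence
leaves the training set and its row leaves the interaction table for all
classes at once -- and the classifier predicts B(C) for every ligand class
that is still valid (non-empty class and complement after the removal).
Each prediction is paired with the held-out protein's true membership
label, and all (protein, class) pairs from all classes are pooled into a
single ROC curve; per-class curves are available as supplementary output.

A class invalidated in a fold contributes no pair for that fold rather
than a default score, so degenerate folds cannot distort the pooled ROC.

The AUC is the tie-aware Mann-Whitney estimate (ties count 1/2), computed
from midranks, so the result does not depend on sort stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifier import predict_from_stack
from .scoring import FragmentConfig, score_stack
from .seqio import InteractionTable, SequenceRecord, check_ids

logger = logging.getLogger("posim")

__all__ = ["LabeledScore", "RocResult", "loocv", "roc_auc", "per_class_auc"]


@dataclass(frozen=True)
class LabeledScore:
    """One pooled ROC observation: a B statistic with its true label."""

    query_id: str
    ligand_id: str
    B: float
    label: int


@dataclass(frozen=True)
class RocResult:
    """Tie-aware ROC curve and its area."""

    auc: float
    n_pos: int
    n_neg: int
    curve: np.ndarray  # (n_points, 2) array of (FPR, TPR), (0,0) .. (1,1)


def loocv(
    sequences: Sequence[SequenceRecord],
    table: InteractionTable,
    cfg: FragmentConfig,
) -> list[LabeledScore]:
    """Leave-one-out predictions for every (protein, class) pair.

    Results are ordered by protein (table order) then class (table order);
    the whole procedure is deterministic.
    """
    check_ids(sequences, table)
    by_id = {r.id: r for r in sequences}
    ordered = [by_id[p] for p in table.protein_ids]
    if len(ordered) < 2:
        raise ValueError("LOOCV requires at least two proteins")
    scores: list[LabeledScore] = []
    for held_out in table.protein_ids:
        Q = by_id[held_out]
        training = [r for r in ordered if r.id != held_out]
        fold_table = table.drop_protein(held_out)
        stack = score_stack(Q, training, cfg)
        for res in predict_from_stack(stack, fold_table):
            scores.append(
                LabeledScore(
                    held_out,
                    res.class_id,
                    res.B,
                    table.membership(held_out, res.class_id),
                )
            )
    if not scores:
        logger.warning(
            "LOOCV produced no labelled scores: every fold left some class "
            "without members or without complement"
        )
    return scores


def roc_auc(scores: Sequence[LabeledScore]) -> RocResult:
    """Pooled ROC over labelled scores; AUC via the Mann-Whitney estimator.

    AUC = U / (n_pos * n_neg) with tied scores counting 1/2, computed from
    midranks.  The curve is the tie-aware step function: one point per
    distinct threshold, so tied scores produce a diagonal segment.
    """
    if not scores:
        raise ValueError("no labelled scores to analyse")
    B = np.array([s.B for s in scores], dtype=float)
    y = np.array([s.label for s in scores], dtype=int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"AUC undefined: need both labels, got {n_pos} positive and "
            f"{n_neg} negative"
        )
    ranks = rankdata(B)  # midranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    auc = float(u / (n_pos * n_neg))

    # Tie-aware step curve: sweep distinct thresholds from high to low.
    order = np.argsort(-B, kind="stable")
    B_sorted = B[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    last_of_threshold = np.nonzero(np.diff(B_sorted, append=-np.inf))[0]
    curve = np.concatenate(
        [
            [[0.0, 0.0]],
            np.column_stack(
                [fp[last_of_threshold] / n_neg, tp[last_of_threshold] / n_pos]
            ),
        ]
    )
    return RocResult(auc, n_pos, n_neg, curve)


def per_class_auc(scores: Sequence[LabeledScore]) -> dict[str, RocResult]:
    """Supplementary per-class ROC; classes with one-sided labels are skipped."""
    out: dict[str, RocResult] = {}
    df = pd.DataFrame(
        [(s.ligand_id, s.B, s.label) for s in scores],
        columns=["ligand_id", "B", "label"],
    )
    for ligand_id, grp in df.groupby("ligand_id", sort=False):
        subset = [
            LabeledScore("", str(ligand_id), b, int(l))
            for b, l in zip(grp["B"], grp["label"])
        ]
        try:
            out[str(ligand_id)] = roc_auc(subset)
        except ValueError:
            logger.warning(
                "class %r has one-sided labels; per-class AUC skipped", ligand_id
            )
    return out
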