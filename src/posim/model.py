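"""Model/Results front end for ligand-specificity classification.

`LigandSpecificityModel` bundles a labelled training set (sequences plus a
binary protein x ligand interaction table) with the fragment-comparison
settings.  `fit()` validates and filters the data and returns a
`LigandSpecificityResults` object carrying the per-class a priori scores;
prediction for new queries, leave-one-out cross-validation and a summary
table hang off the results object.

The classifier is memory-based: fitting stores the training material and
the class priors rather than estimating free parameters, so `fit()` is
cheap and deterministic, and all pairwise scoring happens at prediction
time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classifier as _classifier
from . import evaluation as _evaluation
from .scoring import FragmentConfig, score_stack
from .seqio import (
    InteractionTable,
    SequenceRecord,
    check_ids,
    load_similarity,
    read_fasta,
    read_interactions,
)

__all__ = ["LigandSpecificityModel", "LigandSpecificityResults", "CrossValidationResult"]


class LigandSpecificityModel:
    """Positional-similarity classifier of protein ligand specificity.

    Parameters
    ----------
    sequences : sequence of SequenceRecord
        Training proteins; must cover every id in ``interactions``.
    interactions : InteractionTable
        Binary protein x ligand-class membership.
    fragment_length : int, default 30
        Window size F for fragment comparison.
    similarity : str, default "identity"
        ``"identity"`` or a path to an NCBI-format substitution matrix.
    min_class_size : int, default 5
        Ligand classes with fewer members are dropped at fit time.
    """

    def __init__(
        self,
        sequences: Sequence[SequenceRecord],
        interactions: InteractionTable,
        fragment_length: int = 30,
        similarity: str = "identity",
        min_class_size: int = 5,
    ) -> None:
        check_ids(sequences, interactions)
        self.sequences = list(sequences)
        self.interactions = interactions
        self.config = FragmentConfig(fragment_length, load_similarity(similarity))
        self.min_class_size = min_class_size

    @classmethod
    def from_files(
        cls,
        fasta_path: str | Path,
        interactions_path: str | Path,
        dialect: str = "wide",
        fragment_length: int = 30,
        similarity: str = "identity",
        min_class_size: int = 5,
    ) -> "LigandSpecificityModel":
        """Build a model from a FASTA file and an interaction TSV."""
        sequences = read_fasta(fasta_path)
        table = read_interactions(interactions_path, dialect, min_class_size)
        return cls(sequences, table, fragment_length, similarity, min_class_size)

    def fit(self) -> "LigandSpecificityResults":
        """Validate and filter the training data; return a results object."""
        table = self.interactions.filtered(self.min_class_size)
        by_id = {r.id: r for r in self.sequences}
        ordered = [by_id[p] for p in table.protein_ids]
        return LigandSpecificityResults(self, ordered, table)


@dataclass(frozen=True)
class CrossValidationResult:
    """Pooled LOOCV diagnostics."""

    scores: list[_evaluation.LabeledScore]
    pooled: _evaluation.RocResult
    per_class: dict[str, _evaluation.RocResult]

    @property
    def auc(self) -> float:
        return self.pooled.auc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.query_id, s.ligand_id, s.B, s.label) for s in self.scores],
            columns=["query_id", "ligand_id", "B", "label"],
        )


class LigandSpecificityResults:
    """Fitted classifier: class priors plus prediction and validation methods."""

    def __init__(
        self,
        model: LigandSpecificityModel,
        training: list[SequenceRecord],
        table: InteractionTable,
    ) -> None:
        self.model = model
        self.training = training
        self.table = table
        n = table.n_proteins
        sizes = table.member.sum(axis=0)
        #: per-class a priori score t0 = (|class| - |complement|) / n
        self.prior_scores = pd.Series(
            (2 * sizes - n) / n, index=table.ligand_ids, name="t0"
        )
        self.class_sizes = pd.Series(sizes, index=table.ligand_ids, name="n_members")

    def predict(
        self, query: SequenceRecord, classes: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """B(C) for one query against every (or the requested) ligand class.

        If the query id is present in the training set, that protein is
        held out of the training material for this call.
        """
        training = [r for r in self.training if r.id != query.id]
        if len(training) < len(self.training):
            table = self.table.drop_protein(query.id)
        else:
            table = self.table
        stack = score_stack(query, training, self.model.config)
        results = _classifier.predict_from_stack(stack, table, classes)
        return pd.DataFrame(
            [
                (r.query_id, r.class_id, r.t, r.t0, r.B, r.n_class, r.n_complement)
                for r in results
            ],
            columns=["query_id", "ligand_id", "t", "t0", "B", "n_class", "n_complement"],
        )

    def loocv(self) -> CrossValidationResult:
        """Leave-one-out cross-validation with pooled and per-class ROC."""
        scores = _evaluation.loocv(self.training, self.table, self.model.config)
        pooled = _evaluation.roc_auc(scores)
        per_class = _evaluation.per_class_auc(scores)
        return CrossValidationResult(scores, pooled, per_class)

    def summary(self, cv: CrossValidationResult | None = None) -> str:
        """Human-readable account of the fitted classifier.

        Pass a `CrossValidationResult` to include per-class and pooled AUC.
        """
        cfg = self.model.config
        lines = [
            "Ligand specificity classifier (positional similarity scores)",
            "=" * 62,
            f"Proteins:            {self.table.n_proteins}",
            f"Ligand classes:      {self.table.n_ligands}"
            + (
                f"  ({len(self.table.dropped_ligands)} dropped: "
                f"< {self.model.min_class_size} members)"
                if self.table.dropped_ligands
                else ""
            ),
            f"Fragment length F:   {cfg.fragment_length}",
            f"Similarity measure:  {cfg.similarity.name}",
            "",
        ]
        body = pd.DataFrame(
            {
                "n_members": self.class_sizes,
                "n_complement": self.table.n_proteins - self.class_sizes,
                "t0": self.prior_scores.round(4),
            }
        )
        if cv is not None:
            body["AUC"] = pd.Series(
                {c: r.auc for c, r in cv.per_class.items()}
            ).round(4)
        lines.append(body.to_string())
        if cv is not None:
            lines += [
                "",
                f"Pooled LOOCV AUC:    {cv.auc:.4f} "
                f"({cv.pooled.n_pos} positive / {cv.pooled.n_neg} negative pairs)",
            ]
        return "\n".join(lines)
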