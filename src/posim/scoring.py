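"""Positional similarity scores by exhaustive ungapped fragment comparison.

A query sequence Q is compared with a training sequence K by sliding
length-F windows over both sequences at every relative shift h.  Each
admissible window pair (i, h) -- fully inside both sequences -- gets a
rate

    R_ih = sum_{j=i}^{i+F-1} sim(q_j, k_{j+h}),

the summed residue similarity of the two fragments.  Every query position
p then receives the score

    S_p = max { R_ih : i <= p <= i+F-1, (i, h) admissible },

i.e. the best rate among all windows covering p, over all shifts.  Under
the identity measure S_p is an integer in [0, F]; positions covered by no
admissible window (in particular whenever len(Q) < F or len(K) < F) score
0 -- short sequences provide no fragment evidence rather than evidence at
a reduced scale.

There is no gapping, no seeding and no padding: windows never hang over
either sequence end.  The production algorithm computes per-shift match
vectors with running window sums and a sliding-window maximum per
position, O(len(Q) * len(K)) per pair; its contract is exact agreement
with the brute-force triple loop over (i, h, j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import ResidueSimilarity, SequenceRecord, load_similarity

__all__ = [
    "FragmentConfig",
    "PositionalScores",
    "ScoreStack",
    "window_rate",
    "positional_scores",
    "score_stack",
]


@dataclass(frozen=True)
class FragmentConfig:
    """Fragment-comparison settings.

    Parameters
    ----------
    fragment_length : int
        Window size F in residues.  F = 7 picks up residue-level signal;
        F = 30 captures more distant inter-positional dependencies and is
        the default.
    similarity : ResidueSimilarity
        Residue-pair measure; identity by default.
    """

    fragment_length: int = 30
    similarity: ResidueSimilarity = field(default_factory=load_similarity)

    def __post_init__(self) -> None:
        if self.fragment_length < 1:
            raise ValueError(
                f"fragment_length must be >= 1, got {self.fragment_length}"
            )


@dataclass(frozen=True)
class PositionalScores:
    """Per-position scores S_p of one query against one training sequence."""

    query_id: str
    training_id: str
    S: np.ndarray

    def __len__(self) -> int:
        return len(self.S)


@dataclass(frozen=True)
class ScoreStack:
    """Score matrix of one query against n training sequences.

    ``S[p, k]`` is the positional score of query position p (0-based row
    index; position p+1 in 1-based contract coordinates) against the k-th
    training sequence, columns ordered as ``training_ids``.
    """

    query_id: str
    training_ids: tuple[str, ...]
    S: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.S.shape[0]

    @property
    def n_training(self) -> int:
        return self.S.shape[1]


def _check_window(lq: int, lk: int, i: int, h: int, F: int) -> None:
    # i is 1-based; the window covers query [i, i+F-1], training [i+h, i+h+F-1]
    if not (1 <= i and i + F - 1 <= lq and 1 <= i + h and i + h + F - 1 <= lk):
        raise ValueError(
            f"inadmissible window: i={i}, h={h}, F={F} does not fit inside "
            f"query length {lq} and training length {lk}"
        )


def window_rate(
    Q: SequenceRecord,
    K: SequenceRecord,
    i: int,
    h: int,
    cfg: FragmentConfig,
) -> float:
    """Rate R_ih of one fragment pair (1-based window start i, shift h).

    The window must lie fully inside both sequences; a window that hangs
    over either end is a contract violation, not a zero.
    """
    F = cfg.fragment_length
    _check_window(len(Q), len(K), i, h, F)
    sim = cfg.similarity
    return float(
        sum(
            sim(Q.residues[j - 1], K.residues[j + h - 1])
            for j in range(i, i + F)
        )
    )


def positional_scores(
    Q: SequenceRecord, K: SequenceRecord, cfg: FragmentConfig
) -> PositionalScores:
    """All positional scores S_p of query Q against training sequence K."""
    F = cfg.fragment_length
    lq, lk = len(Q), len(K)
    if lq < F or lk < F:
        return PositionalScores(Q.id, K.id, np.zeros(lq))

    M = cfg.similarity.pair_matrix(Q.residues, K.residues)

    # Skew the pair matrix so each diagonal (constant shift h = col - row)
    # becomes a column; windowed sums along columns give every R_ih at once.
    ndiag = lq + lk - 1
    rows = np.arange(lq)[:, None]
    cols = np.arange(lk)[None, :]
    skew = np.zeros((lq + 1, ndiag))
    skew[1:][rows, cols - rows + lq - 1] = M

    cum = np.cumsum(skew, axis=0)
    # R[i, d]: rate of the window with 0-based query start i on diagonal d
    R = cum[F:] - cum[:-F]  # shape (lq - F + 1, ndiag)

    # Mask windows that hang over a sequence end.  On diagonal h the
    # training-side window is [i+h, i+h+F-1], so i must satisfy
    # max(0, -h) <= i <= min(lq-F, lk-F-h).
    starts = np.arange(lq - F + 1)[:, None]
    h = np.arange(ndiag)[None, :] - (lq - 1)
    valid = (starts >= -h) & (starts <= lk - F - h)
    R = np.where(valid, R, -np.inf)

    row_best = R.max(axis=1)  # best rate over all shifts, per window start

    # S_p = max of row_best over window starts i in [p-F+1, p] (0-based).
    pad = np.full(F - 1, -np.inf)
    padded = np.concatenate([pad, row_best, pad])
    S = np.lib.stride_tricks.sliding_window_view(padded, F).max(axis=1)
    S[np.isneginf(S)] = 0.0
    return PositionalScores(Q.id, K.id, S)


def score_stack(
    Q: SequenceRecord,
    training: list[SequenceRecord],
    cfg: FragmentConfig,
) -> ScoreStack:
    """Positional scores of Q against every training sequence, one column each."""
    if not training:
        raise ValueError("training list is empty")
    columns = [positional_scores(Q, K, cfg).S for K in training]
    return ScoreStack(
        Q.id, tuple(K.id for K in training), np.column_stack(columns)
    )
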