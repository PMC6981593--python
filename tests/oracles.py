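"""Independent reference implementations used only as test oracles.

These stay deliberately naive -- direct transcriptions of the defining
formulas -- so they remain independent of the optimised production code
paths they verify.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_scores(q: str, k: str, F: int) -> np.ndarray:
    """Positional scores by the defining triple loop, identity similarity.

    For every admissible window pair (i, h) -- both length-F fragments
    fully inside their sequences -- compute the summed identity rate and
    propagate it as a candidate maximum to every query position the
    window covers.
    """
    lq, lk = len(q), len(k)
    S = np.zeros(lq)
    for i in range(lq - F + 1):  # 0-based query window start
        for h in range(-i, lk - F - i + 1):  # shift keeping K-window in bounds
            rate = sum(1 for d in range(F) if q[i + d] == k[i + h + d])
            for p in range(i, i + F):
                if rate > S[p]:
                    S[p] = rate
    return S


def rank_auc(scores: list[float], labels: list[int]) -> float:
    """AUC as the exact probability of concordance, ties counting 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def chain_prediction(S: np.ndarray, member: list[int]) -> tuple[float, float, float]:
    """Eqs for t, t0, B transcribed position by position from the stack."""
    a = member
    b = [1 - x for x in a]
    t_ps = []
    for row in S:
        denom = sum(s * (ak + bk) for s, ak, bk in zip(row, a, b))
        num = sum(s * (ak - bk) for s, ak, bk in zip(row, a, b))
        t_ps.append(num / denom if denom else 0.0)
    t = math.sin(sum(math.asin(tp) for tp in t_ps) / len(t_ps))
    t0 = (sum(a) - sum(b)) / len(a)
    B = (t - t0) / (1 - t * t0) if abs(1 - t * t0) > 1e-12 else 0.0
    return t, t0, B
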