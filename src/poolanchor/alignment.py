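"""Smith-Waterman local alignment with a deterministic traceback.

Default scoring is match +1, mismatch -1, gap -2 (linear gap cost).  The
identity of an alignment is matches / alignment columns, and its span is the
number of alignment columns.  Tie-breaks are fixed so the reported alignment
is reproducible: the best-scoring end cell is the first one in row-major
order, and the traceback prefers diagonal over up (gap in the second
sequence) over left (gap in the first sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_VALID = set("ACGTN")


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    identity: float  # matches / columns, in [0, 1]
    span: int  # alignment columns
    matches: int
    query_start: int  # 0-based, half-open on the query
    query_end: int
    target_start: int
    target_end: int


def _check(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{label} contains non-ACGTN characters: {sorted(bad)}")
    return seq


def sw_matrix(query: str, target: str, match: float = 1.0, mismatch: float = -1.0,
              gap: float = -2.0) -> np.ndarray:
    """Score matrix H of shape (len(query)+1, len(target)+1).

    Rows are filled with the horizontal-gap recurrence rewritten as a
    running maximum, so each row is a vectorised numpy pass.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    m, n = len(q), len(t)
    H = np.zeros((m + 1, n + 1))
    g = -gap  # positive gap cost
    j_idx = np.arange(1, n + 1, dtype=float)
    for i in range(1, m + 1):
        sub = np.where(t == q[i - 1], match, mismatch)
        best_vert = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap)
        v = np.maximum(0.0, best_vert)
        # H[i, j] = max_{k<=j} v[k] - g*(j-k): a cumulative maximum
        H[i, 1:] = np.maximum.accumulate(v + g * j_idx) - g * j_idx
    return H


def smith_waterman(query: str, target: str, match: float = 1.0,
                   mismatch: float = -1.0, gap: float = -2.0) -> LocalAlignment:
    """Best-scoring local alignment of ``query`` against ``target``."""
    query = _check(query, "query")
    target = _check(target, "target")
    H = sw_matrix(query, target, match, mismatch, gap)
    flat = int(np.argmax(H))  # first maximum in row-major order
    i, j = divmod(flat, H.shape[1])
    score = float(H[i, j])
    if score <= 0:
        return LocalAlignment(0.0, 0.0, 0, 0, 0, 0, 0, 0)
    qe, te = i, j
    matches = 0
    span = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if query[i - 1] == target[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += int(query[i - 1] == target[j - 1])
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        elif H[i, j] == H[i, j - 1] + gap:
            j -= 1
        else:  # cell restarted at 0
            break
        span += 1
    return LocalAlignment(
        score=score,
        identity=matches / span if span else 0.0,
        span=span,
        matches=matches,
        query_start=i,
        query_end=qe,
        target_start=j,
        target_end=te,
    )
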