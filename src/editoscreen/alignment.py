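"""Exact local alignment (Smith–Waterman, affine gaps) for flanking windows.

The conservation screen aligns 81-nt windows; the search is an exact optimal
local alignment under a dc-megablast-like scheme (match +2, mismatch −3,
gap open −5, gap extend −2).  The first base of a gap scores ``gap_open``
and each further base ``gap_extend``.

Determinism convention (kept identical in the independent test oracle):

* the alignment ends at the highest-scoring match-state cell; ties go to
  the smallest (i, j) in row-major order;
* at each traceback step ties prefer diagonal, then up (gap in subject),
  then left (gap in query); within a gap state, closing the gap (coming
  from the match state) is preferred over extending it;
* the traceback stops when the predecessor score is 0.

N is treated as a mismatch against everything, including N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["ScoringScheme", "LocalAlignment", "smith_waterman", "encode_seq"]

_NEG = -(10**9)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution/gap scores; defaults mirror dc-megablast rewards."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


def encode_seq(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3, anything else (incl. N) as 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _fill(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = q.shape[0], s.shape[0]
    M = np.zeros((n + 1, m + 1), np.int64)
    Ix = np.full((n + 1, m + 1), _NEG, np.int64)  # gap in subject ("up")
    Iy = np.full((n + 1, m + 1), _NEG, np.int64)  # gap in query ("left")
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            qa = q[i - 1]
            sb = s[j - 1]
            sub = match if (qa == sb and qa != 4) else mismatch
            prev = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
            v = prev + sub
            if v < 0:
                v = 0
            M[i, j] = v
            a = M[i - 1, j] + gap_open
            b = Ix[i - 1, j] + gap_extend
            Ix[i, j] = a if a >= b else b
            a = M[i, j - 1] + gap_open
            b = Iy[i, j - 1] + gap_extend
            Iy[i, j] = a if a >= b else b
    return M, Ix, Iy


@dataclass
class LocalAlignment:
    """Traceback of one optimal local alignment.

    ``columns`` lists (qi, sj) pairs with 0-based sequence indices; a gap is
    ``None`` on the gapped side.  ``pairs`` maps query index -> subject index
    over the diagonal (substitution) columns only.
    """

    score: int
    query_start: int
    query_end: int  # half-open
    subject_start: int
    subject_end: int
    columns: list
    identical: int
    aligned_length: int
    gaps: int

    @property
    def pairs(self) -> dict[int, int]:
        return {qi: sj for qi, sj in self.columns
                if qi is not None and sj is not None}


def smith_waterman(
    q: str | np.ndarray, s: str | np.ndarray,
    scoring: ScoringScheme = ScoringScheme(),
) -> LocalAlignment:
    """Optimal local alignment of ``q`` against ``s`` with affine gaps."""
    qa = encode_seq(q) if isinstance(q, str) else q
    sa = encode_seq(s) if isinstance(s, str) else s
    if qa.shape[0] == 0 or sa.shape[0] == 0:
        raise ValueError("cannot align an empty sequence")
    M, Ix, Iy = _fill(
        qa, sa, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend,
    )
    flat = int(np.argmax(M))
    i, j = divmod(flat, M.shape[1])
    score = int(M[i, j])
    if score == 0:
        return LocalAlignment(0, 0, 0, 0, 0, [], 0, 0, 0)

    columns: list[tuple[int | None, int | None]] = []
    identical = 0
    state = "M"
    end_i, end_j = i, j
    while True:
        if state == "M":
            qa_i = qa[i - 1]
            sa_j = sa[j - 1]
            sub = (scoring.match if (qa_i == sa_j and qa_i != 4)
                   else scoring.mismatch)
            columns.append((i - 1, j - 1))
            if qa_i == sa_j and qa_i != 4:
                identical += 1
            prev = M[i, j] - sub
            i -= 1
            j -= 1
            if prev == 0:
                break
            if M[i, j] == prev:
                state = "M"
            elif Ix[i, j] == prev:
                state = "Ix"
            elif Iy[i, j] == prev:
                state = "Iy"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("broken traceback in match state")
        elif state == "Ix":  # consumes query base, gap in subject
            columns.append((i - 1, None))
            if M[i - 1, j] + scoring.gap_open == Ix[i, j]:
                state = "M"
            else:
                state = "Ix"
            i -= 1
        else:  # Iy: consumes subject base, gap in query
            columns.append((None, j - 1))
            if M[i, j - 1] + scoring.gap_open == Iy[i, j]:
                state = "M"
            else:
                state = "Iy"
            j -= 1
    columns.reverse()
    gaps = sum(1 for qi, sj in columns if qi is None or sj is None)
    return LocalAlignment(
        score=score,
        query_start=i,
        query_end=end_i,
        subject_start=j,
        subject_end=end_j,
        columns=columns,
        identical=identical,
        aligned_length=len(columns),
        gaps=gaps,
    )
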