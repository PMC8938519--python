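"""Exact affine-gap local alignment for reverse-complement match discovery.

The finder aligns an upstream intron against the reverse complement of the
downstream intron, so a high-scoring local alignment corresponds to a pair of
intronic segments able to base-pair (an RCM).  At the intron sizes this
package handles (a few kb) an exact, vectorised Smith-Waterman is fast enough
to be used directly, which guarantees the reported top RCM is the optimal
local alignment rather than a heuristic approximation; secondary,
non-overlapping RCMs are produced Waterman-Eggert style by masking the bases
used by previous alignments and re-running the DP.

Scoring is megablast-like by default: match +1, mismatch -3, gap open -5 and
gap extend -2, where a gap of length g costs ``open + (g-1) * extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_NEG = -(2**40)
_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_MASK_CODE = 5  # bases consumed by a previous alignment


@dataclass(frozen=True)
class AlignScoring:
    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        # the row-wise prefix-max recurrence below requires open <= extend <= 0
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("need gap_open <= gap_extend <= 0")

    def gap_cost(self, length: int) -> int:
        return 0 if length == 0 else self.gap_open + (length - 1) * self.gap_extend

    def substitution_matrix(self) -> np.ndarray:
        s = np.full((6, 6), self.mismatch, dtype=np.int64)
        for i in range(4):
            s[i, i] = self.match
        s[4, :] = s[:, 4] = self.mismatch  # N never rewards
        s[_MASK_CODE, :] = s[:, _MASK_CODE] = _NEG
        return s


@dataclass
class LocalAlignment:
    """One local alignment; coordinates are 0-based inclusive in each input."""

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    # one entry per alignment column: (index in a | None, index in b | None)
    columns: list[tuple[int | None, int | None]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.columns)


def encode(seq: str) -> np.ndarray:
    return np.array([_CODES.get(c, 4) for c in seq.upper()], dtype=np.int64)


def _dp_matrix(a: np.ndarray, b: np.ndarray, sc: AlignScoring) -> np.ndarray:
    """Full H matrix of local alignment scores (exact, integer arithmetic).

    Vertical gaps use the standard per-column F recurrence; horizontal gaps
    are resolved within each row by a running prefix maximum, which is exact
    whenever gap_open <= gap_extend (a gap chained onto another gap can never
    beat the single longer gap it shadows).
    """
    n, m = len(a), len(b)
    S = sc.substitution_matrix()
    go, ge = sc.gap_open, sc.gap_extend
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    F = np.full(m, _NEG, dtype=np.int64)
    offs = ge * np.arange(m, dtype=np.int64)
    for i in range(1, n + 1):
        srow = S[a[i - 1], b]
        diag = H[i - 1, :-1] + srow
        F = np.maximum(H[i - 1, 1:] + go, F + ge)
        h0 = np.maximum(diag, F)
        np.maximum(h0, 0, out=h0)
        # E[t] = go + ge*(t-1) + max_{u<t}(h0[u] - ge*u)
        pref = np.maximum.accumulate(h0 - offs)
        e = np.full(m, _NEG, dtype=np.int64)
        if m > 1:
            e[1:] = go + ge * (np.arange(1, m) - 1) + pref[:-1]
        row = np.maximum(h0, e)
        np.maximum(row, 0, out=row)
        H[i, 1:] = row
    return H


def _traceback(H: np.ndarray, a: np.ndarray, b: np.ndarray, sc: AlignScoring,
               i: int, j: int) -> LocalAlignment:
    S = sc.substitution_matrix()
    cols: list[tuple[int | None, int | None]] = []
    score = int(H[i, j])
    while i > 0 and j > 0 and H[i, j] > 0:
        if H[i, j] == H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]:
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            continue
        moved = False
        for g in range(1, j + 1):  # horizontal gap: consumes b only
            if H[i, j] == H[i, j - g] + sc.gap_cost(g):
                for t in range(g):
                    cols.append((None, j - 1 - t))
                j -= g
                moved = True
                break
        if moved:
            continue
        for g in range(1, i + 1):  # vertical gap: consumes a only
            if H[i, j] == H[i - g, j] + sc.gap_cost(g):
                for t in range(g):
                    cols.append((i - 1 - t, None))
                i -= g
                moved = True
                break
        if not moved:  # pragma: no cover - DP invariant
            raise AssertionError("traceback failed to find a predecessor")
    cols.reverse()
    a_idx = [c[0] for c in cols if c[0] is not None]
    b_idx = [c[1] for c in cols if c[1] is not None]
    return LocalAlignment(score=score, a_start=a_idx[0], a_end=a_idx[-1],
                          b_start=b_idx[0], b_end=b_idx[-1], columns=cols)


def smith_waterman(a_seq: str, b_seq: str,
                   scoring: AlignScoring | None = None) -> LocalAlignment | None:
    """Best local alignment of two sequences, or None if nothing scores > 0."""
    sc = scoring or AlignScoring()
    a, b = encode(a_seq), encode(b_seq)
    if len(a) == 0 or len(b) == 0:
        return None
    H = _dp_matrix(a, b, sc)
    best = int(H.max())
    if best <= 0:
        return None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    return _traceback(H, a, b, sc, int(i), int(j))


def local_alignments(a_seq: str, b_seq: str, scoring: AlignScoring | None = None,
                     min_score: int = 20, max_hits: int = 10) -> list[LocalAlignment]:
    """Non-overlapping locally optimal alignments, best first.

    After each traceback the consumed bases of both sequences are masked and
    the DP re-run, so successive alignments share no base with earlier ones.
    """
    sc = scoring or AlignScoring()
    a, b = encode(a_seq), encode(b_seq)
    hits: list[LocalAlignment] = []
    while len(hits) < max_hits and len(a) and len(b):
        H = _dp_matrix(a, b, sc)
        best = int(H.max())
        if best < min_score:
            break
        i, j = np.unravel_index(int(H.argmax()), H.shape)
        aln = _traceback(H, a, b, sc, int(i), int(j))
        hits.append(aln)
        a[aln.a_start : aln.a_end + 1] = _MASK_CODE
        b[aln.b_start : aln.b_end + 1] = _MASK_CODE
    return hits


def alignment_score_from_columns(aln: LocalAlignment, a_seq: str, b_seq: str,
                                 scoring: AlignScoring | None = None) -> int:
    """Recompute an alignment's score from its stored columns (audit path)."""
    sc = scoring or AlignScoring()
    score = 0
    gap_run = 0
    for ai, bi in aln.columns:
        if ai is None or bi is None:
            gap_run += 1
            continue
        if gap_run:
            score += sc.gap_cost(gap_run)
            gap_run = 0
        score += sc.match if a_seq[ai].upper() == b_seq[bi].upper() else sc.mismatch
    if gap_run:
        score += sc.gap_cost(gap_run)
    return score
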