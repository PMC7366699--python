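"""Global RNA alignment over sequence + secondary structure, and its statistics.

The aligner is a Needleman-Wunsch / Gotoh global alignment with affine gaps
(a gap of length L costs ``open + (L-1) * extend``; terminal gaps are
penalized) over a combined structure+sequence scorer.  Two normalized
statistics accompany it: SPS, the fraction of reference-aligned position
pairs recovered by a test alignment, and SSI, the secondary-structure
identity of an alignment (the RNA half of the template-ranking score).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rna_secondary import SecondaryStructure
from .rnablosum import CombinedScorer

GAP = None

_DIAG, _UP, _LEFT = 0, 1, 2  # tie-break priority order


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class GapParams:
    """Affine gap penalties; a length-L gap costs open + (L-1) * extend."""

    open_penalty: float = 10.0
    extend_penalty: float = 2.0

    def __post_init__(self):
        if self.open_penalty <= 0 or self.extend_penalty <= 0:
            raise AlignmentError("gap penalties must be positive")
        if self.extend_penalty > self.open_penalty:
            raise AlignmentError("extend penalty must not exceed open penalty")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Ordered alignment columns ``(i | None, j | None)`` with a total score."""

    aligned_pairs: tuple
    score: float

    def __post_init__(self):
        last_i = last_j = -1
        for i, j in self.aligned_pairs:
            if i is GAP and j is GAP:
                raise AlignmentError("column aligns gap to gap")
            if i is not GAP:
                if i <= last_i:
                    raise AlignmentError("left indices not strictly increasing")
                last_i = i
            if j is not GAP:
                if j <= last_j:
                    raise AlignmentError("right indices not strictly increasing")
                last_j = j

    @property
    def length(self) -> int:
        return len(self.aligned_pairs)

    @property
    def match_pairs(self) -> set:
        """Columns with both sides aligned, as a set of (i, j)."""
        return {(i, j) for i, j in self.aligned_pairs if i is not GAP and j is not GAP}

    @property
    def mapping(self) -> dict:
        """i -> j over aligned (non-gap) columns."""
        return {i: j for i, j in self.match_pairs}

    def swapped(self) -> "PairwiseAlignment":
        return PairwiseAlignment(
            aligned_pairs=tuple((j, i) for i, j in self.aligned_pairs), score=self.score
        )


def gotoh_align(chars_a, chars_b, score_fn, gaps: GapParams) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of two symbol lists.

    ``score_fn(i, j)`` scores aligning position i of a with j of b.
    Traceback is deterministic with tie order diagonal > up > left (up
    consumes from a).
    """
    n, m = len(chars_a), len(chars_b)
    if n == 0 or m == 0:
        raise AlignmentError("cannot align an empty sequence")
    open_p, ext_p = gaps.open_penalty, gaps.extend_penalty
    neg = -np.inf
    # state 0: match/mismatch; state 1: gap in b (consume a, "up"); state 2: gap in a
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(open_p + (i - 1) * ext_p)
    for j in range(1, m + 1):
        Y[0, j] = -(open_p + (j - 1) * ext_p)

    S = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            S[i, j] = score_fn(i, j)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + S[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] - open_p, X[i - 1, j] - ext_p, Y[i - 1, j] - open_p)
            Y[i, j] = max(M[i, j - 1] - open_p, Y[i, j - 1] - ext_p, X[i, j - 1] - open_p)

    tables = (M, X, Y)
    score = max(t[n, m] for t in tables)

    # traceback; state priority M (diagonal) > X (up) > Y (left)
    i, j = n, m
    state = next(s for s in (_DIAG, _UP, _LEFT) if tables[s][i, j] == score)
    columns = []
    while i > 0 or j > 0:
        if state == _DIAG:
            columns.append((i - 1, j - 1))
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = next(s for s in (_DIAG, _UP, _LEFT) if tables[s][i, j] == target)
        elif state == _UP:
            columns.append((i - 1, GAP))
            val = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - open_p == val:
                state = _DIAG
            elif X[i, j] - ext_p == val:
                state = _UP
            else:
                state = _LEFT
        else:
            columns.append((GAP, j - 1))
            val = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - open_p == val:
                state = _DIAG
            elif Y[i, j] - ext_p == val:
                state = _LEFT
            else:
                state = _UP
        if i == 0 and j == 0:
            break
    columns.reverse()
    return PairwiseAlignment(aligned_pairs=tuple(columns), score=float(score))


def global_align(
    a: SecondaryStructure,
    b: SecondaryStructure,
    scorer: CombinedScorer,
    gaps: GapParams = GapParams(),
) -> PairwiseAlignment:
    """Optimal global alignment of two RNAs under the combined scorer."""
    if len(a) == 0 or len(b) == 0:
        raise AlignmentError("cannot align an empty structure")

    def score_fn(i, j):
        return scorer.score(a.sequence[i], a.bear[i], b.sequence[j], b.bear[j])

    return gotoh_align(list(a.sequence), list(b.sequence), score_fn, gaps)


def compute_sps(test: PairwiseAlignment, reference: PairwiseAlignment) -> float:
    """Fraction of reference aligned position pairs recovered by the test alignment."""
    for side in (0, 1):
        t = {c[side] for c in test.aligned_pairs if c[side] is not GAP}
        r = {c[side] for c in reference.aligned_pairs if c[side] is not GAP}
        if t != r:
            raise AlignmentError("alignments do not cover the same sequences")
    ref_pairs = reference.match_pairs
    if not ref_pairs:
        return 0.0
    return len(test.match_pairs & ref_pairs) / len(ref_pairs)


def compute_ssi(
    alignment: PairwiseAlignment,
    bear_a: str,
    bear_b: str,
    denominator: str = "alignment",
) -> float:
    """Secondary-structure identity of an alignment, in [0, 1].

    Counts columns where both sides are aligned and carry the same
    structural-alphabet character.  The denominator is the full alignment
    length by default, or the shorter sequence length
    (``denominator='shorter'``).
    """
    matches = sum(
        1
        for i, j in alignment.aligned_pairs
        if i is not GAP and j is not GAP and bear_a[i] == bear_b[j]
    )
    if denominator == "alignment":
        denom = alignment.length
    elif denominator == "shorter":
        denom = min(len(bear_a), len(bear_b))
    else:
        raise AlignmentError(f"unknown SSI denominator {denominator!r}")
    return matches / denom if denom else 0.0
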