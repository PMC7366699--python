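"""BLOSUM-style substitution matrix over the RNA structural alphabet.

Gapless blocks are harvested from Stockholm seed alignments (consensus
structure from the ``#=GC SS_cons`` line), re-encoded per row into the
structural alphabet, clustered to down-weight redundancy, and turned into a
Henikoff-style log-odds matrix in half-bit units ("RNABLOSUMx" for clustering
identity x).  The trained matrix is combined with the NUC.4.4 nucleotide
matrix (match 5 / mismatch -4) into the scorer used by the structure-aware
aligner::

    score(i, j) = structure_matrix[enc_i][enc_j] + nucleotide_matrix[nt_i][nt_j] * bonus
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from .rna_secondary import (
    DEFAULT_ALPHABET,
    BearAlphabet,
    SecondaryStructure,
    SecondaryStructureError,
    encode_bear,
    resolve_pseudoknots,
)

GAP_CHARS = set(".-~_")
MIN_BLOCK_COLUMNS = 6  # alignment length must exceed five columns

_WUSS_OPEN = {"(": ")", "<": ">", "[": "]", "{": "}"}


class MatrixError(ValueError):
    pass


@dataclass(frozen=True)
class Block:
    """Gapless alignment fragment re-encoded into the structural alphabet."""

    rows: tuple
    source_id: str = "block"

    def __post_init__(self):
        if not self.rows:
            raise MatrixError("empty block")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise MatrixError("block rows have unequal lengths")
        if n < MIN_BLOCK_COLUMNS:
            raise MatrixError(f"block has {n} columns; need >= {MIN_BLOCK_COLUMNS}")
        if any(set(r) & GAP_CHARS for r in self.rows):
            raise MatrixError("block contains gap characters")

    @property
    def columns(self) -> int:
        return len(self.rows[0])


@dataclass
class SubstitutionMatrix:
    """Symmetric score lookup over an ordered alphabet."""

    alphabet: list
    scores: np.ndarray
    clustering_identity: float | None = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.alphabet), len(self.alphabet)):
            raise MatrixError("score matrix shape does not match alphabet")
        if not np.allclose(self.scores, self.scores.T):
            raise MatrixError("score matrix is not symmetric")
        self._index = {c: k for k, c in enumerate(self.alphabet)}

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.scores[self._index[a], self._index[b]])
        except KeyError as exc:
            raise MatrixError(f"character {exc.args[0]!r} not in matrix alphabet") from None

    def to_text(self, path, comment: str = "") -> None:
        """Write in NCBI matrix text format (# comments, header row, score rows)."""
        with open(path, "w") as fh:
            if comment:
                for line in comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("# alphabet order: " + "".join(self.alphabet) + "\n")
            fh.write("  " + " ".join(f"{c:>4}" for c in self.alphabet) + "\n")
            for k, c in enumerate(self.alphabet):
                row = " ".join(f"{self.scores[k, m]:>4.0f}" for m in range(len(self.alphabet)))
                fh.write(f"{c} {row}\n")

    @classmethod
    def from_text(cls, path) -> "SubstitutionMatrix":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
        header = lines[0].split()
        rows = []
        for ln in lines[1:]:
            fields = ln.split()
            if fields[0] != header[len(rows)]:
                raise MatrixError(f"matrix row order mismatch at {fields[0]!r}")
            rows.append([float(x) for x in fields[1:]])
        return cls(alphabet=header, scores=np.array(rows))


def nuc44() -> SubstitutionMatrix:
    """The A/C/G/U submatrix of NCBI NUC.4.4: match 5, mismatch -4.

    Ambiguity codes are deliberately absent and rejected at lookup.
    """
    scores = np.full((4, 4), -4.0)
    np.fill_diagonal(scores, 5.0)
    return SubstitutionMatrix(alphabet=list("ACGU"), scores=scores)


def identity_matrix(alphabet=None, match: float = 2.0, mismatch: float = -2.0) -> SubstitutionMatrix:
    """Simple identity-style structure matrix.

    Hermetic stand-in default for a trained RNABLOSUMx file (training requires
    a seed-alignment corpus, e.g. Rfam, supplied by the user).
    """
    chars = list(alphabet) if alphabet is not None else DEFAULT_ALPHABET.characters
    scores = np.full((len(chars), len(chars)), mismatch)
    np.fill_diagonal(scores, match)
    return SubstitutionMatrix(alphabet=chars, scores=scores)


# ---------------------------------------------------------------------------
# block extraction from Stockholm alignments

def _wuss_pairs(ss_cons: str) -> frozenset:
    """Column pairs from a WUSS/dot-bracket consensus line (pseudoknot letters unpaired)."""
    stacks = {opener: [] for opener in _WUSS_OPEN}
    closers = {v: k for k, v in _WUSS_OPEN.items()}
    pairs = set()
    for pos, ch in enumerate(ss_cons):
        if ch in _WUSS_OPEN:
            stacks[ch].append(pos)
        elif ch in closers:
            stack = stacks[closers[ch]]
            if not stack:
                raise SecondaryStructureError(f"unmatched {ch!r} in SS_cons at column {pos}")
            pairs.add((stack.pop(), pos))
    for opener, stack in stacks.items():
        if stack:
            raise SecondaryStructureError(f"unmatched {opener!r} in SS_cons")
    kept, _ = resolve_pseudoknots(pairs)
    return kept


def _row_bear_by_column(row_seq: str, cons_pairs, alphabet: BearAlphabet) -> dict:
    """Structural-alphabet character per alignment column for one row.

    The consensus pairs are projected onto the row's ungapped positions
    (pairs with a gapped end are dropped), the row is encoded, and characters
    are mapped back to alignment columns.
    """
    col_to_pos = {}
    seq = []
    for col, ch in enumerate(row_seq):
        if ch not in GAP_CHARS:
            col_to_pos[col] = len(seq)
            seq.append(ch.upper().replace("T", "U"))
    pairs = frozenset(
        (col_to_pos[i], col_to_pos[j])
        for i, j in cons_pairs
        if i in col_to_pos and j in col_to_pos
    )
    ss = SecondaryStructure(sequence="".join(seq), pairs=pairs)
    bear = encode_bear(ss, alphabet)
    return {col: bear[pos] for col, pos in col_to_pos.items()}


def extract_blocks(alignment, alphabet: BearAlphabet = DEFAULT_ALPHABET) -> list[Block]:
    """Maximal gap-free column runs of length >= 6 as structural-alphabet blocks.

    ``alignment`` is a Bio.Align MultipleSeqAlignment whose
    ``column_annotations['secondary_structure']`` holds the consensus
    structure (Stockholm ``#=GC SS_cons``).
    """
    ss_cons = alignment.column_annotations.get("secondary_structure")
    if not ss_cons:
        raise MatrixError("alignment has no SS_cons consensus structure line")
    cons_pairs = _wuss_pairs(ss_cons)
    rows = [str(rec.seq) for rec in alignment]
    ncols = alignment.get_alignment_length()
    per_row = [_row_bear_by_column(r, cons_pairs, alphabet) for r in rows]

    gap_free = [all(r[c] not in GAP_CHARS for r in rows) for c in range(ncols)]
    source = getattr(alignment, "annotations", {}).get("accession", "alignment")
    blocks = []
    c = 0
    while c < ncols:
        if not gap_free[c]:
            c += 1
            continue
        start = c
        while c < ncols and gap_free[c]:
            c += 1
        if c - start >= MIN_BLOCK_COLUMNS:
            encoded = tuple(
                "".join(per_row[r][col] for col in range(start, c))
                for r in range(len(rows))
            )
            blocks.append(Block(rows=encoded, source_id=f"{source}:{start}"))
    return blocks


def blocks_from_stockholm(path, alphabet: BearAlphabet = DEFAULT_ALPHABET) -> list[Block]:
    """Extract blocks from every alignment in a Stockholm file."""
    blocks = []
    for alignment in AlignIO.parse(path, "stockholm"):
        blocks.extend(extract_blocks(alignment, alphabet))
    return blocks


# ---------------------------------------------------------------------------
# clustering and the log-odds computation

def row_identity(a: str, b: str) -> float:
    """Percent of positions with identical structural-alphabet characters."""
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def cluster_rows(block: Block, identity: float) -> tuple[list, list]:
    """Single-linkage clustering of block rows; weights are 1/cluster size.

    Rows merge when their pairwise identity strictly exceeds the threshold
    (classic BLOSUM "more than x% identical"), closed transitively.
    """
    if not (0 < identity <= 100):
        raise MatrixError("clustering identity must be in (0, 100]")
    n = len(block.rows)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if row_identity(block.rows[i], block.rows[j]) > identity:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    sizes = defaultdict(int)
    for r in roots:
        sizes[r] += 1
    labels = {}
    cluster_ids = []
    for r in roots:
        cluster_ids.append(labels.setdefault(r, len(labels)))
    weights = [1.0 / sizes[r] for r in roots]
    return cluster_ids, weights


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def pair_frequencies(blocks, identity: float) -> dict:
    """Weighted between-cluster pair counts per unordered character pair."""
    counts = defaultdict(float)
    for block in blocks:
        labels, weights = cluster_rows(block, identity)
        n = len(block.rows)
        for col in range(block.columns):
            for i in range(n):
                for j in range(i + 1, n):
                    if labels[i] == labels[j]:
                        continue
                    a, b = sorted((block.rows[i][col], block.rows[j][col]))
                    counts[(a, b)] += weights[i] * weights[j]
    return dict(counts)


def compute_rnablosum(
    blocks,
    identity: float = 80.0,
    alphabet: BearAlphabet = DEFAULT_ALPHABET,
) -> SubstitutionMatrix:
    """Henikoff log-odds matrix in half-bit units from structural-alphabet blocks.

    Per column, pairs between rows of distinct clusters are counted with
    weight 1/(cluster sizes); observed pair frequency q_ab and background
    p_a give expected frequencies e_aa = p_a^2, e_ab = 2 p_a p_b and scores
    s_ab = round(2 log2(q_ab / e_ab)), rounded half away from zero.  A zero
    pair count between observed characters is scored with pseudo-frequency
    1/(N+1) (N = total weighted pairs) so no score is -infinity; pairs
    involving a never-observed character score 0.
    """
    if not blocks:
        raise MatrixError("no blocks supplied")
    counts = pair_frequencies(blocks, identity)
    total = sum(counts.values())
    if total <= 0:
        raise MatrixError("no between-cluster pairs (all rows clustered together?)")

    chars = alphabet.characters
    q = {pair: c / total for pair, c in counts.items()}
    p = {c: 0.0 for c in chars}
    for (a, b), freq in q.items():
        if a == b:
            p[a] += freq
        else:
            p[a] += freq / 2
            p[b] += freq / 2

    floor_q = 1.0 / (total + 1.0)
    scores = np.zeros((len(chars), len(chars)))
    for i, a in enumerate(chars):
        for j in range(i, len(chars)):
            b = chars[j]
            if p[a] <= 0 or p[b] <= 0:
                continue
            e = p[a] ** 2 if a == b else 2 * p[a] * p[b]
            qq = q.get(tuple(sorted((a, b))), 0.0) or floor_q
            s = _round_half_away(2 * math.log2(qq / e))
            scores[i, j] = scores[j, i] = s
    return SubstitutionMatrix(alphabet=chars, scores=scores, clustering_identity=identity)


# ---------------------------------------------------------------------------
# combined scorer

@dataclass(frozen=True)
class CombinedScorer:
    """Structure + sequence scorer: structure[s_i, s_j] + nuc[n_i, n_j] * bonus."""

    structure_matrix: SubstitutionMatrix
    nucleotide_matrix: SubstitutionMatrix = field(default_factory=nuc44)
    bonus: float = 0.2

    def __post_init__(self):
        if self.bonus < 0:
            raise MatrixError("bonus must be >= 0")

    def score(self, nt_i: str, enc_i: str, nt_j: str, enc_j: str) -> float:
        structure = self.structure_matrix.score(enc_i, enc_j)
        if self.bonus == 0:
            return structure
        return structure + self.nucleotide_matrix.score(nt_i, nt_j) * self.bonus


def build_scorer(structure_matrix: SubstitutionMatrix, bonus: float = 0.2) -> CombinedScorer:
    """Combine a trained structure matrix with NUC.4.4 under a sequence bonus."""
    return CombinedScorer(structure_matrix=structure_matrix, bonus=bonus)
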