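"""RNA secondary-structure representations and the structural-alphabet encoding.

A secondary structure is held as a sequence plus a set of non-crossing base
pairs.  Dot-bracket (Vienna) notation and CT files can be parsed into it, and
every structure can be re-encoded into a per-nucleotide structural alphabet in
which each character identifies the structural element containing the position
(stem, hairpin loop, internal loop / bulge, or exterior) together with the
element's length.  This length-aware encoding is the "BEAR" style
representation used by structure-aware RNA aligners; the exact published
character table is not redistributable, so a documented default table
("BEAR-lite", 4 element types x length classes 1..9) is shipped and a
user-supplied mapping can replace it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGU"

#: element types of the structural alphabet
STEM = "stem"
HAIRPIN = "hairpin_loop"
INTERNAL = "internal_or_bulge"
EXTERIOR = "exterior"
ELEMENT_TYPES = (STEM, HAIRPIN, INTERNAL, EXTERIOR)

_BRACKET_PAIRS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in _BRACKET_PAIRS.items()}


class SecondaryStructureError(ValueError):
    """Raised for malformed dot-bracket, CT, or inconsistent structures."""


@dataclass(frozen=True)
class BearAlphabet:
    """Injective mapping (element type, capped length) -> single character.

    Lengths above ``max_length_per_type`` share the cap's character, so long
    elements never fall off the table.
    """

    mapping: dict
    max_length_per_type: int = 9

    def __post_init__(self):
        chars = list(self.mapping.values())
        if len(set(chars)) != len(chars):
            raise ValueError("alphabet mapping is not injective")
        for etype in ELEMENT_TYPES:
            for length in range(1, self.max_length_per_type + 1):
                if (etype, length) not in self.mapping:
                    raise ValueError(f"missing alphabet entry for ({etype}, {length})")

    @property
    def characters(self) -> list[str]:
        """Alphabet characters in deterministic (type, length) order."""
        return [
            self.mapping[(t, L)]
            for t in ELEMENT_TYPES
            for L in range(1, self.max_length_per_type + 1)
        ]

    def char(self, element_type: str, length: int) -> str:
        return self.mapping[(element_type, min(length, self.max_length_per_type))]

    @classmethod
    def default(cls, cap: int = 9) -> "BearAlphabet":
        """BEAR-lite: stems a-i, hairpins j-r, internal/bulge A-I, exterior J-R."""
        rows = {
            STEM: "abcdefghijklm",
            HAIRPIN: "jklmnopqrstuv",
            INTERNAL: "ABCDEFGHIJKLM",
            EXTERIOR: "JKLMNOPQRSTUV",
        }
        if cap > 9:
            raise ValueError("default table supports caps up to 9")
        mapping = {}
        for etype in ELEMENT_TYPES:
            for length in range(1, cap + 1):
                mapping[(etype, length)] = rows[etype][length - 1]
        return cls(mapping=mapping, max_length_per_type=cap)

    @classmethod
    def from_yaml(cls, path) -> "BearAlphabet":
        """Load a user-supplied table: {type: {length: char}, cap: int}."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cap = int(raw.pop("cap", 9))
        mapping = {
            (etype, int(length)): str(char)
            for etype, row in raw.items()
            for length, char in row.items()
        }
        return cls(mapping=mapping, max_length_per_type=cap)


DEFAULT_ALPHABET = BearAlphabet.default()


def _check_non_crossing(pairs):
    ordered = sorted(pairs)
    for k, (i, j) in enumerate(ordered):
        for i2, j2 in ordered[k + 1 :]:
            if i2 >= j:
                break
            if i < i2 < j < j2:
                raise SecondaryStructureError(
                    f"crossing pairs ({i},{j}) and ({i2},{j2})"
                )


@dataclass(frozen=True)
class SecondaryStructure:
    """One RNA: sequence, base pairs, dot-bracket and structural-alphabet string.

    Pairs are 0-based ``(i, j)`` with ``i < j``, each index in at most one
    pair, non-crossing (pseudoknots must be resolved before construction).
    """

    sequence: str
    pairs: frozenset
    dot_bracket: str = field(default="")
    bear: str = field(default="")

    def __post_init__(self):
        seen = set()
        for i, j in self.pairs:
            if not (0 <= i < j < len(self.sequence)):
                raise SecondaryStructureError(f"pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise SecondaryStructureError(f"index reused in pair ({i},{j})")
            seen.update((i, j))
        _check_non_crossing(self.pairs)
        if not self.dot_bracket:
            object.__setattr__(self, "dot_bracket", render_dot_bracket(self.pairs, len(self.sequence)))
        if not self.bear:
            object.__setattr__(self, "bear", encode_bear(self, DEFAULT_ALPHABET))
        if not (len(self.sequence) == len(self.dot_bracket) == len(self.bear)):
            raise SecondaryStructureError("sequence / dot-bracket / encoding length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def partner(self) -> dict:
        """0-based position -> paired partner, for paired positions only."""
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass(frozen=True)
class CtRecord:
    """One CT-file row: 1-based position, base, 1-based partner (0 = unpaired)."""

    index: int
    base: str
    partner: int


def render_dot_bracket(pairs, length: int) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def parse_dot_bracket(text: str, sequence: str) -> SecondaryStructure:
    """Parse dot-bracket notation against its sequence.

    Supports the extended bracket sets ``()[]{}<>``; every bracket level is
    treated alike (pairs must still be non-crossing overall).
    """
    if len(text) != len(sequence):
        raise SecondaryStructureError(
            f"structure length {len(text)} != sequence length {len(sequence)}"
        )
    stacks = {opener: [] for opener in _BRACKET_PAIRS}
    pairs = set()
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        if ch in _BRACKET_PAIRS:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            stack = stacks[_CLOSERS[ch]]
            if not stack:
                raise SecondaryStructureError(f"unmatched '{ch}' at index {pos}")
            pairs.add((stack.pop(), pos))
        else:
            raise SecondaryStructureError(f"invalid character {ch!r} at index {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise SecondaryStructureError(f"unmatched '{opener}' at index {stack[-1]}")
    return SecondaryStructure(sequence=sequence.upper().replace("T", "U"),
                              pairs=frozenset(pairs), dot_bracket=text)


def _crossing(p, q) -> bool:
    (i, j), (i2, j2) = sorted((p, q))
    return i < i2 < j < j2


def resolve_pseudoknots(pairs) -> tuple[frozenset, list]:
    """Greedily drop crossing pairs until the remainder is non-crossing.

    Repeatedly removes the pair crossing the most others; ties are broken by
    dropping the pair with the larger opening index.  Returns the surviving
    pairs and the removed ones.
    """
    alive = set(pairs)
    removed = []
    while True:
        counts = {p: 0 for p in alive}
        for p in alive:
            for q in alive:
                if p < q and _crossing(p, q):
                    counts[p] += 1
                    counts[q] += 1
        worst = max(counts.values(), default=0)
        if worst == 0:
            break
        victim = max((p for p, c in counts.items() if c == worst), key=lambda p: p[0])
        alive.remove(victim)
        removed.append(victim)
    if removed:
        logger.warning("pseudoknot resolution removed %d pair(s): %s", len(removed), removed)
    return frozenset(alive), removed


def ct_to_dot_bracket(records: list[CtRecord]) -> SecondaryStructure:
    """Convert CT records (1-based) to a dot-bracket secondary structure.

    Partner fields must be mutually consistent.  Crossing pairs (pseudoknots,
    inexpressible in plain dot-bracket) are resolved by the greedy rule of
    :func:`resolve_pseudoknots` and logged.
    """
    partner = {rec.index: rec.partner for rec in records}
    if sorted(partner) != list(range(1, len(records) + 1)):
        raise SecondaryStructureError("CT indices are not 1..N")
    pairs = set()
    for rec in records:
        if rec.partner == 0:
            continue
        if partner.get(rec.partner) != rec.index:
            raise SecondaryStructureError(
                f"inconsistent CT partners at position {rec.index}"
            )
        pairs.add((min(rec.index, rec.partner) - 1, max(rec.index, rec.partner) - 1))
    kept, _ = resolve_pseudoknots(pairs)
    sequence = "".join(rec.base.upper().replace("T", "U") for rec in records)
    return SecondaryStructure(sequence=sequence, pairs=frozenset(kept))


def elements(ss: SecondaryStructure) -> list[tuple[str, int, list[int]]]:
    """Decompose a structure into (element type, length, member positions).

    Stems are maximal runs of stacked pairs; their length is the number of
    pairs in the stack and both strands belong to the stem.  Maximal unpaired
    runs are hairpin loops when their innermost enclosing pair closes a
    pair-free region, exterior when no pair encloses them, and internal
    loop / bulge (which here also covers multiloop segments) otherwise.
    """
    n = len(ss)
    partner = ss.partner
    out = []

    pairs = sorted(ss.pairs)
    pair_set = set(pairs)
    assigned = set()
    for i, j in pairs:
        if (i, j) in assigned:
            continue
        stack = [(i, j)]
        while (stack[-1][0] + 1, stack[-1][1] - 1) in pair_set:
            stack.append((stack[-1][0] + 1, stack[-1][1] - 1))
        assigned.update(stack)
        members = [p for ij in stack for p in ij]
        out.append((STEM, len(stack), sorted(members)))

    pos = 0
    while pos < n:
        if pos in partner:
            pos += 1
            continue
        start = pos
        while pos < n and pos not in partner:
            pos += 1
        run = list(range(start, pos))
        enclosing = None
        for i, j in pairs:  # smallest enclosing span
            if i < start and run[-1] < j:
                if enclosing is None or (j - i) < (enclosing[1] - enclosing[0]):
                    enclosing = (i, j)
        if enclosing is None:
            etype = EXTERIOR
        else:
            i, j = enclosing
            has_inner_pair = any(i < k < j for k in partner)
            etype = HAIRPIN if not has_inner_pair else INTERNAL
        out.append((etype, len(run), run))
    return out


def encode_bear(ss: SecondaryStructure, alphabet: BearAlphabet = DEFAULT_ALPHABET) -> str:
    """Per-nucleotide structural-alphabet string for a secondary structure."""
    chars = [""] * len(ss)
    for etype, length, members in elements(ss):
        c = alphabet.char(etype, length)
        for p in members:
            chars[p] = c
    return "".join(chars)


# ---------------------------------------------------------------------------
# file I/O (1-based conventions in files, 0-based in memory)

def read_dot_bracket(path) -> SecondaryStructure:
    """Read a 3-line Vienna file: '>header', sequence, structure."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise SecondaryStructureError(f"{path}: expected sequence and structure lines")
    return parse_dot_bracket(lines[1], lines[0])


def write_dot_bracket(ss: SecondaryStructure, path, header: str = "rna") -> None:
    with open(path, "w") as fh:
        fh.write(f">{header}\n{ss.sequence}\n{ss.dot_bracket}\n")


def read_ct(path) -> SecondaryStructure:
    """Read a CT file (header line with length, then index/base/.../partner rows)."""
    records = []
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    for ln in lines[1:]:  # first line is the header
        fields = ln.split()
        records.append(CtRecord(index=int(fields[0]), base=fields[1], partner=int(fields[4])))
    return ct_to_dot_bracket(records)


def write_bear_fasta(structures: dict, path, alphabet: BearAlphabet = DEFAULT_ALPHABET) -> None:
    """Write structural-alphabet strings as FASTA-like records."""
    with open(path, "w") as fh:
        for name, ss in structures.items():
            fh.write(f">{name}\n{encode_bear(ss, alphabet)}\n")
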