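"""Deterministic synthetic data: toy complexes, template libraries, Stockholm blocks.

Every generator is a pure function of a :class:`FixtureSpec` (single seeded
RNG stream per call; the seed is recorded in file headers), so the whole
pipeline is testable without downloading any structure or alignment data.
Geometry is deliberately schematic -- a helix-like C-alpha trace and an RNA
C3' trace placed so that exactly the planted positions fall within the
interface cutoff -- not physically realistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pipeline import DEFAULT_CUTOFF, DEFAULT_WEIGHT, Target, TemplateEntry, align_proteins, align_rnas, score_3d2d
from .rna_secondary import SecondaryStructure, parse_dot_bracket, write_dot_bracket
from .structures3d import (
    ChainStructure,
    ComplexStructure,
    Residue,
    RigidTransform,
    annotate_interface,
    write_pdb,
)


class FixtureError(RuntimeError):
    """Requested planted property could not be realized."""


@dataclass(frozen=True)
class FixtureSpec:
    """Everything a generator call depends on; same spec -> identical output."""

    seed: int = 0
    n_residues: int = 30
    n_nucleotides: int = 12
    planted_interface_protein: tuple = (5, 12, 20)
    planted_interface_rna: tuple = (2, 6, 9)
    noise_sigma: float = 0.0  # A, gaussian coordinate jitter
    planted_scores: tuple = (1.0, 0.93, 0.86, 0.2, 0.2, 0.2)  # intended 3D2D levels
    # Stockholm-block generation
    n_block_rows: int = 4
    block_runs: tuple = (8, 7)  # lengths of gap-free column runs
    duplicate_rows: int = 1

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


_HELIX_RADIUS = 2.3  # A
_HELIX_RISE = 1.5  # A per residue
_HELIX_TURN = math.radians(100.0)
_CONTACT_DISTANCE = 4.0  # A, planted C3'-to-CA distance (inside the 4.5 cutoff)

_AA_NAMES = ("ALA", "GLY", "SER", "LEU", "VAL", "THR", "LYS", "ASP", "PHE", "ARG")


def _helix_ca(i: int) -> np.ndarray:
    theta = i * _HELIX_TURN
    return np.array(
        [_HELIX_RADIUS * math.cos(theta), _HELIX_RADIUS * math.sin(theta), _HELIX_RISE * i]
    )


def _radial(i: int) -> np.ndarray:
    theta = i * _HELIX_TURN
    return np.array([math.cos(theta), math.sin(theta), 0.0])


def hairpin_dot_bracket(n: int) -> str:
    """A single hairpin over n nucleotides: maximal stem, loop of >= 3."""
    if n < 5:
        raise FixtureError("need >= 5 nucleotides for a hairpin")
    stem = (n - 3) // 2
    loop = n - 2 * stem
    return "(" * stem + "." * loop + ")" * stem


def make_toy_complex(
    spec: FixtureSpec, out_dir=None
) -> tuple[ComplexStructure, SecondaryStructure]:
    """Toy protein-RNA complex with an exactly planted interface.

    The protein is a helix-like C-alpha trace (dummy CB heavy atoms); RNA
    C3' atoms sit far from the protein except at the planted nucleotide
    positions, each placed 4 A from its planted protein partner residue.
    Generation fails if interface re-annotation does not recover exactly the
    planted sets (only checked for noise-free geometry).
    """
    if spec.n_residues < 4 or spec.n_nucleotides < 5:
        raise FixtureError("sizes too small (need >= 4 residues, >= 5 nucleotides)")
    planted_p = tuple(spec.planted_interface_protein)
    planted_r = tuple(spec.planted_interface_rna)
    if len(planted_p) != len(planted_r):
        raise FixtureError("planted protein and RNA interface sets must pair 1:1")
    if planted_p and (max(planted_p) >= spec.n_residues or max(planted_r) >= spec.n_nucleotides):
        raise FixtureError("planted interface index out of range")
    rng = spec.rng(salt=1)

    protein_residues = []
    for i in range(spec.n_residues):
        ca = _helix_ca(i)
        cb = ca + 0.8 * _radial(i)
        protein_residues.append(
            Residue(
                residue_id=i + 1,
                name=_AA_NAMES[int(rng.integers(len(_AA_NAMES)))],
                atoms=(("CA", ca), ("CB", cb)),
            )
        )

    contact_of = dict(zip(planted_r, planted_p))
    rna_residues = []
    sequence = "".join("ACGU"[int(rng.integers(4))] for _ in range(spec.n_nucleotides))
    for k in range(spec.n_nucleotides):
        if k in contact_of:
            i = contact_of[k]
            c3 = _helix_ca(i) + _CONTACT_DISTANCE * _radial(i)
            o3 = c3 + 0.6 * _radial(i)  # points away from the helix axis
        else:
            c3 = np.array([35.0, 4.0 * k, 0.0])
            o3 = c3 + np.array([0.6, 0.0, 0.0])
        rna_residues.append(
            Residue(residue_id=k + 1, name=sequence[k], atoms=(("C3'", c3), ("O3'", o3)))
        )

    protein = ChainStructure(residues=tuple(protein_residues), kind="protein", chain_id="A")
    rna = ChainStructure(residues=tuple(rna_residues), kind="rna", chain_id="B")
    complex_ = ComplexStructure(protein=protein, rna=rna)
    if spec.noise_sigma > 0:
        complex_ = perturb_complex(complex_, spec.noise_sigma, spec.rng(salt=2))
    complex_ = annotate_interface(complex_)
    if spec.noise_sigma == 0:
        if complex_.interface_protein != frozenset(planted_p) or complex_.interface_rna != frozenset(planted_r):
            raise FixtureError(
                "infeasible planted geometry: interface annotation recovered "
                f"{sorted(complex_.interface_protein)}/{sorted(complex_.interface_rna)}"
            )
    ss = parse_dot_bracket(hairpin_dot_bracket(spec.n_nucleotides), sequence)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_pdb(complex_, out_dir / "complex.pdb", remarks=[f"fixture seed={spec.seed}"])
        write_dot_bracket(ss, out_dir / "rna.dbn", header=f"rna seed={spec.seed}")
    return complex_, ss


def perturb_complex(
    complex_: ComplexStructure, sigma: float, rng: np.random.Generator
) -> ComplexStructure:
    """Gaussian coordinate jitter on every heavy atom of both chains."""

    def jitter(chain: ChainStructure) -> ChainStructure:
        residues = tuple(
            Residue(
                residue_id=r.residue_id,
                name=r.name,
                atoms=tuple((n, xyz + rng.normal(0.0, sigma, 3)) for n, xyz in r.atoms),
            )
            for r in chain.residues
        )
        return ChainStructure(residues=residues, kind=chain.kind, chain_id=chain.chain_id)

    return ComplexStructure(protein=jitter(complex_.protein), rna=jitter(complex_.rna))


def random_rigid_transform(rng: np.random.Generator, max_shift: float = 20.0) -> RigidTransform:
    """Uniformly random proper rotation plus a bounded random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_shift, max_shift, 3)
    return RigidTransform(rotation=Q, translation=t)


def _random_coil_protein(n: int, rng: np.random.Generator) -> ChainStructure:
    pos = np.zeros(3)
    residues = []
    for i in range(n):
        step = rng.normal(size=3)
        pos = pos + 3.8 * step / np.linalg.norm(step)
        residues.append(
            Residue(
                residue_id=i + 1,
                name=_AA_NAMES[int(rng.integers(len(_AA_NAMES)))],
                atoms=(("CA", pos.copy()), ("CB", pos + np.array([0.8, 0.0, 0.0]))),
            )
        )
    return ChainStructure(residues=tuple(residues), kind="protein", chain_id="A")


def make_template_library(
    spec: FixtureSpec, out_dir=None
) -> tuple[Target, list[TemplateEntry]]:
    """Target plus a library whose hits land in the planted score order.

    Planted scores at or above the search cutoff are realized as rigid /
    coordinate-noise variants of the target complex (identical RNA 2D, so
    SSI stays 1 and the ordering is carried by the TM-score, which decreases
    with the noise level); scores below the cutoff become decoys with a
    random-coil protein and an unpaired RNA 2D.  The achieved 3D2D scores
    are measured with the built-in aligners at generation time, and the
    generator fails rather than deliver a library violating the planted
    ordering or cutoff sides.
    """
    base_complex, base_ss = make_toy_complex(spec)
    target = Target(
        id="target", protein=base_complex.protein, rna_secondary=base_ss, rna=base_complex.rna
    )
    rng = spec.rng(salt=3)

    high = sorted([s for s in spec.planted_scores if s >= DEFAULT_CUTOFF], reverse=True)
    n_low = len(spec.planted_scores) - len(high)

    entries = []
    achieved = []
    for rank, planted in enumerate(high):
        sigma = 0.35 * rank  # monotone noise ladder: rank 0 is a rigid copy
        variant = base_complex
        if sigma > 0:
            variant = perturb_complex(variant, sigma, rng)
        variant = annotate_interface(variant.transformed(random_rigid_transform(rng)))
        entry = TemplateEntry(id=f"tmpl{rank:02d}", complex=variant, rna_secondary=base_ss)
        _, tm = align_proteins(target.protein, entry.complex.protein)
        _, ssi = align_rnas(target.rna_secondary, entry.rna_secondary)
        score = score_3d2d(min(tm, 1.0), ssi, DEFAULT_WEIGHT)
        if score < DEFAULT_CUTOFF:
            raise FixtureError(f"entry {entry.id}: achieved score {score:.3f} fell below cutoff")
        achieved.append(score)
        entries.append(entry)
    for a, b in zip(achieved, achieved[1:]):
        if a < b - 1e-9:
            raise FixtureError("achieved scores do not follow the planted order")

    decoy_ss = parse_dot_bracket("." * spec.n_nucleotides, base_ss.sequence)
    for k in range(n_low):
        coil = _random_coil_protein(spec.n_residues, rng)
        decoy = annotate_interface(
            ComplexStructure(protein=coil, rna=base_complex.rna.transformed(random_rigid_transform(rng)))
        )
        entry = TemplateEntry(id=f"tmpl{len(high) + k:02d}", complex=decoy, rna_secondary=decoy_ss)
        _, tm = align_proteins(target.protein, entry.complex.protein)
        _, ssi = align_rnas(target.rna_secondary, entry.rna_secondary)
        score = score_3d2d(min(tm, 1.0), ssi, DEFAULT_WEIGHT)
        if score >= DEFAULT_CUTOFF:
            raise FixtureError(f"decoy {entry.id}: achieved score {score:.3f} is not below cutoff")
        entries.append(entry)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_pdb(
            ComplexStructure(protein=target.protein, rna=target.rna),
            out_dir / "target.pdb",
            remarks=[f"fixture seed={spec.seed}"],
        )
        write_dot_bracket(target.rna_secondary, out_dir / "target.dbn")
        lines = ["id\tpdb\tprotein_chain\trna_chain\tdbn"]
        for entry in entries:
            write_pdb(entry.complex, out_dir / f"{entry.id}.pdb",
                      remarks=[f"fixture seed={spec.seed}"])
            write_dot_bracket(entry.rna_secondary, out_dir / f"{entry.id}.dbn")
            lines.append(f"{entry.id}\t{entry.id}.pdb\tA\tB\t{entry.id}.dbn")
        (out_dir / "library.tsv").write_text("\n".join(lines) + "\n")
    return target, entries


# ---------------------------------------------------------------------------
# Stockholm toy families

def make_toy_blocks(spec: FixtureSpec, out_path=None) -> str:
    """Small Stockholm family with SS_cons, planted gap columns and redundancy.

    The alignment consists of the gap-free column runs requested in
    ``spec.block_runs`` separated by single columns that are gapped in the
    last row, so block extraction finds exactly ``len(block_runs)`` blocks.
    One hairpin spans the whole alignment: the stem halves sit at the two
    ends and the loop covers the separator columns, so the gapped row gets a
    shorter loop and different length-coded characters inside the blocks
    (the structural variation the matrix trainer needs).  The first
    ``duplicate_rows`` rows after row 0 are byte-identical copies of row 0.
    """
    runs = spec.block_runs
    if min(runs, default=0) < 6:
        raise FixtureError("each requested run must have >= 6 columns")
    rng = spec.rng(salt=4)
    n_rows = spec.n_block_rows
    if n_rows < 2:
        raise FixtureError("need at least 2 rows")
    if spec.duplicate_rows + 1 >= n_rows:
        raise FixtureError("duplicate_rows must leave room for the gapped row")

    n_sep = len(runs) - 1
    ncols = sum(runs) + n_sep
    stem = min(4, runs[0] - 2, runs[-1] - 2)
    ss_cons = "<" * stem + "." * (ncols - 2 * stem) + ">" * stem
    separator_cols = set()
    col = 0
    for run in runs[:-1]:
        col += run
        separator_cols.add(col)
        col += 1

    rows = []
    for r in range(n_rows):
        if r <= spec.duplicate_rows and rows:
            rows.append(rows[0])
            continue
        chars = []
        for c in range(ncols):
            if c in separator_cols and r == n_rows - 1:
                chars.append("-")  # the planted gap making the column dirty
            else:
                chars.append("ACGU"[int(rng.integers(4))])
        rows.append("".join(chars))

    name_width = 12
    lines = ["# STOCKHOLM 1.0", f"#=GF AC toyfam.seed{spec.seed}"]
    for r, row in enumerate(rows):
        lines.append(f"{f'seq{r}':<{name_width}} {row}")
    lines.append(f"{'#=GC SS_cons':<{name_width}} {ss_cons}")
    lines.append("//")
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
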