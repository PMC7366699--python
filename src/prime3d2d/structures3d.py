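"""3D structure handling: PDB I/O, interface annotation, superposition, RMSDs.

Chains are reduced to ordered residues carrying their heavy atoms and a
representative atom (C-alpha for protein, C3' for RNA).  Interfaces are
defined by a heavy-atom distance cutoff (default 4.5 A).  Superposition is
the Kabsch least-squares fit; on top of it sit the TM-score (iterative
fragment superposition, normalized by target length), the interface RMSD
between two complexes, and the ligand RMSD of a docked model against the
native complex (RNA C3' RMSD after protein-frame superposition; <= 10 A is
the conventional "acceptable" model).

TM-align and LocARNA can be used through thin subprocess wrappers when the
executables are present; the package falls back to its built-in aligners
otherwise.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

INTERFACE_CUTOFF = 4.5  # A, heavy-atom distance defining a binding site
ACCEPTABLE_LRMSD = 10.0  # A, ligand-RMSD bound for an "acceptable" model

PROTEIN_REP_ATOM = "CA"
RNA_REP_ATOMS = ("C3'", "C3*")


class StructureError(ValueError):
    pass


class ExternalToolError(RuntimeError):
    """External aligner failed or produced unparseable output."""


@dataclass(frozen=True)
class Residue:
    residue_id: int
    name: str
    atoms: tuple  # ((atom_name, xyz ndarray), ...) heavy atoms only

    def atom(self, name: str):
        for atom_name, xyz in self.atoms:
            if atom_name == name:
                return xyz
        return None

    def representative(self, kind: str):
        names = (PROTEIN_REP_ATOM,) if kind == "protein" else RNA_REP_ATOMS
        for name in names:
            xyz = self.atom(name)
            if xyz is not None:
                return xyz
        return None


@dataclass(frozen=True)
class ChainStructure:
    """Ordered residues of one chain; ``kind`` is 'protein' or 'rna'."""

    residues: tuple
    kind: str
    chain_id: str = "A"

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def alignment_indices(self) -> list:
        """Residue indices usable for alignment (representative atom present)."""
        return [
            k for k, r in enumerate(self.residues) if r.representative(self.kind) is not None
        ]

    @property
    def rep_coords(self) -> np.ndarray:
        """Representative-atom coordinates for alignment-usable residues."""
        return np.array(
            [self.residues[k].representative(self.kind) for k in self.alignment_indices]
        )

    def rep_coord(self, index: int):
        return self.residues[index].representative(self.kind)

    @property
    def sequence(self) -> str:
        return "".join(_one_letter(r.name) for r in self.residues)

    def heavy_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(N, 3) heavy-atom coordinates and the residue index of each atom."""
        coords, owner = [], []
        for k, res in enumerate(self.residues):
            for _, xyz in res.atoms:
                coords.append(xyz)
                owner.append(k)
        return np.array(coords), np.array(owner)

    def transformed(self, transform: "RigidTransform") -> "ChainStructure":
        residues = tuple(
            Residue(
                residue_id=r.residue_id,
                name=r.name,
                atoms=tuple((n, transform.apply(xyz)) for n, xyz in r.atoms),
            )
            for r in self.residues
        )
        return ChainStructure(residues=residues, kind=self.kind, chain_id=self.chain_id)


_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _one_letter(resname: str) -> str:
    resname = resname.strip().upper()
    if resname in _AA3TO1:
        return _AA3TO1[resname]
    if resname in {"A", "C", "G", "U", "T"}:
        return "U" if resname == "T" else resname
    return "X"


@dataclass(frozen=True)
class ComplexStructure:
    protein: ChainStructure
    rna: ChainStructure
    interface_protein: frozenset = frozenset()
    interface_rna: frozenset = frozenset()
    interface_cutoff: float = INTERFACE_CUTOFF

    def transformed(self, transform: "RigidTransform") -> "ComplexStructure":
        return ComplexStructure(
            protein=self.protein.transformed(transform),
            rna=self.rna.transformed(transform),
            interface_protein=self.interface_protein,
            interface_rna=self.interface_rna,
            interface_cutoff=self.interface_cutoff,
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation (det = +1) plus translation, in A."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation.T, translation=-self.rotation.T @ self.translation
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


# ---------------------------------------------------------------------------
# PDB I/O

def read_structure(path, protein_chain: str, rna_chain: str) -> ComplexStructure:
    """Load a two-chain complex from a PDB file.

    Hydrogens and waters are dropped; alternate locations other than
    'A'/blank are skipped.  Residues lacking their representative atom are
    kept (their heavy atoms still count toward the interface) but excluded
    from alignment index sets, with a warning.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    available = [c.id for c in model.get_chains()]
    chains = {}
    for chain_id, kind in ((protein_chain, "protein"), (rna_chain, "rna")):
        if chain_id not in available:
            raise StructureError(
                f"chain {chain_id!r} not found; available chains: {available}"
            )
        residues = []
        for res in model[chain_id]:
            if res.get_resname().strip() in {"HOH", "WAT"}:
                continue
            atoms = []
            for atom in res.get_unpacked_list():
                if atom.get_altloc() not in (" ", "A"):
                    continue
                if (atom.element or "").upper() == "H":
                    continue
                atoms.append((atom.get_name(), np.array(atom.get_coord(), dtype=float)))
            if atoms:
                residues.append(
                    Residue(residue_id=res.get_id()[1], name=res.get_resname().strip(),
                            atoms=tuple(atoms))
                )
        chain = ChainStructure(residues=tuple(residues), kind=kind, chain_id=chain_id)
        n_missing = len(chain) - len(chain.alignment_indices)
        if n_missing:
            import logging

            logging.getLogger(__name__).warning(
                "%d residue(s) of chain %s lack a representative atom and are "
                "excluded from alignment", n_missing, chain_id,
            )
        chains[kind] = chain
    return annotate_interface(
        ComplexStructure(protein=chains["protein"], rna=chains["rna"])
    )


def write_pdb(complex_: ComplexStructure, path, remarks=()) -> None:
    """Write a two-chain model as a PDB file with provenance REMARK lines."""
    serial = 0
    with open(path, "w") as fh:
        for remark in remarks:
            fh.write(f"REMARK 999 {remark}\n")
        for chain in (complex_.protein, complex_.rna):
            for res in chain.residues:
                for atom_name, xyz in res.atoms:
                    serial += 1
                    element = atom_name[0] if atom_name[0].isalpha() else atom_name[1]
                    fh.write(
                        "ATOM  {:>5} {:<4} {:>3} {}{:>4}    "
                        "{:8.3f}{:8.3f}{:8.3f}{:6.2f}{:6.2f}          {:>2}\n".format(
                            serial, atom_name[:4], res.name[:3], chain.chain_id,
                            res.residue_id, xyz[0], xyz[1], xyz[2], 1.0, 0.0, element,
                        )
                    )
            fh.write("TER\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# interface annotation

def annotate_interface(
    complex_: ComplexStructure, cutoff: float = INTERFACE_CUTOFF
) -> ComplexStructure:
    """Mark residues whose minimum heavy-atom cross-chain distance is <= cutoff."""
    p_coords, p_owner = complex_.protein.heavy_coords()
    r_coords, r_owner = complex_.rna.heavy_coords()
    interface_p, interface_r = set(), set()
    if len(p_coords) and len(r_coords):
        tree = cKDTree(r_coords)
        pairs = tree.query_ball_point(p_coords, r=cutoff)
        for p_idx, hits in enumerate(pairs):
            if hits:
                interface_p.add(int(p_owner[p_idx]))
                interface_r.update(int(r_owner[h]) for h in hits)
    return ComplexStructure(
        protein=complex_.protein,
        rna=complex_.rna,
        interface_protein=frozenset(interface_p),
        interface_rna=frozenset(interface_r),
        interface_cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# superposition and scores

def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns the proper-rotation transform (reflections corrected through the
    determinant of the SVD factors) and the minimized RMSD.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise StructureError("point sets differ in size")
    if len(moving) < 3:
        raise StructureError("need at least 3 points for superposition")
    mu_m, mu_f = moving.mean(axis=0), fixed.mean(axis=0)
    H = (moving - mu_m).T @ (fixed - mu_f)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_f - R @ mu_m
    transform = RigidTransform(rotation=R, translation=t)
    diff = transform.apply(moving) - fixed
    rmsd = float(np.sqrt((diff ** 2).sum() / len(moving)))
    return transform, rmsd


def tm_d0(l_target: int) -> float:
    return max(0.5, 1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8) if l_target > 15 else 0.5


def tm_score_from_distances(distances: np.ndarray, l_target: int) -> float:
    """TM-score sum for given aligned-pair distances, normalized by target length."""
    d0 = tm_d0(l_target)
    distances = np.asarray(distances, dtype=float)
    return float(np.sum(1.0 / (1.0 + (distances / d0) ** 2)) / l_target)


def tm_score(mapping, moving: ChainStructure, fixed: ChainStructure,
             l_target: int | None = None) -> float:
    """TM-score of ``moving`` vs ``fixed`` under a fixed residue mapping.

    Maximizes the score over iterative Kabsch superpositions seeded from
    alignment fragments of decreasing length; within each seed, pairs closer
    than d0 are kept and the fit repeated until the kept set converges.
    Normalized by the target (``fixed``) chain length unless overridden.
    """
    pairs = sorted(mapping.match_pairs)
    if len(pairs) < 3:
        raise StructureError("need at least 3 aligned pairs for TM-score")
    mov = np.array([moving.rep_coord(i) for i, _ in pairs])
    fix = np.array([fixed.rep_coord(j) for _, j in pairs])
    if any(c is None for c in mov) or any(c is None for c in fix):
        raise StructureError("aligned residue lacks a representative atom")
    L = l_target if l_target is not None else len(fixed)
    d0 = tm_d0(L)
    n = len(pairs)

    best = 0.0
    frag_len = n
    seeds = []
    while frag_len >= 4:
        step = max(1, frag_len // 2)
        for start in range(0, n - frag_len + 1, step):
            seeds.append(np.arange(start, start + frag_len))
        frag_len //= 2
    if not seeds:
        seeds = [np.arange(n)]

    for seed in seeds:
        keep = seed
        for _ in range(20):
            transform, _ = kabsch(mov[keep], fix[keep])
            d = np.linalg.norm(transform.apply(mov) - fix, axis=1)
            best = max(best, float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L))
            new_keep = np.where(d < max(d0, 0.5))[0]
            if len(new_keep) < 3:
                order = np.argsort(d)
                new_keep = order[:3]
            if len(new_keep) == len(keep) and np.array_equal(new_keep, keep):
                break
            keep = new_keep
    return min(best, 1.0)


def irmsd(a: ComplexStructure, b: ComplexStructure, protein_map, rna_map) -> float | None:
    """Interface RMSD between two complexes, or None if under-determined.

    Uses representative atoms of positions that are interface in either
    complex and aligned in both maps, superposes b's onto a's, and returns
    the minimized RMSD.
    """
    coords_a, coords_b = [], []
    for chain_map, chain_a, chain_b, int_a, int_b in (
        (protein_map, a.protein, b.protein, a.interface_protein, b.interface_protein),
        (rna_map, a.rna, b.rna, a.interface_rna, b.interface_rna),
    ):
        for i, j in sorted(chain_map.match_pairs):
            if i in int_a or j in int_b:
                ca, cb = chain_a.rep_coord(i), chain_b.rep_coord(j)
                if ca is not None and cb is not None:
                    coords_a.append(ca)
                    coords_b.append(cb)
    if len(coords_a) < 3:
        return None
    _, rmsd = kabsch(np.array(coords_b), np.array(coords_a))
    return rmsd


def ligand_rmsd(model: ComplexStructure, native: ComplexStructure) -> float:
    """RNA C3' RMSD of a model against the native after protein superposition.

    Assumes a 1:1 residue/nucleotide correspondence between model and native
    (same target molecule).
    """
    if len(model.protein) != len(native.protein) or len(model.rna) != len(native.rna):
        raise StructureError("model and native complexes do not correspond 1:1")
    p_idx = [
        k
        for k in range(len(model.protein))
        if model.protein.rep_coord(k) is not None and native.protein.rep_coord(k) is not None
    ]
    if len(p_idx) < 3:
        raise StructureError("too few usable protein residues for superposition")
    transform, _ = kabsch(
        np.array([model.protein.rep_coord(k) for k in p_idx]),
        np.array([native.protein.rep_coord(k) for k in p_idx]),
    )
    r_idx = [
        k
        for k in range(len(model.rna))
        if model.rna.rep_coord(k) is not None and native.rna.rep_coord(k) is not None
    ]
    if not r_idx:
        raise StructureError("no usable RNA nucleotides for ligand RMSD")
    model_rna = transform.apply(np.array([model.rna.rep_coord(k) for k in r_idx]))
    native_rna = np.array([native.rna.rep_coord(k) for k in r_idx])
    return float(np.sqrt(((model_rna - native_rna) ** 2).sum() / len(r_idx)))


# ---------------------------------------------------------------------------
# external aligner wrappers (TM-align / LocARNA)

_EXECUTABLES = {"tmalign": ("TMalign", "tmalign"), "locarna": ("locarna", "mlocarna")}


def external_available(kind: str, executable_path: str | None = None) -> bool:
    """Capability probe: is the external aligner on PATH (or at the given path)?"""
    if executable_path:
        return shutil.which(executable_path) is not None
    return any(shutil.which(name) for name in _EXECUTABLES.get(kind, ()))


def parse_tmalign_output(text: str):
    """Parse TM-align stdout into (alignment, tm_score normalized by chain 2)."""
    from .rna2da import GAP, PairwiseAlignment

    score = None
    lines = text.splitlines()
    for line in lines:
        if line.startswith("TM-score=") and "Chain_2" in line:
            score = float(line.split("=")[1].split()[0])
    if score is None:
        for line in lines:
            if line.startswith("TM-score="):
                score = float(line.split("=")[1].split()[0])
    aln_rows = []
    for k, line in enumerate(lines):
        if '":" denotes' in line:
            aln_rows = [lines[k + 1], lines[k + 3]]
            break
    if score is None or not aln_rows:
        raise ExternalToolError("could not parse TM-align output")
    columns = []
    i = j = 0
    for ca, cb in zip(aln_rows[0], aln_rows[1]):
        if ca != "-" and cb != "-":
            columns.append((i, j))
            i, j = i + 1, j + 1
        elif ca != "-":
            columns.append((i, GAP))
            i += 1
        elif cb != "-":
            columns.append((GAP, j))
            j += 1
    return PairwiseAlignment(aligned_pairs=tuple(columns), score=score), score


def parse_locarna_output(text: str):
    """Parse LocARNA pairwise output (Score line + gapped alignment rows)."""
    from .rna2da import GAP, PairwiseAlignment

    score = None
    rows: dict[str, str] = {}
    order: list[str] = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("Score:"):
            score = float(stripped.split(":")[1])
            continue
        fields = stripped.split()
        if len(fields) == 2 and set(fields[1]) <= set("ACGUTacgut-.~_N"):
            name, chunk = fields
            if name not in rows:
                order.append(name)
            rows[name] = rows.get(name, "") + chunk
    if score is None or len(order) < 2:
        raise ExternalToolError("could not parse LocARNA output")
    row_a, row_b = rows[order[0]], rows[order[1]]
    columns = []
    i = j = 0
    gapchars = set("-.~_")
    for ca, cb in zip(row_a, row_b):
        ga, gb = ca in gapchars, cb in gapchars
        if not ga and not gb:
            columns.append((i, j))
            i, j = i + 1, j + 1
        elif not ga:
            columns.append((i, GAP))
            i += 1
        elif not gb:
            columns.append((GAP, j))
            j += 1
    return PairwiseAlignment(aligned_pairs=tuple(columns), score=score), score


def run_external_aligner(kind: str, inputs: tuple, executable_path: str | None = None):
    """Run TM-align or LocARNA on two input files and parse the result.

    Raises :class:`ExternalToolError` when the tool is unavailable, exits
    nonzero, or emits unparseable output; callers fall back to the built-in
    aligners.
    """
    if kind not in _EXECUTABLES:
        raise ValueError(f"unknown external aligner {kind!r}")
    exe = executable_path or next(
        (shutil.which(name) for name in _EXECUTABLES[kind] if shutil.which(name)), None
    )
    if exe is None:
        raise ExternalToolError(f"{kind} executable not found")
    proc = subprocess.run(
        [exe, *map(str, inputs)], capture_output=True, text=True, check=False
    )
    if proc.returncode != 0:
        raise ExternalToolError(f"{kind} exited {proc.returncode}: {proc.stderr.strip()}")
    parser = parse_tmalign_output if kind == "tmalign" else parse_locarna_output
    try:
        return parser(proc.stdout)
    except ExternalToolError as exc:
        raise ExternalToolError(f"{kind}: {exc}") from exc
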