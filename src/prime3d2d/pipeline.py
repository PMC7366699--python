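"""Template search, model building, binding-site transfer and evaluation.

A target (protein 3D structure + RNA secondary structure, optionally RNA 3D)
is compared against a library of template complexes.  For each template the
protein similarity (TM-score) and the RNA secondary-structure identity (SSI)
are combined into the 3D2D score

    score = W * TM-score + (1 - W) * SSI

with default weight W = 0.8; templates scoring below the cutoff (default
0.45, the empirical phase-transition point at W = 0.8) are discarded.  A
surviving template yields (a) a rigid-body model, by superposing the target
protein and RNA onto the template frame, and (b) binding-site predictions,
by transferring the template's interface annotation through the alignments.

Evaluation helpers implement the top-N success rate (fraction of targets
with a model of ligand RMSD <= 10 A among the N best-scored models) and the
phase-transition analysis (per-0.05-bin fraction of template pairs whose
interface RMSD is <= 5 A, and the score above which that fraction leaves 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .metrics import confusion, evaluate
from .rna2da import GapParams, PairwiseAlignment, compute_ssi, global_align, gotoh_align
from .rna_secondary import SecondaryStructure
from .rnablosum import CombinedScorer, build_scorer, identity_matrix
from .structures3d import (
    ACCEPTABLE_LRMSD,
    ChainStructure,
    ComplexStructure,
    annotate_interface,
    kabsch,
    ligand_rmsd,
    tm_score,
)

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT = 0.8
DEFAULT_CUTOFF = 0.45

#: phase-transition 3D2D score per weight W, as determined empirically on the
#: all-to-all template-library comparison (reference data, not re-derived here)
TRANSITION_BY_WEIGHT = {0.9: 0.40, 0.8: 0.45, 0.7: 0.50, 0.6: 0.60, 0.5: 0.65, 0.4: 0.70}


class PipelineError(ValueError):
    pass


class NoTemplatesError(RuntimeError):
    """No template survived the score cutoff."""


@dataclass(frozen=True)
class TemplateEntry:
    """One library complex with its RNA secondary structure and interfaces."""

    id: str
    complex: ComplexStructure
    rna_secondary: SecondaryStructure

    def __post_init__(self):
        if len(self.rna_secondary) != len(self.complex.rna):
            raise PipelineError(
                f"template {self.id}: RNA 2D length {len(self.rna_secondary)} != "
                f"RNA chain length {len(self.complex.rna)}"
            )


@dataclass(frozen=True)
class Target:
    id: str
    protein: ChainStructure
    rna_secondary: SecondaryStructure
    rna: ChainStructure | None = None  # 3D, needed for model building only


@dataclass(frozen=True)
class TemplateHit:
    template_id: str
    tm_score: float
    ssi: float
    score3d2d: float
    protein_alignment: PairwiseAlignment
    rna_alignment: PairwiseAlignment

    def __post_init__(self):
        # score must be a convex combination of its two components
        lo = min(self.tm_score, self.ssi) - 1e-12
        hi = max(self.tm_score, self.ssi) + 1e-12
        if not lo <= self.score3d2d <= hi:
            raise PipelineError("3D2D score inconsistent with its components")


@dataclass(frozen=True)
class SitePrediction:
    protein_sites: frozenset
    rna_sites: frozenset
    support: dict = field(default_factory=dict)  # ("protein"|"rna", index) -> best score3d2d

    def sites(self, side: str) -> frozenset:
        return self.protein_sites if side == "protein" else self.rna_sites


def score_3d2d(tm: float, ssi: float, weight: float = DEFAULT_WEIGHT) -> float:
    """Combined template-ranking score W * TM-score + (1 - W) * SSI."""
    for name, value in (("tm", tm), ("ssi", ssi), ("weight", weight)):
        if not 0.0 <= value <= 1.0:
            raise PipelineError(f"{name}={value} outside [0, 1]")
    return weight * tm + (1.0 - weight) * ssi


# ---------------------------------------------------------------------------
# built-in aligners (used when TM-align / LocARNA are not wired in)

_PROTEIN_GAPS = GapParams(open_penalty=5.0, extend_penalty=1.0)


def align_proteins(target: ChainStructure, template: ChainStructure) -> tuple[PairwiseAlignment, float]:
    """Sequence-guided protein alignment + TM-score (built-in fallback).

    Residue sequences are globally aligned (match 2 / mismatch -1, affine
    gaps), the mapping restricted to residues with C-alpha coordinates, and
    the TM-score computed over it, normalized by the target length.  Parity
    with the TM-align program is not claimed.
    """
    seq_t, seq_p = target.sequence, template.sequence

    def score_fn(i, j):
        return 2.0 if seq_t[i] == seq_p[j] else -1.0

    aln = gotoh_align(list(seq_t), list(seq_p), score_fn, _PROTEIN_GAPS)
    usable_t = set(target.alignment_indices)
    usable_p = set(template.alignment_indices)
    columns = tuple(
        (i, j) for i, j in aln.aligned_pairs
        if (i is None or i in usable_t) and (j is None or j in usable_p)
    )
    mapping = PairwiseAlignment(aligned_pairs=columns, score=aln.score)
    tm = tm_score(mapping, moving=target, fixed=template, l_target=len(target))
    return mapping, tm


def default_rna_scorer(bonus: float = 0.2) -> CombinedScorer:
    return build_scorer(identity_matrix(), bonus=bonus)


def align_rnas(
    target: SecondaryStructure,
    template: SecondaryStructure,
    scorer: CombinedScorer | None = None,
) -> tuple[PairwiseAlignment, float]:
    """Structure+sequence RNA alignment and its SSI (built-in fallback)."""
    scorer = scorer or default_rna_scorer()
    aln = global_align(target, template, scorer)
    ssi = compute_ssi(aln, target.bear, template.bear)
    return aln, ssi


# ---------------------------------------------------------------------------
# template search

def search_templates(
    target: Target,
    library,
    weight: float = DEFAULT_WEIGHT,
    cutoff: float = DEFAULT_CUTOFF,
    scorer: CombinedScorer | None = None,
    protein_aligner=None,
    rna_aligner=None,
) -> list[TemplateHit]:
    """Rank library templates for a target by 3D2D score.

    Self-hits (matching id) are excluded; hits under the cutoff dropped;
    the rest sorted by score descending with ties broken by template id.
    A failing aligner skips that template with a warning.
    """
    if not library:
        raise PipelineError("empty template library")
    protein_aligner = protein_aligner or align_proteins
    rna_aligner = rna_aligner or (lambda a, b: align_rnas(a, b, scorer))
    hits = []
    for entry in library:
        if entry.id == target.id:
            continue
        try:
            p_aln, tm = protein_aligner(target.protein, entry.complex.protein)
            r_aln, ssi = rna_aligner(target.rna_secondary, entry.rna_secondary)
        except Exception as exc:  # noqa: BLE001 - one bad template must not kill the run
            logger.warning("template %s skipped: %s", entry.id, exc)
            continue
        score = score_3d2d(min(tm, 1.0), ssi, weight)
        if score < cutoff:
            continue
        hits.append(
            TemplateHit(
                template_id=entry.id,
                tm_score=min(tm, 1.0),
                ssi=ssi,
                score3d2d=score,
                protein_alignment=p_aln,
                rna_alignment=r_aln,
            )
        )
    hits.sort(key=lambda h: (-h.score3d2d, h.template_id))
    return hits


# ---------------------------------------------------------------------------
# model building and site transfer

def build_model(
    target_protein: ChainStructure,
    target_rna: ChainStructure,
    hit: TemplateHit,
    template: TemplateEntry,
) -> ComplexStructure | None:
    """Rigid-body model of the target complex in the template frame.

    The target protein is superposed on the template protein through the
    protein alignment; the target RNA through a Kabsch fit of aligned C3'
    atoms.  Returns None when either side has fewer than 3 usable aligned
    pairs.
    """
    import numpy as np

    p_pairs = [
        (i, j)
        for i, j in sorted(hit.protein_alignment.match_pairs)
        if target_protein.rep_coord(i) is not None
        and template.complex.protein.rep_coord(j) is not None
    ]
    r_pairs = [
        (i, j)
        for i, j in sorted(hit.rna_alignment.match_pairs)
        if target_rna.rep_coord(i) is not None
        and template.complex.rna.rep_coord(j) is not None
    ]
    if len(p_pairs) < 3 or len(r_pairs) < 3:
        return None
    p_transform, _ = kabsch(
        np.array([target_protein.rep_coord(i) for i, _ in p_pairs]),
        np.array([template.complex.protein.rep_coord(j) for _, j in p_pairs]),
    )
    r_transform, _ = kabsch(
        np.array([target_rna.rep_coord(i) for i, _ in r_pairs]),
        np.array([template.complex.rna.rep_coord(j) for _, j in r_pairs]),
    )
    model = ComplexStructure(
        protein=target_protein.transformed(p_transform),
        rna=target_rna.transformed(r_transform),
    )
    return annotate_interface(model)


def transfer_sites(
    hit: TemplateHit, template: TemplateEntry, target_lengths: tuple[int, int]
) -> SitePrediction:
    """Binding sites transferred from the template through the alignments.

    A target position is predicted positive iff it is aligned (non-gap on
    both sides) to a template interface position; positions aligned to
    non-interface template positions, or unaligned, are negative.
    """
    n_protein, n_rna = target_lengths
    support: dict = {}
    sides = (
        ("protein", hit.protein_alignment, template.complex.interface_protein, n_protein),
        ("rna", hit.rna_alignment, template.complex.interface_rna, n_rna),
    )
    predicted = {"protein": set(), "rna": set()}
    for side, alignment, template_interface, limit in sides:
        for i, j in alignment.match_pairs:
            if j in template_interface and 0 <= i < limit:
                predicted[side].add(i)
                key = (side, i)
                support[key] = max(support.get(key, 0.0), hit.score3d2d)
    return SitePrediction(
        protein_sites=frozenset(predicted["protein"]),
        rna_sites=frozenset(predicted["rna"]),
        support=support,
    )


def aggregate_topn(
    predictions,
    n: int,
    side: str = "protein",
    truth: set | None = None,
    universe: set | None = None,
    mode: str = "best",
) -> SitePrediction:
    """Single prediction representing the top-n templates.

    ``mode='best'`` (the benchmark convention) returns, among the n
    highest-ranked predictions, the one maximizing MCC against ``truth``;
    ties keep the higher-ranked prediction.  ``mode='union'`` is a
    label-free extension returning the union of predicted sites.
    """
    if n < 1:
        raise PipelineError("n must be >= 1")
    top = list(predictions[:n])
    if not top:
        raise NoTemplatesError("no predictions to aggregate")
    if mode == "union":
        support: dict = {}
        p_sites, r_sites = set(), set()
        for pred in top:
            p_sites |= pred.protein_sites
            r_sites |= pred.rna_sites
            for key, val in pred.support.items():
                support[key] = max(support.get(key, 0.0), val)
        return SitePrediction(frozenset(p_sites), frozenset(r_sites), support)
    if mode != "best":
        raise PipelineError(f"unknown aggregation mode {mode!r}")
    if truth is None or universe is None:
        raise PipelineError("best-mode aggregation needs truth and universe")
    best, best_mcc = None, None
    for pred in top:
        mcc = evaluate(confusion(pred.sites(side), truth, universe))["MCC"]
        if best_mcc is None or mcc > best_mcc:
            best, best_mcc = pred, mcc
    return best


# ---------------------------------------------------------------------------
# benchmark-style evaluation

def success_rate(
    ranked_models: dict,
    natives: dict,
    n: int,
    threshold: float = ACCEPTABLE_LRMSD,
) -> float:
    """Fraction of targets with >= 1 acceptable model among their top n.

    ``ranked_models`` maps target id to its score-ranked model list (may be
    empty: counts as failure); ``natives`` maps target id to the native
    complex.  A model is acceptable when its ligand RMSD is <= threshold.
    """
    if n < 1:
        raise PipelineError("n must be >= 1")
    missing = set(ranked_models) - set(natives)
    if missing:
        raise PipelineError(f"no native structure for target(s): {sorted(missing)}")
    if not ranked_models:
        raise PipelineError("no targets supplied")
    successes = 0
    for target_id, models in ranked_models.items():
        native = natives[target_id]
        for model in models[:n]:
            if model is not None and ligand_rmsd(model, native) <= threshold:
                successes += 1
                break
    return successes / len(ranked_models)


def phase_transition(
    pairs, bin_width: float = 0.05, irmsd_cut: float = 5.0
) -> tuple[pd.DataFrame, float | None]:
    """Accumulative fraction of near-native binding modes per score bin.

    ``pairs`` are (3D2D score, interface RMSD) tuples from an all-to-all
    comparison.  Scores are binned in [0, 1) with the given width (1.0 falls
    in the last bin); each bin's fraction is the share of its pairs with
    iRMSD <= the cut.  The transition point is the left edge of the
    lowest-score non-empty bin such that every non-empty bin at or above it
    has fraction > 0; None when no such bin exists.
    """
    pairs = list(pairs)
    if not pairs:
        raise PipelineError("no (score, iRMSD) pairs supplied")
    n_bins = round(1.0 / bin_width)
    counts = [0] * n_bins
    good = [0] * n_bins
    for score, rmsd in pairs:
        if not 0.0 <= score <= 1.0:
            raise PipelineError(f"score {score} outside [0, 1]")
        b = min(int(score / bin_width), n_bins - 1)
        counts[b] += 1
        if rmsd is not None and rmsd <= irmsd_cut:
            good[b] += 1
    table = pd.DataFrame(
        {
            "bin_left": [round(b * bin_width, 10) for b in range(n_bins)],
            "n_pairs": counts,
            "fraction": [g / c if c else float("nan") for g, c in zip(good, counts)],
        }
    )
    transition = None
    for b in range(n_bins - 1, -1, -1):
        if counts[b] == 0:
            continue
        if good[b] > 0:
            transition = table.loc[b, "bin_left"]
        else:
            break
    return table, transition
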