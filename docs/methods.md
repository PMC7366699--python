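# Methods

## Problem and approach

Protein–RNA complex structures are scarce relative to protein structures and
RNA secondary structures. This package models a protein–RNA complex and
predicts its binding sites *template-based*: a target (protein 3D structure +
RNA secondary structure) is compared against a library of known complexes,
and the best-matching template donates both its binding geometry (for a
rigid-body model) and its interface annotation (for per-position binding-site
predictions). The key design point is that the RNA is compared in secondary-
structure space only, so the pipeline also runs genome-wide where no RNA 3D
structure exists.

## RNA secondary-structure encoding

A structure is a sequence plus a set of non-crossing base pairs. For
alignment, each nucleotide is re-encoded into a structural alphabet where the
character identifies the containing element and its length:

* **stem** — maximal stack of pairs; length = number of stacked pairs;
* **hairpin loop** — unpaired run whose innermost enclosing pair closes a
  pair-free region;
* **internal loop / bulge** — any other enclosed unpaired run (multiloop
  segments are lumped here);
* **exterior** — unpaired run not enclosed by any pair.

Lengths are capped at 9 (longer elements share the cap's character), giving a
36-character alphabet ("BEAR-lite": stems `a–i`, hairpins `j–r`,
internal/bulge `A–I`, exterior `J–R`). The published encoding's exact table
is not redistributable; ours is injective, documented, and replaceable by a
user-supplied YAML table (`BearAlphabet.from_yaml`), which is sufficient
because every downstream computation depends only on the (type, length)
partition, not on which glyph represents it.

Pseudoknots cannot be written in plain dot-bracket; crossing pairs from CT
files are removed greedily (drop the pair crossing the most others; ties drop
the larger opening index) and logged. Indexing is 0-based in memory, 1-based
in all files.

## Substitution matrix (structure log-odds)

Training data are gapless blocks (≥ 6 columns) cut from Stockholm seed
alignments. The consensus `SS_cons` pairs are projected per row onto its
ungapped positions (pairs with a gapped side dropped), each row is encoded,
and the block columns extracted. Rows more than x % identical (structural-
alphabet identity, single linkage) form clusters weighted 1/size — the
classic BLOSUM redundancy treatment; the matrix trained at x is named by that
identity (e.g. x = 80).

Per column, weighted pairs between rows of *distinct* clusters are counted.
With observed pair frequency `q_ab` and background `p_a`, expected
frequencies are `e_aa = p_a²`, `e_ab = 2·p_a·p_b`, and scores are half-bit
log-odds `s_ab = round(2·log2(q_ab/e_ab))`, rounded half away from zero.

**Zero counts.** Observed frequencies are left unsmoothed (so small worked
examples are exactly reproducible by hand); a pair of observed characters
with zero count is scored with the pseudo-frequency `1/(N+1)` (N = total
weighted pairs), and pairs involving a never-observed character score 0.
This keeps every score finite without distorting observed statistics.

## Combined scorer and aligner

The aligner scores position pairs as

```
score(i, j) = S_struct[enc_i, enc_j] + S_nuc[nt_i, nt_j] · bonus
```

where `S_nuc` is the A/C/G/U part of NUC.4.4 (match 5, mismatch −4; ambiguity
codes are rejected) and `bonus` defaults to 0.2 — the regime that combines
sequence with secondary structure; `bonus = 0` is pure-structure alignment.
Alignment is global Needleman–Wunsch/Gotoh with affine gaps: a gap of length
L costs `open + (L−1)·extend`, defaults open 10 / extend 2, terminal gaps
penalized. Traceback ties resolve diagonal > up > left, so alignments are
reproducible. The DP is verified against exhaustive enumeration of all global
alignments for short sequences.

Two statistics summarize alignments: **SPS**, the fraction of
reference-aligned position pairs recovered by a test alignment (0 when the
reference aligns nothing), and **SSI**, the fraction of alignment columns
whose two structural characters match. SSI's denominator is the full
alignment length by default; normalizing by the shorter sequence is exposed
as an option since conventions differ.

## 3D machinery

Interfaces use the standard heavy-atom criterion: a residue or nucleotide is
a binding site iff its minimum heavy-atom distance to the other chain is
≤ 4.5 Å. Superposition is the Kabsch SVD fit with determinant correction
(proper rotations only). The TM-score uses the published distance scale
`d0 = max(0.5, 1.24·(L−15)^⅓ − 1.8)`, is normalized by the *target* length
(the chain being modeled, matching template-search use), and is maximized
over iterative fragment-seeded superpositions (seed fragments of halving
length; within each seed, pairs under d0 are kept and refit until
convergence). The built-in protein aligner is sequence-guided (global
alignment of residue letters, then TM-score over the mapping) so the pipeline
is hermetic; TM-align and LocARNA are used through subprocess wrappers when
their executables exist, with parsers tested on synthetic captures of their
output formats. Parity with TM-align is not claimed.

**Ligand RMSD** superposes model protein Cα onto native protein Cα, applies
that transform to the model RNA and reports C3′ RMSD; ≤ 10 Å is an
"acceptable" model. **Interface RMSD (iRMSD)** — conventions differ in the
literature; ours is: representative atoms of positions that are interface in
*either* complex and aligned in both chain maps, optimally superposed;
fewer than 3 usable positions yields a missing value.

## Template ranking, models, site transfer

Each template gets `score = W·TM + (1−W)·SSI` with default `W = 0.8`.
Templates under the cutoff (default 0.45) are dropped; the cutoff is the
empirical phase-transition point at W = 0.8, and the reference transition
table per W (0.9→0.40 … 0.4→0.70) ships as data, not re-derived. Ties in
ranking break lexicographically by template id. Self-hits (identical id) are
excluded. A model places the target protein and RNA into the template frame
by per-chain Kabsch fits over the aligned representative atoms (≥ 3 pairs per
chain required). Binding sites transfer through the alignments: a target
position is positive iff aligned to a template interface position; gapped or
non-interface-aligned positions are negative. Per-position confidence is the
maximum ranking score among templates voting that position positive.

The phase-transition analysis bins (score, iRMSD) pairs into 0.05-wide score
bins; the transition point is the left edge of the lowest-score non-empty bin
above which every non-empty bin has a nonzero fraction of iRMSD ≤ 5 Å pairs.
Top-N success rate counts targets with ≥ 1 acceptable model among their N
best-scored models. Best-of-top-N site prediction picks, among the N
highest-ranked templates, the prediction maximizing MCC against the labels
(ties keep the higher rank); a label-free union mode is provided as an
extension.

## Metrics

SN, SP, PRE, ACC, MCC, Strength = (SN+SP)/2, and F-measure follow the
standard formulas; AUC is the rank-based Mann–Whitney statistic with midrank
ties (via scikit-learn, cross-checked against direct pair counting). A metric
with a zero denominator is reported as 0 and flagged, so per-target
macro-averaging (the package's averaging convention) never drops targets.

## Synthetic data: what it does and does not establish

Generators are pure functions of a `FixtureSpec` (seeded RNG; seeds recorded
in file headers). The toy complex is a helix-like Cα trace with dummy CB
atoms plus an RNA C3′/O3′ trace positioned so that *exactly* the planted
positions are within 4.5 Å (contact distance 4.0 Å; non-contact nucleotides
≥ 20 Å away); generation fails if re-annotation does not recover the planted
sets. Default sizes (30 residues, 12 nucleotides, 3 contacts) keep every
test sub-second while exercising all code paths.

The template-library generator cannot plant arbitrary exact 3D2D scores: a
rigid copy with identical RNA 2D pins SSI at 1, bounding scores below by
1−W. Instead, requested scores ≥ cutoff become coordinate-noise variants
(noise ladder 0.35 Å·rank; ordering verified at generation), and requested
scores < cutoff become decoys (random-coil protein, fully unpaired RNA 2D)
verified to fall below the cutoff. The generator raises rather than deliver
a library violating the planted ordering or cutoff sides.

The Stockholm generator plants gap-free runs separated by columns gapped in
the last row; one hairpin spans the whole alignment so the gapped row's
shorter loop yields genuinely different length-coded characters inside the
blocks — without this, consensus-projected rows would be identical and the
matrix degenerate.

Green tests on these fixtures establish algorithmic correctness (exact
geometry recovery, planted orderings, formula fidelity), **not** benchmark
performance on real complexes: the geometry is not physical, the decoys are
trivially separable, and no claim about success rates or MCC on PDB-scale
data follows from them.

## Numerical choices and limitations

* Rounding of matrix scores: half away from zero (classic matrix practice).
* Score comparisons in traceback use exact float equality of identically
  computed quantities; gap-state switches (gap-in-A directly after gap-in-B)
  are allowed and each run is charged its own opening penalty.
* Degenerate inputs: empty sequences, < 3 superposition points, single-class
  AUC and empty confusion tables raise or report missing values explicitly.
* The built-in protein aligner is sequence-guided; for remote homologs with
  conserved folds but divergent sequences it will underestimate TM-scores
  relative to TM-align. Wire in the real executables for production use.
* mmCIF, flexible docking, base-pair probabilities and structure prediction
  are out of scope.
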