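# prime3d2d

Template-based protein–RNA complex modelling and binding-site prediction
from a protein 3D structure plus an RNA *secondary* structure.

Experimentally solved protein–RNA complexes are rare, but protein structures
and RNA secondary structures are plentiful. This package turns known
complexes into "3D2D" templates (protein keeps its 3D coordinates, the RNA is
reduced to its secondary structure) and ranks them for a new target with

```
3D2D score = W · TM-score + (1 − W) · SSI        (default W = 0.8)
```

where the TM-score measures protein structural similarity and SSI (secondary
structure identity) is the fraction of alignment columns whose structural-
alphabet characters match. Templates scoring below the empirical
phase-transition cutoff (0.45 at W = 0.8) are discarded; the survivors donate

* a rigid-body model of the complex (target chains superposed into the
  template frame; a model is "acceptable" when its ligand RMSD — RNA C3′
  RMSD after protein superposition — is ≤ 10 Å), and
* per-position binding-site predictions on both protein and RNA, transferred
  through the alignments from the template's ≤ 4.5 Å heavy-atom interface.

Because the RNA side needs only secondary structure, binding sites can be
predicted transcriptome-wide where no RNA 3D structure exists.

The RNA aligner is a global Needleman–Wunsch/Gotoh alignment (gap open 10,
extend 2) over a combined scorer: a BLOSUM-style log-odds matrix trained on
gapless blocks from Stockholm seed alignments, re-encoded into a per-
nucleotide structural alphabet (element type × capped length), plus the
NUC.4.4 nucleotide matrix (match 5 / mismatch −4) weighted by a `bonus`
(default 0.2; 0 = structure only). The matrix trainer, the aligner, all 3D
machinery (Kabsch, TM-score, interface and ligand RMSD) and the evaluation
metrics (SN/SP/PRE/ACC/MCC/Strength/F, AUC) are implemented here; see
`docs/methods.md` for the full model description and conventions.

## Worked example

Generate a synthetic target + template library (a rigid copy, two perturbed
variants, three decoys) and dock the target against it:

```sh
prime3d2d fixtures --preset library --seed 7 --out lib
prime3d2d dock --target-protein lib/target.pdb --target-rna lib/target.pdb \
    --target-rna-2d lib/target.dbn --library lib --out dock
cat dock/templates.tsv
```

```
rank    template  tm      ssi     score3d2d  model
1       tmpl00    1.0000  1.0000  1.0000     model_01.pdb
2       tmpl01    0.8298  1.0000  0.8639     model_02.pdb
3       tmpl02    0.5991  1.0000  0.6793     model_03.pdb
```

The rigid copy (`tmpl00`) is recovered with perfect protein (tm) and RNA
(ssi) similarity, so its 3D2D score is 1.0 and its model reproduces the
native complex (ligand RMSD 0); the noisier variants rank below it; the three
decoys scored under the 0.45 cutoff and were dropped. `dock/model_01.pdb` is
the corresponding two-chain model with the template id and score in REMARK
lines. `prime3d2d sites` produces the per-position binding-site table in the
same way without needing target RNA coordinates.

Aligning two hairpins directly (structure + sequence, identity fallback
matrix):

```sh
rna2da a.dbn b.dbn
GGGAAACCC
 ||||||||
-GGAAAACC
score   -19.8
```

Other subcommands: `prime3d2d train` (fit a substitution matrix from
Stockholm seed alignments, written in NCBI matrix text format),
`prime3d2d eval` (per-target metric table + macro-average row),
`prime3d2d fixtures` (synthetic complexes / libraries / alignments).

## Acceptance script

`scripts/acceptance.py` recomputes, by running the package's aligner and
scorer on inputs built at run time, the reference scoring constants: the
combined scorer's match and mismatch behaviour under a zeroed structure
matrix, and the default-weight 3D2D score for a perfect-protein /
zero-RNA-similarity template pair. Run it as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
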