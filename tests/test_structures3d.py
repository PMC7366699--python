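"""Interface annotation, Kabsch, TM-score, iRMSD/ligand-RMSD, tool wrappers."""

import numpy as np
import pytest

from prime3d2d.fixtures import FixtureSpec, make_toy_complex, random_rigid_transform
from prime3d2d.rna2da import GAP, PairwiseAlignment
from prime3d2d.structures3d import (
    ChainStructure,
    ComplexStructure,
    ExternalToolError,
    Residue,
    RigidTransform,
    StructureError,
    annotate_interface,
    external_available,
    irmsd,
    kabsch,
    ligand_rmsd,
    parse_locarna_output,
    parse_tmalign_output,
    read_structure,
    tm_d0,
    tm_score,
    tm_score_from_distances,
    write_pdb,
)


def _chain(coords, kind="protein", atom=None):
    atom = atom or ("CA" if kind == "protein" else "C3'")
    residues = tuple(
        Residue(residue_id=k + 1, name="GLY" if kind == "protein" else "A",
                atoms=((atom, np.asarray(c, dtype=float)),))
        for k, c in enumerate(coords)
    )
    return ChainStructure(residues=residues, kind=kind)


def _identity_map(n):
    return PairwiseAlignment(aligned_pairs=tuple((k, k) for k in range(n)), score=0.0)


class TestPdbIO:
    def test_round_trip_two_residue_fixture(self, tmp_path, toy_complex):
        complex_, _ = toy_complex
        path = tmp_path / "toy.pdb"
        write_pdb(complex_, path, remarks=["test fixture"])
        back = read_structure(path, "A", "B")
        assert len(back.protein) == len(complex_.protein)
        assert len(back.rna) == len(complex_.rna)
        np.testing.assert_allclose(
            back.protein.rep_coords, complex_.protein.rep_coords, atol=1e-3
        )
        # interface annotations regenerate identically from the coordinates
        assert back.interface_protein == complex_.interface_protein
        assert back.interface_rna == complex_.interface_rna

    def test_missing_chain_names_available(self, tmp_path, toy_complex):
        complex_, _ = toy_complex
        path = tmp_path / "toy.pdb"
        write_pdb(complex_, path)
        with pytest.raises(StructureError, match="available chains.*'A', 'B'"):
            read_structure(path, "X", "B")

    def test_residue_without_representative_excluded_from_alignment(self):
        residues = (
            Residue(residue_id=1, name="A", atoms=(("C3'", np.zeros(3)),)),
            Residue(residue_id=2, name="A", atoms=(("P", np.ones(3)),)),  # no C3'
        )
        chain = ChainStructure(residues=residues, kind="rna")
        assert chain.alignment_indices == [0]


class TestAnnotateInterface:
    @pytest.mark.parametrize("gap, expect", [(4.4, True), (4.6, False)])
    def test_cutoff_is_sharp(self, gap, expect):
        protein = _chain([(0, 0, 0), (0, 0, 3.8), (0, 0, 7.6)])
        rna = _chain([(gap, 0, 0), (50, 0, 0)], kind="rna")
        cx = annotate_interface(ComplexStructure(protein=protein, rna=rna))
        assert (0 in cx.interface_protein) is expect
        assert (0 in cx.interface_rna) is expect

    def test_distant_chains_have_empty_interface(self):
        protein = _chain([(0, 0, 0), (0, 0, 3.8), (0, 0, 7.6)])
        rna = _chain([(100, 0, 0), (104, 0, 0)], kind="rna")
        cx = annotate_interface(ComplexStructure(protein=protein, rna=rna))
        assert not cx.interface_protein and not cx.interface_rna

    def test_monotone_in_cutoff(self, rng):
        protein = _chain(rng.uniform(0, 10, (15, 3)))
        rna = _chain(rng.uniform(5, 15, (8, 3)), kind="rna")
        base = ComplexStructure(protein=protein, rna=rna)
        previous_p, previous_r = frozenset(), frozenset()
        for cutoff in (2.0, 4.5, 8.0, 15.0):
            cx = annotate_interface(base, cutoff=cutoff)
            assert previous_p <= cx.interface_protein
            assert previous_r <= cx.interface_rna
            previous_p, previous_r = cx.interface_protein, cx.interface_rna


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        transform, rmsd = kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation(self, rng):
        pts = rng.normal(size=(10, 3))
        transform, rmsd = kabsch(pts, pts + np.array([1.0, 2.0, 3.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(transform.translation, [1, 2, 3], atol=1e-9)

    def test_planted_rotation_recovered(self, rng):
        pts = rng.normal(size=(10, 3))
        planted = random_rigid_transform(rng)
        transform, rmsd = kabsch(pts, planted.apply(pts))
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(transform.rotation, planted.rotation, atol=1e-6)

    def test_noise_leaves_residual(self, rng):
        pts = rng.normal(scale=10, size=(200, 3))
        noisy = pts + rng.normal(scale=0.1, size=pts.shape)
        _, rmsd = kabsch(pts, noisy)
        # residual close to sigma * sqrt(3) for large n
        assert rmsd == pytest.approx(0.1 * np.sqrt(3), rel=0.2)

    def test_rigid_premotion_invariance(self, rng):
        pts_a = rng.normal(size=(12, 3))
        pts_b = rng.normal(size=(12, 3))
        _, rmsd0 = kabsch(pts_a, pts_b)
        moved = random_rigid_transform(rng).apply(pts_a)
        _, rmsd1 = kabsch(moved, pts_b)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)

    def test_reflection_not_allowed(self, rng):
        pts = rng.normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        transform, _ = kabsch(pts, mirrored)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0)

    def test_input_validation(self, rng):
        with pytest.raises(StructureError, match="size"):
            kabsch(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
        with pytest.raises(StructureError, match="3 points"):
            kabsch(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))

    def test_transform_inverse(self, rng):
        transform = random_rigid_transform(rng)
        pts = rng.normal(size=(7, 3))
        np.testing.assert_allclose(
            transform.inverse().apply(transform.apply(pts)), pts, atol=1e-9
        )


class TestTmScore:
    def test_self_superposition_is_one(self, rng):
        chain = _chain(rng.normal(scale=10, size=(25, 3)))
        assert tm_score(_identity_map(25), chain, chain) == pytest.approx(1.0)

    def test_rigid_copy_is_one(self, rng):
        coords = rng.normal(scale=10, size=(30, 3))
        moved = random_rigid_transform(rng).apply(coords)
        score = tm_score(_identity_map(30), _chain(moved), _chain(coords))
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_far_chains_score_near_zero(self, rng):
        a = rng.normal(scale=2, size=(20, 3))
        b = rng.normal(scale=2, size=(20, 3)) * np.array([1, -1, 1]) + 50
        score = tm_score(_identity_map(20), _chain(a), _chain(b))
        assert 0 < score < 0.35

    def test_closed_form_at_d0(self):
        # all aligned distances exactly d0: sum = n_aligned * 0.5
        L = 20
        distances = np.full(12, tm_d0(L))
        assert tm_score_from_distances(distances, L) == pytest.approx(12 / L * 0.5)

    def test_needs_three_pairs(self, rng):
        chain = _chain(rng.normal(size=(5, 3)))
        short = PairwiseAlignment(aligned_pairs=((0, 0), (1, 1)), score=0.0)
        with pytest.raises(StructureError, match="3 aligned"):
            tm_score(short, chain, chain)

    def test_bounded_by_one(self, rng):
        for _ in range(5):
            coords = rng.normal(scale=5, size=(10, 3))
            noisy = coords + rng.normal(scale=1.0, size=coords.shape)
            score = tm_score(_identity_map(10), _chain(noisy), _chain(coords))
            assert 0 < score <= 1.0


class TestIrmsd:
    def test_identical_complexes(self, toy_complex):
        cx, _ = toy_complex
        maps = (_identity_map(len(cx.protein)), _identity_map(len(cx.rna)))
        assert irmsd(cx, cx, *maps) == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_moved_copy(self, toy_complex, rng):
        cx, _ = toy_complex
        moved = annotate_interface(cx.transformed(random_rigid_transform(rng)))
        maps = (_identity_map(len(cx.protein)), _identity_map(len(cx.rna)))
        assert irmsd(cx, moved, *maps) == pytest.approx(0.0, abs=1e-7)

    def test_displaced_rna_gives_known_value(self):
        # protein: 4 interface points at the corners of a square (z=0);
        # RNA: 2 interface points; complex b displaces the RNA by 3 A in z.
        protein = _chain([(0, 0, 0), (10, 0, 0), (0, 10, 0), (10, 10, 0)])
        rna_a = _chain([(4, 5, 1.0), (6, 5, 1.0)], kind="rna")
        rna_b = _chain([(4, 5, 4.0), (6, 5, 4.0)], kind="rna")
        a = ComplexStructure(protein=protein, rna=rna_a,
                             interface_protein=frozenset(range(4)),
                             interface_rna=frozenset(range(2)))
        b = ComplexStructure(protein=protein, rna=rna_b,
                             interface_protein=frozenset(range(4)),
                             interface_rna=frozenset(range(2)))
        maps = (_identity_map(4), _identity_map(2))
        value = irmsd(a, b, *maps)
        # independent oracle: grid-search over rigid motions is unnecessary --
        # by symmetry the optimum shifts the 3 A displacement equally across
        # the 6 points: residual per RNA point 2 A (4/6*3), per protein 1 A
        expected = np.sqrt((4 * 1.0**2 + 2 * 2.0**2) / 6)
        assert value == pytest.approx(expected, abs=1e-2)

    def test_too_few_positions_is_missing(self):
        protein = _chain([(0, 0, 0), (10, 0, 0)])
        rna = _chain([(4, 5, 1.0)], kind="rna")
        cx = ComplexStructure(protein=protein, rna=rna,
                              interface_protein=frozenset({0}),
                              interface_rna=frozenset({0}))
        assert irmsd(cx, cx, _identity_map(2), _identity_map(1)) is None


class TestLigandRmsd:
    def test_identity(self, toy_complex):
        cx, _ = toy_complex
        assert ligand_rmsd(cx, cx) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_rna_translation_survives_protein_fit(self, toy_complex):
        cx, _ = toy_complex
        shift = RigidTransform(rotation=np.eye(3), translation=np.array([2.0, 0, 0]))
        model = ComplexStructure(protein=cx.protein, rna=cx.rna.transformed(shift))
        assert ligand_rmsd(model, cx) == pytest.approx(2.0, abs=1e-9)

    def test_joint_rigid_motion_invariance(self, toy_complex, rng):
        cx, _ = toy_complex
        moved = cx.transformed(random_rigid_transform(rng))
        assert ligand_rmsd(moved, cx) == pytest.approx(0.0, abs=1e-7)

    def test_correspondence_mismatch_rejected(self, toy_complex):
        cx, _ = toy_complex
        truncated = ComplexStructure(
            protein=cx.protein,
            rna=ChainStructure(residues=cx.rna.residues[:-1], kind="rna"),
        )
        with pytest.raises(StructureError, match="1:1"):
            ligand_rmsd(truncated, cx)

    def test_acceptable_threshold_classification(self, toy_complex):
        cx, _ = toy_complex
        for shift, acceptable in ((9.9, True), (10.1, False)):
            t = RigidTransform(rotation=np.eye(3), translation=np.array([0, 0, shift]))
            model = ComplexStructure(protein=cx.protein, rna=cx.rna.transformed(t))
            assert (ligand_rmsd(model, cx) <= 10.0) is acceptable


SYNTHETIC_TMALIGN_OUTPUT = """\
 *********************************************************************
 * TM-align: synthetic capture for parser testing                    *
 *********************************************************************

Name of Chain_1: a.pdb
Name of Chain_2: b.pdb
Length of Chain_1: 6 residues
Length of Chain_2: 5 residues

Aligned length= 5, RMSD= 1.20, Seq_ID=n_identical/n_aligned= 0.800
TM-score= 0.71234 (if normalized by length of Chain_1)
TM-score= 0.81234 (if normalized by length of Chain_2)

(":" denotes residue pairs of d < 5.0 A, "." denotes other aligned residues)
GAVLI-K
::::: .
GAVLIW-

"""

SYNTHETIC_LOCARNA_OUTPUT = """\
Score: 123

seqA ACGU-ACG
seqB ACGUUAC-
"""


class TestExternalWrappers:
    def test_probe_for_missing_tool_is_false(self):
        assert external_available("tmalign", executable_path="/nonexistent/TMalign") is False

    def test_parse_tmalign_synthetic_fixture(self):
        aln, score = parse_tmalign_output(SYNTHETIC_TMALIGN_OUTPUT)
        assert score == pytest.approx(0.81234)  # normalized by chain 2
        # hand-read mapping: 5 aligned columns, one gap on each side
        assert aln.match_pairs == {(0, 0), (1, 1), (2, 2), (3, 3), (4, 4)}
        assert (5, GAP) not in aln.match_pairs
        assert aln.aligned_pairs[5] == (GAP, 5) or (5, GAP) in aln.aligned_pairs

    def test_parse_locarna_synthetic_fixture(self):
        aln, score = parse_locarna_output(SYNTHETIC_LOCARNA_OUTPUT)
        assert score == 123
        # round-trip: regenerating the gapped rows from the pairs matches
        row_a = "".join("-" if i is GAP else "ACGUACG"[i] for i, _ in aln.aligned_pairs)
        row_b = "".join("-" if j is GAP else "ACGUUAC"[j] for _, j in aln.aligned_pairs)
        assert row_a == "ACGU-ACG"
        assert row_b == "ACGUUAC-"

    def test_unparseable_output_raises(self):
        with pytest.raises(ExternalToolError):
            parse_tmalign_output("garbage\n")
        with pytest.raises(ExternalToolError):
            parse_locarna_output("garbage\n")


class TestFixtureGeometry:
    def test_planted_interface_recovered(self):
        spec = FixtureSpec(seed=3, planted_interface_protein=(2, 8, 14, 21),
                           planted_interface_rna=(0, 3, 7, 11))
        cx, _ = make_toy_complex(spec)
        assert cx.interface_protein == frozenset({2, 8, 14, 21})
        assert cx.interface_rna == frozenset({0, 3, 7, 11})

    def test_same_seed_reproducible(self, tmp_path):
        spec = FixtureSpec(seed=9)
        make_toy_complex(spec, out_dir=tmp_path / "a")
        make_toy_complex(spec, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "complex.pdb").read_text() == \
            (tmp_path / "b" / "complex.pdb").read_text()
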