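"""Global alignment, position maps, and the homology gate."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from motorsnp import (
    AlignmentParams,
    HomologyGate,
    IndelEvent,
    SyntheticFamilySpec,
    VariantRecord,
    align_to_reference,
    fixture_mapped_position,
    generate_isoform_family,
    map_position,
    parse_substitution,
)
from motorsnp.variant_ingest import PositionNotation

from oracles import brute_force_global_score

AA = list("ACDEFGHIKLMNPQRSTVWY")


def biopython_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def make_record(native, pos, sub="A", rs=1, isoform="iso"):
    if sub == native:
        sub = "V" if native != "V" else "A"
    return VariantRecord(
        rs_id=rs, gene=isoform, isoform=isoform, native_residue=native,
        substituted_residues=(sub,), isoform_positions=(pos,),
    )


class TestAlignToReference:
    def test_identical_sequences_give_identity_map(self):
        seq = "MKVLATPQRSWEDFGHIKLMNPQRSTVWYA"
        amap = align_to_reference(seq, seq)
        assert amap.percent_identity == 100.0
        assert amap.pairs == {i: i for i in range(1, len(seq) + 1)}

    def test_internal_insertion_offsets_downstream_positions(self):
        # child carries a 7-residue insert after position 10; every child
        # position past the insert maps back with offset -7
        parent = "MKVLATPQRSWEDFGHIKLMNPQRSTVWYA"
        child = parent[:10] + "GGSGGSG" + parent[10:]
        amap = align_to_reference(child, parent)
        for p in range(1, 11):
            assert amap.pairs[p] == p
        for p in range(18, len(child) + 1):
            assert amap.pairs[p] == p - 7
        assert all(amap.pairs.get(p) is None for p in range(11, 18))

    def test_score_matches_brute_force_and_library_oracles(self):
        rng = np.random.default_rng(42)
        aligner = biopython_aligner()
        for _ in range(200):
            n, m = rng.integers(1, 61, size=2)
            a = "".join(rng.choice(AA, n))
            b = "".join(rng.choice(AA, m))
            amap = align_to_reference(a, b)
            assert amap.score == pytest.approx(brute_force_global_score(a, b))
            assert amap.score == pytest.approx(aligner.score(a, b))

    def test_traceback_score_is_self_consistent(self):
        # the emitted columns must re-score to the reported optimum
        matrix = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(7)
        for _ in range(50):
            n, m = rng.integers(1, 61, size=2)
            a = "".join(rng.choice(AA, n))
            b = "".join(rng.choice(AA, m))
            amap = align_to_reference(a, b)
            score, in_gap = 0.0, None
            for ci, cj in amap.columns:
                if ci is not None and cj is not None:
                    score += matrix[a[ci - 1], b[cj - 1]]
                    in_gap = None
                else:
                    state = "x" if cj is None else "y"
                    score += -1.0 if in_gap == state else -11.0
                    in_gap = state
            assert score == pytest.approx(amap.score)

    def test_monotone_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = "".join(rng.choice(AA, 40))
            b = "".join(rng.choice(AA, 40))
            pairs = sorted(align_to_reference(a, b).pairs.items())
            iso, ref = zip(*pairs)
            assert list(iso) == sorted(iso)
            assert list(ref) == sorted(set(ref))  # strictly increasing, no reuse

    def test_determinism(self):
        rng = np.random.default_rng(11)
        a = "".join(rng.choice(AA, 80))
        b = "".join(rng.choice(AA, 80))
        m1, m2 = align_to_reference(a, b), align_to_reference(a, b)
        assert m1.columns == m2.columns and m1.score == m2.score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_to_reference("", "MKVL")

    def test_low_homology_flag(self):
        amap = align_to_reference("W" * 60, "P" * 60)
        assert amap.low_homology

    def test_synthetic_family_truth_recovered_outside_indel_windows(self):
        spec = SyntheticFamilySpec(
            reference_length=500,
            n_isoforms=2,
            target_identity=0.9,
            indel_events=(IndelEvent(200, 7, "insert"), IndelEvent(350, 4, "delete")),
            seed=5,
        )
        family = generate_isoform_family(spec)
        for name, seq in family.isoforms.items():
            amap = align_to_reference(seq, family.reference_seq)
            disturbed = family.indel_disturbed(name)
            truth = family.truth_maps[name]
            for iso_pos, ref_pos in truth.items():
                if ref_pos is None or ref_pos in disturbed:
                    continue
                assert amap.pairs.get(iso_pos) == ref_pos


class TestMapPosition:
    def test_native_differing_from_reference_is_flagged(self):
        # an aspartate in the isoform sits where the reference has glutamate
        ref = "MKVLATPQRSWEDFGHIKLM"
        assert ref[11] == "E"
        iso = ref[:11] + "D" + ref[12:]
        amap = align_to_reference(iso, ref)
        mp = map_position(amap, make_record("D", 12))
        assert mp.status == "mapped"
        assert mp.reference_position == 12
        assert mp.reference_native_residue == "E"
        assert mp.native_differs

    def test_self_map_keeps_position_without_differs_flag(self):
        ref = "MKVLATPQRSWEDFGHIKLM"
        amap = align_to_reference(ref, ref)
        mp = map_position(amap, make_record("S", 10))
        assert (mp.reference_position, mp.native_differs) == (10, False)

    def test_upstream_bound_notation_is_unmappable(self):
        native, subs, notation, positions, bound, rng = parse_substitution("P(<82)L")
        rec = VariantRecord(
            rs_id=2, gene="g", isoform="iso", native_residue=native,
            substituted_residues=subs, isoform_positions=positions,
            notation=notation, upstream_bound=bound, ambiguous_range=rng,
        )
        ref = "MKVLATPQRSWEDFGHIKLM"
        mp = map_position(align_to_reference(ref, ref), rec)
        assert mp.status == "unmappable" and mp.reference_position is None

    def test_position_beyond_isoform_length_errors(self):
        ref = "MKVLATPQRSWEDFGHIKLM"
        amap = align_to_reference(ref, ref)
        with pytest.raises(ValueError, match="beyond"):
            map_position(amap, make_record("A", 99))

    def test_position_in_gap_is_unmappable(self):
        parent = "MKVLATPQRSWEDFGHIKLMNPQRSTVWYA"
        child = parent[:10] + "GGSGGSG" + parent[10:]
        amap = align_to_reference(child, parent)
        inserted = child[12]
        mp = map_position(amap, make_record(inserted, 13))
        assert mp.status == "unmappable"

    def test_local_identity_gate(self):
        # identical termini, all-mismatch middle (a proline run against a
        # proline-free reference keeps the diagonal uniquely optimal):
        # positions inside the mismatch window fail a strict local-identity
        # floor but pass a lax one
        ref = ("ACDEFGHIKLMNQRSTVWY" * 7)[:120]
        iso = ref[:50] + "P" * 20 + ref[70:]
        amap = align_to_reference(iso, ref)
        assert amap.pairs.get(60) == 60
        native = iso[59]
        strict = map_position(amap, make_record(native, 60), HomologyGate(21, 80.0))
        lax = map_position(amap, make_record(native, 60), HomologyGate(21, 0.0))
        assert strict.status == "unmappable"
        assert lax.status == "mapped"

    def test_alternative_frames_resolve_by_native_residue(self):
        # a record reported in two numbering frames 7 apart: the frame whose
        # isoform residue matches the native wins
        parent = "MKVLATPQRSWEDFGHIKLMNPQRSTVWYA"
        child = parent[:10] + "GGSGGSG" + parent[10:]
        amap = align_to_reference(child, parent)
        native = child[24]  # position 25 == parent position 18
        rec = VariantRecord(
            rs_id=3, gene="g", isoform="iso", native_residue=native,
            substituted_residues=("A" if native != "A" else "V",),
            isoform_positions=(18, 25) if child[17] != native else (25,),
        )
        mp = map_position(amap, rec)
        assert mp.status == "mapped"
        assert mp.reference_position == 18


class TestFixtureMapping:
    def test_printed_position_accepted_directly(self):
        rec = make_record("D", 108, "E")
        mp = fixture_mapped_position(rec, "E")
        assert (mp.reference_position, mp.reference_native_residue) == (108, "E")
        assert mp.native_differs

    def test_bound_notation_unmappable(self):
        rec = VariantRecord(
            rs_id=4, gene="g", isoform="iso", native_residue="P",
            substituted_residues=("L",), isoform_positions=(),
            notation=PositionNotation.UPSTREAM_BOUND, upstream_bound=82,
        )
        assert fixture_mapped_position(rec, None).status == "unmappable"
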