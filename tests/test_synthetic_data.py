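"""Synthetic family generation, variant planting, and the dialect round trip."""

import math

import numpy as np
import pytest

from motorsnp import (
    DialectOptions,
    IndelEvent,
    PlantSpec,
    SyntheticFamilySpec,
    consolidate_clusters,
    emit_cluster_table,
    generate_isoform_family,
    parse_cluster_table,
    plant_variants,
)


def family_spec(**kw):
    base = dict(reference_length=200, n_isoforms=2, target_identity=1.0, seed=0)
    base.update(kw)
    return SyntheticFamilySpec(**base)


class TestGenerateFamily:
    def test_full_identity_reproduces_reference(self):
        fam = generate_isoform_family(family_spec())
        for name, seq in fam.isoforms.items():
            assert seq == fam.reference_seq
            assert fam.truth_maps[name] == {i: i for i in range(1, 201)}
            assert fam.realized_identity[name] == 1.0

    def test_insertion_offsets_truth_map(self):
        fam = generate_isoform_family(
            family_spec(indel_events=(IndelEvent(50, 7, "insert"),))
        )
        tm = fam.truth_maps["iso1"]
        assert all(tm[p] == p for p in range(1, 50))
        assert all(tm[p] is None for p in range(50, 57))
        assert all(tm[p] == p - 7 for p in range(57, 208))

    def test_deletion_shifts_truth_map(self):
        fam = generate_isoform_family(
            family_spec(indel_events=(IndelEvent(50, 5, "delete"),))
        )
        tm = fam.truth_maps["iso1"]
        assert tm[49] == 49
        assert tm[50] == 55
        assert len(fam.isoforms["iso1"]) == 195

    def test_realized_identity_within_binomial_interval(self):
        fam = generate_isoform_family(
            family_spec(reference_length=500, target_identity=0.90, seed=3)
        )
        half_width = 2.58 * math.sqrt(0.9 * 0.1 / 500)
        for name in fam.isoforms:
            assert abs(fam.realized_identity[name] - 0.90) < half_width

    def test_same_seed_is_byte_identical(self):
        a = generate_isoform_family(family_spec(target_identity=0.9, seed=7))
        b = generate_isoform_family(family_spec(target_identity=0.9, seed=7))
        assert a.reference_seq == b.reference_seq and a.isoforms == b.isoforms

    def test_out_of_bounds_indel_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            family_spec(indel_events=(IndelEvent(198, 5, "delete"),))

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            family_spec(reference_length=30)

    def test_isoform_restricted_indel(self):
        fam = generate_isoform_family(
            family_spec(indel_events=(IndelEvent(50, 7, "insert", ("iso2",)),))
        )
        assert len(fam.isoforms["iso1"]) == 200
        assert len(fam.isoforms["iso2"]) == 207


class TestPlantVariants:
    def test_zero_rates_give_empty_table(self, model):
        fam = generate_isoform_family(family_spec(reference_length=813))
        variants, truth = plant_variants(fam, model, PlantSpec({"sh3": 0.0}, seed=1))
        assert variants == [] and truth.empty

    def test_poisson_mean_on_a_50_residue_domain(self, model):
        # sh3 spans 51 residues; use a synthetic 50-residue region via loop2+
        fam = generate_isoform_family(family_spec(reference_length=813))
        rate, extent = 0.1, model.domain("sh3").extent
        counts = [
            len(
                plant_variants(fam, model, PlantSpec({"sh3": rate}, seed=s))[0]
            )
            for s in range(200)
        ]
        expected = rate * extent
        se = math.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_disease_fraction_one_flags_everything(self, model):
        fam = generate_isoform_family(family_spec(reference_length=813))
        variants, _ = plant_variants(
            fam, model, PlantSpec({"u50": 0.1}, disease_fraction=1.0, seed=2)
        )
        assert variants and all(v.disease for v in variants)
        assert all(v.true_category == "disease_implicated" for v in variants)

    def test_truth_labels_match_model(self, model):
        fam = generate_isoform_family(family_spec(reference_length=813))
        variants, _ = plant_variants(
            fam, model, PlantSpec({"converter": 0.2}, disease_fraction=0.0, seed=3)
        )
        assert variants
        assert all(v.true_group == "converter" for v in variants)
        assert all(716 <= v.reference_position <= 772 for v in variants)

    def test_ahp_mixture_recovers_generator_mean(self, model):
        fam = generate_isoform_family(family_spec(reference_length=813))
        spec = PlantSpec(
            {"u50": 0.5, "n_term": 0.5, "l50": 0.5},
            ahp_missing_p=0.3,
            ahp_zero_p=0.2,
            ahp_mean=5.0,
            seed=4,
        )
        variants, _ = plant_variants(fam, model, spec)
        positive = [v.ahp for v in variants if v.ahp not in (None, 0.0)]
        assert len(positive) > 80
        # exponential component, mean 5 (the cap at 50 is a ~e-10 correction)
        assert abs(np.mean(positive) - 5.0) < 3 * 5.0 / math.sqrt(len(positive))
        missing = sum(v.ahp is None for v in variants) / len(variants)
        assert abs(missing - 0.3) < 0.1

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            PlantSpec({"sh3": 0.1}, disease_fraction=1.5)
        with pytest.raises(ValueError, match="negative"):
            PlantSpec({"sh3": -0.1})


class TestDialect:
    def test_empty_table_is_header_only(self):
        text = emit_cluster_table([], DialectOptions())
        assert text.splitlines() == ["\t".join(DialectOptions().header)]

    def test_alternative_frame_rows_differ_by_insert_length(self, model):
        fam = generate_isoform_family(family_spec(reference_length=813))
        variants, _ = plant_variants(fam, model, PlantSpec({"sh3": 0.1}, seed=5))
        dialect = DialectOptions(alt_frame_offset={"iso1": 7, "iso2": 7})
        rows, errors = parse_cluster_table(emit_cluster_table(variants, dialect))
        assert not errors
        for v in variants:
            positions = {r.peptide_position for r in rows if r.rs_id == v.rs_id}
            assert positions == {v.isoform_position, v.isoform_position + 7}

    def test_round_trip_recovers_planted_set(self, model):
        fam = generate_isoform_family(family_spec(reference_length=813, seed=6))
        variants, _ = plant_variants(
            fam, model, PlantSpec({"sh3": 0.1, "u50": 0.05}, seed=6)
        )
        assert variants
        rows, errors = parse_cluster_table(emit_cluster_table(variants, DialectOptions()))
        assert not errors
        records = {r.rs_id: r for r in consolidate_clusters(rows)}
        assert len(records) == len(variants)
        for v in variants:
            rec = records[v.rs_id]
            assert rec.native_residue == v.native_residue
            assert rec.substituted_residues == tuple(sorted(v.substituted_residues))
            assert rec.isoform_positions == (v.isoform_position,)
            assert rec.isoform == v.isoform

    def test_same_seed_emits_identical_bytes(self, model):
        def render(seed):
            fam = generate_isoform_family(family_spec(reference_length=813, seed=seed))
            variants, _ = plant_variants(fam, model, PlantSpec({"sh3": 0.1}, seed=seed))
            return emit_cluster_table(variants, DialectOptions())

        assert render(9) == render(9)
        assert render(9) != render(10)

    def test_configurable_header_and_arrow(self, model):
        fam = generate_isoform_family(family_spec())
        variants, _ = plant_variants(fam, model, PlantSpec({"sh3": 0.2}, seed=11))
        dialect = DialectOptions(
            header=("cluster", "gene", "fn", "base", "aa", "pos"), arrow="->"
        )
        text = emit_cluster_table(variants, dialect)
        assert text.startswith("cluster\tgene\tfn\tbase\taa\tpos")
        rows, errors = parse_cluster_table(text)
        assert not errors and len({r.rs_id for r in rows}) == len(variants)
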