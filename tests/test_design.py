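"""Primer/probe design, Tm thermodynamics, in-silico PCR, assay sheets."""

import dataclasses
import json

import pytest

import breaktracer as bt
from breaktracer.design import (
    NN_DH,
    NN_DS,
    gc_fraction,
    max_homopolymer_run,
    complementarity_score,
)
from breaktracer.junction import revcomp


def nn_tm_oracle(seq, na_mM=50.0, oligo_nM=250.0):
    """Independent hand-summed nearest-neighbor Tm (same published tables)."""
    import math

    dh = sum(NN_DH[seq[i : i + 2]] for i in range(len(seq) - 1))
    ds = sum(NN_DS[seq[i : i + 2]] for i in range(len(seq) - 1))
    for t in (seq[0], seq[-1]):
        dh += 0.1 if t in "GC" else 2.3
        ds += -2.8 if t in "GC" else 4.1
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return dh * 1000.0 / (ds + 1.987 * math.log(oligo_nM * 1e-9 / 4.0)) - 273.15


class TestMeltingTemperature:
    def test_matches_hand_summed_oracle(self):
        seq = "AACGTACGTACGTACGTACG"
        # non-self-complementary check sequence
        assert seq != revcomp(seq)
        assert bt.melting_temperature(seq, 50, 250) == pytest.approx(
            nn_tm_oracle(seq), abs=0.01
        )

    @pytest.mark.parametrize(
        "seq",
        ["AGTTCTTCTGTATGGAGAGAGGT", "TGATGGTACTGAGGCTGTGG", "TTTAAACCACAGAGTGCGCC"],
    )
    def test_matches_independent_nn_implementation(self, seq):
        """Cross-check against an established NN Tm implementation."""
        from Bio.SeqUtils import MeltingTemp as mt

        ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=125, dnac2=125,
                       saltcorr=5)
        assert bt.melting_temperature(seq, 50, 250) == pytest.approx(ref, abs=0.01)

    def test_gc_raises_tm(self):
        assert bt.melting_temperature("GCGCGCGCGCGC") > bt.melting_temperature(
            "ATATATATATAT"
        )

    def test_short_sequence_rejected(self):
        with pytest.raises(bt.ValidationError):
            bt.melting_temperature("ACGT")

    def test_ambiguous_base_rejected(self):
        with pytest.raises(bt.ValidationError):
            bt.melting_temperature("ACGTNACGTACG")

    def test_salt_dependence_monotone(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert bt.melting_temperature(seq, 100) > bt.melting_temperature(seq, 50)


class TestPrimerEnumeration:
    def test_candidates_pass_brute_force_recheck(self, junction_ref):
        c = bt.DesignConstraints()
        for side in ("5prime", "3prime"):
            cands = bt.enumerate_primer_candidates(junction_ref, side, c)
            assert cands, side
            for o in cands:
                window = junction_ref.sequence[o.start - 1 : o.end]
                assert o.sequence == (window if o.strand == "+" else revcomp(window))
                assert c.primer_min_len <= len(o) <= c.primer_max_len
                assert c.gc_min <= gc_fraction(o.sequence) <= c.gc_max
                assert max_homopolymer_run(o.sequence) <= c.max_run
                assert abs(o.tm_C - c.tm_target_C) <= c.tm_tolerance_C
                if side == "5prime":
                    assert o.end <= junction_ref.junction_offset
                else:
                    assert o.start >= junction_ref.junction_offset + 1

    def test_no_candidate_overlaps_junction(self, junction_ref):
        off = junction_ref.junction_offset
        for side in ("5prime", "3prime"):
            for o in bt.enumerate_primer_candidates(junction_ref, side):
                assert not (o.start <= off < o.end)

    def test_homopolymer_flank_yields_empty_list(self):
        ref = bt.JunctionReference(
            sequence="A" * 300 + "T" * 300,
            junction_offset=300,
            flank_len=300,
            provenance=(
                bt.junction.SegmentProvenance("chrA", 1, 300, "+"),
                bt.junction.SegmentProvenance("chrB", 1, 300, "+"),
            ),
        )
        assert bt.enumerate_primer_candidates(ref, "5prime") == []


class TestProbePlacement:
    def test_every_overlap_value_represented(self, junction_ref):
        c = bt.DesignConstraints()
        probes = bt.place_probe(junction_ref, "+", c)
        ks = {bt.probe_overlap_3prime(p, junction_ref.junction_offset) for p in probes}
        assert ks == {2, 3, 4, 5, 6}
        for p in probes:
            assert p.start <= junction_ref.junction_offset < p.end
            assert p.sequence[0] != "G"

    def test_overlap_beyond_six_never_returned(self, junction_ref):
        for strand in "+-":
            for p in bt.place_probe(junction_ref, strand):
                k = bt.probe_overlap_3prime(p, junction_ref.junction_offset)
                assert 2 <= k <= 6

    def test_infeasible_geometry_yields_empty(self):
        ref = bt.JunctionReference(
            sequence="ACGTACGTAC",
            junction_offset=1,
            flank_len=5,
            provenance=(
                bt.junction.SegmentProvenance("chrA", 1, 1, "+"),
                bt.junction.SegmentProvenance("chrB", 1, 9, "+"),
            ),
        )
        assert bt.place_probe(ref, "+") == []


class TestDesignAssay:
    def test_output_passes_validator(self, junction_ref, assay):
        report = bt.validate_assay(assay, junction_ref)
        assert all(report.values()), report

    def test_deterministic(self, junction_ref):
        a1 = bt.design_assay(junction_ref)
        a2 = bt.design_assay(junction_ref)
        assert a1 == a2

    def test_annealing_tier_nearest_mean_tm(self, assay):
        mean_tm = (assay.fwd_primer.tm_C + assay.rev_primer.tm_C) / 2
        tiers = bt.DesignConstraints().annealing_tiers_C
        assert assay.annealing_temp_C == min(tiers, key=lambda t: abs(t - mean_tm))

    def test_all_n_flank_gives_no_assay_error(self):
        ref = bt.JunctionReference(
            sequence="N" * 300 + "ACGT" * 75,
            junction_offset=300,
            flank_len=300,
            provenance=(
                bt.junction.SegmentProvenance("chrA", 1, 300, "+"),
                bt.junction.SegmentProvenance("chrB", 1, 300, "+"),
            ),
        )
        with pytest.raises(bt.NoAssayError) as exc:
            bt.design_assay(ref)
        assert exc.value.stage == "fwd_primers"


class TestInSilicoPcr:
    def test_single_product_on_fusion_template(self, junction_ref, assay):
        products = bt.in_silico_pcr(junction_ref.sequence, assay)
        assert len(products) == 1
        start, end, length = products[0]
        assert length == assay.amplicon_length
        assert (start, end) == (assay.amplicon_start, assay.amplicon_end)

    def test_no_product_on_wild_type_chromosomes(self, toy_genome, assay):
        assert bt.in_silico_pcr(toy_genome["chrA"], assay) == []
        assert bt.in_silico_pcr(toy_genome["chrB"], assay) == []

    def test_template_without_primers_empty(self, assay):
        assert bt.in_silico_pcr("ACGT" * 100, assay) == []

    def test_product_found_on_reverse_complement_template(self, junction_ref, assay):
        products = bt.in_silico_pcr(revcomp(junction_ref.sequence), assay)
        assert len(products) == 1
        assert products[0][2] == assay.amplicon_length

    def test_internal_mismatch_tolerance(self, junction_ref, assay):
        f = assay.fwd_primer
        template = junction_ref.sequence
        i = f.start - 1 + len(f) // 2  # internal base of the fwd site
        mutated = template[:i] + ("A" if template[i] != "A" else "C") + template[i + 1:]
        assert bt.in_silico_pcr(mutated, assay, max_mismatches=0) == []
        assert len(bt.in_silico_pcr(mutated, assay, max_mismatches=1)) == 1

    def test_three_prime_terminal_mismatch_always_blocks(self, junction_ref, assay):
        f = assay.fwd_primer
        template = junction_ref.sequence
        i = f.end - 1  # 3'-terminal base of the fwd site
        mutated = template[:i] + ("A" if template[i] != "A" else "C") + template[i + 1:]
        assert bt.in_silico_pcr(mutated, assay, max_mismatches=2) == []

    def test_empty_template_rejected(self, assay):
        with pytest.raises(bt.ValidationError):
            bt.in_silico_pcr("", assay)


class TestValidateAssay:
    def test_probe_shifted_past_window_fails_overlap_rule(self, junction_ref, assay):
        shifted = dataclasses.replace(
            assay,
            probe=dataclasses.replace(
                assay.probe, start=assay.probe.start + 5, end=assay.probe.end + 5
            ),
        )
        report = bt.validate_assay(shifted, junction_ref)
        assert not report["probe_3prime_overlap_2_6"]

    def test_swapped_primers_fail_side_rules(self, junction_ref, assay):
        swapped = dataclasses.replace(
            assay, fwd_primer=assay.rev_primer, rev_primer=assay.fwd_primer
        )
        report = bt.validate_assay(swapped, junction_ref)
        assert not report["fwd_primer_on_5prime_side"]
        assert not report["rev_primer_on_3prime_side"]


class TestAssaySheetAndProtocol:
    def test_bundled_sheet_byte_identical_round_trip(self, tmp_path):
        from importlib import resources

        src = resources.files("breaktracer").joinpath("data/ewsfli1_assays.tsv")
        original = src.read_bytes()
        rows = bt.bundled_ewsfli1_sheet()
        assert len(rows) == 6
        out = tmp_path / "sheet.tsv"
        bt.emit_assay_sheet(rows, out)
        assert out.read_bytes() == original

    def test_empty_sheet_rejected(self, tmp_path):
        with pytest.raises(bt.ValidationError):
            bt.emit_assay_sheet([], tmp_path / "empty.tsv")

    def test_designed_assay_row_round_trips(self, assay, implanted, tmp_path):
        row = bt.assay_to_sheet_row(assay, implanted.spec, "SIM")
        out = tmp_path / "one.tsv"
        bt.emit_assay_sheet([row], out)
        (again,) = bt.read_assay_sheet(out)
        assert again == row
        assert again.junction_spec() == implanted.spec

    def test_protocol_structure(self, assay):
        protocol = bt.emit_protocol(assay)
        assert protocol.cycle_count == 40
        temps = [s["temperature_C"] for s in protocol.steps]
        assert temps == [96.0, 94.0, assay.annealing_temp_C, 98.0, 4.0]
        assert protocol.steps[0]["duration_s"] == 600
        assert protocol.steps[1]["duration_s"] == 30
        assert protocol.steps[3]["duration_s"] == 600
        payload = json.loads(protocol.to_json())
        assert len(payload["steps"]) == 5


def test_complementarity_score_known_cases():
    # the central ACGT stretches can pair (ACGT is its own reverse complement)
    assert complementarity_score("CCACGTCC", "CCACGTCC") == 4
    assert complementarity_score("AAAAAAAA", "AAAAAAAA") == 0
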