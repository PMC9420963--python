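"""Breakend parsing, bracket notation, fusion-call selection, read support."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import breaktracer as bt
from breaktracer.breakends import Side, parse_bracket_token


class TestBracketNotation:
    def test_fwd_row(self):
        spec = bt.parse_bracket_notation(
            "[chr22:29288203]G", "T [chr11:128806738]", "fwd"
        )
        assert spec.end5 == bt.Breakend("chr22", 29288203, Side.LEFT, "G")
        assert spec.end3 == bt.Breakend("chr11", 128806738, Side.RIGHT, "T")
        assert spec.assay_orientation == "fwd"

    def test_rev_row_normalizes_left_retained_to_end5(self):
        spec = bt.parse_bracket_notation(
            "G [chr22:29289258]", "[chr11:128777239] A", "rev"
        )
        assert spec.end5 == bt.Breakend("chr11", 128777239, Side.LEFT, "A")
        assert spec.end3 == bt.Breakend("chr22", 29289258, Side.RIGHT, "G")
        assert spec.assay_orientation == "rev"

    @pytest.mark.parametrize(
        "token", ["chr22:123", "[chr22:123]", "G chr22:123", "[chr22:123]GG", ""]
    )
    def test_malformed_token_raises(self, token):
        with pytest.raises(bt.ParseError):
            parse_bracket_token(token)

    def test_unknown_orientation_rejected(self):
        with pytest.raises(bt.ValidationError):
            bt.parse_bracket_notation(
                "[chr22:29288203]G", "T [chr11:128806738]", "forward"
            )

    def test_same_side_tokens_rejected(self):
        with pytest.raises(bt.ValidationError):
            bt.parse_bracket_notation("[chr1:10]G", "[chr2:20]A", "fwd")

    def test_bundled_sheet_round_trips(self):
        for row in bt.bundled_ewsfli1_sheet():
            spec = row.junction_spec()
            tok_a, tok_b, orientation = bt.format_bracket_notation(spec)
            assert (tok_a, tok_b, orientation) == (
                row.breakpoint_a,
                row.breakpoint_b,
                row.orientation,
            )
            assert bt.parse_bracket_notation(tok_a, tok_b, orientation) == spec

    @given(
        chrom5=st.sampled_from(["chr1", "chr22", "chrX"]),
        chrom3=st.sampled_from(["chr2", "chr11"]),
        pos5=st.integers(1, 10**9),
        pos3=st.integers(1, 10**9),
        base5=st.sampled_from("ACGT"),
        base3=st.sampled_from("ACGT"),
        orientation=st.sampled_from(["fwd", "rev"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_random_spec_round_trip(
        self, chrom5, chrom3, pos5, pos3, base5, base3, orientation
    ):
        spec = bt.JunctionSpec(
            end5=bt.Breakend(chrom5, pos5, Side.LEFT, base5),
            end3=bt.Breakend(chrom3, pos3, Side.RIGHT, base3),
            assay_orientation=orientation,
        )
        assert bt.parse_bracket_notation(*bt.format_bracket_notation(spec)) == spec


class TestVcfBnd:
    # the four ALT shapes of the breakend grammar, enumerated by hand
    TRUTH = [
        ("A[chr11:128806738[", Side.LEFT, Side.RIGHT),
        ("A]chr11:128806738]", Side.LEFT, Side.LEFT),
        ("]chr11:128806738]A", Side.RIGHT, Side.LEFT),
        ("[chr11:128806738[A", Side.RIGHT, Side.RIGHT),
    ]

    @pytest.mark.parametrize("alt,this_side,mate_side", TRUTH)
    def test_alt_shape_truth_table(self, alt, this_side, mate_side):
        local, mate = bt.parse_bnd_alt("chr22", 29288203, "A", alt)
        assert (local.chrom, local.pos, local.retained_side) == (
            "chr22",
            29288203,
            this_side,
        )
        assert (mate.chrom, mate.pos, mate.retained_side) == (
            "chr11",
            128806738,
            mate_side,
        )

    def test_four_shapes_are_distinct(self):
        pairs = {
            (this, mate)
            for _, this, mate in self.TRUTH
        }
        assert len(pairs) == 4

    def test_record_line_parsing(self):
        line = "chr22\t29288203\tbnd_1\tA\tA[chr11:128806738[\t.\tPASS\tSVTYPE=BND"
        (local, mate), = bt.parse_vcf_bnd(line)
        assert local.retained_side is Side.LEFT
        assert mate.retained_side is Side.RIGHT

    def test_non_bnd_record_warns_and_skips(self):
        line = "chr1\t100\t.\tA\tT\t.\tPASS\t."
        with pytest.warns(UserWarning):
            assert bt.parse_vcf_bnd(line) == []

    def test_mate_records_deduplicate(self, toy_genome, implanted, tmp_path):
        vcf = tmp_path / "truth.vcf"
        vcf.write_text(implanted.vcf_text)
        pairs = bt.read_vcf_bnd(vcf)
        assert len(pairs) == 1
        sides = {be.key: be.retained_side for be in pairs[0]}
        truth = {be.key: be.retained_side for be in implanted.spec.breakends}
        assert sides == truth

    def test_inconsistent_mates_rejected(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chrA,length=5000>\n##contig=<ID=chrB,length=5000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        body = (
            "chrA\t100\ta\tA\tA[chrB:200[\t.\tPASS\t.\n"
            "chrB\t200\tb\tC\tC[chrA:100[\t.\tPASS\t.\n"  # wrong mirror shape
        )
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(header + body)
        with pytest.raises(bt.ValidationError):
            bt.read_vcf_bnd(vcf)


class TestSelectFusionCall:
    LOCUS_A = bt.GeneLocus("GENEA", "chrA", 1000, 2000)
    LOCUS_B = bt.GeneLocus("GENEB", "chrB", 3000, 4000)

    def _call(self, pos_a, pos_b, support=None):
        return bt.JunctionSpec(
            end5=bt.Breakend("chrA", pos_a, Side.LEFT),
            end3=bt.Breakend("chrB", pos_b, Side.RIGHT),
            support=support,
        )

    def _brute_force(self, calls):
        """Independent interval-membership scan."""
        hits = [
            c
            for c in calls
            if any(self.LOCUS_A.contains(*b.key) for b in c.breakends)
            and any(self.LOCUS_B.contains(*b.key) for b in c.breakends)
        ]
        return max(hits, key=lambda c: (c.support or 0), default=None)

    def test_unique_linking_call_selected(self):
        calls = [
            self._call(100, 3500),  # outside locus A
            self._call(1500, 3500),  # links both
            self._call(1500, 5000),  # outside locus B
        ]
        picked = bt.select_fusion_call(calls, self.LOCUS_A, self.LOCUS_B)
        assert picked == self._brute_force(calls) == calls[1]

    def test_highest_support_wins(self):
        calls = [self._call(1500, 3500, support=3), self._call(1600, 3600, support=7)]
        picked = bt.select_fusion_call(calls, self.LOCUS_A, self.LOCUS_B)
        assert picked.support == 7
        assert picked == self._brute_force(calls)

    def test_tie_breaks_by_position(self):
        calls = [self._call(1600, 3600, support=5), self._call(1500, 3500, support=5)]
        picked = bt.select_fusion_call(calls, self.LOCUS_A, self.LOCUS_B)
        assert picked.end5.pos == 1500

    def test_permutation_invariance(self):
        calls = [
            self._call(1500, 3500, support=2),
            self._call(1600, 3600, support=9),
            self._call(1700, 3700, support=4),
        ]
        results = {
            bt.select_fusion_call(list(perm), self.LOCUS_A, self.LOCUS_B).end5.pos
            for perm in itertools.permutations(calls)
        }
        assert results == {1600}

    def test_no_candidate_raises(self):
        with pytest.raises(bt.NoFusionCandidateError, match="GENEA"):
            bt.select_fusion_call(
                [self._call(100, 5000)], self.LOCUS_A, self.LOCUS_B
            )


class TestReadSupport:
    def _sam(self, tmp_path, reads):
        path = tmp_path / "reads.sam"
        header = (
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chrA\tLN:5000\n@SQ\tSN:chrB\tLN:5000\n"
        )
        path.write_text(header + "".join(reads))
        return path

    @staticmethod
    def _read(name, chrom, pos, cigar, flag=0):
        seq = "A" * 50
        return (
            f"{name}\t{flag}\t{chrom}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
        )

    def _spec(self):
        return bt.JunctionSpec(
            end5=bt.Breakend("chrA", 2500, Side.LEFT),
            end3=bt.Breakend("chrB", 2600, Side.RIGHT),
        )

    def test_clipped_reads_at_breakend_counted(self, tmp_path):
        # 30M20S starting at 2471 -> last aligned base 2500 (right clip there)
        reads = [self._read(f"r{i}", "chrA", 2471, "30M20S") for i in range(5)]
        sam = self._sam(tmp_path, reads)
        assert bt.junction_read_support(sam, self._spec(), window=5) == 5

    def test_unclipped_reads_not_counted(self, tmp_path):
        sam = self._sam(tmp_path, [self._read("r0", "chrA", 2480, "50M")])
        assert bt.junction_read_support(sam, self._spec(), window=5) == 0

    def test_clip_outside_window_not_counted(self, tmp_path):
        # clip boundaries at pos +/- (window+1)
        reads = [
            self._read("r0", "chrA", 2477, "30M20S"),  # ends 2506 = 2500+6
            self._read("r1", "chrA", 2465, "30M20S"),  # ends 2494 = 2500-6
        ]
        sam = self._sam(tmp_path, reads)
        assert bt.junction_read_support(sam, self._spec(), window=5) == 0

    def test_unmapped_only_returns_zero(self, tmp_path):
        sam = self._sam(
            tmp_path, ["u0\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n"]
        )
        assert bt.junction_read_support(sam, self._spec(), window=5) == 0


def test_read_loci_tsv_and_bed(tmp_path):
    tsv = tmp_path / "loci.tsv"
    tsv.write_text("name\tchrom\tstart\tend\nGENEA\tchrA\t1000\t2000\n")
    bed = tmp_path / "loci.bed"
    bed.write_text("chrA\t999\t2000\tGENEA\n")
    (locus_tsv,) = bt.read_loci(tsv)
    (locus_bed,) = bt.read_loci(bed)
    assert locus_tsv == locus_bed == bt.GeneLocus("GENEA", "chrA", 1000, 2000)
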