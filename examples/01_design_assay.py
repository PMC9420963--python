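"""Design a breakpoint-spanning ddPCR assay for a synthetic fusion patient.

Builds a toy two-chromosome genome with an implanted translocation, parses
the breakend pair back out of the truth VCF, selects the fusion-defining
call using the partner-gene loci, constructs the junction reference and
designs primers plus a junction-overlapping hydrolysis probe.  The final
in-silico PCR shows why the assay is fusion-specific: one product on the
derivative sequence, none on either wild-type chromosome.
"""

import breaktracer as bt

genome = bt.make_toy_genome(seed=5)
implant = bt.implant_translocation(genome, pos_a=2400, pos_b=2700)

# parse the caller output (here: the truth VCF) and pick the fusion call
import tempfile, pathlib

with tempfile.TemporaryDirectory() as tmp:
    vcf = pathlib.Path(tmp) / "calls.vcf"
    vcf.write_text(implant.vcf_text)
    calls = [bt.pair_to_spec(pair) for pair in bt.read_vcf_bnd(vcf)]
spec = bt.select_fusion_call(calls, genome.locus_a, genome.locus_b)
tok_a, tok_b, orientation = bt.format_bracket_notation(spec)
print(f"fusion call: {tok_a} / {tok_b} ({orientation})")

ref = bt.build_junction(spec, genome.sequences, flank_len=300)
assay = bt.design_assay(ref)
protocol = bt.emit_protocol(assay)

print(f"junction reference: {len(ref.sequence)} bp, breakpoint after base "
      f"{ref.junction_offset}")
print(f"fwd primer : {assay.fwd_primer.sequence}  (Tm {assay.fwd_primer.tm_C:.1f} C)")
print(f"rev primer : {assay.rev_primer.sequence}  (Tm {assay.rev_primer.tm_C:.1f} C)")
k = bt.probe_overlap_3prime(assay.probe, ref.junction_offset)
print(f"probe      : {assay.probe.sequence}  ({k} bases past the breakpoint "
      f"at its 3' end)")
print(f"amplicon   : {assay.amplicon_length} bp, annealing tier "
      f"{assay.annealing_temp_C:.0f} C, {protocol.cycle_count} cycles")

for name, template in [
    ("fusion junction", ref.sequence),
    ("wild-type chrA", genome["chrA"]),
    ("wild-type chrB", genome["chrB"]),
]:
    products = bt.in_silico_pcr(template, assay)
    print(f"in-silico PCR on {name}: {len(products)} product(s)")
# Exactly one product on the junction and zero on the wild types means only
# the tumor-derived allele can light droplets up.
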