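# breaktracer

Patient-specific fusion-breakpoint ddPCR assays and circulating-tumor-DNA
(ctDNA) minimal-residual-disease (MRD) tracking.

Translocation-driven sarcomas — the canonical case is Ewing sarcoma, where
a t(11;22) translocation fuses *EWSR1* on chromosome 22 with *FLI1* on
chromosome 11 — carry a fusion breakpoint that is unique to each patient
and stable through clonal evolution.  That makes it a near-perfect plasma
marker: a PCR assay whose primers straddle the breakpoint can only amplify
the tumor-derived allele, and droplet-digital PCR (ddPCR) counts single
molecules of it in blood plasma.  `breaktracer` implements the
computational side of that workflow for clinical and research use:

1. **Breakend parsing** — fusion breakpoints from structural-variant VCF
   `BND` records or compact bracketed sheet notation, with partner-gene
   prior knowledge to select the fusion-defining call and a split-read
   support counter.
2. **Junction construction** — the patient-specific "synthetic reference"
   joining the retained flank of each partner chromosome.
3. **Assay design** — breakpoint-spanning primer pair plus a hydrolysis
   probe overlapping the junction with 2–6 bases past it at the 3′ end,
   nearest-neighbor Tm thermodynamics, and in-silico PCR proving one
   product on the fusion allele and none on wild type.
4. **Droplet quantification** — Poisson statistics λ = −ln(1−p) over
   ~20,000 droplets, replicate pooling, Wilson confidence intervals, QC
   against control wells, copies/mL plasma via the volume chain, allelic
   fraction against a genome-equivalents reference assay, and a
   rule-of-three (3/N) detection limit.
5. **MRD tracking** — longitudinal status calls per timepoint: baseline
   positivity, molecular response, sustained negativity, molecular
   recurrence, rising/falling trends.

A synthetic-data module generates every input with known ground truth
(toy genomes with implanted translocations + truth VCF, droplet wells at
known λ with two-population fluorescence and rain, whole patient courses),
so the entire pipeline is testable end to end without patient data.

## Worked example

`examples/` contains one narrative script per capability.  Designing an
assay for a synthetic fusion patient (`python examples/01_design_assay.py`):

```
fusion call: [chrA:2400]C / G [chrB:2700] (fwd)
junction reference: 600 bp, breakpoint after base 300
fwd primer : TGGTTGTGACCCTTGATACG  (Tm 54.0 C)
rev primer : CGCGATGACAGTGTAGGTAA  (Tm 53.9 C)
probe      : ACCCTTGATACGCTTACACTTCCGAT  (3 bases past the breakpoint at its 3' end)
amplicon   : 90 bp, annealing tier 55 C, 40 cycles
in-silico PCR on fusion junction: 1 product(s)
in-silico PCR on wild-type chrA: 0 product(s)
in-silico PCR on wild-type chrB: 0 product(s)
```

The bracket tokens name the two breakends (coordinate plus retained
reference base); the probe's 3′ end sits 3 bases past the junction, inside
the required 2–6 window, so only molecules spanning the breakpoint light
up; the wild-type chromosomes each carry only one primer site and yield no
product.  Quantifying a duplicate run simulated at 120 copies/mL
(`python examples/02_quantify_droplets.py`):

```
pooled droplets     : 49 positive of 40000
lambda              : 0.00123 targets/droplet
concentration       : 1.442 copies/uL (95% CI 1.091-1.906)
plasma concentration: 144.2 copies/mL (truth 120.0)
allelic fraction    : 0.01394
detection limit     : 8.82 copies/mL at 95%
detectability       : detectable; QC flags: none
```

The 95% interval brackets the simulated truth; the detection limit says
what a blank run of this droplet count could have excluded.  Tracking a
simulated relapse course (`python examples/03_track_mrd.py`) prints the
per-timepoint calls ending in `molecular_recurrence` — positivity after
documented negativity, the molecular correlate of clinical relapse.

The same stages are available as a command-line tool:

```bash
breaktracer simulate genome --seed 5 --out-dir sim/
breaktracer design --genome sim/genome.fasta --sv sim/truth.vcf \
    --loci sim/loci.tsv --out-dir assay/
breaktracer quantify --droplets run1.csv --out-prefix results/run1
breaktracer track results/*.csv --metadata metadata.csv --out-prefix series/
```

## Documentation

`docs/methods.md` describes the models and assumptions in detail: the
breakend conventions, the junction-construction geometry, the
nearest-neighbor thermodynamics and design penalty, the Poisson/Wilson
statistics and volume chain, the MRD state machine, and what the
simulators do and do not emulate about real cell-free DNA data.
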