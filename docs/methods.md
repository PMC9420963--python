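# Methods

`breaktracer` implements a tumor-informed liquid-biopsy workflow for
translocation-driven sarcomas (the motivating case is the EWSR1–FLI1 fusion
of Ewing sarcoma): from a patient-specific structural-variant breakpoint it
derives a junction reference, designs a breakpoint-spanning droplet-digital
PCR (ddPCR) assay, quantifies droplet data into absolute plasma
concentrations, and calls longitudinal minimal-residual-disease (MRD)
transitions.  This note records the models, parameter choices and numerical
conventions behind each stage, and what the synthetic-data generators do
and do not emulate.

## Breakend model

A fusion adjacency is a pair of *breakends*: for each partner chromosome,
the 1-based coordinate of the terminal retained base and the flank
(`left`/`right`) the derivative allele keeps.  The four VCF 4.2 `BND` ALT
shapes map onto retained-side pairs as

| ALT shape | this record | mate |
|---|---|---|
| `t[p[` | left  | right |
| `t]p]` | left  | left  |
| `]p]t` | right | left  |
| `[p[t` | right | right |

Mated records are deduplicated by coordinate pair; a mate whose bracket
shape contradicts the first record is an error.  The compact bracketed
sheet notation (`[chrom:pos]B` / `B [chrom:pos]`) has no published
semantics; the convention declared here — bracket-first ⇒ left-retained,
base-first ⇒ right-retained, with the annotated base being the reference
base at `pos` — is internal, symmetric, and round-trips every row of the
bundled six-assay sheet.  `fwd` and `rev` rows describing the same
biological adjacency normalize to the same breakend pair with an
orientation flag.

Fusion-call selection uses partner-gene loci as prior knowledge: the unique
call with one breakend in each locus wins; ties resolve by supporting-read
count, then by coordinates.  Read support replaces visual inspection of
breakpoint reads with a deterministic count of soft/hard-clipped alignments
whose clip boundary falls within a window (default 5 bp) of a breakend.
Split reads only; discordant-pair evidence is out of scope.

## Junction construction

The junction ("synthetic reference") joins one flank per breakend, default
300 bp per side — comfortably more than an amplicon, small enough that
off-target containment is checked explicitly.  The breakend base itself is
part of the retained segment, which makes the sheet's annotated bases
checkable against the genome.  A left-retained side contributes
`[pos−flank+1, pos]` on the plus strand; a right-retained side contributes
`[pos, pos+flank−1]`, reverse-complemented whenever it must be read toward
the junction — the same geometry the VCF breakend grammar encodes, so all
four retained-side combinations round-trip exactly against the simulator's
independent string-concatenation oracle.  Flanks truncate (flagged in
provenance) at chromosome ends.  Coordinates are 1-based inclusive
throughout; the only 0-based arithmetic happens inside sequence slicing.
`rev`-orientation references are the exact reverse complement of the
forward construction with the junction offset mirrored (offsets sum to the
sequence length).

## Assay design

The design engine is a compact constraint solver, not a wrapper around a
full primer-design suite: the contract is the breakpoint geometry, not any
particular penalty model.

* **Melting temperature.**  Nearest-neighbor thermodynamics with the
  unified ΔH/ΔS stack parameters, duplex-initiation terms, the entropic
  salt correction 0.368·(N−1)·ln[Na⁺], and CT/4 strand-concentration term
  (CT for self-complementary oligos, with the −1.4 cal/mol/K symmetry
  entropy).  Defaults: 50 mM Na⁺, 250 nM oligo.  Deterministic to well
  below 0.01 °C; tests cross-check a hand-summed oracle and an independent
  published implementation.
* **Primer constraints.**  Length 18–27 nt, GC 0.30–0.70, no homopolymer
  run > 4, no ambiguous bases, Tm within 54 ± 5 °C.  The 54 °C target was
  chosen because the six published EWSR1–FLI1 assay primers evaluate to
  53–55 °C under exactly these NN settings, i.e. the defaults reproduce the
  style of assay the workflow is modeled on.  Forward candidates sit wholly
  on the 5′ flank (plus strand), reverse candidates wholly on the 3′ flank
  (minus strand); no candidate may touch the junction.
* **Probe.**  The hydrolysis probe (FAM/BHQ labeling convention) must cover
  the junction with its 3′ terminus exactly k ∈ [2, 6] bases past it on the
  probe's strand — the junction-overlap rule that makes the probe
  fusion-specific — and may not start with G (a 5′ G quenches the
  fluorophore even after cleavage).  Probe length 18–28 nt; the probe whose
  Tm is closest to the primer target + 6 °C wins, ties to the leftmost.
* **Pair selection.**  penalty = |Tm_f−target| + |Tm_r−target| +
  0.05·|amplicon−90| + 0.5·(longest complementary stretch + 3′-anchored
  complementary run).  Amplicon bounds 60–150 bp (short amplicons suit the
  fragmented cell-free DNA template).  The dimer terms are non-negative, so
  pairs are scanned in order of the Tm/length lower bound and the dimer
  terms evaluated lazily — an exact branch-and-bound, not a heuristic cut.
  Ties break deterministically: leftmost forward primer, shortest amplicon,
  leftmost reverse primer.  The annealing temperature is snapped to the
  tier ({55, 58} °C) nearest the primer-pair mean Tm.
* **In-silico PCR.**  Both template strands are scanned for primer sites;
  the 3′-terminal base must always match (polymerase extension chemistry),
  other positions up to `max_mismatches` (default 0).  Every convergent
  site pair within 1000 bp is reported.  Because both primers straddle the
  breakpoint, the derivative allele yields exactly one product and each
  wild-type chromosome carries only one primer site — the structural basis
  of the assay's specificity, verified on 50 random junctions.
* **Thermal protocol.**  96 °C/10 min; 40 × (94 °C/30 s + combined
  anneal/extend at the assay tier, 60 s); 98 °C/10 min droplet
  stabilization; hold at 4 °C.  The anneal/extend duration is a
  conventional choice; the remaining steps and the cycle count are fixed
  workflow constants.

## Droplet quantification

Partitioning ~20,000 droplets makes target occupancy Poisson: with positive
fraction p, λ = −ln(1−p) targets/droplet (computed via `log1p` for
small-count accuracy), and concentration = λ / droplet volume.  Droplet
volume defaults to 0.85 nL (the QX-generation instrument convention; the
instrument class is named in the motivating workflow but not the volume).

* **Classification.**  One fluorescence channel; the exact two-class 1-D
  split minimizing within-class variance (equivalently 1-D k-means/Otsu)
  locates the two cluster means, and the threshold is their midpoint;
  droplets strictly above are positive.  A genuine positive cluster must be
  separated from the negative cloud by more than 3× the summed class
  standard deviations; otherwise the well is called single-population
  all-negative — without this guard an empty well's noise would be sliced
  in half.  The symmetric degenerate case (a fully saturated single-cluster
  well) therefore requires an explicit threshold; in practice wells always
  retain negative droplets short of saturation.
* **Replicates** are pooled — counts summed before the Poisson correction —
  which is the exact treatment of merged partitions (pooling then
  quantifying is identical to quantifying pooled counts).
* **Confidence intervals.**  95% Wilson score interval on p, endpoints
  transformed through −ln(1−·); chosen for its sensible behavior at zero
  counts.  Saturated wells (p = 1) flag rather than raise, with an infinite
  concentration sentinel.
* **Volume chain.**  copies/mL plasma = conc × reaction volume ×
  (eluate / template volume) / plasma volume.  Defaults 20 µL reaction,
  5 µL template of a 50 µL eluate, 2 mL plasma; only the 1–2 mL plasma
  volume is dictated by the workflow, the others are ordinary kit values
  and all are per-sample overridable.  Absolute copies/mL therefore depend
  on these factors and are comparable within, not across, laboratories.
* **QC.**  A valid run carries a no-template control, a diluted positive
  control and (optionally) a healthy-donor negative.  Flags: droplet count
  not strictly above 12,000; any positive NTC droplet; a blank positive
  control; a detectable healthy donor.  Flagged results are retained but
  excluded from MRD status logic.
* **Detectability and LOD.**  0 pooled positive droplets → undetectable,
  exactly 1 → borderline, ≥ 2 → detectable.  The rule documents why a
  ~2 copies/mL single-droplet observation reads as borderline rather than
  positive.  The 95% detection limit at zero positives is the rule of
  three, λ95 = 3/N, pushed through the same volume chain (≈ 8.8 copies/mL
  for pooled duplicates of 20,000 droplets under default volumes); it is
  flagged degenerate when λ95 ≥ 1.
* **Allelic fraction** divides the fusion-assay concentration by a
  reference assay counting total genome equivalents (modeled on a
  chromosome 2p14 locus assay); a zero reference leaves AF undefined
  (flagged) while copies/mL remains reportable.

## MRD status calling

Statuses are called per timepoint, on QC-valid points only, looking only
backward (appending a timepoint can never rewrite history): a detectable
first point is `baseline_positive`; an undetectable point ending a
positivity run is `molecular_response`; the second consecutive undetectable
point begins `sustained_negativity`; a detectable point after ≥ 1
undetectable point is `molecular_recurrence`; the third point of a strictly
monotone run of copies/mL across consecutive detectable points is
`rising`/`falling` (three points were chosen as the minimal evidence for a
"steady" trend; no published rule exists).  Borderline single-droplet
points are inconclusive: they break both positivity and negativity runs and
carry no status.  Detectability is taken verbatim from the quantification
stage — the tracker never re-thresholds concentrations.

## Synthetic data

Generators are pure functions of (parameters, seed).

* **Toy genomes**: two uniform-random ACGT chromosomes (≥ 2 kb) with one
  central "gene" locus each; translocations are implanted by exact string
  concatenation per retained-side combination, with a mated-BND truth VCF.
  This is the independent oracle for junction construction.  Real genomes'
  repeats, homology and N-runs are *not* modeled, so design feasibility on
  random sequence does not prove feasibility near repetitive breakpoints;
  the in-silico PCR containment check is the guard a real deployment would
  run against the whole assembly.
* **Droplets**: each droplet is positive with probability 1−e^(−λ);
  negatives draw from N(2000, 100) and positives from N(8000, 200)
  arbitrary fluorescence units, and a rain fraction (default 0.5%) of
  *positive* droplets is re-drawn uniformly between the population means —
  rain is physically late-amplifying positive partitions, and attaching it
  to positives keeps empty wells clean, as real NTCs are.  Overlapping
  populations (means within 2 summed SDs) set a warning flag.  Instrument
  drift, multi-channel crosstalk and volume variation are not modeled.
* **Patient courses**: piecewise copies/mL templates inside a 6–4,000
  copies/mL dynamic range — responder (50, 0, 0, 0, 0), recurrence
  (1700, 0, 0, 0, 0, 600), progression (30, 90, 300, 900, 2700) — no
  pharmacokinetics are implied.  Template values were chosen once so that
  transitions are unambiguous for pooled duplicates of 20,000 droplets
  (baseline expectations ≥ ~10 pooled positive droplets); each timepoint
  run includes NTC, positive-control and healthy-donor wells so QC is
  always exercised.  Truth transition indices come from the noise-free
  template through the same status rules.

## Verification problem sizes

The test suite checks the Poisson estimator against a high-precision
closed form over a (k, N) grid up to N = 10⁶ (relative error < 10⁻¹²);
recovers λ ∈ {0.001, 0.01, 0.05, 0.5} from 100 seeded wells of 20,000
droplets each (every estimate within 3 binomial-propagated SEs; the mean
relative bias averaged over the λ grid stays below 1% — at λ = 0.001 a
single-λ mean over 100 wells has a Monte-Carlo SE of ≈ 2%, so only the
grid-level mean is a meaningful bias statistic at this sample size);
round-trips 50 random junctions over all four retained-side combinations;
designs and specificity-checks assays on 50 random junctions; and recovers
MRD transition indices on 50 seeds × 3 course profiles (≥ 95% agreement
required; observed misses are isolated borderline droplet events).

## Known limitations

Single-channel classification only (no duplex assays); no microhomology or
untemplated-insertion modeling at junctions (callers report these; an
insertion longer than a few bases would shift primer distances); no
genome-wide off-target scan beyond supplied wild-type sequences; no
secondary-structure (hairpin ΔG) screening of oligos; absolute copies/mL
depend on laboratory volume factors and are not comparable across sites;
lead-time analysis relative to clinical events is deliberately left as a
difference of user-supplied dates.
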