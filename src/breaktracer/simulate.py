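"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here: toy two-chromosome
genomes carrying one reciprocal-translocation-derived junction (with a
truth VCF of the mated breakend pair), droplet wells Poisson-loaded at a
known λ with two-population fluorescence and rain, and whole patient
courses following responder / recurrence / progression trajectory
templates.  Every generator is a pure function of its parameters and seed.

The fluorescence model places negative droplets at N(2000, 100) and
positive droplets at N(8000, 200) arbitrary units; "rain" re-draws a small
fraction of *positive* droplets uniformly between the two population means,
emulating late-amplifying partitions with intermediate fluorescence.
Trajectory templates stay within a 6–4,000 copies/mL dynamic range, the
spread observed across real fusion-positive courses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .breakends import Breakend, GeneLocus, JunctionSpec, Side
from .errors import BoundsError, ValidationError
from .junction import revcomp
from .quant import (
    ROLE_HEALTHY_DONOR,
    ROLE_NTC,
    ROLE_POSITIVE_CONTROL,
    ROLE_SAMPLE,
    DropletWell,
    VolumesConfig,
)

_BASES = np.array(list("ACGT"))


# --------------------------------------------------------------------------
# Toy genomes and implanted translocations
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyGenome:
    """Two uniform-random chromosomes with one 'gene' locus on each."""

    sequences: dict[str, str]
    locus_a: GeneLocus
    locus_b: GeneLocus
    seed: int

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def make_toy_genome(
    seed: int,
    chrom_lengths: tuple[int, int] = (5000, 5000),
    chrom_names: tuple[str, str] = ("chrA", "chrB"),
    gene_names: tuple[str, str] = ("GENEA", "GENEB"),
) -> ToyGenome:
    """Uniform-random ACGT chromosomes with one central gene locus each.

    Loci span the middle half of each chromosome, keeping implanted
    breakpoints well away from chromosome ends.
    """
    if any(n < 2000 for n in chrom_lengths):
        raise ValidationError("chromosome lengths must be >= 2 kb")
    rng = np.random.default_rng(seed)
    sequences = {}
    loci = []
    for name, gene, n in zip(chrom_names, gene_names, chrom_lengths):
        sequences[name] = "".join(_BASES[rng.integers(0, 4, size=n)])
        loci.append(GeneLocus(gene, name, n // 4, 3 * n // 4))
    return ToyGenome(sequences=sequences, locus_a=loci[0], locus_b=loci[1], seed=seed)


@dataclass(frozen=True)
class ImplantedTranslocation:
    """Ground truth for one implanted fusion junction."""

    derivative: str
    junction_offset: int  # bases of the derivative contributed by end5
    spec: JunctionSpec
    vcf_text: str


def _vcf_alt(ref_base: str, this_side: Side, mate: Breakend, mate_side: Side) -> str:
    loc = f"{mate.chrom}:{mate.pos}"
    if this_side is Side.LEFT:
        return (
            f"{ref_base}[{loc}[" if mate_side is Side.RIGHT else f"{ref_base}]{loc}]"
        )
    return f"]{loc}]{ref_base}" if mate_side is Side.LEFT else f"[{loc}[{ref_base}"


def implant_translocation(
    genome: ToyGenome | Mapping[str, str],
    pos_a: int,
    pos_b: int,
    retained_sides: tuple[Side | str, Side | str] = (Side.LEFT, Side.RIGHT),
    chroms: tuple[str, str] | None = None,
) -> ImplantedTranslocation:
    """Create the derivative sequence and truth records for one junction.

    ``retained_sides`` gives the flank each partner keeps, in (end5, end3)
    order.  The derivative is the full-length concatenation: a left-retained
    end5 contributes its chromosome up to ``pos``; a right-retained end5
    contributes the reverse complement of the sequence from ``pos`` onward
    (so the breakend base is always the junction-adjacent base), and
    symmetrically for end3.  The truth VCF carries the mated BND pair.
    """
    side_a, side_b = (Side(retained_sides[0]), Side(retained_sides[1]))
    if chroms is None:
        if isinstance(genome, ToyGenome):
            chroms = (genome.locus_a.chrom, genome.locus_b.chrom)
        else:
            chroms = tuple(genome)[:2]
    chrom_a, chrom_b = chroms
    seq_a = str(genome[chrom_a]).upper()
    seq_b = str(genome[chrom_b]).upper()
    if not (1 <= pos_a <= len(seq_a)):
        raise BoundsError(f"pos_a {pos_a} outside {chrom_a} (len {len(seq_a)})")
    if not (1 <= pos_b <= len(seq_b)):
        raise BoundsError(f"pos_b {pos_b} outside {chrom_b} (len {len(seq_b)})")

    part5 = seq_a[:pos_a] if side_a is Side.LEFT else revcomp(seq_a[pos_a - 1 :])
    part3 = seq_b[pos_b - 1 :] if side_b is Side.RIGHT else revcomp(seq_b[:pos_b])
    derivative = part5 + part3

    base_a = seq_a[pos_a - 1]
    base_b = seq_b[pos_b - 1]
    end5 = Breakend(chrom_a, pos_a, side_a, base_a)
    end3 = Breakend(chrom_b, pos_b, side_b, base_b)
    spec = JunctionSpec(end5=end5, end3=end3, assay_orientation="fwd")

    header = "\n".join(
        [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={chrom_a},length={len(seq_a)}>",
            f"##contig=<ID={chrom_b},length={len(seq_b)}>",
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
            '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
    )
    rec1 = (
        f"{chrom_a}\t{pos_a}\tbnd_1\t{base_a}\t"
        f"{_vcf_alt(base_a, side_a, end3, side_b)}\t.\tPASS\t"
        "SVTYPE=BND;MATEID=bnd_2"
    )
    rec2 = (
        f"{chrom_b}\t{pos_b}\tbnd_2\t{base_b}\t"
        f"{_vcf_alt(base_b, side_b, end5, side_a)}\t.\tPASS\t"
        "SVTYPE=BND;MATEID=bnd_1"
    )
    vcf_text = header + "\n" + rec1 + "\n" + rec2 + "\n"
    return ImplantedTranslocation(
        derivative=derivative,
        junction_offset=len(part5),
        spec=spec,
        vcf_text=vcf_text,
    )


# --------------------------------------------------------------------------
# Droplet simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FluorescenceModel:
    neg_mean: float = 2000.0
    neg_sd: float = 100.0
    pos_mean: float = 8000.0
    pos_sd: float = 200.0
    rain_frac: float = 0.005

    @property
    def overlapping(self) -> bool:
        return self.pos_mean - self.neg_mean < 2 * (self.neg_sd + self.pos_sd)


@dataclass(frozen=True)
class DropletSim:
    """Simulated droplet fluorescence with per-droplet truth labels."""

    values: np.ndarray
    truth_positive: np.ndarray
    true_lambda: float
    overlap_warning: bool
    seed: int

    @property
    def n_true_positive(self) -> int:
        return int(self.truth_positive.sum())


def simulate_droplets(
    true_lambda: float,
    n_droplets: int = 20000,
    fluor: FluorescenceModel | None = None,
    seed: int = 0,
) -> DropletSim:
    """Draw one well of droplet fluorescence at a known mean occupancy.

    Each droplet is positive with probability 1−exp(−λ); fluorescence comes
    from the two configured normal populations, and ``rain_frac`` of the
    positive droplets is re-drawn uniformly between the population means.
    """
    if true_lambda < 0:
        raise ValidationError("true_lambda must be >= 0")
    if n_droplets < 100:
        raise ValidationError("n_droplets must be >= 100")
    fluor = fluor or FluorescenceModel()
    rng = np.random.default_rng(seed)
    p = 1.0 - math.exp(-true_lambda)
    positive = rng.random(n_droplets) < p
    values = rng.normal(fluor.neg_mean, fluor.neg_sd, size=n_droplets)
    n_pos = int(positive.sum())
    if n_pos:
        values[positive] = rng.normal(fluor.pos_mean, fluor.pos_sd, size=n_pos)
        rain = positive & (rng.random(n_droplets) < fluor.rain_frac)
        n_rain = int(rain.sum())
        if n_rain:
            values[rain] = rng.uniform(fluor.neg_mean, fluor.pos_mean, size=n_rain)
    return DropletSim(
        values=values,
        truth_positive=positive,
        true_lambda=true_lambda,
        overlap_warning=fluor.overlapping,
        seed=seed,
    )


def simulate_well(
    well_id: str,
    sample_id: str,
    assay_id: str,
    true_lambda: float,
    role: str = ROLE_SAMPLE,
    n_droplets: int = 20000,
    fluor: FluorescenceModel | None = None,
    seed: int = 0,
) -> DropletWell:
    sim = simulate_droplets(true_lambda, n_droplets, fluor, seed)
    return DropletWell(
        well_id=well_id,
        sample_id=sample_id,
        assay_id=assay_id,
        role=role,
        fluorescence=sim.values,
    )


# --------------------------------------------------------------------------
# Patient courses
# --------------------------------------------------------------------------

# copies/mL trajectory templates; None marks a molecularly undetectable
# point.  Values sit inside the 6-4000 copies/mL dynamic range.
COURSE_PROFILES: dict[str, tuple[float, ...]] = {
    # detectable at diagnosis, then durable molecular response
    "responder": (50.0, 0.0, 0.0, 0.0, 0.0),
    # high baseline, documented negativity, then molecular recurrence
    "recurrence": (1700.0, 0.0, 0.0, 0.0, 0.0, 600.0),
    # steadily increasing burden under failing therapy
    "progression": (30.0, 90.0, 300.0, 900.0, 2700.0),
}

REFERENCE_GE_PER_ML = 10000.0  # total genome equivalents per mL plasma
FUSION_ASSAY_ID = "fusion"
REFERENCE_ASSAY_ID = "ref_chr2p14"


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated patient course."""

    profile: str
    copies_per_ml: tuple[float, ...]
    well_lambda: tuple[float, ...]
    transitions: dict[str, int | None]
    seed: int


@dataclass(frozen=True)
class SimCourse:
    patient_id: str
    timepoint_wells: tuple[tuple[DropletWell, ...], ...]  # per timepoint
    controls: tuple[tuple[DropletWell, ...], ...]  # per timepoint run
    reference_wells: tuple[tuple[DropletWell, ...], ...]
    dates: tuple[str, ...]  # ISO dates
    truth: SimTruth


def copies_per_ml_to_lambda(cpm: float, volumes: VolumesConfig) -> float:
    """Invert the volume chain: plasma concentration to per-droplet λ."""
    conc_uL = (
        cpm
        * volumes.plasma_volume_mL
        / (
            volumes.reaction_volume_uL
            * (volumes.eluate_volume_uL / volumes.template_per_well_uL)
        )
    )
    return conc_uL * volumes.droplet_volume_uL


def _truth_transitions(copies: Sequence[float]) -> dict[str, int | None]:
    """Transition indices implied by a noise-free trajectory template."""
    out: dict[str, int | None] = {
        "molecular_response": None,
        "molecular_recurrence": None,
        "rising": None,
    }
    rise = 0
    prev_det = False
    prev_val = None
    undet_run = 0
    for i, v in enumerate(copies):
        det = v > 0
        if det:
            if undet_run >= 1 and out["molecular_recurrence"] is None and i > 0:
                out["molecular_recurrence"] = i
            rise = rise + 1 if (prev_det and prev_val is not None and v > prev_val) else 1
            if rise >= 3 and out["rising"] is None:
                out["rising"] = i
            undet_run = 0
            prev_val = v
        else:
            if prev_det and out["molecular_response"] is None:
                out["molecular_response"] = i
            undet_run += 1
            rise = 0
            prev_val = None
        prev_det = det
    return out


def simulate_patient_course(
    profile: str,
    volumes: VolumesConfig | None = None,
    seed: int = 0,
    patient_id: str = "SIM",
    n_droplets: int = 20000,
    n_replicates: int = 2,
    fluor: FluorescenceModel | None = None,
    interval_days: int = 42,
) -> SimCourse:
    """Simulate a full patient course of duplicate ddPCR runs.

    Each timepoint gets ``n_replicates`` fusion-assay wells, duplicate
    reference-assay wells at a fixed total-genome-equivalents load, and a
    control trio (NTC at λ=0, a diluted positive control, a healthy-donor
    negative) so QC is always exercised.
    """
    if profile not in COURSE_PROFILES:
        raise ValidationError(
            f"unknown profile {profile!r}; choose from {sorted(COURSE_PROFILES)}"
        )
    volumes = volumes or VolumesConfig()
    fluor = fluor or FluorescenceModel()
    copies = COURSE_PROFILES[profile]
    lam_ref = copies_per_ml_to_lambda(REFERENCE_GE_PER_ML, volumes)
    rng = np.random.default_rng(seed)

    timepoint_wells = []
    reference_wells = []
    controls = []
    dates = []
    well_lams = []
    start = np.datetime64("2024-01-01")
    for t, cpm in enumerate(copies):
        lam = copies_per_ml_to_lambda(cpm, volumes)
        well_lams.append(lam)
        sample_id = f"{patient_id}_T{t}"
        fus = tuple(
            simulate_well(
                f"{sample_id}_{FUSION_ASSAY_ID}_r{r}",
                sample_id,
                FUSION_ASSAY_ID,
                lam,
                n_droplets=n_droplets,
                fluor=fluor,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            for r in range(n_replicates)
        )
        ref = tuple(
            simulate_well(
                f"{sample_id}_{REFERENCE_ASSAY_ID}_r{r}",
                sample_id,
                REFERENCE_ASSAY_ID,
                lam_ref,
                n_droplets=n_droplets,
                fluor=fluor,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            for r in range(n_replicates)
        )
        ctrl = (
            simulate_well(
                f"{sample_id}_ntc", f"NTC_T{t}", FUSION_ASSAY_ID, 0.0,
                role=ROLE_NTC, n_droplets=n_droplets, fluor=fluor,
                seed=int(rng.integers(0, 2**31 - 1)),
            ),
            simulate_well(
                f"{sample_id}_pc", f"PC_T{t}", FUSION_ASSAY_ID, 0.1,
                role=ROLE_POSITIVE_CONTROL, n_droplets=n_droplets, fluor=fluor,
                seed=int(rng.integers(0, 2**31 - 1)),
            ),
            simulate_well(
                f"{sample_id}_hd", f"HD_T{t}", FUSION_ASSAY_ID, 0.0,
                role=ROLE_HEALTHY_DONOR, n_droplets=n_droplets, fluor=fluor,
                seed=int(rng.integers(0, 2**31 - 1)),
            ),
        )
        timepoint_wells.append(fus)
        reference_wells.append(ref)
        controls.append(ctrl)
        dates.append(str(start + np.timedelta64(t * interval_days, "D")))

    truth = SimTruth(
        profile=profile,
        copies_per_ml=copies,
        well_lambda=tuple(well_lams),
        transitions=_truth_transitions(copies),
        seed=seed,
    )
    return SimCourse(
        patient_id=patient_id,
        timepoint_wells=tuple(timepoint_wells),
        controls=tuple(controls),
        reference_wells=tuple(reference_wells),
        dates=tuple(dates),
        truth=truth,
    )
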