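"""Droplet digital PCR quantification.

A ddPCR reaction partitions the template into ~20,000 droplets; the number
of target molecules per droplet is Poisson, so from the fraction of
positive droplets p the mean occupancy is recovered as λ = −ln(1−p).
Division by the droplet volume gives the concentration in the reaction,
and the volume chain (reaction volume, fraction of the cfDNA eluate loaded
per well, plasma volume extracted) converts to copies per mL of the
original plasma — the scale on which MRD courses are reported.  The
fusion-assay concentration divided by a reference-locus assay (total genome
equivalents) gives the allelic fraction.

Replicate wells are pooled (counts summed) before the Poisson correction,
which is the exact treatment for merged partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError

# role vocabulary for wells
ROLE_SAMPLE = "sample"
ROLE_NTC = "NTC"
ROLE_POSITIVE_CONTROL = "positive_control"
ROLE_HEALTHY_DONOR = "healthy_donor"

# QC flags
LOW_DROPLETS = "LOW_DROPLETS"
NTC_CONTAMINATION = "NTC_CONTAMINATION"
CONTROL_FAILURE = "CONTROL_FAILURE"
HEALTHY_DONOR_POSITIVE = "HEALTHY_DONOR_POSITIVE"
SATURATED = "SATURATED"
REFERENCE_ZERO = "REFERENCE_ZERO"
LOD_DEGENERATE = "LOD_DEGENERATE"

MIN_DROPLETS_PER_WELL = 12000  # accepted runs must exceed this count
MIN_DROPLETS_FOR_CLASSIFICATION = 100


@dataclass(frozen=True)
class VolumesConfig:
    """Volume chain from droplet to plasma.

    Defaults: 0.85 nL droplets (QX-generation instruments), 20 µL reactions
    loaded with 5 µL of a 50 µL cfDNA eluate extracted from 2 mL plasma.
    All overridable per sample; plasma volume is the per-sample quantity
    most often 1 or 2 mL.
    """

    droplet_volume_nL: float = 0.85
    reaction_volume_uL: float = 20.0
    template_per_well_uL: float = 5.0
    eluate_volume_uL: float = 50.0
    plasma_volume_mL: float = 2.0

    def __post_init__(self):
        for name, value in vars(self).items():
            if value <= 0:
                raise ValidationError(f"VolumesConfig.{name} must be > 0")

    @property
    def droplet_volume_uL(self) -> float:
        return self.droplet_volume_nL * 1e-3


@dataclass
class DropletWell:
    """One ddPCR well: either per-droplet fluorescence or summary counts."""

    well_id: str
    sample_id: str
    assay_id: str
    role: str = ROLE_SAMPLE
    n_total: int | None = None
    n_positive: int | None = None
    fluorescence: np.ndarray | None = None

    def __post_init__(self):
        if self.fluorescence is not None:
            self.fluorescence = np.asarray(self.fluorescence, dtype=float)
            if not np.all(np.isfinite(self.fluorescence)):
                raise ValidationError(f"well {self.well_id}: non-finite fluorescence")
        if (
            self.n_total is not None
            and self.n_positive is not None
            and self.n_positive > self.n_total
        ):
            raise ValidationError(
                f"well {self.well_id}: n_positive {self.n_positive} > "
                f"n_total {self.n_total}"
            )

    def counts(self, threshold: float | None = None) -> tuple[int, int]:
        """Summary counts, classifying fluorescence on demand."""
        if self.n_total is not None and self.n_positive is not None:
            return self.n_total, self.n_positive
        if self.fluorescence is None:
            raise ValidationError(f"well {self.well_id}: no droplet data")
        n_total, n_positive, _ = classify_droplets(self.fluorescence, threshold)
        return n_total, n_positive


@dataclass(frozen=True)
class PoissonEstimate:
    lam: float
    conc_copies_per_uL: float
    lam_ci95: tuple[float, float]
    conc_ci95: tuple[float, float]
    saturated: bool = False


@dataclass
class QuantResult:
    """Quantification of one sample/assay: λ through copies/mL plasma."""

    sample_id: str
    assay_id: str
    n_total: int
    n_positive: int
    lam: float
    conc_copies_per_uL: float
    conc_ci95: tuple[float, float]
    copies_per_mL_plasma: float
    copies_per_mL_ci95: tuple[float, float]
    lod_copies_per_mL: float
    detectability: str
    allelic_fraction: float | None = None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def qc_valid(self) -> bool:
        return not self.qc_flags


def classify_droplets(
    fluorescence, threshold: float | None = None
) -> tuple[int, int, float]:
    """Split a 1-D fluorescence distribution into negative/positive droplets.

    With no explicit threshold, the two cluster means are found by the exact
    two-class split minimizing within-class variance over all cut points
    (1-D k-means / Otsu) and the threshold is their midpoint.  Droplets
    strictly above the threshold count as positive.

    A genuine positive cluster must be separated from the negative cloud:
    if the two class means differ by less than 3x the summed class standard
    deviations the well is treated as a single (all-negative) population —
    otherwise the split would slice the noise of an empty well in half.
    Saturated single-cluster wells therefore need an explicit threshold.
    """
    values = np.asarray(fluorescence, dtype=float)
    n = values.size
    if n < MIN_DROPLETS_FOR_CLASSIFICATION:
        raise ValidationError(
            f"need >= {MIN_DROPLETS_FOR_CLASSIFICATION} droplets to classify, got {n}"
        )
    if threshold is None:
        v = np.sort(values)
        if v[0] == v[-1]:
            raise ValidationError("cannot classify: all fluorescence values identical")
        csum = np.cumsum(v)
        csum2 = np.cumsum(v * v)
        k = np.arange(1, n)  # size of the lower class
        lower_mean = csum[:-1] / k
        upper_mean = (csum[-1] - csum[:-1]) / (n - k)
        lower_ss = csum2[:-1] - k * lower_mean**2
        upper_ss = (csum2[-1] - csum2[:-1]) - (n - k) * upper_mean**2
        within = lower_ss + upper_ss
        # only splits between distinct values are meaningful
        valid = v[1:] > v[:-1]
        within[~valid] = np.inf
        i = int(np.argmin(within))
        sd_lo = math.sqrt(max(lower_ss[i], 0.0) / (i + 1))
        sd_hi = math.sqrt(max(upper_ss[i], 0.0) / (n - i - 1))
        if upper_mean[i] - lower_mean[i] <= 3.0 * (sd_lo + sd_hi):
            threshold = float(v[-1])  # single population: call all negative
        else:
            threshold = (lower_mean[i] + upper_mean[i]) / 2.0
    n_positive = int(np.sum(values > threshold))
    return n, n_positive, float(threshold)


def poisson_concentration(
    n_positive: int, n_total: int, volumes: VolumesConfig | None = None
) -> PoissonEstimate:
    """Poisson-corrected target concentration from droplet counts.

    λ = −ln(1−p) with p = n_positive/n_total; concentration in copies/µL of
    reaction is λ over the droplet volume.  The 95% CI is a Wilson score
    interval on p transformed through −ln(1−·), which behaves sensibly at
    zero counts.
    """
    volumes = volumes or VolumesConfig()
    if not (0 <= n_positive <= n_total) or n_total < 1:
        raise ValidationError(
            f"invalid droplet counts: {n_positive} positive of {n_total}"
        )
    v = volumes.droplet_volume_uL
    p_lo, p_hi = proportion_confint(n_positive, n_total, alpha=0.05, method="wilson")
    if n_positive == n_total:
        lam_lo = -math.log1p(-min(p_lo, 1.0 - 1e-12))
        return PoissonEstimate(
            lam=math.inf,
            conc_copies_per_uL=math.inf,
            lam_ci95=(lam_lo, math.inf),
            conc_ci95=(lam_lo / v, math.inf),
            saturated=True,
        )
    p = n_positive / n_total
    lam = -math.log1p(-p)
    lam_lo = -math.log1p(-float(p_lo))
    lam_hi = -math.log1p(-float(p_hi))
    return PoissonEstimate(
        lam=lam,
        conc_copies_per_uL=lam / v,
        lam_ci95=(lam_lo, lam_hi),
        conc_ci95=(lam_lo / v, lam_hi / v),
    )


def merge_replicates(wells: Sequence[DropletWell]) -> tuple[int, int]:
    """Pool duplicate wells: counts are summed before Poisson correction."""
    if not wells:
        raise ValidationError("no wells to merge")
    assays = {w.assay_id for w in wells}
    samples = {w.sample_id for w in wells}
    if len(assays) > 1:
        raise ValidationError(f"cannot pool wells with mixed assay ids: {assays}")
    if len(samples) > 1:
        raise ValidationError(f"cannot pool wells with mixed sample ids: {samples}")
    n_total = n_positive = 0
    for w in wells:
        t, p = w.counts()
        n_total += t
        n_positive += p
    return n_total, n_positive


def detectability(n_positive_pooled: int) -> str:
    """Detection call from pooled positive-droplet count.

    0 pooled positives → undetectable, exactly 1 → borderline (a single
    droplet, e.g. the 1.8 copies/mL borderline class), ≥ 2 → detectable.
    """
    if n_positive_pooled < 0:
        raise ValidationError("negative droplet count")
    if n_positive_pooled == 0:
        return "undetectable"
    if n_positive_pooled == 1:
        return "borderline"
    return "detectable"


def qc_well(
    well: DropletWell,
    run_controls: Sequence[DropletWell],
    min_droplets: int = MIN_DROPLETS_PER_WELL,
) -> list[str]:
    """QC flags for a sample well against the run's control wells.

    A run must include an NTC and a positive control (healthy donor
    optional).  Flags: LOW_DROPLETS if the well's droplet count is not
    strictly above ``min_droplets``; NTC_CONTAMINATION for any positive NTC
    droplet; CONTROL_FAILURE for a blank positive control;
    HEALTHY_DONOR_POSITIVE when the donor reads detectable.  A flagged well
    keeps its quantification but is marked invalid.
    """
    roles = {c.role for c in run_controls}
    if ROLE_NTC not in roles or ROLE_POSITIVE_CONTROL not in roles:
        raise ValidationError(
            "run controls must include NTC and positive_control wells"
        )
    flags = []
    n_total, _ = well.counts()
    if n_total <= min_droplets:
        flags.append(LOW_DROPLETS)
    for c in run_controls:
        _, pos = c.counts()
        if c.role == ROLE_NTC and pos > 0:
            flags.append(NTC_CONTAMINATION)
        elif c.role == ROLE_POSITIVE_CONTROL and pos == 0:
            flags.append(CONTROL_FAILURE)
        elif c.role == ROLE_HEALTHY_DONOR and detectability(pos) == "detectable":
            flags.append(HEALTHY_DONOR_POSITIVE)
    return sorted(set(flags))


def copies_per_ml_plasma(
    conc_copies_per_uL: float, volumes: VolumesConfig | None = None
) -> float:
    """Convert reaction concentration to copies per mL of original plasma.

    copies/well = conc × reaction volume; scaling by eluate/template volumes
    gives eluate-wide copies, divided by the plasma volume extracted.
    """
    volumes = volumes or VolumesConfig()
    copies_per_well = conc_copies_per_uL * volumes.reaction_volume_uL
    eluate_copies = copies_per_well * (
        volumes.eluate_volume_uL / volumes.template_per_well_uL
    )
    return eluate_copies / volumes.plasma_volume_mL


def allelic_fraction(
    fusion_conc: float, reference_conc: float
) -> tuple[float | None, list[str]]:
    """Fusion copies over total genome equivalents (reference assay).

    A zero reference concentration leaves the fraction undefined (flagged);
    the fusion result itself remains reportable in copies/mL.
    """
    if fusion_conc < 0 or reference_conc < 0:
        raise ValidationError("concentrations must be non-negative")
    if reference_conc == 0:
        return None, [REFERENCE_ZERO]
    return fusion_conc / reference_conc, []


def limit_of_detection(
    n_total_pooled: int, volumes: VolumesConfig | None = None
) -> tuple[float, list[str]]:
    """95% detection limit in copies/mL at zero positive droplets.

    Rule of three: observing 0 positives among N droplets bounds λ at
    λ95 = 3/N, converted through the same volume chain as a measurement.
    Flagged degenerate when λ95 ≥ 1 (too few droplets to mean anything).
    """
    if n_total_pooled < 1:
        raise ValidationError("pooled droplet count must be >= 1")
    volumes = volumes or VolumesConfig()
    lam95 = 3.0 / n_total_pooled
    conc95 = lam95 / volumes.droplet_volume_uL
    flags = [LOD_DEGENERATE] if lam95 >= 1.0 else []
    return copies_per_ml_plasma(conc95, volumes), flags


def quantify_sample(
    wells: Sequence[DropletWell],
    volumes: VolumesConfig | None = None,
    run_controls: Sequence[DropletWell] | None = None,
    reference_conc_copies_per_uL: float | None = None,
) -> QuantResult:
    """Full per-sample quantification: pool replicates, Poisson-correct,
    convert to copies/mL, attach LOD, detectability, QC and (optionally)
    allelic fraction against a reference-assay concentration."""
    volumes = volumes or VolumesConfig()
    n_total, n_positive = merge_replicates(wells)
    est = poisson_concentration(n_positive, n_total, volumes)
    flags: list[str] = []
    if est.saturated:
        flags.append(SATURATED)
    if run_controls is not None:
        for w in wells:
            flags.extend(qc_well(w, run_controls))
    lod, lod_flags = limit_of_detection(n_total, volumes)
    flags.extend(lod_flags)
    af = None
    if reference_conc_copies_per_uL is not None and not est.saturated:
        af, af_flags = allelic_fraction(
            est.conc_copies_per_uL, reference_conc_copies_per_uL
        )
        flags.extend(af_flags)
    cpm = (
        math.inf
        if est.saturated
        else copies_per_ml_plasma(est.conc_copies_per_uL, volumes)
    )
    return QuantResult(
        sample_id=wells[0].sample_id,
        assay_id=wells[0].assay_id,
        n_total=n_total,
        n_positive=n_positive,
        lam=est.lam,
        conc_copies_per_uL=est.conc_copies_per_uL,
        conc_ci95=est.conc_ci95,
        copies_per_mL_plasma=cpm,
        copies_per_mL_ci95=(
            copies_per_ml_plasma(est.conc_ci95[0], volumes),
            copies_per_ml_plasma(est.conc_ci95[1], volumes)
            if math.isfinite(est.conc_ci95[1])
            else math.inf,
        ),
        lod_copies_per_mL=lod,
        detectability=detectability(n_positive),
        allelic_fraction=af,
        qc_flags=sorted(set(flags)),
    )
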