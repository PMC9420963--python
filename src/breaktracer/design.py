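"""Breakpoint-spanning ddPCR assay design.

Given a junction reference, pick a forward primer entirely on the 5' flank,
a reverse primer entirely on the 3' flank, and a hydrolysis probe that
overlaps the junction with 2–6 bases past it at the probe's 3' end.  Because
both primers sit on opposite sides of the breakpoint, only the derivative
(fusion) allele can template an amplicon — wild-type chromosomes carry only
one primer site each.  Specificity is checked by in-silico PCR.

The design engine is a compact nearest-neighbor/constraint implementation:
unified NN thermodynamics for Tm, GC/homopolymer/length filters, and a
penalty combining Tm deviation, amplicon-length deviation and
self/cross-complementarity.  It is deliberately simpler than a full
primer-design suite; the contract is the breakpoint geometry, not a
particular penalty model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

from .errors import NoAssayError, ValidationError
from .junction import JunctionReference, revcomp

# Unified DNA nearest-neighbor parameters (kcal/mol, cal/mol/K), 1 M NaCl.
NN_DH = {
    "AA": -7.9, "TT": -7.9,
    "AT": -7.2,
    "TA": -7.2,
    "CA": -8.5, "TG": -8.5,
    "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8,
    "GA": -8.2, "TC": -8.2,
    "CG": -10.6,
    "GC": -9.8,
    "GG": -8.0, "CC": -8.0,
}
NN_DS = {
    "AA": -22.2, "TT": -22.2,
    "AT": -20.4,
    "TA": -21.3,
    "CA": -22.7, "TG": -22.7,
    "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0,
    "GA": -22.2, "TC": -22.2,
    "CG": -27.2,
    "GC": -24.4,
    "GG": -19.9, "CC": -19.9,
}
_INIT_GC = (0.1, -2.8)  # dH, dS per duplex end closing on G·C
_INIT_AT = (2.3, 4.1)
_SYM_DS = -1.4
_R = 1.987  # cal/mol/K


def melting_temperature(seq: str, na_mM: float = 50.0, oligo_nM: float = 250.0) -> float:
    """Nearest-neighbor duplex melting temperature in °C.

    Unified NN stack parameters with entropic salt correction
    (0.368·(N−1)·ln[Na+]) and total strand concentration ``oligo_nM``
    (CT/4 for non-self-complementary duplexes).
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValidationError(f"sequence too short for NN Tm: {len(seq)} < 8")
    if set(seq) - set("ACGT"):
        raise ValidationError(f"ambiguous bases in sequence: {seq}")
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        dh += NN_DH[pair]
        ds += NN_DS[pair]
    for terminal in (seq[0], seq[-1]):
        ih, is_ = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += ih
        ds += is_
    selfcomp = seq == revcomp(seq)
    x = 1.0 if selfcomp else 4.0
    if selfcomp:
        ds += _SYM_DS
    ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    ct = oligo_nM * 1e-9
    tm_k = (dh * 1000.0) / (ds_salt + _R * math.log(ct / x))
    return tm_k - 273.15


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def complementarity_score(a: str, b: str) -> int:
    """Longest contiguous complementary stretch between two oligos.

    Computed as the longest common substring of ``a`` and ``revcomp(b)``
    (both 5'→3'), the usual first-order primer-dimer screen.
    """
    target = revcomp(b)
    best = 0
    prev = [0] * (len(target) + 1)
    for ca in a:
        cur = [0] * (len(target) + 1)
        for j, cb in enumerate(target, 1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def three_prime_complementarity(a: str, b: str) -> int:
    """Length of the complementary run anchored at both 3' ends."""
    n = 0
    for ca, cb in zip(reversed(a), reversed(b)):
        if ca == revcomp(cb):
            n += 1
        else:
            break
    return n


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable assay-design parameters.

    Tm values are NN Tm at ``na_mM``/``oligo_nM``; the annealing temperature
    of the emitted protocol is snapped to the tier nearest the primer-pair
    mean Tm.
    """

    primer_min_len: int = 18
    primer_max_len: int = 27
    probe_min_len: int = 18
    probe_max_len: int = 28
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_run: int = 4
    tm_target_C: float = 54.0
    tm_tolerance_C: float = 5.0
    probe_tm_delta_C: float = 6.0
    amplicon_min: int = 60
    amplicon_max: int = 150
    amplicon_target: int = 90
    probe_overlap_min: int = 2
    probe_overlap_max: int = 6
    annealing_tiers_C: tuple[float, ...] = (55.0, 58.0)
    na_mM: float = 50.0
    oligo_nM: float = 250.0
    w_tm: float = 1.0
    w_len: float = 0.05
    w_dimer: float = 0.5

    def __post_init__(self):
        if not (15 <= self.primer_min_len <= self.primer_max_len <= 30):
            raise ValidationError("primer length bounds must satisfy 15<=min<=max<=30")
        if self.amplicon_min > self.amplicon_max:
            raise ValidationError("amplicon_min > amplicon_max")


@dataclass(frozen=True)
class Oligo:
    """A primer or probe placed on the junction reference.

    ``start``/``end`` are 1-based inclusive positions on the junction
    reference; ``sequence`` is 5'→3' (the reverse complement of the
    reference slice for strand "-").
    """

    sequence: str
    strand: str
    start: int
    end: int
    role: str  # primer_fwd | primer_rev | probe
    tm_C: float
    gc_frac: float

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class AssayDesign:
    """One breakpoint-spanning assay: primer pair + junction probe."""

    junction_id: str
    fwd_primer: Oligo
    rev_primer: Oligo
    probe: Oligo
    annealing_temp_C: float
    amplicon_start: int
    amplicon_end: int
    penalty: float
    fluorophore: str = "FAM"
    quencher: str = "BHQ"

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start + 1


@dataclass(frozen=True)
class ThermalProtocol:
    """Ordered thermal steps; cycled steps carry cycles > 1."""

    steps: tuple[dict, ...]

    @property
    def cycle_count(self) -> int:
        return max(s["cycles"] for s in self.steps)

    def to_json(self, path=None) -> str:
        payload = json.dumps({"steps": list(self.steps)}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _passes_common(seq: str, c: DesignConstraints) -> bool:
    if set(seq) - set("ACGT"):
        return False
    if not (c.gc_min <= gc_fraction(seq) <= c.gc_max):
        return False
    if max_homopolymer_run(seq) > c.max_run:
        return False
    return True


def enumerate_primer_candidates(
    ref: JunctionReference, side: str, constraints: DesignConstraints | None = None
) -> list[Oligo]:
    """All primer windows wholly on one side of the junction passing filters.

    5'-side candidates anneal on the "+" strand (sequence as in the
    reference), 3'-side candidates on "−" (reverse complement).  Candidates
    are ordered by start position then length.
    """
    c = constraints or DesignConstraints()
    if side not in ("5prime", "3prime"):
        raise ValidationError(f"side must be '5prime' or '3prime', got {side!r}")
    seq = ref.sequence.upper()
    offset = ref.junction_offset
    out = []
    lo, hi = (1, offset) if side == "5prime" else (offset + 1, len(seq))
    for start in range(lo, hi + 1):
        for length in range(c.primer_min_len, c.primer_max_len + 1):
            end = start + length - 1
            if end > hi:
                break
            window = seq[start - 1 : end]
            if not _passes_common(window, c):
                continue
            oligo_seq = window if side == "5prime" else revcomp(window)
            tm = melting_temperature(oligo_seq, c.na_mM, c.oligo_nM)
            if abs(tm - c.tm_target_C) > c.tm_tolerance_C:
                continue
            out.append(
                Oligo(
                    sequence=oligo_seq,
                    strand="+" if side == "5prime" else "-",
                    start=start,
                    end=end,
                    role="primer_fwd" if side == "5prime" else "primer_rev",
                    tm_C=tm,
                    gc_frac=gc_fraction(oligo_seq),
                )
            )
    return out


def place_probe(
    ref: JunctionReference,
    strand: str = "+",
    constraints: DesignConstraints | None = None,
) -> list[Oligo]:
    """All junction-overlapping hydrolysis-probe placements.

    Each probe covers the junction and its 3' terminus lies exactly
    ``k`` bases past it, k in [probe_overlap_min, probe_overlap_max].
    Hydrolysis-probe convention: no G at the probe's 5' end (a 5' G
    quenches the fluorophore even after cleavage).
    """
    c = constraints or DesignConstraints()
    if strand not in ("+", "-"):
        raise ValidationError("strand must be + or -")
    seq = ref.sequence.upper()
    offset = ref.junction_offset
    n = len(seq)
    out = []
    for k in range(c.probe_overlap_min, c.probe_overlap_max + 1):
        for length in range(c.probe_min_len, c.probe_max_len + 1):
            if strand == "+":
                end = offset + k
                start = end - length + 1
            else:
                start = offset + 1 - k
                end = start + length - 1
            if start < 1 or end > n:
                continue
            # probe must genuinely cover the junction (bases on both sides)
            if not (start <= offset and end >= offset + 1):
                continue
            window = seq[start - 1 : end]
            if not _passes_common(window, c):
                continue
            oligo_seq = window if strand == "+" else revcomp(window)
            if oligo_seq[0] == "G":
                continue
            out.append(
                Oligo(
                    sequence=oligo_seq,
                    strand=strand,
                    start=start,
                    end=end,
                    role="probe",
                    tm_C=melting_temperature(oligo_seq, c.na_mM, c.oligo_nM),
                    gc_frac=gc_fraction(oligo_seq),
                )
            )
    return out


def probe_overlap_3prime(probe: Oligo, junction_offset: int) -> int:
    """Bases past the junction at the probe's 3' terminus, on its strand."""
    if probe.strand == "+":
        return probe.end - junction_offset
    return junction_offset + 1 - probe.start


def design_assay(
    ref: JunctionReference, constraints: DesignConstraints | None = None
) -> AssayDesign:
    """Pick the minimum-penalty primer pair and probe for a junction.

    penalty = w_tm·(|Tm_f−target| + |Tm_r−target|) + w_len·|amplicon−target|
              + w_dimer·(cross-complementarity + 3'-anchored self terms).
    Deterministic: ties break by leftmost forward primer, then shortest
    amplicon, then leftmost reverse primer.
    """
    c = constraints or DesignConstraints()
    fwd = enumerate_primer_candidates(ref, "5prime", c)
    if not fwd:
        raise NoAssayError("no forward-primer candidates on the 5' flank",
                           stage="fwd_primers")
    rev = enumerate_primer_candidates(ref, "3prime", c)
    if not rev:
        raise NoAssayError("no reverse-primer candidates on the 3' flank",
                           stage="rev_primers")
    probes = place_probe(ref, "+", c) or place_probe(ref, "-", c)
    if not probes:
        raise NoAssayError("no junction-overlapping probe placement possible",
                           stage="probe")

    probe_target = c.tm_target_C + c.probe_tm_delta_C
    probe = min(probes, key=lambda p: (abs(p.tm_C - probe_target), p.start, len(p)))

    # The dimer term is non-negative, so the Tm/length base penalty is a
    # lower bound: sort pairs by it and evaluate the expensive
    # complementarity terms lazily until the bound passes the incumbent.
    candidates = []
    for f in fwd:
        for r in rev:
            amp = r.end - f.start + 1
            if not (c.amplicon_min <= amp <= c.amplicon_max):
                continue
            base = (
                c.w_tm * (abs(f.tm_C - c.tm_target_C) + abs(r.tm_C - c.tm_target_C))
                + c.w_len * abs(amp - c.amplicon_target)
            )
            candidates.append((base, f.start, amp, r.start, f, r))
    candidates.sort(key=lambda t: t[:4])
    best = None
    best_key = None
    for base, f_start, amp, r_start, f, r in candidates:
        if best_key is not None and base > best_key[0]:
            break
        penalty = base + c.w_dimer * (
            complementarity_score(f.sequence, r.sequence)
            + three_prime_complementarity(f.sequence, r.sequence)
        )
        key = (round(penalty, 9), f_start, amp, r_start)
        if best_key is None or key < best_key:
            best_key = key
            best = (f, r, penalty, amp)
    if best is None:
        raise NoAssayError(
            "no primer pair yields an amplicon within "
            f"[{c.amplicon_min}, {c.amplicon_max}] bp",
            stage="pairing",
        )
    f, r, penalty, amp = best
    mean_tm = (f.tm_C + r.tm_C) / 2.0
    annealing = min(c.annealing_tiers_C, key=lambda t: (abs(t - mean_tm), t))
    return AssayDesign(
        junction_id=ref.junction_id,
        fwd_primer=f,
        rev_primer=r,
        probe=probe,
        annealing_temp_C=annealing,
        amplicon_start=f.start,
        amplicon_end=r.end,
        penalty=penalty,
    )


# --------------------------------------------------------------------------
# In-silico PCR
# --------------------------------------------------------------------------


def _find_sites(template: str, primer: str, max_mismatches: int, minus: bool):
    """Match positions of a primer on a template strand.

    Plus-strand sites: window equals the primer with the 3'-terminal (last)
    base exact.  Minus-strand sites: window equals revcomp(primer) with the
    window's *first* base exact (it maps to the primer's 3' end).
    """
    pat = revcomp(primer) if minus else primer
    L = len(pat)
    anchor = 0 if minus else L - 1
    hits = []
    for i in range(len(template) - L + 1):
        window = template[i : i + L]
        if window[anchor] != pat[anchor]:
            continue
        mm = sum(1 for a, b in zip(window, pat) if a != b)
        if mm <= max_mismatches:
            hits.append(i)
    return hits


def in_silico_pcr(
    template: str,
    assay: AssayDesign,
    max_mismatches: int = 0,
    max_product_len: int = 1000,
) -> list[tuple[int, int, int]]:
    """Predict PCR products of an assay on an arbitrary template.

    Scans both template strands for primer annealing sites (3'-terminal base
    always exact) and reports every convergent site pair within
    ``max_product_len`` as ``(start, end, length)``, 1-based inclusive on
    the given template.  An empty list means no product.
    """
    if not template:
        raise ValidationError("template must be nonempty")
    if max_mismatches < 0:
        raise ValidationError("max_mismatches must be >= 0")
    template = template.upper()
    primers = (assay.fwd_primer.sequence, assay.rev_primer.sequence)
    products = set()
    for left, right in (primers, primers[::-1]):
        plus = _find_sites(template, left, max_mismatches, minus=False)
        minus = _find_sites(template, right, max_mismatches, minus=True)
        for i in plus:
            for j in minus:
                if j < i:
                    continue
                end = j + len(right)
                length = end - i
                if length <= max_product_len:
                    products.add((i + 1, end, length))
    return sorted(products)


# --------------------------------------------------------------------------
# Validation and artifact emission
# --------------------------------------------------------------------------


def _oligo_matches_reference(oligo: Oligo, ref: JunctionReference) -> bool:
    window = ref.sequence.upper()[oligo.start - 1 : oligo.end]
    expected = window if oligo.strand == "+" else revcomp(window)
    return oligo.sequence.upper() == expected


def validate_assay(assay: AssayDesign, ref: JunctionReference,
                   constraints: DesignConstraints | None = None) -> dict[str, bool]:
    """Check every structural rule of a breakpoint-spanning assay.

    Returns a rule→pass mapping; ``all(report.values())`` is the overall
    verdict.
    """
    c = constraints or DesignConstraints()
    offset = ref.junction_offset
    k = probe_overlap_3prime(assay.probe, offset)
    report = {
        "fwd_primer_on_5prime_side": assay.fwd_primer.end <= offset,
        "rev_primer_on_3prime_side": assay.rev_primer.start >= offset + 1,
        "amplicon_spans_junction": (
            assay.amplicon_start <= offset and assay.amplicon_end >= offset + 1
        ),
        "probe_covers_junction": (
            assay.probe.start <= offset and assay.probe.end >= offset + 1
        ),
        "probe_3prime_overlap_2_6": c.probe_overlap_min <= k <= c.probe_overlap_max,
        "probe_no_5prime_G": assay.probe.sequence[0] != "G",
        "primer_lengths_in_bounds": all(
            c.primer_min_len <= len(o) <= c.primer_max_len
            for o in (assay.fwd_primer, assay.rev_primer)
        ),
        "gc_in_bounds": all(
            c.gc_min <= o.gc_frac <= c.gc_max
            for o in (assay.fwd_primer, assay.rev_primer, assay.probe)
        ),
        "amplicon_length_in_bounds": (
            c.amplicon_min <= assay.amplicon_length <= c.amplicon_max
        ),
        "oligos_match_reference": all(
            _oligo_matches_reference(o, ref)
            for o in (assay.fwd_primer, assay.rev_primer, assay.probe)
        ),
    }
    return report


def emit_protocol(assay: AssayDesign, cycles: int = 40) -> ThermalProtocol:
    """Thermal profile for the assay: hot start, 40 two-step cycles
    (denaturation + combined anneal/extend at the assay's annealing tier),
    droplet-stabilization bake, hold."""
    return ThermalProtocol(
        steps=(
            {"temperature_C": 96.0, "duration_s": 600, "cycles": 1},
            {"temperature_C": 94.0, "duration_s": 30, "cycles": cycles},
            {
                "temperature_C": assay.annealing_temp_C,
                "duration_s": 60,
                "cycles": cycles,
            },
            {"temperature_C": 98.0, "duration_s": 600, "cycles": 1},
            {"temperature_C": 4.0, "duration_s": None, "cycles": 1},
        )
    )
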