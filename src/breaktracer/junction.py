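"""Construction of the patient-specific junction reference.

The junction ("synthetic reference") is the derivative-allele sequence
spanning the fusion breakpoint: a flank retrieved from each partner
chromosome, joined at the breakend positions.  It is the template on which
the breakpoint-spanning ddPCR assay is designed.

Coordinate conventions: all positions are 1-based inclusive; the breakend
position itself is part of the retained segment (terminal retained base).
A left-retained breakend contributes ``[pos-flank+1, pos]`` on the plus
strand; a right-retained breakend contributes ``[pos, pos+flank-1]`` and is
reverse-complemented when it has to be read toward the junction (end5) —
the same geometry the VCF breakend grammar encodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .breakends import Breakend, JunctionSpec, Side
from .errors import BoundsError, ValidationError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (ACGTN alphabet, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SegmentProvenance:
    """Genomic origin of one junction flank, as used in the construction."""

    chrom: str
    start: int
    end: int
    strand: str  # "+" as fetched, "-" reverse-complemented
    truncated: bool = False


@dataclass(frozen=True)
class JunctionReference:
    """The junction sequence plus where it came from.

    ``junction_offset`` is the number of bases contributed by the end5 side;
    the junction lies between positions ``offset`` and ``offset+1`` (1-based).
    """

    sequence: str
    junction_offset: int
    flank_len: int
    provenance: tuple[SegmentProvenance, SegmentProvenance]
    orientation: str = "fwd"
    junction_id: str = "junction"

    def __post_init__(self):
        n = len(self.sequence)
        if not (1 <= self.junction_offset < n):
            raise ValidationError(
                f"junction_offset {self.junction_offset} outside 1..{n - 1}"
            )
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValidationError("junction sequence contains non-ACGTN characters")

    @property
    def has_ambiguous(self) -> bool:
        return "N" in self.sequence.upper()

    @property
    def flank5(self) -> str:
        return self.sequence[: self.junction_offset]

    @property
    def flank3(self) -> str:
        return self.sequence[self.junction_offset :]


def _chrom_len(genome, chrom: str) -> int:
    try:
        return len(genome[chrom])
    except KeyError as exc:
        raise BoundsError(f"unknown chromosome {chrom!r}") from exc


def fetch_segment(genome, chrom: str, start: int, end: int, strand: str = "+") -> str:
    """Fetch ``[start, end]`` (1-based inclusive) from an indexed genome.

    ``genome`` is a pyfaidx.Fasta handle or any mapping of chromosome name to
    sequence.  ``strand="-"`` returns the reverse complement.
    """
    if strand not in ("+", "-"):
        raise ValidationError(f"strand must be + or -, got {strand!r}")
    n = _chrom_len(genome, chrom)
    if not (1 <= start <= end <= n):
        raise BoundsError(
            f"interval {chrom}:{start}-{end} outside chromosome of length {n}"
        )
    seq = str(genome[chrom][start - 1 : end]).upper()
    return revcomp(seq) if strand == "-" else seq


def _fetch_flank(genome, be: Breakend, flank_len: int, toward_junction: str):
    """Fetch one breakend flank, truncating at chromosome ends.

    ``toward_junction`` is "end5" or "end3": for end5 the retained segment
    must finish at the breakend base, for end3 it must start there, which
    decides whether a retained flank needs reverse-complementing.
    """
    n = _chrom_len(genome, be.chrom)
    if not (1 <= be.pos <= n):
        raise BoundsError(
            f"breakend {be.chrom}:{be.pos} outside chromosome of length {n}"
        )
    if be.retained_side is Side.LEFT:
        start = max(1, be.pos - flank_len + 1)
        end = be.pos
        truncated = start != be.pos - flank_len + 1
        plus = str(genome[be.chrom][start - 1 : end]).upper()
        # left-retained reads toward the junction on "+"; as end3 it is the
        # second part and must be flipped so the breakend base comes first
        if toward_junction == "end5":
            return plus, SegmentProvenance(be.chrom, start, end, "+", truncated)
        return revcomp(plus), SegmentProvenance(be.chrom, start, end, "-", truncated)
    else:
        start = be.pos
        end = min(n, be.pos + flank_len - 1)
        truncated = end != be.pos + flank_len - 1
        plus = str(genome[be.chrom][start - 1 : end]).upper()
        if toward_junction == "end3":
            return plus, SegmentProvenance(be.chrom, start, end, "+", truncated)
        return revcomp(plus), SegmentProvenance(be.chrom, start, end, "-", truncated)


def build_junction(
    spec: JunctionSpec, genome, flank_len: int = 300, junction_id: str = "junction"
) -> JunctionReference:
    """Build the junction reference for a fusion adjacency.

    Flanks of ``flank_len`` bp are retrieved around each breakend and joined
    in end5→end3 order; flanks are truncated (and flagged in provenance) at
    chromosome ends.  For ``assay_orientation="rev"`` the returned sequence
    is the reverse complement of the forward construction with the junction
    offset mirrored.
    """
    if flank_len < 1:
        raise ValidationError("flank_len must be >= 1")
    seq5, prov5 = _fetch_flank(genome, spec.end5, flank_len, "end5")
    seq3, prov3 = _fetch_flank(genome, spec.end3, flank_len, "end3")
    sequence = seq5 + seq3
    offset = len(seq5)
    provenance = (prov5, prov3)
    if spec.assay_orientation == "rev":
        sequence = revcomp(sequence)
        offset = len(sequence) - offset
        flip = {"+": "-", "-": "+"}
        provenance = (
            SegmentProvenance(prov3.chrom, prov3.start, prov3.end,
                              flip[prov3.strand], prov3.truncated),
            SegmentProvenance(prov5.chrom, prov5.start, prov5.end,
                              flip[prov5.strand], prov5.truncated),
        )
    return JunctionReference(
        sequence=sequence,
        junction_offset=offset,
        flank_len=flank_len,
        provenance=provenance,
        orientation=spec.assay_orientation,
        junction_id=junction_id,
    )


def write_junction_fasta(ref: JunctionReference, path) -> None:
    """Write a single-record FASTA with provenance in the header.

    Header tokens are ``key=value``; sequence is wrapped at 60 columns.
    """
    if not ref.sequence:
        raise ValidationError("refusing to write empty junction sequence")
    prov = ";".join(
        f"{p.chrom}:{p.start}-{p.end}({p.strand}){'!' if p.truncated else ''}"
        for p in ref.provenance
    )
    header = (
        f">{ref.junction_id} offset={ref.junction_offset} "
        f"flank={ref.flank_len} orientation={ref.orientation} segments={prov}"
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(0, len(ref.sequence), 60):
            fh.write(ref.sequence[i : i + 60] + "\n")


def read_junction_fasta(path) -> JunctionReference:
    """Re-read a junction FASTA written by :func:`write_junction_fasta`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        seq = "".join(line.strip() for line in fh)
    if not header.startswith(">"):
        raise ValidationError(f"{path}: not a FASTA file")
    name, *tokens = header[1:].split()
    kv = dict(t.split("=", 1) for t in tokens if "=" in t)
    segs = []
    for part in kv.get("segments", "").split(";"):
        m = part.rstrip("!")
        truncated = part.endswith("!")
        chrom, rest = m.rsplit(":", 1)
        coords, strand = rest[:-3], rest[-2]
        start, end = coords.split("-")
        segs.append(SegmentProvenance(chrom, int(start), int(end), strand, truncated))
    return JunctionReference(
        sequence=seq,
        junction_offset=int(kv["offset"]),
        flank_len=int(kv.get("flank", 0)),
        provenance=(segs[0], segs[1]),
        orientation=kv.get("orientation", "fwd"),
        junction_id=name,
    )
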