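"""Fusion breakpoint representation and parsing.

A translocation junction is described by two *breakends*: for each partner
chromosome, the 1-based coordinate of the terminal base retained on the
derivative allele, plus which flank of that base (``left`` or ``right``)
the derivative keeps.  Breakends arrive either as mated VCF ``BND`` records
(the output of a structural-variant caller) or in a compact bracketed text
notation used on assay sheets, e.g. ``[chr22:29288203]G`` paired with
``T [chr11:128806738]``.

Bracket-token convention (declared here, since assay sheets in the wild do
not define one): a token with the coordinate bracketed first and the base
after (``[chrom:pos]B``) retains the *left* flank of ``pos``; a token with
the base before the bracket (``B [chrom:pos]``) retains the *right* flank.
A :class:`JunctionSpec` is stored normalized so that ``end5`` is the
left-retained breakend; ``rev`` rows keep the same biological adjacency and
record ``assay_orientation="rev"``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import NoFusionCandidateError, ParseError, ValidationError

_VALID_BASES = frozenset("ACGTN")


class Side(str, Enum):
    """Which flank of a breakend position the derivative allele retains."""

    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class Breakend:
    """One side of a structural-variant adjacency.

    ``pos`` is the 1-based coordinate of the terminal retained base;
    ``retained_side`` says whether the derivative keeps the flank to the
    left or to the right of (and including) that base.
    """

    chrom: str
    pos: int
    retained_side: Side
    ref_base: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"breakend position must be >= 1, got {self.pos}")
        if not isinstance(self.retained_side, Side):
            object.__setattr__(self, "retained_side", Side(self.retained_side))
        if self.ref_base is not None and self.ref_base not in _VALID_BASES:
            raise ValidationError(
                f"ref_base must be one of A,C,G,T,N; got {self.ref_base!r}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class GeneLocus:
    """A partner-gene interval used as prior knowledge for fusion selection."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"locus {self.name}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"locus {self.name}: strand must be + or -")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class JunctionSpec:
    """A fusion-defining adjacency in assay orientation.

    ``end5`` contributes the first part of the junction sequence as read in
    assay orientation, ``end3`` the second.  ``support`` is an optional
    supporting-read count from the caller.
    """

    end5: Breakend
    end3: Breakend
    assay_orientation: str = "fwd"
    support: int | None = None

    def __post_init__(self):
        if self.assay_orientation not in ("fwd", "rev"):
            raise ValidationError(
                f"assay_orientation must be 'fwd' or 'rev', got "
                f"{self.assay_orientation!r}"
            )
        if self.end5.chrom == self.end3.chrom and self.end5.pos == self.end3.pos:
            raise ValidationError(
                "end5 and end3 may share a chromosome only at distinct positions"
            )

    @property
    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.end5, self.end3)


# --------------------------------------------------------------------------
# Bracketed assay-sheet notation
# --------------------------------------------------------------------------

_BRACKET_FIRST = re.compile(r"^\[([^\[\]:\s]+):(\d+)\]\s*([ACGTN])$")
_BASE_FIRST = re.compile(r"^([ACGTN])\s*\[([^\[\]:\s]+):(\d+)\]$")


def parse_bracket_token(token: str) -> Breakend:
    """Parse one bracketed breakpoint token into a :class:`Breakend`."""
    token = token.strip()
    m = _BRACKET_FIRST.match(token)
    if m:
        chrom, pos, base = m.group(1), int(m.group(2)), m.group(3)
        return Breakend(chrom, pos, Side.LEFT, base)
    m = _BASE_FIRST.match(token)
    if m:
        base, chrom, pos = m.group(1), m.group(2), int(m.group(3))
        return Breakend(chrom, pos, Side.RIGHT, base)
    raise ParseError(f"malformed breakpoint token: {token!r}")


def parse_bracket_notation(
    token: str, partner_token: str, orientation: str
) -> JunctionSpec:
    """Parse a pair of bracketed breakpoint tokens into a JunctionSpec.

    The left-retained breakend becomes ``end5`` and the right-retained one
    ``end3`` regardless of token order, so ``fwd`` and ``rev`` rows describing
    the same adjacency normalize to the same breakend pair.
    """
    if orientation not in ("fwd", "rev"):
        raise ValidationError(f"unknown orientation: {orientation!r}")
    a = parse_bracket_token(token)
    b = parse_bracket_token(partner_token)
    sides = {a.retained_side, b.retained_side}
    if sides != {Side.LEFT, Side.RIGHT}:
        raise ValidationError(
            "bracket notation requires one left-retained and one "
            f"right-retained token, got {a.retained_side.value}/"
            f"{b.retained_side.value}"
        )
    end5 = a if a.retained_side is Side.LEFT else b
    end3 = b if end5 is a else a
    return JunctionSpec(end5=end5, end3=end3, assay_orientation=orientation)


def format_bracket_notation(spec: JunctionSpec) -> tuple[str, str, str]:
    """Inverse of :func:`parse_bracket_notation` (token, partner, orientation)."""

    def _fmt(be: Breakend, second: bool) -> str:
        base = be.ref_base or "N"
        if be.retained_side is Side.LEFT:
            # assay sheets put a space before a trailing base in the
            # partner (second) column only
            return f"[{be.chrom}:{be.pos}] {base}" if second else f"[{be.chrom}:{be.pos}]{base}"
        return f"{base} [{be.chrom}:{be.pos}]"

    if spec.assay_orientation == "fwd":
        return _fmt(spec.end5, False), _fmt(spec.end3, True), "fwd"
    return _fmt(spec.end3, False), _fmt(spec.end5, True), "rev"


# --------------------------------------------------------------------------
# VCF breakend (BND) records
# --------------------------------------------------------------------------

# The four ALT shapes of the VCF 4.2 breakend grammar and the flank each
# side retains:  t[p[ -> (left, right);  t]p] -> (left, left);
# ]p]t -> (right, left);  [p[t -> (right, right).
_BND_SHAPES = (
    (re.compile(r"^(?P<t>[ACGTN]+)\[(?P<c>[^\[\]:]+):(?P<p>\d+)\[$"), Side.LEFT, Side.RIGHT),
    (re.compile(r"^(?P<t>[ACGTN]+)\](?P<c>[^\[\]:]+):(?P<p>\d+)\]$"), Side.LEFT, Side.LEFT),
    (re.compile(r"^\](?P<c>[^\[\]:]+):(?P<p>\d+)\](?P<t>[ACGTN]+)$"), Side.RIGHT, Side.LEFT),
    (re.compile(r"^\[(?P<c>[^\[\]:]+):(?P<p>\d+)\[(?P<t>[ACGTN]+)$"), Side.RIGHT, Side.RIGHT),
)


def parse_bnd_alt(
    chrom: str, pos: int, ref: str, alt: str
) -> tuple[Breakend, Breakend] | None:
    """Map one BND ALT string to its (local, mate) breakend pair.

    Returns None (with a warning) for non-BND ALT alleles.
    """
    for pattern, this_side, mate_side in _BND_SHAPES:
        m = pattern.match(alt)
        if m:
            base = ref[0].upper() if ref and ref[0].upper() in _VALID_BASES else None
            local = Breakend(chrom, pos, this_side, base)
            mate = Breakend(m.group("c"), int(m.group("p")), mate_side)
            return (local, mate)
    warnings.warn(f"skipping non-BND ALT {alt!r} at {chrom}:{pos}", stacklevel=2)
    return None


def parse_vcf_bnd(record: str) -> list[tuple[Breakend, Breakend]]:
    """Parse a raw VCF body line, returning its breakend pairs.

    Multiple ALT alleles yield multiple pairs; non-BND alleles are skipped
    with a warning.
    """
    fields = record.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise ParseError(f"not a VCF body line: {record!r}")
    chrom, pos_s, _id, ref, alt_field = fields[:5]
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise ParseError(f"non-integer POS in record: {pos_s!r}") from exc
    pairs = []
    for alt in alt_field.split(","):
        pair = parse_bnd_alt(chrom, pos, ref, alt)
        if pair is not None:
            pairs.append(pair)
    return pairs


def _mirrored(pair: tuple[Breakend, Breakend]) -> tuple[Breakend, Breakend]:
    return (pair[1], pair[0])


def _sides_of(pair: tuple[Breakend, Breakend]) -> dict[tuple[str, int], Side]:
    return {be.key: be.retained_side for be in pair}


def read_vcf_bnd(path) -> list[tuple[Breakend, Breakend]]:
    """Read BND adjacencies from a VCF file (plain or bgzipped).

    Mated records are deduplicated by their (chrom, pos) coordinate pair;
    a mate whose bracket shape contradicts the first record raises a
    :class:`ValidationError`.  With multiple samples the site records are
    shared, so per-sample fields are ignored (first sample semantics).
    """
    import pysam

    seen: dict[frozenset, tuple[Breakend, Breakend]] = {}
    with pysam.VariantFile(str(path)) as vf:
        if len(vf.header.samples) > 1:
            warnings.warn(
                "VCF has multiple samples; using site records only "
                "(first-sample semantics)",
                stacklevel=2,
            )
        for rec in vf:
            for alt in rec.alts or ():
                pair = parse_bnd_alt(rec.chrom, rec.pos, rec.ref or "N", alt)
                if pair is None:
                    continue
                key = frozenset(be.key for be in pair)
                if key in seen:
                    if _sides_of(seen[key]) != _sides_of(pair):
                        raise ValidationError(
                            f"inconsistent mate pair at {sorted(key)}: bracket "
                            "shapes disagree between mates"
                        )
                    # keep the first record, but adopt the mate's ref_base
                    prev = seen[key]
                    filled = []
                    for be in prev:
                        if be.ref_base is None:
                            match = next(
                                (x for x in pair if x.key == be.key and x.ref_base),
                                None,
                            )
                            if match is not None:
                                be = replace(be, ref_base=match.ref_base)
                        filled.append(be)
                    seen[key] = (filled[0], filled[1])
                else:
                    seen[key] = pair
    return list(seen.values())


def pair_to_spec(
    pair: tuple[Breakend, Breakend],
    orientation: str = "fwd",
    support: int | None = None,
) -> JunctionSpec:
    """Normalize an unordered breakend pair into a JunctionSpec.

    The left-retained breakend becomes ``end5`` when exactly one side is
    left-retained; otherwise the pair is kept in the given order.
    """
    a, b = pair
    if {a.retained_side, b.retained_side} == {Side.LEFT, Side.RIGHT}:
        end5 = a if a.retained_side is Side.LEFT else b
        end3 = b if end5 is a else a
    else:
        end5, end3 = a, b
    return JunctionSpec(end5=end5, end3=end3, assay_orientation=orientation,
                        support=support)


# --------------------------------------------------------------------------
# Fusion-call selection and read support
# --------------------------------------------------------------------------


def select_fusion_call(
    calls: Sequence[JunctionSpec], locus_a: GeneLocus, locus_b: GeneLocus
) -> JunctionSpec:
    """Pick the call linking the two partner-gene loci.

    One breakend must fall inside ``locus_a`` and the other inside
    ``locus_b``.  Among several matches the highest supporting-read count
    wins; residual ties break by the smallest (pos-in-A, pos-in-B) pair.
    """
    matches = []
    for call in calls:
        e5, e3 = call.breakends
        if locus_a.contains(*e5.key) and locus_b.contains(*e3.key):
            in_a, in_b = e5, e3
        elif locus_a.contains(*e3.key) and locus_b.contains(*e5.key):
            in_a, in_b = e3, e5
        else:
            continue
        matches.append((call, in_a.pos, in_b.pos))
    if not matches:
        raise NoFusionCandidateError(
            f"no fusion candidate links {locus_a.name} "
            f"({locus_a.chrom}:{locus_a.start}-{locus_a.end}) and {locus_b.name} "
            f"({locus_b.chrom}:{locus_b.start}-{locus_b.end})"
        )
    matches.sort(key=lambda m: (-(m[0].support or 0), m[1], m[2]))
    return matches[0][0]


def junction_read_support(alignments, spec: JunctionSpec, window: int = 5) -> int:
    """Count split/clipped reads supporting the junction.

    A read supports the junction if a soft/hard-clip boundary lies within
    ``window`` bp of either breakend position on the matching chromosome.
    ``alignments`` is a SAM/BAM path or an iterable of pysam aligned
    segments.  This is the programmatic stand-in for visual breakpoint-read
    inspection.
    """
    import pysam

    if window < 0:
        raise ValidationError("window must be >= 0")
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        with pysam.AlignmentFile(str(alignments)) as af:
            return junction_read_support(list(af), spec, window)

    targets = [(be.chrom, be.pos) for be in spec.breakends]
    count = 0
    for read in alignments:
        if read.is_unmapped or not read.cigartuples:
            continue
        boundaries = []
        if read.cigartuples[0][0] in (4, 5):  # leading S/H clip
            boundaries.append(read.reference_start + 1)
        if read.cigartuples[-1][0] in (4, 5):  # trailing S/H clip
            boundaries.append(read.reference_end)
        if any(
            read.reference_name == chrom and abs(b - pos) <= window
            for chrom, pos in targets
            for b in boundaries
        ):
            count += 1
    return count


def read_loci(path) -> list[GeneLocus]:
    """Read partner-gene loci from BED (0-based half-open) or TSV.

    TSV columns: name, chrom, start, end[, strand], 1-based inclusive, with
    or without a header row.
    """
    loci = []
    text = [
        line.rstrip("\n")
        for line in open(path)
        if line.strip() and not line.startswith(("#", "track", "browser"))
    ]
    is_bed = str(path).endswith(".bed")
    for line in text:
        cols = line.split("\t")
        if is_bed:
            chrom, start0, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else f"{chrom}:{start0 + 1}-{end}"
            strand = cols[5] if len(cols) > 5 else "+"
            loci.append(GeneLocus(name, chrom, start0 + 1, end, strand))
        else:
            if cols[0].lower() == "name":  # header row
                continue
            name, chrom, start, end = cols[0], cols[1], int(cols[2]), int(cols[3])
            strand = cols[4] if len(cols) > 4 else "+"
            loci.append(GeneLocus(name, chrom, start, end, strand))
    return loci
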