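"""Assay-sheet TSV: the tabular exchange format for designed assays.

One row per patient assay: the two bracketed breakpoint tokens, the two
primers, the assay orientation, the junction-overlapping probe (3'-FAM +
5'-BHQ labelling convention) and the annealing temperature tier.  The
package bundles a six-assay EWSR1-FLI1 reference sheet in this dialect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from importlib import resources
from typing import Sequence

from .breakends import JunctionSpec, format_bracket_notation, parse_bracket_notation
from .design import AssayDesign
from .errors import ValidationError

SHEET_COLUMNS = (
    "sample",
    "breakpoint_a",
    "breakpoint_b",
    "primer_a",
    "primer_b",
    "orientation",
    "probe",
    "annealing_temp_C",
)


@dataclass(frozen=True)
class AssaySheetRow:
    sample: str
    breakpoint_a: str
    breakpoint_b: str
    primer_a: str
    primer_b: str
    orientation: str
    probe: str
    annealing_temp_C: str

    def junction_spec(self) -> JunctionSpec:
        return parse_bracket_notation(
            self.breakpoint_a, self.breakpoint_b, self.orientation
        )


def assay_to_sheet_row(
    assay: AssayDesign, spec: JunctionSpec, sample: str
) -> AssaySheetRow:
    tok_a, tok_b, orientation = format_bracket_notation(spec)
    return AssaySheetRow(
        sample=sample,
        breakpoint_a=tok_a,
        breakpoint_b=tok_b,
        primer_a=assay.fwd_primer.sequence,
        primer_b=assay.rev_primer.sequence,
        orientation=orientation,
        probe=assay.probe.sequence,
        annealing_temp_C=f"{assay.annealing_temp_C:g}",
    )


def emit_assay_sheet(rows: Sequence[AssaySheetRow], path) -> None:
    """Write a tab-separated assay sheet (UTF-8, header row)."""
    if not rows:
        raise ValidationError("refusing to emit an empty assay sheet")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SHEET_COLUMNS)
        for row in rows:
            writer.writerow([getattr(row, f.name) for f in fields(AssaySheetRow)])


def read_assay_sheet(path) -> list[AssaySheetRow]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(SHEET_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"assay sheet missing columns: {sorted(missing)}")
        return [AssaySheetRow(**{k: row[k] for k in SHEET_COLUMNS}) for row in reader]


def bundled_ewsfli1_sheet() -> list[AssaySheetRow]:
    """The bundled six-assay EWSR1-FLI1 reference sheet."""
    ref = resources.files("breaktracer").joinpath("data/ewsfli1_assays.tsv")
    with resources.as_file(ref) as path:
        return read_assay_sheet(path)
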