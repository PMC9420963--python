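"""CSV dialects for droplet data, sample metadata and quantification results.

Droplet dialect A: one row per droplet — ``well,sample,assay,role,
fluorescence``.  Dialect B: one row per well — ``well,sample,assay,role,
n_total,n_positive``.  The dialect is detected from the header.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .quant import DropletWell, QuantResult

_DIALECT_A = {"well", "sample", "assay", "role", "fluorescence"}
_DIALECT_B = {"well", "sample", "assay", "role", "n_total", "n_positive"}


def write_droplet_csv(wells: Sequence[DropletWell], path) -> None:
    """Write wells in dialect A (fluorescence) or B (counts-only)."""
    if not wells:
        raise ValidationError("no wells to write")
    if all(w.fluorescence is not None for w in wells):
        rows = []
        for w in wells:
            for v in w.fluorescence:
                rows.append((w.well_id, w.sample_id, w.assay_id, w.role, float(v)))
        df = pd.DataFrame(rows, columns=["well", "sample", "assay", "role", "fluorescence"])
    else:
        rows = []
        for w in wells:
            t, p = w.counts()
            rows.append((w.well_id, w.sample_id, w.assay_id, w.role, t, p))
        df = pd.DataFrame(
            rows, columns=["well", "sample", "assay", "role", "n_total", "n_positive"]
        )
    df.to_csv(path, index=False)


def read_droplet_csv(path) -> list[DropletWell]:
    """Read droplet wells from either CSV dialect."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if _DIALECT_A <= cols:
        wells = []
        for (well, sample, assay, role), grp in df.groupby(
            ["well", "sample", "assay", "role"], sort=False
        ):
            wells.append(
                DropletWell(
                    well_id=str(well),
                    sample_id=str(sample),
                    assay_id=str(assay),
                    role=str(role),
                    fluorescence=grp["fluorescence"].to_numpy(float),
                )
            )
        return wells
    if _DIALECT_B <= cols:
        return [
            DropletWell(
                well_id=str(r.well),
                sample_id=str(r.sample),
                assay_id=str(r.assay),
                role=str(r.role),
                n_total=int(r.n_total),
                n_positive=int(r.n_positive),
            )
            for r in df.itertuples()
        ]
    raise ValidationError(
        f"unrecognized droplet CSV columns {sorted(cols)}; expected "
        f"{sorted(_DIALECT_A)} or {sorted(_DIALECT_B)}"
    )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    date: dt.date
    plasma_volume_mL: float = 2.0
    note: str | None = None


def read_sample_metadata(path) -> list[SampleMeta]:
    """Sample metadata CSV: sample,patient,date[,plasma_ml,note]."""
    df = pd.read_csv(path)
    required = {"sample", "patient", "date"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"metadata CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out = []
    for r in df.itertuples():
        out.append(
            SampleMeta(
                sample_id=str(r.sample),
                patient_id=str(r.patient),
                date=dt.date.fromisoformat(str(r.date)),
                plasma_volume_mL=float(getattr(r, "plasma_ml", 2.0)),
                note=str(r.note) if hasattr(r, "note") and pd.notna(r.note) else None,
            )
        )
    return out


def _result_record(res: QuantResult) -> dict:
    return {
        "sample": res.sample_id,
        "assay": res.assay_id,
        "n_total": res.n_total,
        "n_positive": res.n_positive,
        "lambda": res.lam,
        "conc_copies_per_ul": res.conc_copies_per_uL,
        "conc_ci95_low": res.conc_ci95[0],
        "conc_ci95_high": res.conc_ci95[1],
        "copies_per_ml": res.copies_per_mL_plasma,
        "copies_per_ml_ci95_low": res.copies_per_mL_ci95[0],
        "copies_per_ml_ci95_high": res.copies_per_mL_ci95[1],
        "lod_copies_per_ml": res.lod_copies_per_mL,
        "allelic_fraction": res.allelic_fraction,
        "detectability": res.detectability,
        "qc_flags": ";".join(res.qc_flags),
    }


def write_results_csv(results: Sequence[QuantResult], path) -> None:
    if not results:
        raise ValidationError("no results to write")
    pd.DataFrame([_result_record(r) for r in results]).to_csv(path, index=False)


def write_results_json(results: Sequence[QuantResult], path, provenance=None) -> None:
    payload = {"results": [_result_record(r) for r in results]}
    if provenance:
        payload["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    raise TypeError(f"not JSON serializable: {obj!r}")


def read_results_csv(path) -> list[QuantResult]:
    df = pd.read_csv(path)
    out = []
    for r in df.to_dict("records"):
        raw_flags = r.get("qc_flags")
        flags = (
            str(raw_flags).split(";")
            if raw_flags is not None and pd.notna(raw_flags) and str(raw_flags)
            else []
        )
        af = r.get("allelic_fraction")
        out.append(
            QuantResult(
                sample_id=str(r["sample"]),
                assay_id=str(r["assay"]),
                n_total=int(r["n_total"]),
                n_positive=int(r["n_positive"]),
                lam=float(r["lambda"]),
                conc_copies_per_uL=float(r["conc_copies_per_ul"]),
                conc_ci95=(float(r["conc_ci95_low"]), float(r["conc_ci95_high"])),
                copies_per_mL_plasma=float(r["copies_per_ml"]),
                copies_per_mL_ci95=(
                    float(r["copies_per_ml_ci95_low"]),
                    float(r["copies_per_ml_ci95_high"]),
                ),
                lod_copies_per_mL=float(r["lod_copies_per_ml"]),
                detectability=str(r["detectability"]),
                allelic_fraction=float(af) if af is not None and pd.notna(af) else None,
                qc_flags=flags,
            )
        )
    return out
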