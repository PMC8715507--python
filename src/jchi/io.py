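"""Delimited-text readers/writers for the package's table formats.

All tables are comma- or tab-separated (autodetected), require a header
row, use decimal points, degrees and Hz.  Unknown columns are preserved
on read and round-tripped on write.

Schemas
-------
coefficient table : residue_type, coupling_id, c0, c1, c2, c3, s1, s2
                    [+ optional backbone, method, basis, chi2_treatment]
scan table        : chi1_deg, coupling_id, j_hz
coupling table    : residue_id, residue_type, coupling_id, j_exp_hz
angle table       : residue_id, chi1_deg [+ optional source]
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping

import pandas as pd

from .conformers import ResidueCouplings
from .errors import SchemaError
from .karplus import FourierCoefficients, KarplusSet, ScanTable, TERM_NAMES

__all__ = [
    "read_table",
    "write_table",
    "read_scan_table",
    "write_scan_table",
    "read_coefficient_table",
    "write_coefficient_table",
    "karplus_sets_from_frame",
    "read_coupling_table",
    "read_angle_table",
]

_SCHEMAS = {
    "scan": ("chi1_deg", "coupling_id", "j_hz"),
    "coefficients": ("residue_type", "coupling_id") + TERM_NAMES,
    "couplings": ("residue_id", "residue_type", "coupling_id", "j_exp_hz"),
    "angles": ("residue_id", "chi1_deg"),
}


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise SchemaError(f"{path}: file is empty")


def read_table(path, kind: str) -> pd.DataFrame:
    """Read a delimited table and validate its mandatory columns."""
    path = Path(path)
    required = _SCHEMAS[kind]
    frame = pd.read_csv(path, sep=_detect_sep(path), comment="#")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {missing}; expected schema "
            f"for a {kind} table: {list(required)}"
        )
    return frame


def write_table(frame: pd.DataFrame, path, sep: str = ",") -> None:
    frame.to_csv(Path(path), sep=sep, index=False)


def read_scan_table(path) -> ScanTable:
    frame = read_table(path, "scan")
    return ScanTable(
        chi1=frame["chi1_deg"].to_numpy(),
        coupling_id=frame["coupling_id"].to_numpy(),
        j_value=frame["j_hz"].to_numpy(),
        provenance={"path": str(path)},
    )


def write_scan_table(scan: ScanTable, path, sep: str = ",") -> None:
    write_table(scan.to_frame(), path, sep=sep)


def _coefficients_from_row(row) -> FourierCoefficients:
    meta = {}
    for attr in ("method", "basis", "backbone", "chi2_treatment"):
        if attr in row.index and not pd.isna(row[attr]):
            meta[attr] = str(row[attr])
    return FourierCoefficients(
        **{t: float(row[t]) for t in TERM_NAMES},
        residue_type=str(row["residue_type"]),
        **meta,
    )


def read_coefficient_table(path) -> pd.DataFrame:
    return read_table(path, "coefficients")


def karplus_sets_from_frame(frame: pd.DataFrame) -> Dict[str, KarplusSet]:
    """Build one KarplusSet per residue type from a coefficient table."""
    out = {}
    for rtype, group in frame.groupby("residue_type"):
        dupes = group["coupling_id"][group["coupling_id"].duplicated()]
        if not dupes.empty:
            raise SchemaError(
                f"duplicate coupling_id rows for {rtype}: {sorted(set(dupes))}"
            )
        entries = {
            str(row["coupling_id"]): _coefficients_from_row(row)
            for _, row in group.iterrows()
        }
        out[str(rtype).upper()] = KarplusSet(str(rtype), entries)
    return out


def read_karplus_sets(path) -> Dict[str, KarplusSet]:
    return karplus_sets_from_frame(read_coefficient_table(path))


def write_coefficient_table(
    ksets: Mapping[str, KarplusSet] | KarplusSet, path, sep: str = ","
) -> None:
    if isinstance(ksets, KarplusSet):
        ksets = {ksets.residue_type: ksets}
    rows = []
    for rtype, kset in ksets.items():
        for cid in kset.coupling_ids:
            c = kset.coefficients(cid)
            rows.append(
                {
                    "residue_type": rtype,
                    "coupling_id": cid,
                    **{t: getattr(c, t) for t in TERM_NAMES},
                    "backbone": c.backbone,
                    "method": c.method,
                    "basis": c.basis,
                }
            )
    write_table(pd.DataFrame(rows), path, sep=sep)


def read_coupling_table(path) -> List[ResidueCouplings]:
    """Read per-residue experimental couplings, preserving file order."""
    frame = read_table(path, "couplings")
    residues: List[ResidueCouplings] = []
    for (rid, rtype), group in frame.groupby(
        ["residue_id", "residue_type"], sort=False
    ):
        dupes = group["coupling_id"][group["coupling_id"].duplicated()]
        if not dupes.empty:
            raise SchemaError(
                f"duplicate coupling rows for residue {rid}: {sorted(set(dupes))}"
            )
        measurements = dict(
            zip(group["coupling_id"].astype(str), group["j_exp_hz"].astype(float))
        )
        residues.append(
            ResidueCouplings(
                residue_id=str(rid),
                residue_type=str(rtype),
                measurements=measurements,
            )
        )
    return residues


def read_angle_table(path) -> pd.DataFrame:
    return read_table(path, "angles")
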