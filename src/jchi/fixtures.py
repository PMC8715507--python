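"""Packaged reference tables: 29 Val/Leu/Ile residues of D. vulgaris
flavodoxin with per-residue model results, coupling counts and reference
angles (25 unimodal residues in ``table1``, 4 trimodal residues with two
UMS minima and dual X-ray means in ``table4``).

Populations are stored in percent, angles in degrees, rmsd values in Hz.
File integrity is verified by SHA-256 on load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import FixtureIntegrityError

__all__ = ["FixtureTables", "load_fixture"]

_CHECKSUMS = {
    "table1.csv": "9d577ede80fd245a06e0f91775f4ae0cf314fc39f1706958a97abe50feabf578",
    "table4.csv": "319290dc5201628fe0ed6f8ee9e4b7119029b240cda877ebdb472ba9368dc299",
}

_TRIMODAL_IDS = ("Val88", "Val144", "Leu78", "Ile148")


@dataclass(frozen=True)
class FixtureTables:
    table1: pd.DataFrame
    table4: pd.DataFrame

    @property
    def residue_ids(self) -> tuple:
        return tuple(self.table1["residue_id"]) + tuple(self.table4["residue_id"])


def _read_checked(name: str) -> pd.DataFrame:
    ref = resources.files("jchi.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"packaged table {name} failed its checksum "
            f"(got {digest}, expected {_CHECKSUMS[name]})"
        )
    import io

    return pd.read_csv(io.BytesIO(raw))


def load_fixture() -> FixtureTables:
    """Load the packaged reference tables, validating integrity."""
    table1 = _read_checked("table1.csv")
    table4 = _read_checked("table4.csv")
    if len(table1) != 25 or len(table4) != 4:
        raise FixtureIntegrityError("unexpected fixture row counts")
    if int(table1["n_j"].sum()) != 181:
        raise FixtureIntegrityError("table1 coupling counts do not sum to 181")
    if tuple(table4["residue_id"]) != _TRIMODAL_IDS:
        raise FixtureIntegrityError("table4 residue ids are corrupted")
    if table1["residue_id"].iloc[0] != "Val7" or table1["residue_id"].iloc[-1] != "Ile137":
        raise FixtureIntegrityError("table1 residue ids are corrupted")
    return FixtureTables(table1=table1, table4=table4)
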