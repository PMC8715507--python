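"""Coupling topologies around the Calpha-Cbeta bond.

For Val, Leu and Ile nine vicinal couplings cross the Calpha-Cbeta bond;
they fall into six types depending on the coupled nuclei:
J(HA,HB), J(HA,CG), J(CP,HB), J(CP,CG), J(NP,HB) and J(NP,CG), where
HA is the alpha proton, CP the carbonyl carbon and NP the backbone amide
nitrogen of the preceding peptide unit.

Each coupling path has a dihedral theta = chi1 + delta_theta.  The
default phase shifts shipped here follow the ideal tetrahedral
convention (delta_theta in {0, +120, -120}); branch assignments for the
beta protons and gamma substituents are recorded in ``data/topology.csv``
and can be overridden per coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, Mapping

import pandas as pd

from ._angles import wrap_degrees
from .errors import InvalidInputError, MissingCouplingError

__all__ = [
    "CouplingTopology",
    "ResidueTopology",
    "coupling_type",
    "residue_topology",
    "register_topology",
    "known_residue_types",
    "COUPLING_TYPES",
]

#: The six coupling types, keyed by (alpha-side class, beta-side class).
COUPLING_TYPES = (
    "HA_HB",
    "HA_CG",
    "CP_HB",
    "CP_CG",
    "NP_HB",
    "NP_CG",
)

_ALPHA_CLASSES = {"HA": "HA", "CP": "CP", "NP": "NP"}


def _beta_class(nucleus: str) -> str:
    if nucleus.startswith("HB"):
        return "HB"
    if nucleus.startswith("CG"):
        return "CG"
    raise InvalidInputError(f"unrecognised beta-side nucleus {nucleus!r}")


def coupling_type(nucleus_x: str, nucleus_y: str) -> str:
    """Map a coupled-nucleus pair to one of the six coupling types."""
    if nucleus_x not in _ALPHA_CLASSES:
        raise InvalidInputError(f"unrecognised alpha-side nucleus {nucleus_x!r}")
    return f"{_ALPHA_CLASSES[nucleus_x]}_{_beta_class(nucleus_y)}"


@dataclass(frozen=True)
class CouplingTopology:
    """Identity of one vicinal coupling path around Calpha-Cbeta.

    ``delta_theta`` (degrees, in (-180, 180]) maps chi1 to the dihedral
    of the coupled-nucleus pair: theta = chi1 + delta_theta.
    """

    coupling_id: str
    nucleus_x: str
    nucleus_y: str
    delta_theta: float

    def __post_init__(self):
        dt = float(self.delta_theta)
        if not -180.0 < dt <= 180.0:
            raise InvalidInputError(
                f"delta_theta must lie in (-180, 180], got {dt}"
            )
        coupling_type(self.nucleus_x, self.nucleus_y)  # validates nuclei

    @property
    def type(self) -> str:
        return coupling_type(self.nucleus_x, self.nucleus_y)


class ResidueTopology:
    """The coupling-topology table of one residue type."""

    def __init__(self, residue_type: str, couplings: Iterable[CouplingTopology]):
        self.residue_type = residue_type
        self._by_id: Dict[str, CouplingTopology] = {}
        for c in couplings:
            if c.coupling_id in self._by_id:
                raise InvalidInputError(
                    f"duplicate coupling_id {c.coupling_id!r} in topology for "
                    f"{residue_type}"
                )
            self._by_id[c.coupling_id] = c
        types = {c.type for c in self._by_id.values()}
        if len(self._by_id) == 9 and types != set(COUPLING_TYPES):
            raise InvalidInputError(
                f"nine-coupling topology for {residue_type} must cover the six "
                f"coupling types; found {sorted(types)}"
            )

    def __contains__(self, coupling_id: str) -> bool:
        return coupling_id in self._by_id

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def coupling_ids(self) -> tuple:
        return tuple(self._by_id)

    def __getitem__(self, coupling_id: str) -> CouplingTopology:
        try:
            return self._by_id[coupling_id]
        except KeyError:
            raise MissingCouplingError(
                f"coupling {coupling_id!r} not in topology for {self.residue_type}"
            ) from None

    def with_overrides(self, delta_theta: Mapping[str, float]) -> "ResidueTopology":
        """Return a copy with per-coupling delta_theta replacements."""
        new = []
        for c in self:
            if c.coupling_id in delta_theta:
                new.append(
                    CouplingTopology(
                        c.coupling_id,
                        c.nucleus_x,
                        c.nucleus_y,
                        wrap_degrees(delta_theta[c.coupling_id]),
                    )
                )
            else:
                new.append(c)
        return ResidueTopology(self.residue_type, new)


_REGISTRY: Dict[str, ResidueTopology] = {}


def _load_builtin() -> None:
    with resources.files("jchi.data").joinpath("topology.csv").open() as fh:
        frame = pd.read_csv(fh, comment="#")
    for rtype, group in frame.groupby("residue_type"):
        _REGISTRY[str(rtype)] = ResidueTopology(
            str(rtype),
            (
                CouplingTopology(
                    row.coupling_id, row.nucleus_x, row.nucleus_y, row.delta_theta
                )
                for row in group.itertuples()
            ),
        )


def residue_topology(residue_type: str) -> ResidueTopology:
    """Look up the (possibly user-registered) topology for a residue type."""
    if not _REGISTRY:
        _load_builtin()
    try:
        return _REGISTRY[residue_type.upper()]
    except KeyError:
        raise MissingCouplingError(
            f"no coupling topology registered for residue type {residue_type!r}"
        ) from None


def register_topology(topology: ResidueTopology) -> None:
    """Register (or replace) a residue-type topology table."""
    if not _REGISTRY:
        _load_builtin()
    _REGISTRY[topology.residue_type.upper()] = topology


def known_residue_types() -> tuple:
    if not _REGISTRY:
        _load_builtin()
    return tuple(sorted(_REGISTRY))
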