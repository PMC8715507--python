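"""Synthetic scan tables and residue couplings with known ground truth.

Every inference stage can be exercised without external data: couplings
are generated from a Karplus set as a pure conformer or a rotamer
mixture, optionally masked and perturbed with independent Gaussian noise
(numpy ``default_rng``, i.e. the PCG64 generator, so fixed seeds give
identical output on every platform).

The demonstration coefficient sets returned by :func:`demo_karplus_set`
are synthetic: Karplus-like in shape and magnitude but not taken from
any published parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .conformers import ResidueCouplings
from .errors import InvalidInputError
from .karplus import FourierCoefficients, KarplusSet, ScanTable, evaluate_karplus
from .topology import residue_topology

__all__ = [
    "GroundTruth",
    "generate_scan",
    "generate_residue",
    "demo_karplus_set",
]


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of one synthetic residue.

    ``mode`` is ``pure`` (single conformer at ``chi1``), ``staggered``
    (mixture at 60/180/-60 with ``populations``) or ``trigonal``
    (mixture at ``chi1``, ``chi1+120``, ``chi1-120``).
    """

    kset: KarplusSet
    mode: str = "pure"
    chi1: float = 180.0
    populations: tuple = (1.0, 0.0, 0.0)
    sigma: float = 0.0
    mask: tuple = ()  # coupling_ids to drop; empty = keep all
    seed: int = 0
    residue_id: str = "synthetic"

    def __post_init__(self):
        if self.mode not in ("pure", "staggered", "trigonal"):
            raise InvalidInputError(f"unknown generating mode {self.mode!r}")
        if self.sigma < 0:
            raise InvalidInputError("noise sigma must be >= 0")
        p = np.asarray(self.populations, dtype=float)
        if self.mode != "pure" and (
            p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9
        ):
            raise InvalidInputError("populations must be a 3-vector on the simplex")

    @property
    def conformers(self) -> tuple:
        """((chi1, population), ...) of the generating mixture."""
        if self.mode == "pure":
            return ((self.chi1, 1.0),)
        if self.mode == "staggered":
            angles = (60.0, 180.0, -60.0)
        else:
            angles = (self.chi1, self.chi1 + 120.0, self.chi1 - 120.0)
        return tuple(zip(angles, map(float, self.populations)))


def generate_scan(
    kset: KarplusSet,
    angles: Sequence[float],
    sigma: float = 0.0,
    seed: int = 0,
) -> ScanTable:
    """Sample every coupling of *kset* at the given chi1 angles.

    With ``sigma=0`` the rows are exact curve samples; otherwise
    independent Gaussian noise (Hz) is added per row.
    """
    if sigma < 0:
        raise InvalidInputError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    chi1_col, cid_col, j_col = [], [], []
    for cid in kset.coupling_ids:
        coeffs = kset.coefficients(cid)
        dtheta = kset.topology[cid].delta_theta
        for chi1 in angles:
            chi1_col.append(float(chi1))
            cid_col.append(cid)
            j_col.append(evaluate_karplus(coeffs, chi1 + dtheta))
    j = np.asarray(j_col, dtype=float)
    if sigma > 0:
        j = j + rng.normal(0.0, sigma, size=j.shape)
    return ScanTable(
        chi1=np.asarray(chi1_col),
        coupling_id=np.asarray(cid_col, dtype=object),
        j_value=j,
        provenance={"generator": "jchi.synth.generate_scan", "seed": str(seed)},
    )


def generate_residue(truth: GroundTruth) -> ResidueCouplings:
    """Generate one residue's couplings from a ground-truth mixture."""
    kset = truth.kset
    ids = tuple(c for c in kset.coupling_ids if c not in set(truth.mask))
    if not ids:
        raise InvalidInputError("mask removes every coupling")
    values = {cid: 0.0 for cid in ids}
    for angle, pop in truth.conformers:
        if pop == 0.0:
            continue
        evaluated = kset.evaluate_at_chi1(angle, ids)
        for cid in ids:
            values[cid] += pop * evaluated[cid]
    if truth.sigma > 0:
        rng = np.random.default_rng(truth.seed)
        noise = rng.normal(0.0, truth.sigma, size=len(ids))
        values = {cid: v + e for (cid, v), e in zip(values.items(), noise)}
    return ResidueCouplings(
        residue_id=truth.residue_id,
        residue_type=kset.residue_type,
        measurements=values,
    )


# Synthetic demonstration coefficients, one per coupling type.  Shapes are
# Karplus-like (dominant cos/cos2 terms, negative C1 for C/H couplings,
# positive C1 for the nitrogen couplings) but the numbers are invented.
_DEMO_BY_TYPE: Mapping[str, tuple] = {
    #         c0     c1     c2    c3    s1     s2
    "HA_HB": (6.94, -1.20, 5.01, 0.30, 0.15, -0.20),
    "HA_CG": (3.66, -0.82, 2.55, 0.12, 0.10, 0.08),
    "CP_HB": (3.87, -0.95, 2.90, 0.18, -0.12, 0.10),
    "CP_CG": (1.82, -0.60, 1.30, 0.05, 0.06, -0.04),
    "NP_HB": (-2.70, 0.65, -1.95, -0.08, 0.05, 0.06),
    "NP_CG": (-1.10, 0.42, -0.95, -0.04, -0.03, 0.02),
}


def demo_karplus_set(residue_type: str = "VAL") -> KarplusSet:
    """A clearly-synthetic Karplus set covering all nine couplings of the
    given residue type (for demos, tests and the ``simulate`` command)."""
    topo = residue_topology(residue_type)
    entries = {}
    for coupling in topo:
        base = _DEMO_BY_TYPE[coupling.type]
        # small deterministic per-coupling offset so branch couplings differ
        tweak = 0.07 * (sum(ord(ch) for ch in coupling.coupling_id) % 5 - 2)
        values = (base[0] + tweak,) + base[1:]
        entries[coupling.coupling_id] = FourierCoefficients.from_array(
            values,
            method="synthetic-demo",
            residue_type=residue_type.upper(),
        )
    return KarplusSet(residue_type, entries, topology=topo)
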