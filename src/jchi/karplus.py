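"""Extended Karplus (Fourier) equations: evaluation, fitting, comparison.

The coupling/dihedral relationship is the six-term truncated Fourier
series

    J(theta) = C0 + C1 cos(theta) + C2 cos(2 theta) + C3 cos(3 theta)
                  + S1 sin(theta) + S2 sin(2 theta)

with theta in degrees and J in Hz.  Coefficients are obtained by ordinary
least squares on dihedral scans; the canonical scan samples the six
angles 0, 60, 120, 180, -120, -60 degrees, on which the design is a
complete real Fourier basis and the fit interpolates exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._angles import wrap_degrees
from .errors import (
    InvalidInputError,
    MissingCouplingError,
    RankDeficientError,
)
from .topology import CouplingTopology, ResidueTopology, residue_topology

__all__ = [
    "FourierCoefficients",
    "KarplusSet",
    "ScanTable",
    "CANONICAL_ANGLES",
    "TERM_NAMES",
    "evaluate_karplus",
    "fit_coefficients",
    "rmsd_couplings",
    "rmsd_coefficients",
    "awrmsd",
]

#: Scan angles (degrees) on which six Fourier terms are exactly determined.
CANONICAL_ANGLES = (0.0, 60.0, 120.0, 180.0, -120.0, -60.0)

#: Order of the Fourier terms throughout the package.
TERM_NAMES = ("c0", "c1", "c2", "c3", "s1", "s2")


@dataclass(frozen=True)
class FourierCoefficients:
    """Six Fourier coefficients (Hz) of one extended Karplus equation.

    Metadata labels are opaque strings describing provenance; ``backbone``
    is one of ``alpha``, ``beta`` or ``unspecified``.
    """

    c0: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    s1: float = 0.0
    s2: float = 0.0
    method: str = ""
    basis: str = ""
    residue_type: str = ""
    backbone: str = "unspecified"
    chi2_treatment: str = ""

    def __post_init__(self):
        for name in TERM_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise InvalidInputError(f"coefficient {name} must be finite")
        if self.backbone not in ("alpha", "beta", "unspecified"):
            raise InvalidInputError(
                f"backbone label must be alpha/beta/unspecified, got {self.backbone!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TERM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float], **metadata) -> "FourierCoefficients":
        if len(values) != 6:
            raise InvalidInputError("expected six coefficients (c0..s2)")
        return cls(**dict(zip(TERM_NAMES, map(float, values))), **metadata)


def _design_matrix(theta_deg: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    t = np.radians(theta_deg)
    columns = {
        "c0": np.ones_like(t),
        "c1": np.cos(t),
        "c2": np.cos(2 * t),
        "c3": np.cos(3 * t),
        "s1": np.sin(t),
        "s2": np.sin(2 * t),
    }
    return np.column_stack([columns[name] for name in terms])


def evaluate_karplus(coeffs: FourierCoefficients, theta) -> float | np.ndarray:
    """Evaluate the Karplus curve at dihedral *theta* (degrees).

    Accepts scalars or arrays; periodic with period 360 degrees.
    """
    t = np.radians(np.asarray(theta, dtype=float))
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("theta must be finite")
    value = (
        coeffs.c0
        + coeffs.c1 * np.cos(t)
        + coeffs.c2 * np.cos(2 * t)
        + coeffs.c3 * np.cos(3 * t)
        + coeffs.s1 * np.sin(t)
        + coeffs.s2 * np.sin(2 * t)
    )
    if value.ndim == 0:
        return float(value)
    return value


class KarplusSet:
    """Karplus coefficients for (a subset of) one residue type's couplings."""

    def __init__(
        self,
        residue_type: str,
        entries: Mapping[str, FourierCoefficients],
        topology: ResidueTopology | None = None,
    ):
        self.residue_type = residue_type.upper()
        self.entries: Dict[str, FourierCoefficients] = dict(entries)
        self.topology = topology if topology is not None else residue_topology(
            self.residue_type
        )
        for cid in self.entries:
            self.topology[cid]  # raises MissingCouplingError if absent

    @property
    def coupling_ids(self) -> tuple:
        return tuple(self.entries)

    def __contains__(self, coupling_id: str) -> bool:
        return coupling_id in self.entries

    def coefficients(self, coupling_id: str) -> FourierCoefficients:
        try:
            return self.entries[coupling_id]
        except KeyError:
            raise MissingCouplingError(
                f"no Karplus coefficients for coupling {coupling_id!r} "
                f"({self.residue_type})"
            ) from None

    def evaluate_at_chi1(
        self, chi1, coupling_ids: Iterable[str] | None = None
    ) -> Dict[str, float | np.ndarray]:
        """Evaluate every requested coupling at theta = chi1 + delta_theta."""
        ids = tuple(coupling_ids) if coupling_ids is not None else self.coupling_ids
        out = {}
        for cid in ids:
            coeffs = self.coefficients(cid)
            dtheta = self.topology[cid].delta_theta
            out[cid] = evaluate_karplus(coeffs, np.asarray(chi1, dtype=float) + dtheta)
        return out


@dataclass(frozen=True)
class ScanTable:
    """Rows of (chi1 degrees, coupling_id, J Hz) from a dihedral scan."""

    chi1: np.ndarray
    coupling_id: np.ndarray
    j_value: np.ndarray
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        chi1 = wrap_degrees(np.asarray(self.chi1, dtype=float))
        cid = np.asarray(self.coupling_id, dtype=object)
        j = np.asarray(self.j_value, dtype=float)
        if not (len(chi1) == len(cid) == len(j)):
            raise InvalidInputError("scan table columns must have equal length")
        if not np.all(np.isfinite(j)):
            raise InvalidInputError("scan J values must be finite")
        pairs = list(zip(np.round(chi1, 9), cid))
        dupes = {p for p in pairs if pairs.count(p) > 1}
        if dupes:
            raise InvalidInputError(
                f"duplicate (chi1, coupling) rows in scan table: {sorted(dupes)}"
            )
        object.__setattr__(self, "chi1", chi1)
        object.__setattr__(self, "coupling_id", cid)
        object.__setattr__(self, "j_value", j)

    def select(self, coupling_id: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.coupling_id == coupling_id
        if not mask.any():
            raise MissingCouplingError(
                f"scan table has no rows for coupling {coupling_id!r}"
            )
        return self.chi1[mask], self.j_value[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chi1_deg": self.chi1,
                "coupling_id": self.coupling_id,
                "j_hz": self.j_value,
            }
        )


def _deficient_columns(design: np.ndarray, terms: Sequence[str]) -> list[str]:
    # greedy rank growth; columns that add no rank are reported
    bad, kept = [], np.empty((design.shape[0], 0))
    for j, name in enumerate(terms):
        trial = np.column_stack([kept, design[:, j]])
        if np.linalg.matrix_rank(trial, tol=1e-8) > kept.shape[1]:
            kept = trial
        else:
            bad.append(name)
    return bad


def fit_coefficients(
    scan: ScanTable,
    coupling_id: str,
    terms: Sequence[str] = TERM_NAMES,
    delta_theta: float = 0.0,
    constrain_c1: str | None = None,
) -> tuple[FourierCoefficients, float]:
    """Least-squares fit of the requested Fourier terms to one coupling's scan.

    Scan angles are chi1 values; they are mapped to the coupling-path
    dihedral theta = chi1 + delta_theta before fitting.  Unrequested terms
    are fixed at zero.  Returns ``(coefficients, rms_residual_hz)``.

    ``constrain_c1`` may be ``"negative"`` or ``"positive"``: if the
    unconstrained C1 estimate violates the sign, the fit is repeated with
    C1 pinned at zero (the active-constraint optimum of the convex
    problem), mirroring the sign conventions of empirical
    parameterizations (positive for 15N couplings, negative otherwise).
    """
    terms = tuple(t.lower() for t in terms)
    unknown = [t for t in terms if t not in TERM_NAMES]
    if unknown:
        raise InvalidInputError(f"unknown Fourier terms {unknown}")
    if len(set(terms)) != len(terms):
        raise InvalidInputError("duplicate Fourier terms requested")
    chi1, j = scan.select(coupling_id)
    theta = wrap_degrees(chi1 + float(delta_theta))
    n_distinct = len(np.unique(np.round(theta, 9)))
    if n_distinct < len(terms):
        raise InvalidInputError(
            f"{n_distinct} distinct angles cannot determine {len(terms)} terms"
        )
    design = _design_matrix(theta, terms)
    rank = np.linalg.matrix_rank(design, tol=1e-8)
    if rank < len(terms):
        bad = _deficient_columns(design, terms)
        raise RankDeficientError(
            f"design matrix rank {rank} < {len(terms)} requested terms; "
            f"deficient columns: {bad}",
            deficient_columns=bad,
        )
    beta, *_ = np.linalg.lstsq(design, j, rcond=None)
    values = dict(zip(terms, beta))
    if constrain_c1 in ("negative", "positive") and "c1" in terms:
        sign = -1.0 if constrain_c1 == "negative" else 1.0
        if sign * values["c1"] < 0.0:
            reduced = tuple(t for t in terms if t != "c1")
            if reduced:
                sub = _design_matrix(theta, reduced)
                beta_r, *_ = np.linalg.lstsq(sub, j, rcond=None)
                values = dict(zip(reduced, beta_r))
            else:
                values = {}
            values["c1"] = 0.0
    elif constrain_c1 not in (None, "negative", "positive"):
        raise InvalidInputError(
            f"constrain_c1 must be None, 'negative' or 'positive', got {constrain_c1!r}"
        )
    full = {name: float(values.get(name, 0.0)) for name in TERM_NAMES}
    coeffs = FourierCoefficients(**full)
    residual = j - evaluate_karplus(coeffs, theta)
    rms = float(np.sqrt(np.mean(residual**2)))
    return coeffs, rms


def rmsd_couplings(
    set1: Mapping[str, float], set2: Mapping[str, float]
) -> float:
    """Root-mean-square deviation (Hz) over the couplings shared by two sets."""
    shared = sorted(set(set1) & set(set2))
    if not shared:
        raise InvalidInputError("coupling sets share no keys")
    d = np.array([set1[k] - set2[k] for k in shared], dtype=float)
    return float(np.sqrt(np.mean(d**2)))


def rmsd_coefficients(
    k1: FourierCoefficients, k2: FourierCoefficients, mode: str = "grid"
) -> float:
    """rmsd (Hz) between two coefficient sets.

    ``mode="grid"`` (default) is exactly equivalent to sampling both
    curves at the six canonical angles and applying :func:`rmsd_couplings`;
    by discrete orthogonality on the 60-degree grid the C3 harmonic
    aliases onto itself with full weight:

        sqrt(dC0^2 + (dC1^2 + dC2^2 + dS1^2 + dS2^2)/2 + dC3^2)

    ``mode="continuous"`` uses the continuous Parseval weights (1/2 also
    for the C3 term).
    """
    d = k1.as_array() - k2.as_array()
    dc0, dc1, dc2, dc3, ds1, ds2 = d
    half = (dc1**2 + dc2**2 + ds1**2 + ds2**2) / 2.0
    if mode == "grid":
        return float(np.sqrt(dc0**2 + half + dc3**2))
    if mode == "continuous":
        return float(np.sqrt(dc0**2 + half + dc3**2 / 2.0))
    raise InvalidInputError(f"mode must be 'grid' or 'continuous', got {mode!r}")


def awrmsd(
    rmsds: Mapping[str, float], reference_c0: Mapping[str, float]
) -> float:
    """Average weighted relative rmsd, in percent.

    Weights are reference |C0| values (the average couplings); the result
    is 100 * sum(rmsd_i) / sum(|C0_i|) over the rmsd keys.  Rescaling all
    rmsds and weights by a common factor (a change of Hz units) leaves
    the value unchanged.
    """
    if not rmsds:
        raise InvalidInputError("no rmsd values supplied")
    missing = sorted(set(rmsds) - set(reference_c0))
    if missing:
        raise InvalidInputError(f"no |C0| weight for couplings {missing}")
    weights = {k: abs(float(reference_c0[k])) for k in rmsds}
    bad = sorted(k for k, w in weights.items() if w <= 0)
    if bad:
        raise InvalidInputError(f"nonpositive |C0| weights for {bad}")
    num = sum(float(rmsds[k]) for k in rmsds)
    den = sum(weights.values())
    return float(100.0 * num / den)
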