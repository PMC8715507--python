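"""Side-chain chi1 inference from experimental couplings.

Three models are fitted per residue:

* UMS (unimodal static): one conformer; chi1 minimizes the rms deviation
  between measured couplings and the Karplus predictions.  The profile
  generally shows two minima ~180 degrees apart (Karplus degeneracy);
  the reported minimum prefers staggered-compatible solutions.
* TMSS (trimodal static staggered): three conformers fixed at chi1 = 60,
  180, -60 degrees; populations solved exactly on the probability
  simplex by active-set enumeration.
* TMST (trimodal static trigonal): three conformers at chi1, chi1+120,
  chi1-120; chi1 scanned over a 120-degree fundamental domain with an
  exact population solve at each angle.

A residue is classified unimodal when the UMS angle falls within a
tolerance of a staggered rotamer and the dominant model population
exceeds a threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np

from ._angles import STAGGERED_ANGLES, nearest_staggered, wrap_degrees
from .circstats import circ_distance
from .errors import DegenerateProfileError, InvalidInputError
from .karplus import KarplusSet
from .topology import residue_topology

__all__ = [
    "ResidueCouplings",
    "UMSProfile",
    "UMSResult",
    "TMSSResult",
    "TMSTResult",
    "ResidueClassification",
    "ums_profile",
    "ums_minima",
    "fit_ums",
    "tmss_populations",
    "tmst_fit",
    "classify_residue",
    "predict_couplings",
    "rmsd_j_tot",
]

#: Width (Hz) above the minimum rmsd defining the chi1 uncertainty region.
DEFAULT_UNCERTAINTY_WINDOW = 0.2


@dataclass(frozen=True)
class ResidueCouplings:
    """One residue's experimental couplings (coupling_id -> Hz)."""

    residue_id: str
    residue_type: str
    measurements: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "measurements", dict(self.measurements))
        if not 1 <= len(self.measurements) <= 9:
            raise InvalidInputError(
                f"{self.residue_id}: expected 1..9 couplings, "
                f"got {len(self.measurements)}"
            )
        topo = residue_topology(self.residue_type)
        for cid, value in self.measurements.items():
            topo[cid]  # raises MissingCouplingError on unknown ids
            if not math.isfinite(value):
                raise InvalidInputError(
                    f"{self.residue_id}: non-finite J for {cid}"
                )
        if len(self.measurements) < 3:
            warnings.warn(
                f"{self.residue_id}: only {len(self.measurements)} couplings; "
                "rotamer populations are under-determined",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return len(self.measurements)

    @property
    def coupling_ids(self) -> tuple:
        return tuple(self.measurements)


@dataclass(frozen=True)
class UMSProfile:
    """rmsd_J(chi1) sampled on a regular grid covering (-180, 180]."""

    chi1: np.ndarray
    rmsd: np.ndarray
    step: float


@dataclass(frozen=True)
class UMSResult:
    """Minima of a UMS profile.  ``minima`` is sorted by ascending rmsd;
    ``uncertainty`` holds the below-/above-minimum extents (degrees) of
    the contiguous region within the uncertainty window of the selected
    minimum."""

    minima: tuple  # ((chi1, rmsd), ...) ascending rmsd
    selected_index: int
    uncertainty: tuple  # (minus_extent, plus_extent)

    @property
    def chi1(self) -> float:
        return self.minima[self.selected_index][0]

    @property
    def rmsd(self) -> float:
        return self.minima[self.selected_index][1]


@dataclass(frozen=True)
class TMSSResult:
    """Staggered-rotamer populations (fractions summing to 1) and the
    minimized rmsd (Hz)."""

    p60: float
    p180: float
    pm60: float
    rmsd: float

    @property
    def populations(self) -> Dict[float, float]:
        return {60.0: self.p60, 180.0: self.p180, -60.0: self.pm60}

    @property
    def dominant_angle(self) -> float:
        return max(self.populations, key=self.populations.get)

    @property
    def max_population(self) -> float:
        return max(self.p60, self.p180, self.pm60)


@dataclass(frozen=True)
class TMSTResult:
    """Trigonal three-conformer fit.  ``chi1`` is the angle of the most
    populated conformer; ``conformers`` lists (angle, population,
    nearest staggered bin) for all three."""

    chi1: float
    conformers: tuple  # ((angle, population, bin), ...) by descending population
    rmsd: float

    @property
    def populations_by_bin(self) -> Dict[float, float]:
        out = {60.0: 0.0, 180.0: 0.0, -60.0: 0.0}
        for _, pop, b in self.conformers:
            out[b] += pop
        return out

    @property
    def max_population(self) -> float:
        return self.conformers[0][1]


@dataclass(frozen=True)
class ResidueClassification:
    label: str  # "unimodal" | "trimodal"
    dominant_bin: float | None
    staggered_test: bool
    staggered_deviation: float
    population_test: bool
    population_value: float


def _prediction_matrix(
    res: ResidueCouplings, kset: KarplusSet, chi1_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(J_exp vector, matrix J_calc[coupling, angle]) for the residue."""
    ids = res.coupling_ids
    j_exp = np.array([res.measurements[c] for c in ids], dtype=float)
    calc = kset.evaluate_at_chi1(chi1_values, ids)
    j_calc = np.vstack([np.atleast_1d(calc[c]) for c in ids])
    return j_exp, j_calc


def ums_profile(
    res: ResidueCouplings, kset: KarplusSet, step: float = 0.1
) -> UMSProfile:
    """Sample rmsd_J,res(chi1) on a regular grid covering (-180, 180]."""
    if step <= 0:
        raise InvalidInputError("grid step must be positive")
    n = int(round(360.0 / step))
    grid = -180.0 + step * np.arange(1, n + 1)
    j_exp, j_calc = _prediction_matrix(res, kset, grid)
    rmsd = np.sqrt(np.mean((j_calc - j_exp[:, None]) ** 2, axis=0))
    return UMSProfile(chi1=grid, rmsd=rmsd, step=step)


def _local_minima(rmsd: np.ndarray) -> list[int]:
    """Indices of local minima of a periodic sequence (plateau left edges)."""
    prev = np.roll(rmsd, 1)
    nxt = np.roll(rmsd, -1)
    is_min = (rmsd <= prev) & (rmsd <= nxt) & ((rmsd < prev) | (rmsd < nxt))
    return list(np.flatnonzero(is_min))


def ums_minima(
    profile: UMSProfile,
    uncertainty_window: float = DEFAULT_UNCERTAINTY_WINDOW,
    staggered_tolerance: float = 30.0,
    prefer_staggered: bool = True,
) -> UMSResult:
    """Locate and rank the minima of a UMS profile.

    Minima are sorted by ascending rmsd (ties by smaller deviation from
    the nearest staggered angle).  The selected minimum is the lowest-rmsd
    minimum lying within ``staggered_tolerance`` of a staggered angle when
    one exists (set ``prefer_staggered=False`` to always take the global
    minimum).  Uncertainty extents are the angular distances from the
    selected minimum to the edges of the contiguous region with
    rmsd <= rmsd_min + window.
    """
    if profile.step > 0.5 + 1e-12:
        raise InvalidInputError("profile must be sampled at <= 0.5 degree steps")
    rmsd, grid = profile.rmsd, profile.chi1
    if np.ptp(rmsd) < 1e-12:
        raise DegenerateProfileError("rmsd profile is flat; chi1 is undetermined")
    idx = _local_minima(rmsd)

    def stag_dev(i: int) -> float:
        return min(circ_distance(grid[i], s) for s in STAGGERED_ANGLES)

    idx.sort(key=lambda i: (rmsd[i], stag_dev(i)))
    minima = tuple((float(grid[i]), float(rmsd[i])) for i in idx)

    selected = 0
    if prefer_staggered:
        for rank, i in enumerate(idx):
            if stag_dev(i) <= staggered_tolerance:
                selected = rank
                break

    i_sel = idx[selected]
    n = len(grid)
    limit = rmsd[i_sel] + uncertainty_window
    minus = plus = 0
    while minus < n - 1 and rmsd[(i_sel - minus - 1) % n] <= limit:
        minus += 1
    while plus < n - 1 and rmsd[(i_sel + plus + 1) % n] <= limit:
        plus += 1
    uncertainty = (minus * profile.step, plus * profile.step)
    return UMSResult(minima=minima, selected_index=selected, uncertainty=uncertainty)


def fit_ums(
    res: ResidueCouplings,
    kset: KarplusSet,
    step: float = 0.1,
    uncertainty_window: float = DEFAULT_UNCERTAINTY_WINDOW,
    staggered_tolerance: float = 30.0,
    prefer_staggered: bool = True,
) -> UMSResult:
    """Convenience wrapper: profile + minima in one call."""
    profile = ums_profile(res, kset, step=step)
    return ums_minima(
        profile,
        uncertainty_window=uncertainty_window,
        staggered_tolerance=staggered_tolerance,
        prefer_staggered=prefer_staggered,
    )


def _simplex_lstsq(a: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimize ||y - A p||^2 subject to sum(p) = 1, p >= 0, for A with
    three columns.  Exact: enumerate the 7 nonempty supports; for each,
    solve the equality-constrained normal equations and keep feasible
    candidates.  Provably optimal at this size (convex QP, finitely many
    active sets)."""
    m, k = a.shape
    best_p, best_obj = None, np.inf
    # the full-support interior solution, when feasible, is globally optimal
    supports = sorted(
        chain.from_iterable(combinations(range(k), r) for r in range(1, k + 1)),
        key=len,
        reverse=True,
    )
    for support in supports:
        s = list(support)
        asub = a[:, s]
        ns = len(s)
        kkt = np.zeros((ns + 1, ns + 1))
        kkt[:ns, :ns] = 2.0 * asub.T @ asub
        kkt[:ns, ns] = 1.0
        kkt[ns, :ns] = 1.0
        rhs = np.concatenate([2.0 * asub.T @ y, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        p_sub = sol[:ns]
        if np.any(p_sub < -1e-10):
            continue
        p = np.zeros(k)
        p[s] = np.clip(p_sub, 0.0, None)
        p /= p.sum()
        obj = float(np.sum((y - a @ p) ** 2))
        if obj < best_obj - 1e-15 or best_p is None:
            best_p, best_obj = p, obj
        if ns == k and np.all(p_sub > 1e-10):
            break  # interior KKT point of the convex QP: optimal
    rms = float(np.sqrt(best_obj / m))
    return best_p, rms


def tmss_populations(res: ResidueCouplings, kset: KarplusSet) -> TMSSResult:
    """Exact staggered-rotamer population fit on the probability simplex."""
    angles = np.array(STAGGERED_ANGLES)
    j_exp, j_calc = _prediction_matrix(res, kset, angles)
    p, rms = _simplex_lstsq(j_calc, j_exp)
    return TMSSResult(p60=p[0], p180=p[1], pm60=p[2], rmsd=rms)


def tmst_fit(
    res: ResidueCouplings, kset: KarplusSet, step: float = 0.1
) -> TMSTResult:
    """Trigonal fit: scan chi1 over a 120-degree fundamental domain,
    solving the population simplex exactly at each angle.

    The result is canonicalized so that ``chi1`` is the most populated
    conformer's angle and each conformer is tagged with its nearest
    staggered bin.
    """
    if step <= 0:
        raise InvalidInputError("grid step must be positive")
    n = int(round(120.0 / step))
    base = -60.0 + step * np.arange(1, n + 1)  # (-60, 60]
    ids = res.coupling_ids
    j_exp = np.array([res.measurements[c] for c in ids], dtype=float)
    # J_calc[coupling, grid, conformer] for offsets 0/+120/-120
    offsets = np.array([0.0, 120.0, -120.0])
    cube = np.empty((len(ids), n, 3))
    for j, off in enumerate(offsets):
        calc = kset.evaluate_at_chi1(base + off, ids)
        cube[:, :, j] = np.vstack([calc[c] for c in ids])
    best = (np.inf, None, None)
    for g in range(n):
        p, rms = _simplex_lstsq(cube[:, g, :], j_exp)
        if rms < best[0] - 1e-15:
            best = (rms, base[g], p)
    rms, chi_base, p = best
    conf = sorted(
        (
            (wrap_degrees(chi_base + off), float(pop))
            for off, pop in zip(offsets, p)
        ),
        key=lambda t: -t[1],
    )
    conformers = tuple(
        (angle, pop, nearest_staggered(angle)) for angle, pop in conf
    )
    return TMSTResult(chi1=conformers[0][0], conformers=conformers, rmsd=rms)


def classify_residue(
    ums: UMSResult,
    tmst: TMSTResult,
    tmss: TMSSResult | None = None,
    population_threshold: float = 0.60,
    staggered_tolerance: float = 30.0,
    population_source: str = "tmst",
) -> ResidueClassification:
    """Unimodal/trimodal classification.

    A residue is unimodal iff (a) the selected UMS chi1 lies within
    ``staggered_tolerance`` (inclusive) of 60, 180 or -60 degrees and
    (b) the maximum conformer population exceeds ``population_threshold``.
    The population is taken from the TMST fit by default; pass
    ``population_source="tmss"`` to use the staggered model instead.
    """
    if population_source == "tmst":
        pop = tmst.max_population
    elif population_source == "tmss":
        if tmss is None:
            raise InvalidInputError("tmss result required for population_source='tmss'")
        pop = tmss.max_population
    else:
        raise InvalidInputError("population_source must be 'tmst' or 'tmss'")
    stag = nearest_staggered(ums.chi1)
    deviation = circ_distance(ums.chi1, stag)
    staggered_ok = deviation <= staggered_tolerance
    population_ok = pop > population_threshold
    unimodal = staggered_ok and population_ok
    return ResidueClassification(
        label="unimodal" if unimodal else "trimodal",
        dominant_bin=stag if unimodal else None,
        staggered_test=staggered_ok,
        staggered_deviation=deviation,
        population_test=population_ok,
        population_value=pop,
    )


def predict_couplings(
    model_result,
    kset: KarplusSet,
    coupling_ids: Iterable[str],
) -> Dict[str, float]:
    """Couplings predicted by a fitted model (Hz per coupling).

    UMS results evaluate at the selected chi1; TMSS/TMST results are
    population-weighted sums over the conformers.
    """
    ids = tuple(coupling_ids)
    if isinstance(model_result, UMSResult):
        weighted = [(model_result.chi1, 1.0)]
    elif isinstance(model_result, TMSSResult):
        weighted = [(a, p) for a, p in model_result.populations.items()]
    elif isinstance(model_result, TMSTResult):
        weighted = [(a, p) for a, p, _ in model_result.conformers]
    else:
        raise InvalidInputError(
            f"unsupported model result type {type(model_result).__name__}"
        )
    out = {cid: 0.0 for cid in ids}
    for angle, pop in weighted:
        if pop == 0.0:
            continue
        vals = kset.evaluate_at_chi1(angle, ids)
        for cid in ids:
            out[cid] += pop * vals[cid]
    return out


def rmsd_j_tot(
    fitted: Sequence[tuple[ResidueCouplings, object, KarplusSet]],
) -> tuple[float, int]:
    """Global rms deviation (Hz) between experimental and model couplings
    over all residues, and the total coupling count m."""
    if not fitted:
        raise InvalidInputError("no fitted residues supplied")
    sq, m = 0.0, 0
    for res, result, kset in fitted:
        pred = predict_couplings(result, kset, res.coupling_ids)
        for cid in res.coupling_ids:
            sq += (res.measurements[cid] - pred[cid]) ** 2
            m += 1
    return float(np.sqrt(sq / m)), m
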