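"""Cross-method agreement statistics and classification counts computed
from the packaged reference tables."""

from __future__ import annotations

from typing import Dict

import pandas as pd

from ._angles import nearest_staggered
from .circstats import circ_distance, rmsd_chi1
from .fixtures import FixtureTables, load_fixture

__all__ = ["fixture_chi1_columns", "cross_method_stats", "classification_counts"]

_STAGGERED_BY_COLUMN = {"tmss_p60": 60.0, "tmss_p180": 180.0, "tmss_pm60": -60.0}


def fixture_chi1_columns(fixture: FixtureTables | None = None) -> Dict[str, Dict[str, float]]:
    """Per-method residue->chi1 mappings from the 25-residue table.

    The TMSS angle is the staggered rotamer carrying the largest fitted
    population.
    """
    if fixture is None:
        fixture = load_fixture()
    t1 = fixture.table1
    rid = t1["residue_id"]
    columns = {
        "ums": dict(zip(rid, t1["ums_chi1"])),
        "tmst": dict(zip(rid, t1["tmst_chi1"])),
        "schmidt": dict(zip(rid, t1["schmidt_chi1"])),
        "perez": dict(zip(rid, t1["perez_chi1"])),
        "xray": dict(zip(rid, t1["xray_chi1"])),
    }
    pops = t1[list(_STAGGERED_BY_COLUMN)]
    dominant = pops.idxmax(axis=1).map(_STAGGERED_BY_COLUMN)
    columns["tmss"] = dict(zip(rid, dominant))
    return columns


def cross_method_stats(
    fixture: FixtureTables | None = None, exclusion: float = 40.0
) -> pd.DataFrame:
    """Pairwise circular rmsd between the chi1 columns of the reference
    table (degrees; with n used and the maximum single-residue deviation)."""
    cols = fixture_chi1_columns(fixture)
    methods = list(cols)
    rows = []
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1 :]:
            value, n, max_dev = rmsd_chi1(cols[m1], cols[m2], exclusion=exclusion)
            rows.append(
                {
                    "set1": m1,
                    "set2": m2,
                    "rmsd_chi1_deg": round(value, 1),
                    "n_used": n,
                    "max_deviation_deg": round(max_dev, 1),
                }
            )
    return pd.DataFrame(rows)


def classification_counts(
    fixture: FixtureTables | None = None,
    population_threshold: float = 60.0,
    staggered_tolerance: float = 30.0,
) -> Dict[str, object]:
    """Apply the two unimodality criteria to all 29 fixture residues.

    Criteria: the UMS chi1 lies within ``staggered_tolerance`` of a
    staggered angle, and the largest TMST population (percent) exceeds
    ``population_threshold``.
    """
    if fixture is None:
        fixture = load_fixture()
    unimodal, trimodal = [], []

    def judge(rid: str, ums_chi1: float, max_pop: float) -> None:
        stag_ok = (
            circ_distance(ums_chi1, nearest_staggered(ums_chi1))
            <= staggered_tolerance
        )
        pop_ok = max_pop > population_threshold
        (unimodal if (stag_ok and pop_ok) else trimodal).append(rid)

    for _, row in fixture.table1.iterrows():
        max_pop = max(row["tmst_p60"], row["tmst_p180"], row["tmst_pm60"])
        judge(row["residue_id"], row["ums_chi1"], max_pop)
    for _, row in fixture.table4.iterrows():
        max_pop = max(row["tmst_p60"], row["tmst_p180"], row["tmst_pm60"])
        judge(row["residue_id"], row["ums_chi1_a"], max_pop)

    return {
        "n_unimodal": len(unimodal),
        "n_trimodal": len(trimodal),
        "unimodal": unimodal,
        "trimodal": trimodal,
    }
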