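"""chi1 extraction from PDB-format structures.

chi1 is the N-CA-CB-CG dihedral, where the gamma reference atom depends
on the residue type (CG1 for Val/Ile, CG for Leu; configurable because
the branch choice shifts chi1 by +/-120 degrees).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

from Bio.PDB import PDBParser
from Bio.PDB.vectors import calc_dihedral

from ._angles import wrap_degrees
from .errors import InvalidInputError

__all__ = ["GAMMA_ATOMS", "chi1_from_structure"]

#: Default gamma reference atom per residue type.
GAMMA_ATOMS: Mapping[str, str] = {"VAL": "CG1", "ILE": "CG1", "LEU": "CG"}


def _resolve_atom(residue, name: str):
    """Pick an atom by name, resolving altlocs by highest occupancy
    (ties by altloc label order)."""
    if name not in residue:
        raise InvalidInputError(
            f"residue {residue.get_resname()} {residue.id[1]} lacks atom {name!r}"
        )
    atom = residue[name]
    if atom.is_disordered():
        children = sorted(
            atom.disordered_get_list(),
            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
        )
        return children[0]
    return atom


def chi1_from_structure(
    source,
    chain: str | None = None,
    residue_number: int | None = None,
    gamma_atoms: Mapping[str, str] | None = None,
) -> float:
    """chi1 (degrees, in (-180, 180]) of one residue in a PDB structure.

    *source* is a path or PDB-format text.  The first model is used.
    *chain* defaults to the only/first chain; *residue_number* selects the
    residue by author numbering.
    """
    gammas = dict(GAMMA_ATOMS)
    if gamma_atoms:
        gammas.update({k.upper(): v for k, v in gamma_atoms.items()})

    parser = PDBParser(QUIET=True)
    if isinstance(source, Path):
        structure = parser.get_structure("s", str(source))
    elif isinstance(source, str):
        try:
            is_file = "\n" not in source and Path(source).exists()
        except OSError:
            is_file = False
        if is_file:
            structure = parser.get_structure("s", source)
        else:
            structure = parser.get_structure("s", _io.StringIO(source))
    else:
        structure = parser.get_structure("s", source)

    model = next(iter(structure))
    if chain is None:
        chain_obj = next(iter(model))
    else:
        if chain not in model:
            raise InvalidInputError(f"chain {chain!r} not found in structure")
        chain_obj = model[chain]

    residue = None
    for res in chain_obj:
        if res.id[0] != " ":
            continue
        if residue_number is None or res.id[1] == residue_number:
            residue = res
            break
    if residue is None:
        raise InvalidInputError(
            f"residue {residue_number} not found in chain {chain_obj.id!r}"
        )

    rtype = residue.get_resname().upper()
    if rtype not in gammas:
        raise InvalidInputError(
            f"no gamma reference atom configured for residue type {rtype!r}"
        )
    atoms = [
        _resolve_atom(residue, name)
        for name in ("N", "CA", "CB", gammas[rtype])
    ]
    import math

    import numpy as np
    from Bio.PDB.vectors import Vector

    # upcast the parser's float32 coordinates before the dihedral math
    vectors = [Vector(a.get_coord().astype(np.float64)) for a in atoms]
    angle = math.degrees(calc_dihedral(*vectors))
    return wrap_degrees(angle)
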