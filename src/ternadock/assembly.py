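"""Rigid composition of the final ternary structure from pocket point pairs.

protein1 is the fixed reference frame.  For PROTACs the ligand is first
superposed onto the E3-side (anchor) pocket, the warhead pocket points are
carried through that transform, and the POI is then superposed onto the
transported warhead points.  For molecular glues both the ligand and
protein2 are superposed directly onto protein1's predicted pocket points.
Only rigid motions are applied: internal geometry of every entity is
preserved bit-for-bit up to floating error, and no post-assembly clash
relaxation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoder import PocketPrediction
from .errors import ContractError
from .geometry import RigidTransform, kabsch


@dataclass
class AssembledComplex:
    p1_coords: np.ndarray         # fixed frame, identical to input p1
    ligand_coords: np.ndarray
    p2_coords: np.ndarray
    ligand_transform: RigidTransform
    p2_transform: RigidTransform
    mode: str
    pae: float | None = None
    seed: int | None = None


def _np(x) -> np.ndarray:
    return np.asarray(x.data if hasattr(x, "data") else x, dtype=float)


def assemble_protac(p1_coords: np.ndarray, ligand_conformer: np.ndarray,
                    p2_unbound_coords: np.ndarray,
                    pockets: PocketPrediction) -> AssembledComplex:
    """Two-stage assembly: ligand onto the anchor pocket, then POI onto the warhead."""
    if pockets.mode != "protac":
        raise ContractError("assemble_protac needs protac-mode pockets")
    for name in ("p_p1", "p_p2", "p_lig_p1", "p_lig_p2"):
        if getattr(pockets, name) is None:
            raise ContractError(f"protac pockets missing {name}")
    p_lig_p1 = _np(pockets.p_lig_p1)
    p_p1 = _np(pockets.p_p1)
    p_lig_p2 = _np(pockets.p_lig_p2)
    p_p2 = _np(pockets.p_p2)

    tr_lig = kabsch(p_lig_p1, p_p1)
    lig = tr_lig.apply(np.asarray(ligand_conformer, float))
    warhead_moved = tr_lig.apply(p_lig_p2)
    tr_p2 = kabsch(p_p2, warhead_moved)
    p2 = tr_p2.apply(np.asarray(p2_unbound_coords, float))
    return AssembledComplex(np.asarray(p1_coords, float).copy(), lig, p2,
                            tr_lig, tr_p2, "protac")


def assemble_mgd(p1_coords: np.ndarray, ligand_conformer: np.ndarray,
                 p2_coords: np.ndarray, pockets: PocketPrediction) -> AssembledComplex:
    """Direct assembly: ligand and protein2 each superposed onto protein1's pockets."""
    if pockets.mode != "mgd":
        raise ContractError("assemble_mgd needs mgd-mode pockets")
    for name in ("p_lig", "p_p1_lig", "p_p2", "p_p1_p2"):
        if getattr(pockets, name) is None:
            raise ContractError(f"mgd pockets missing {name}")
    tr_lig = kabsch(_np(pockets.p_lig), _np(pockets.p_p1_lig))
    tr_p2 = kabsch(_np(pockets.p_p2), _np(pockets.p_p1_p2))
    lig = tr_lig.apply(np.asarray(ligand_conformer, float))
    p2 = tr_p2.apply(np.asarray(p2_coords, float))
    return AssembledComplex(np.asarray(p1_coords, float).copy(), lig, p2,
                            tr_lig, tr_p2, "mgd")
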