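"""Self-contained synthetic ternary-complex fixtures.

Generates toy complexes with exactly known geometry so every stage of the
pipeline — curation gates, featurization, encoding, assembly, training,
scoring — can be exercised without downloading structures.  "Proteins" are
C-alpha-trace alpha-helices (2.3 A radius, 1.5 A rise, 100 deg/residue)
with canonical residue types assigned cyclically; the "ligand" is a
3-dimensional carbon coil bridging the two helices with at least three
sub-4 A contacts to each protein and no inter-entity pair closer than 2 A.
Ground-truth pocket correspondences and the native pose are returned
alongside each complex, which is what makes exact assembly round-trip and
planted-filter tests possible.

These fixtures emulate the rigid-body re-docking task only: they contain
no side chains, no realistic fold, and no ligand chemistry beyond a bonded
carbon chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ContractError
from .geometry import RigidTransform, random_rigid_transform
from .structures_io import (AMINO_ACIDS, AtomRecord, LigandEntity, ProteinEntity,
                            Residue, TernaryComplexRecord)

HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TURN = np.deg2rad(100.0)


@dataclass
class SyntheticComplexSpec:
    n_residues_p1: int = 20
    n_residues_p2: int = 20
    n_ligand_atoms: int = 12
    n_pocket_points: int = 8
    p2_offset: float = 12.4          # x-distance between helix axes (A)
    p2_tilt_deg: float = 28.0        # tilt of p2 toward p1 (direct contact arm)
    p2_shift: float = 0.55           # x backoff keeping the ligand channel clear
    jitter: float = 0.03             # coordinate jitter sigma (A)
    min_contacts: int = 3
    clearance: float = 2.0

    def __post_init__(self):
        if self.n_pocket_points > self.n_ligand_atoms:
            raise ContractError("pocket point count exceeds ligand atom count")
        if min(self.n_residues_p1, self.n_residues_p2) < self.n_pocket_points:
            raise ContractError("pocket point count exceeds protein length")


@dataclass
class GroundTruth:
    """Exact correspondences for one synthetic complex (native frame)."""

    native_lig: np.ndarray           # (n_lig, 3)
    native_p1_ca: np.ndarray
    native_p2_ca: np.ndarray
    lig_p1_indices: np.ndarray       # ligand atoms contacting p1 (anchor side)
    lig_p2_indices: np.ndarray       # ligand atoms contacting p2 (warhead side)
    p1_interface_residues: np.ndarray
    p2_interface_residues: np.ndarray
    lig_pocket_indices: np.ndarray   # K ligand atoms: the lig<->p1 pocket set
    p2_pocket_residues: np.ndarray   # K p2 residues: the p1<->p2 pocket set


@dataclass
class PlantedViolation:
    kind: str                        # resolution|rfree|contacts|clash|buffer|chain_length
    params: dict = field(default_factory=dict)


def _helix(n: int, phase: float = 0.0) -> np.ndarray:
    i = np.arange(n)
    ang = HELIX_TURN * i + phase
    z = HELIX_RISE * i
    pts = np.column_stack([HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), z])
    pts[:, 2] -= pts[:, 2].mean()
    return pts


def _protein_from_ca(ca: np.ndarray, chain_id: str) -> ProteinEntity:
    residues = []
    for idx, c in enumerate(ca):
        name = AMINO_ACIDS[idx % 20]
        atom = AtomRecord("C", "CA", np.asarray(c, float).copy(), 1.0, False, idx, chain_id)
        residues.append(Residue(name, atom.coord, [atom]))
    return ProteinEntity(chain_id, residues)


def make_ternary_complex(spec: SyntheticComplexSpec, rng: np.random.Generator,
                         entry_id: str = "SYN0001"
                         ) -> tuple[TernaryComplexRecord, GroundTruth]:
    """Build one native complex plus its exact ground-truth correspondences."""
    p1_ca = _helix(spec.n_residues_p1)
    p2_ca = _helix(spec.n_residues_p2, phase=np.pi)
    p2_ca[:, 0] = spec.p2_offset - p2_ca[:, 0]  # mirror about the midplane
    # Tilt p2 about a pivot near its ligand-facing surface so one end forms a
    # direct protein-protein contact arm (pairs in the 4-5 A window) while the
    # ligand channel at z ~ 0 keeps its clearance.
    pivot = np.array([spec.p2_offset - 2.9, 0.0, 0.0])
    th = np.deg2rad(spec.p2_tilt_deg)
    R_tilt = np.array([[np.cos(th), 0.0, np.sin(th)],
                       [0.0, 1.0, 0.0],
                       [-np.sin(th), 0.0, np.cos(th)]])
    p2_ca = (p2_ca - pivot) @ R_tilt.T + pivot + np.array([spec.p2_shift, 0.0, 0.0])
    n = spec.n_ligand_atoms
    t = np.linspace(0.0, 1.0, n)
    x_lo, x_hi = 4.35, spec.p2_offset - 4.35
    lig = np.column_stack([
        x_lo + (x_hi - x_lo) * t,
        1.0 * np.sin(9.0 * t + 0.4),
        0.9 * np.cos(11.0 * t - 0.2),
    ])
    if spec.jitter > 0:
        lig = lig + rng.normal(0.0, spec.jitter, size=lig.shape)

    # Verify the construction actually satisfies the curation geometry.
    prot = np.vstack([p1_ca, p2_ca])
    d_all = cdist(lig, prot)
    if d_all.min() < spec.clearance:
        raise ContractError("synthetic geometry violates the clearance bound")
    for ca in (p1_ca, p2_ca):
        d = cdist(lig, ca)
        if int((d.min(axis=1) <= 4.0).sum()) < spec.min_contacts:
            raise ContractError("synthetic geometry yields too few contacts")

    d1 = cdist(lig, p1_ca).min(axis=1)
    d2 = cdist(lig, p2_ca).min(axis=1)
    half = max(3, n // 3)
    lig_p1_idx = np.argsort(d1)[:half]
    lig_p2_idx = np.argsort(d2)[:half]
    K = spec.n_pocket_points
    lig_pocket = np.argsort(d1)[:K]
    p1_iface = np.argsort(cdist(p1_ca, lig).min(axis=1))[:K]
    p2_iface = np.argsort(cdist(p2_ca, lig).min(axis=1))[:K]

    atoms = [AtomRecord("C", f"C{i + 1}", lig[i].copy(), 1.0, True, 0, "B")
             for i in range(n)]
    bonds = [(i, i + 1, 1.0) for i in range(n - 1)]
    ligand = LigandEntity("LIG", atoms, bonds, lig.copy())
    record = TernaryComplexRecord(
        p1=_protein_from_ca(p1_ca, "A"),
        p2=_protein_from_ca(p2_ca, "C"),
        ligand=ligand,
        entry_id=entry_id,
        metadata={"method": "X-RAY DIFFRACTION", "resolution": 2.0, "r_free": 0.20},
    )
    gt = GroundTruth(
        native_lig=lig.copy(),
        native_p1_ca=p1_ca.copy(),
        native_p2_ca=p2_ca.copy(),
        lig_p1_indices=np.sort(lig_p1_idx),
        lig_p2_indices=np.sort(lig_p2_idx),
        p1_interface_residues=np.sort(p1_iface),
        p2_interface_residues=np.sort(p2_iface),
        lig_pocket_indices=np.sort(lig_pocket),
        p2_pocket_residues=np.sort(p2_iface),
    )
    return record, gt


def displace_complex(record: TernaryComplexRecord, rng: np.random.Generator,
                     box: float = 5.0
                     ) -> tuple[TernaryComplexRecord, RigidTransform, RigidTransform]:
    """Rigidly displace the ligand and protein2 away from protein1.

    Returns the displaced record and the two transforms applied, so tests
    can construct exact pocket correspondences in the displaced frame.
    """
    tr_lig = random_rigid_transform(rng, box)
    tr_p2 = random_rigid_transform(rng, box)
    new_lig = record.ligand.with_coords(tr_lig.apply(record.ligand.coords))
    new_p2 = record.p2.with_coords(tr_p2.apply(record.p2.ca_coords))
    displaced = TernaryComplexRecord(record.p1, new_p2, new_lig,
                                     record.entry_id, dict(record.metadata))
    return displaced, tr_lig, tr_p2


def make_decoy_ladder(record: TernaryComplexRecord, levels, n_per_level: int,
                      rng: np.random.Generator) -> list[list[TernaryComplexRecord]]:
    """Rigidly perturb p2 by increasing magnitudes; level 0 equals the native."""
    levels = list(levels)
    if levels != sorted(levels):
        raise ContractError("levels must be sorted ascending")
    ladder = []
    p2_ca = record.p2.ca_coords
    center = p2_ca.mean(axis=0)
    for level in levels:
        decoys = []
        for _ in range(n_per_level):
            if level == 0:
                decoys.append(record)
                continue
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(min(2.0 * level, 60.0))
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
            shift = rng.normal(size=3)
            shift = shift / np.linalg.norm(shift) * level
            new_ca = (p2_ca - center) @ R.T + center + shift
            decoys.append(TernaryComplexRecord(
                record.p1, record.p2.with_coords(new_ca), record.ligand,
                record.entry_id, dict(record.metadata)))
        ladder.append(decoys)
    return ladder


def make_curation_fixture(n_clean: int, violations: list[PlantedViolation],
                          rng: np.random.Generator
                          ) -> tuple[list[TernaryComplexRecord], int]:
    """n_clean passing complexes plus one deliberately failing entry per violation.

    Every planted violation trips exactly one curation gate (protac mode),
    so the expected survivor count is exactly ``n_clean``.
    """
    spec = SyntheticComplexSpec()
    records = []
    for i in range(n_clean):
        rec, _ = make_ternary_complex(spec, rng, entry_id=f"SYN{i + 1:04d}")
        records.append(rec)
    for v in violations:
        rec, _ = make_ternary_complex(spec, rng, entry_id=f"VIO_{v.kind.upper()}")
        meta = dict(rec.metadata)
        if v.kind == "resolution":
            meta["resolution"] = v.params.get("resolution", 4.0)
        elif v.kind == "rfree":
            meta["r_free"] = v.params.get("r_free", 0.30)
        elif v.kind == "contacts":
            shifted = rec.ligand.coords + np.array([100.0, 0.0, 0.0])
            rec = dc_replace(rec, ligand=rec.ligand.with_coords(shifted))
        elif v.kind == "clash":
            coords = rec.ligand.coords.copy()
            target = rec.p1.ca_coords[0]
            direction = coords[0] - target
            direction /= np.linalg.norm(direction)
            coords[0] = target + direction * v.params.get("distance", 1.5)
            rec = dc_replace(rec, ligand=rec.ligand.with_coords(coords))
        elif v.kind == "buffer":
            lig = rec.ligand
            rec = dc_replace(rec, ligand=LigandEntity(
                v.params.get("code", "GOL"), lig.atoms, lig.bonds,
                lig.conformer_coords))
        elif v.kind == "chain_length":
            short = ProteinEntity(rec.p2.chain_id,
                                  rec.p2.residues[:v.params.get("length", 5)])
            rec = dc_replace(rec, p2=short)
        else:
            raise ContractError(f"unknown violation kind {v.kind!r}")
        rec = dc_replace(rec, metadata=meta)
        records.append(rec)
    return records, n_clean
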