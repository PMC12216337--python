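"""Interface-quality metrics and buried surface area.

Implements the standard docking-quality stack used to score predicted
ternary complexes against natives:

* ``Fnat`` — fraction of native inter-protein residue contacts (any
  heavy-atom pair < 5 A) preserved in the prediction;
* ``LRMS`` — backbone RMSD of the smaller partner after superposing the
  larger (receptor) partner;
* ``iRMS`` — backbone RMSD over native interface residues (any heavy atom
  within 10 A of the other protein) after interface superposition;
* ``DockQ = (Fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2)) / 3`` with
  CAPRI-style bands: incorrect < 0.23 <= acceptable < 0.49 <= medium
  < 0.80 <= high;
* the acceptable-rank metric over PAE-ranked prediction lists (sentinel 41
  when nothing reaches DockQ >= 0.23);
* Shrake-Rupley solvent-accessible surface area and pairwise buried
  surface area (BSA), summed over the three entity pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ContractError, MetricError
from .geometry import kabsch, rmsd
from .structures_io import ProteinEntity, TernaryComplexRecord

CONTACT_CUTOFF = 5.0       # A, native-contact definition
INTERFACE_CUTOFF = 10.0    # A, interface-residue definition
DOCKQ_LRMS_SCALE = 8.5
DOCKQ_IRMS_SCALE = 1.5
ACCEPTABLE_DOCKQ = 0.23
MEDIUM_DOCKQ = 0.49
HIGH_DOCKQ = 0.80
RANK_SENTINEL = 41

BACKBONE_NAMES = ("N", "CA", "C", "O")

# United-atom style radii (A) for SASA; probe 1.4 A.
VDW_RADII = {
    "C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_RADIUS = 1.80
PROBE_RADIUS = 1.4


@dataclass
class DockQComponents:
    fnat: float
    lrms: float
    irms: float
    dockq: float
    capri_class: str


@dataclass
class BSAResult:
    p1_p2: float
    p1_lig: float
    p2_lig: float

    @property
    def total(self) -> float:
        return self.p1_p2 + self.p1_lig + self.p2_lig


# ---------------------------------------------------------------------------
# residue bookkeeping
# ---------------------------------------------------------------------------

def _residue_heavy(protein: ProteinEntity) -> list[np.ndarray]:
    out = []
    for res in protein.residues:
        pts = [a.coord for a in res.atoms] or [res.ca]
        out.append(np.asarray(pts, float).reshape(-1, 3))
    return out


def _backbone(protein: ProteinEntity, residue_subset=None) -> np.ndarray:
    pts = []
    indices = range(protein.length) if residue_subset is None else residue_subset
    for i in indices:
        res = protein.residues[i]
        bb = [a.coord for a in res.atoms if a.name in BACKBONE_NAMES]
        pts.extend(bb if bb else [res.ca])
    return np.asarray(pts, float).reshape(-1, 3)


def _contact_pairs(p1: ProteinEntity, p2: ProteinEntity,
                   cutoff: float) -> set[tuple[int, int]]:
    r1, r2 = _residue_heavy(p1), _residue_heavy(p2)
    a1 = np.vstack(r1)
    a2 = np.vstack(r2)
    idx1 = np.repeat(np.arange(len(r1)), [len(r) for r in r1])
    idx2 = np.repeat(np.arange(len(r2)), [len(r) for r in r2])
    tree = cKDTree(a2)
    pairs = set()
    for ai, ri in zip(a1, idx1):
        for j in tree.query_ball_point(ai, cutoff):
            pairs.add((int(ri), int(idx2[j])))
    return pairs


# ---------------------------------------------------------------------------
# DockQ components
# ---------------------------------------------------------------------------

def fnat(pred: TernaryComplexRecord, native: TernaryComplexRecord,
         contact_cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of native inter-protein residue contacts preserved in pred."""
    native_contacts = _contact_pairs(native.p1, native.p2, contact_cutoff)
    if not native_contacts:
        raise MetricError("native complex has no inter-protein contacts")
    pred_contacts = _contact_pairs(pred.p1, pred.p2, contact_cutoff)
    return len(native_contacts & pred_contacts) / len(native_contacts)


def _interface_residues(native: TernaryComplexRecord,
                        cutoff: float = INTERFACE_CUTOFF) -> tuple[list[int], list[int]]:
    h1 = _residue_heavy(native.p1)
    h2 = _residue_heavy(native.p2)
    a1, a2 = np.vstack(h1), np.vstack(h2)
    tree2 = cKDTree(a2)
    tree1 = cKDTree(a1)
    iface1 = [i for i, pts in enumerate(h1)
              if any(tree2.query_ball_point(p, cutoff) for p in pts)]
    iface2 = [j for j, pts in enumerate(h2)
              if any(tree1.query_ball_point(p, cutoff) for p in pts)]
    return iface1, iface2


def lrms_irms(pred: TernaryComplexRecord,
              native: TernaryComplexRecord) -> tuple[float, float]:
    """Ligand-protein RMSD after receptor fit, and interface backbone RMSD."""
    # Receptor = larger protein; the smaller partner plays the "ligand protein".
    if native.p1.length >= native.p2.length:
        rec_pred, rec_nat = pred.p1, native.p1
        sml_pred, sml_nat = pred.p2, native.p2
    else:
        rec_pred, rec_nat = pred.p2, native.p2
        sml_pred, sml_nat = pred.p1, native.p1
    fit = kabsch(_backbone(rec_pred), _backbone(rec_nat))
    lrms = rmsd(fit.apply(_backbone(sml_pred)), _backbone(sml_nat))

    iface1, iface2 = _interface_residues(native)
    if not iface1 and not iface2:
        raise MetricError("native complex has no interface residues")
    nat_iface = np.vstack([_backbone(native.p1, iface1), _backbone(native.p2, iface2)])
    pred_iface = np.vstack([_backbone(pred.p1, iface1), _backbone(pred.p2, iface2)])
    ifit = kabsch(pred_iface, nat_iface)
    irms = rmsd(ifit.apply(pred_iface), nat_iface)
    return lrms, irms


def dockq(fnat_value: float, lrms: float, irms: float) -> tuple[float, str]:
    """Combine the three components; returns (score, CAPRI class)."""
    if not 0.0 <= fnat_value <= 1.0:
        raise ContractError("fnat must lie in [0, 1]")
    if lrms < 0 or irms < 0:
        raise ContractError("RMSD components must be non-negative")
    score = (fnat_value
             + 1.0 / (1.0 + (irms / DOCKQ_IRMS_SCALE) ** 2)
             + 1.0 / (1.0 + (lrms / DOCKQ_LRMS_SCALE) ** 2)) / 3.0
    return score, capri_class(score)


def capri_class(score: float) -> str:
    if score >= HIGH_DOCKQ:
        return "high"
    if score >= MEDIUM_DOCKQ:
        return "medium"
    if score >= ACCEPTABLE_DOCKQ:
        return "acceptable"
    return "incorrect"


def dockq_components(pred: TernaryComplexRecord,
                     native: TernaryComplexRecord) -> DockQComponents:
    f = fnat(pred, native)
    lrms, irms = lrms_irms(pred, native)
    score, cls = dockq(f, lrms, irms)
    return DockQComponents(f, lrms, irms, score, cls)


def acceptable_rank(dockq_scores, threshold: float = ACCEPTABLE_DOCKQ,
                    sentinel: int = RANK_SENTINEL) -> int:
    """1-based rank of the first PAE-ranked prediction with DockQ >= threshold."""
    for rank, score in enumerate(dockq_scores, start=1):
        if score >= threshold:
            return rank
    return sentinel


def rmsd_criterion(pred: TernaryComplexRecord, native: TernaryComplexRecord,
                   cutoff: float = 10.0) -> bool:
    """True iff the smaller partner's C-alpha RMSD after receptor fit is < cutoff."""
    if native.p1.length >= native.p2.length:
        rec_pred, rec_nat, sml_pred, sml_nat = pred.p1, native.p1, pred.p2, native.p2
    else:
        rec_pred, rec_nat, sml_pred, sml_nat = pred.p2, native.p2, pred.p1, native.p1
    fit = kabsch(rec_pred.ca_coords, rec_nat.ca_coords)
    return rmsd(fit.apply(sml_pred.ca_coords), sml_nat.ca_coords) < cutoff


# ---------------------------------------------------------------------------
# SASA / BSA
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere sampling."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = PROBE_RADIUS,
         n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley per-atom solvent-accessible surface areas (A^2)."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if coords.shape[0] != radii.shape[0]:
        raise ContractError("one radius per atom required")
    sphere = _sphere_points(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    areas = np.zeros(len(coords))
    max_ext = ext.max() if len(ext) else 0.0
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * sphere
        nbrs = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext) if j != i]
        if nbrs:
            d = cdist(pts, coords[nbrs])
            buried = (d < ext[nbrs]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return areas


def _entity_atoms(record: TernaryComplexRecord) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    def protein(p: ProteinEntity):
        coords, radii = [], []
        for res in p.residues:
            for a in res.atoms or []:
                coords.append(a.coord)
                radii.append(VDW_RADII.get(a.element.upper(), DEFAULT_RADIUS))
            if not res.atoms:
                coords.append(res.ca)
                radii.append(VDW_RADII["C"])
        return np.asarray(coords, float), np.asarray(radii, float)

    lig_coords = record.ligand.coords
    lig_radii = np.array([VDW_RADII.get(a.element.upper(), DEFAULT_RADIUS)
                          for a in record.ligand.atoms])
    return {
        "p1": protein(record.p1),
        "p2": protein(record.p2),
        "lig": (np.asarray(lig_coords, float), lig_radii),
    }


def buried_surface_area(record: TernaryComplexRecord, pair: tuple[str, str],
                        probe: float = PROBE_RADIUS, n_points: int = 960) -> float:
    """BSA of one entity pair: SASA(A) + SASA(B) - SASA(A U B)."""
    ents = _entity_atoms(record)
    (ca, ra), (cb, rb) = ents[pair[0]], ents[pair[1]]
    sa = sasa(ca, ra, probe, n_points).sum()
    sb = sasa(cb, rb, probe, n_points).sum()
    sab = sasa(np.vstack([ca, cb]), np.concatenate([ra, rb]), probe, n_points).sum()
    return sa + sb - sab


def total_bsa(record: TernaryComplexRecord, probe: float = PROBE_RADIUS,
              n_points: int = 960) -> BSAResult:
    """Buried surface area summed over all protein-protein and protein-ligand pairs."""
    return BSAResult(
        p1_p2=buried_surface_area(record, ("p1", "p2"), probe, n_points),
        p1_lig=buried_surface_area(record, ("p1", "lig"), probe, n_points),
        p2_lig=buried_surface_area(record, ("p2", "lig"), probe, n_points),
    )


def average_top_bsa(records_with_pae, n_top: int = 5, probe: float = PROBE_RADIUS,
                    n_points: int = 960) -> float:
    """Mean total BSA over the n_top lowest-PAE predicted complexes."""
    ranked = sorted(records_with_pae, key=lambda rp: rp[1])[:n_top]
    if not ranked:
        raise ContractError("no predictions supplied")
    return float(np.mean([total_bsa(r, probe, n_points).total for r, _ in ranked]))
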