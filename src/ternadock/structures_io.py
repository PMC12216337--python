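"""Molecular structure and ligand I/O.

Reads PDB/mmCIF protein structures through gemmi and ligand chemistry
through RDKit, producing the entity-level records the rest of the package
consumes: :class:`ProteinEntity` (residue-level, C-alpha anchored),
:class:`LigandEntity` (heavy atoms + bonds + optional conformer), and
:class:`TernaryComplexRecord` binding the three entities with curation
metadata.

Conventions (applied on load):

* first model only;
* hydrogens dropped everywhere (heavy-atom convention);
* one alternate location per atom, chosen by highest occupancy with ties
  broken by label order;
* residue numbering is the author's; internal indices are 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import ConformerError, ContractError, FormatError, SelectorError

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AMINO_ACIDS = tuple(THREE_TO_ONE) + ("UNK",)
AA_INDEX = {name: i for i, name in enumerate(AMINO_ACIDS)}


@dataclass
class AtomRecord:
    element: str
    name: str
    coord: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False
    residue_index: int = 0
    chain_id: str = "A"


@dataclass
class Residue:
    name: str
    ca: np.ndarray
    atoms: list[AtomRecord] = field(default_factory=list)


@dataclass
class ProteinEntity:
    chain_id: str
    residues: list[Residue]

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float).reshape(-1, 3)

    @property
    def heavy_coords(self) -> np.ndarray:
        pts = [a.coord for r in self.residues for a in r.atoms]
        return np.array(pts, dtype=float).reshape(-1, 3)

    @property
    def residue_types(self) -> list[str]:
        return [r.name if r.name in AA_INDEX else "UNK" for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def with_coords(self, ca: np.ndarray) -> "ProteinEntity":
        """Copy with replaced C-alpha (and co-moving heavy-atom) coordinates."""
        ca = np.asarray(ca, float)
        if ca.shape != (self.length, 3):
            raise ContractError("coordinate override shape mismatch")
        out = []
        for res, new in zip(self.residues, ca):
            shift = new - res.ca
            atoms = [AtomRecord(a.element, a.name, a.coord + shift, a.occupancy,
                                a.is_hetero, a.residue_index, a.chain_id)
                     for a in res.atoms]
            out.append(Residue(res.name, new.copy(), atoms))
        return ProteinEntity(self.chain_id, out)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "ProteinEntity":
        out = []
        for res in self.residues:
            atoms = [AtomRecord(a.element, a.name, R @ a.coord + t, a.occupancy,
                                a.is_hetero, a.residue_index, a.chain_id)
                     for a in res.atoms]
            out.append(Residue(res.name, R @ res.ca + t, atoms))
        return ProteinEntity(self.chain_id, out)


@dataclass
class LigandEntity:
    identifier: str
    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    conformer_coords: np.ndarray | None = None
    seed: int = 0
    mol: object | None = None  # underlying RDKit molecule when built from chemistry

    def __post_init__(self):
        if len(self.atoms) < 1:
            raise ContractError("ligand must have at least one atom")
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ContractError(f"bond ({i},{j}) out of range for {n} atoms")
        if self.conformer_coords is not None:
            self.conformer_coords = np.asarray(self.conformer_coords, float)
            if self.conformer_coords.shape != (n, 3):
                raise ContractError("conformer_coords must be n x 3")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if self.conformer_coords is not None:
            return self.conformer_coords
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, coords: np.ndarray) -> "LigandEntity":
        coords = np.asarray(coords, float)
        if coords.shape != (self.n_atoms, 3):
            raise ContractError("coordinate override shape mismatch")
        atoms = [AtomRecord(a.element, a.name, c.copy(), a.occupancy, a.is_hetero,
                            a.residue_index, a.chain_id)
                 for a, c in zip(self.atoms, coords)]
        return LigandEntity(self.identifier, atoms, list(self.bonds), coords.copy(),
                            self.seed, self.mol)


@dataclass
class TernaryComplexRecord:
    p1: ProteinEntity
    p2: ProteinEntity
    ligand: LigandEntity
    entry_id: str
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Structure loading
# ---------------------------------------------------------------------------

def _dedupe_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties by label order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # Preserve the original atom order.
    seen = set()
    out = []
    for atom in residue:
        if atom.name not in seen and best[atom.name] is atom:
            seen.add(atom.name)
            out.append(atom)
        elif atom.name not in seen and best[atom.name] is not atom:
            seen.add(atom.name)
            out.append(best[atom.name])
    return out


def _parse_ligand_selector(selector) -> tuple[str, int | None]:
    if isinstance(selector, tuple):
        code, num = selector
        return str(code), (int(num) if num is not None else None)
    text = str(selector)
    if ":" in text:
        code, num = text.split(":", 1)
        return code, int(num)
    return text, None


def _extract_header_meta(path: Path) -> tuple[float | None, str | None]:
    """Scan PDB header lines for the R-free value and experimental method."""
    rfree_pat = re.compile(r"FREE R VALUE\s*:\s*([0-9.]+)")
    r_free, method = None, None
    try:
        for line in path.read_text().splitlines():
            if line.startswith("EXPDTA"):
                method = line[6:].strip() or None
            elif line.startswith("REMARK") and r_free is None:
                m = rfree_pat.search(line)
                if m:
                    r_free = float(m.group(1))
            elif line.startswith(("ATOM", "HETATM")):
                break
    except (OSError, UnicodeDecodeError):
        pass
    return r_free, method


def load_complex(path, p1_chain: str, p2_chain: str, ligand_selector) -> TernaryComplexRecord:
    """Load a two-protein + one-ligand complex from a PDB or mmCIF file."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")
    st.remove_hydrogens()
    model = st[0]

    lig_code, lig_seqnum = _parse_ligand_selector(ligand_selector)

    def build_protein(chain_id: str) -> ProteinEntity:
        chain = model.find_chain(chain_id)
        if chain is None:
            raise SelectorError(f"chain {chain_id!r} not found in {path.name}")
        residues = []
        for ridx, res in enumerate(chain):
            if res.name not in AA_INDEX and res.name not in THREE_TO_ONE:
                continue
            atoms = _dedupe_altlocs(res)
            records = [
                AtomRecord(a.element.name, a.name, np.array(a.pos.tolist()), a.occ,
                           False, ridx, chain_id)
                for a in atoms
            ]
            ca = next((a for a in records if a.name == "CA"), None)
            if ca is not None:
                ca_coord = ca.coord.copy()
            elif records:
                # Missing C-alpha: fall back to the heavy-atom centroid.
                ca_coord = np.mean([a.coord for a in records], axis=0)
            else:
                continue
            residues.append(Residue(res.name, ca_coord, records))
        if not residues:
            raise SelectorError(f"chain {chain_id!r} in {path.name} has no amino acids")
        return ProteinEntity(chain_id, residues)

    def build_ligand() -> LigandEntity:
        for chain in model:
            for res in chain:
                if res.name != lig_code:
                    continue
                if lig_seqnum is not None and res.seqid.num != lig_seqnum:
                    continue
                atoms = _dedupe_altlocs(res)
                records = [
                    AtomRecord(a.element.name, a.name, np.array(a.pos.tolist()), a.occ,
                               True, 0, chain.name)
                    for a in atoms
                ]
                if not records:
                    continue
                coords = np.array([r.coord for r in records])
                bonds = perceive_bonds(coords, [r.element for r in records])
                return LigandEntity(lig_code, records, bonds, coords)
        raise SelectorError(f"ligand {lig_code!r} not found in {path.name}")

    p1 = build_protein(p1_chain)
    p2 = build_protein(p2_chain)
    ligand = build_ligand()

    r_free, method = _extract_header_meta(path)
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    metadata = {
        "method": method,
        "resolution": resolution,
        "r_free": r_free,
    }
    entry_id = f"{(st.name or path.stem).upper()}_{p1_chain}_{p2_chain}_{lig_code}"
    return TernaryComplexRecord(p1, p2, ligand, entry_id, metadata)


def perceive_bonds(coords: np.ndarray, elements: list[str],
                   cutoff: float = 1.9) -> list[tuple[int, int, float]]:
    """Distance-based single-bond perception for file-loaded ligands."""
    coords = np.asarray(coords, float)
    n = len(coords)
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                bonds.append((i, j, 1.0))
    return bonds


# ---------------------------------------------------------------------------
# Ligand chemistry (RDKit)
# ---------------------------------------------------------------------------

def ligand_from_smiles(smiles: str, identifier: str | None = None) -> LigandEntity:
    """Build a (conformer-less) heavy-atom ligand from a SMILES string."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormatError(f"invalid SMILES: {smiles!r}")
    atoms = [
        AtomRecord(a.GetSymbol(), f"{a.GetSymbol()}{a.GetIdx() + 1}",
                   np.zeros(3), 1.0, True, 0, "B")
        for a in mol.GetAtoms()
    ]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), float(b.GetBondTypeAsDouble()))
             for b in mol.GetBonds()]
    return LigandEntity(identifier or smiles, atoms, bonds, None, 0, mol)


def ligand_from_file(path) -> LigandEntity:
    """Load a ligand from an SDF or mol2 file (first molecule, heavy atoms)."""
    from rdkit import Chem

    path = Path(path)
    if path.suffix.lower() == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=True)
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise FormatError(f"cannot read ligand from {path}")
    lig = ligand_from_smiles(Chem.MolToSmiles(mol), identifier=path.stem)
    lig.mol = mol
    if mol.GetNumConformers() > 0:
        lig.conformer_coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    return lig


def generate_conformer(ligand: LigandEntity, seed: int) -> LigandEntity:
    """Embed one 3D conformer by ETKDG distance geometry; deterministic per seed."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    if ligand.mol is None:
        # No chemical graph available (e.g. synthetic point ligands): the
        # stored coordinates are the only conformation.
        if ligand.conformer_coords is None:
            raise ConformerError(f"ligand {ligand.identifier!r} has neither a "
                                 "chemical graph nor stored coordinates")
        out = ligand.with_coords(ligand.conformer_coords)
        out.seed = seed
        return out

    mol = Chem.AddHs(Chem.Mol(ligand.mol))
    params = AllChem.ETKDGv3()
    # +1 keeps distinct user seeds distinct (the embedder collapses 0 and 1).
    params.randomSeed = int(seed) % (2 ** 31 - 2) + 1
    conf_id = AllChem.EmbedMolecule(mol, params)
    if conf_id < 0:
        params.useRandomCoords = True
        conf_id = AllChem.EmbedMolecule(mol, params)
    if conf_id < 0:
        raise ConformerError(f"embedding failed for ligand {ligand.identifier!r}")
    mol = Chem.RemoveHs(mol)
    coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    if not np.isfinite(coords).all():
        raise ConformerError(f"non-finite conformer for {ligand.identifier!r}")
    out = ligand.with_coords(coords)
    out.seed = seed
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_complex(record: TernaryComplexRecord, path,
                  coords_override: dict[str, np.ndarray] | None = None) -> None:
    """Write the complex as a PDB file: p1 chain A, ligand chain B, p2 chain C.

    ``coords_override`` may carry per-entity coordinate matrices under the
    keys ``"p1"``/``"p2"`` (C-alpha, n_res x 3) and ``"ligand"`` (n_atoms x 3).
    """
    override = coords_override or {}
    p1 = record.p1.with_coords(override["p1"]) if "p1" in override else record.p1
    p2 = record.p2.with_coords(override["p2"]) if "p2" in override else record.p2
    lig = record.ligand.with_coords(override["ligand"]) if "ligand" in override \
        else record.ligand

    st = gemmi.Structure()
    st.name = record.entry_id
    model = gemmi.Model("1")

    def add_protein(entity: ProteinEntity, chain_id: str):
        chain = gemmi.Chain(chain_id)
        for i, res in enumerate(entity.residues):
            gres = gemmi.Residue()
            gres.name = res.name if res.name in AA_INDEX else "UNK"
            gres.seqid = gemmi.SeqId(i + 1, " ")
            atoms = res.atoms or [AtomRecord("C", "CA", res.ca)]
            for a in atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = a.occupancy
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)

    add_protein(p1, "A")

    lig_chain = gemmi.Chain("B")
    gres = gemmi.Residue()
    code = lig.identifier if re.fullmatch(r"[A-Za-z0-9]{1,3}", lig.identifier) else "LIG"
    gres.name = code.upper()
    gres.seqid = gemmi.SeqId(1, " ")
    gres.het_flag = "H"
    for a, c in zip(lig.atoms, lig.coords):
        ga = gemmi.Atom()
        ga.name = a.name[:4]
        ga.element = gemmi.Element(a.element)
        ga.pos = gemmi.Position(*c)
        ga.occ = a.occupancy
        gres.add_atom(ga)
    lig_chain.add_residue(gres)
    model.add_chain(lig_chain)

    add_protein(p2, "C")
    st.add_model(model)
    st.setup_entities()

    doc_lines = []
    meta = record.metadata or {}
    if meta.get("resolution") is not None:
        doc_lines.append(f"REMARK   2 RESOLUTION. {meta['resolution']:6.2f} ANGSTROMS.")
    if meta.get("r_free") is not None:
        doc_lines.append(f"REMARK   3   FREE R VALUE                     : {meta['r_free']:.3f}")
    body = st.make_pdb_string()
    header = ""
    if meta.get("method"):
        header += f"EXPDTA    {str(meta['method']).upper()}\n"
    header += "\n".join(doc_lines)
    if header and not header.endswith("\n"):
        header += "\n"
    Path(path).write_text(header + body)
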