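"""Entity-to-graph featurization.

Ligands become atom-level geometric graphs (distance-cutoff edges < 4 A,
chemistry-derived node features); proteins become residue-level graphs
anchored at C-alpha positions (k-nearest-neighbour edges, amino-acid-type
node indices).  Edge features are a radial-basis expansion of the edge
length plus a bonded flag and bond order.

Also provides the training-time coordinate transforms: Gaussian noise
injection and uniform random rigid displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ContractError
from .geometry import RigidTransform, random_rigid_transform
from .structures_io import AA_INDEX, LigandEntity, ProteinEntity

LIGAND_FEATURE_DIM = 10  # atomic number, chirality, degree, charge, implicit H,
#                          total H, radicals, hybridization, aromatic, in-ring
EDGE_EXTRA_DIM = 2  # bonded flag, bond order

_HYBRIDIZATION_CODES = {"S": 1, "SP": 2, "SP2": 3, "SP3": 4, "SP3D": 5, "SP3D2": 6}
_ELEMENT_Z = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
    "CL": 17, "BR": 35, "I": 53, "SE": 34,
}


@dataclass
class FeaturizerConfig:
    ligand_edge_cutoff: float = 4.0
    protein_knn_k: int = 10
    protein_edge_cap: float = 30.0
    noise_level: float = 2.0
    noise_sigma_per_level: float = 0.02
    rbf_bins: int = 16
    displacement_box: float = 5.0


@dataclass
class GeometricGraph:
    """One entity as a directed geometric graph (edges stored j -> i)."""

    node_features: np.ndarray      # (n, F) float, or (n,) int indices for proteins
    coords: np.ndarray             # (n, 3) A
    edge_index: np.ndarray         # (2, E) int: row 0 = source j, row 1 = target i
    edge_features: np.ndarray      # (E, D)
    entity_kind: str               # "lig" | "p1" | "p2"
    pocket_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.coords)
        if len(self.node_features) != n:
            raise ContractError("node feature / coordinate count mismatch")
        if self.edge_index.size and (self.edge_index.min() < 0 or self.edge_index.max() >= n):
            raise ContractError("edge endpoint out of range")
        if self.pocket_mask is not None and len(self.pocket_mask) != n:
            raise ContractError("pocket mask length mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.coords)


def rbf_encode(distances: np.ndarray, n_bins: int, d_max: float) -> np.ndarray:
    """Gaussian radial-basis expansion of distances on centres in [0, d_max]."""
    centers = np.linspace(0.0, d_max, n_bins)
    width = d_max / max(n_bins - 1, 1)
    d = np.asarray(distances, float).reshape(-1, 1)
    return np.exp(-((d - centers) ** 2) / (2.0 * width ** 2))


def _ligand_node_features(ligand: LigandEntity) -> np.ndarray:
    if ligand.mol is not None:
        feats = []
        for atom in ligand.mol.GetAtoms():
            feats.append([
                atom.GetAtomicNum(),
                int(atom.GetChiralTag()),
                atom.GetTotalDegree(),
                atom.GetFormalCharge(),
                atom.GetNumImplicitHs(),
                atom.GetTotalNumHs(),
                atom.GetNumRadicalElectrons(),
                _HYBRIDIZATION_CODES.get(str(atom.GetHybridization()), 0),
                int(atom.GetIsAromatic()),
                int(atom.IsInRing()),
            ])
        return np.array(feats, dtype=float)
    # Chemistry-free fallback (synthetic point ligands): derive what we can
    # from the element symbols and the bond list.
    degree = np.zeros(ligand.n_atoms)
    for i, j, _ in ligand.bonds:
        degree[i] += 1
        degree[j] += 1
    feats = np.zeros((ligand.n_atoms, LIGAND_FEATURE_DIM))
    for idx, atom in enumerate(ligand.atoms):
        feats[idx, 0] = _ELEMENT_Z.get(atom.element.upper(), 6)
        feats[idx, 2] = degree[idx]
        feats[idx, 7] = 4  # sp3 by default
    return feats


def build_ligand_graph(ligand: LigandEntity,
                       config: FeaturizerConfig | None = None) -> GeometricGraph:
    """Atom-level graph with bidirectional edges for pairs closer than 4 A.

    An atom with no neighbour inside the cutoff is connected to its nearest
    atom so the graph never contains isolated nodes.
    """
    config = config or FeaturizerConfig()
    coords = ligand.coords
    if coords is None:
        raise ContractError("ligand has no conformer coordinates")
    n = len(coords)
    feats = _ligand_node_features(ligand)
    bond_order = {}
    for i, j, order in ligand.bonds:
        bond_order[(i, j)] = order
        bond_order[(j, i)] = order

    dist = cdist(coords, coords)
    src, dst = [], []
    within = dist < config.ligand_edge_cutoff
    np.fill_diagonal(within, False)
    for i in range(n):
        nbrs = np.flatnonzero(within[:, i])
        if nbrs.size == 0 and n > 1:
            # Fallback: nearest atom, so no node is isolated.
            d = dist[:, i].copy()
            d[i] = np.inf
            nbrs = np.array([int(np.argmin(d))])
        for j in nbrs:
            src.append(int(j))
            dst.append(int(i))
    edge_index = np.array([src, dst], dtype=int).reshape(2, -1)
    if edge_index.size:
        lengths = dist[edge_index[0], edge_index[1]]
        rbf = rbf_encode(lengths, config.rbf_bins, config.ligand_edge_cutoff)
        extra = np.zeros((edge_index.shape[1], EDGE_EXTRA_DIM))
        for e, (j, i) in enumerate(edge_index.T):
            order = bond_order.get((int(j), int(i)))
            if order is not None:
                extra[e] = (1.0, order)
        edge_features = np.hstack([rbf, extra])
    else:
        edge_features = np.zeros((0, config.rbf_bins + EDGE_EXTRA_DIM))
    return GeometricGraph(feats, coords.copy(), edge_index, edge_features, "lig")


def build_protein_graph(protein: ProteinEntity, config: FeaturizerConfig | None = None,
                        kind: str = "p1") -> GeometricGraph:
    """Residue-level graph: nodes at C-alpha, symmetrized k-NN edges."""
    config = config or FeaturizerConfig()
    if protein.length == 0:
        raise ContractError("protein has no residues")
    coords = protein.ca_coords
    n = len(coords)
    node_idx = np.array([AA_INDEX.get(t, AA_INDEX["UNK"]) for t in protein.residue_types])

    dist = cdist(coords, coords)
    pairs: set[tuple[int, int]] = set()
    k = min(config.protein_knn_k, n - 1)
    for i in range(n):
        if k <= 0:
            break
        order = np.argsort(dist[i])
        nbrs = [int(j) for j in order[1:k + 1] if dist[i, j] <= config.protein_edge_cap]
        for j in nbrs:
            pairs.add((j, i))
            pairs.add((i, j))  # symmetrize
    if pairs:
        edge_index = np.array(sorted(pairs), dtype=int).T
        lengths = dist[edge_index[0], edge_index[1]]
        rbf = rbf_encode(lengths, config.rbf_bins, config.protein_edge_cap)
        edge_features = np.hstack([rbf, np.zeros((edge_index.shape[1], EDGE_EXTRA_DIM))])
    else:
        edge_index = np.zeros((2, 0), dtype=int)
        edge_features = np.zeros((0, config.rbf_bins + EDGE_EXTRA_DIM))
    return GeometricGraph(node_idx, coords.copy(), edge_index, edge_features, kind)


def apply_pocket_embedding(graph: GeometricGraph, pocket_mask: np.ndarray,
                           embedding: np.ndarray) -> GeometricGraph:
    """Sum a pocket embedding vector into the features of masked nodes.

    For float feature matrices the vector is added row-wise; the graph also
    records the mask so the model can inject its learned hidden-level pocket
    embedding at the same nodes.
    """
    pocket_mask = np.asarray(pocket_mask, bool)
    if len(pocket_mask) != graph.n_nodes:
        raise ContractError("pocket mask length mismatch")
    feats = np.array(graph.node_features, dtype=float, copy=True)
    embedding = np.asarray(embedding, float)
    if feats.ndim == 2:
        if embedding.shape != (feats.shape[1],):
            raise ContractError("pocket embedding dimension mismatch")
        feats[pocket_mask] += embedding
        node_features = feats
    else:
        # Index-coded protein nodes: the raw features are categorical, so the
        # summation happens at the hidden level (mask recorded here).
        node_features = graph.node_features
    return replace(graph, node_features=node_features, pocket_mask=pocket_mask)


def add_noise(graph: GeometricGraph, level: float, rng: np.random.Generator,
              config: FeaturizerConfig | None = None) -> GeometricGraph:
    """Training-time i.i.d. Gaussian noise on coordinates and float features."""
    if level < 0:
        raise ContractError("noise level must be non-negative")
    config = config or FeaturizerConfig()
    sigma = config.noise_sigma_per_level * level
    if sigma == 0:
        return graph
    coords = graph.coords + rng.normal(0.0, sigma, size=graph.coords.shape)
    feats = graph.node_features
    if np.issubdtype(np.asarray(feats).dtype, np.floating):
        feats = feats + rng.normal(0.0, sigma, size=np.asarray(feats).shape)
    return replace(graph, coords=coords, node_features=feats)


def random_rigid_displace(graph: GeometricGraph, rng: np.random.Generator,
                          box: float = 5.0) -> tuple[GeometricGraph, RigidTransform]:
    """Apply a uniform random rotation + boxed translation; returns the transform."""
    tr = random_rigid_transform(rng, box=box)
    return replace(graph, coords=tr.apply(graph.coords)), tr
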