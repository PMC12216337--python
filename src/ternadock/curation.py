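"""Ternary-complex corpus curation, leakage-safe splitting, and sampling.

Quality gates keep X-ray entries at resolution <= 3.5 A and R-free <= 0.26
(with a manual whitelist for marginal entries of established significance);
geometric gates demand at least three ligand-protein contacts within 4 A,
no inter-entity heavy-atom pair closer than 2 A, no crystallization-buffer
ligand codes, and per-mode minimum chain lengths (7 residues for PROTAC
corpora, 3 for molecular-glue corpora, short enough to keep recognition
motifs).

Splitting clusters proteins at 50% sequence identity; every cluster that
touches a test entry is removed from training, and its non-test members
are kept for validation only when their ligands are dissimilar to every
test ligand (Tanimoto < 0.85 on 1024-bit Morgan fingerprints, radius 2).

Training entries are drawn cluster-uniformly, taking the cluster
representative with 20% probability and a uniform member otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ContractError
from .structures_io import TernaryComplexRecord

DEFAULT_BUFFER_CODES = frozenset(
    {"ACT", "GOL", "PEG", "SO4", "TRS", "XYP", "BME", "EDO", "PG4", "PG5"})


@dataclass
class EntryMeta:
    entry_id: str
    method: str | None = None
    resolution: float | None = None
    r_free: float | None = None

    def __post_init__(self):
        if self.resolution is not None and self.resolution <= 0:
            raise ContractError("resolution must be positive")
        if self.r_free is not None and not 0.0 <= self.r_free <= 1.0:
            raise ContractError("r_free must lie in [0, 1]")


@dataclass
class CurationConfig:
    max_resolution: float = 3.5
    max_rfree: float = 0.26
    min_contacts: int = 3
    contact_cutoff: float = 4.0     # inclusive ("within 4 A")
    clash_cutoff: float = 2.0       # strict ("less than 2 A")
    min_chain_len_protac: int = 7
    min_chain_len_mgd: int = 3
    buffer_codes: frozenset = DEFAULT_BUFFER_CODES
    whitelist: frozenset = frozenset()

    def min_chain_len(self, mode: str) -> int:
        if mode == "protac":
            return self.min_chain_len_protac
        if mode == "mgd":
            return self.min_chain_len_mgd
        raise ContractError(f"unknown mode {mode!r}")


@dataclass
class ClusterAssignment:
    cluster_id: int
    members: list[str]
    representative: str

    def __post_init__(self):
        if self.representative not in self.members:
            raise ContractError("representative must be a cluster member")


@dataclass
class SplitResult:
    train: list[str] = field(default_factory=list)
    validation: list[str] = field(default_factory=list)
    test: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def passes_quality_gate(meta: EntryMeta, config: CurationConfig | None = None,
                        log: list | None = None) -> bool:
    """X-ray AND resolution <= 3.5 AND R-free <= 0.26, or whitelisted."""
    config = config or CurationConfig()
    if meta.entry_id in config.whitelist:
        return True
    reasons = []
    if meta.method is None or "x-ray" not in meta.method.lower().replace(" ", "-"):
        reasons.append("method is not X-ray")
    if meta.resolution is None:
        reasons.append("missing resolution")
    elif meta.resolution > config.max_resolution:
        reasons.append(f"resolution {meta.resolution:.2f} > {config.max_resolution}")
    if meta.r_free is None:
        reasons.append("missing r_free")
    elif meta.r_free > config.max_rfree:
        reasons.append(f"r_free {meta.r_free:.3f} > {config.max_rfree}")
    if reasons and log is not None:
        log.append((meta.entry_id, "quality", "; ".join(reasons)))
    return not reasons


def count_ligand_contacts(ligand_coords: np.ndarray, protein_coords: np.ndarray,
                          cutoff: float = 4.0) -> int:
    """Number of ligand atoms with >= 1 protein heavy atom at distance <= cutoff."""
    ligand_coords = np.asarray(ligand_coords, float)
    protein_coords = np.asarray(protein_coords, float)
    if ligand_coords.size == 0 or protein_coords.size == 0:
        raise ContractError("both coordinate sets must be non-empty")
    d = cdist(ligand_coords, protein_coords)
    return int((d.min(axis=1) <= cutoff).sum())


def has_steric_clash(ligand_coords: np.ndarray, protein_coords: np.ndarray,
                     cutoff: float = 2.0) -> bool:
    """True iff any inter-entity heavy-atom pair is strictly closer than cutoff."""
    d = cdist(np.asarray(ligand_coords, float), np.asarray(protein_coords, float))
    return bool(d.min() < cutoff)


def is_buffer_ligand(code: str, config: CurationConfig | None = None) -> bool:
    config = config or CurationConfig()
    return code.upper() in config.buffer_codes


def passes_chain_length(record: TernaryComplexRecord, mode: str,
                        config: CurationConfig | None = None) -> bool:
    config = config or CurationConfig()
    minimum = config.min_chain_len(mode)
    return record.p1.length >= minimum and record.p2.length >= minimum


def curate_records(records, mode: str = "protac",
                   config: CurationConfig | None = None,
                   metas: dict[str, EntryMeta] | None = None
                   ) -> tuple[list[TernaryComplexRecord], list[tuple[str, str, str]]]:
    """Apply every gate; returns (survivors, rejection log).

    The whitelist overrides the quality and clash gates only, never the
    buffer-ligand gate.  Filters are independent predicates, so the
    surviving set does not depend on their order.
    """
    config = config or CurationConfig()
    survivors, log = [], []
    for record in records:
        eid = record.entry_id
        whitelisted = eid in config.whitelist
        meta = (metas or {}).get(eid) or EntryMeta(
            eid,
            method=record.metadata.get("method"),
            resolution=record.metadata.get("resolution"),
            r_free=record.metadata.get("r_free"),
        )
        rejected = False
        if is_buffer_ligand(record.ligand.identifier, config):
            log.append((eid, "buffer", f"buffer ligand {record.ligand.identifier}"))
            rejected = True
        if not passes_quality_gate(meta, config, log):
            rejected = True
        if not passes_chain_length(record, mode, config):
            log.append((eid, "chain_length",
                        f"chain below minimum {config.min_chain_len(mode)}"))
            rejected = True
        prot = np.vstack([record.p1.heavy_coords, record.p2.heavy_coords])
        lig = record.ligand.coords
        n_contacts = count_ligand_contacts(lig, prot, config.contact_cutoff)
        if n_contacts < config.min_contacts:
            log.append((eid, "contacts",
                        f"{n_contacts} contacts < {config.min_contacts}"))
            rejected = True
        if has_steric_clash(lig, prot, config.clash_cutoff) and not whitelisted:
            log.append((eid, "clash", "inter-entity pair closer than "
                        f"{config.clash_cutoff} A"))
            rejected = True
        if not rejected:
            survivors.append(record)
    return survivors, log


# ---------------------------------------------------------------------------
# sequence clustering and splitting
# ---------------------------------------------------------------------------

def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches over alignment length."""
    from Bio import Align

    if not a or not b:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length if aln.length else 0.0


def cluster_by_sequence(sequences: dict[str, str],
                        identity_threshold: float = 0.5) -> list[ClusterAssignment]:
    """Greedy incremental clustering against cluster representatives."""
    if not sequences:
        raise ContractError("no sequences to cluster")
    clusters: list[ClusterAssignment] = []
    for entry_id, seq in sequences.items():
        placed = False
        for cluster in clusters:
            rep_seq = sequences[cluster.representative]
            if sequence_identity(seq, rep_seq) >= identity_threshold:
                cluster.members.append(entry_id)
                placed = True
                break
        if not placed:
            clusters.append(ClusterAssignment(len(clusters), [entry_id], entry_id))
    return clusters


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity of two bit vectors (numpy bool arrays or on-bit sets)."""
    a = set(np.flatnonzero(fp_a)) if isinstance(fp_a, np.ndarray) else set(fp_a)
    b = set(np.flatnonzero(fp_b)) if isinstance(fp_b, np.ndarray) else set(fp_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def morgan_fingerprint(smiles: str, n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """1024-bit circular (Morgan) fingerprint, radius 2."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ContractError(f"invalid SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.array(gen.GetFingerprint(mol), dtype=bool)


def split_dataset(clusters: list[ClusterAssignment], test_ids,
                  ligand_fingerprints: dict[str, object] | None = None,
                  tanimoto_threshold: float = 0.85) -> SplitResult:
    """Leakage-safe split: clusters touching the test set never reach training."""
    test_ids = set(test_ids)
    fps = ligand_fingerprints or {}
    test_fps = [fps[t] for t in test_ids if t in fps]
    result = SplitResult()
    for cluster in clusters:
        members = set(cluster.members)
        cluster_test = members & test_ids
        if not cluster_test:
            result.train.extend(sorted(members))
            continue
        result.test.extend(sorted(cluster_test))
        for member in sorted(members - cluster_test):
            fp = fps.get(member)
            if fp is not None and test_fps:
                max_sim = max(tanimoto(fp, tfp) for tfp in test_fps)
            else:
                max_sim = 0.0
            if max_sim < tanimoto_threshold:
                result.validation.append(member)
            else:
                result.dropped.append(member)
    return result


def sample_training_entry(clusters: list[ClusterAssignment],
                          rng: np.random.Generator) -> str:
    """Cluster-uniform draw, then representative with 20% likelihood."""
    if not clusters:
        raise ContractError("no clusters to sample from")
    cluster = clusters[rng.integers(len(clusters))]
    if rng.random() < 0.2:
        return cluster.representative
    return cluster.members[rng.integers(len(cluster.members))]
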