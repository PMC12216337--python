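"""End-to-end prediction: conformers, forward pass, assembly, PAE ranking.

For PROTACs, ``n_conformers`` (default 40) RDKit conformations are
embedded with different seeds, each is pushed through the network and
assembled via the unbound pocket points, and the resulting poses are
ranked by ascending predicted aligned error (PAE), ties broken by seed.
For molecular glues a single conformation is used; the bound-form protein
inputs are first subjected to a seeded random rigid displacement so
inference never sees the answer pose.

Every prediction is a pure function of the input entities and the seed
list, so repeated calls are bitwise-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import AssembledComplex, assemble_mgd, assemble_protac
from .decoder import UnboundPockets
from .errors import ConformerError, ContractError
from .featurize import FeaturizerConfig, build_ligand_graph, build_protein_graph
from .geometry import random_rigid_transform
from .metrics import dockq_components
from .structures_io import (LigandEntity, ProteinEntity, TernaryComplexRecord,
                            generate_conformer)
from .training import TernaryModel


@dataclass
class InferenceConfig:
    mode: str = "protac"
    n_conformers: int | None = None     # defaults: 40 protac / 1 mgd
    seeds: list[int] | None = None      # defaults to 0..n-1
    displacement_box: float = 5.0       # mgd input re-posing

    def __post_init__(self):
        if self.mode not in ("protac", "mgd"):
            raise ContractError(f"unknown mode {self.mode!r}")
        if self.n_conformers is None:
            self.n_conformers = 40 if self.mode == "protac" else 1
        if self.n_conformers < 1:
            raise ContractError("need at least one conformer")
        if self.seeds is None:
            self.seeds = list(range(self.n_conformers))
        if len(self.seeds) != self.n_conformers:
            raise ContractError("|seeds| must equal n_conformers")


@dataclass
class RankedPredictions:
    """Predictions sorted by (PAE ascending, seed ascending)."""

    predictions: list[AssembledComplex] = field(default_factory=list)

    def __post_init__(self):
        self.predictions.sort(key=lambda p: (p.pae, p.seed))

    def __len__(self):
        return len(self.predictions)

    def __iter__(self):
        return iter(self.predictions)

    @property
    def paes(self) -> list[float]:
        return [p.pae for p in self.predictions]


def top1(ranked: RankedPredictions) -> AssembledComplex:
    if len(ranked) == 0:
        raise ContractError("empty prediction list")
    return ranked.predictions[0]


def predict(model: TernaryModel, p1: ProteinEntity, p2: ProteinEntity,
            ligand: LigandEntity, config: InferenceConfig,
            pockets: UnboundPockets | None = None,
            feat_config: FeaturizerConfig | None = None) -> RankedPredictions:
    """Predict the assembled ternary complex for every seed and rank by PAE."""
    if config.mode == "protac" and pockets is None:
        raise ContractError("protac mode requires unbound pocket point sets")
    feat_config = feat_config or FeaturizerConfig()
    center = p1.ca_coords.mean(axis=0)
    p1_n = p1.ca_coords - center
    g_p1 = build_protein_graph(p1.with_coords(p1_n), feat_config, kind="p1")

    predictions = []
    failures = 0
    for seed in config.seeds:
        try:
            conf = generate_conformer(ligand, seed)
        except ConformerError:
            failures += 1
            continue
        rng = np.random.default_rng(seed)
        lig_coords = conf.conformer_coords - conf.conformer_coords.mean(axis=0)
        if config.mode == "mgd":
            # Re-pose the bound-form inputs so the answer pose is never seen.
            lig_coords = random_rigid_transform(rng, config.displacement_box).apply(lig_coords)
            p2_coords = random_rigid_transform(rng, config.displacement_box).apply(
                p2.ca_coords - p2.ca_coords.mean(axis=0))
            unbound = None
        else:
            p2_coords = p2.ca_coords - center
            unbound = UnboundPockets(pockets.anchor_indices, pockets.warhead_indices,
                                     pockets.p1_points - center,
                                     pockets.p2_points - center)
        g_lig = build_ligand_graph(conf.with_coords(lig_coords), feat_config)
        g_p2 = build_protein_graph(p2.with_coords(p2_coords), feat_config, kind="p2")
        state = model.encoder.forward(g_p1, g_lig, g_p2)
        pk = model.decoder.decode(config.mode, state, unbound)
        lig_pred = state.x["lig"].data
        if config.mode == "mgd":
            assembled = assemble_mgd(p1_n, lig_pred, p2_coords, pk)
        else:
            assembled = assemble_protac(p1_n, lig_pred, p2_coords, pk)
        assembled = AssembledComplex(
            p1_coords=assembled.p1_coords + center,
            ligand_coords=assembled.ligand_coords + center,
            p2_coords=assembled.p2_coords + center,
            ligand_transform=assembled.ligand_transform,
            p2_transform=assembled.p2_transform,
            mode=assembled.mode,
            pae=float(pk.pae.data),
            seed=seed,
        )
        predictions.append(assembled)
    if not predictions:
        raise ConformerError("all conformer embeddings failed")
    return RankedPredictions(predictions)


def assembled_to_record(template: TernaryComplexRecord,
                        assembled: AssembledComplex) -> TernaryComplexRecord:
    """Pose the template record's entities at an assembled prediction's coordinates."""
    return TernaryComplexRecord(
        p1=template.p1.with_coords(assembled.p1_coords),
        p2=template.p2.with_coords(assembled.p2_coords),
        ligand=template.ligand.with_coords(assembled.ligand_coords),
        entry_id=template.entry_id,
        metadata=dict(template.metadata),
    )


def validation_score(ranked: RankedPredictions,
                     native: TernaryComplexRecord) -> float:
    """Mean of the top-ranked prediction's DockQ and the best DockQ overall."""
    if len(ranked) == 0:
        raise ContractError("empty prediction list")
    scores = [dockq_components(assembled_to_record(native, p), native).dockq
              for p in ranked]
    return 0.5 * (scores[0] + max(scores))
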