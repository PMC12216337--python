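"""Curation gates at their quoted boundaries, clustering, splitting, sampling."""

import numpy as np
import pytest

from ternadock.curation import (ClusterAssignment, CurationConfig, EntryMeta,
                                cluster_by_sequence, count_ligand_contacts,
                                curate_records, has_steric_clash, is_buffer_ligand,
                                morgan_fingerprint, passes_chain_length,
                                passes_quality_gate, sample_training_entry,
                                sequence_identity, split_dataset, tanimoto)
from ternadock.errors import ContractError
from ternadock.synthetic import (PlantedViolation, SyntheticComplexSpec,
                                 make_curation_fixture, make_ternary_complex)

XRAY = "X-RAY DIFFRACTION"


class TestQualityGate:
    @pytest.mark.parametrize("method,res,rfree,expected", [
        (XRAY, 3.5, 0.26, True),       # both boundaries inclusive
        (XRAY, 3.51, 0.26, False),
        (XRAY, 3.5, 0.261, False),
        (XRAY, 2.0, 0.20, True),
        ("ELECTRON MICROSCOPY", 2.0, 0.20, False),
        (None, 2.0, 0.20, False),
        (XRAY, None, 0.20, False),
        (XRAY, 2.0, None, False),
    ])
    def test_boundaries(self, method, res, rfree, expected):
        meta = EntryMeta("X", method, res, rfree)
        assert passes_quality_gate(meta) is expected

    def test_whitelist_rescues_marginal_rfree_entry(self):
        # An entry whose R-free marginally exceeds 0.26 fails unless whitelisted.
        meta = EntryMeta("6HAXLIKE", XRAY, 3.4, 0.268)
        assert passes_quality_gate(meta) is False
        config = CurationConfig(whitelist=frozenset({"6HAXLIKE"}))
        assert passes_quality_gate(meta, config) is True

    def test_missing_fields_log_a_reason(self):
        log = []
        passes_quality_gate(EntryMeta("X", XRAY, None, 0.2), log=log)
        assert log and "resolution" in log[0][2]


class TestGeometryGates:
    def test_far_ligand_has_zero_contacts(self):
        lig = np.zeros((4, 3)) + 100.0
        prot = np.zeros((10, 3))
        assert count_ligand_contacts(lig, prot) == 0

    def test_constructed_three_contact_toy(self):
        prot = np.zeros((1, 3))
        lig = np.array([[3.9, 0, 0], [0, 3.9, 0], [0, 0, 3.9],
                        [6.0, 0, 0], [0, 6.0, 0]])
        assert count_ligand_contacts(lig, prot, cutoff=4.0) == 3

    def test_contact_cutoff_is_inclusive(self):
        assert count_ligand_contacts(np.array([[4.0, 0, 0]]), np.zeros((1, 3))) == 1

    @pytest.mark.parametrize("dist,expected", [(1.97, True), (2.00, False), (3.0, False)])
    def test_clash_is_strict_inequality(self, dist, expected):
        lig = np.array([[dist, 0.0, 0.0]])
        prot = np.zeros((1, 3))
        assert has_steric_clash(lig, prot, cutoff=2.0) is expected

    @pytest.mark.parametrize("code,expected", [
        ("GOL", True), ("PG5", True), ("ACT", True), ("SO4", True),
        ("ZZZ", False), ("LIG", False),
    ])
    def test_buffer_codes(self, code, expected):
        assert is_buffer_ligand(code) is expected

    def test_chain_length_minimums_by_mode(self, complex_and_truth):
        record, _ = complex_and_truth
        assert passes_chain_length(record, "protac")
        assert passes_chain_length(record, "mgd")
        from dataclasses import replace
        from ternadock.structures_io import ProteinEntity
        short6 = replace(record, p2=ProteinEntity("C", record.p2.residues[:6]))
        assert not passes_chain_length(short6, "protac")   # 6 < 7
        short3 = replace(record, p2=ProteinEntity("C", record.p2.residues[:3]))
        assert passes_chain_length(short3, "mgd")          # 3 residues suffice


class TestCurationPipeline:
    VIOLATIONS = ["resolution", "rfree", "contacts", "clash", "buffer", "chain_length"]

    def test_planted_fixture_survivor_count_is_exact(self):
        rng = np.random.default_rng(11)
        records, expected = make_curation_fixture(
            10, [PlantedViolation(k) for k in self.VIOLATIONS], rng)
        survivors, log = curate_records(records, mode="protac")
        assert len(survivors) == expected == 10

    def test_each_violation_trips_exactly_its_filter(self):
        rng = np.random.default_rng(12)
        records, _ = make_curation_fixture(
            0, [PlantedViolation(k) for k in self.VIOLATIONS], rng)
        _, log = curate_records(records, mode="protac")
        reasons = {}
        for eid, gate, _ in log:
            reasons.setdefault(eid, set()).add(gate)
        expected_gate = {"resolution": "quality", "rfree": "quality",
                         "contacts": "contacts", "clash": "clash",
                         "buffer": "buffer", "chain_length": "chain_length"}
        for kind, gate in expected_gate.items():
            assert reasons[f"VIO_{kind.upper()}"] == {gate}

    def test_whitelisted_rfree_violation_survives(self):
        rng = np.random.default_rng(13)
        records, _ = make_curation_fixture(2, [PlantedViolation("rfree")], rng)
        config = CurationConfig(whitelist=frozenset({"VIO_RFREE"}))
        survivors, _ = curate_records(records, mode="protac", config=config)
        assert len(survivors) == 3

    def test_filters_are_order_independent(self):
        # Filters are independent predicates: shuffling the record order (and
        # hence evaluation order) never changes the surviving set.
        rng = np.random.default_rng(14)
        records, _ = make_curation_fixture(
            5, [PlantedViolation(k) for k in self.VIOLATIONS], rng)
        base = {r.entry_id for r in curate_records(records, "protac")[0]}
        for seed in range(3):
            shuffled = list(records)
            np.random.default_rng(seed).shuffle(shuffled)
            assert {r.entry_id for r in curate_records(shuffled, "protac")[0]} == base


class TestClusteringAndSplit:
    def test_identical_sequences_cluster_together(self):
        clusters = cluster_by_sequence({"a": "MKVLA" * 6, "b": "MKVLA" * 6})
        assert len(clusters) == 1

    def test_unrelated_sequences_split(self):
        rng = np.random.default_rng(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        s1 = "".join(rng.choice(list(aa), 40))
        s2 = "".join(rng.choice(list(aa), 40))
        assert sequence_identity(s1, s2) < 0.5
        assert len(cluster_by_sequence({"a": s1, "b": s2})) == 2

    def test_planted_family_plus_singletons_gives_expected_clusters(self):
        rng = np.random.default_rng(1)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(aa, 60))

        def mutate(seq, n):
            s = list(seq)
            for pos in rng.choice(len(s), n, replace=False):
                s[pos] = rng.choice(aa)
            return "".join(s)

        sequences = {f"fam{i}": mutate(base, 6) for i in range(5)}
        for i in range(3):
            sequences[f"single{i}"] = "".join(rng.choice(aa, 60))
        # Brute-force oracle: all-pairs identity with the same scorer.
        ids = list(sequences)
        n_related = sum(
            sequence_identity(sequences[a], sequences[b]) >= 0.5
            for i, a in enumerate(ids) for b in ids[i + 1:])
        assert n_related == 10  # exactly the 5-member family pairs
        clusters = cluster_by_sequence(sequences)
        assert len(clusters) == 4

    def test_empty_input_raises(self):
        with pytest.raises(ContractError):
            cluster_by_sequence({})

    def test_split_with_no_test_cluster_keeps_all_in_train(self):
        clusters = [ClusterAssignment(0, ["a", "b"], "a"),
                    ClusterAssignment(1, ["c"], "c")]
        result = split_dataset(clusters, test_ids=[])
        assert sorted(result.train) == ["a", "b", "c"]
        assert result.validation == [] and result.test == []

    def test_planted_cluster_routes_by_tanimoto(self):
        clusters = [ClusterAssignment(0, ["A", "B", "C"], "A"),
                    ClusterAssignment(1, ["D"], "D")]
        fps = {"A": {1, 2, 3, 4, 5, 6, 7, 8, 9, 10},
               "B": {1, 2, 30, 40, 50, 60, 70, 80, 90, 100},   # tanimoto 1/9 ~ 0.11
               "C": {1, 2, 3, 4, 5, 6, 7, 8, 9, 11},           # tanimoto 9/11 ~ 0.82
               "D": {200}}
        result = split_dataset(clusters, test_ids=["A"], ligand_fingerprints=fps,
                               tanimoto_threshold=0.8)
        assert result.test == ["A"]
        assert result.validation == ["B"]
        assert result.dropped == ["C"]
        assert result.train == ["D"]

    def test_no_train_entry_shares_cluster_with_test(self):
        clusters = [ClusterAssignment(0, ["A", "B"], "A"),
                    ClusterAssignment(1, ["C", "D"], "C")]
        result = split_dataset(clusters, test_ids=["B"])
        member_cluster = {m: c.cluster_id for c in clusters for m in c.members}
        test_clusters = {member_cluster[t] for t in result.test}
        assert all(member_cluster[t] not in test_clusters for t in result.train)

    def test_morgan_tanimoto_identical_and_disjoint(self):
        fp1 = morgan_fingerprint("CCO")
        fp2 = morgan_fingerprint("CCO")
        assert fp1.shape == (1024,)
        assert tanimoto(fp1, fp2) == 1.0
        assert tanimoto(morgan_fingerprint("CCCCC"),
                        morgan_fingerprint("c1ccc2ccccc2c1")) < 0.2


class TestSampler:
    def test_single_member_cluster_always_returns_it(self):
        clusters = [ClusterAssignment(0, ["only"], "only")]
        rng = np.random.default_rng(0)
        assert all(sample_training_entry(clusters, rng) == "only" for _ in range(20))

    def test_cluster_stage_is_uniform_regardless_of_size(self):
        clusters = [ClusterAssignment(0, ["a0"], "a0"),
                    ClusterAssignment(1, [f"b{i}" for i in range(100)], "b0")]
        rng = np.random.default_rng(7)
        n = 100_000
        hits = sum(sample_training_entry(clusters, rng).startswith("a") for _ in range(n))
        p = hits / n
        sigma = np.sqrt(0.25 / n)
        assert abs(p - 0.5) < 3 * sigma

    def test_representative_frequency_in_size_10_cluster(self):
        # P(rep) = 0.2 + 0.8 * (1/10) = 0.28
        clusters = [ClusterAssignment(0, [f"m{i}" for i in range(10)], "m0")]
        rng = np.random.default_rng(8)
        n = 100_000
        hits = sum(sample_training_entry(clusters, rng) == "m0" for _ in range(n))
        p = hits / n
        sigma = np.sqrt(0.28 * 0.72 / n)
        assert abs(p - 0.28) < 3 * sigma

    def test_empty_cluster_list_raises(self):
        with pytest.raises(ContractError):
            sample_training_entry([], np.random.default_rng(0))
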