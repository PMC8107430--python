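"""Synthetic generators: determinism, validity, planted structure, recovery."""

import dataclasses
import math

import numpy as np
import pytest

from pdgene.io import read_evidence_table
from pdgene.network import Statistic, load_edge_list, within_set_stats
from pdgene.records import Layer
from pdgene.scoring import Grade, ScoreMap, score_evidence
from pdgene.simulate import (
    DEFAULT_TIERS,
    AAOGroupSpec,
    GroundTruth,
    NetworkSpec,
    RecordKind,
    SimulationConfig,
    SimulationConfigError,
    TierSpec,
    check_tiers,
    generate_aao,
    generate_evidence,
    generate_network,
    recipe_score,
    simulate_all,
)

SMALL = SimulationConfig(
    seed=7,
    tiers=(
        TierSpec(Grade.HIGH, 3, {RecordKind.CNV: 2, RecordKind.LOF: 2}),
        TierSpec(Grade.SUGGESTIVE, 4, {RecordKind.CNV: 1}),
        TierSpec(Grade.UNCERTAIN, 5, {RecordKind.TMIS: 1}),
    ),
    network=NetworkSpec(n_nodes=60, p_background=0.05, module_sizes=(7,),
                        p_within=1.0),
    aao_groups=(AAOGroupSpec(2, 25.0, 5.0, lof_shift=4.0, n_lof=8, n_dmis=8),),
)


def read_dir(out):
    records = []
    for layer, fname in [
        (Layer.RARE_VARIANT, "variants.tsv"), (Layer.CNV, "cnvs.tsv"),
        (Layer.GWAS_SNP, "gwas_snps.tsv"), (Layer.DEG, "degs.tsv"),
        (Layer.DMG, "dmgs.tsv"),
    ]:
        records.extend(read_evidence_table(out / fname, layer))
    return records


def test_same_seed_gives_byte_identical_files(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_all(SMALL, d1)
    simulate_all(SMALL, d2)
    for f in sorted(p.name for p in d1.iterdir()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f


def test_different_seed_changes_output(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_all(SMALL, d1)
    simulate_all(dataclasses.replace(SMALL, seed=8), d2)
    assert (d1 / "variants.tsv").read_bytes() != (d2 / "variants.tsv").read_bytes()


def test_generated_files_pass_validators_and_recover_grades(tmp_path):
    """Full-pipeline parameter recovery: every gene re-grades to its
    intended tier; generated tables parse under the layer validators."""
    _, truth = generate_evidence(SMALL, tmp_path)
    records = read_dir(tmp_path)
    cards = score_evidence(records)
    assert len(cards) == len(truth.intended_grades)
    for card in cards:
        assert card.grade.value == truth.intended_grades[card.gene]


def test_default_tiers_recover_grades(tmp_path):
    cfg = SimulationConfig(seed=3)
    _, truth = generate_evidence(cfg, tmp_path)
    cards = score_evidence(read_dir(tmp_path))
    mismatches = [c for c in cards if c.grade.value != truth.intended_grades[c.gene]]
    assert not mismatches


def test_inconsistent_recipe_rejected_before_writing(tmp_path):
    bad = dataclasses.replace(
        SMALL,
        tiers=(TierSpec(Grade.HIGH, 2, {RecordKind.CNV: 1}),),  # scores 5, not HIGH
    )
    out = tmp_path / "nothing"
    with pytest.raises(SimulationConfigError, match="grade"):
        generate_evidence(bad, out)
    assert not out.exists()


def test_recipe_score_closed_form():
    sm = ScoreMap()
    assert recipe_score({RecordKind.CNV: 4}, sm) == 20.0
    assert recipe_score({RecordKind.LOF: 1, RecordKind.DMIS: 1}, sm) == 9.0
    assert recipe_score({RecordKind.GWAS_GENOMEWIDE: 2}, sm) == 6.0
    check_tiers(DEFAULT_TIERS, sm)


class TestGenerateNetwork:
    def test_clique_when_p_within_one_and_no_background(self, tmp_path):
        cfg = dataclasses.replace(
            SMALL, network=NetworkSpec(n_nodes=30, p_background=0.0,
                                       module_sizes=(6,), p_within=1.0))
        path, truth = generate_network(cfg, tmp_path)
        net = load_edge_list(path)
        module = truth.module_members[0]
        k = len(module)
        assert net.n_edges == k * (k - 1) // 2
        assert within_set_stats(net, module) == (k, k * (k - 1) // 2)

    def test_expected_edge_count_matches_closed_form(self, tmp_path):
        n, p_out = 300, 0.02
        cfg = dataclasses.replace(
            SMALL, network=NetworkSpec(n_nodes=n, p_background=p_out,
                                       module_sizes=(), p_within=1.0))
        path, _ = generate_network(cfg, tmp_path)
        net = load_edge_list(path)
        n_pairs = n * (n - 1) // 2
        expected = n_pairs * p_out
        sd = math.sqrt(n_pairs * p_out * (1 - p_out))
        assert abs(net.n_edges - expected) <= 4 * sd

    def test_all_confidences_pass_default_filter(self, tmp_path):
        path, _ = generate_network(SMALL, tmp_path)
        net = load_edge_list(path, min_confidence=0.4)
        raw_rows = sum(1 for line in open(path) if not line.startswith("node_a"))
        assert net.n_edges == raw_rows  # nothing fell below the filter

    def test_node_roster_covers_all_nodes(self, tmp_path):
        path, truth = generate_network(SMALL, tmp_path)
        roster = (tmp_path / "network_nodes.txt").read_text().split()
        assert roster == truth.network_nodes
        assert len(roster) == SMALL.network.n_nodes

    def test_modules_larger_than_network_rejected(self):
        with pytest.raises(SimulationConfigError):
            NetworkSpec(n_nodes=10, module_sizes=(8, 8))


class TestGenerateAAO:
    def test_lof_shift_and_group_sizes(self, tmp_path):
        path, truth = generate_aao(SMALL, tmp_path)
        records = read_evidence_table(path, Layer.RARE_VARIANT)
        genes = {r.gene for r in records}
        assert genes == set(truth.aao_params)
        for gene in genes:
            lof = [r.aao for r in records if r.gene == gene and r.patho_score is None]
            dmis = [r.aao for r in records if r.gene == gene and r.patho_score is not None]
            assert len(lof) == 8 and len(dmis) == 8
            assert all(a >= 1.0 for a in lof + dmis)

    def test_shift_recovered_in_aggregate(self, tmp_path):
        """With many carriers the LoF-vs-Dmis mean gap estimates lof_shift."""
        cfg = dataclasses.replace(
            SMALL, aao_groups=(AAOGroupSpec(1, 50.0, 8.0, lof_shift=10.0,
                                            n_lof=400, n_dmis=400),))
        path, _ = generate_aao(cfg, tmp_path)
        records = read_evidence_table(path, Layer.RARE_VARIANT)
        lof = np.array([r.aao for r in records if r.patho_score is None])
        dmis = np.array([r.aao for r in records if r.patho_score is not None])
        gap = dmis.mean() - lof.mean()
        se = 8.0 * math.sqrt(2 / 400)
        assert abs(gap - 10.0) <= 4 * se

    def test_medians_land_in_intended_bins(self, tmp_path):
        """mean 25, sd 3, n=30: the gene median falls in the juvenile bin."""
        from pdgene.onset import analyze_onsets, OnsetBin
        cfg = dataclasses.replace(
            SMALL, aao_groups=(AAOGroupSpec(5, 25.0, 3.0, n_lof=15, n_dmis=15),))
        path, _ = generate_aao(cfg, tmp_path)
        records = read_evidence_table(path, Layer.RARE_VARIANT)
        summaries, _, _ = analyze_onsets(records)
        assert len(summaries) == 5
        assert all(s.bin is OnsetBin.JUVENILE for s in summaries)

    def test_gamma_noise_model(self, tmp_path):
        from pdgene.simulate import NoiseModel
        cfg = dataclasses.replace(SMALL, noise_model=NoiseModel.GAMMA)
        path, _ = generate_aao(cfg, tmp_path)
        records = read_evidence_table(path, Layer.RARE_VARIANT)
        assert all(r.aao >= 1.0 for r in records)


def test_ground_truth_round_trip(tmp_path):
    truth = simulate_all(SMALL, tmp_path)
    back = GroundTruth.read(tmp_path / "ground_truth.json")
    assert back == truth
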