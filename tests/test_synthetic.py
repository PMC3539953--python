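import math

import numpy as np
import pytest

from estforge.core_io import reverse_complement
from estforge.synthetic_data import (SimulationConfig, end_to_end_recovery,
                                     simulate_ests, simulate_references)


def small_config(**kw):
    defaults = dict(n_transcripts=20, n_ests=100, seed=11)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestReferences:
    def test_zero_branch_lengths_identical_species(self):
        tree = "((a:0,b:0):0,c:0);"
        cfg = small_config(tree_newick=tree, focal_species="a", n_transcripts=5)
        refs, _ = simulate_references(cfg)
        seqs = {sp: [r.sequence for r in rs] for sp, rs in refs.items()}
        assert seqs["a"] == seqs["b"] == seqs["c"]

    def test_zero_cds_rate_freezes_cds_only(self):
        cfg = small_config(region_rates={"utr5": 2.0, "cds": 0.0, "utr3": 1.5},
                           n_transcripts=5)
        refs, _ = simulate_references(cfg)
        by_gene = {}
        for sp, rs in refs.items():
            for r in rs:
                by_gene.setdefault(r.gene_id, []).append(r)
        diverged_utr = 0
        for gene, rs in by_gene.items():
            cds = {r.sequence[r.cds_start - 1 : r.cds_end] for r in rs}
            assert len(cds) == 1  # frozen CDS
            utr = {r.sequence[: r.cds_start - 1] for r in rs}
            diverged_utr += len(utr) > 1
        assert diverged_utr > 0  # UTRs keep evolving

    def test_realized_p_matches_jc_expectation(self):
        # one long CDS -> binomial CI on the realized mismatch fraction
        cfg = SimulationConfig(tree_newick="(a:0.05,b:0.05);", focal_species="a",
                               n_transcripts=1, utr5_length=(10, 10),
                               cds_length=(20000, 20000), utr3_length=(10, 10),
                               seed=5)
        refs, truth = simulate_references(cfg)
        a = refs["a"][0]
        b = refs["b"][0]
        sa = a.sequence[a.cds_start - 1 : a.cds_end]
        sb = b.sequence[b.cds_start - 1 : b.cds_end]
        realized = sum(x != y for x, y in zip(sa, sb)) / len(sa)
        expected = truth.expected_p("cds", "a", "b")
        se = math.sqrt(expected * (1 - expected) / len(sa))
        assert abs(realized - expected) < 4 * se

    def test_presence_sampling_keeps_focal_complete(self):
        cfg = small_config(presence_prob=0.5, n_transcripts=40)
        refs, truth = simulate_references(cfg)
        assert len(refs[cfg.focal_species]) == 40
        other = [sp for sp in refs if sp != cfg.focal_species][0]
        assert len(refs[other]) < 40
        assert truth.presence[other] == {r.gene_id for r in refs[other]}


class TestEsts:
    def test_artifact_free_ests_are_exact_substrings(self):
        cfg = small_config().artifact_free()
        rng = np.random.default_rng(cfg.seed)
        refs, truth = simulate_references(cfg, rng)
        ests, truths = simulate_ests(cfg, refs, truth, rng)
        by_tid = {r.transcript_id: r.sequence for r in refs[cfg.focal_species]}
        for est in ests:
            t = truths[est.id]
            expected = by_tid[t.transcript_id][t.start : t.end]
            if t.strand == "-":
                expected = reverse_complement(expected)
            assert est.sequence == expected

    def test_every_est_has_exactly_one_truth_record(self):
        cfg = small_config()
        rng = np.random.default_rng(0)
        refs, truth = simulate_references(cfg, rng)
        ests, truths = simulate_ests(cfg, refs, truth, rng)
        assert {e.id for e in ests} == set(truths)

    def test_length_moments_near_configured(self):
        cfg = SimulationConfig(n_transcripts=30, n_ests=1500, seed=2,
                               cds_length=(1200, 1600)).artifact_free()
        rng = np.random.default_rng(cfg.seed)
        refs, truth = simulate_references(cfg, rng)
        ests, _ = simulate_ests(cfg, refs, truth, rng)
        lengths = np.array([len(e) for e in ests])
        assert abs(lengths.mean() - cfg.est_length_mean) < 25
        assert abs(lengths.std() - cfg.est_length_sd) < 25

    def test_explicit_abundance_weights_drive_counts(self):
        cfg = small_config(n_transcripts=3, n_ests=200,
                           abundance_weights=[0.9, 0.08, 0.02]).artifact_free()
        rng = np.random.default_rng(1)
        refs, truth = simulate_references(cfg, rng)
        _, truths = simulate_ests(cfg, refs, truth, rng)
        counts = {}
        for t in truths.values():
            counts[t.transcript_id] = counts.get(t.transcript_id, 0) + 1
        assert max(counts, key=counts.get).startswith("T0000")

    def test_determinism_same_seed(self):
        cfg = small_config()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(cfg.seed)
            refs, truth = simulate_references(cfg, rng)
            ests, _ = simulate_ests(cfg, refs, truth, rng)
            out.append([(e.id, e.sequence) for e in ests])
        assert out[0] == out[1]


class TestExpectedDivergence:
    def test_boost_only_affects_named_lineage_region(self):
        cfg = small_config(rate_boosts={("csab", "utr5"): 3.0})
        _, truth = simulate_references(cfg)
        base = small_config()
        _, truth0 = simulate_references(base)
        assert truth.expected_d("cds", "csab", "mmul") == pytest.approx(
            truth0.expected_d("cds", "csab", "mmul"))
        assert truth.expected_d("utr5", "csab", "mmul") > \
            truth0.expected_d("utr5", "csab", "mmul")
        assert truth.expected_d("utr5", "hsap", "mmul") == pytest.approx(
            truth0.expected_d("utr5", "hsap", "mmul"))


class TestEndToEnd:
    def test_error_free_run_recovers_everything(self):
        cfg = SimulationConfig(n_transcripts=25, n_ests=150, seed=4).artifact_free()
        rep = end_to_end_recovery(cfg, regions=("cds",))
        assert rep["regions"]["cds"]["rf_vs_true"] == 0
        assert rep["region_annotation_accuracy"] == 1.0
        assert rep["expression_exact_fraction"] == 1.0

    def test_same_seed_identical_report(self):
        cfg = SimulationConfig(n_transcripts=10, n_ests=60, seed=9).artifact_free()
        a = end_to_end_recovery(cfg, regions=("cds",))
        b = end_to_end_recovery(cfg, regions=("cds",))
        assert a == b

    def test_assembly_included_conserves_ests(self):
        cfg = SimulationConfig(n_transcripts=8, n_ests=60, seed=12).artifact_free()
        rep = end_to_end_recovery(cfg, regions=("cds",), include_assembly=True)
        assert rep["assembly"]["n_ests"] == rep["n_kept"]
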