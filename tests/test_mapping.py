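import numpy as np
import pytest

from conftest import random_seq
from estforge.core_io import EstRecord, ReferenceTranscript, reverse_complement
from estforge.mapping_annotation import (AlignmentHit, AlignmentParams,
                                         align_local, best_hits,
                                         expression_ranking, mapping_summary,
                                         species_overlap, transfer_regions)

EXHAUSTIVE = AlignmentParams(prescreen=False, band=None)


def _ref(seq, species="sp", tid="t1", gene="g1", cds=None):
    cs, ce = cds if cds else (None, None)
    return ReferenceTranscript(tid, gene, species, seq, cs, ce)


class TestAlignLocal:
    def test_exact_substring_full_coverage(self, rng):
        t = random_seq(rng, 300)
        est = t[100:180]
        hit = align_local(EstRecord("e", est), _ref(t), EXHAUSTIVE)
        assert hit.est_coverage == 1.0
        assert hit.identity == 1.0
        assert hit.score == 5.0 * len(est)  # NUC44 match score per column
        assert hit.transcript_interval == (100, 180)

    def test_random_est_vs_unrelated_transcript_low_coverage(self, rng):
        est = random_seq(rng, 60)
        t = random_seq(rng, 500)
        hit = align_local(EstRecord("e", est), _ref(t), EXHAUSTIVE)
        assert hit is None or hit.est_coverage < 0.8

    def test_reverse_complement_same_score(self, rng):
        t = random_seq(rng, 250)
        est = t[50:150]
        fwd = align_local(EstRecord("e", est), _ref(t), EXHAUSTIVE)
        rev = align_local(EstRecord("e", reverse_complement(est)), _ref(t), EXHAUSTIVE)
        assert rev.score == fwd.score
        assert fwd.orientation == "+" and rev.orientation == "-"

    def test_column_map_strictly_increasing(self, rng):
        t = random_seq(rng, 200)
        hit = align_local(EstRecord("e", t[20:120]), _ref(t), EXHAUSTIVE)
        e, tt = hit.column_map
        assert (np.diff(e) > 0).all() and (np.diff(tt) > 0).all()


class TestBestHits:
    def _library_and_refs(self, rng):
        t1 = random_seq(rng, 400)
        t2 = random_seq(rng, 400)
        refs = {"spA": [_ref(t1, "spA", "tA1", "gA1"), _ref(t2, "spA", "tA2", "gA2")]}
        covered = EstRecord("covered", t1[50:250])       # full-coverage hit
        partial = EstRecord("partial", t1[330:400] + random_seq(rng, 130))  # 35% cover
        stray = EstRecord("stray", random_seq(rng, 200))  # no hit anywhere
        return [covered, partial, stray], refs

    def test_coverage_threshold_and_unmapped(self, rng):
        lib, refs = self._library_and_refs(rng)
        hits, unmapped = best_hits(lib, refs, EXHAUSTIVE)
        assert set(hits["spA"]) == {"covered"}
        assert set(unmapped) == {"partial", "stray"}

    def test_max_score_hit_kept(self, rng):
        t1 = random_seq(rng, 300)
        # t2 shares a shorter fragment -> lower best score
        t2 = random_seq(rng, 100) + t1[100:200] + random_seq(rng, 100)
        refs = {"sp": [_ref(t1, "sp", "t1", "g1"), _ref(t2, "sp", "t2", "g2")]}
        est = EstRecord("e", t1[80:240])
        hits, _ = best_hits([est], refs, AlignmentParams(prescreen=False, band=None,
                                                         min_est_coverage=0.2))
        assert hits["sp"]["e"].transcript_id == "t1"

    def test_monotone_in_coverage_threshold(self, rng):
        lib, refs = self._library_and_refs(rng)
        lo, _ = best_hits(lib, refs, AlignmentParams(prescreen=False, band=None,
                                                     min_est_coverage=0.3))
        hi, _ = best_hits(lib, refs, AlignmentParams(prescreen=False, band=None,
                                                     min_est_coverage=0.9))
        assert set(hi["spA"]) <= set(lo["spA"])

    def test_prescreen_agrees_with_exhaustive(self, rng):
        t = random_seq(rng, 600)
        refs = {"sp": [_ref(t, "sp", "t1", "g1"),
                       _ref(random_seq(rng, 600), "sp", "t2", "g2")]}
        lib = [EstRecord(f"e{i}", t[s : s + 200]) for i, s in enumerate((0, 150, 350))]
        fast, _ = best_hits(lib, refs, AlignmentParams())
        slow, _ = best_hits(lib, refs, EXHAUSTIVE)
        assert {k: v.transcript_id for k, v in fast["sp"].items()} == \
               {k: v.transcript_id for k, v in slow["sp"].items()}
        assert {k: v.score for k, v in fast["sp"].items()} == \
               {k: v.score for k, v in slow["sp"].items()}


class TestSummaryAndVenn:
    def _hit(self, eid, sp, tid, gene):
        one = np.arange(1)
        return AlignmentHit(eid, sp, tid, gene, 10.0, 1.0, 1.0, (0, 1), (0, 1),
                            "+", (one, one), 1, 1)

    def test_three_ests_one_transcript(self):
        hits = {"sp": {f"e{i}": self._hit(f"e{i}", "sp", "t1", "g1")
                       for i in range(3)}}
        df = mapping_summary(hits)
        row = df.iloc[0]
        assert (row.aligned_ests, row.mapped_transcripts, row.mapped_genes) == (3, 1, 1)

    def test_empty_hits(self):
        df = mapping_summary({"sp": {}})
        assert df.iloc[0].aligned_ests == 0

    def test_pigeonhole_ordering(self, rng):
        hits = {"sp": {}}
        for i in range(10):
            tid = f"t{i % 4}"
            gene = f"g{i % 2}"
            hits["sp"][f"e{i}"] = self._hit(f"e{i}", "sp", tid, gene)
        row = mapping_summary(hits).iloc[0]
        assert row.mapped_genes <= row.mapped_transcripts <= row.aligned_ests

    def test_venn_cells_partition_union(self):
        hits = {
            "A": {"e1": self._hit("e1", "A", "t", "g"),
                  "e2": self._hit("e2", "A", "t", "g")},
            "B": {"e1": self._hit("e1", "B", "t", "g"),
                  "e3": self._hit("e3", "B", "t", "g")},
        }
        cells = species_overlap(hits, ["A", "B"])
        assert cells[frozenset({"A", "B"})] == 1
        assert cells[frozenset({"A"})] == 1 and cells[frozenset({"B"})] == 1
        assert sum(cells.values()) == 3  # |A union B|

    def test_unknown_species_errors(self):
        with pytest.raises(KeyError):
            species_overlap({"A": {}}, ["A", "Z"])


class TestTransferRegions:
    def _perfect_hit(self, ref, e0, e1):
        idx = np.arange(e1 - e0)
        return AlignmentHit("e", ref.species, ref.transcript_id, ref.gene_id,
                            5.0 * (e1 - e0), 1.0, 1.0, (0, e1 - e0), (e0, e1),
                            "+", (idx, idx + e0), e1 - e0, e1 - e0)

    def test_est_inside_cds(self):
        ref = _ref("A" * 100, cds=(21, 60))
        ann = transfer_regions(self._perfect_hit(ref, 25, 55), ref)
        assert ann.region_lengths == {"utr5": 0, "cds": 30, "utr3": 0}

    def test_junction_split_exact(self):
        ref = _ref("A" * 100, cds=(21, 60))
        # EST spans transcript positions 40..79 (0-based): 20 CDS + 20 UTR3
        ann = transfer_regions(self._perfect_hit(ref, 40, 80), ref)
        assert ann.region_lengths == {"utr5": 0, "cds": 20, "utr3": 20}
        assert ann.region_est_intervals["cds"] == (0, 20)
        assert ann.region_est_intervals["utr3"] == (20, 40)

    def test_quasi_complete_flag(self):
        ref = _ref("A" * 100, cds=(21, 60))
        ann = transfer_regions(self._perfect_hit(ref, 2, 97), ref)
        assert ann.transcript_coverage == 0.95 and ann.quasi_complete
        ann2 = transfer_regions(self._perfect_hit(ref, 10, 90), ref)
        assert not ann2.quasi_complete

    def test_missing_cds_rejected(self):
        ref = _ref("A" * 100)
        with pytest.raises(ValueError):
            transfer_regions(self._perfect_hit(ref, 0, 50), ref)


class TestExpression:
    def test_counts_and_ordering(self):
        one = np.arange(1)

        def hit(eid, tid):
            return AlignmentHit(eid, "sp", tid, tid + "_g", 1.0, 1.0, 1.0,
                                (0, 1), (0, 1), "+", (one, one), 1, 1)

        hits = {f"e{i}": hit(f"e{i}", "tB") for i in range(5)}
        hits |= {f"f{i}": hit(f"f{i}", "tA") for i in range(5)}
        hits["g0"] = hit("g0", "tC")
        df = expression_ranking(hits)
        assert list(df.est_count) == [5, 5, 1]
        assert list(df.transcript_id) == ["tA", "tB", "tC"]  # tie broken by id
        assert list(expression_ranking(hits, k=2).transcript_id) == ["tA", "tB"]

    def test_counts_match_simulated_allocation(self):
        from estforge.synthetic_data import (SimulationConfig, simulate_ests,
                                             simulate_references)

        cfg = SimulationConfig(n_transcripts=12, n_ests=120, seed=3).artifact_free()
        rng = np.random.default_rng(cfg.seed)
        refs, truth = simulate_references(cfg, rng)
        ests, truths = simulate_ests(cfg, refs, truth, rng)
        hits, _ = best_hits(ests, {"mmul": refs["mmul"]}, AlignmentParams())
        df = expression_ranking(hits["mmul"])
        true_counts = {}
        for t in truths.values():
            tid = t.transcript_id.replace(".csab", ".mmul")
            true_counts[tid] = true_counts.get(tid, 0) + 1
        obs = dict(zip(df.transcript_id, df.est_count))
        assert obs == true_counts
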