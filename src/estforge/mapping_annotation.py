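"""EST-to-reference mapping, annotation transfer, and expression ranking.

ESTs are aligned to each species' cDNA set with a local (Smith-Waterman)
alignment under the NUC44 matrix and a linear gap penalty; hits are
ranked by raw alignment score and filtered to the single best hit per
EST per species among those covering at least ``min_est_coverage`` of
the EST ("best hit with 80% support").  Reference CDS coordinates are
then transferred through the alignment column map to classify aligned
EST bases into 5'UTR/CDS/3'UTR, quasi-complete reference transcripts
(covered beyond ``quasi_complete_threshold``) are flagged, and
per-transcript EST counts give the expression ranking.

By default candidate transcripts are pre-screened with a shared-k-mer
index (which also supplies the strand and the expected diagonal) and the
local alignment runs in a diagonal band; exhaustive full-matrix search
is available with ``prescreen=False`` / ``band=None``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import NUC44, encode, sw_pairs
from .core_io import (EstRecord, PipelineConfig, ReferenceTranscript,
                      provenance_header, reverse_complement)

__all__ = [
    "AlignmentParams", "AlignmentHit", "RegionAnnotation",
    "align_local", "best_hits", "mapping_summary", "species_overlap",
    "transfer_regions", "expression_ranking", "write_hits_tsv",
]


@dataclass
class AlignmentParams:
    """Mapping thresholds and alignment scoring parameters."""

    matrix: np.ndarray = field(default_factory=lambda: NUC44.copy())
    gap_penalty: float = 8.0
    min_est_coverage: float = 0.80
    quasi_complete_threshold: float = 0.90
    prescreen: bool = True
    kmer_size: int = 12
    max_candidates: int = 5
    band: int | None = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.min_est_coverage <= 1.0:
            raise ValueError("min_est_coverage must be in (0, 1]")
        if not 0.0 < self.quasi_complete_threshold <= 1.0:
            raise ValueError("quasi_complete_threshold must be in (0, 1]")


@dataclass
class AlignmentHit:
    """One EST-vs-transcript local alignment.

    ``est_interval`` / ``transcript_interval`` are 0-based half-open; EST
    coordinates refer to the aligned orientation (the reverse complement
    of the input when ``orientation == '-'``).  ``column_map`` is a pair
    of equally long, strictly increasing index arrays pairing aligned
    (substituted or matched) EST and transcript positions; gap columns
    are not part of the map but do count into ``n_columns``.
    """

    est_id: str
    species: str
    transcript_id: str
    gene_id: str
    score: float
    identity: float
    est_coverage: float
    est_interval: tuple[int, int]
    transcript_interval: tuple[int, int]
    orientation: str
    column_map: tuple[np.ndarray, np.ndarray]
    n_columns: int
    est_length: int

    def __post_init__(self) -> None:
        e, t = self.column_map
        if len(e) != len(t):
            raise ValueError("column_map arrays differ in length")
        if len(e) > 1 and not ((np.diff(e) > 0).all() and (np.diff(t) > 0).all()):
            raise ValueError("column_map must be strictly increasing on both sides")


def _hit_from_sw(est_id: str, oriented_seq: str, est_len: int, orientation: str,
                 ref: ReferenceTranscript, params: AlignmentParams,
                 band: int | None, diag: int) -> AlignmentHit | None:
    ea = encode(oriented_seq)
    eb = encode(ref.sequence)
    score, acols, bcols = sw_pairs(ea, eb, params.matrix, params.gap_penalty,
                                   band=band, diag=diag)
    if score <= 0.0 or len(acols) == 0:
        return None
    pair_mask = (acols >= 0) & (bcols >= 0)
    e_idx = acols[pair_mask]
    t_idx = bcols[pair_mask]
    matches = int((ea[e_idx] == eb[t_idx]).sum())
    n_columns = len(acols)
    e_cons = acols[acols >= 0]
    t_cons = bcols[bcols >= 0]
    e0, e1 = int(e_cons.min()), int(e_cons.max()) + 1
    t0, t1 = int(t_cons.min()), int(t_cons.max()) + 1
    return AlignmentHit(
        est_id=est_id,
        species=ref.species,
        transcript_id=ref.transcript_id,
        gene_id=ref.gene_id,
        score=score,
        identity=matches / n_columns,
        est_coverage=(e1 - e0) / est_len,
        est_interval=(e0, e1),
        transcript_interval=(t0, t1),
        orientation=orientation,
        column_map=(e_idx, t_idx),
        n_columns=n_columns,
        est_length=est_len,
    )


def align_local(est: EstRecord | str, ref: ReferenceTranscript,
                params: AlignmentParams | None = None,
                band: int | None = None, diag: int = 0) -> AlignmentHit | None:
    """Best local alignment of an EST against one reference transcript.

    Both orientations of the EST are tried and the higher-scoring one
    kept (ties favour the forward strand).  Returns None when no
    alignment scores above zero.
    """
    params = params or AlignmentParams()
    est_id = est.id if isinstance(est, EstRecord) else "query"
    seq = est.sequence if isinstance(est, EstRecord) else est
    if not seq or not ref.sequence:
        raise ValueError("sequences must be non-empty")
    fwd = _hit_from_sw(est_id, seq, len(seq), "+", ref, params, band, diag)
    rev = _hit_from_sw(est_id, reverse_complement(seq), len(seq), "-", ref,
                       params, band, diag)
    if fwd is None:
        return rev
    if rev is None or rev.score <= fwd.score:
        return fwd
    return rev


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(packed 2-bit k-mer codes, start positions); k-mers with any
    non-ACGT base are dropped."""
    e = encode(seq)
    if len(e) < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    win = np.lib.stride_tricks.sliding_window_view(e, k).astype(np.int64)
    valid = (win < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ powers
    pos = np.nonzero(valid)[0]
    return codes[valid], pos


class _KmerIndex:
    """Shared-k-mer candidate screen over one species' transcripts.

    Transcript k-mers are packed into integers and kept sorted, so a
    query is a vectorised searchsorted; votes are binned by (transcript,
    strand, diagonal bucket) and the best-voted diagonal per transcript
    and strand seeds the banded alignment.
    """

    def __init__(self, refs: Sequence[ReferenceTranscript], k: int,
                 bucket: int = 16):
        self.k = k
        self.bucket = bucket
        codes_parts = []
        pos_parts = []
        tid_parts = []
        for ti, r in enumerate(refs):
            c, p = _kmer_codes(r.sequence, k)
            codes_parts.append(c)
            pos_parts.append(p)
            tid_parts.append(np.full(len(c), ti, np.int64))
        codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.int64)
        pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        tids = np.concatenate(tid_parts) if tid_parts else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]
        self.tids = tids[order]

    def candidates(self, seq: str, max_candidates: int,
                   min_votes_fraction: float = 0.25
                   ) -> list[tuple[int, str, int]]:
        """Top (transcript index, strand, diagonal) candidates by k-mer votes."""
        per_key: dict[tuple[int, str], tuple[int, int]] = {}  # -> (votes, diag)
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            qcodes, qpos = _kmer_codes(s, self.k)
            if len(qcodes) == 0 or len(self.codes) == 0:
                continue
            lo = np.searchsorted(self.codes, qcodes, "left")
            hi = np.searchsorted(self.codes, qcodes, "right")
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            base = np.repeat(lo, counts)
            within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
            idx = base + within
            ti = self.tids[idx]
            diag = self.pos[idx] - np.repeat(qpos, counts)
            db = diag // self.bucket
            key = ti * 4_000_003 + (db + 2_000_000)
            uniq, votes = np.unique(key, return_counts=True)
            u_ti = uniq // 4_000_003
            u_db = uniq % 4_000_003 - 2_000_000
            for t, b, v in zip(u_ti.tolist(), u_db.tolist(), votes.tolist()):
                k2 = (t, strand)
                best = per_key.get(k2)
                cand = (v, int(b) * self.bucket + self.bucket // 2)
                if best is None or cand[0] > best[0]:
                    per_key[k2] = cand
        ranked = sorted(per_key.items(), key=lambda kv: (-kv[1][0], kv[0]))
        if not ranked:
            return []
        # candidates far below the best-voted one cannot win the alignment
        floor = max(1, int(ranked[0][1][0] * min_votes_fraction))
        return [(t, strand, diag) for (t, strand), (v, diag) in
                ranked[:max_candidates] if v >= floor]


def _better(a: AlignmentHit, b: AlignmentHit) -> AlignmentHit:
    """Best-hit tie rule: score, then identity, then transcript_id."""
    ka = (-a.score, -a.identity, a.transcript_id)
    kb = (-b.score, -b.identity, b.transcript_id)
    return a if ka <= kb else b


def best_hits(
    library: Sequence[EstRecord],
    references: Mapping[str, Sequence[ReferenceTranscript]],
    params: AlignmentParams | None = None,
) -> tuple[dict[str, dict[str, AlignmentHit]], list[str]]:
    """Best alignment per EST per species at >= ``min_est_coverage`` support.

    Returns (hits, unmapped): ``hits[species][est_id]`` is the retained
    hit; ``unmapped`` lists ESTs with no qualifying hit in any species
    (the "potentially specific" class).
    """
    params = params or AlignmentParams()
    if any(not refs for refs in references.values()):
        raise ValueError("every species needs a non-empty reference set")
    hits: dict[str, dict[str, AlignmentHit]] = {}
    for sp in sorted(references):
        refs = list(references[sp])
        sp_hits: dict[str, AlignmentHit] = {}
        idx = (_KmerIndex(refs, params.kmer_size, bucket=max(8, (params.band or 50) // 3))
               if params.prescreen else None)
        for est in library:
            if len(est) == 0:
                continue
            best: AlignmentHit | None = None
            if idx is not None:
                cands = idx.candidates(est.sequence, params.max_candidates)
                for ti, strand, diag in cands:
                    ref = refs[ti]
                    seq = (est.sequence if strand == "+"
                           else reverse_complement(est.sequence))
                    hit = _hit_from_sw(est.id, seq, len(est), strand, ref,
                                       params, params.band, diag)
                    if hit is None or hit.est_coverage < params.min_est_coverage:
                        continue
                    best = hit if best is None else _better(best, hit)
            else:
                for ref in refs:
                    hit = align_local(est, ref, params)  # exhaustive: full matrix
                    if hit is None or hit.est_coverage < params.min_est_coverage:
                        continue
                    best = hit if best is None else _better(best, hit)
            if best is not None:
                sp_hits[est.id] = best
        hits[sp] = sp_hits
    mapped = set().union(*(set(h) for h in hits.values())) if hits else set()
    unmapped = [e.id for e in library if e.id not in mapped]
    return hits, unmapped


def mapping_summary(hits: Mapping[str, Mapping[str, AlignmentHit]],
                    library_size: int | None = None) -> pd.DataFrame:
    """Per-species aligned ESTs / mapped transcripts / mapped genes."""
    rows = []
    for sp in sorted(hits):
        sp_hits = hits[sp]
        aligned = len(sp_hits)
        transcripts = len({h.transcript_id for h in sp_hits.values()})
        genes = len({h.gene_id for h in sp_hits.values()})
        row = {"species": sp, "aligned_ests": aligned,
               "mapped_transcripts": transcripts, "mapped_genes": genes}
        if library_size:
            row["fraction_aligned"] = aligned / library_size
        rows.append(row)
    return pd.DataFrame(rows)


def species_overlap(hits: Mapping[str, Mapping[str, AlignmentHit]],
                    species_subset: Sequence[str]) -> dict[frozenset, int]:
    """Exact-combination (Venn cell) EST counts for up to 6 species."""
    unknown = [sp for sp in species_subset if sp not in hits]
    if unknown:
        raise KeyError(f"unknown species: {unknown}")
    if len(species_subset) > 6:
        raise ValueError("at most 6 species for a Venn breakdown")
    membership: dict[str, frozenset] = {}
    for sp in species_subset:
        for eid in hits[sp]:
            membership[eid] = membership.get(eid, frozenset()) | {sp}
    cells: dict[frozenset, int] = {}
    for r in range(1, len(species_subset) + 1):
        for combo in combinations(sorted(species_subset), r):
            cells[frozenset(combo)] = 0
    for combo_set in membership.values():
        cells[combo_set] += 1
    return cells


@dataclass
class RegionAnnotation:
    """Region classification of one EST's alignment to one reference.

    ``region_lengths`` counts aligned (gap-free) columns per region;
    ``region_est_intervals`` gives the EST-coordinate span (0-based
    half-open, aligned orientation) of each region with >= 1 aligned
    base.  ``transcript_coverage`` is the spanned fraction of the
    reference transcript.
    """

    est_id: str
    transcript_id: str
    region_lengths: dict[str, int]
    region_est_intervals: dict[str, tuple[int, int] | None]
    transcript_coverage: float
    quasi_complete: bool


def transfer_regions(hit: AlignmentHit, ref: ReferenceTranscript,
                     quasi_complete_threshold: float = 0.90) -> RegionAnnotation:
    """Transfer the reference's 5'UTR/CDS/3'UTR layout onto the EST."""
    if not ref.has_cds:
        raise ValueError(f"{ref.transcript_id} lacks a CDS annotation")
    if ref.transcript_id != hit.transcript_id:
        raise ValueError("hit and reference transcript ids differ")
    e_idx, t_idx = hit.column_map
    lengths = {"utr5": 0, "cds": 0, "utr3": 0}
    intervals: dict[str, tuple[int, int] | None] = {"utr5": None, "cds": None, "utr3": None}
    for region in lengths:
        r0, r1 = ref.region_interval0(region)
        mask = (t_idx >= r0) & (t_idx < r1)
        n = int(mask.sum())
        lengths[region] = n
        if n:
            e = e_idx[mask]
            intervals[region] = (int(e.min()), int(e.max()) + 1)
    t0, t1 = hit.transcript_interval
    coverage = (t1 - t0) / len(ref.sequence)
    return RegionAnnotation(
        est_id=hit.est_id,
        transcript_id=ref.transcript_id,
        region_lengths=lengths,
        region_est_intervals=intervals,
        transcript_coverage=coverage,
        quasi_complete=coverage > quasi_complete_threshold,
    )


def expression_ranking(species_hits: Mapping[str, AlignmentHit],
                       k: int | None = None) -> pd.DataFrame:
    """Per-transcript EST counts, sorted descending (ties by transcript id)."""
    counts: Counter = Counter()
    genes: dict[str, str] = {}
    for hit in species_hits.values():
        counts[hit.transcript_id] += 1
        genes[hit.transcript_id] = hit.gene_id
    rows = [{"transcript_id": t, "gene_id": genes[t], "est_count": c}
            for t, c in counts.items()]
    df = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "est_count"])
    df = df.sort_values(["est_count", "transcript_id"],
                        ascending=[False, True], ignore_index=True)
    return df.head(k) if k else df


def write_hits_tsv(hits: Mapping[str, Mapping[str, AlignmentHit]],
                   path, config: PipelineConfig | None = None) -> None:
    """Hit table (1-based inclusive coordinates) for all species."""
    with open(path, "w") as fh:
        fh.write(provenance_header(config) + "\n")
        fh.write("est_id\tspecies\ttranscript_id\tgene_id\tscore\tidentity\t"
                 "est_coverage\test_start\test_end\tt_start\tt_end\torientation\n")
        for sp in sorted(hits):
            for eid in sorted(hits[sp]):
                h = hits[sp][eid]
                (e0, e1), (t0, t1) = h.est_interval, h.transcript_interval
                fh.write(f"{h.est_id}\t{h.species}\t{h.transcript_id}\t{h.gene_id}\t"
                         f"{h.score:.6g}\t{h.identity:.4f}\t{h.est_coverage:.4f}\t"
                         f"{e0 + 1}\t{e1}\t{t0 + 1}\t{t1}\t{h.orientation}\n")
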