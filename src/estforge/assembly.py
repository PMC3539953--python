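"""Greedy overlap assembly of ESTs into contigs and singletons.

A deterministic best-overlap-first agglomeration: all admissible
pairwise overlaps (ungapped suffix-prefix or containment, identity >=
``overlap_identity`` over >= ``min_overlap_length`` columns, both
orientations) are found, the best one (highest identity, then longest
overlap, then lexicographically smallest id pair) is merged, the merged
cluster's consensus is re-called by per-column majority vote over its
member ESTs, and the process repeats until no admissible overlap
remains.  Contigs (>= 2 members) plus singletons form the "distinct
transcripts".
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._align import encode
from .core_io import EstRecord, reverse_complement

__all__ = ["AssemblyParams", "Overlap", "Contig", "AssemblyResult",
           "overlap_score", "assemble", "assembly_stats"]


@dataclass
class AssemblyParams:
    overlap_identity: float = 0.80
    min_overlap_length: int = 40
    consider_reverse_complement: bool = True
    kmer_size: int = 14

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_identity <= 1.0:
            raise ValueError("overlap_identity must be in (0, 1]")
        if self.min_overlap_length < 1:
            raise ValueError("min_overlap_length must be >= 1")


@dataclass
class Overlap:
    """Best ungapped overlap of b against a.

    ``offset`` is the position of b's first base on a's coordinates
    (negative when b extends past a's 5' end); ``orientation`` is '+'
    when b aligns forward, '-' when its reverse complement does.
    """

    length: int
    identity: float
    offset: int
    orientation: str


@dataclass
class Contig:
    """Consensus sequence plus member-EST placements.

    Members are ``(est_id, offset, orientation)`` with 0-based offsets on
    the consensus; a 1-member contig is a singleton.
    """

    contig_id: str
    consensus: str
    members: list[tuple[str, int, str]]

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class AssemblyResult:
    contigs: list[Contig]
    singletons: list[Contig]
    stats: dict = field(default_factory=dict)

    @property
    def distinct_transcripts(self) -> list[Contig]:
        return self.contigs + self.singletons

    @property
    def total_members(self) -> int:
        return sum(c.n_members for c in self.distinct_transcripts)


def _offset_candidates(a: str, b: str, params: AssemblyParams) -> set[int]:
    """Offsets worth scoring: all of them for small pairs, else k-mer seeds."""
    la, lb = len(a), len(b)
    lo = -(lb - params.min_overlap_length)
    hi = la - params.min_overlap_length
    if la * lb <= 250_000:
        return set(range(lo, hi + 1))
    k = params.kmer_size
    pos: dict[str, list[int]] = defaultdict(list)
    for p in range(la - k + 1):
        pos[a[p : p + k]].append(p)
    offsets: set[int] = set()
    for q in range(lb - k + 1):
        for p in pos.get(b[q : q + k], ()):
            off = p - q
            if lo <= off <= hi:
                offsets.add(off)
    return offsets


def _score_offset(ea: np.ndarray, eb: np.ndarray, off: int) -> tuple[int, int]:
    """(overlap columns, matches) of b placed at ``off`` on a (ungapped)."""
    la, lb = len(ea), len(eb)
    a0 = max(0, off)
    a1 = min(la, off + lb)
    if a1 <= a0:
        return 0, 0
    sa = ea[a0:a1]
    sb = eb[a0 - off : a1 - off]
    return a1 - a0, int((sa == sb).sum())


def overlap_score(a: str, b: str, params: AssemblyParams | None = None
                  ) -> Overlap | None:
    """Best admissible-length overlap between two sequences.

    Among all candidate placements with overlap >= ``min_overlap_length``
    the one maximising (identity, overlap length) is returned; None when
    no placement reaches the minimum length.  The identity threshold is
    applied by the caller, so rejected-at-threshold overlaps can still be
    inspected.
    """
    params = params or AssemblyParams()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    best: Overlap | None = None
    orientations = [("+", b)]
    if params.consider_reverse_complement:
        orientations.append(("-", reverse_complement(b)))
    ea = encode(a)
    for orient, bseq in orientations:
        if len(bseq) < params.min_overlap_length or len(a) < params.min_overlap_length:
            continue
        eb = encode(bseq)
        for off in sorted(_offset_candidates(a, bseq, params)):
            length, matches = _score_offset(ea, eb, off)
            if length < params.min_overlap_length:
                continue
            cand = Overlap(length, matches / length, off, orient)
            if best is None or (cand.identity, cand.length) > (best.identity, best.length):
                best = cand
    return best


class _Cluster:
    """Mutable assembly cluster; rep is its smallest member EST id."""

    __slots__ = ("rep", "members", "consensus")

    def __init__(self, rep: str, members: list[tuple[str, int, str, str]],
                 consensus: str):
        self.rep = rep
        self.members = members  # (est_id, offset, orientation, oriented_seq)
        self.consensus = consensus


def _call_consensus(members: list[tuple[str, int, str, str]]) -> str:
    """Per-column majority vote; ties go to the earliest-added member."""
    length = max(off + len(seq) for _, off, _, seq in members)
    counts = np.zeros((length, 15), dtype=np.int32)
    for _, off, _, seq in members:
        e = encode(seq)
        np.add.at(counts, (np.arange(off, off + len(e)), e), 1)
    best = counts.max(axis=1)
    arg = counts.argmax(axis=1)
    # resolve ties by earliest-added member covering the column
    tied = (counts == best[:, None]).sum(axis=1) > 1
    out = arg.copy()
    if tied.any():
        from ._align import ALPHABET

        for col in np.nonzero(tied)[0]:
            for _, off, _, seq in members:
                if off <= col < off + len(seq):
                    code = encode(seq[col - off])[0]
                    if counts[col, code] == best[col]:
                        out[col] = code
                        break
    from ._align import ALPHABET

    return "".join(ALPHABET[c] for c in out)


def _merge(a: _Cluster, b: _Cluster, ov: Overlap) -> _Cluster:
    members = list(a.members)
    b_members = b.members
    if ov.orientation == "-":
        blen = len(b.consensus)
        flipped = []
        for eid, off, orient, seq in b_members:
            new_orient = "-" if orient == "+" else "+"
            flipped.append((eid, blen - (off + len(seq)),
                            new_orient, reverse_complement(seq)))
        b_members = flipped
    members += [(eid, off + ov.offset, orient, seq)
                for eid, off, orient, seq in b_members]
    shift = min(off for _, off, _, _ in members)
    if shift:
        members = [(eid, off - shift, orient, seq)
                   for eid, off, orient, seq in members]
    return _Cluster(min(a.rep, b.rep), members, _call_consensus(members))


def assemble(library: Sequence[EstRecord],
             params: AssemblyParams | None = None) -> AssemblyResult:
    """Greedy best-overlap-first assembly; every EST lands in exactly one contig."""
    params = params or AssemblyParams()
    clusters: dict[str, _Cluster] = {}
    for est in library:
        if est.id in clusters:
            raise ValueError(f"duplicate EST id {est.id!r}")
        if len(est) == 0:
            continue
        clusters[est.id] = _Cluster(est.id, [(est.id, 0, "+", est.sequence)],
                                    est.sequence)

    # global consensus k-mer index: kmer -> set of cluster reps holding it
    k = min(params.kmer_size, params.min_overlap_length)
    kindex: dict[str, set[str]] = defaultdict(set)

    def cluster_kmers(seq: str) -> set[str]:
        return {seq[p : p + k] for p in range(len(seq) - k + 1)}

    def index_add(rep: str) -> None:
        for km in cluster_kmers(clusters[rep].consensus):
            kindex[km].add(rep)

    def index_remove(rep: str) -> None:
        for km in cluster_kmers(clusters[rep].consensus):
            kindex[km].discard(rep)

    def kmer_partners(rep: str) -> set[str]:
        """Clusters sharing a consensus k-mer (either strand) with ``rep``."""
        s = clusters[rep].consensus
        query = cluster_kmers(s)
        if params.consider_reverse_complement:
            query |= cluster_kmers(reverse_complement(s))
        out: set[str] = set()
        for km in query:
            out |= kindex.get(km, set())
        out.discard(rep)
        return out

    for rep in clusters:
        index_add(rep)

    # candidate overlap cache keyed by (rep_a, rep_b) with rep_a < rep_b
    cache: dict[tuple[str, str], Overlap] = {}

    def refresh(rep: str) -> None:
        for other in kmer_partners(rep):
            key = (rep, other) if rep < other else (other, rep)
            ov = overlap_score(clusters[key[0]].consensus,
                               clusters[key[1]].consensus, params)
            if ov is not None and ov.identity >= params.overlap_identity:
                cache[key] = ov
            else:
                cache.pop(key, None)

    for rep in list(clusters):
        for other in kmer_partners(rep):
            key = (rep, other) if rep < other else (other, rep)
            if key in cache:
                continue
            ov = overlap_score(clusters[key[0]].consensus,
                               clusters[key[1]].consensus, params)
            if ov is not None and ov.identity >= params.overlap_identity:
                cache[key] = ov

    while cache:
        key, ov = min(cache.items(),
                      key=lambda kv: (-kv[1].identity, -kv[1].length, kv[0]))
        ra, rb = key
        index_remove(ra)
        index_remove(rb)
        a, b = clusters.pop(ra), clusters.pop(rb)
        cache = {kk: v for kk, v in cache.items() if ra not in kk and rb not in kk}
        merged = _merge(a, b, ov)
        clusters[merged.rep] = merged
        index_add(merged.rep)
        refresh(merged.rep)

    contigs: list[Contig] = []
    singletons: list[Contig] = []
    ordered = sorted(clusters.values(), key=lambda c: (-len(c.members), c.rep))
    for i, cl in enumerate(ordered, 1):
        contig = Contig(f"Contig{i:05d}", cl.consensus,
                        [(eid, off, orient) for eid, off, orient, _ in cl.members])
        (contigs if contig.n_members >= 2 else singletons).append(contig)
    result = AssemblyResult(contigs, singletons)
    result.stats = assembly_stats(result)
    return result


def assembly_stats(result: AssemblyResult) -> dict:
    """Length and membership statistics of the distinct transcripts."""
    transcripts = result.distinct_transcripts
    lengths = [len(c.consensus) for c in transcripts]
    members = [c.n_members for c in result.contigs]

    def summary(xs):
        if not xs:
            return {"median": 0.0, "mean": 0.0, "sd": 0.0}
        return {
            "median": float(statistics.median(xs)),
            "mean": float(statistics.fmean(xs)),
            "sd": float(statistics.stdev(xs)) if len(xs) > 1 else 0.0,
        }

    return {
        "n_contigs": len(result.contigs),
        "n_singletons": len(result.singletons),
        "n_distinct_transcripts": len(transcripts),
        "n_ests": result.total_members,
        "transcript_length": summary(lengths),
        "members_per_contig": summary(members),
        "total_transcript_nt": int(sum(lengths)),
    }
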