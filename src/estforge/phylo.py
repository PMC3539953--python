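"""Evolutionary-distance quantification and UPGMA tree building.

Pairwise global alignment under the NUC44 scoring matrix with a linear
gap penalty gives, per sequence pair, a p-distance over the gap-free,
unambiguous columns; the Jukes-Cantor maximum-likelihood transform
d = -(3/4) ln(1 - (4/3) p) converts it into an estimated number of
substitutions per site.  Per-region distance matrices are arithmetic
means over a set of ESTs commonly aligned to every species of interest
(the focal species being represented by the EST itself), and trees are
built with UPGMA (group average), producing a rooted ultrametric tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._align import NUC44, encode, nw_pairs
from .core_io import ReferenceTranscript, reverse_complement

__all__ = [
    "ScoringMatrix", "PairwiseAlignment", "PairwiseDistance", "DistanceMatrix",
    "PhyloTree", "TreeNode", "SaturationError", "UndefinedDistanceError",
    "nw_align", "p_distance", "jukes_cantor", "pairwise_distance",
    "common_est_set", "average_distance_matrix", "average_score_matrix",
    "ScoreMatrix", "upgma",
    "region_tree_suite", "robinson_foulds",
]

REGIONS = ("all", "utr5", "cds", "utr3")


class SaturationError(ValueError):
    """p-distance at or beyond 0.75: the JC distance diverges."""


class UndefinedDistanceError(ValueError):
    """No gap-free unambiguous columns to estimate a distance from."""


@dataclass(frozen=True)
class ScoringMatrix:
    """Named nucleotide scoring matrix over the 15-letter IUPAC alphabet."""

    name: str = "NUC44"
    table: np.ndarray = field(default_factory=lambda: NUC44.copy())

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (15, 15) or not np.allclose(t, t.T):
            raise ValueError("scoring matrix must be symmetric 15x15")
        object.__setattr__(self, "table", t)


@dataclass
class PairwiseAlignment:
    """Gapped global alignment of two sequences ('-' marks gaps)."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


@dataclass
class PairwiseDistance:
    id_a: str
    id_b: str
    aligned_columns: int
    p: float
    d: float
    score: float


@dataclass
class DistanceMatrix:
    """Mean pairwise distances with per-cell sample counts."""

    labels: list[str]
    matrix: np.ndarray
    n_common: np.ndarray
    region: str = "all"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        k = len(self.labels)
        if m.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.nanmin(m) < 0:
            raise ValueError("negative distances")
        self.matrix = m
        self.n_common = np.asarray(self.n_common, dtype=int)

    def is_complete(self) -> bool:
        return not np.isnan(self.matrix).any()


def nw_align(a: str, b: str, matrix: ScoringMatrix | np.ndarray | None = None,
             gap: float = 8.0, band: int | None = None) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch) alignment, linear gap penalty.

    Traceback ties resolve diagonal > up > left, so the result is
    deterministic.  ``band`` optionally restricts the DP to a diagonal
    band (exact when the optimal path stays inside it).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    S = matrix.table if isinstance(matrix, ScoringMatrix) else (
        NUC44 if matrix is None else np.asarray(matrix, dtype=float))
    ea, eb = encode(a), encode(b)
    score, ai, bj = nw_pairs(ea, eb, S, gap, band)
    out_a = "".join(a[i] if i >= 0 else "-" for i in ai)
    out_b = "".join(b[j] if j >= 0 else "-" for j in bj)
    return PairwiseAlignment(out_a, out_b, score)


def p_distance(aln: PairwiseAlignment) -> tuple[float, int]:
    """Fraction of differing sites among gap-free, unambiguous columns."""
    canonical = set("ACGT")
    cols = 0
    diff = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x in canonical and y in canonical:
            cols += 1
            if x != y:
                diff += 1
    if cols == 0:
        raise UndefinedDistanceError("no comparable columns in alignment")
    return diff / cols, cols


def jukes_cantor(p: float) -> float:
    """JC69 maximum-likelihood distance d = -(3/4) ln(1 - (4/3) p)."""
    if not 0.0 <= p:
        raise ValueError(f"p={p} out of range")
    if p >= 0.75:
        raise SaturationError(f"p={p} >= 0.75: distance saturated")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def pairwise_distance(a: str, b: str, id_a: str = "a", id_b: str = "b",
                      matrix: ScoringMatrix | None = None, gap: float = 8.0,
                      band: int | None = None) -> PairwiseDistance:
    """Align two sequences and return their Jukes-Cantor distance.

    Equivalent to ``p_distance(nw_align(a, b))`` followed by
    ``jukes_cantor`` but works on the encoded alignment directly.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    S = matrix.table if isinstance(matrix, ScoringMatrix) else (
        NUC44 if matrix is None else np.asarray(matrix, dtype=float))
    ea, eb = encode(a), encode(b)
    if band is not None:
        # widen so the corner stays reachable whatever the length difference
        band = max(band, abs(len(ea) - len(eb)) + 8)
    score, ai, bj = nw_pairs(ea, eb, S, gap, band)
    mask = (ai >= 0) & (bj >= 0)
    ca, cb = ea[ai[mask]], eb[bj[mask]]
    canonical = (ca < 4) & (cb < 4)  # codes 0..3 are A,C,G,T
    cols = int(canonical.sum())
    if cols == 0:
        raise UndefinedDistanceError("no comparable columns in alignment")
    p = float((ca[canonical] != cb[canonical]).mean())
    return PairwiseDistance(id_a, id_b, cols, p, jukes_cantor(p), score)


# ---------------------------------------------------------------------------
# Common EST sets and averaged matrices

@dataclass
class CommonEst:
    """One EST's per-species sequences for distance averaging."""

    est_id: str
    sequences: dict[str, str]  # species label (incl. focal) -> sequence


def _ref_index(references: Mapping[str, Sequence[ReferenceTranscript]]
               ) -> dict[str, dict[str, ReferenceTranscript]]:
    return {sp: {r.transcript_id: r for r in refs} for sp, refs in references.items()}


def common_est_set(
    hits: Mapping[str, Mapping[str, object]],
    ests: Mapping[str, object],
    references: Mapping[str, Sequence[ReferenceTranscript]],
    species_subset: Sequence[str],
    focal_label: str,
    region: str = "all",
    annotation_species: str | None = None,
) -> list[CommonEst]:
    """ESTs with a qualifying best hit in every species of the subset.

    For each such EST the mapped transcript subsequence (alignment
    interval intersected with the requested region) is extracted per
    species; the focal species is represented by the EST bases aligned to
    the ``annotation_species`` reference within that region.  ESTs with
    no aligned bases in the region for some species are excluded.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    subset = [sp for sp in species_subset if sp != focal_label]
    for sp in subset:
        if sp not in hits:
            raise KeyError(f"no hits for species {sp!r}")
    annotation_species = annotation_species or subset[0]
    refs = _ref_index(references)
    common_ids = sorted(set.intersection(*(set(hits[sp]) for sp in subset)))
    if not common_ids:
        raise ValueError(
            "no EST is mapped in every requested species; try a smaller subset")
    out: list[CommonEst] = []
    for eid in common_ids:
        seqs: dict[str, str] = {}
        ok = True
        for sp in subset:
            hit = hits[sp][eid]
            ref = refs[sp][hit.transcript_id]
            if region != "all" and not ref.has_cds:
                ok = False
                break
            r0, r1 = ref.region_interval0(region)
            t0, t1 = hit.transcript_interval
            lo, hi = max(t0, r0), min(t1, r1)
            if hi <= lo:
                ok = False
                break
            seqs[sp] = ref.sequence[lo:hi]
        if not ok:
            continue
        # focal: EST bases aligned to the annotation species' region
        hit = hits[annotation_species][eid]
        ref = refs[annotation_species][hit.transcript_id]
        r0, r1 = ref.region_interval0(region)
        in_region = (hit.column_map[1] >= r0) & (hit.column_map[1] < r1)
        if not in_region.any():
            continue
        epos = hit.column_map[0][in_region]
        est = ests[eid]
        oriented = est.sequence if hit.orientation == "+" else reverse_complement(est.sequence)
        seqs[focal_label] = oriented[int(epos.min()): int(epos.max()) + 1]
        out.append(CommonEst(eid, seqs))
    if not out:
        raise ValueError(f"common EST set empty for region {region!r}")
    return out


def average_distance_matrix(
    common: Sequence[CommonEst],
    labels: Sequence[str],
    region: str = "all",
    matrix: ScoringMatrix | None = None,
    gap: float = 8.0,
    band: int | None = None,
) -> DistanceMatrix:
    """Mean Jukes-Cantor distance per species pair over the common ESTs.

    Saturated (p >= 0.75) or undefined pairs are dropped from the average
    and excluded from the per-cell count; a cell with no finite pair is
    NaN, which ``upgma`` refuses.
    """
    if not common:
        raise ValueError("empty common EST set")
    k = len(labels)
    sums = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    for ce in common:
        for i in range(k):
            for j in range(i + 1, k):
                la, lb = labels[i], labels[j]
                if la not in ce.sequences or lb not in ce.sequences:
                    continue
                try:
                    pd = pairwise_distance(ce.sequences[la], ce.sequences[lb],
                                           la, lb, matrix, gap, band)
                except (SaturationError, UndefinedDistanceError):
                    continue
                sums[i, j] += pd.d
                counts[i, j] += 1
    mean = np.full((k, k), np.nan)
    np.fill_diagonal(mean, 0.0)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    iu = np.triu_indices(k, 1)
    mean[(iu[1], iu[0])] = mean[iu]
    counts = counts + counts.T
    return DistanceMatrix(list(labels), mean, counts, region)


def average_score_matrix(
    common: Sequence[CommonEst],
    labels: Sequence[str],
    region: str = "all",
    matrix: ScoringMatrix | None = None,
    gap: float = 8.0,
    band: int | None = None,
    scale: float = 1e-4,
) -> "ScoreMatrix":
    """Mean pairwise NW alignment score per species pair, rescaled.

    A presentation-oriented companion to ``average_distance_matrix`` (the
    distance average is the quantity used for tree building): raw NUC44
    scores are similarity values, so the result is NOT a distance matrix.
    ``scale`` defaults to 1e-4 so thousands-scale scores print compactly.
    """
    if not common:
        raise ValueError("empty common EST set")
    S = matrix.table if isinstance(matrix, ScoringMatrix) else (
        NUC44 if matrix is None else np.asarray(matrix, dtype=float))
    k = len(labels)
    sums = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    for ce in common:
        for i in range(k):
            for j in range(i + 1, k):
                la, lb = labels[i], labels[j]
                if la not in ce.sequences or lb not in ce.sequences:
                    continue
                a, b = ce.sequences[la], ce.sequences[lb]
                bnd = band
                if bnd is not None:
                    bnd = max(bnd, abs(len(a) - len(b)) + 8)
                score, _, _ = nw_pairs(encode(a), encode(b), S, gap, bnd)
                sums[i, j] += score * scale
                counts[i, j] += 1
    mean = np.zeros((k, k))
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    iu = np.triu_indices(k, 1)
    mean[(iu[1], iu[0])] = mean[iu]
    return ScoreMatrix(list(labels), mean, counts + counts.T, region)


@dataclass
class ScoreMatrix:
    """Mean alignment scores (similarities, not distances) per pair."""

    labels: list[str]
    matrix: np.ndarray
    n_common: np.ndarray
    region: str = "all"


# ---------------------------------------------------------------------------
# Trees

@dataclass
class TreeNode:
    height: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Rooted ultrametric tree; branch length = parent height - child height."""

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float | None) -> str:
            if node.is_leaf:
                body = node.label
            else:
                body = "(" + ",".join(fmt(c, node.height) for c in node.children) + ")"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - node.height:.10g}"

        return fmt(self.root, None) + ";"

    def path_distance(self, a: str, b: str) -> float:
        """Leaf-to-leaf distance (twice the MRCA height for ultrametric trees)."""

        def find(node: TreeNode) -> TreeNode | None:
            got = [c for c in node.children if {a, b} <= {l.label for l in c.leaves()}]
            if got:
                return find(got[0])
            labels = {l.label for l in node.leaves()}
            return node if {a, b} <= labels else None

        mrca = find(self.root)
        if mrca is None:
            raise KeyError(f"labels {a!r}, {b!r} not both in tree")
        return 2.0 * mrca.height

    def distance_matrix(self, labels: Sequence[str] | None = None) -> DistanceMatrix:
        labels = list(labels) if labels else sorted(self.leaf_labels())
        k = len(labels)
        m = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                m[i, j] = m[j, i] = self.path_distance(labels[i], labels[j])
        return DistanceMatrix(labels, m, np.ones((k, k), dtype=int))


def upgma(dm: DistanceMatrix) -> PhyloTree:
    """UPGMA (group-average) clustering into a rooted ultrametric tree.

    Ties on the minimum distance break on the lexicographically smallest
    (representative label) pair, so the result is label-order invariant.
    """
    if len(dm.labels) < 2:
        raise ValueError("need at least 2 labels")
    if not dm.is_complete():
        raise ValueError("distance matrix has missing cells; UPGMA refuses")
    # cluster state: representative (smallest leaf label), size, node
    clusters: dict[int, tuple[str, int, TreeNode]] = {
        i: (lab, 1, TreeNode(0.0, lab)) for i, lab in enumerate(dm.labels)
    }
    dist: dict[tuple[int, int], float] = {}
    k = len(dm.labels)
    for i in range(k):
        for j in range(i + 1, k):
            dist[(i, j)] = float(dm.matrix[i, j])
    next_id = k
    while len(clusters) > 1:
        best_key = None
        best = (math.inf, "", "")
        for (i, j), d in dist.items():
            ri, rj = clusters[i][0], clusters[j][0]
            lo, hi = (ri, rj) if ri < rj else (rj, ri)
            cand = (d, lo, hi)
            if cand < best:
                best = cand
                best_key = (i, j)
        i, j = best_key
        d = dist.pop((i, j))
        rep_i, si, ni = clusters.pop(i)
        rep_j, sj, nj = clusters.pop(j)
        node = TreeNode(d / 2.0, None, [ni, nj] if rep_i < rep_j else [nj, ni])
        new_rep = min(rep_i, rep_j)
        # group-average distances to the merged cluster
        for m_id in list(clusters):
            a = dist.pop((min(i, m_id), max(i, m_id)))
            b = dist.pop((min(j, m_id), max(j, m_id)))
            dist[(min(m_id, next_id), max(m_id, next_id))] = (si * a + sj * b) / (si + sj)
        clusters[next_id] = (new_rep, si + sj, node)
        next_id += 1
    (_, _, root) = next(iter(clusters.values()))
    return PhyloTree(root)


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds (bipartition symmetric difference).

    Computed with dendropy on a shared taxon namespace; 0 means identical
    topologies.
    """
    import dendropy

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))


@dataclass
class RegionTreeResult:
    region: str
    matrix: DistanceMatrix
    tree: PhyloTree
    n_common: int


def region_tree_suite(
    hits: Mapping[str, Mapping[str, object]],
    ests: Mapping[str, object],
    references: Mapping[str, Sequence[ReferenceTranscript]],
    species_subset: Sequence[str],
    focal_label: str,
    annotation_species: str | None = None,
    regions: Iterable[str] = REGIONS,
    matrix: ScoringMatrix | None = None,
    gap: float = 8.0,
    band: int | None = None,
) -> dict[str, RegionTreeResult]:
    """Distance matrix + UPGMA tree per transcript region."""
    labels = sorted(set(species_subset) | {focal_label})
    out: dict[str, RegionTreeResult] = {}
    for region in regions:
        common = common_est_set(hits, ests, references, species_subset,
                                focal_label, region, annotation_species)
        dm = average_distance_matrix(common, labels, region, matrix, gap, band)
        out[region] = RegionTreeResult(region, dm, upgma(dm), len(common))
    return out
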