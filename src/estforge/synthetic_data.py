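"""Ground-truthed synthetic data for every pipeline stage.

The generator draws root transcripts with a 5'UTR/CDS/3'UTR block
structure, evolves them down a known ultrametric species tree under the
JC69 substitution model with region-specific rate multipliers (and
optional per-lineage boosts on terminal branches), and samples an EST
library from the focal species with the empirical length distribution
of PBMC EST libraries (Normal mean 563, sd 167, truncated) plus the
classical single-pass artifacts: strand flips, point sequencing errors,
poly-A tails and terminal Ns.  Every EST carries a truth record, and
closed-form JC69 expectations make the generator and the distance
estimator mutual oracles.

No indels are simulated, so region coordinates are identical across
species; indel robustness is only exercised through EST artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .core_io import EstRecord, ReferenceTranscript, reverse_complement

__all__ = ["SimulationConfig", "EstTruth", "SimulationTruth",
           "simulate_references", "simulate_ests", "end_to_end_recovery"]

#: 5-taxon ultrametric default: apes (hsap, ptro), old-world monkeys
#: (csab = the focal green monkey, mmul), and a new-world outgroup.
DEFAULT_TREE = ("(((hsap:0.01,ptro:0.01):0.01,"
                "(csab:0.015,mmul:0.015):0.005):0.01,cjac:0.03);")

REGIONS = ("utr5", "cds", "utr3")
_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study conditions."""

    tree_newick: str = DEFAULT_TREE
    focal_species: str = "csab"
    n_transcripts: int = 200
    utr5_length: tuple[int, int] = (60, 300)
    cds_length: tuple[int, int] = (300, 900)
    utr3_length: tuple[int, int] = (90, 450)
    rate: float = 1.0  # branch lengths are substitutions/site at multiplier 1
    region_rates: dict = field(default_factory=lambda:
                               {"utr5": 2.0, "cds": 1.0, "utr3": 1.5})
    #: (leaf label, region) -> factor applied on that leaf's terminal branch
    rate_boosts: dict = field(default_factory=dict)
    presence_prob: float = 1.0
    n_ests: int = 1000
    est_length_mean: float = 563.0
    est_length_sd: float = 167.0
    est_length_min: int = 100
    est_length_max: int = 1200
    polya_prob: float = 0.4
    polya_length: tuple[int, int] = (8, 20)
    terminal_n_prob: float = 0.15
    terminal_n_length: tuple[int, int] = (1, 8)
    error_rate: float = 0.005
    strand_flip_prob: float = 0.5
    abundance_alpha: float = 1.0  # power-law skew of transcript abundances
    abundance_weights: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("presence_prob", "polya_prob", "terminal_n_prob",
                     "error_rate", "strand_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rate < 0 or any(r < 0 for r in self.region_rates.values()):
            raise ValueError("rates must be non-negative")
        if self.est_length_min <= 0 or self.est_length_max < self.est_length_min:
            raise ValueError("bad EST length truncation bounds")

    def artifact_free(self) -> "SimulationConfig":
        """Copy with no sequencing errors and no library artifacts."""
        return replace(self, polya_prob=0.0, terminal_n_prob=0.0,
                       error_rate=0.0, strand_flip_prob=0.0)


@dataclass
class EstTruth:
    """Origin of one generated EST (coordinates on the source transcript)."""

    est_id: str
    transcript_id: str
    gene_id: str
    start: int  # 0-based on the focal transcript
    end: int    # half-open
    strand: str
    clipped: bool


@dataclass
class SimulationTruth:
    """Everything needed to score the pipeline against the generator."""

    tree_newick: str
    focal_species: str
    species: list[str]
    region_coords: dict[str, dict[str, tuple[int, int]]]  # gene -> region -> 0-based half-open
    presence: dict[str, set[str]]  # species -> gene ids present
    patristic: dict[frozenset, float]
    terminal_lengths: dict[str, float]
    region_rates: dict[str, float]
    rate: float
    rate_boosts: dict
    ests: dict[str, EstTruth] = field(default_factory=dict)

    def effective_divergence(self, region: str, a: str, b: str) -> float:
        """Expected substitutions/site between two species in one region."""
        mult = self.region_rates[region]
        t = self.patristic[frozenset((a, b))]
        for sp in (a, b):
            boost = self.rate_boosts.get((sp, region), 1.0)
            t += (boost - 1.0) * self.terminal_lengths[sp]
        return self.rate * mult * t

    def expected_d(self, region: str, a: str, b: str) -> float:
        return self.effective_divergence(region, a, b)

    def expected_p(self, region: str, a: str, b: str) -> float:
        d = self.effective_divergence(region, a, b)
        return 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * d))


def _jc_substitute(seq: np.ndarray, d: float, rng: np.random.Generator
                   ) -> np.ndarray:
    """Apply JC69 evolution over branch length d (substitutions/site)."""
    if d <= 0:
        return seq.copy()
    p_sub = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * d))
    mask = rng.random(seq.size) < p_sub
    out = seq.copy()
    out[mask] = (out[mask] + rng.integers(1, 4, mask.sum())) % 4
    return out


def _parse_tree(config: SimulationConfig):
    tree = dendropy.Tree.get(data=config.tree_newick, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if config.focal_species not in leaves:
        raise ValueError(
            f"focal species {config.focal_species!r} not a leaf of the tree")
    pdm = tree.phylogenetic_distance_matrix()
    patristic = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            patristic[frozenset((t1.label, t2.label))] = float(
                pdm.patristic_distance(t1, t2))
    terminal = {lf.taxon.label: float(lf.edge.length or 0.0)
                for lf in tree.leaf_node_iter()}
    return tree, leaves, patristic, terminal


def simulate_references(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[ReferenceTranscript]], SimulationTruth]:
    """Generate per-species reference transcript sets plus the truth record.

    Root transcripts are uniform over {A,C,G,T} per region and evolve
    down the tree region by region; CDS coordinates are preserved across
    species.  Presence/absence is sampled per species per transcript
    (the focal species always keeps every transcript, since the EST
    library is drawn from it).
    """
    rng = rng or np.random.default_rng(config.seed)
    tree, leaves, patristic, terminal = _parse_tree(config)
    region_coords: dict[str, dict[str, tuple[int, int]]] = {}
    refs: dict[str, list[ReferenceTranscript]] = {sp: [] for sp in leaves}
    presence: dict[str, set[str]] = {sp: set() for sp in leaves}
    ranges = {"utr5": config.utr5_length, "cds": config.cds_length,
              "utr3": config.utr3_length}
    for ti in range(config.n_transcripts):
        gene = f"G{ti:04d}"
        lengths = {r: int(rng.integers(lo, hi + 1)) for r, (lo, hi) in ranges.items()}
        u5, cds, u3 = lengths["utr5"], lengths["cds"], lengths["utr3"]
        region_coords[gene] = {
            "utr5": (0, u5),
            "cds": (u5, u5 + cds),
            "utr3": (u5 + cds, u5 + cds + u3),
        }
        root = {r: rng.integers(0, 4, lengths[r]).astype(np.uint8) for r in REGIONS}
        # evolve each region down the tree
        seqs_at = {tree.seed_node: root}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent_seqs = seqs_at[node.parent_node]
            edge_len = float(node.edge.length or 0.0)
            evolved = {}
            for r in REGIONS:
                mult = config.region_rates[r]
                boost = 1.0
                if node.is_leaf():
                    boost = config.rate_boosts.get((node.taxon.label, r), 1.0)
                d = config.rate * mult * boost * edge_len
                evolved[r] = _jc_substitute(parent_seqs[r], d, rng)
            seqs_at[node] = evolved
        for lf in tree.leaf_node_iter():
            sp = lf.taxon.label
            present = (sp == config.focal_species
                       or rng.random() < config.presence_prob)
            if not present:
                continue
            presence[sp].add(gene)
            seq = "".join(
                "".join(_BASES[c] for c in seqs_at[lf][r]) for r in REGIONS)
            refs[sp].append(ReferenceTranscript(
                transcript_id=f"T{ti:04d}.{sp}", gene_id=gene, species=sp,
                sequence=seq, cds_start=u5 + 1, cds_end=u5 + cds))
    truth = SimulationTruth(
        tree_newick=config.tree_newick,
        focal_species=config.focal_species,
        species=leaves,
        region_coords=region_coords,
        presence=presence,
        patristic=patristic,
        terminal_lengths=terminal,
        region_rates=dict(config.region_rates),
        rate=config.rate,
        rate_boosts=dict(config.rate_boosts),
    )
    return refs, truth


def _truncated_normal_int(mean: float, sd: float, lo: int, hi: int,
                          rng: np.random.Generator) -> int:
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return int(round(x))


def simulate_ests(
    config: SimulationConfig,
    references: Mapping[str, Sequence[ReferenceTranscript]],
    truth: SimulationTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[EstRecord], dict[str, EstTruth]]:
    """Sample an EST library from the focal species' transcripts.

    Artifacts are applied in order: strand flip, point sequencing
    errors, 3' poly-A tail, terminal Ns.  ESTs longer than their source
    transcript are clipped and flagged in the truth record.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    focal = list(references[config.focal_species])
    if not focal:
        raise ValueError("focal species has no transcripts")
    if config.abundance_weights is not None:
        w = np.asarray(config.abundance_weights, dtype=float)
        if len(w) != len(focal):
            raise ValueError("abundance_weights length != number of transcripts")
    else:
        w = (np.arange(1, len(focal) + 1, dtype=float)) ** (-config.abundance_alpha)
    w = w / w.sum()
    ests: list[EstRecord] = []
    truths: dict[str, EstTruth] = {}
    for i in range(config.n_ests):
        eid = f"EST{i:06d}"
        t = focal[int(rng.choice(len(focal), p=w))]
        length = _truncated_normal_int(config.est_length_mean, config.est_length_sd,
                                       config.est_length_min, config.est_length_max,
                                       rng)
        clipped = length > len(t.sequence)
        if clipped:
            length = len(t.sequence)
        start = int(rng.integers(0, len(t.sequence) - length + 1))
        seq = t.sequence[start : start + length]
        strand = "+"
        if rng.random() < config.strand_flip_prob:
            strand = "-"
            seq = reverse_complement(seq)
        if config.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            codes = np.zeros(arr.size, dtype=np.uint8)
            for b_i, b in enumerate(_BASES):
                codes[arr == ord(b)] = b_i
            mask = rng.random(arr.size) < config.error_rate
            codes[mask] = (codes[mask] + rng.integers(1, 4, mask.sum())) % 4
            seq = "".join(_BASES[c] for c in codes)
        if rng.random() < config.polya_prob:
            seq = seq + "A" * int(rng.integers(config.polya_length[0],
                                               config.polya_length[1] + 1))
        for end in ("5", "3"):
            if rng.random() < config.terminal_n_prob:
                n_len = int(rng.integers(config.terminal_n_length[0],
                                         config.terminal_n_length[1] + 1))
                seq = ("N" * n_len + seq) if end == "5" else (seq + "N" * n_len)
        ests.append(EstRecord(eid, seq, f"simulated from {t.transcript_id}"))
        rec = EstTruth(eid, t.transcript_id, t.gene_id, start, start + length,
                       strand, clipped)
        truths[eid] = rec
        if truth is not None:
            truth.ests[eid] = rec
    return ests, truths


# ---------------------------------------------------------------------------
# End-to-end recovery harness

def end_to_end_recovery(
    config: SimulationConfig,
    regions: Sequence[str] = ("all", "utr5", "cds", "utr3"),
    include_assembly: bool = False,
    annotation_species: str | None = None,
    align_params=None,
    trim_params=None,
    distance_band: int | None = 64,
) -> dict:
    """Run trim -> (assemble) -> map -> annotate -> quantify -> phylo on
    simulated data and score every stage against the generator's truth.

    Reports Robinson-Foulds distance to the true topology and mean
    relative distance errors per region, region-annotation base accuracy,
    and expression-count exactness.  Deterministic for a fixed config.
    """
    from . import assembly as asm
    from . import mapping_annotation as ma
    from . import phylo as ph
    from . import preprocess as pp

    rng = np.random.default_rng(config.seed)
    references, truth = simulate_references(config, rng)
    ests, est_truths = simulate_ests(config, references, truth, rng)

    kept, dropped, trim_report = pp.quality_filter(ests, trim_params)
    report: dict = {
        "seed": config.seed,
        "n_ests": len(ests),
        "n_kept": len(kept),
        "n_dropped": len(dropped),
        "trim": trim_report.__dict__,
    }

    if include_assembly:
        result = asm.assemble(kept)
        report["assembly"] = result.stats

    focal = config.focal_species
    mapping_refs = {sp: refs for sp, refs in references.items()
                    if sp != focal and refs}
    params = align_params or ma.AlignmentParams()
    hits, unmapped = ma.best_hits(kept, mapping_refs, params)
    report["n_unmapped"] = len(unmapped)
    report["mapping"] = ma.mapping_summary(hits, len(kept)).to_dict("records")

    subset = sorted(mapping_refs)
    annotation_species = annotation_species or subset[0]
    est_index = {e.id: e for e in kept}

    # region-annotation accuracy against the generator's coordinates
    correct = total = 0
    ref_index = {r.transcript_id: r for r in mapping_refs[annotation_species]}
    for eid, hit in hits[annotation_species].items():
        ref = ref_index[hit.transcript_id]
        tr = truth.region_coords[ref.gene_id]
        _e_idx, t_idx = hit.column_map
        for region in REGIONS:
            r0, r1 = tr[region]
            in_region = (t_idx >= r0) & (t_idx < r1)
            n = int(in_region.sum())
            total += n
            ann_r0, ann_r1 = ref.region_interval0(region)
            agree = (t_idx[in_region] >= ann_r0) & (t_idx[in_region] < ann_r1)
            correct += int(agree.sum())
    report["region_annotation_accuracy"] = (correct / total) if total else float("nan")

    # expression exactness: best-hit counts vs the generator's allocation
    expr = ma.expression_ranking(hits[annotation_species])
    true_counts = {}
    for eid in est_index:
        et = est_truths[eid]
        tid = f"{et.transcript_id.rsplit('.', 1)[0]}.{annotation_species}"
        true_counts[tid] = true_counts.get(tid, 0) + 1
    obs_counts = dict(zip(expr["transcript_id"], expr["est_count"]))
    exact = sum(1 for t, c in true_counts.items() if obs_counts.get(t, 0) == c)
    report["expression_exact_fraction"] = exact / len(true_counts) if true_counts else 1.0
    report["top_expression_count"] = int(expr["est_count"].iloc[0]) if len(expr) else 0

    # region-restricted trees and distances
    suite = ph.region_tree_suite(hits, est_index, mapping_refs, subset, focal,
                                 annotation_species, regions,
                                 gap=params.gap_penalty, band=distance_band)
    true_tree = config.tree_newick
    report["regions"] = {}
    for region, res in suite.items():
        rel_errors = []
        labels = res.matrix.labels
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                exp = truth.expected_d("cds" if region == "all" else region,
                                       labels[i], labels[j]) if region != "all" else None
                if region == "all":
                    # "all" mixes regions; compare against the length-weighted mean
                    exp = _weighted_expected_d(truth, config, labels[i], labels[j])
                obs = float(res.matrix.matrix[i, j])
                if exp and exp > 0:
                    rel_errors.append(abs(obs - exp) / exp)
        report["regions"][region] = {
            "n_common": res.n_common,
            "tree": res.tree.to_newick(),
            "rf_vs_true": ph.robinson_foulds(res.tree.to_newick(), true_tree),
            "mean_rel_distance_error": float(np.mean(rel_errors)) if rel_errors else float("nan"),
            "max_rel_distance_error": float(np.max(rel_errors)) if rel_errors else float("nan"),
        }
    if "utr5" in suite and "cds" in suite:
        report["rf_utr5_vs_cds"] = ph.robinson_foulds(
            suite["utr5"].tree.to_newick(), suite["cds"].tree.to_newick())
    return report


def _weighted_expected_d(truth: SimulationTruth, config: SimulationConfig,
                         a: str, b: str) -> float:
    """Expected whole-transcript distance: region expectation weighted by
    mean region length (an approximation for reporting only)."""
    weights = {r: (lo + hi) / 2.0 for r, (lo, hi) in
               {"utr5": config.utr5_length, "cds": config.cds_length,
                "utr3": config.utr3_length}.items()}
    tot = sum(weights.values())
    exp_p = sum(weights[r] * truth.expected_p(r, a, b) for r in REGIONS) / tot
    if exp_p >= 0.75:
        return float("inf")
    return -0.75 * math.log1p(-(4.0 / 3.0) * exp_p)
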