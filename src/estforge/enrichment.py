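"""Gene-set over-representation analysis.

Right-tailed Fisher exact test (hypergeometric upper tail) of the mapped
gene list against user-supplied gene sets (GMT), with Benjamini-Hochberg
FDR adjustment.  The universe defaults to the union of all genes in the
gene-set collection and the mapped genes; pass an explicit universe to
override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSet

__all__ = ["EnrichmentResult", "fisher_right_tail", "bh_adjust", "enrich"]


@dataclass
class EnrichmentResult:
    name: str
    gen_a: int  # mapped genes in the set
    gen_b: int  # set size (within the universe)
    universe_hits: int
    universe_size: int
    p_value: float
    q_value: float

    @property
    def ratio(self) -> float:
        return self.gen_a / self.gen_b if self.gen_b else 0.0

    @property
    def minus_log10_q(self) -> float:
        return -math.log10(self.q_value) if self.q_value > 0 else math.inf


def fisher_right_tail(gen_a: int, gen_b: int, universe_hits: int,
                      universe_size: int) -> float:
    """P(X >= gen_a) for X ~ Hypergeometric(universe_size, gen_b, universe_hits).

    This is the right tail of Fisher's exact test on the 2x2 table of
    set membership vs mapped status.
    """
    if not (0 <= gen_a <= min(gen_b, universe_hits)
            and gen_b <= universe_size and universe_hits <= universe_size):
        raise ValueError(
            f"inconsistent counts: gen_a={gen_a}, gen_b={gen_b}, "
            f"universe_hits={universe_hits}, universe_size={universe_size}")
    return float(hypergeom.sf(gen_a - 1, universe_size, gen_b, universe_hits))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(mapped_genes: Iterable[str], gene_sets: Sequence[GeneSet],
           universe: Iterable[str] | None = None) -> list[EnrichmentResult]:
    """Test every gene set for over-representation among the mapped genes.

    Gene sets are intersected with the universe before testing; results
    are sorted by (q, p, name).
    """
    mapped = set(mapped_genes)
    if universe is None:
        uni = set().union(*(s.genes for s in gene_sets)) | mapped
    else:
        uni = set(universe)
        if not mapped <= uni:
            raise ValueError("universe must contain every mapped gene")
    if not uni:
        raise ValueError("empty universe")
    mapped &= uni
    rows = []
    for s in gene_sets:
        genes = s.genes & uni
        gen_b = len(genes)
        gen_a = len(genes & mapped)
        p = fisher_right_tail(gen_a, gen_b, len(mapped), len(uni)) if gen_b else 1.0
        rows.append((s.name, gen_a, gen_b, p))
    q = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(name, gen_a, gen_b, len(mapped), len(uni), p, float(qv))
        for (name, gen_a, gen_b, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.name))
    return results


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path,
                         config=None) -> None:
    from .core_io import provenance_header

    with open(path, "w") as fh:
        fh.write(provenance_header(config) + "\n")
        fh.write("set\tgen_a\tgen_b\tratio\tp\tq\tminus_log10_q\n")
        for r in results:
            fh.write(f"{r.name}\t{r.gen_a}\t{r.gen_b}\t{r.ratio:.4f}\t"
                     f"{r.p_value:.6g}\t{r.q_value:.6g}\t{r.minus_log10_q:.4f}\n")
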