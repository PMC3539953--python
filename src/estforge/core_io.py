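"""Shared domain types and readers/writers for the pipeline's file formats.

Formats handled: FASTA (sequences, via Biopython), TSV (hit tables,
annotations, expression, stats), GMT (gene sets), Newick (trees), and
square TSV distance matrices.  Coordinates are 0-based half-open
internally and 1-based inclusive in all TSV outputs, matching the
Ensembl-style transcript annotation convention.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_CODES = set("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC nucleotide alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class DuplicateIdError(ValueError):
    """Two records in one file share an id."""


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class EstRecord:
    """One EST sequence with provenance and trim history.

    ``trim_log`` records tuples ``(operation, bases_removed_5p,
    bases_removed_3p)``; the removed lengths always sum to the difference
    between the original and current sequence length.
    """

    id: str
    sequence: str
    description: str = ""
    trim_log: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("EST id must be non-empty")
        self.sequence = normalize_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def trimmed(self, op: str, left: int, right: int) -> "EstRecord":
        """Return a copy with ``left``/``right`` terminal bases removed."""
        n = len(self.sequence)
        if left + right > n:
            left, right = min(left, n), 0
        new_seq = self.sequence[left : n - right if right else n]
        return EstRecord(
            self.id,
            new_seq,
            self.description,
            self.trim_log + [(op, left, right)],
        )


@dataclass
class ReferenceTranscript:
    """A reference cDNA with optional CDS coordinates (1-based inclusive).

    Region layout on the transcript: 5'UTR = [1, cds_start-1],
    CDS = [cds_start, cds_end], 3'UTR = [cds_end+1, length].
    """

    transcript_id: str
    gene_id: str
    species: str
    sequence: str
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(
                f"{self.transcript_id}: cds_start and cds_end must both be set or both absent"
            )
        if self.cds_start is not None:
            if not (1 <= self.cds_start <= self.cds_end <= len(self.sequence)):
                raise ValueError(
                    f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}] "
                    f"outside transcript of length {len(self.sequence)}"
                )

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    def region_of(self, pos0: int) -> str:
        """Region name ('utr5' | 'cds' | 'utr3') of a 0-based position."""
        if not self.has_cds:
            raise ValueError(f"{self.transcript_id} has no CDS annotation")
        if pos0 < self.cds_start - 1:
            return "utr5"
        if pos0 <= self.cds_end - 1:
            return "cds"
        return "utr3"

    def region_interval0(self, region: str) -> tuple[int, int]:
        """0-based half-open interval of a region on the transcript."""
        if not self.has_cds:
            raise ValueError(f"{self.transcript_id} has no CDS annotation")
        n = len(self.sequence)
        if region == "utr5":
            return 0, self.cds_start - 1
        if region == "cds":
            return self.cds_start - 1, self.cds_end
        if region == "utr3":
            return self.cds_end, n
        if region == "all":
            return 0, n
        raise ValueError(f"unknown region {region!r}")


@dataclass
class GeneSet:
    """A named set of gene symbols/ids (one GMT line)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with the printed defaults.

    window/max_n_fraction are the terminal-N trimming constants (30, 0.20);
    overlap_identity the assembly cutoff (0.80); min_est_coverage the
    best-hit support threshold (0.80); quasi_complete_threshold the
    coverage above which a reference transcript counts as quasi-complete
    (0.90).  The seed is recorded in every output header.
    """

    window: int = 30
    max_n_fraction: float = 0.20
    min_tail_length: int = 4
    tail_mismatches_allowed: int = 1
    min_length_after_trim: int = 100
    overlap_identity: float = 0.80
    min_overlap_length: int = 40
    min_est_coverage: float = 0.80
    quasi_complete_threshold: float = 0.90
    gap_penalty: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_n_fraction", "overlap_identity", "min_est_coverage",
                     "quasi_complete_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.window < 1 or self.min_overlap_length < 1:
            raise ValueError("window and min_overlap_length must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U to T; reject characters outside the IUPAC set."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - IUPAC_CODES
    if bad:
        raise FormatError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


def provenance_header(config: PipelineConfig | None = None) -> str:
    """Comment line stamped at the top of every writer's output."""
    from . import __version__

    cfg = config or PipelineConfig()
    return f"# estforge {__version__} config={cfg.config_hash()} seed={cfg.seed}"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[EstRecord]:
    """Read a FASTA file into EstRecords (id = first header token)."""
    path = Path(path)
    records: list[EstRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(EstRecord(rec.id, str(rec.seq), rec.description))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    """Write EstRecords / Contigs / (id, seq) pairs as FASTA."""
    out = []
    for r in records:
        if hasattr(r, "consensus"):  # Contig
            out.append(SeqRecord(Seq(r.consensus), id=r.contig_id, description=""))
        elif hasattr(r, "sequence"):
            out.append(SeqRecord(Seq(r.sequence), id=r.id, description=r.description))
        else:
            rid, seq = r
            out.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(out)


def read_reference_fasta(
    path: str | Path,
    annotation: str | Path | None = None,
    species: str | None = None,
) -> list[ReferenceTranscript]:
    """Read one species' cDNA set, optionally joining a CDS annotation table.

    The annotation TSV has columns transcript_id, gene_id, cds_start,
    cds_end (1-based inclusive; empty cds fields mean unannotated).
    """
    path = Path(path)
    sp = species or path.stem
    annot: dict[str, tuple[str, int | None, int | None]] = {}
    if annotation is not None:
        for tid, gid, cs, ce in _read_annotation_rows(annotation):
            annot[tid] = (gid, cs, ce)
    out: list[ReferenceTranscript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate transcript id {rec.id!r} in {path}")
        seen.add(rec.id)
        gid, cs, ce = annot.get(rec.id, (rec.id, None, None))
        out.append(ReferenceTranscript(rec.id, gid, sp, str(rec.seq), cs, ce))
    return out


def _read_annotation_rows(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "transcript_id":
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            tid, gid, cs, ce = fields[:4]
            yield tid, gid, (int(cs) if cs else None), (int(ce) if ce else None)


def write_annotation_table(refs: Sequence[ReferenceTranscript], path: str | Path,
                           config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config) + "\n")
        fh.write("transcript_id\tgene_id\tcds_start\tcds_end\n")
        for r in refs:
            cs = "" if r.cds_start is None else str(r.cds_start)
            ce = "" if r.cds_end is None else str(r.cds_end)
            fh.write(f"{r.transcript_id}\t{r.gene_id}\t{cs}\t{ce}\n")


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name TAB description TAB gene [TAB gene ...]``."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name = fields[0]
            if name in names:
                raise DuplicateIdError(f"{path}:{lineno}: duplicate gene set {name!r}")
            names.add(name)
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name, genes))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na"] + sorted(s.genes)) + "\n")


# ---------------------------------------------------------------------------
# Distance matrices and trees

def write_distance_matrix(labels: Sequence[str], matrix, path: str | Path,
                          config: PipelineConfig | None = None) -> None:
    """Square tab-separated matrix with species header row and column."""
    import numpy as np

    m = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write(provenance_header(config) + "\n")
        fh.write("\t" + "\t".join(labels) + "\n")
        for i, lab in enumerate(labels):
            fh.write(lab + "\t" + "\t".join(f"{m[i, j]:.6g}" for j in range(len(labels))) + "\n")


def read_distance_matrix(path: str | Path):
    import numpy as np

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    labels = lines[0].split("\t")[1:]
    rows = []
    for lab, ln in zip(labels, lines[1:]):
        fields = ln.split("\t")
        if fields[0] != lab:
            raise FormatError(f"{path}: row label {fields[0]!r} != column label {lab!r}")
        rows.append([float(x) for x in fields[1:]])
    return labels, np.asarray(rows)


def write_newick(tree, path: str | Path, config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config) + "\n")
        fh.write(tree.to_newick() + "\n")


def read_newick(path: str | Path) -> str:
    with open(path) as fh:
        return "".join(ln for ln in fh if not ln.startswith("#")).strip()


def write_outputs(objects, path: str | Path, format: str) -> None:
    """Format-dispatching writer: FASTA, TSV, Newick or distance-matrix.

    ``objects`` is a list of records for FASTA, a (labels, matrix) pair
    for ``distance``, a tree with ``to_newick`` for ``newick``, or a list
    of row-tuples (first row = header) for ``tsv``.
    """
    fmt = format.lower()
    if fmt == "fasta":
        write_fasta(objects, path)
    elif fmt == "newick":
        write_newick(objects, path)
    elif fmt == "distance":
        labels, matrix = objects
        write_distance_matrix(labels, matrix, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(provenance_header() + "\n")
            for row in objects:
                fh.write("\t".join(str(x) for x in row) + "\n")
    else:
        raise ValueError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# Misc

_ACC_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def accession_range_size(first: str, last: str) -> int:
    """Number of entries in an inclusive accession range like JK088433..JK126219."""
    m1, m2 = _ACC_RE.match(first), _ACC_RE.match(last)
    if not m1 or not m2 or m1.group(1) != m2.group(1):
        raise ValueError(f"incompatible accessions {first!r}, {last!r}")
    return int(m2.group(2)) - int(m1.group(2)) + 1
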