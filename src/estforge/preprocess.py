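"""EST quality filtering: poly-A/T tail trimming and terminal-N windows.

Trimming removes a terminal run of A at the 3' end and/or T at the 5' end
(single-pass reads carry the poly-A tail on either strand), then scans
terminal windows of W bases and advances inward while any window anchored
at the end holds more than ``max_n_fraction`` Ns.  Tails are re-trimmed
once after N-window trimming, because removing an N-rich terminus can
expose a new tail; the combined operation is idempotent.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .core_io import EstRecord


@dataclass
class TrimParams:
    """Trimming thresholds.

    window/max_n_fraction follow the published terminal-N rule (20% Ns in
    a window of 30 nucleotides); tail semantics (minimum run 4, one
    mismatch allowed inside the run) and the 100-nt length floor are
    package defaults, exposed here.
    """

    window: int = 30
    max_n_fraction: float = 0.20
    min_tail_length: int = 4
    tail_mismatches_allowed: int = 1
    min_length_after_trim: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.max_n_fraction < 1.0:
            raise ValueError("max_n_fraction must be in (0, 1)")
        if self.window < 1 or self.min_tail_length < 1:
            raise ValueError("window and min_tail_length must be >= 1")


def _tail_run(seq: str, base: str, end: str, params: TrimParams) -> int:
    """Length of the longest terminal run of ``base`` allowing mismatches.

    The innermost position of the run must itself be ``base`` so no body
    bases beyond the tail are eaten.
    """
    n = len(seq)
    best = 0
    mismatches = 0
    for k in range(1, n + 1):
        c = seq[n - k] if end == "3" else seq[k - 1]
        if c != base:
            mismatches += 1
            if mismatches > params.tail_mismatches_allowed:
                break
        else:
            best = k
    return best if best >= params.min_tail_length else 0


def trim_poly_tails(est: EstRecord, params: TrimParams | None = None) -> EstRecord:
    """Trim a 3' poly-A run and/or a 5' poly-T run.

    Runs to a fixed point: the mismatch allowance can expose a fresh
    admissible run once the outer one is gone, so a single pass would not
    be idempotent.  Only terminal bases are ever removed.
    """
    params = params or TrimParams()
    current = est
    while True:
        right = _tail_run(current.sequence, "A", "3", params)
        seq_after = current.sequence[: len(current.sequence) - right]
        left = _tail_run(seq_after, "T", "5", params)
        if left == 0 and right == 0:
            return current
        current = current.trimmed("poly_tails", left, right)


def _n_clean_prefix(seq: str, params: TrimParams) -> int:
    """Bases to cut so no window anchored at the start exceeds the N fraction.

    Windows shorter than W (at the sequence end) use their actual length
    as the denominator, so any terminal N fails the length-1 window.
    """
    n = len(seq)
    cut = 0
    while cut < n:
        wmax = min(params.window, n - cut)
        # cumulative N counts over the anchored windows
        bad = False
        n_count = 0
        for w in range(1, wmax + 1):
            if seq[cut + w - 1] == "N":
                n_count += 1
            if n_count > params.max_n_fraction * w:
                bad = True
                break
        if not bad:
            break
        cut += 1
    return cut


def trim_terminal_ns(est: EstRecord, params: TrimParams | None = None) -> EstRecord:
    """Trim N-rich termini from both ends."""
    params = params or TrimParams()
    left = _n_clean_prefix(est.sequence, params)
    rest = est.sequence[left:]
    right = _n_clean_prefix(rest[::-1], params)
    if left == 0 and right == 0:
        return est
    return est.trimmed("terminal_ns", left, right)


def trim_est(est: EstRecord, params: TrimParams | None = None) -> EstRecord:
    """Full trim: alternate tail and N-window trimming to a fixed point.

    N-window trimming can expose a new terminal tail (the generator
    appends terminal Ns outside the poly-A tail) and vice versa, so the
    two passes are interleaved until the sequence stops changing; the
    combined operation is therefore idempotent.
    """
    params = params or TrimParams()
    current = est
    while True:
        after = trim_terminal_ns(trim_poly_tails(current, params), params)
        if after.sequence == current.sequence:
            return after
        current = after


@dataclass
class TrimReport:
    n_input: int
    n_kept: int
    n_dropped: int
    bases_trimmed: int
    length_median: float
    length_mean: float
    length_sd: float

    def to_tsv(self) -> str:
        head = "n_input\tn_kept\tn_dropped\tbases_trimmed\tlength_median\tlength_mean\tlength_sd"
        row = (f"{self.n_input}\t{self.n_kept}\t{self.n_dropped}\t{self.bases_trimmed}"
               f"\t{self.length_median:.1f}\t{self.length_mean:.2f}\t{self.length_sd:.2f}")
        return head + "\n" + row + "\n"


def quality_filter(
    library: list[EstRecord],
    params: TrimParams | None = None,
    trim: bool = True,
) -> tuple[list[EstRecord], list[EstRecord], TrimReport]:
    """Trim every EST and keep those at least ``min_length_after_trim`` long.

    Returns (kept, dropped, report); kept and dropped partition the input.
    """
    params = params or TrimParams()
    import warnings

    if not library:
        warnings.warn("quality_filter: empty input library", stacklevel=2)
        return [], [], TrimReport(0, 0, 0, 0, 0.0, 0.0, 0.0)
    trimmed = [trim_est(e, params) if trim else e for e in library]
    kept = [e for e in trimmed if len(e) >= params.min_length_after_trim]
    dropped = [e for e in trimmed if len(e) < params.min_length_after_trim]
    lengths = [len(e) for e in kept]
    bases_trimmed = sum(len(a) - len(b) for a, b in zip(library, trimmed))
    report = TrimReport(
        n_input=len(library),
        n_kept=len(kept),
        n_dropped=len(dropped),
        bases_trimmed=bases_trimmed,
        length_median=float(statistics.median(lengths)) if lengths else 0.0,
        length_mean=float(statistics.fmean(lengths)) if lengths else 0.0,
        length_sd=float(statistics.stdev(lengths)) if len(lengths) > 1 else 0.0,
    )
    return kept, dropped, report
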