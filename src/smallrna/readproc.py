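"""Raw FASTQ to per-sample collapsed unique-sequence count tables.

Stages mirror a standard small-RNA preprocessing pipeline: strip the 3'
adapter (rejecting reads without one), drop low-quality reads, drop
short inserts, then collapse identical inserts into per-sequence
counts.  The stage tallies are conserved exactly: every input read is
either retained or attributed to exactly one rejection reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .core import TRUSEQ_SMALL_RNA_ADAPTER


def strip_adaptor(
    sequence: str,
    adaptor: str = TRUSEQ_SMALL_RNA_ADAPTER,
    min_overlap: int = 6,
    max_mismatch: int = 0,
) -> str | None:
    """Return the insert before the leftmost 3' adapter match, or None.

    A match is either the full adapter anywhere in the read, or a
    prefix of the adapter of length >= ``min_overlap`` ending exactly at
    the read's 3' end.  ``max_mismatch`` (0 or 1) allows Hamming
    mismatches in the full-adapter match; the terminal-prefix match is
    always exact.  None means the read carries no adapter and is
    discarded.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    sequence = sequence.upper()
    adaptor = adaptor.upper()
    if max_mismatch == 0:
        idx = sequence.find(adaptor)
        if idx >= 0:
            return sequence[:idx]
    else:
        for idx in range(len(sequence) - len(adaptor) + 1):
            window = sequence[idx: idx + len(adaptor)]
            if sum(a != b for a, b in zip(window, adaptor)) <= max_mismatch:
                return sequence[:idx]
    for k in range(min(len(adaptor) - 1, len(sequence)), min_overlap - 1, -1):
        if sequence.endswith(adaptor[:k]):
            return sequence[: len(sequence) - k]
    return None


def quality_pass(
    quality: np.ndarray | list[int],
    threshold: float = 30.0,
    mode: str = "mean",
) -> bool:
    """True iff the read's Phred profile clears ``threshold``.

    ``mode`` selects the summary: ``mean`` (default, inclusive at the
    threshold) or ``min`` (every base must clear it).  Empty profiles
    fail.
    """
    q = np.asarray(quality)
    if q.size == 0:
        return False
    if mode == "mean":
        return bool(q.mean() >= threshold)
    if mode == "min":
        return bool(q.min() >= threshold)
    raise ValueError(f"unknown quality mode {mode!r}")


def length_pass(insert: str, min_len: int = 13) -> bool:
    """True iff the insert survives the length filter (>= ``min_len``)."""
    return len(insert) >= min_len


def collapse(inserts) -> pd.Series:
    """Collapse an iterable of insert sequences into per-sequence counts.

    Returns a Series indexed by sequence in lexicographic order; counts
    sum to the number of inserts.  Collapsing is idempotent in the sense
    that re-collapsing the expanded table reproduces it.
    """
    counts: dict[str, int] = {}
    for seq in inserts:
        counts[seq] = counts.get(seq, 0) + 1
    return pd.Series(
        {s: counts[s] for s in sorted(counts)}, dtype=np.int64, name="count"
    )


@dataclass
class QCReport:
    """Per-stage read accounting for one FASTQ file."""

    total_reads: int = 0
    rejected_no_adaptor: int = 0
    rejected_low_quality: int = 0
    rejected_too_short: int = 0
    retained: int = 0
    stage_order: tuple[str, ...] = ("strip", "quality", "length")
    path: str | None = field(default=None)

    def as_dict(self) -> dict:
        return {
            "path": self.path,
            "total_reads": self.total_reads,
            "rejected_no_adaptor": self.rejected_no_adaptor,
            "rejected_low_quality": self.rejected_low_quality,
            "rejected_too_short": self.rejected_too_short,
            "retained": self.retained,
            "stage_order": list(self.stage_order),
        }

    @property
    def conserved(self) -> bool:
        return self.total_reads == (
            self.rejected_no_adaptor
            + self.rejected_low_quality
            + self.rejected_too_short
            + self.retained
        )


def _mean_phred(quality_string: str) -> float:
    return float((np.frombuffer(quality_string.encode(), np.uint8) - 33).mean())


def _min_phred(quality_string: str) -> float:
    return float((np.frombuffer(quality_string.encode(), np.uint8) - 33).min())


def process_fastq(
    path: str,
    adaptor: str = TRUSEQ_SMALL_RNA_ADAPTER,
    min_qual: float = 30.0,
    min_len: int = 13,
    qual_mode: str = "mean",
    min_overlap: int = 6,
    max_mismatch: int = 0,
) -> tuple[pd.Series, QCReport]:
    """Run strip -> quality -> length -> collapse on one FASTQ file.

    Reads containing N fail the quality stage (downstream matching is
    exact).  Quality is judged on the raw read's Phred profile.  Returns
    the collapsed insert counts and a conserving QC report.  Accepts
    plain or gzipped FASTQ; a malformed record raises with its index.
    """
    adaptor = adaptor.upper()
    report = QCReport(path=str(path))
    retained: dict[str, int] = {}
    # Libraries are dominated by a modest number of distinct reads, so
    # memoise per-sequence and per-quality-string decisions.
    strip_cache: dict[str, str | None] = {}
    qual_cache: dict[str, bool] = {}
    summarise = _mean_phred if qual_mode == "mean" else _min_phred
    if qual_mode not in ("mean", "min"):
        raise ValueError(f"unknown quality mode {qual_mode!r}")

    idx = -1
    try:
        with pysam.FastxFile(str(path)) as fh:
            for idx, rec in enumerate(fh):
                seq = rec.sequence.upper()
                insert = strip_cache.get(seq, "?")
                if insert == "?":
                    insert = strip_adaptor(seq, adaptor, min_overlap, max_mismatch)
                    if "N" in seq and insert is not None:
                        insert = "N"  # sentinel: has adapter but fails QC
                    strip_cache[seq] = insert
                if insert is None:
                    report.rejected_no_adaptor += 1
                    continue
                qual = rec.quality
                if qual is None:
                    raise ValueError(f"FASTQ record {idx} has no quality string")
                ok = qual_cache.get(qual)
                if ok is None:
                    ok = qual_cache[qual] = summarise(qual) >= min_qual
                if insert == "N" or not ok:
                    report.rejected_low_quality += 1
                    continue
                if not length_pass(insert, min_len):
                    report.rejected_too_short += 1
                    continue
                retained[insert] = retained.get(insert, 0) + 1
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed FASTQ record near index {idx + 1}: {exc}") from exc
    report.total_reads = idx + 1
    report.retained = sum(retained.values())
    table = pd.Series(
        {s: retained[s] for s in sorted(retained)}, dtype=np.int64, name="count"
    )
    return table, report
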