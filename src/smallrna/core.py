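"""Shared containers for the small-RNA pipeline.

The pipeline passes three kinds of objects between stages: reference
records (small-RNA sequences with a category, and, for tRNA loci, the
coordinates of the mature tRNA body inside its genomic flanks), count
matrices with donor/treatment/timepoint sample metadata, and plain
per-sample collapsed read tables (pandas Series keyed by sequence).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("miRNA_hairpin", "tRNA_locus", "snoRNA", "rRNA", "yRNA")

#: Illumina TruSeq small-RNA 3' adapter.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_DNA = re.compile(r"^[ACGT]+$")


def is_dna(seq: str) -> bool:
    return bool(_DNA.match(seq))


@dataclass(frozen=True)
class ReferenceRecord:
    """One small-RNA reference sequence.

    For ``tRNA_locus`` records the sequence is the genomic locus padded
    with up to 30 nt of flank on each side; ``body_start``/``body_end``
    delimit the mature tRNA body as 0-based half-open coordinates within
    the padded sequence.  The post-transcriptional 3' CCA is not part of
    the record: 3' fragment positions are read against the genomic body
    end.  Other categories carry no body coordinates.
    """

    id: str
    category: str
    sequence: str
    body_start: int | None = None
    body_end: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not is_dna(self.sequence):
            raise ValueError(f"non-ACGT sequence in record {self.id!r}")
        if self.category == "tRNA_locus":
            if self.body_start is None or self.body_end is None:
                raise ValueError(f"tRNA locus {self.id!r} lacks body coordinates")
            if not (0 <= self.body_start < self.body_end <= len(self.sequence)):
                raise ValueError(f"invalid body coordinates in {self.id!r}")
            if self.body_start > 30 or len(self.sequence) - self.body_end > 30:
                raise ValueError(f"flank longer than 30 nt in {self.id!r}")


def write_reference_fasta(records: list[ReferenceRecord], path: str) -> None:
    """Write references with headers ``id|category|start-end|flank=N``.

    Body coordinates are emitted 1-based inclusive; non-tRNA records get
    ``id|category`` headers.
    """
    out = []
    for rec in records:
        if rec.category == "tRNA_locus":
            name = (
                f"{rec.id}|{rec.category}|{rec.body_start + 1}-{rec.body_end}"
                f"|flank={rec.body_start}"
            )
        else:
            name = f"{rec.id}|{rec.category}"
        out.append(SeqRecord(Seq(rec.sequence), id=name, description=""))
    SeqIO.write(out, path, "fasta")


def read_reference_fasta(path: str) -> list[ReferenceRecord]:
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 2:
            records.append(ReferenceRecord(parts[0], parts[1], str(rec.seq).upper()))
        elif len(parts) == 4:
            start, end = parts[2].split("-")
            records.append(
                ReferenceRecord(
                    parts[0], parts[1], str(rec.seq).upper(),
                    body_start=int(start) - 1, body_end=int(end),
                )
            )
        else:
            raise ValueError(f"unparseable reference header {rec.id!r}")
    return records


@dataclass
class CountMatrix:
    """Features x samples matrix with sample metadata.

    ``values`` is features (rows) by samples (columns); ``meta`` is
    indexed by sample id with columns ``donor``, ``treatment`` (``LPS``
    or ``medium``) and ``timepoint`` (hours).  ``unit`` is ``raw`` or
    ``CPM``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    unit: str = "raw"
    truth: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.unit not in ("raw", "CPM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        for col in ("donor", "treatment", "timepoint"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks column {col!r}")
        bad = set(self.meta["treatment"]) - {"LPS", "medium"}
        if bad:
            raise ValueError(f"unknown treatment labels: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(
            self.values[samples].copy(), self.meta.loc[samples].copy(), self.unit,
            truth=self.truth,
        )

    def write_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")


def read_count_matrix(values_path: str, meta_path: str, unit: str = "raw") -> CountMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(values, meta, unit)
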