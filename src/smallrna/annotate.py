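"""Map collapsed reads onto the small-RNA reference and build count matrices.

Alignment is exact, sense-strand, ungapped, full-length substring
matching (small-RNA inserts are short and already error-filtered, so
exactness keeps the unique-mapping rule well defined).  A sequence is
retained when all of its hits fall in one category and share the
identical matched subsequence - multi-locus hits to identical tRNA (or
hairpin) copies count as one reference sequence, which is what lets a
fragment shared by nine identical tRNA gene copies survive the
unique-mapping filter.  Cross-category hits are discarded as
multi-mapped.  Retained counts are normalised to counts per million
(CPM) over each sample's total retained mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountMatrix, ReferenceRecord

SEED_LEN = 13  # minimum insert length; also the index seed size

UNMAPPED = "unmapped"
MULTIMAPPED = "multimapped"
RETAINED = "retained"


@dataclass(frozen=True)
class Hit:
    """One exact occurrence of a query in a reference record."""

    query: str
    ref_id: str
    category: str
    offset: int

    @property
    def matched(self) -> str:
        return self.query

    @property
    def end(self) -> int:
        return self.offset + len(self.query)


class ReferenceIndex:
    """Seed-and-verify index over reference records.

    Every 13-mer start position in every record is indexed; a query's
    leading 13-mer locates candidate offsets which are then verified by
    full comparison.  Equivalent to a naive scan for queries >= 13 nt.
    """

    def __init__(self, records: list[ReferenceRecord]):
        self.records = list(records)
        self.by_id = {r.id: r for r in self.records}
        if len(self.by_id) != len(self.records):
            raise ValueError("duplicate reference ids")
        self._seeds: dict[str, list[tuple[int, int]]] = {}
        for ri, rec in enumerate(self.records):
            seq = rec.sequence
            for off in range(len(seq) - SEED_LEN + 1):
                self._seeds.setdefault(seq[off: off + SEED_LEN], []).append((ri, off))

    def find(self, query: str) -> list[Hit]:
        hits = []
        for ri, off in self._seeds.get(query[:SEED_LEN], ()):
            rec = self.records[ri]
            if rec.sequence[off: off + len(query)] == query:
                hits.append(Hit(query, rec.id, rec.category, off))
        hits.sort(key=lambda h: (h.ref_id, h.offset))
        return hits


def align_exact(
    query: str, reference: list[ReferenceRecord] | ReferenceIndex
) -> list[Hit]:
    """All sense-strand exact occurrences of ``query`` in the reference,
    ordered by (record id, offset)."""
    if len(query) < SEED_LEN:
        raise ValueError(f"query shorter than {SEED_LEN} nt")
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    return index.find(query)


@dataclass(frozen=True)
class Assignment:
    """Unique-mapping decision for one collapsed sequence."""

    query: str
    status: str  # RETAINED | MULTIMAPPED | UNMAPPED
    category: str | None = None
    ref_ids: tuple[str, ...] = ()
    hits: tuple[Hit, ...] = field(default=(), repr=False)

    @property
    def feature_id(self) -> str:
        """Canonical feature id: the sorted reference ids joined by '|'."""
        return "|".join(self.ref_ids)


def assign(query: str, hits: list[Hit]) -> Assignment:
    """Apply the unique-mapping rule to a query's hits.

    Retained iff every hit is in the same category and matches the
    identical subsequence (trivially true for exact full-length
    matches); hits spanning categories are discarded as multi-mapped.
    """
    if not hits:
        return Assignment(query, UNMAPPED)
    categories = {h.category for h in hits}
    contexts = {h.matched for h in hits}
    if len(categories) > 1 or len(contexts) > 1:
        return Assignment(query, MULTIMAPPED)
    ref_ids = tuple(sorted({h.ref_id for h in hits}))
    return Assignment(query, RETAINED, categories.pop(), ref_ids, tuple(hits))


def assign_all(
    collapsed_tables: dict[str, pd.Series],
    reference: list[ReferenceRecord] | ReferenceIndex,
) -> dict[str, Assignment]:
    """Assignments for the union of sequences across samples."""
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    sequences = sorted(set().union(*[t.index for t in collapsed_tables.values()]))
    return {s: assign(s, index.find(s)) for s in sequences}


@dataclass
class AnnotationResult:
    """Count matrices and mapping summaries for a set of samples."""

    by_category: dict[str, CountMatrix]
    combined: CountMatrix          # feature-level, all categories
    sequence_level: CountMatrix    # retained sequences x samples
    fractions: pd.DataFrame        # per-sample share of mapped reads per category
    mapped_totals: pd.Series       # per-sample retained mapped read counts
    sequence_category: pd.Series   # retained sequence -> category


def build_counts(
    collapsed_tables: dict[str, pd.Series],
    assignments: dict[str, Assignment],
    meta: pd.DataFrame,
) -> AnnotationResult:
    """Aggregate retained sequences into per-category count matrices.

    Features are canonical assignment ids (sorted reference ids joined
    by '|'), so each retained read is counted exactly once and totals
    conserve the collapsed counts of retained sequences.
    """
    missing = set(collapsed_tables) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    samples = list(collapsed_tables)

    retained = {s: a for s, a in assignments.items() if a.status == RETAINED}
    seq_ids = sorted(retained)
    seq_values = pd.DataFrame(0, index=seq_ids, columns=samples, dtype=np.int64)
    for sample, table in collapsed_tables.items():
        common = table.index.intersection(seq_ids)
        seq_values.loc[common, sample] = table.loc[common].astype(np.int64)

    feat_of = {s: retained[s].feature_id for s in seq_ids}
    cat_of = pd.Series({s: retained[s].category for s in seq_ids}, dtype=object)
    combined_values = seq_values.groupby(
        pd.Index([feat_of[s] for s in seq_ids], name="feature")
    ).sum()
    feat_cat = {feat_of[s]: retained[s].category for s in seq_ids}

    meta = meta.loc[samples]
    by_category = {}
    for cat in sorted({a.category for a in retained.values()}):
        feats = sorted([f for f, c in feat_cat.items() if c == cat])
        by_category[cat] = CountMatrix(combined_values.loc[feats].copy(), meta, "raw")

    mapped_totals = seq_values.sum(axis=0)
    frac_rows = {}
    for cat, cm in by_category.items():
        frac_rows[cat] = cm.values.sum(axis=0) / mapped_totals.replace(0, np.nan)
    fractions = pd.DataFrame(frac_rows).T

    return AnnotationResult(
        by_category=by_category,
        combined=CountMatrix(combined_values, meta, "raw"),
        sequence_level=CountMatrix(seq_values, meta, "raw"),
        fractions=fractions,
        mapped_totals=mapped_totals,
        sequence_category=cat_of,
    )


def to_cpm(matrix: CountMatrix, totals: pd.Series | None = None) -> CountMatrix:
    """Normalise a raw matrix to counts per million.

    ``totals`` supplies the per-sample denominator (the sample's total
    retained mapped reads across all categories); when omitted, the
    matrix's own column sums are used.  A zero-total sample is an error.
    """
    if matrix.unit != "raw":
        raise ValueError("matrix is already normalised")
    denom = matrix.values.sum(axis=0) if totals is None else totals[matrix.values.columns]
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    values = matrix.values * 1e6 / denom
    return CountMatrix(values, matrix.meta, "CPM", truth=matrix.truth)


def top_n_share(matrix: CountMatrix, n: int = 100) -> float:
    """Share of total abundance captured by the ``n`` features with the
    highest mean CPM.  If fewer than ``n`` features exist, all are used
    (share 1.0) with a warning."""
    if matrix.unit != "CPM":
        raise ValueError("top_n_share expects a CPM matrix")
    means = matrix.values.mean(axis=1)
    if n > len(means):
        import warnings

        warnings.warn(f"n={n} exceeds feature count {len(means)}; using all features")
        n = len(means)
    top = means.sort_values(ascending=False).iloc[:n]
    total = means.sum()
    return float(top.sum() / total) if total > 0 else 0.0
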