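"""tRNA-derived fragment (tRF) discovery screen and positional classing.

The screen looks for a single dominant fragment per tRNA gene locus:
across all distinct sequences mapped to a locus (the locus profile), a
candidate is accepted when it is 18-30 nt, averages at least 500 CPM,
and is at least 100-fold more abundant than the second-highest distinct
sequence at that locus.  The dominance requirement separates stable,
reproducibly processed fragments from random degradation, which spreads
reads thinly over many distinct subsequences.  Accepted fragments are
classed by where they sit in the locus: 5' end, 3' end, middle of the
mature body, or the 3' downstream trailer released by tRNA 3'-end
processing.

The default length window is 18-30 nt rather than 20-30: the published
catalogue itself contains a 19-nt trailer fragment, and tRNA-derived
insert lengths concentrate near 18 nt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .annotate import RETAINED, Assignment
from .core import CountMatrix, ReferenceRecord
from .syndata import Table4Fixture

POSITION_CLASSES = ("5p", "3p", "M", "trailer3")

_CODE_TO_CLASS = {"5": "5p", "3": "3p", "M": "M", "3down": "trailer3"}


@dataclass
class ProfileEntry:
    sequence: str
    offset: int
    mean_cpm: float
    cpm: pd.Series  # per-sample


@dataclass
class LocusProfile:
    """Every distinct retained sequence mapped to one tRNA locus."""

    locus_id: str
    entries: dict[str, ProfileEntry] = field(default_factory=dict)

    @property
    def total_mean_cpm(self) -> float:
        return sum(e.mean_cpm for e in self.entries.values())


@dataclass
class Candidate:
    sequence: str
    locus_id: str
    offset: int
    mean_cpm: float
    dominance: float
    position_class: str | None = None


@dataclass
class TRFRecord:
    """A conserved tRF merged across its source loci."""

    sequence: str
    locus_ids: tuple[str, ...]
    position_class: str | None
    mean_cpm: float
    dominance: float  # most conservative (minimum) across loci
    trna_types: tuple[str, ...]
    amino_acids: tuple[str, ...]
    classes_seen: frozenset = frozenset()
    flagged: bool = False


def build_profiles(
    assignments: dict[str, Assignment],
    sequence_cpm: CountMatrix,
    reference: list[ReferenceRecord],
) -> dict[str, LocusProfile]:
    """One profile per tRNA locus listing each mapped distinct sequence.

    A sequence retained across several identical tRNA copies appears in
    every copy's profile with the same CPM.  Loci with no mapped
    sequences get empty profiles.
    """
    if sequence_cpm.unit != "CPM":
        raise ValueError("build_profiles expects sequence-level CPM")
    profiles = {
        r.id: LocusProfile(r.id) for r in reference if r.category == "tRNA_locus"
    }
    for seq, a in assignments.items():
        if a.status != RETAINED or a.category != "tRNA_locus":
            continue
        if seq not in sequence_cpm.values.index:
            continue
        cpm = sequence_cpm.values.loc[seq]
        for hit in a.hits:
            prof = profiles[hit.ref_id]
            # tandem repeats inside one locus: keep the leftmost offset
            if seq not in prof.entries:
                prof.entries[seq] = ProfileEntry(
                    seq, hit.offset, float(cpm.mean()), cpm
                )
    return profiles


def screen(
    profiles: dict[str, LocusProfile],
    min_len: int = 18,
    max_len: int = 30,
    min_cpm: float = 500.0,
    min_dominance: float = 100.0,
) -> list[Candidate]:
    """Accept locus candidates by length, abundance, and dominance.

    Dominance is the candidate's mean CPM over the second-highest
    distinct sequence at the locus (infinite when the candidate is
    alone; ties at the top give dominance 1 and fail).  The accepted set
    shrinks monotonically as thresholds rise.
    """
    if min_cpm <= 0 or min_dominance <= 0:
        raise ValueError("thresholds must be positive")
    accepted = []
    for locus_id in sorted(profiles):
        prof = profiles[locus_id]
        for seq, entry in prof.entries.items():
            if not min_len <= len(seq) <= max_len:
                continue
            if entry.mean_cpm < min_cpm:
                continue
            others = [e.mean_cpm for s, e in prof.entries.items() if s != seq]
            second = max(others) if others else 0.0
            dominance = math.inf if second == 0 else entry.mean_cpm / second
            if dominance >= min_dominance:
                accepted.append(
                    Candidate(seq, locus_id, entry.offset, entry.mean_cpm, dominance)
                )
    return accepted


def classify_position(
    candidate: Candidate, record: ReferenceRecord, tol: int = 3
) -> str:
    """Positional class of an accepted candidate within its locus.

    ``trailer3`` when the match starts at or after the body end; else
    ``5p`` when it starts within ``tol`` of the body start; else ``3p``
    when it ends within ``tol`` of the body end; else ``M``.  Precedence
    is trailer3 > 5p > 3p > M.
    """
    if record.category != "tRNA_locus":
        raise ValueError(f"{record.id!r} is not a tRNA locus")
    start = candidate.offset
    end = candidate.offset + len(candidate.sequence)
    if start < 0 or end > len(record.sequence):
        raise ValueError(
            f"match {start}-{end} outside locus {record.id!r} bounds"
        )
    if start >= record.body_end:
        return "trailer3"
    if start <= record.body_start + tol:
        return "5p"
    if end >= record.body_end - tol:
        return "3p"
    return "M"


def _parse_locus_id(locus_id: str) -> tuple[str, str]:
    """('GlnTTG', 'Gln') from ids like 'tRNA64-GlnTTG(ch6)'."""
    core = locus_id.split("(")[0]
    trna_type = core.split("-", 1)[1] if "-" in core else core
    return trna_type, trna_type[:3]


def merge(candidates: list[Candidate]) -> list[TRFRecord]:
    """Merge identical accepted sequences across loci into tRF records.

    Locus ids accumulate as a sorted union; the dominance kept is the
    minimum across member loci.  A sequence classified differently at
    different loci is flagged rather than silently merged (its class is
    left None and all observed classes are recorded).
    """
    groups: dict[str, list[Candidate]] = {}
    for c in candidates:
        if c.position_class is None:
            raise ValueError("candidates must be classified before merging")
        groups.setdefault(c.sequence, []).append(c)
    records = []
    for seq in sorted(groups):
        grp = groups[seq]
        classes = frozenset(c.position_class for c in grp)
        loci = tuple(sorted({c.locus_id for c in grp}))
        types = sorted({_parse_locus_id(l)[0] for l in loci})
        aas = sorted({_parse_locus_id(l)[1] for l in loci})
        records.append(
            TRFRecord(
                sequence=seq,
                locus_ids=loci,
                position_class=next(iter(classes)) if len(classes) == 1 else None,
                mean_cpm=max(c.mean_cpm for c in grp),
                dominance=min(c.dominance for c in grp),
                trna_types=tuple(types),
                amino_acids=tuple(aas),
                classes_seen=classes,
                flagged=len(classes) > 1,
            )
        )
    return records


def summarize(trfs: list[TRFRecord]) -> dict:
    """Counts of records, source loci, tRNA types, amino acids, and the
    per-class histogram."""
    loci = {l for t in trfs for l in t.locus_ids}
    types = {ty for t in trfs for ty in t.trna_types}
    aas = {aa for t in trfs for aa in t.amino_acids}
    hist = {cls: 0 for cls in POSITION_CLASSES}
    flagged = 0
    for t in trfs:
        if t.position_class is None:
            flagged += 1
        else:
            hist[t.position_class] += 1
    return {
        "n_trfs": len(trfs),
        "n_loci": len(loci),
        "n_types": len(types),
        "n_amino_acids": len(aas),
        "positions": hist,
        "n_flagged": flagged,
    }


def records_from_fixture(fixture: Table4Fixture) -> list[TRFRecord]:
    """Interpret the published catalogue directly as tRF records (for
    bookkeeping summaries without a simulation run)."""
    return [
        TRFRecord(
            sequence=row.trf_sequence,
            locus_ids=tuple(sorted(row.locus_ids)),
            position_class=_CODE_TO_CLASS[row.position_code],
            mean_cpm=float("nan"),
            dominance=float("nan"),
            trna_types=(row.trna_type,),
            amino_acids=(row.amino_acid,),
        )
        for row in fixture.rows
    ]


def write_trf_tsv(trfs: list[TRFRecord], path: str) -> None:
    rows = [
        {
            "sequence": t.sequence,
            "position_class": t.position_class or "conflict:" + ",".join(sorted(t.classes_seen)),
            "loci": ",".join(t.locus_ids),
            "mean_cpm": t.mean_cpm,
            "dominance": t.dominance,
            "trna_types": ",".join(t.trna_types),
        }
        for t in trfs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_trf_bed(
    candidates: list[Candidate], reference_by_id: dict[str, ReferenceRecord], path: str
) -> None:
    """BED6 (0-based half-open, reference-record coordinates)."""
    with open(path, "w") as fh:
        for c in sorted(candidates, key=lambda c: (c.locus_id, c.offset)):
            fh.write(
                f"{c.locus_id}\t{c.offset}\t{c.offset + len(c.sequence)}\t"
                f"{c.sequence}\t{min(int(c.mean_cpm), 1000)}\t+\n"
            )
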