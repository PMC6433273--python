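"""Synthetic inputs for the monocyte small-RNA pipeline.

Real raw sequencing data for this study design is not redistributable,
so every input the pipeline consumes can be generated here instead:

* a synthetic small-RNA reference in which the 18 conserved
  tRNA-derived fragments (tRFs) catalogued in monocytes are embedded in
  50 synthetic tRNA gene loci (with 30-nt genomic flanks) at their
  reported positions, alongside decoy miRNA-hairpin / snoRNA / rRNA /
  Y-RNA records;
* adapter-ligated FASTQ reads whose insert abundances follow caller-
  specified counts-per-million (CPM) targets plus a low-level random
  tRNA degradation background;
* donor-paired negative-binomial count matrices with known spiked
  treatment effects, mimicking the study layout of seven donors each
  contributing one LPS-stimulated and one medium-only sample.

The packaged tables in ``smallrna/data`` record, as printed, the
published tRF catalogue, the 6-h and 24-h differential-expression
tables, and the multi-assay miRNA evidence grid; loaders live here.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import TRUSEQ_SMALL_RNA_ADAPTER, CountMatrix, ReferenceRecord, is_dna

POSITION_CODES = ("5", "M", "3", "3down")

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("smallrna.data").joinpath(name)


@dataclass(frozen=True)
class TRFRow:
    trna_type: str
    position_code: str
    trf_sequence: str
    trf_name: str
    locus_ids: tuple[str, ...]

    @property
    def amino_acid(self) -> str:
        return self.trna_type[:3]


@dataclass(frozen=True)
class Table4Fixture:
    """The published catalogue of 18 conserved monocyte tRFs."""

    rows: tuple[TRFRow, ...]

    @property
    def locus_ids(self) -> set[str]:
        return {lid for row in self.rows for lid in row.locus_ids}

    @property
    def trna_types(self) -> set[str]:
        return {row.trna_type for row in self.rows}

    @property
    def amino_acids(self) -> set[str]:
        return {row.amino_acid for row in self.rows}

    @property
    def numbered_trf_names(self) -> set[str]:
        """tRFs carrying previously assigned numeric identifiers."""
        return {r.trf_name for r in self.rows if r.trf_name[4:].isdigit()}


def load_table4_fixture() -> Table4Fixture:
    """Load the packaged tRF catalogue (18 rows, transcribed as printed)."""
    df = pd.read_csv(_data_path("monocyte_trf_catalog.tsv"), sep="\t", dtype=str)
    rows = []
    for rec in df.itertuples(index=False):
        seq = rec.sequence.upper()
        if not is_dna(seq) or not 19 <= len(seq) <= 21:
            raise ValueError(f"corrupted tRF catalogue row {rec.trf_name!r}")
        if rec.position not in POSITION_CODES:
            raise ValueError(f"unknown position code {rec.position!r}")
        loci = tuple(rec.loci.split(","))
        if not loci:
            raise ValueError(f"no loci for {rec.trf_name!r}")
        rows.append(TRFRow(rec.trna_type, rec.position, seq, rec.trf_name, loci))
    if len(rows) != 18:
        raise ValueError(f"expected 18 catalogue rows, found {len(rows)}")
    return Table4Fixture(tuple(rows))


@dataclass(frozen=True)
class SpikeSpec:
    """A feature with a known treatment effect for paired-count simulation.

    ``dispersion`` overrides the simulation-wide negative-binomial
    dispersion when not None; the convention throughout is
    ``var = mu + dispersion * mu**2``.
    """

    feature_id: str
    baseline_mean: float
    log2fc: float
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError(f"baseline_mean must be positive for {self.feature_id!r}")


def load_de_table(timepoint: int) -> pd.DataFrame:
    """Published differential-expression table at 6 or 24 hours."""
    if timepoint not in (6, 24):
        raise ValueError("timepoint must be 6 or 24")
    return pd.read_csv(_data_path(f"de_mirna_{timepoint}h.tsv"), sep="\t")


def load_spikes(timepoint: int) -> list[SpikeSpec]:
    """Published medium-condition means and log2 fold changes as spike-ins."""
    df = load_de_table(timepoint)
    return [
        SpikeSpec(r.gene, float(r.mean_medium), float(r.log2fc))
        for r in df.itertuples(index=False)
    ]


def load_evidence_table() -> pd.DataFrame:
    """Multi-assay miRNA evidence grid (tri-state entries, as printed)."""
    df = pd.read_csv(_data_path("mirna_evidence.tsv"), sep="\t", dtype=str)
    allowed = {"yes", "no", "not_tested", "not_detected"}
    states = df.drop(columns=["locus", "mature"])
    bad = set(states.to_numpy().ravel()) - allowed
    if bad:
        raise ValueError(f"unknown evidence states: {sorted(bad)}")
    return df.set_index("locus")


def load_target_links() -> pd.DataFrame:
    """Synthetic miRNA-to-target link table (stand-in for a curated
    target database export; users supply their own TSV for real data)."""
    return pd.read_csv(_data_path("synthetic_target_links.tsv"), sep="\t")


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


_DECOY_PLAN = (
    # category, share of decoys, (min_len, max_len)
    ("miRNA_hairpin", 0.67, (70, 90)),
    ("snoRNA", 0.13, (100, 150)),
    ("rRNA", 0.10, (120, 200)),
    ("yRNA", 0.10, (80, 112)),
)


def build_reference(
    fixture: Table4Fixture,
    flank: int = 30,
    n_decoys: int = 60,
    seed: int = 0,
    body_len_range: tuple[int, int] = (70, 90),
    interior_margin: int = 4,
) -> list[ReferenceRecord]:
    """Build the synthetic small-RNA reference around a tRF catalogue.

    One tRNA locus record is created per catalogue locus id: a random
    mature body of 70-90 nt flanked by ``flank`` random nt on each side,
    with the row's tRF sequence embedded at the coordinate its position
    code implies (``5``: body start; ``3``: ending at the body 3' end;
    ``M``: interior, at least ``interior_margin`` nt from either body
    terminus; ``3down``: immediately after the body, inside the
    downstream flank).  Loci sharing a catalogue row embed the identical
    tRF subsequence; everything else is random.  Decoy records for the
    other small-RNA categories contain no catalogue sequence, which is
    enforced by rejection sampling.  The result is a pure function of
    the arguments.
    """
    trf_seqs = [row.trf_sequence for row in fixture.rows]
    max_trf = max(len(s) for s in trf_seqs)
    if flank < max_trf:
        raise ValueError(f"flank {flank} shorter than the longest tRF ({max_trf})")
    lo, hi = body_len_range
    if lo < max_trf + 2 * (interior_margin + 1):
        raise ValueError("body length range too short for interior placement")

    rng = np.random.default_rng(seed)
    records: list[ReferenceRecord] = []
    seen: set[str] = set()

    def occurrences(hay: str) -> int:
        total = 0
        for s in trf_seqs:
            start = 0
            while (idx := hay.find(s, start)) != -1:
                total += 1
                start = idx + 1
        return total

    for row in fixture.rows:
        trf = row.trf_sequence
        for locus_id in row.locus_ids:
            if locus_id in seen:
                raise ValueError(f"duplicate locus id {locus_id!r}")
            seen.add(locus_id)
            for _ in range(100):
                body_len = int(rng.integers(lo, hi + 1))
                left = _random_dna(rng, flank)
                right = _random_dna(rng, flank)
                body = list(_random_dna(rng, body_len))
                if row.position_code == "5":
                    body[: len(trf)] = trf
                elif row.position_code == "3":
                    body[body_len - len(trf):] = trf
                elif row.position_code == "M":
                    start = int(
                        rng.integers(
                            interior_margin + 1,
                            body_len - len(trf) - interior_margin,
                        )
                    )
                    body[start: start + len(trf)] = trf
                else:  # 3down: starts right after the body
                    right = trf + right[len(trf):]
                seq = left + "".join(body) + right
                if occurrences(seq) == 1:
                    records.append(
                        ReferenceRecord(
                            locus_id, "tRNA_locus", seq,
                            body_start=flank, body_end=flank + body_len,
                        )
                    )
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError(f"could not place tRF cleanly in {locus_id!r}")

    serial = 0
    for category, share, (dlo, dhi) in _DECOY_PLAN:
        n_cat = max(1, round(n_decoys * share)) if n_decoys else 0
        for _ in range(n_cat):
            serial += 1
            for _ in range(100):
                seq = _random_dna(rng, int(rng.integers(dlo, dhi + 1)))
                if occurrences(seq) == 0:
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not draw a clean decoy")
            records.append(ReferenceRecord(f"decoy-{category}-{serial:03d}", category, seq))
    return records


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimSpec:
    """Configuration for one simulated small-RNA library.

    ``foreground`` maps insert sequences (which must occur in the
    reference) to target CPM.  ``background_fraction`` of the reads are
    random 14-30 nt subfragments of the tRNA locus records, emulating
    degradation; foreground CPM plus background must account for the
    whole library.  Sequencing error, PCR duplication and ligation bias
    are not modelled.
    """

    foreground: dict[str, float]
    total_reads: int
    background_fraction: float = 0.0
    adaptor: str = TRUSEQ_SMALL_RNA_ADAPTER
    quality_char: str = "I"
    seed: int = 0
    background_len_range: tuple[int, int] = (14, 30)

    def __post_init__(self) -> None:
        if len(self.adaptor) < 10:
            raise ValueError("adaptor must be at least 10 nt")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        for seq, cpm in self.foreground.items():
            if cpm <= 0:
                raise ValueError(f"non-positive CPM for {seq!r}")
        if sum(self.foreground.values()) > 1e6 + 1e-6:
            raise ValueError("foreground CPM targets exceed 1e6")


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment by largest remainder."""
    raw = weights / 1e6 * total
    base = np.floor(raw).astype(int)
    short = int(round(raw.sum())) - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base


def simulate_reads(
    reference: list[ReferenceRecord],
    spec: ReadSimSpec,
    path: str,
) -> dict[str, int]:
    """Write a FASTQ library of adapter-ligated inserts.

    Every record is insert + 3' adapter with a constant quality string.
    Foreground inserts appear at their target CPM (deterministic
    largest-remainder apportionment, so counts match CPM up to
    rounding); the remaining reads are degradation background.  Output
    is byte-identical for identical arguments.  Returns the realised
    per-insert foreground counts.
    """
    rng = np.random.default_rng(spec.seed)
    ref_seq = "\n".join(r.sequence for r in reference)  # concatenated for lookup
    for seq in spec.foreground:
        if seq not in ref_seq:
            raise ValueError(f"foreground insert {seq!r} not found in reference")

    fg_seqs = sorted(spec.foreground)
    fg_counts = _apportion(
        np.array([spec.foreground[s] for s in fg_seqs]), spec.total_reads
    )
    n_bg = spec.total_reads - int(fg_counts.sum())
    if n_bg < 0:
        raise ValueError("foreground CPM targets exceed the library size")
    if abs(n_bg / spec.total_reads - spec.background_fraction) > 0.01:
        raise ValueError(
            "infeasible CPM allocation: foreground CPM and background_fraction "
            f"must account for the whole library (residual background "
            f"{n_bg / spec.total_reads:.4f} vs requested {spec.background_fraction:.4f})"
        )

    loci = [r.sequence for r in reference if r.category == "tRNA_locus"]
    if n_bg and not loci:
        raise ValueError("background requested but the reference has no tRNA loci")

    blo, bhi = spec.background_len_range
    out_lines: list[str] = []
    serial = 0

    def emit(insert: str) -> None:
        nonlocal serial
        serial += 1
        read = insert + spec.adaptor
        out_lines.append(f"@r{serial}\n{read}\n+\n{spec.quality_char * len(read)}")

    for seq, n in zip(fg_seqs, fg_counts):
        for _ in range(int(n)):
            emit(seq)
    if n_bg:
        locus_idx = rng.integers(0, len(loci), n_bg)
        lengths = rng.integers(blo, bhi + 1, n_bg)
        starts = rng.random(n_bg)
        for i in range(n_bg):
            locus = loci[locus_idx[i]]
            length = min(int(lengths[i]), len(locus))
            start = int(starts[i] * (len(locus) - length + 1))
            emit(locus[start: start + length])

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("\n".join(out_lines))
        fh.write("\n")
    return dict(zip(fg_seqs, (int(c) for c in fg_counts)))


# ---------------------------------------------------------------------------
# donor-paired count simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws under var = mu + dispersion * mu^2 (Poisson when 0)."""
    mean = np.asarray(mean, float)
    if (mean < 0).any():
        raise ValueError("negative mean passed to the count sampler")
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def simulate_paired_counts(
    spikes: list[SpikeSpec],
    n_null: int,
    n_donors: int = 7,
    dispersion: float = 0.05,
    seed: int = 0,
    timepoint: int = 6,
    donor_sd_log: float = 0.5,
    null_mean_log: float = math.log(100.0),
    null_sd_log: float = 2.0,
) -> CountMatrix:
    """Simulate a donor-paired count matrix with known effects.

    Each donor contributes one LPS and one medium sample sharing a
    log-normal multiplicative donor effect; spiked features follow their
    ``SpikeSpec`` baseline and fold change, null features have log2fc 0
    with log-normal baselines spanning several orders of magnitude (the
    observed dynamic range of monocyte miRNA expression).  The true
    per-feature log2 fold changes are attached as ``CountMatrix.truth``.
    """
    if n_donors < 2:
        raise ValueError("need at least 2 donors")
    rng = np.random.default_rng(seed)

    null_ids = [f"null-{i + 1:04d}" for i in range(n_null)]
    features = [s.feature_id for s in spikes] + null_ids
    if len(set(features)) != len(features):
        raise ValueError("duplicate feature ids")
    base = np.concatenate([
        np.array([s.baseline_mean for s in spikes]),
        rng.lognormal(null_mean_log, null_sd_log, n_null),
    ])
    lfc = np.concatenate([
        np.array([s.log2fc for s in spikes]), np.zeros(n_null)
    ])
    disp = np.full(len(features), float(dispersion))
    for i, s in enumerate(spikes):
        if s.dispersion is not None:
            disp[i] = s.dispersion

    donor_effect = rng.lognormal(0.0, donor_sd_log, n_donors)
    cols, meta_rows = {}, []
    for d in range(n_donors):
        donor = f"donor{d + 1}"
        for trt, mult in (("medium", 1.0), ("LPS", 2.0 ** lfc)):
            sample = f"{donor}_{trt}_{timepoint}h"
            mean = base * mult * donor_effect[d]
            counts = np.empty(len(features), dtype=np.int64)
            for phi in np.unique(disp):
                mask = disp == phi
                counts[mask] = _nb_draw(rng, mean[mask], float(phi))
            cols[sample] = counts
            meta_rows.append((sample, donor, trt, timepoint))

    values = pd.DataFrame(cols, index=features)
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "donor", "treatment", "timepoint"]
    ).set_index("sample")
    return CountMatrix(values, meta, "raw", truth=pd.Series(lfc, index=features))
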