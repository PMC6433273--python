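"""Multi-assay evidence integration and miRNA-target expression joins.

Three assays can vouch for a miRNA's upregulation at a timepoint:
sequencing-based differential expression (NGS), Taqman qPCR relative to
U6 (delta-delta-Ct), and a tagged RT-PCR that visualises the mature
band.  Evidence entries are tri-state - ``yes``, ``no``, or
``not_tested``/``not_detected`` - and an untested assay never counts
for or against.  A miRNA is *upregulated* at a timepoint when at least
two methods say yes, and a *signature* miRNA when that holds at both
6 h and 24 h.  Evidence is aggregated per mature miRNA: distinct
genomic loci producing the same mature sequence (mir-9-1 and mir-9-2
both yield mir-9) pool their locus-level NGS calls, and mature-level
assays (qPCR, RT-PCR) speak for the whole group.

The RT-PCR precursor band is informative about transcriptional
activation but is not counted as an independent upregulation method by
default (``count_precursor=True`` switches that on).
"""

from __future__ import annotations

import warnings

import pandas as pd

YES = "yes"

_METHODS_6H = ("ngs_6h", "qpcr_6h", "rtpcr_mature_6h")
_METHODS_24H = ("ngs_24h", "qpcr_24h")


def ddct_relative_expression(
    ct_target: float,
    ct_reference: float,
    ct_target_cal: float,
    ct_reference_cal: float,
) -> float:
    """Relative quantity by the delta-delta-Ct method.

    ``2 ** -((ct_target - ct_reference) - (ct_target_cal - ct_reference_cal))``
    against a reference RNA (e.g. U6) and a calibrator sample.
    """
    ddct = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)
    return float(2.0 ** (-ddct))


def _collapse_groups(evidence: pd.DataFrame) -> pd.DataFrame:
    """Pool locus-level rows into mature-miRNA groups.

    A method column becomes ``yes`` for the group if any member row
    says yes; ``not_tested``/``not_detected`` entries contribute
    nothing either way and survive only if no member was tested.
    """
    def pool(col: pd.Series) -> str:
        vals = set(col)
        if YES in vals:
            return YES
        if "no" in vals:
            return "no"
        return sorted(vals)[0]

    cols = [c for c in evidence.columns if c != "mature"]
    return evidence.groupby("mature")[cols].agg(pool)


def upregulated_at(row: pd.Series, timepoint: int, count_precursor: bool = False) -> bool:
    """True iff >= 2 methods report yes at the timepoint.

    At 6 h the candidate methods are NGS significance, qPCR
    upregulation, and the RT-PCR mature band (plus the precursor band
    if ``count_precursor``); at 24 h, NGS and qPCR.
    """
    if timepoint == 6:
        methods = list(_METHODS_6H) + (
            ["rtpcr_precursor_6h"] if count_precursor else []
        )
    elif timepoint == 24:
        methods = list(_METHODS_24H)
    else:
        raise ValueError("timepoint must be 6 or 24")
    return sum(row[m] == YES for m in methods) >= 2


def signature(evidence: pd.DataFrame, count_precursor: bool = False) -> set[str]:
    """Mature miRNAs upregulated by >= 2 methods at both timepoints.

    ``evidence`` is locus-level with a ``mature`` column mapping each
    locus to its mature name; groups are collapsed before the rule is
    applied.  Adding a yes anywhere can only grow the result.
    """
    if evidence.empty:
        return set()
    grouped = _collapse_groups(evidence)
    return {
        mature
        for mature, row in grouped.iterrows()
        if upregulated_at(row, 6, count_precursor)
        and upregulated_at(row, 24, count_precursor)
    }


def join_targets(
    de_results: dict[int, pd.DataFrame],
    links: pd.DataFrame,
    timepoint: int,
    mirnas: set[str] | None = None,
) -> pd.DataFrame:
    """Differentially expressed genes that are validated miRNA targets.

    ``de_results`` maps timepoint -> DE table (indexed by gene symbol
    with ``log2fc``/``direction``); ``links`` has columns ``mirna`` and
    ``gene``.  Rows are genes significant at ``timepoint`` that appear
    in the link table (optionally restricted to ``mirnas``); each row
    lists every regulating miRNA once and carries the gene's log2 fold
    change at every available timepoint.
    """
    links = links.drop_duplicates(subset=["mirna", "gene"])
    if mirnas is not None:
        links = links[links["mirna"].isin(mirnas)]
    if links.empty:
        warnings.warn("empty miRNA-target link table; join is empty")
        return pd.DataFrame(columns=["gene", "mirnas", "direction"]).set_index("gene")
    de = de_results[timepoint]
    sig = de[de["direction"] != "ns"]
    joined = links[links["gene"].isin(sig.index)]
    if joined.empty:
        return pd.DataFrame(columns=["gene", "mirnas", "direction"]).set_index("gene")
    rows = []
    for gene, grp in joined.groupby("gene"):
        row = {
            "gene": gene,
            "mirnas": ";".join(sorted(set(grp["mirna"]))),
            "direction": sig.loc[gene, "direction"],
        }
        for tp, table in sorted(de_results.items()):
            row[f"log2fc_{tp}h"] = (
                float(table.loc[gene, "log2fc"]) if gene in table.index else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene").sort_index()


def classify_trajectory(
    gene: str,
    cpm_by_timepoint: dict[int, pd.Series],
    relative_direction: dict[int, str] | None = None,
    flat_tol: float = 0.10,
) -> dict:
    """Absolute LPS expression trend of a gene from 6 h to 24 h.

    ``cpm_by_timepoint`` maps timepoint -> per-sample LPS CPM for the
    gene.  The trend compares mean LPS CPM at the two timepoints with a
    relative tolerance band: within ``flat_tol`` of the 6-h level is
    ``flat`` (inclusive), otherwise ``increase``/``decrease``.
    """
    for tp in (6, 24):
        if tp not in cpm_by_timepoint or len(cpm_by_timepoint[tp]) == 0:
            raise ValueError(f"gene {gene!r} missing timepoint {tp}")
    m6 = float(pd.Series(cpm_by_timepoint[6]).mean())
    m24 = float(pd.Series(cpm_by_timepoint[24]).mean())
    if m6 == 0:
        trend = "flat" if m24 == 0 else "increase"
    else:
        rel = (m24 - m6) / m6
        trend = "flat" if abs(rel) <= flat_tol else ("increase" if rel > 0 else "decrease")
    out = {"gene": gene, "mean_lps_6h": m6, "mean_lps_24h": m24, "trend": trend}
    if relative_direction:
        out["relative_direction"] = dict(relative_direction)
    return out
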