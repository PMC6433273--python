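# smallrna

Analysis pipeline for the small-RNA transcriptome of LPS-stimulated
human monocytes, built for transcriptomics analysts who want the full
chain — read QC, hierarchical small-RNA annotation, CPM normalisation,
tRNA-derived-fragment (tRF) discovery, donor-paired differential
expression, and multi-assay miRNA evidence integration — as a tested,
reusable library and CLI. Raw sequencing data for this study design is
not redistributable, so a first-class synthetic-data generator
reproduces the statistical structure the analysis assumes, and the
published summary tables ship as packaged fixtures.

## What it computes

* **Read processing**: adapter stripping (TruSeq small-RNA 3′ adapter
  by default), mean-Phred ≥ 30 quality filter, ≥ 13 nt length filter,
  collapsing to unique-sequence counts with an exactly conserving QC
  report.
* **Annotation**: exact sense-strand substring alignment against a
  miRNA-hairpin / tRNA-locus / snoRNA / rRNA / Y-RNA reference;
  sequences hitting a single category (multi-locus hits to identical
  copies count as one reference sequence) are retained and normalised
  to counts per million mapped reads,
  `CPM = count · 10⁶ / mapped_total`.
* **tRF screen**: per tRNA locus, accept fragments of 18–30 nt with
  mean CPM ≥ 500 that are ≥ 100× more abundant than the second-highest
  distinct sequence at that locus (the dominance ratio separates
  processed fragments from random degradation), then class each as
  5′-end, 3′-end, middle, or 3′-downstream trailer.
* **Paired DE**: per-donor log2 ratios of CPM between LPS and medium
  samples, median-centred across features, tested with an
  empirical-Bayes moderated paired t and Benjamini–Hochberg
  correction (`q < 0.05`).
* **Evidence integration**: the ΔΔCt closed form `2^−ΔΔCt`, the
  ≥ 2-methods-at-both-timepoints signature rule over tri-state
  NGS/qPCR/RT-PCR evidence, miRNA→target joins, and absolute
  expression trajectory classing.

## Worked example

Recover the published 24-hour differential-expression table from a
donor-paired spike-in simulation (7 donors, negative-binomial
dispersion 0.05, 800 null features):

```python
from smallrna import workflows

run = workflows.de_recovery_run(timepoint=24, seed=1)
print(run["n_recovered"], "of", run["n_spikes"], "spikes recovered,",
      run["n_false_positives"], "false positives among",
      run["n_tested"], "tested features")
print(run["results"].loc["hsa-mir-7151", "direction"])
```

prints

```
13 of 13 spikes recovered, 0 false positives among 774 tested features
down
```

i.e. every spiked miRNA — including the one down-regulated feature —
is re-called with the correct direction at q < 0.05, with no null
feature called. The same workflow at `timepoint=6` typically recovers
14 of 15: the remaining feature is the table's weakest effect
(log2 fold change 0.76), which sits at the detection boundary for
seven donors at this dispersion (see `docs/methods.md`).

The tRF screen end-to-end (builds the 50-locus synthetic reference,
simulates four libraries of 10⁶ adapter-ligated reads, runs
process → annotate → screen):

```python
r = workflows.trf_discovery_run(seed=1)
print(r.summary)
```

prints

```
{'n_trfs': 18, 'n_loci': 50, 'n_types': 16, 'n_amino_acids': 12, 'positions': {'5p': 7, '3p': 8, 'M': 1, 'trailer3': 2}, 'n_flagged': 0}
```

— exactly the 18 catalogued tRF sequences from their 50 source loci,
with 7 fragments at the 5′ end, 8 at the 3′ end, 1 in the middle and
2 in the 3′ trailer.

On the command line, the packaged evidence grid yields the five
signature miRNAs:

```
$ smallrna signature
mir-146a
mir-147b
mir-155
mir-193a
mir-9
```

Other commands (`smallrna reference`, `simulate-reads`, `process`,
`count`, `trf`, `de`, `targets`) wire the same library stages to
FASTA/FASTQ/TSV files; see `--help` on each.

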