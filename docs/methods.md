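# Methods

This package re-implements, as a tested pipeline over synthetic data, a
small-RNA transcriptome analysis of LPS-stimulated human monocytes:
read QC and collapsing, hierarchical small-RNA annotation, CPM
normalisation, a tRNA-derived-fragment (tRF) discovery screen,
donor-paired differential expression (DE), and multi-assay evidence
integration for signature miRNAs. This note records the models, the
defaults that matter, and the choices made where the design was open.

## Read processing

Reads are insert + 3′ adapter (Illumina TruSeq small-RNA adapter by
default, configurable). The pipeline applies, in order: adapter
stripping, quality filtering, length filtering, collapsing.

* **Adapter stripping** removes everything from the leftmost full
  adapter occurrence, or from a terminal adapter *prefix* of at least
  `min_overlap = 6` nt; reads with neither are rejected ("no adapter").
  Matching is exact by default (`max_mismatch` 0, optionally 1):
  inserts are short and error-filtered, and exactness keeps the
  downstream unique-mapping rule well defined.
* **Quality**: a read passes when its mean base Phred score is ≥ 30,
  inclusive at the boundary. Whether the original filter was mean,
  minimum, or windowed is not knowable from its one-line description;
  mean is the least aggressive common reading and `qual_mode="min"` is
  available. Reads containing `N` fail QC regardless (exact matching
  downstream cannot use them).
* **Length**: inserts ≤ 12 nt are dropped (`min_len = 13`).
* **Collapsing** tallies distinct insert sequences per sample
  (lexicographic order, counts conserved). The QC report accounts for
  every input read exactly once across
  retained/no-adapter/low-quality/too-short.

## Annotation

Alignment is exact, sense-strand, ungapped, full-length substring
search over the reference (a 13-mer seed index verified by full
comparison; equivalent to a naive scan, which the tests assert).
Antisense matching is off: TruSeq small-RNA libraries are stranded.

A collapsed sequence is **retained** when all of its hits fall in one
category and match the identical subsequence — so a fragment shared by
nine identical tRNA gene copies counts as hitting one *reference
sequence* and survives, which is essential for multi-copy tRFs.
Cross-category hits are discarded as multi-mapped; zero hits are
unmapped. With exact full-length matching the "identical subsequence"
clause is automatic, so in practice the rule is single-category
membership; counts are aggregated per canonical feature (the sorted
hit ids joined by `|`), which conserves retained totals exactly.

**CPM** uses each sample's total retained mapped reads as the
denominator (not per-category totals): an abundance threshold phrased
as "counts per million reads" reads most naturally against the mapped
library size. Configurable by passing different totals.

## tRF discovery screen

Per tRNA locus, the profile of distinct mapped sequences is screened;
a candidate is accepted when

* its length is in `[18, 30]` nt,
* its mean CPM across samples is ≥ 500, and
* its mean CPM is ≥ 100 × that of the second-highest distinct sequence
  at the same locus (dominance; infinite when it is alone — passes; a
  tie at the top gives dominance 1 and fails, conservatively).

The dominance ratio separates reproducibly processed fragments from
random degradation, which spreads reads over many distinct
subsequences. The published screen quotes a 20–30 bp window, but the
published catalogue itself contains a 19-nt trailer fragment and
tRNA-derived insert lengths concentrate near 18 nt, so the default
window is 18–30 (configurable). Mean-CPM (rather than
max-in-any-sample) is used for the abundance threshold; both the
abundance statistic and the thresholds are parameters.

Accepted candidates are positioned against the locus body
(0-based half-open `body_start`/`body_end`, flanks ≤ 30 nt):
`trailer3` when the match starts at/after the body end, else `5p`
within `tol = 3` nt of the body start, else `3p` when ending within
`tol` of the body end, else `M` (middle); precedence
trailer3 > 5p > 3p > M. The 3-nt tolerance is a package choice (no
published value); the synthetic generator places fragments so that
every catalogue row classifies as printed under it. Identical
sequences accepted at several loci merge into one record (union of
loci; minimum dominance across loci; conflicting position classes are
flagged, never silently merged).

## Donor-paired differential expression

Each donor contributes one LPS and one medium sample per timepoint.
The pipeline computes per-donor per-feature
`log2((CPM_LPS + 1) / (CPM_medium + 1))` (pseudocount configurable) and
tests the donor-mean against zero. Three defaults matter:

* **Median centering** (`center=True`): the per-donor median log ratio
  across features is subtracted — a median-of-ratios normalisation.
  With mostly-null features this removes the composition bias that
  total-count CPM scaling introduces when a few features change
  strongly (their reads dilute everything else's CPM and every null
  feature drifts off zero).
* **Variance moderation** (`moderate=True`): per-feature ratio
  variances (6 df at 7 donors) are shrunk toward a scaled
  inverse-chi-square prior fitted across features by matching moments
  of log sample variances; the moderated t gains the prior df. With a
  handful of donors a per-feature variance is too noisy to rank
  hundreds of features; sharing information across features is the
  standard remedy and is what NB-GLM engines do via dispersion
  shrinkage. The unmoderated per-feature Student t remains available
  and is the engine validated against an exact sign-flip enumeration;
  under moderation a feature with constant nonzero ratios is genuine
  evidence (finite p), while the unmoderated engine reports the
  degenerate p = 1.
* **Expression filter** (`min_mean_cpm = 5`): features below a mean-CPM
  floor are dropped before testing. Low-count features produce
  discrete, poorly calibrated ratio statistics; filtering them also
  shrinks the multiple-testing burden, as independent filtering does in
  standard DE engines.

Multiple testing is Benjamini–Hochberg (`statsmodels`); calls are
up/down at q < α (default 0.05) split by the sign of the mean log
ratio. The published analysis used a NB GLM with donor as a covariate;
its exact fold changes and p-values are deliberately not reproduced —
validation is by simulation recovery of known spiked effects, plus
null calibration (uniform p under the global null) and empirical FDR
control, all asserted in the test suite.

Power limit worth knowing: with 7 donors and NB dispersion 0.05 the
per-donor log2-ratio noise floor is ≈ sqrt(2·0.05)/ln 2 ≈ 0.46, so a
spiked log2 fold change of ~0.76 (1.7-fold) sits near the detection
boundary after BH correction among ~800 features. In repeated
simulations the 24-h published table (weakest effect 1.23) is
recovered completely, while the 6-h table (weakest effect 0.76)
typically recovers 14 of 15 — the one miss being exactly the most
modest published call.

## Evidence integration

qPCR relative quantities use the delta-delta-Ct closed form
`2^−ΔΔCt` against a reference RNA (U6) and a calibrator sample.
Evidence entries are tri-state: `not_tested`/`not_detected` never count
for or against (they are distinct states in the packaged grid, as
printed). A miRNA is *upregulated* at a timepoint when ≥ 2 methods say
yes — at 6 h the candidates are NGS significance, qPCR, and the RT-PCR
mature band (the precursor band is transcription evidence, not an
independent upregulation method; `count_precursor=True` switches it
on), at 24 h NGS and qPCR. Loci producing the same mature miRNA pool
their NGS calls and share mature-level assay results (mir-9-1/mir-9-2
→ mir-9). The *signature* is the set of mature miRNAs upregulated at
both timepoints; on the packaged grid the default settings reproduce
the published five-miRNA signature.

Target integration inner-joins DE genes with a miRNA→target link
table (a packaged *synthetic* stand-in covers tests; real analyses
supply their own TSV, e.g. a curated database export). Absolute
trajectories compare mean LPS CPM at 6 h vs 24 h with a ±10% relative
"flat" band (inclusive; invented here — the original report is
qualitative — and configurable).

## Synthetic data: what it does and does not emulate

`build_reference` embeds each catalogued tRF into synthetic random
tRNA bodies (70–90 nt, 30-nt flanks) at the position its class
implies; loci sharing a catalogue row share only the embedded tRF.
Decoy records for the other categories are rejection-sampled to
contain no catalogue sequence. Bodies are *not* real tRNA genes: the
screen depends only on positional structure and sequence identity, so
realism is limited to lengths and placements — cloverleaf structure,
real flanking genomic context, and sequence composition are not
modelled.

`simulate_reads` emits insert + full adapter with constant Q40
qualities; foreground inserts hit their CPM targets exactly
(largest-remainder apportionment), background reads are uniform random
14–30-nt locus subfragments. Sequencing error, PCR duplication, and
ligation bias are not simulated, so read-level QC behaviour on real
data (quality failures, partial adapters) is exercised only by
dedicated unit fixtures, not by the generator.

`simulate_paired_counts` draws NB counts (`var = μ + φμ²`; φ ≤ 0 means
Poisson) with a shared log-normal per-donor effect (sdlog 0.5,
motivated by the reported donor-to-donor spread exceeding the
treatment effect) and log-normal null baselines (meanlog ln 100,
sdlog 2.0, spanning ~5 orders of magnitude like the observed miRNA
dynamic range). It does not model donor-by-treatment interactions,
library-size variation beyond the donor effect, or correlated
features; passing recovery tests therefore demonstrates correctness of
the paired engine under its assumed noise model, not robustness to
every real-data pathology.

Problem sizes used by the packaged study-scale runs: four libraries of
10⁶ reads for the tRF screen (tRF CPMs geometrically spaced 600–5000,
3% degradation background, synthetic mature-miRNA inserts filling
~93% of each library), and 800 null features with 7 donors at
dispersion 0.05 for DE recovery.

## Numerical notes

* Screen thresholds are compared with `>=`; dominance of a lone
  sequence is `inf`; ties fail.
* BH q-values come from `statsmodels` and are asserted against a
  hand-rolled step-up in tests.
* The moderated-variance prior uses Brent root-finding on the trigamma
  moment equation; when observed variances are (near-)homogeneous the
  prior df is infinite and the test degenerates to a z-test on the
  pooled variance.
* All generators are `numpy.random.default_rng` seeded explicitly;
  reference building and read simulation are pure functions of their
  arguments (byte-identical FASTQ under a fixed seed).

## Known limitations

* Exact matching cannot absorb sequencing errors or isomiR variation;
  the mismatch option extends only to a single mismatch in adapter
  detection, not in alignment.
* One reference record = one feature; hairpins yielding multiple
  mature products are not sub-resolved.
* The DE engine tests a location shift on log ratios; it does not
  estimate per-feature dispersions and will not reproduce NB-GLM fold
  changes or p-values on real data.
* tRF differential expression is possible by running the DE module on
  tRF counts but makes no claims here (the motivating study found
  none significant).
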