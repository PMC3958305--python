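# Methods

## Problem setting

U12-type introns (< 0.5% of human introns, present in roughly 700 genes) are
excised by the minor spliceosome and are normally spliced more slowly than
the U2-type introns that surround them in the same genes. When the minor
spliceosome is impaired, three RNA-seq signatures appear at U12 introns in
affected individuals: fewer split reads across the U12 junction, elevated
read coverage over the intron body (retention), and novel junctions from
cryptic U2-type splice sites or exon skipping. `minorsplice` turns these
signatures into a per-gene case/control outlier statistic.

The design is deliberately a *within-gene contrast*: every U12 measurement
is normalised either by two U2-type reference introns of the same gene or by
the gene's expression (FPKM). This cancels per-gene expression differences
and most library-size and length effects, so the cohort comparison operates
on approximately scale-free ratios.

## Quantification

* **Junction counts** `J`. A read supports a junction when one of its N
  operations skips exactly the intron's genomic span and at least
  `min_anchor` aligned bases flank the skip on both sides. Default
  `min_anchor = 6` bp — small enough to keep most spanning reads, large
  enough to suppress spurious 1–2 bp anchors; configurable. Reads skipping a
  *superset* span (e.g. exon-skipping reads) never count toward the
  canonical junction; they are distinct events handled by the events module.
* **Intron depth** `D`. Mean per-base M-op coverage over the intron body
  with `edge_trim = 10` bp removed at each end, so that alignment bleed next
  to the splice sites does not masquerade as retention. Introns shorter than
  `2 × edge_trim` are unquantifiable (reason-coded, not an error).
* **FPKM**. Computed internally by leftmost-position counting over the
  canonical exon union: reads / (exonic kb) / (mapped reads ⁄ 10⁶). It is
  used only as a per-gene normaliser, so a transcript-assembly estimate is
  unnecessary. A sample with zero mapped reads is rejected.
* **Reference selection**. The two U2-type introns immediately flanking the
  U12 intron on the canonical transcript are the references; a terminal U12
  intron takes the two nearest U2 introns on the available side. Introns
  with unknown type are never eligible. Genes that cannot provide two U2
  references are excluded with reason `insufficient_U2_references`. The
  canonical transcript is the one with the longest exonic length (ties by
  smallest transcript id) — the isoform choice is otherwise arbitrary and
  this rule is deterministic.
* Counting is unstranded, exact (integer/rational), independent of record
  order, and bit-identical across reruns.

## Metrics and cohort statistics

Per gene and sample (pseudocount `pc = 0.5` on denominators only; a zero
numerator is meaningful — complete splicing failure — and is preserved):

| metric | definition | deficiency direction |
|---|---|---|
| `r_u12_u2` | `J_U12 / (mean(J_U2a, J_U2b) + pc)` | decreased |
| `r_u12_fpkm` | `J_U12 / (FPKM + pc)` | decreased |
| `ir_u2` | `D_U12 / (mean(D_U2a, D_U2b) + pc)` | increased |
| `ir_fpkm` | `D_U12 / (FPKM + pc)` | increased |

Genes with several U12 introns are averaged arithmetically across introns.
The mean (not min or sum) of the two references keeps the normaliser
symmetric in the two introns. Junction-based and depth-based
FPKM-normalisations are kept as two separate metrics because "efficiency"
and "retention" are distinct readings of the signal; the ranking rule counts
metrics, so this choice is visible and configurable downstream.

**Detection filter.** A gene enters the comparison only if, in *every*
sample, FPKM ≥ 1 and `J_U2a + J_U2b ≥ 10`. Below these levels the ratios are
dominated by counting noise.

**Variability filter.** Genes with control CV (sample SD / mean over
controls, mean floored at `sd_floor = 1e-6`) above `cv_max = 0.5` on any
metric are discarded: an outlier call against an unstable baseline is
meaningless. 0.5 operationalises "high variability" — at CV 0.5 a 2 SD
excursion equals the control mean itself.

**z-scores and flagging.** `z = (case statistic − control mean) /
max(control SD, sd_floor)`. A metric is flagged beyond `z_threshold = 2` in
its deficiency direction; a gene is flagged when ≥ `min_metrics = 2` of the
4 metrics are flagged. Ranking is by the largest |z| among flagged metrics,
ties broken by gene id. A two-sided mode exists for exploratory use. No
multiple-testing correction is applied: this is an SD-threshold rank, not a
p-value procedure, and should be read as a prioritisation, not a test.

### Case aggregation: why the default is "all"

With `case_aggregation="mean"` the case statistic is the mean over case
samples. For the cohort sizes this design targets (2 cases vs 4 controls) we
analysed the null behaviour of that statistic before implementation: with
the control SD estimated from 4 samples, the group-mean z is distributed
approximately as √0.75·t₃ under exchangeability, so a single metric exceeds
2 SD one-sidedly with probability ≈ 5% (not the ≈ 2.3% Gaussian intuition
suggests), and because the two efficiency metrics (and the two retention
metrics) share their numerator noise, the "≥ 2 metrics" rule inherits almost
the full per-metric rate — roughly one gene in twenty falsely flagged.

The default is therefore `case_aggregation="all"`: a metric counts only if
*every* case sample exceeds the threshold, and the least-extreme case z is
reported. For a familial phenotype where all cases carry the same lesion,
requiring consistency across patients is the natural reading of "different
in cases", and it restores the false-flag rate to the low single percents
while costing essentially no sensitivity at the effect sizes of interest
(retention rising from 2% to 30% moves the retention metrics by tens of
SDs). The group-mean variant remains available in the config.

## Aberrant-event detection

All N spans inside a gene's extent that match no annotated intron of any
transcript and carry ≥ `min_support = 3` anchored reads are novel junctions.
Classification is strand-aware (donor = 5' splice site in transcript
orientation):

* shares the U12 donor with the acceptor within `window = 100` bp of the
  U12 acceptor → `cryptic_3p`; the mirror case → `cryptic_5p`. The window
  bounds the search to "nearby" cryptic sites; recurrent aberrant
  transcripts sit within tens of bp of the failed U12 splice sites.
* joins an annotated donor to a downstream annotated acceptor spanning the
  whole U12 intron → `exon_skip`;
* otherwise `other`.

Abundance is reported as **support / (support + canonical)** — the fraction
of spliced transcripts using the aberrant path — per sample and pooled by
condition; pooled denominators include the canonical reads of *all* samples
of the condition, so an event seen only in one sample is not overstated.
These are read-level fractions; they approximate transcript-level fractions
up to small isoform-length differences. An event is `case_exclusive` when
its pooled control fraction is < 1% while the pooled case fraction is > 5%.

## The simulator

The generator emulates the statistical structure the analysis assumes, with
every parameter exposed in `SimulationConfig`:

* **Gene structures**: 4–8 exons of 80–300 bp separated by introns of
  200–2000 bp, placed non-overlapping on synthetic chromosomes; 90% of genes
  carry exactly one U12-type intron at a random position, 10% are all-U2
  negative controls.
* **Expression**: per-gene relative expression is lognormal (σ = 0.5,
  mean-normalised), shared across samples; per-sample molecule counts are
  negative binomial with mean `mean_fragments_per_gene × rel` and dispersion
  size 60 (count CV ≈ 13% between samples, a tight within-family cohort).
  The default `mean_fragments_per_gene = 4000` corresponds to well-expressed
  genes in a deep blood RNA-seq library; it was chosen by a pre-hoc power
  analysis so that the control-side depth metrics have CV ≈ 0.2, i.e. the
  retention baseline is measurable with the default `cv_max` filter. An
  explicit per-gene `expression_profile` can replace the lognormal draw.
* **Isoform classes**: each molecule retains its U12 intron with probability
  `r` (baseline 0.02 everywhere; 0.3 in affected genes of case samples);
  conditional on splicing it uses a cryptic site with probability `c`
  (baseline 0; 0.3 in affected cases; split evenly 5'/3') or skips an exon
  with probability `k` (baseline 0; 0.05 in affected cases), else canonical.
  The hierarchical form makes the expected cryptic/(cryptic + canonical)
  junction-read fraction equal `c` independent of `r`, which is what the
  recovery tests check. Independently, every U2-type intron is retained with
  the baseline probability in all samples and conditions.
* **Gene-fixed aberrant sites**: cryptic donors/acceptors sit 30–90 bp
  inside the U12 intron and the skipped exon is the U12-adjacent one,
  drawn once per gene and reused across samples — aberrant transcripts are
  recurrent properties of a gene's sequence.
* **Reads**: each molecule yields exactly one 100 bp single-end read placed
  uniformly along its isoform, projected to genomic M/N operations, written
  as valid coordinate-sorted SAM (MAPQ 60, seeded arbitrary bases, QUAL
  `I×100`). Truth tables record per-(sample, gene, intron) class counts and
  per-gene expression, both as expected molecules and per-exonic-kb density
  (the quantity FPKM estimates in a one-read-per-molecule model). An
  optional read-level sidecar maps read ids to isoform classes; truth never
  appears in the SAM itself.
* **Determinism**: one master seed; the gene set, expression and affected
  genes derive from it directly, and each sample uses a substream seeded by
  (master seed, CRC32 of the sample id). Identical configuration reproduces
  byte-identical outputs.

What the simulator does **not** model: paired-end fragments (junction
counting and depth are read-level, so pairing adds no coverage of the
method), sequencing errors and mapping ambiguity (alignment is upstream of
this tool), positional coverage bias, overlapping genes, alternative
isoforms, and NMD-driven loss of aberrant transcripts. Passing tests
therefore demonstrate correctness of the statistics under idealised
alignments, not robustness to alignment artefacts.

## Numerical choices

* Internal coordinates are 0-based half-open; GTF and the intron-type table
  are 1-based inclusive; SAM positions 1-based. Conversions happen only at
  I/O boundaries.
* Junction matching is exact-coordinate; no fuzzy matching of splice sites.
* All thresholds live in one config and are recorded in the run manifest;
  rerunning from the manifest reproduces outputs byte-identically.
* Tie-breaks (canonical transcript, ranking) are lexicographic and
  deterministic; sorting is stable.
* Degenerate inputs: zero-read samples are rejected; genes without two U2
  references, or with intron bodies shorter than the trim, are excluded
  with reason codes rather than exceptions.

## Test and validation scales

The validation suite runs the full pipeline at a scaled-down analogue of a
real cohort: 500 genes with 20 affected, 2 cases vs 4 controls at default
coverage (~12M reads per cohort), a matched retention grid (0 / 0.1 / 0.3)
at ~10,000 molecules per gene for parameter recovery, and a 50-gene
two-sample simulation for exact oracle equivalence against naive
reimplementations (text-parsed SAM, per-base pileup). These sizes keep the
whole suite in the minutes range on a single CPU while leaving the binomial
error bars of the recovery checks far smaller than the effects being
verified.

## Known limitations

* The SD-threshold rule is a ranking heuristic; with 4 controls the SD
  estimate is noisy and absolute z values should not be over-interpreted.
* FPKM-normalised metrics inherit any expression difference between cases
  and controls; the U2-normalised metrics are the more robust pair.
* Whole-body mean depth is one reading of "intron retention"; single-point
  depth probes would be noisier but less sensitive to partial cryptic
  retention inside the intron.
* Intron-type labels are taken entirely from the annotation table; genes
  absent from it are invisible to the analysis.
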