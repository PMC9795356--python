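# Methods

## The measurement model

Nascent-transcript capture assays isolate elongating RNAPII complexes and
sequence the short RNA fragments (20–90 nt inserts) protected inside them.
Because the RNA 3′ end is the last base the polymerase incorporated, each
fragment reports one genomic base occupied by one polymerase. The pipeline's
job is to recover that base per fragment and to summarize the resulting
per-bp occupancy.

Two sequencing dialects are handled:

- **Single-end** libraries: the read aligns on the nascent-RNA strand and its
  3′ end (rightmost aligned base on +, leftmost on −) is the event.
- **Paired-end FR** libraries: the first mate aligns on the RNA strand, the
  second mate antisense to it, with the second mate's 5′ end at the fragment
  3′ end. The event is therefore the second mate's 5′ end with the strand
  **flipped** relative to its alignment. First mates yield no event.

5′/3′ are defined on the alignment's orientation (the 5′ end of a − alignment
is its rightmost base), and ends are taken from the aligned span, never from
soft-clipped bases — clipped bases were not templated at the reported locus.

## Filtering

Post-alignment filters drop, in order: unmapped records;
secondary/supplementary records; multimappers (alignment-count field NH > 1,
falling back to MAPQ = 0 when the field is absent); improperly paired records
(paired mode); then exact coordinate duplicates. The duplicate key is
(chrom, start, end, strand) for single-end records and (chrom, fragment
start, fragment end, first-mate strand) for pairs, mates being matched by
query name. Both endpoints matter: with 20–90 nt fragments the 3′ end is
informative, and collapsing by start alone would destroy distinct events.
Improper pairs are removed before the duplicate pass because the paired key
needs both mates' coordinates. Counts are exhaustive and mutually exclusive;
`retained + Σ dropped == input` is asserted on every run. A diagnostic
`keep_duplicates` mode skips deduplication — note that genuinely distinct
fragments sharing exact coordinates are indistinguishable from PCR
duplicates, so the default mode necessarily collapses them too.

Upstream trimming filters (read length, error rate) belong to the trimmer and
are not re-implemented; an optional minimum aligned-length filter (off by
default) exists for parity experiments.

## Tracks and profiles

Coverage tracks hold per-chromosome int64 count vectors at single-bp
resolution, allocated lazily per chromosome. SNR tracks add each event's
weight at one base; read-level tracks add 1 over each aligned span (pairs:
the union span of the two mates on the first mate's strand). Replicates are
merged by summing raw counts — merging exists to increase depth, so it
happens before any normalization. bedGraph output is 0-based half-open with
equal-value runs merged and zeros omitted; bigWig output keeps single-bp
resolution. Round trips through either format reproduce the track exactly.

Binning schemes (defaults in parentheses):

- **point_window** (TES: ±5 kb, 100-bp bins → 100 bins; polyA: ±2 kb, 40-bp
  bins → 100 bins): the window is tiled in transcription direction, each bin
  holding the mean per-bp sense-strand count. The anchor base falls in the
  first downstream bin; for − anchors the window is `[a+1−f, a+1+f)`
  reversed, which preserves that convention exactly.
- **scale_regions** (metagene: ±5 kb flanks, body → 15 kb, 100-bp bins →
  50+150+50 bins): the gene body is mapped linearly onto the target length
  with proportional-overlap weighting — each genomic base contributes to the
  virtual bins its image spans. A bin's value is its received mass divided by
  the genomic-equivalent bin width L/n_bins, so uniform coverage v gives
  every bin v regardless of gene length, a delta event lands in one (or, at a
  boundary, two adjacent) bins, and Σ body bins × L/n_bins equals the body's
  total mass to rounding error. Genes shorter than one bin are retained via
  the same weighting.

Aggregation across regions is the per-bin mean (sum and median available).
Density scaling divides the aggregated profile by its sum, making the area
under each sample's curve 1; it is idempotent and invariant to global count
scaling. It is applied per sample after binning and aggregation. This is the
appropriate cross-sample comparison here because a double-IP workflow cannot
carry spike-ins, so absolute depths are not comparable — only binding shapes
are. Profiles count sense-strand signal only (antisense available by
option); per-region normalization of heatmap matrices is offered as an
option, with per-sample the default.

## Readthrough quantification

For each gene, one representative transcript is chosen: strongest (lowest)
support level first, then the widest genomic span, then the
lexicographically smallest transcript id — a total order, so selection is
deterministic and order-independent. Transcripts lacking a support level
rank after level 5: an unevidenced model should never beat an evidenced one.
"Width" is read as *widest preferred*, which matches the purpose of the rule
(a representative that spans the locus).

The readthrough ratio is RPK in the 50 kb window downstream of the gene's
most distal TES divided by RPK in the representative transcript's last exon,
where RPK = sense-strand SNR events per kilobase of (chromosome-clamped)
region length. SNR counts, not read-level coverage, feed RPK: events are
one-per-read, so "number of reads" and event mass coincide. Ratios are
invariant to global scaling of the track, which is what makes cross-sample
comparison meaningful without depth normalization. A gene with downstream
signal but an empty last exon would produce an infinite ratio and is dropped
(`infinite_dropped`); a gene with no signal in either region is
`empty_dropped`. Dropped genes never enter statistics. Genes whose downstream
window overlaps another annotated gene body are flagged (kept by default,
excludable) so a neighbor's signal is not silently attributed to
readthrough.

Group comparisons use two-sided Wilcoxon tests: rank-sum (Mann–Whitney U)
for unpaired gene sets — exact null distribution for small tie-free samples,
normal approximation with continuity correction otherwise — and signed-rank
for gene-matched pairs. A brute-force enumeration oracle
(`exact_ranksum_p`) verifies the small-n exact p values independently.

## IP-MS enrichment

Protein-group tables are ingested with zeros recorded as missing (the
MaxQuant convention) and reverse/contaminant rows dropped. Proteins must
have a **combined peptide count strictly greater than 3** summed across
biological replicates — applied at the protein-group level, the only reading
compatible with a protein-level table. Intensities are log2-transformed and
missing cells imputed per column from N(mean − 1.8·sd, (0.3·sd)²), the
standard left-censoring model (absent usually means below detection);
imputation is seeded and imputed cells are flagged. The test is a two-sided
two-sample Student t-test (equal variance, the Perseus-style default; Welch
by flag) with injections as observations (n = 6 per side at two replicates ×
triplicate injections; a replicate-means mode with n = 2 exists for
sensitivity analysis). Degenerate rows: zero pooled variance with equal
means → p = 1; with unequal means → smallest positive float, flagged.

Enrichment is log2 difference > 2 **and** −log2 p > 2, both strict. The
−log2 scale is deliberate and implemented verbatim: the thresholds mean
p < 0.25 together with > 4-fold enrichment — a permissive p gate made
stringent by the fold-change requirement. No multiple-testing correction is
applied, matching that design. Double-IP results are interpreted against the
single-IP reference by restricting to reference-enriched proteins and
reporting both log2 differences side by side; proteins absent from the
double-IP table are reported with missing values, never dropped silently.
Factor-specific tables (e.g. two paralogous baits sharing peptides) are
processed in separate runs so shared peptides are never misassigned.

## Synthetic data

The generators exist so every stage can be scored against a known truth.

**Annotation**: genes laid left-to-right per chromosome with random gaps
(gene length 2–20 kb, 1–3 transcripts per gene with varied support levels);
an isolation flag forces ≥ downstream-window spacing between gene bodies so
readthrough windows never reach a neighbor. Emitted as GTF + chromosome
sizes; deterministic per seed.

**Reads**: per-gene occupancy is a mixture density over
[TSS − 5 kb, TES + horizon]: a Gaussian pause peak just downstream of the
TSS (weight 0.15, sd 100 bp, offset +50 bp), a uniform gene body (0.55), a
Gaussian TES peak (0.15, sd 200 bp), an exponential readthrough tail beyond
the TES (0.15, mean 5 kb), and an optional intronic-polyA Gaussian bump.
Weights sum to 1; the horizon must cover ≥ 3 decay lengths. Fragment 3′ ends
are drawn from this density, lengths uniform on 20–90 nt, and records are
emitted as coordinate-sorted SAM — single-end on the RNA strand, or FR pairs
with the second mate's 5′ end at the fragment 3′ end. Duplicates are exact
coordinate copies under fresh names; multimappers carry NH > 1 on the
primary record only (no secondary records — the filter contract operates on
the count field). A plain-TSV truth table (fragment → 3′ end, strand,
multimapper flag) accompanies every run.

**LFQ tables**: protein log2 means spread N(25, 2²) across proteins,
per-injection noise sd 0.5 (a parameter of this package — the across-protein
spread alone provides no error term for a t-test), spiked proteins shifted
by `log2_effect` in the test group. Missingness is left-censored: within
each injection column the missing probability is 2·rate·(1 − intensity rank
percentile), so low-abundance cells drop out preferentially while the
marginal missing fraction equals `missing_rate` exactly. This mirrors how
label-free data actually go missing and is the premise of down-shifted
imputation; it is not missing-completely-at-random.

What the generators do **not** emulate: sequence content and sequencing
error (reads carry placeholder sequence), base qualities, splicing-aware
alignment artifacts, mappability structure, batch effects, or
intensity-dependent variance in MS data. Passing tests therefore demonstrate
the correctness of the pipeline's arithmetic and contracts on data with the
assumed statistical structure — not robustness to alignment or acquisition
artifacts absent from the simulation.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere internally (BED convention);
  GTF's 1-based inclusive coordinates are converted on input. The TES of a +
  gene at half-open end E is base E−1; its downstream window starts at E.
- Off-chromosome window portions are clamped, the clamping is reported, and
  clamped lengths are used in RPK denominators; a fully off-chromosome
  window is an error.
- Exact small-sample Wilcoxon is used below scipy's tie-free exact-method
  threshold; ties switch to midranks with normal approximation.
- Density scaling of an all-zero profile is an error rather than NaN.
- Histogram-vs-density convergence checks in the tests operate on 100-bp
  bins: at realistic depths, per-bp comparisons are dominated by multinomial
  sampling noise rather than by any property of the pipeline.
- Problem sizes in the test and reproduction experiments — 10,000 fragments
  for the extraction oracle, 200 genes × 250 reads per readthrough group,
  1,050 proteins × 12 injections for spike recovery — were chosen as the
  smallest sizes at which the measured quantities are stable across seeds.

## Known limitations

- No UMI-aware deduplication or optical-duplicate handling; coordinate
  dedup cannot distinguish true duplicates from coincident fragments.
- Spliced alignments contribute their full reference span to read-level
  coverage (N operations are not excised); SNR events are unaffected.
- The readthrough module does not call readthrough genes de novo; gene sets
  come from the caller.
- MS processing starts from a quantified protein-group table; spectra,
  peptide inference and match-between-runs are upstream concerns.
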