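# Methods

## Problem and model

Insertion sequences (ISs) are the simplest mobile genetic elements: a
transposase ORF of roughly one kilobase flanked by inverted repeats.
Their abundance in bacterial genomes spans zero to >1000 copies and
responds to selection for genomic plasticity, so the transposase content
of a community is an ecological signal in its own right.  `tnpquant`
quantifies that signal in shotgun metagenomes and metatranscriptomes of
size-fractionated aquatic communities: how large a share of a
community's (or one taxon's) reads derive from transposase genes, how
many transposase copies an average genome carries, and whether
transposases are transcribed above or below their genomic abundance.

The analysis operates on assembled contigs, translated-search hits of
those contigs against a curated IS transposase protein database
(ISfinder-style, with per-ORF family labels), per-contig taxonomy, and
per-sample read-to-contig mapping tables.  Identification proceeds in
three steps:

1. **Footprints.**  Translated hits with E < 10⁻⁶ frequently pile up
   over the same nucleotide stretch.  Per contig and strand, hits whose
   intervals transitively overlap are merged; the union extent is a
   *footprint* — the unit to be explained.
2. **Greedy resolution.**  A footprint may be occupied by more than one
   transposase.  Among hits intersecting the still-unassigned part of
   the footprint, the highest-scoring one (bitscore; ties broken by
   E-value, then query-interval length, then reference id) is taken as
   the occupying transposase; its intersection with the unassigned
   region becomes a call segment and is subtracted.  This repeats while
   any residual piece of at least `min_residual_nt` (default 30 nt ≈ 10
   aa, below any meaningful transposase fragment) still intersects a
   hit.  The re-ranking uses the already-collected hits rather than a
   second alignment pass: the ranking information is the same and the
   procedure becomes deterministic.
3. **Filters.**  A call is retained when its E-value is strictly below
   10⁻⁶ and the segment covers at least 30% of the reference ORF's
   amino-acid length (the boundary value is retained).  Segment
   coverage is computed proportionally along the source hit; a config
   flag switches to full-hit coverage.

Footprints are built per strand (`merge_across_strands=False`) because
translated hits on opposite strands represent different ORFs.

### Normalizations

With calls in hand, a mapped read interval is attributed to
transposases when ≥50% of its length (configurable; 0 = any overlap)
overlaps the union of call segments on its contig, strand-agnostically.
Its IS family is the family of the call with the largest overlap
(lexicographic tie-break).  From per-sample profiles the package
derives:

- **fraction of bacterial reads** = transposase reads / total reads on
  taxonomically classified (bacterial) contigs; unclassified reads are
  excluded from the denominator;
- **per-taxon fraction** — the same quotient restricted to one taxon's
  reads (e.g. cyanobacterial transposase transcripts over all
  cyanobacterial transcripts);
- **per-genome count** = transposase reads / mean hit count over 35
  single-copy marker gene families.  Zero-hit markers stay in the mean
  (the denominator is the fixed marker panel size), making the mean a
  genome-equivalent estimate.  The metric is invariant to uniform
  sequencing-depth rescaling;
- **transcript:gene expression ratio** — the scope's transposase
  fraction in an RNA sample over the same fraction in the matched DNA
  sample (pairing on station, depth, size fraction); pairs with a zero
  DNA-side fraction are excluded; the cross-pair aggregator is the
  median, as it is for all group summaries;
- **transposases per Mbp** for reference-strain tables, reported to one
  decimal;
- **genome-size proxy** = total scope reads / mean single-copy marker
  hits — relative units, comparable across samples of one study.

Note a structural caveat of read-count-based copy estimation: read
counts are proportional to (copy number × gene length), so the
per-genome count is an unbiased copy-number estimate only when the
transposase genes and the marker genes have similar lengths.  Both are
of order 1 kb in practice; the synthetic generator makes them equal in
expectation so that recovery tests measure the normalization rather
than this length bias.

### Statistics

Group contrasts use the two-sided Wilcoxon rank-sum (Mann–Whitney)
test: exact when both groups have ≤25 observations and the pooled data
are tie-free, otherwise the normal approximation with tie and
continuity corrections.  This mirrors the standard R `wilcox.test`
behavior and the two paths agree to well under 0.01 at moderate sizes.
The reported statistic is the U of the first group (R's W).  Raw P
values are reported; Benjamini–Hochberg adjustment is available but off
by default.  Continuous relationships (genome-size proxy vs transposase
fraction, RNA vs DNA fraction) use ordinary least squares with adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2) and the Pearson correlation t-test.

## Built-in translated search

For desk-scale data (≤ ~1 Mb of contig) the package provides its own
translated search so the whole pipeline is self-contained and
deterministic.  Contigs are translated in six frames (stops as `*`,
ambiguous codons as `X`); candidate (frame, reference) pairs are found
by exact 6-mer amino-acid word seeding, seeds are clustered by
diagonal, and a local Smith–Waterman alignment (BLOSUM62, gap open 11,
extend 1, via Biopython's `PairwiseAligner`) is run on a padded peptide
window per cluster.  Bitscores use the Karlin–Altschul transform with
gapped BLOSUM62 defaults (λ = 0.267, K = 0.041); E-values use the frame
peptide length × total database residues.  Word size 6 keeps spurious
window alignments rare on random background while exact planted copies
(and 85%-identity family siblings) always seed.  `word_size=None`
disables seeding for exhaustive small-input runs.  This searcher is a
correctness oracle for synthetic fixtures, not a BLAST replacement: it
reports the single best local alignment per window, does not emulate
NCBI statistics exactly, and has no frameshift tolerance.

## Synthetic community generator

The generator emulates the study design end-to-end with known truth:

- **Design.**  Five brackish and two marine stations × one depth ×
  three size fractions (small 0.1–0.8, medium 0.8–3.0, large 3.0–200
  µm) × {DNA, RNA} = 42 samples, 10,000 reads each.  Six taxa with
  genus-to-phylum lineages (Synechococcus, Pelagibacter,
  Flavobacterium, Ilumatobacter, Rubritalea, Alteromonas) at fixed
  relative weights.
- **Contigs.**  Per taxon, six contigs of 10–16 kb of i.i.d. uniform
  ACGT background (which keeps spurious translated hits negligible),
  hosting exactly one interval per single-copy marker label (35 by
  default, 990 nt each — one "genome" per taxon) and a configurable
  number of planted transposase ORFs: exact reverse-translations
  (fixed most-preferred-codon table) of references from a generated
  IS database (6 families × 3 members, 280–380 aa, 15% within-family
  divergence from a family ancestor), on either strand.  One contig
  set serves all samples, as a co-assembly would.
- **Reads.**  Interval-based (contig, start, end, sample, count) — the
  analysis consumes counts, not base calls.  In the default
  `planted_fraction` mode the transposase read share of each sample is
  a configured fraction: brackish stations 0.7% × {0.5 small, 1.0
  medium, 1.6 large}, marine stations 0.2% × the same multipliers —
  placing every sample in the 0.1–2% range with brackish/marine
  medians of 0.7%/0.2% and a small < medium < large gradient.
  Transposase reads fall fully inside planted ORFs (allocated across
  copies by host weight × copy length); background reads are uniform
  with <50% overlap with planted ORFs, so the ≥50% attribution rule
  reproduces the truth exactly.  RNA samples scale each (family,
  taxon) transposase category by an expression multiplier —
  defaults 2.3 (Cyanobacteria), 1.2 (Verrucomicrobia), 0.24
  (Actinobacteria), 1.0 otherwise.  A `uniform` mode instead spreads
  reads uniformly along each taxon's genome (transposase regions
  scaled by the RNA multiplier), giving known truth for per-genome
  copy counts and genome-size proxies.
- **What it does not emulate.**  Sequencing error, assembly artifacts,
  chimeras, rRNA contamination, inter-sample taxon-composition shifts,
  partial/decayed IS copies, and compositional biases of real filters.
  Passing recovery tests therefore demonstrates the correctness of the
  identification/normalization machinery under clean mappings, not
  robustness to real-data noise.

## Numerical and design choices

- Coordinates are 0-based half-open on the forward strand everywhere;
  BLAST's 1-based, orientation-encoded convention is converted at the
  parser boundary only.
- E-value threshold is a strict `<`; ORF-coverage threshold is `≥`
  ("at least 30%").
- Tie-break chain in resolution (bitscore → E-value → length → ref id)
  is fixed for determinism.
- All randomness flows from `numpy.random.default_rng` seeded from the
  config; identical configs give byte-identical outputs.
- Degenerate inputs: empty hit lists produce empty call sets; samples
  with no marker hits raise an undefined-value error rather than
  returning 0; contigs too short for their features fail generation
  with the contig named.
- Problem sizes in the validation suite (communities of ~0.5 Mb of
  contig, 10–20 k reads/sample, 50 fraction-recovery and 20
  ratio-recovery replicates) were chosen as the smallest sizes at which
  binomial sampling error is far below the tested tolerances.

## Known limitations

- The greedy footprint resolution is order-deterministic but not
  globally optimal; it matches the brute-force re-scan of the same
  greedy rule exactly (tested on 1,000 random instances), not a
  maximum-weight segmentation.
- The number of retained calls is not monotone in the E-value
  threshold: excluding a dominating hit can split a footprint into
  several calls.  (Raising the coverage threshold, by contrast, can
  only remove calls.)
- Per-genome counts inherit the length bias discussed above when
  transposase and marker genes differ in length.
- The built-in search reports one alignment per (frame, reference,
  window); two copies of the same reference on one contig are found
  only if their seeds cluster into separate windows (true for
  non-overlapping planted copies separated by background).
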