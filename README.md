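# tnpquant

Transposase gene abundance and expression in size-fractionated aquatic
metagenomes and metatranscriptomes.

Insertion sequences (ISs) — transposase ORFs flanked by inverted
repeats — are the simplest mobile genetic elements in bacterial
genomes, and their community-level abundance is a marker of selection
for genomic plasticity in variable or stressful habitats.  `tnpquant`
is a pipeline for microbial ecologists who want to measure that signal
in shotgun data: it identifies transposase genes on assembled contigs
from translated-search hits, normalizes their read counts at several
levels, compares transcription with genomic abundance, and runs the
standard statistical contrasts between size fractions and regions.  A
built-in synthetic-community generator with known ground truth
validates every stage.

## Method in brief

Contigs are compared against a curated IS transposase protein database
(ISfinder-style, with per-ORF family labels) in translated mode.  Hits
with E < 10⁻⁶ that pile up over the same nucleotide stretch define a
**footprint**; each footprint is resolved by iteratively assigning the
highest-bitscore hit to the still-unexplained region until no residual
of ≥30 nt remains, and calls covering <30% of their reference ORF's
amino-acid length are discarded.  From calls and read-to-contig maps,
per-sample profiles yield:

- transposase fraction  f = T / B  (transposase reads over bacterial
  reads), also per taxon (T_t / B_t) and per IS family;
- per-genome count  T / mean(m₁…m₃₅)  where mᵢ are hit counts of 35
  single-copy marker gene families (genome equivalents);
- transcript:gene expression ratio  f_RNA / f_DNA  per matched
  DNA/RNA sample pair, aggregated by median;
- transposases per Mbp for reference-strain tables, and a relative
  genome-size proxy (total reads / mean single-copy hits).

Contrasts use the two-sided Wilcoxon rank-sum test (exact for small
tie-free groups, normal approximation with tie/continuity corrections
otherwise); trends use OLS with adjusted R² and the Pearson test.
See `docs/methods.md` for the full model, parameter table, and
limitations.

## Worked example

Run the whole synthetic study — simulate, search, call, quantify,
stats, report — with one command:

```sh
tnpquant run --seed 1 --out run1
```

`run1/report.md` then contains, among other tables (output abridged):

```
## Transposase fraction of bacterial reads (median per sample group)

station  depth_m fraction    DNA    RNA
  GS665      5.0    large 0.0112 0.0125
  GS665      5.0   medium 0.0066 0.0074
  GS665      5.0    small 0.0031 0.0036
  ...

## Reference strains: transposases per Mbp

                  strain  tnp_count  genome_size_mbp   group  tnp_per_mbp
Synechococcus sp. CB0101         15              2.7 coastal          5.6
Synechococcus sp. RS9917         22              2.6 coastal          8.5
 Synechococcus sp. BL107          0              2.3  marine          0.0
  ...
```

Reading the numbers: each row of the first table is the transposase
share of one sample's bacterial reads — e.g. 0.0066 means 0.66% of the
medium-fraction DNA reads at station GS665 derive from transposase
genes.  The simulated design plants brackish-station fractions around
0.7% (marine 0.2%) with a small < medium < large gradient, and the
pipeline recovers exactly that.  The strain table divides transposase
counts of reference *Synechococcus* genomes by genome size: coastal
strains carry 3.7–16.7 transposases per Mbp, open-ocean strains none.
`run1/contrasts.tsv` holds the rank-sum results (e.g. small fraction
vs medium+large: P ≈ 0.015; brackish vs marine: P ≈ 0.0016 at seed 1),
`run1/expression_ratios.tsv` the per-phylum and per-family
transcript:gene ratios (Cyanobacteria ≈ 2.1 at seed 1, configured
truth 2.3), and `run1/manifest.json` the digests that make the run
reproducible.  Each stage is also available separately
(`tnpquant simulate|search|call|quantify|stats|report`) and as library
functions.

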