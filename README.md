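# ilpkit

Genome-wide **intron length polymorphism (ILP)** marker development and
population-genetic analysis, built for plant genetics work such as tea
(*Camellia*) germplasm characterisation.

ILP markers exploit the fact that introns evolve faster than the exons
around them: a primer pair placed on the two exons flanking an intron
amplifies a product whose length shifts whenever the intron gains or
loses sequence. Because the primers sit in conserved coding sequence,
the markers are codominant, gene-anchored, and transfer well across
related species.

## What the package does

1. **Intron extraction** (`ilpkit.genome_io`) — parse a genome FASTA and
   GFF3 annotation, pick each gene's primary transcript (largest summed
   exon length), and emit every intron in a configurable length window
   (default 80–300 bp) with its flanking exon sequences.
2. **Primer design** (`ilpkit.primer_design`) — enumerate candidate
   primers (18–27 nt, GC 30–70%, Tm 55–65 °C, homopolymer ≤ 4, G/C 3'
   end, no 3' self-complementarity) on the intron-proximal 60 bp of each
   flanking exon and return the pair minimising
   `|Tm_f − Tm_r| + w_p·|product − product_opt| + w_t·(|Tm_f − 60| + |Tm_r − 60|)`.
   Wallace-rule and SantaLucia nearest-neighbour Tm are built in.
3. **Electronic PCR** (`ilpkit.insilico_pcr`) — locate binding sites on
   both strands under a mismatch/gap budget (default 4 substitutions,
   2 indels, exact 3-base 3' anchor), enumerate inward-facing amplicons
   in a product window (default 80–1200 bp, ±60 bp of the expected size
   on the source genome), classify band counts (0/1/2/3/>3), and call a
   **marker** where every screened genome yields exactly one band —
   **polymorphic** when those single-band sizes differ.
4. **Catalog summaries** (`ilpkit.marker_catalog`) — `Tea_ILP####`-style
   naming, per-chromosome density (markers/Mb), intron-length bins
   (1–200 / 201–300 / 301–500 / >500 bp), cross-species transferability
   rates, and amplification/polymorphism percentage tables.
5. **Population genetics** (`ilpkit.popgen`) — score 0/1 band matrices
   into codominant genotypes (1 band = homozygote, 2 = heterozygote,
   else missing) and compute Na, Ne = 1/Σp², Shannon I = −Σp ln p,
   observed/expected homo-/heterozygosity (Levene-corrected), Nei gene
   diversity H = 1 − Σp², PIC, PPB, Fis/Fit/Fst with gene flow
   Nm = 0.25(1 − Fst)/Fst, AMOVA on band vectors with permutation
   tests, Nei identity/distance, NJ and UPGMA trees (with similarity-
   threshold cuts), and PCoA.
6. **Synthetic study systems** (`ilpkit.synthetic_data`) — annotated toy
   genomes with exact intron truth tables, variant genomes with planted
   intron indels, and Balding–Nichols multi-population genotype tables
   at a chosen Fst, so the whole pipeline is testable end to end.

A bundled reference dataset (`ilpkit.datasets`) carries a published
40-locus ILP diversity panel scored on 176 cultivated *C. tetracocca*
trees from three town populations, plus its validation-screen counts,
AMOVA table, and Nei similarity matrix.

## Worked example

`examples/01_marker_discovery.py` simulates a 20-gene genome, plants 12
intron indels into a variant copy, and runs the full discovery chain:

```
44 introns in window, 44 primer pairs designed
44 single-band markers, 12 polymorphic
called == planted: True
  Tea_ILP0001 (gene001_i1): base:283 bp, variant:328 bp
  Tea_ILP0002 (gene001_i2): base:217 bp, variant:257 bp
  ...
```

Every intron in the design window received a primer pair; all pairs
amplify a single band in both genomes, and exactly the 12 loci carrying
planted indels are called polymorphic — each printed size difference is
the planted indel length. The other examples cover primer scoring, ePCR
stringency, diversity/F-statistics/AMOVA, and trees/PCoA, each printing
a short annotated result.

The same stages are available as a CLI for shell pipelines:

```sh
ilpkit simulate genome --prefix sim
ilpkit design-primers --genome sim.fa --gff sim.gff3 --out primers.tsv
ilpkit epcr --primers primers.tsv --genome base=sim.fa --out amplicons.tsv
ilpkit --config my.yaml pipeline --genome sim.fa --gff sim.gff3 \
    --target variant=var.fa --outdir out/
```

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions, and limitations in detail.
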