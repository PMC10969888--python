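"""Design a primer pair on the exons flanking one intron.

Builds a single-gene toy genome, extracts its intron, and prints the
best-scoring pair: sequences, melting temperatures (Wallace rule), GC
fractions, and the expected product size (primers + intron + any exon
bases between primer and splice site).
"""

from ilpkit import genome_io, primer_design, synthetic_data

cfg = synthetic_data.SimGenomeConfig(
    seed=7, n_chromosomes=1, genes_per_chromosome=1,
    exons_per_gene=(2, 2), intron_len=(150, 150))
genome, models, _ = synthetic_data.simulate_annotated_genome(cfg)
intron = genome_io.extract_introns(genome, models, 80, 300)[0]
print(f"intron: {intron.gene_id} #{intron.intron_index}, "
      f"{intron.length} bp at {intron.seq_id}:{intron.start}-{intron.end}")

pair = primer_design.design_pairs_for_intron(intron)
print(f"forward  5'-{pair.fwd_seq}-3'  Tm {pair.fwd_tm:.1f} C  GC {pair.fwd_gc:.2f}")
print(f"reverse  5'-{pair.rev_seq}-3'  Tm {pair.rev_tm:.1f} C  GC {pair.rev_gc:.2f}")
print(f"expected product: {pair.expected_product_bp} bp "
      f"(intron {intron.length} bp + primers + intervening exon bases)")
# Tm values sit in the 55-65 C window and the product spans the intron,
# so a length change in the intron shifts the product size one-for-one.
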