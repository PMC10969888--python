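# Methods

## Scope and model

`ilpkit` implements intron length polymorphism (ILP) marker development
— intron extraction, flanking-exon primer design, electronic PCR (ePCR)
screening, polymorphism calling — and the population-genetic statistics
conventionally used to characterise the resulting marker panels. The
design target is the classic plant-genetics workflow: markers are
anchored in conserved exons, score codominantly on denaturing gels, and
owe their polymorphism to intron indels.

## Coordinates and strand

All in-memory coordinates are 0-based half-open on the plus strand;
GFF3 (1-based inclusive) converts at the I/O boundary, and the intron
table re-emits 1-based inclusive coordinates for human readers. Introns
and exon sequences are always reported on the forward genome strand
regardless of gene orientation: PCR is strand-symmetric, so design and
screening never need the transcribed strand. The primary transcript of
a gene is the one with the largest summed exon length (ties broken by
transcript id); this maximises designable flanking exon sequence.

## Primer design

Candidates are all 18–27-mers whose intron-proximal end lies within 60
bp (`margin_from_intron`) of the splice site, filtered by GC ∈ [0.30,
0.70], Tm ∈ [55, 65] °C, homopolymer runs ≤ 4, a non-A/T 3' terminus
(configurable), no Ns, and rejection of 3'-terminal 4-mers that are
their own reverse complement (the primer-dimer-prone configuration; a
full thermodynamic folding model is deliberately out of scope).

Two Tm models are provided. The Wallace 2–4 rule is the default scorer:
for 18–27-mers it ranks candidates adequately and is orders of
magnitude faster. The nearest-neighbour model uses the SantaLucia-1998
unified ΔH/ΔS table with the entropy salt correction
0.368·(N−1)·ln[Na⁺] at 50 mM monovalent cation and C_T/4 with 0.5 µM
total oligo; the test suite cross-checks it against an independently
maintained implementation of the same published table (agreement is
exact to floating point, asserted at 1 °C).

Pair selection minimises an explicit additive penalty,

    |Tm_f − Tm_r| + w_p·|product − product_opt| + w_t·(|Tm_f − 60| + |Tm_r − 60|),

with w_p = 0.02 /bp and w_t = 0.5 (so a 50 bp product deviation weighs
like a 1 °C Tm imbalance, and Tm centring matters half as much as
balance), product_opt defaulting to intron length + 100 bp (two 18-mer
primers plus breathing room inside the exons), and the product
constrained to the ePCR window [80, 1200] bp. Ties break by smaller
product, then forward and reverse sequence, making the design a pure
function of its inputs. A full Primer3-style objective was rejected on
purpose: its dozens of interacting penalties are not reproducible
without pinning an external binary, whereas this scorer is completely
specified here.

## Electronic PCR

A primer binds where an alignment against the genome has at most
`n_max` substitutions (default 4) and `g_max` indels (default 2) and
matches exactly over its 3'-terminal `anchor_len` bases (default 3) —
polymerase extension requires a paired 3' end. For each anchor
placement the engine reports the alignment minimising (substitutions,
gap operations, site length) lexicographically, among feasible ones.

Two search routes return provably identical site sets. The default
seeds on exact occurrences of the 3' anchor (C-level string scanning)
and verifies each placement with a banded dynamic program whose state
is (query position, insertions, deletions). Because every valid site
contains the exact anchor, anchor seeding is complete. Seeding on a
longer 3' word (the classic ePCR speed-up) was considered and rejected:
a site may carry a substitution within bases 4–7 from the 3' end,
breaking a 7-mer seed while satisfying the binding rule, so word
seeding cannot satisfy the oracle-equivalence property this module
promises. The reference route is an independent exhaustive scan that
computes Pareto-minimal (substitution, gap) sets for every anchor
placement and window length; the test suite asserts set equality on
randomised instances, and strand symmetry and budget monotonicity as
separate properties.

Amplicons are inward-facing plus/minus site pairs (either primer may
bind upstream) with non-overlapping footprints; `product_bp` is the 5'
end of the forward site to the 5' end of the reverse site (end − start,
half-open) — the physical amplicon length. Products must lie in
[product_min, product_max] (default 80–1200 bp) and, when an expected
size is known for that genome (the pair's own source genome), within
`margin` (default 60 bp) of it; foreign genomes in transferability-
style screens are constrained by the absolute window only.

A primer pair becomes a **marker** when it yields exactly one band in
every screened genome, and **polymorphic** when its single-band sizes
span at least `min_size_diff` bp. The default is 1 bp (any detected
difference); ~3 bp is a practical setting for 6% denaturing
polyacrylamide resolution and is configurable. Markers are named
sequentially (`Tea_ILP0001`, …) in input order.

Note that the default 4-substitution/2-indel budget is *permissive by
construction* (it models PCR tolerance, and drives the realistic
preponderance of multi-band profiles); truth-recovery checks on
synthetic genome pairs therefore screen at exact-match stringency
(`n_max=0, g_max=0`), where, with unmutated primer sites, single-band
behaviour and complete planted-indel recall are the correct
expectations.

## Population statistics

Conventions follow the Popgene/PowerMarker/GenAlEx lineage:

- **Band scoring.** 1 band → homozygote, 2 bands → heterozygote, 0 or
  >2 bands → missing; allele labels are band sizes.
- **Allele frequencies.** Counts over 2 × typed individuals, missing
  excluded, per stratum.
- **Per-locus diversity.** Na (observed alleles), Ne = 1/Σp²,
  I = −Σp ln p (natural log), H = 1 − Σp² (plain Nei gene diversity),
  Exp_He = (2N/(2N−1))·H with Levene's small-sample correction (H and
  Exp_He therefore differ in the last digit at moderate N — both are
  reported), Exp_Ho = 1 − Exp_He, Obs_Ho/Obs_He from genotype counts,
  PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j². Monomorphic loci return Na=1,
  Ne=1, I=H=PIC=0 without error.
- **Per-population summaries.** Locus means of Na/Ne/I/H plus PPB%
  (share of loci with Na ≥ 2; no rare-allele frequency cutoff).
- **F-statistics.** Per locus: Ho = sample-size-weighted observed
  heterozygosity, Hs = weighted mean within-population 1 − Σp²,
  Ht = 1 − Σp̄² at the weighted pooled frequencies; multi-locus
  combining by ratio of locus averages: Fis = 1 − H̄o/H̄s,
  Fit = 1 − H̄o/H̄t, Fst = (H̄t − H̄s)/H̄t; Nm = 0.25(1 − Fst)/Fst.
  This G_st-style quantity measures differentiation **among the K
  sampled demes**; under an island/Balding–Nichols model with
  ancestral-pool parameter F its expectation is F(K−1)/K/(1 − F/K).
  `fst_finite_demes_correction` inverts that relation
  (F = G·K/(K−1+G)) and is used whenever an estimate is compared with
  a simulation's target Fst.
- **AMOVA.** Squared Euclidean distances on 0/1 band-presence vectors;
  SS_total = Σ_{i<j} d²/N, SS_within pooled per population, df =
  (P−1, N−P), σ²_within = MS_within, σ²_among = (MS_among −
  MS_within)/n₀ with n₀ = (N − Σn_k²/N)/(P−1); PMV normalises
  components after truncating negatives at zero. The optional
  permutation test (default 999 shuffles, seeded) permutes population
  labels and compares σ²_among.
- **Nei identity/distance.** J's averaged over loci first,
  S = J_xy/√(J_x·J_y), D = −ln S (D = +∞ sentinel at S ≤ 0, unreachable
  for valid frequencies).
- **Trees.** NJ is Saitou–Nei via scikit-bio (exact on additive
  matrices); UPGMA is scipy average linkage, serialised to Newick with
  ultrametric node heights (merge distance / 2) so leaf-to-leaf path
  lengths equal cophenetic distances, and cut at a distance (or 1 − S
  similarity) threshold for cluster assignments. Band-based distances
  between taxa default to simple matching (Jaccard available) — the
  choice used for species-level dominant scoring is genuinely
  convention-dependent, so it is configurable and no printed
  species-tree similarity is asserted.
- **PCoA.** Gower double-centering of −d²/2, symmetric
  eigendecomposition, coordinates eigenvector·√λ for positive
  eigenvalues only; axis percentages normalise over the positive
  eigenvalue sum (so they total 100% even when negative eigenvalues
  exist). This is authored directly rather than delegated because the
  negative-eigenvalue and normalisation conventions are part of the
  module contract.

## Synthetic data: what it emulates, and what it does not

The genome generator places genes with alternating exons (150–400 bp)
and introns (90–290 bp, inside the standard 80–300 bp design window)
separated by 200–600 bp intergenic stretches of uniform-GC random
sequence, one transcript per gene, and records every intron exactly.
The variant generator plants signed indels (default ±3–50 bp, the
PAGE-resolvable range within the product window) at intron midpoints
and, optionally, exonic point mutations at a stated per-base rate.
The population generator draws per-deme allele frequencies from the
Balding–Nichols Dirichlet (concentration p·(1−Fst)/Fst) around
uniform-Dirichlet ancestral frequencies, genotypes with inbreeding
coefficient `fis` (autozygous with probability fis), and missing calls
at a stated rate. All generators are deterministic under their seed.

Passing tests on these systems demonstrate the pipeline's correctness
(coordinate arithmetic, search completeness, estimator calibration),
not field realism: real genomes have repeat families, GC heterogeneity,
alternative isoforms, paralogy, and linkage among loci, none of which
the generators model. Cross-genome screening of real assemblies will
produce far more multi-band and dropout profiles than the clean
synthetic pairs.

## Problem sizes and numerical choices

Bundled checks run on deliberately small instances chosen to exercise
every code path: 2-chromosome / 20-gene genomes (~35 kb), ~40 designed
pairs, 20-instance oracle comparisons, Fst recovery at 20 loci × 3
populations × 200 individuals (5 replicate simulations averaged in the
acceptance script to reduce Monte Carlo error), AMOVA at the 55/30/91
three-population layout. Determinism: every stochastic routine takes an
explicit seed; ties in design and search break lexicographically;
AMOVA permutations use a dedicated generator. Degenerate inputs follow
the rule "empty is an answer, inconsistent is an error": zero binding
sites, monomorphic loci, or a threshold outside the observed similarity
range return empty/identity results, while non-symmetric matrices,
populations of size < 2, or unknown sequence ids raise.

## Known limitations

- RNA/transcript-database screening (used in some published marker
  filters alongside genomic ePCR) is not implemented; marker counts on
  real data are therefore not expected to match published totals.
- One primer pair is emitted per intron (the published pipelines'
  pair-per-intron mapping is unstated).
- Introns are not deduplicated across overlapping genes; one record
  per (gene, primary transcript, index).
- No thermodynamic duplex model, degenerate bases, or circular
  templates in ePCR; no bootstrap supports on trees; no Bayesian
  admixture inference (cluster-count selection belongs to dedicated
  tools).
- Overall cross-transferability is reported under two aggregations
  (cell-wise and unweighted family mean) because published summaries
  are ambiguous about which is meant; neither is privileged.
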