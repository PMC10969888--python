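"""Synthetic study systems with known ground truth.

Three generators cover the pipeline end to end without any external data:

* annotated toy genomes (FASTA + GFF3) whose intron coordinates and
  lengths are recorded exactly;
* variant genomes derived from a base genome by planting intron indels
  (introns evolve faster than exons, so length differences concentrate
  there) and, optionally, exonic point mutations that degrade primer
  binding sites;
* multi-population codominant genotype tables drawn under the
  Balding-Nichols model at a chosen differentiation level (Fst), with a
  within-population inbreeding coefficient and a missing-data rate.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GeneModel, IntronRecord, SequenceRecord, Transcript
from .popgen import BandMatrix, GenotypeTable

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimGenomeConfig:
    """Dimensions and length distributions of a simulated annotated genome.

    Intron lengths default to the 90-290 bp range so that every intron
    falls inside the standard [80, 300] design-targeting window.
    """

    seed: int
    n_chromosomes: int = 2
    genes_per_chromosome: int = 10
    exons_per_gene: tuple[int, int] = (2, 4)       # inclusive range
    exon_len: tuple[int, int] = (150, 400)
    intron_len: tuple[int, int] = (90, 290)
    intergenic_len: tuple[int, int] = (200, 600)
    gc: float = 0.5

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name}: need 0 < lo <= hi")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data."""

    introns: pd.DataFrame = field(default_factory=pd.DataFrame)
    # variant genomes: one row per planted indel
    indels: pd.DataFrame = field(default_factory=pd.DataFrame)
    # population simulation
    ancestral_freqs: dict = field(default_factory=dict)
    population_freqs: dict = field(default_factory=dict)
    target_fst: float | None = None
    fis: float | None = None


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def simulate_annotated_genome(
    config: SimGenomeConfig,
) -> tuple[list[SequenceRecord], list[GeneModel], SimTruth]:
    """Genes with alternating exons and introns placed without overlap.

    Returns the genome sequences, the gene models (one transcript per
    gene), and a truth table with one row per intron.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    models: list[GeneModel] = []
    truth_rows = []
    gene_no = 0
    for c in range(config.n_chromosomes):
        seq_id = f"chr{c + 1}"
        parts: list[str] = []
        pos = 0
        for _ in range(config.genes_per_chromosome):
            gene_no += 1
            gid, tid = f"gene{gene_no:03d}", f"gene{gene_no:03d}.t1"
            gap = int(rng.integers(*config.intergenic_len, endpoint=True))
            parts.append(_random_seq(rng, gap, config.gc))
            pos += gap
            n_exons = int(rng.integers(*config.exons_per_gene, endpoint=True))
            exons: list[tuple[int, int]] = []
            for e in range(n_exons):
                if e > 0:
                    ilen = int(rng.integers(*config.intron_len, endpoint=True))
                    istart = pos
                    parts.append(_random_seq(rng, ilen, config.gc))
                    pos += ilen
                    truth_rows.append({
                        "gene_id": gid, "transcript_id": tid, "intron_index": e,
                        "seq_id": seq_id, "start": istart, "end": pos,
                        "length": ilen,
                    })
                elen = int(rng.integers(*config.exon_len, endpoint=True))
                exons.append((pos, pos + elen))
                parts.append(_random_seq(rng, elen, config.gc))
                pos += elen
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(GeneModel(gid, seq_id, strand,
                                    (Transcript(tid, tuple(exons)),)))
        tail = int(rng.integers(*config.intergenic_len, endpoint=True))
        parts.append(_random_seq(rng, tail, config.gc))
        records.append(SequenceRecord(seq_id, "".join(parts)))
    truth = SimTruth(introns=pd.DataFrame(truth_rows))
    return records, models, truth


def derive_variant_genome(
    genome: list[SequenceRecord],
    truth: SimTruth,
    intron_indel_spec: int | list[tuple[str, int, int]],
    primer_site_mutation_rate: float = 0.0,
    seed: int = 0,
    indel_sizes: tuple[int, int] = (3, 50),
    models: list[GeneModel] | None = None,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Plant intron length changes (and optional exonic point mutations)
    into a copy of a simulated genome.

    ``intron_indel_spec`` is either a number of introns to mutate (chosen
    uniformly, signed sizes uniform over +-[indel_sizes]) or an explicit
    list of (gene_id, intron_index, signed_delta). Deletions must leave
    at least 1 bp of intron. Exon mutations require ``models``.
    """
    rng = np.random.default_rng(seed)
    introns = truth.introns
    if isinstance(intron_indel_spec, int):
        if intron_indel_spec > len(introns):
            raise ValueError("more indels requested than introns available")
        idx = rng.choice(len(introns), size=intron_indel_spec, replace=False)
        spec = []
        for i in sorted(idx):
            row = introns.iloc[i]
            size = int(rng.integers(indel_sizes[0], indel_sizes[1], endpoint=True))
            sign = 1 if rng.random() < 0.5 else -1
            if sign < 0 and size >= row["length"]:
                size = int(row["length"]) - 1
            spec.append((row["gene_id"], int(row["intron_index"]), sign * size))
    else:
        spec = list(intron_indel_spec)

    lookup = introns.set_index(["gene_id", "intron_index"])
    edits: dict[str, list[tuple[int, int, str]]] = {}  # seq_id -> (start, end, repl)
    indel_rows = []
    for gene_id, intron_index, delta in spec:
        row = lookup.loc[(gene_id, intron_index)]
        length = int(row["length"])
        if delta < 0 and -delta >= length:
            raise ValueError(
                f"deletion of {-delta} bp exceeds intron length {length} "
                f"({gene_id} intron {intron_index})")
        mid = int(row["start"]) + length // 2
        if delta >= 0:
            repl = _random_seq(rng, delta, 0.5)
            edits.setdefault(row["seq_id"], []).append((mid, mid, repl))
        else:
            edits.setdefault(row["seq_id"], []).append((mid, mid - delta, ""))
        indel_rows.append({
            "gene_id": gene_id, "intron_index": intron_index,
            "seq_id": row["seq_id"], "delta": delta,
            "new_length": length + delta,
        })

    exon_mut_rows = []
    if primer_site_mutation_rate > 0:
        if models is None:
            raise ValueError("exon mutations require gene models")
        for m in models:
            for t in m.transcripts:
                for (s, e) in t.exons:
                    n_mut = rng.binomial(e - s, primer_site_mutation_rate)
                    for p in rng.choice(e - s, size=n_mut, replace=False):
                        pos = s + int(p)
                        edits.setdefault(m.seq_id, []).append((pos, pos + 1, "*"))

    out_records = []
    for rec in genome:
        seq = rec.sequence
        evs = sorted(edits.get(rec.seq_id, []), key=lambda x: x[0], reverse=True)
        for start, end, repl in evs:
            if repl == "*":  # point mutation to a different base
                old = seq[start]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                repl = new
            seq = seq[:start] + repl + seq[end:]
        out_records.append(SequenceRecord(rec.seq_id, seq))
    new_truth = SimTruth(
        introns=truth.introns.copy(),
        indels=pd.DataFrame(indel_rows),
        ancestral_freqs=truth.ancestral_freqs,
        population_freqs=truth.population_freqs,
        target_fst=truth.target_fst,
        fis=truth.fis,
    )
    return out_records, new_truth


# ---------------------------------------------------------------------------
# Population genotypes
# ---------------------------------------------------------------------------

def simulate_population_genotypes(
    n_loci: int = 40,
    n_pops: int = 3,
    n_per_pop: int | list[int] = 50,
    target_fst: float = 0.05,
    fis: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    alleles_per_locus: tuple[int, int] = (2, 6),
) -> tuple[GenotypeTable, SimTruth]:
    """Draw codominant genotypes for several populations under the
    Balding-Nichols model.

    Ancestral allele frequencies per locus are uniform-Dirichlet; each
    population's frequencies are Dirichlet(p * (1 - Fst)/Fst) around the
    ancestral vector (Fst = 0 copies the ancestral frequencies).
    Within a population, an individual is autozygous (one allele drawn,
    doubled) with probability ``fis``, otherwise two alleles are drawn
    independently. Allele labels are band sizes in bp.
    """
    if not (0.0 <= target_fst < 1.0):
        raise ValueError("target_fst must be in [0, 1)")
    if not (0.0 <= fis <= 1.0):
        raise ValueError("fis must be in [0, 1]")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sizes = [n_per_pop] * n_pops if isinstance(n_per_pop, int) else list(n_per_pop)
    if len(sizes) != n_pops or any(s < 2 for s in sizes):
        raise ValueError("need a size >= 2 for each population")
    pops = [f"pop{i + 1}" for i in range(n_pops)]
    loci = [f"L{i + 1:03d}" for i in range(n_loci)]

    ancestral: dict = {}
    per_pop: dict = {p: {} for p in pops}
    allele_labels: dict = {}
    for li, locus in enumerate(loci):
        k = int(rng.integers(alleles_per_locus[0], alleles_per_locus[1],
                             endpoint=True))
        labels = [100 + 10 * li + a for a in range(k)]  # band sizes, bp
        allele_labels[locus] = labels
        p = rng.dirichlet(np.ones(k))
        ancestral[locus] = pd.Series(p, index=labels)
        for pop in pops:
            if target_fst == 0.0:
                q = p.copy()
            else:
                conc = p * (1.0 - target_fst) / target_fst
                q = rng.dirichlet(np.maximum(conc, 1e-9))
            per_pop[pop][locus] = pd.Series(q, index=labels)

    index, pop_labels = [], []
    for pop, size in zip(pops, sizes):
        for i in range(size):
            index.append(f"{pop}_ind{i + 1:03d}")
            pop_labels.append(pop)
    data: dict = {}
    for locus in loci:
        labels = allele_labels[locus]
        col = []
        for pop, size in zip(pops, sizes):
            q = per_pop[pop][locus].to_numpy()
            for _ in range(size):
                if missing_rate > 0 and rng.random() < missing_rate:
                    col.append(None)
                    continue
                if rng.random() < fis:
                    a = labels[int(rng.choice(len(labels), p=q))]
                    col.append((a, a))
                else:
                    i1 = labels[int(rng.choice(len(labels), p=q))]
                    i2 = labels[int(rng.choice(len(labels), p=q))]
                    col.append(tuple(sorted((i1, i2))))
        data[locus] = col
    df = pd.DataFrame(data, index=index)
    genos = GenotypeTable(df, pd.Series(pop_labels, index=index))
    truth = SimTruth(
        ancestral_freqs=ancestral, population_freqs=per_pop,
        target_fst=target_fst, fis=fis,
    )
    return genos, truth


def genotypes_to_bands(genos: GenotypeTable) -> BandMatrix:
    """Inverse of codominant band scoring: each allele becomes a band
    column; missing genotypes leave a locus's columns all zero."""
    columns: list[tuple] = []
    for locus in genos.loci:
        alleles = sorted({a for g in genos.df[locus] if g is not None for a in g})
        columns.extend((locus, a) for a in alleles)
    mi = pd.MultiIndex.from_tuples(columns, names=["locus", "band"])
    mat = pd.DataFrame(0, index=genos.df.index, columns=mi)
    for locus in genos.loci:
        for ind in genos.df.index:
            g = genos.df.at[ind, locus]
            if g is None:
                continue
            for a in g:
                mat.loc[ind, (locus, a)] = 1
    return BandMatrix(mat, genos.populations)
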