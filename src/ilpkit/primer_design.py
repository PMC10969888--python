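"""Primer-pair design on the exons flanking a target intron.

For every intron in the design window, candidate primers are enumerated on
the intron-proximal ends of both flanking exons, filtered by conventional
PCR constraints (length, GC, Tm, homopolymers, 3' rules), and the pair
minimising a transparent additive penalty is returned. The scorer is
deliberately simple and fully specified so that designs are reproducible:

    penalty = |Tm_f - Tm_r|
            + w_product * |product - product_opt|
            + w_tm * (|Tm_f - 60| + |Tm_r - 60|)

Ties break deterministically by (smaller product, forward sequence,
reverse sequence).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .genome_io import IntronRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: SantaLucia (1998) unified nearest-neighbour parameters.
#: (delta_H kcal/mol, delta_S cal/(mol*K)) per 5'->3' dinucleotide stack.
_NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
#: Duplex-initiation terms for terminal A/T and terminal G/C base pairs.
_NN_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}

_R_GAS = 1.987  # cal/(mol*K)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Fraction of G+C bases. N is not allowed."""
    if not seq:
        raise ValueError("empty sequence")
    if any(c not in "ACGT" for c in seq):
        raise ValueError(f"non-ACGT character in {seq!r}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(
    seq: str,
    method: str = "wallace",
    monovalent_mM: float = 50.0,
    oligo_uM: float = 0.5,
) -> float:
    """Oligo melting temperature in degrees Celsius.

    ``wallace``: the 2-4 rule, 2*(A+T) + 4*(G+C); adequate for ranking
    short primers and extremely fast.

    ``nearest_neighbor``: two-state model with the SantaLucia-1998 unified
    stack parameters, entropy salt correction 0.368*(N-1)*ln[Na+], and
    total strand concentration C_T/4 in the denominator. Defaults: 50 mM
    monovalent cation, 0.5 uM total oligo.
    """
    if not (10 <= len(seq) <= 36):
        raise ValueError("primer length must be in [10, 36]")
    if any(c not in "ACGT" for c in seq):
        raise ValueError(f"unsupported character in {seq!r}")
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return float(2 * at + 4 * gc)
    if method == "nearest_neighbor":
        dh, ds = 0.0, 0.0
        for end in (seq[0], seq[-1]):
            h, s = _NN_INIT[end]
            dh += h
            ds += s
        for i in range(len(seq) - 1):
            h, s = _NN_UNIFIED[seq[i : i + 2]]
            dh += h
            ds += s
        ds += 0.368 * (len(seq) - 1) * math.log(monovalent_mM / 1000.0)
        c_t = oligo_uM * 1e-6
        tm_k = (dh * 1000.0) / (ds + _R_GAS * math.log(c_t / 4.0))
        return tm_k - 273.15
    raise ValueError(f"unknown Tm method {method!r}")


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def has_3prime_selfcomp(seq: str, k: int = 4) -> bool:
    """True when the 3'-terminal k-mer is its own reverse complement,
    a configuration prone to primer-dimer extension."""
    tail = seq[-k:]
    return len(tail) == k and tail == reverse_complement(tail)


@dataclass(frozen=True)
class PrimerParams:
    """Primer constraint set and pair-scoring weights."""

    min_len: int = 18
    max_len: int = 27
    gc_min: float = 0.30
    gc_max: float = 0.70
    tm_min: float = 55.0
    tm_max: float = 65.0
    tm_method: str = "wallace"
    max_homopolymer: int = 4
    reject_3prime_at: bool = True
    selfcomp_3prime_len: int = 4
    margin_from_intron: int = 60
    product_min: int = 80
    product_max: int = 1200
    product_opt: int | None = None  # None: intron length + 100
    w_product: float = 0.02
    w_tm: float = 0.5


@dataclass(frozen=True)
class PrimerCandidate:
    """A filtered primer; ``start``/``end`` index the plus-strand window
    within the exon the candidate was enumerated on."""

    seq: str
    start: int
    end: int
    tm: float
    gc: float


@dataclass(frozen=True)
class PrimerPair:
    pair_id: str
    gene_id: str
    intron_index: int
    seq_id: str
    fwd_seq: str
    rev_seq: str
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    expected_product_bp: int
    source_genome: str = ""
    # plus-strand genomic coordinates of the two primer windows
    fwd_start: int = 0
    fwd_end: int = 0
    rev_start: int = 0
    rev_end: int = 0

    @property
    def intron_ref(self) -> tuple[str, int]:
        return (self.gene_id, self.intron_index)


def _passes_filters(primer: str, params: PrimerParams) -> tuple[bool, float, float]:
    if "N" in primer:
        return False, 0.0, 0.0
    gc = gc_content(primer)
    if not (params.gc_min <= gc <= params.gc_max):
        return False, 0.0, 0.0
    tm = melting_temperature(primer, params.tm_method)
    if not (params.tm_min <= tm <= params.tm_max):
        return False, 0.0, 0.0
    if max_homopolymer_run(primer) > params.max_homopolymer:
        return False, 0.0, 0.0
    if params.reject_3prime_at and primer[-1] in "AT":
        return False, 0.0, 0.0
    if has_3prime_selfcomp(primer, params.selfcomp_3prime_len):
        return False, 0.0, 0.0
    return True, tm, gc


def enumerate_candidate_primers(
    exon_seq: str, side: str, params: PrimerParams | None = None
) -> list[PrimerCandidate]:
    """All acceptable primers of length [min_len, max_len] whose
    intron-proximal end lies within ``margin_from_intron`` bases of the
    exon edge bordering the intron.

    ``side="left"`` enumerates forward primers (plus strand, 3' end near
    the exon's right edge); ``side="right"`` enumerates reverse primers
    (reverse complement of a plus-strand window whose left edge is near
    the exon's left edge).
    """
    params = params or PrimerParams()
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    n = len(exon_seq)
    out: list[PrimerCandidate] = []
    if n < params.min_len:
        return out
    for length in range(params.min_len, params.max_len + 1):
        if side == "left":
            # window [s, s+length); require n - (s+length) < margin
            lo = max(0, n - params.margin_from_intron - length + 1)
            for s in range(lo, n - length + 1):
                window = exon_seq[s : s + length]
                ok, tm, gc = _passes_filters(window, params)
                if ok:
                    out.append(PrimerCandidate(window, s, s + length, tm, gc))
        else:
            hi = min(n - length, params.margin_from_intron - 1)
            for s in range(0, hi + 1):
                window = exon_seq[s : s + length]
                primer = reverse_complement(window)
                ok, tm, gc = _passes_filters(primer, params)
                if ok:
                    out.append(PrimerCandidate(primer, s, s + length, tm, gc))
    return out


def pair_penalty(
    fwd: PrimerCandidate, rev: PrimerCandidate, product_bp: int, params: PrimerParams,
    product_opt: int,
) -> float:
    return (
        abs(fwd.tm - rev.tm)
        + params.w_product * abs(product_bp - product_opt)
        + params.w_tm * (abs(fwd.tm - 60.0) + abs(rev.tm - 60.0))
    )


def design_pairs_for_intron(
    intron: IntronRecord, params: PrimerParams | None = None,
    source_genome: str = "",
) -> PrimerPair | None:
    """Best-scoring primer pair for one intron, or None when either flank
    yields no acceptable candidate or no pair satisfies the product window."""
    params = params or PrimerParams()
    fwd_cands = enumerate_candidate_primers(intron.left_exon_seq, "left", params)
    rev_cands = enumerate_candidate_primers(intron.right_exon_seq, "right", params)
    if not fwd_cands or not rev_cands:
        logger.info(
            "%s intron %d: no candidates (%d fwd, %d rev)",
            intron.gene_id, intron.intron_index, len(fwd_cands), len(rev_cands),
        )
        return None
    left_start = intron.left_exon_interval[0]
    right_start = intron.right_exon_interval[0]
    product_opt = params.product_opt if params.product_opt is not None \
        else intron.length + 100
    best: tuple | None = None
    for f in fwd_cands:
        f_gstart = left_start + f.start
        for r in rev_cands:
            r_gend = right_start + r.end
            product = r_gend - f_gstart
            if not (params.product_min <= product <= params.product_max):
                continue
            pen = pair_penalty(f, r, product, params, product_opt)
            key = (pen, product, f.seq, r.seq)
            if best is None or key < best[0]:
                best = (key, f, r, product, f_gstart, r_gend)
    if best is None:
        logger.info("%s intron %d: no pair in product window",
                    intron.gene_id, intron.intron_index)
        return None
    _, f, r, product, f_gstart, r_gend = best
    return PrimerPair(
        pair_id=f"{intron.gene_id}_i{intron.intron_index}",
        gene_id=intron.gene_id,
        intron_index=intron.intron_index,
        seq_id=intron.seq_id,
        fwd_seq=f.seq,
        rev_seq=r.seq,
        fwd_tm=f.tm,
        rev_tm=r.tm,
        fwd_gc=f.gc,
        rev_gc=r.gc,
        expected_product_bp=product,
        source_genome=source_genome,
        fwd_start=f_gstart,
        fwd_end=f_gstart + len(f.seq),
        rev_start=r_gend - len(r.seq),
        rev_end=r_gend,
    )


def design_primers(
    introns: list[IntronRecord], params: PrimerParams | None = None,
    source_genome: str = "",
) -> list[PrimerPair]:
    """One best pair per intron; introns without a viable pair are skipped."""
    pairs = []
    for intron in introns:
        pair = design_pairs_for_intron(intron, params, source_genome)
        if pair is not None:
            pairs.append(pair)
    return pairs


_TABLE_COLS = [
    "pair_id", "gene_id", "intron_index", "seq_id", "fwd_seq", "rev_seq",
    "fwd_tm", "rev_tm", "fwd_gc", "rev_gc", "expected_product_bp",
    "source_genome", "fwd_start", "fwd_end", "rev_start", "rev_end",
]


def write_primer_table(pairs: list[PrimerPair], path: str) -> None:
    df = pd.DataFrame([{c: getattr(p, c) for c in _TABLE_COLS} for p in pairs])
    df.to_csv(path, sep="\t", index=False)


def read_primer_table(path: str) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _int = {"intron_index", "expected_product_bp", "fwd_start", "fwd_end",
            "rev_start", "rev_end"}
    _float = {"fwd_tm", "rev_tm", "fwd_gc", "rev_gc"}
    pairs = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in _TABLE_COLS:
            v = row[c]
            kwargs[c] = int(v) if c in _int else float(v) if c in _float else str(v)
        pairs.append(PrimerPair(**kwargs))
    return pairs
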