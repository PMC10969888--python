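"""Electronic PCR: primer binding-site search, amplicon enumeration, and
cross-genome ILP polymorphism calling.

A primer binds where a banded alignment against the genome has at most
``n_max`` substitutions and ``g_max`` indels, with the 3'-terminal
``anchor_len`` bases matching exactly (polymerase extension requires a
matched 3' end). Amplicons are inward-facing site pairs within a product
size window, optionally constrained to lie within ``margin`` bp of the
expected product size when one is known for that genome.

Two search routes are provided. ``seeded`` locates exact occurrences of
the 3' anchor with C-level string scanning and verifies each with a banded
dynamic program; because every valid site must contain the exact anchor,
this route is complete. ``exhaustive`` runs an independent full
dynamic-programming scan at every genome position and exists as the
reference oracle; both must return identical site sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genome_io import SequenceRecord
from .primer_design import PrimerPair, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpcrParams:
    """ePCR screening parameters (mismatch/gap/anchor/size/margin)."""

    n_max: int = 4
    g_max: int = 2
    anchor_len: int = 3
    product_min: int = 80
    product_max: int = 1200
    margin: int = 60
    method: str = "seeded"


@dataclass(frozen=True)
class BindingSite:
    seq_id: str
    strand: str  # '+' or '-'
    start: int   # 0-based half-open, plus strand
    end: int
    mismatches: int
    gaps: int


@dataclass(frozen=True)
class Amplicon:
    genome_id: str
    seq_id: str
    start: int
    end: int
    fwd_site: BindingSite
    rev_site: BindingSite

    @property
    def product_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EpcrProfile:
    """Per-genome amplification outcome of one primer pair."""

    pair_id: str
    amplicons: dict[str, tuple[Amplicon, ...]]  # genome_id -> amplicons

    def band_count_class(self, genome_id: str) -> str:
        return classify_band_count(self.amplicons[genome_id])


@dataclass(frozen=True)
class MarkerRecord:
    marker_name: str
    pair_id: str
    product_sizes: dict[str, int | None]  # genome_id -> single-band size
    band_classes: dict[str, str]
    is_single_band_everywhere: bool
    is_polymorphic: bool
    intron_length_class: str = ""


# ---------------------------------------------------------------------------
# Binding-site search
# ---------------------------------------------------------------------------

def _banded_prefix_align(
    query: str, genome: str, origin: int, direction: int,
    n_max: int, g_max: int,
) -> tuple[int, int, int] | None:
    """Align ``query`` against the genome starting at ``origin`` and moving
    ``direction`` (+1 rightwards consuming query left-to-right; -1
    leftwards consuming query right-to-left).

    Returns the feasibility-filtered lexicographic minimum of
    (substitutions, gap_ops, genome_bases_consumed), or None when no
    alignment satisfies subs <= n_max and gaps <= g_max.
    """
    n = len(query)
    L = len(genome)
    # state: (inserts, deletes) -> min substitutions; insert = extra genome
    # base inside the alignment, delete = skipped query base. After i query
    # chars the genome has consumed (i - deletes) + inserts bases.
    states: dict[tuple[int, int], int] = {(0, 0): 0}
    for i in range(n):
        qc = query[i] if direction > 0 else query[n - 1 - i]
        nxt: dict[tuple[int, int], int] = {}

        def relax(key: tuple[int, int], cost: int) -> None:
            if cost <= n_max and cost < nxt.get(key, n_max + 1):
                nxt[key] = cost

        for (ins, dele), subs in states.items():
            budget = g_max - ins - dele
            # skip qc (deletion)
            if budget > 0:
                relax((ins, dele + 1), subs)
            # k genome insertions, then align qc to the next genome base
            for k in range(0, budget + 1):
                consumed = (i - dele) + ins + k
                gpos = origin + consumed if direction > 0 else origin - 1 - consumed
                if not (0 <= gpos < L):
                    continue
                relax((ins + k, dele), subs + (qc != genome[gpos]))
        if not nxt:
            return None
        states = nxt
    best: tuple[int, int, int] | None = None
    for (ins, dele), subs in states.items():
        glen = (n - dele) + ins
        lo = origin if direction > 0 else origin - glen
        if lo < 0 or lo + glen > L:
            continue
        cand = (subs, ins + dele, glen)
        if best is None or cand < best:
            best = cand
    return best


def _all_occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _sites_one_strand_seeded(
    primer: str, rec: SequenceRecord, strand: str,
    n_max: int, g_max: int, anchor_len: int,
) -> list[BindingSite]:
    g = rec.sequence
    a = anchor_len
    sites = []
    if strand == "+":
        anchor, prefix = primer[-a:], primer[:-a]
        for pos in _all_occurrences(g, anchor):
            e = pos + a
            res = _banded_prefix_align(prefix, g, pos, -1, n_max, g_max)
            if res is not None:
                subs, gaps, glen = res
                sites.append(BindingSite(rec.seq_id, "+", pos - glen, e, subs, gaps))
    else:
        q = reverse_complement(primer)
        anchor, suffix = q[:a], q[a:]
        for s in _all_occurrences(g, anchor):
            res = _banded_prefix_align(suffix, g, s + a, +1, n_max, g_max)
            if res is not None:
                subs, gaps, glen = res
                sites.append(BindingSite(rec.seq_id, "-", s, s + a + glen, subs, gaps))
    return sites


def _pareto_align(q: str, g: str, n_max: int, g_max: int) -> list[tuple[int, int]]:
    """Pareto-minimal (substitutions, gap_ops) for a full global alignment
    of q against g. Straightforward O(|q||g|) table of candidate sets;
    reference implementation only."""
    def prune(cands: set[tuple[int, int]]) -> set[tuple[int, int]]:
        keep = set()
        for c in cands:
            if c[0] > n_max or c[1] > g_max:
                continue
            if not any(d != c and d[0] <= c[0] and d[1] <= c[1] for d in cands):
                keep.add(c)
        return keep

    nq, ng = len(q), len(g)
    table: list[list[set]] = [[set() for _ in range(ng + 1)] for _ in range(nq + 1)]
    table[0][0] = {(0, 0)}
    for i in range(nq + 1):
        for j in range(ng + 1):
            if i == 0 and j == 0:
                continue
            cands: set[tuple[int, int]] = set()
            if i > 0 and j > 0:
                for s, gp in table[i - 1][j - 1]:
                    cands.add((s + (q[i - 1] != g[j - 1]), gp))
            if i > 0:
                for s, gp in table[i - 1][j]:
                    cands.add((s, gp + 1))
            if j > 0:
                for s, gp in table[i][j - 1]:
                    cands.add((s, gp + 1))
            table[i][j] = prune(cands)
    return sorted(table[nq][ng])


def _sites_one_strand_exhaustive(
    primer: str, rec: SequenceRecord, strand: str,
    n_max: int, g_max: int, anchor_len: int,
) -> list[BindingSite]:
    g = rec.sequence
    a = anchor_len
    sites = []
    if strand == "+":
        anchor, prefix = primer[-a:], primer[:-a]
        n = len(prefix)
        for e in range(a, len(g) + 1):
            if g[e - a : e] != anchor:
                continue
            best = None
            for glen in range(max(0, n - g_max), n + g_max + 1):
                lo = e - a - glen
                if lo < 0:
                    continue
                for subs, gaps in _pareto_align(prefix, g[lo : e - a], n_max, g_max):
                    cand = (subs, gaps, glen)
                    if best is None or cand < best:
                        best = cand
            if best is not None:
                subs, gaps, glen = best
                sites.append(BindingSite(rec.seq_id, "+", e - a - glen, e, subs, gaps))
    else:
        q = reverse_complement(primer)
        anchor, suffix = q[:a], q[a:]
        n = len(suffix)
        for s in range(0, len(g) - a + 1):
            if g[s : s + a] != anchor:
                continue
            best = None
            for glen in range(max(0, n - g_max), n + g_max + 1):
                hi = s + a + glen
                if hi > len(g):
                    continue
                for subs, gaps in _pareto_align(suffix, g[s + a : hi], n_max, g_max):
                    cand = (subs, gaps, glen)
                    if best is None or cand < best:
                        best = cand
            if best is not None:
                subs, gaps, glen = best
                sites.append(BindingSite(rec.seq_id, "-", s, s + a + glen, subs, gaps))
    return sites


def find_binding_sites(
    primer: str,
    genome: SequenceRecord | list[SequenceRecord],
    n_max: int = 4,
    g_max: int = 2,
    anchor_len: int = 3,
    method: str = "seeded",
) -> list[BindingSite]:
    """All binding sites of ``primer`` on both strands of the genome.

    One site is reported per exact 3'-anchor placement; its extent and
    mismatch/gap counts come from the best (fewest substitutions, then
    fewest gaps, then shortest) feasible alignment at that placement.
    """
    if len(primer) < anchor_len + 1:
        raise ValueError("primer shorter than anchor_len + 1")
    records = genome if isinstance(genome, list) else [genome]
    impl = _sites_one_strand_seeded if method == "seeded" \
        else _sites_one_strand_exhaustive
    sites: list[BindingSite] = []
    for rec in records:
        for strand in "+-":
            sites.extend(impl(primer, rec, strand, n_max, g_max, anchor_len))
    return sorted(sites, key=lambda s: (s.seq_id, s.start, s.end, s.strand))


# ---------------------------------------------------------------------------
# Amplicons
# ---------------------------------------------------------------------------

def enumerate_amplicons(
    pair: PrimerPair,
    genome: SequenceRecord | list[SequenceRecord],
    genome_id: str = "",
    params: EpcrParams | None = None,
    expected_product_bp: int | None = None,
) -> list[Amplicon]:
    """All inward-facing amplicons of a primer pair on a genome.

    Either primer may bind upstream. Products outside
    [product_min, product_max] are dropped; when ``expected_product_bp``
    is given (the pair's own source genome), products further than
    ``margin`` bp from it are dropped too. Overlapping primer footprints
    are rejected.
    """
    params = params or EpcrParams()
    records = genome if isinstance(genome, list) else [genome]
    fwd_sites = find_binding_sites(
        pair.fwd_seq, records, params.n_max, params.g_max,
        params.anchor_len, params.method)
    rev_sites = find_binding_sites(
        pair.rev_seq, records, params.n_max, params.g_max,
        params.anchor_len, params.method)
    out: list[Amplicon] = []
    for up_sites, down_sites in ((fwd_sites, rev_sites), (rev_sites, fwd_sites)):
        for up in up_sites:
            if up.strand != "+":
                continue
            for down in down_sites:
                if down.strand != "-" or down.seq_id != up.seq_id:
                    continue
                if down.start < up.end:  # overlapping or outward footprints
                    continue
                product = down.end - up.start
                if not (params.product_min <= product <= params.product_max):
                    continue
                if expected_product_bp is not None and \
                        abs(product - expected_product_bp) > params.margin:
                    continue
                # keep fwd/rev roles as designed regardless of orientation
                fwd_site, rev_site = (up, down) if up_sites is fwd_sites \
                    else (down, up)
                out.append(Amplicon(genome_id, up.seq_id, up.start, down.end,
                                    fwd_site, rev_site))
    # orientation loop can rediscover the same interval; deduplicate
    seen, uniq = set(), []
    for amp in sorted(out, key=lambda x: (x.seq_id, x.start, x.end)):
        key = (amp.seq_id, amp.start, amp.end)
        if key not in seen:
            seen.add(key)
            uniq.append(amp)
    return uniq


def classify_band_count(amplicons: list[Amplicon] | tuple[Amplicon, ...]) -> str:
    """Band-count class: "0", "1", "2", "3", or ">3"."""
    n = len(amplicons)
    return str(n) if n <= 3 else ">3"


def screen_genomes(
    pairs: list[PrimerPair],
    genomes: dict[str, list[SequenceRecord]],
    params: EpcrParams | None = None,
    apply_expected_margin_to_source: bool = True,
) -> list[EpcrProfile]:
    """Run ePCR for every pair against every genome.

    The expected-size margin constraint applies only on a pair's own
    source genome (where an expected product size exists); foreign
    genomes are constrained by the absolute size window alone.
    """
    params = params or EpcrParams()
    profiles = []
    for pair in pairs:
        amps: dict[str, tuple[Amplicon, ...]] = {}
        for gid, records in genomes.items():
            expected = pair.expected_product_bp if (
                apply_expected_margin_to_source and gid == pair.source_genome
            ) else None
            amps[gid] = tuple(enumerate_amplicons(pair, records, gid, params, expected))
        profiles.append(EpcrProfile(pair.pair_id, amps))
    return profiles


# ---------------------------------------------------------------------------
# Marker calling
# ---------------------------------------------------------------------------

def call_ilp_markers(
    profiles: list[EpcrProfile],
    min_size_diff: int = 1,
    prefix: str = "Tea_ILP",
    width: int = 4,
) -> list[MarkerRecord]:
    """Call ILP markers from multi-genome ePCR profiles.

    A pair is a candidate marker when it amplifies exactly one band in
    every screened genome; it is polymorphic when those single-band sizes
    span at least ``min_size_diff`` bp. Markers are named sequentially in
    input order.
    """
    if not profiles:
        return []
    genome_ids = list(profiles[0].amplicons.keys())
    if not genome_ids:
        raise ValueError("no genomes screened")
    markers: list[MarkerRecord] = []
    counter = 0
    for prof in profiles:
        classes = {g: prof.band_count_class(g) for g in genome_ids}
        single = all(c == "1" for c in classes.values())
        if not single:
            continue
        sizes = {g: prof.amplicons[g][0].product_bp for g in genome_ids}
        distinct = sorted(set(sizes.values()))
        polymorphic = len(distinct) >= 2 and \
            (distinct[-1] - distinct[0]) >= min_size_diff
        counter += 1
        markers.append(MarkerRecord(
            marker_name=f"{prefix}{counter:0{width}d}",
            pair_id=prof.pair_id,
            product_sizes=dict(sizes),
            band_classes=classes,
            is_single_band_everywhere=True,
            is_polymorphic=polymorphic,
        ))
    return markers


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_amplicon_table(profiles: list[EpcrProfile], path: str) -> None:
    rows = []
    for prof in profiles:
        for gid, amps in prof.amplicons.items():
            for a in amps:
                rows.append({
                    "pair_id": prof.pair_id, "genome_id": gid,
                    "seq_id": a.seq_id, "start": a.start, "end": a.end,
                    "product_bp": a.product_bp,
                    "fwd_mm": a.fwd_site.mismatches, "rev_mm": a.rev_site.mismatches,
                    "fwd_gaps": a.fwd_site.gaps, "rev_gaps": a.rev_site.gaps,
                })
    pd.DataFrame(rows, columns=[
        "pair_id", "genome_id", "seq_id", "start", "end", "product_bp",
        "fwd_mm", "rev_mm", "fwd_gaps", "rev_gaps",
    ]).to_csv(path, sep="\t", index=False)


def write_marker_table(markers: list[MarkerRecord], path: str) -> None:
    rows = []
    for m in markers:
        row = {
            "marker_name": m.marker_name, "pair_id": m.pair_id,
            "single_band_everywhere": int(m.is_single_band_everywhere),
            "polymorphic": int(m.is_polymorphic),
            "intron_length_class": m.intron_length_class,
        }
        for gid, size in m.product_sizes.items():
            row[f"size_{gid}"] = size
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
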