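"""Primer filtering, melting temperature, and pair scoring."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from ilpkit import insilico_pcr
from ilpkit.genome_io import IntronRecord
from ilpkit.primer_design import (
    PrimerParams,
    design_pairs_for_intron,
    enumerate_candidate_primers,
    gc_content,
    max_homopolymer_run,
    melting_temperature,
    pair_penalty,
    reverse_complement,
)


@pytest.mark.parametrize("seq, expected", [
    ("ATAT", 0.0), ("GCGC", 1.0), ("ACGT", 0.5),
])
def test_gc_content(seq, expected):
    assert gc_content(seq) == expected


def test_gc_content_rejects_n_and_empty():
    with pytest.raises(ValueError):
        gc_content("ACGN")
    with pytest.raises(ValueError):
        gc_content("")


@pytest.mark.parametrize("seq, expected", [
    ("ACGTACGTACGTACGTACGT", 60.0),  # 10 AT + 10 GC
    ("AAAAAAAAAA", 20.0),
])
def test_wallace_rule(seq, expected):
    assert melting_temperature(seq, "wallace") == expected


def test_nearest_neighbor_matches_independent_implementation():
    """SantaLucia unified-table Tm agrees within 1 degree C with an
    independently maintained implementation of the same published table."""
    rng = np.random.default_rng(17)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), 20))
        mine = melting_temperature(seq, "nearest_neighbor")
        ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, saltcorr=5,
                       dnac1=250, dnac2=250)
        assert abs(mine - ref) < 1.0


def test_melting_temperature_input_validation():
    with pytest.raises(ValueError):
        melting_temperature("ACG", "wallace")  # too short
    with pytest.raises(ValueError):
        melting_temperature("ACGTACGTACNT", "wallace")


def _oracle_candidates(exon, side, p):
    """Independent brute-force enumeration with the documented filters."""
    out = []
    n = len(exon)
    for length in range(p.min_len, p.max_len + 1):
        for s in range(0, n - length + 1):
            if side == "left" and (n - (s + length)) >= p.margin_from_intron:
                continue
            if side == "right" and s >= p.margin_from_intron:
                continue
            window = exon[s:s + length]
            primer = window if side == "left" else reverse_complement(window)
            if "N" in primer:
                continue
            gc = (primer.count("G") + primer.count("C")) / len(primer)
            if not (p.gc_min <= gc <= p.gc_max):
                continue
            tm = melting_temperature(primer, p.tm_method)
            if not (p.tm_min <= tm <= p.tm_max):
                continue
            if max_homopolymer_run(primer) > p.max_homopolymer:
                continue
            if p.reject_3prime_at and primer[-1] in "AT":
                continue
            tail = primer[-p.selfcomp_3prime_len:]
            if tail == reverse_complement(tail):
                continue
            out.append((primer, s, s + length))
    return sorted(out)


def test_candidate_enumeration_matches_bruteforce_oracle():
    rng = np.random.default_rng(23)
    params = PrimerParams()
    for _ in range(20):
        exon = "".join(rng.choice(list("ACGT"), int(rng.integers(18, 200))))
        for side in ("left", "right"):
            got = sorted(
                (c.seq, c.start, c.end)
                for c in enumerate_candidate_primers(exon, side, params))
            assert got == _oracle_candidates(exon, side, params)


def test_single_window_exon_and_hopeless_exon():
    assert enumerate_candidate_primers("A" * 30, "left") == []  # GC filter
    assert enumerate_candidate_primers("ACGT", "left") == []    # too short
    # an 18-mer exon has exactly one window; whether it survives depends
    # only on the filters, cross-checked against the oracle
    exon = "ACGTACGTAGCAGCTGCG"
    got = enumerate_candidate_primers(exon, "left")
    assert len(got) == len(_oracle_candidates(exon, "left", PrimerParams()))


def _make_intron(rng, intron_len=150, exon_len=200):
    left = "".join(rng.choice(list("ACGT"), exon_len))
    mid = "".join(rng.choice(list("ACGT"), intron_len))
    right = "".join(rng.choice(list("ACGT"), exon_len))
    start = exon_len
    return IntronRecord(
        gene_id="g", transcript_id="g.t1", intron_index=1, seq_id="chr1",
        start=start, end=start + intron_len, sequence=mid,
        left_exon_seq=left, right_exon_seq=right,
        left_exon_interval=(0, exon_len),
        right_exon_interval=(start + intron_len, start + intron_len + exon_len),
    ), left + mid + right


def test_design_returns_minimum_penalty_pair_vs_exhaustive():
    rng = np.random.default_rng(5)
    params = PrimerParams()
    checked = 0
    for _ in range(30):
        intron, _ = _make_intron(rng, int(rng.integers(90, 290)))
        pair = design_pairs_for_intron(intron, params)
        fw = enumerate_candidate_primers(intron.left_exon_seq, "left", params)
        rv = enumerate_candidate_primers(intron.right_exon_seq, "right", params)
        product_opt = intron.length + 100
        best = None
        for f in fw:
            for r in rv:
                product = (intron.right_exon_interval[0] + r.end) - f.start
                if not (params.product_min <= product <= params.product_max):
                    continue
                pen = pair_penalty(f, r, product, params, product_opt)
                if best is None or (pen, product, f.seq, r.seq) < best[:1] + best[1:]:
                    best = (pen, product, f.seq, r.seq)
        if best is None:
            assert pair is None
            continue
        assert pair is not None
        got_pen = pair_penalty(
            next(c for c in fw if c.seq == pair.fwd_seq and
                 c.start == pair.fwd_start),
            next(c for c in rv if pair.rev_seq == c.seq and
                 intron.right_exon_interval[0] + c.end == pair.rev_end),
            pair.expected_product_bp, params, product_opt)
        assert got_pen == pytest.approx(best[0])
        checked += 1
    assert checked >= 20


def test_design_is_deterministic():
    rng = np.random.default_rng(9)
    intron, _ = _make_intron(rng)
    a = design_pairs_for_intron(intron)
    b = design_pairs_for_intron(intron)
    assert a == b


def test_design_fails_gracefully_without_candidates():
    rng = np.random.default_rng(9)
    intron, _ = _make_intron(rng)
    from dataclasses import replace
    bad = replace(intron, left_exon_seq="A" * 200)
    assert design_pairs_for_intron(bad) is None


def test_designed_pair_round_trips_through_exact_epcr(sim_genome, sim_pairs):
    """Every designed pair amplifies exactly one product of exactly the
    expected size from its own unmutated genome under exact-match ePCR."""
    records, _, _ = sim_genome
    params = insilico_pcr.EpcrParams(n_max=0, g_max=0)
    for pair in sim_pairs:
        amps = insilico_pcr.enumerate_amplicons(
            pair, records, "base", params, pair.expected_product_bp)
        assert len(amps) == 1
        assert amps[0].product_bp == pair.expected_product_bp


def test_expected_product_equals_component_lengths(sim_introns, sim_pairs):
    by_ref = {(i.gene_id, i.intron_index): i for i in sim_introns}
    for pair in sim_pairs:
        intron = by_ref[pair.intron_ref]
        intervening_left = intron.left_exon_interval[1] - pair.fwd_end
        intervening_right = pair.rev_start - intron.right_exon_interval[0]
        assert pair.expected_product_bp == (
            len(pair.fwd_seq) + len(pair.rev_seq) + intron.length
            + intervening_left + intervening_right)
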