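"""Marker naming, genome-wide distribution summaries, intron-length
binning, and cross-species transferability statistics."""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .insilico_pcr import MarkerRecord

#: Intron-length histogram bins, inclusive on both printed ends.
LENGTH_BINS: tuple[tuple[int, float, str], ...] = (
    (1, 200, "1-200"),
    (201, 300, "201-300"),
    (301, 500, "301-500"),
    (501, float("inf"), ">500"),
)


def intron_length_class(length: int) -> str:
    for lo, hi, label in LENGTH_BINS:
        if lo <= length <= hi:
            return label
    raise ValueError(f"non-positive intron length {length}")


def assign_marker_names(
    records: list[MarkerRecord], prefix: str = "Tea_ILP", width: int = 4
) -> list[MarkerRecord]:
    """Zero-padded sequential names in input order (Tea_ILP0001, ...).

    Input pair_ids must be unique; the resulting naming is a bijection.
    """
    pair_ids = [r.pair_id for r in records]
    if len(set(pair_ids)) != len(pair_ids):
        raise ValueError("duplicate pair_ids in marker records")
    return [
        replace(r, marker_name=f"{prefix}{i:0{width}d}")
        for i, r in enumerate(records, start=1)
    ]


def marker_density(
    seq_ids: list[str], chrom_lengths: dict[str, int]
) -> tuple[pd.Series, float]:
    """Markers per Mb for each chromosome plus the genome-wide average
    (total count / total length).

    ``seq_ids``: the chromosome of each marker (one entry per marker).
    """
    counts = pd.Series(0, index=sorted(chrom_lengths), dtype=int)
    for sid in seq_ids:
        if sid not in chrom_lengths:
            raise KeyError(f"unknown seq_id {sid!r}")
        counts[sid] += 1
    lengths_mb = pd.Series(
        {k: v / 1e6 for k, v in chrom_lengths.items()}
    ).reindex(counts.index)
    per_chrom = counts / lengths_mb
    overall = len(seq_ids) / lengths_mb.sum()
    return per_chrom, float(overall)


def intron_length_bins(lengths: list[int]) -> dict[str, int]:
    """Histogram over the bins 1-200, 201-300, 301-500, >500."""
    hist = {label: 0 for _, _, label in LENGTH_BINS}
    for length in lengths:
        hist[intron_length_class(length)] += 1
    return hist


def band_count_histogram(classes: list[str]) -> dict[str, int]:
    hist = {c: 0 for c in ("0", "1", "2", "3", ">3")}
    for c in classes:
        hist[c] += 1
    return hist


@dataclass(frozen=True)
class TransferabilityRates:
    per_taxon: pd.Series        # fraction of markers amplifying, per taxon
    per_family: pd.Series       # amplified cells / (markers x taxa in family)
    overall_cellwise: float     # amplified cells / all cells
    overall_family_mean: float  # unweighted mean of per-family rates

    def as_percent(self) -> "TransferabilityRates":
        return TransferabilityRates(
            self.per_taxon * 100.0, self.per_family * 100.0,
            self.overall_cellwise * 100.0, self.overall_family_mean * 100.0,
        )


def transferability_rates(
    matrix: pd.DataFrame, taxon_family: dict[str, str]
) -> TransferabilityRates:
    """Cross-species transferability from a markers x taxa 0/1 table.

    Per-taxon rate = amplified markers / all markers; per-family rate pools
    cells over the family's taxa. Two overall aggregations are reported
    (cell-wise and unweighted mean of family rates) because published
    summaries are ambiguous about which is meant.
    """
    if matrix.empty:
        raise ValueError("empty transferability matrix")
    vals = matrix.to_numpy()
    if not ((vals == 0) | (vals == 1)).all():
        raise ValueError("transferability matrix must be binary")
    per_taxon = matrix.mean(axis=0)
    fam_rates = {}
    for fam in sorted(set(taxon_family.values())):
        taxa = [t for t in matrix.columns if taxon_family.get(t) == fam]
        sub = matrix[taxa]
        fam_rates[fam] = sub.to_numpy().sum() / sub.size
    per_family = pd.Series(fam_rates)
    overall = vals.sum() / vals.size
    return TransferabilityRates(
        per_taxon, per_family, float(overall), float(per_family.mean())
    )


def amplification_summary(
    counts: dict[str, tuple[int, int, int]]
) -> pd.DataFrame:
    """Per-origin (tested, amplified, polymorphic) counts -> summary table
    with percentages on the tested denominator, 2 decimals, plus a Total
    row.
    """
    rows = []
    tot_t = tot_a = tot_p = 0
    for origin, (tested, amplified, polymorphic) in counts.items():
        if tested <= 0:
            raise ValueError(f"{origin}: tested must be positive")
        if not (polymorphic <= amplified <= tested):
            raise ValueError(f"{origin}: require polymorphic <= amplified <= tested")
        rows.append({
            "origin": origin, "tested": tested, "amplified": amplified,
            "amplified_pct": round(100.0 * amplified / tested, 2),
            "polymorphic": polymorphic,
            "polymorphic_pct": round(100.0 * polymorphic / tested, 2),
        })
        tot_t += tested
        tot_a += amplified
        tot_p += polymorphic
    rows.append({
        "origin": "Total", "tested": tot_t, "amplified": tot_a,
        "amplified_pct": round(100.0 * tot_a / tot_t, 2),
        "polymorphic": tot_p,
        "polymorphic_pct": round(100.0 * tot_p / tot_t, 2),
    })
    return pd.DataFrame(rows)


def windowed_density_table(
    positions: dict[str, list[int]], chrom_lengths: dict[str, int],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Marker counts per fixed genomic window, one row per (chrom, window);
    a plain-text stand-in for circos-style density tracks."""
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        pos = sorted(positions.get(chrom, []))
        for start in range(0, length, window):
            end = min(start + window, length)
            n = sum(1 for p in pos if start <= p < end)
            rows.append({"seq_id": chrom, "start": start, "end": end, "count": n})
    return pd.DataFrame(rows)
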