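"""End-to-end marker development: extract introns from an annotated
source genome, design flanking-exon primer pairs, screen every genome by
electronic PCR, call polymorphic ILP markers, and summarise the catalog.

All outputs are plain-text tables plus a machine-readable manifest
sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

from . import __version__, genome_io, insilico_pcr, marker_catalog, primer_design
from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    introns: list
    pairs: list
    profiles: list
    markers: list
    summary: dict


def run_pipeline(
    config: PipelineConfig,
    source_fasta: str,
    source_gff: str,
    target_fastas: dict[str, str],
    outdir: str,
    source_id: str = "source",
) -> PipelineResult:
    """Run every stage in order, writing each intermediate table under
    ``outdir``. Stage failures propagate with the stage name attached."""
    os.makedirs(outdir, exist_ok=True)

    def stage(name: str, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    genome = stage("read-genome", genome_io.read_fasta, source_fasta)
    models = stage("read-annotation", genome_io.read_gff3, source_gff, genome)
    introns = stage(
        "extract-introns", genome_io.extract_introns, genome, models,
        config.min_intron_len, config.max_intron_len)
    genome_io.write_intron_table(introns, os.path.join(outdir, "introns.tsv"))

    pairs = stage("design-primers", primer_design.design_primers,
                  introns, config.primer_params(), source_id)
    primer_design.write_primer_table(pairs, os.path.join(outdir, "primers.tsv"))

    genomes = {source_id: genome}
    for gid, path in target_fastas.items():
        genomes[gid] = stage(f"read-target:{gid}", genome_io.read_fasta, path)
    profiles = stage("epcr", insilico_pcr.screen_genomes, pairs, genomes,
                     config.epcr_params())
    insilico_pcr.write_amplicon_table(
        profiles, os.path.join(outdir, "amplicons.tsv"))

    markers = stage("call-markers", insilico_pcr.call_ilp_markers, profiles,
                    config.min_size_diff, config.marker_prefix,
                    config.marker_width)
    # annotate markers with their target intron's length class
    intron_len = {(i.gene_id, i.intron_index): i.length for i in introns}
    pair_ref = {p.pair_id: p.intron_ref for p in pairs}
    markers = [
        insilico_pcr.MarkerRecord(
            m.marker_name, m.pair_id, m.product_sizes, m.band_classes,
            m.is_single_band_everywhere, m.is_polymorphic,
            marker_catalog.intron_length_class(intron_len[pair_ref[m.pair_id]]),
        )
        for m in markers
    ]
    insilico_pcr.write_marker_table(markers, os.path.join(outdir, "markers.tsv"))

    chrom_lengths = {r.seq_id: r.length for r in genome}
    pair_seq = {p.pair_id: p.seq_id for p in pairs}
    marker_seq_ids = [pair_seq[m.pair_id] for m in markers]
    per_chrom, avg_density = marker_catalog.marker_density(
        marker_seq_ids, chrom_lengths)
    summary = {
        "n_introns": len(introns),
        "n_primer_pairs": len(pairs),
        "n_markers_single_band": len(markers),
        "n_markers_polymorphic": sum(m.is_polymorphic for m in markers),
        "density_per_mb": {k: round(v, 4) for k, v in per_chrom.items()},
        "avg_density_per_mb": round(avg_density, 4),
        "intron_length_bins": marker_catalog.intron_length_bins(
            [i.length for i in introns]),
        "band_count_histogram": marker_catalog.band_count_histogram(
            [p.band_count_class(g) for p in profiles for g in p.amplicons]),
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)

    cfg_hash = hashlib.sha256(
        json.dumps(config.as_dict(), sort_keys=True).encode()).hexdigest()[:16]
    manifest = {
        "ilpkit_version": __version__,
        "config": config.as_dict(),
        "config_sha256": cfg_hash,
        "inputs": {
            "source_fasta": source_fasta, "source_gff": source_gff,
            "targets": target_fastas,
        },
        "outputs": ["introns.tsv", "primers.tsv", "amplicons.tsv",
                    "markers.tsv", "summary.json"],
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(introns, pairs, profiles, markers, summary)
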