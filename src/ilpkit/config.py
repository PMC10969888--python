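"""Pipeline configuration: every tunable of the marker-development
pipeline with validated defaults, loadable from a YAML mapping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
import logging

import yaml

from .insilico_pcr import EpcrParams
from .primer_design import PrimerParams

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # intron design-targeting window (bp)
    min_intron_len: int = 80
    max_intron_len: int = 300
    # primer constraints
    primer_min_len: int = 18
    primer_max_len: int = 27
    gc_min: float = 0.30
    gc_max: float = 0.70
    tm_min: float = 55.0
    tm_max: float = 65.0
    tm_method: str = "wallace"
    max_homopolymer: int = 4
    margin_from_intron: int = 60
    # ePCR screening
    mismatch: int = 4
    gap: int = 2
    anchor_len: int = 3
    epcr_margin: int = 60
    product_min: int = 80
    product_max: int = 1200
    # marker calling
    min_size_diff: int = 1
    marker_prefix: str = "Tea_ILP"
    marker_width: int = 4
    # statistics
    band_distance_metric: str = "simple_matching"
    amova_permutations: int = 999
    levene_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        def req(cond: bool, key: str, msg: str) -> None:
            if not cond:
                raise ValueError(f"config key {key!r}: {msg}")

        req(0 < self.min_intron_len <= self.max_intron_len,
            "min_intron_len", "need 0 < min <= max_intron_len")
        req(10 <= self.primer_min_len <= self.primer_max_len <= 36,
            "primer_min_len", "need 10 <= min <= max <= 36")
        req(0.0 <= self.gc_min <= self.gc_max <= 1.0, "gc_min",
            "need 0 <= gc_min <= gc_max <= 1")
        req(self.tm_min <= self.tm_max, "tm_min", "need tm_min <= tm_max")
        req(self.tm_method in ("wallace", "nearest_neighbor"), "tm_method",
            "must be wallace or nearest_neighbor")
        req(self.mismatch >= 0, "mismatch", "must be >= 0")
        req(self.gap >= 0, "gap", "must be >= 0")
        req(self.anchor_len >= 1, "anchor_len", "must be >= 1")
        req(0 < self.product_min <= self.product_max, "product_min",
            "need 0 < product_min <= product_max")
        req(self.min_size_diff >= 1, "min_size_diff", "must be >= 1")
        req(self.amova_permutations >= 0, "amova_permutations", "must be >= 0")
        req(self.band_distance_metric in ("simple_matching", "jaccard"),
            "band_distance_metric", "must be simple_matching or jaccard")

    def primer_params(self) -> PrimerParams:
        return PrimerParams(
            min_len=self.primer_min_len, max_len=self.primer_max_len,
            gc_min=self.gc_min, gc_max=self.gc_max,
            tm_min=self.tm_min, tm_max=self.tm_max, tm_method=self.tm_method,
            max_homopolymer=self.max_homopolymer,
            margin_from_intron=self.margin_from_intron,
            product_min=self.product_min, product_max=self.product_max,
        )

    def epcr_params(self) -> EpcrParams:
        return EpcrParams(
            n_max=self.mismatch, g_max=self.gap, anchor_len=self.anchor_len,
            product_min=self.product_min, product_max=self.product_max,
            margin=self.epcr_margin,
        )

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | None = None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file and/or keyword overrides.

    Unknown keys are rejected by name; the effective configuration is
    echoed to the log.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: expected a YAML mapping")
            data.update(loaded)
    data.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    logger.info("effective config: %s", cfg.as_dict())
    return cfg
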