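"""Run configuration: every tunable threshold of the two genotyping methods,
with its standard default, plus platform presets and YAML round-tripping."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from .irr import PLATFORM_PRESETS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of a genotyping run.

    Defaults are the standard operating values of the methods: a 250-kb
    barcode search window, 1-kb minimum molecule length, 10-kb maximum
    molecule-to-locus boundary distance, 1-kb JI flanks with 5-kb collection
    windows, E = 200 nearest profiles, F = 4 (small grid) / 200 (large
    grid), and interval grids of 200–4,000 bp (step 100) and 5,000–40,000 bp
    (step 500).
    """

    platform: str = "10x"                  # 10x | stlfr | tellseq
    barcode_encoding: str | None = None    # None -> platform preset / auto
    # barcode selection
    window_bp: int = 250_000
    min_molecule_bp: int = 1_000
    max_boundary_distance_bp: int = 10_000
    split_gap_bp: int = 50_000
    # IRR classification & sizing
    max_impurity: float = 0.0
    i_definition: str = "2p+a"
    haplotype_depth: str = "haplotype"     # haplotype | diploid | half
    min_anchor_bases: int = 20
    # JI estimation
    flank_bp: int = 1_000
    collect_bp: int = 5_000
    e_nearest: int = 200
    f_small: float = 4.0
    f_large: float = 200.0
    grid_small: tuple[int, int, int] = (200, 4_000, 100)     # start, stop, step
    grid_large: tuple[int, int, int] = (5_000, 40_000, 500)
    containment: bool = True
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORM_PRESETS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.barcode_encoding is None:
            self.barcode_encoding = PLATFORM_PRESETS[self.platform]["barcode_encoding"]

    @property
    def read_lengths(self) -> tuple[int, ...]:
        return PLATFORM_PRESETS[self.platform]["read_lengths"]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_small"] = list(self.grid_small)
        d["grid_large"] = list(self.grid_large)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("grid_small", "grid_large"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def log_resolved(self) -> None:
        """Log the full resolved configuration (reproducibility contract)."""
        logger.info("resolved run configuration:\n%s",
                    yaml.safe_dump(self.to_dict(), sort_keys=True))
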