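"""Pipeline configuration.

Every threshold used by the discovery, target, prominence and phasing stages
lives here (never as a code constant), so sensitivity analyses are single-flag
changes.  The defaults are the study's published cut-offs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # small-RNA candidate filter
    mirna_min_len: int = 20
    mirna_max_len: int = 24
    stringent_min_tp2m: float = 10.0
    homology_min_tp2m: float = 1.0
    max_genome_hits: int = 20
    tp2m_basis: str = "genome_matched"  # or "raw"

    # precursor evaluation
    strand_bias_min: float = 0.9
    abundance_bias_min_stringent: float = 0.7
    abundance_bias_min_homology: float = 0.4
    max_defects_stringent: int = 4
    max_bulge_len_stringent: int = 1
    max_defects_homology: int = 8
    max_bulge_len_homology: int | None = None  # unlimited on the homology route
    homology_window_upstream: int = 150
    homology_window_downstream: int = 150
    merge_distance: int = 100

    # naming
    naming_max_mismatches: int = 2
    manual_family_max_mismatches: int = 3

    # target scoring presets: name -> (scheme, max_score)
    target_presets: dict = field(
        default_factory=lambda: {
            "cleaveland": ("uniform", 7.0),
            "cleaveland_m": ("core-weighted", 4.0),
            "expectation": ("uniform", 5.0),
        }
    )

    # PARE processing / prominence criteria
    pare_tag_length: int = 20
    low_complexity_max_run: int = 12
    low_complexity_on_tag: bool = True  # filter inspects the tag itself
    abundance_cutoff_tp10m: float = 10.0
    rank_cutoff: int = 2
    peak_cutoff_percent: float = 20.0
    peak_variant: str = "top2"  # or "site"

    # phasing
    phasing_min_score: float = 25.0
    phasing_edge_score: float = 20.0
    phasing_locus_max_gap_cycles: int = 2
    trigger_window_cycles: int = 5
    trigger_max_score: float = 5.0
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    strict_register: bool = False  # hard-filter triggers to |offset| <= 1

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
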