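"""Design configuration shared by the selection, pooling and screening stages.

Defaults follow the published parameterization of the barcode probe system:
50-nt oligos stepped every 5 bp, a 75% intra-genome homology cutoff, read-depth
quantile filters (q=0.1, p=0.9, d=25), a density cap of 2500 oligos per 1-Mb
tile (2.5/kb), a 200-kb minimum separation between paired oligos, 100-kb
cross-mapping windows, and a 0.8 query-coverage cutoff for rDNA hits.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml


@dataclass
class DesignConfig:
    oligo_length: int = 50
    step: int = 5
    homology_threshold: float = 0.75
    kmer_q: float = 0.1
    kmer_p: float = 0.9
    kmer_d: float = 25.0
    density_window: int = 1_000_000
    density_step: int = 1_000_000
    density_cap: int = 2500
    min_pair_separation: int = 200_000
    map_window: int = 100_000
    rdna_min_coverage: float = 0.8
    rdna_min_identity: float = 0.8
    # ancillary knobs (package defaults, not published values)
    min_region_density: float = 0.9      # oligos/kb floor flagged per region
    terminal_fraction: float = 0.15      # outer fraction of an arm = terminal
    pericentromeric_fraction: float = 0.10  # of chromosome length around cen
    min_map_identity: float = 0.9        # cross-mapping identity floor
    homology_seed_k: int = 12            # seed length for seeded homology mode
    exact_homology_max_bases: int = 250_000  # auto-switch to exact scan below

    def __post_init__(self):
        if not (0 < self.kmer_q < self.kmer_p < 1):
            raise ValueError("require 0 < kmer_q < kmer_p < 1")
        for name in ("oligo_length", "step", "density_window", "density_step",
                     "density_cap", "min_pair_separation", "map_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.homology_threshold <= 1):
            raise ValueError("homology_threshold must be in (0, 1]")

    @property
    def density_per_kb(self) -> float:
        return self.density_cap / (self.density_window / 1000)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
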