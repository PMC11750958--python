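"""End-to-end probe-design pipeline: select -> design -> pool.

Wires the selection filters, barcode design validation, pairing, primer
design and in-silico PCR verification into one reproducible run driven by a
config, emitting artifact files plus a deterministic JSON report of stage
counts and effective parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import barcodedesign, oligoselect, poolbuilder
from .config import DesignConfig
from .io import read_fasta
from .simgenome import KmerTable


@dataclass
class RunConfig:
    genome_path: str
    design_spec_path: str
    centromeres_path: str
    out_dir: str
    seed: int
    kmer_table_path: str = None
    homology_mode: str = "auto"
    design: DesignConfig = field(default_factory=DesignConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        design = DesignConfig.from_dict(d.pop("design", {}) or {})
        return cls(design=design, **d)

    def validate(self):
        for name in ("genome_path", "design_spec_path", "centromeres_path"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p!r} does not exist")
        if self.kmer_table_path and not Path(self.kmer_table_path).exists():
            raise FileNotFoundError(f"kmer_table_path: {self.kmer_table_path!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def read_centromeres_bed(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        out[fields[0]] = int(fields[1])
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute select -> design -> pool and write artifacts + report.

    Returns the report dict (also written as ``report.json``).  All stages
    are deterministic functions of the config and seed; rerunning with the
    same inputs is byte-identical.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dcfg = cfg.design

    genome = read_fasta(cfg.genome_path)
    chrom_lengths = {name: len(seq) for name, seq in genome.items()}
    centromeres = read_centromeres_bed(cfg.centromeres_path)

    # --- selection -----------------------------------------------------
    cands = oligoselect.extract_candidates(genome, dcfg)
    n_candidates = len(cands)
    cands = oligoselect.filter_homology(cands, genome, dcfg, mode=cfg.homology_mode)
    n_post_homology = len(cands)
    if cfg.kmer_table_path:
        table = KmerTable.from_tsv(cfg.kmer_table_path)
        cands = oligoselect.filter_kmer_depth(cands, table, dcfg)
    n_post_kmer = len(cands)
    cands = oligoselect.cap_density(cands, dcfg)
    n_post_density = len(cands)
    oligoselect.write_oligos_bed(cands, out_dir / "oligos.bed")

    # --- barcode design ------------------------------------------------
    with open(cfg.design_spec_path) as fh:
        regions = barcodedesign.load_design(fh, chrom_lengths, centromeres)
    signatures = []
    by_chrom = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        signatures.append(
            barcodedesign.signature_of(
                by_chrom[chrom], centromeres[chrom], chrom_lengths[chrom],
                dcfg.terminal_fraction, dcfg.pericentromeric_fraction,
            )
        )
    uniqueness = barcodedesign.validate_uniqueness(signatures)
    regions, density_report = barcodedesign.assign_oligos(
        regions, cands, dcfg.min_region_density
    )
    barcodedesign.regions_bed9(regions, out_dir / "regions.bed")

    # --- pooling -------------------------------------------------------
    by_id = {c.id: c for c in cands}
    groups = {}  # (chrom, color) -> [oligo]
    for r in regions:
        bucket = groups.setdefault((r.chrom, r.color), [])
        bucket.extend(by_id[i] for i in r.oligo_ids)
    n_assigned = sum(len(v) for v in groups.values())

    pairs_by_group = {}
    for key in sorted(groups):
        pairs, _ = poolbuilder.pair_oligos(groups[key], dcfg)
        pairs_by_group[key] = pairs
    n_pairs = sum(len(p) for p in pairs_by_group.values())

    colors = sorted({color for _, color in groups})
    chroms = sorted({chrom for chrom, _ in groups})
    primers = poolbuilder.design_primer_sets(
        n_forward=len(colors), n_reverse_group=len(chroms), n_reverse_pool=1,
        genome=genome, seed=cfg.seed,
    )
    fwd_by_color = {
        color: p for color, p in zip(
            colors, [p for p in primers if p.scope == poolbuilder.FORWARD_COLOR]
        )
    }
    group_by_chrom = {
        chrom: p for chrom, p in zip(
            chroms, [p for p in primers if p.scope == poolbuilder.REVERSE_GROUP]
        )
    }
    pool_primer = [p for p in primers if p.scope == poolbuilder.REVERSE_POOL][0]

    pool = []
    for (chrom, color) in sorted(pairs_by_group):
        for pair in pairs_by_group[(chrom, color)]:
            pool.append(
                poolbuilder.build_unit(
                    pair, fwd_by_color[color], group_by_chrom[chrom], pool_primer,
                    unit_id=f"U{len(pool):06d}", color=color, group=chrom,
                )
            )

    # --- in-silico PCR verification -------------------------------------
    pcr_errors = 0
    for color in colors:
        expect = {u.unit_id for u in pool if u.color == color}
        got = set(poolbuilder.insilico_pcr(pool, fwd_by_color[color], pool_primer))
        pcr_errors += len(expect ^ got)
        for chrom in chroms:
            expect_g = {u.unit_id for u in pool if u.color == color and u.group == chrom}
            got_g = set(
                poolbuilder.insilico_pcr(pool, fwd_by_color[color], group_by_chrom[chrom])
            )
            pcr_errors += len(expect_g ^ got_g)

    poolbuilder.primer_table(primers, out_dir / "primers.tsv")
    if pool:
        poolbuilder.emit_order_file(pool, out_dir / "order.tsv")

    report = {
        "seed": cfg.seed,
        "parameters": dcfg.to_dict(),
        "homology_mode": cfg.homology_mode,
        "counts": {
            "candidates": n_candidates,
            "post_homology": n_post_homology,
            "post_kmer": n_post_kmer,
            "post_density": n_post_density,
            "regions": len(regions),
            "assigned_oligos": n_assigned,
            "pairs": n_pairs,
            "units": len(pool),
            "units_by_color": {
                c: sum(1 for u in pool if u.color == c) for c in colors
            },
        },
        "uniqueness": {
            "unique": uniqueness["unique"],
            "collisions": [list(t) for t in uniqueness["collisions"]],
        },
        "region_density": density_report,
        "min_separation": min((u.genomic_separation for u in pool), default=None),
        "pcr_errors": pcr_errors,
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
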