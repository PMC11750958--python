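"""Barcode region definition, oligo assignment and signature uniqueness.

A barcode design paints chosen chromosomal intervals in one of two colors
(Cy3/red, FAM/green).  On a metaphase chromosome, exact base-pair positions
are invisible; what a cytogeneticist reads is the ordered pattern of colored
bands and their coarse position along the chromosome.  A chromosome's
*signature* is therefore the ordered list of (position-class, color) bands,
with position classes terminal-p / interstitial-p / pericentromeric /
interstitial-q / terminal-q assigned from each region's midpoint relative to
the centromere.  Two chromosomes are distinguishable iff their signatures
differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

COLORS = ("RED", "GREEN")

POSITION_CLASSES = (
    "terminal-p",
    "interstitial-p",
    "pericentromeric",
    "interstitial-q",
    "terminal-q",
)


@dataclass
class BarcodeRegion:
    label: str
    chrom: str
    start: int
    end: int
    color: str
    oligo_ids: list = field(default_factory=list)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BarcodeSignature:
    chrom: str
    bands: tuple  # ordered ((position-class, color), ...)


def load_design(spec, chrom_lengths: dict, centromeres: dict = None) -> list:
    """Validate a barcode design spec and return its regions.

    ``spec`` is a YAML path/string or an already-parsed mapping/list with
    entries ``{label, chrom, start, end, color}``.  Regions must lie inside
    known chromosomes, be disjoint per chromosome, use the two allowed
    colors, and carry unique labels; any violation raises ``ValueError``
    naming the offending region.
    """
    if isinstance(spec, (str, bytes)):
        data = yaml.safe_load(spec)
    elif hasattr(spec, "read"):
        data = yaml.safe_load(spec.read())
    else:
        data = spec
    if isinstance(data, dict):
        data = data.get("regions", [])

    regions, labels = [], set()
    for entry in data:
        r = BarcodeRegion(
            label=str(entry["label"]),
            chrom=str(entry["chrom"]),
            start=int(entry["start"]),
            end=int(entry["end"]),
            color=str(entry["color"]).upper(),
        )
        if r.color not in COLORS:
            raise ValueError(f"region {r.label}: color must be RED or GREEN")
        if r.chrom not in chrom_lengths:
            raise ValueError(f"region {r.label}: unknown chromosome {r.chrom}")
        if not (0 <= r.start < r.end <= chrom_lengths[r.chrom]):
            raise ValueError(
                f"region {r.label}: [{r.start},{r.end}) outside {r.chrom} "
                f"(length {chrom_lengths[r.chrom]})"
            )
        if r.label in labels:
            raise ValueError(f"duplicate region label {r.label}")
        labels.add(r.label)
        regions.append(r)

    by_chrom = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"regions {a.label} and {b.label} overlap on {chrom}"
                )
    return regions


def position_class(
    midpoint: float,
    centromere: int,
    chrom_length: int,
    terminal_fraction: float = 0.15,
    pericentromeric_fraction: float = 0.10,
) -> str:
    """Coarse cytological position of a band midpoint.

    Pericentromeric takes precedence (within ``pericentromeric_fraction`` of
    the chromosome length around the centromere); terminal is the outer
    ``terminal_fraction`` of each arm; everything else is interstitial on
    its arm.
    """
    if abs(midpoint - centromere) <= pericentromeric_fraction * chrom_length:
        return "pericentromeric"
    if midpoint < centromere:
        return "terminal-p" if midpoint <= terminal_fraction * centromere else "interstitial-p"
    q_len = chrom_length - centromere
    if midpoint >= chrom_length - terminal_fraction * q_len:
        return "terminal-q"
    return "interstitial-q"


def signature_of(
    regions,
    centromere: int,
    chrom_length: int,
    terminal_fraction: float = 0.15,
    pericentromeric_fraction: float = 0.10,
) -> BarcodeSignature:
    """Signature of one chromosome from its regions (ordered by start)."""
    if not (0 < centromere < chrom_length):
        raise ValueError("centromere must lie strictly inside the chromosome")
    rs = sorted(regions, key=lambda r: r.start)
    chrom = rs[0].chrom if rs else ""
    bands = tuple(
        (
            position_class(
                r.midpoint, centromere, chrom_length,
                terminal_fraction, pericentromeric_fraction,
            ),
            r.color,
        )
        for r in rs
    )
    return BarcodeSignature(chrom=chrom, bands=bands)


def validate_uniqueness(signatures) -> dict:
    """Check that all chromosome signatures are pairwise distinct.

    Returns ``{"unique": bool, "collisions": [(chrom_a, chrom_b), ...]}``.
    """
    collisions = []
    sigs = list(signatures)
    for i in range(len(sigs)):
        for j in range(i + 1, len(sigs)):
            if sigs[i].bands == sigs[j].bands:
                collisions.append((sigs[i].chrom, sigs[j].chrom))
    return {"unique": not collisions, "collisions": collisions}


def assign_oligos(regions, oligos, min_density: float = 0.9):
    """Assign filtered oligos to regions by full containment.

    An oligo is assigned to a region iff its interval lies entirely inside
    the region (so region amplification cannot light up flanking sequence).
    Returns ``(regions, report)`` where the report lists per-region density
    in oligos/kb and flags regions below ``min_density``.
    """
    by_chrom = {}
    for r in regions:
        r.oligo_ids.clear()
        by_chrom.setdefault(r.chrom, []).append(r)
    for o in oligos:
        for r in by_chrom.get(o.chrom, ()):
            if r.start <= o.start and o.end <= r.end:
                r.oligo_ids.append(o.id)
                break  # regions are disjoint: at most one can contain it
    report = []
    for r in regions:
        density = len(r.oligo_ids) / (r.length / 1000)
        report.append(
            {
                "label": r.label,
                "chrom": r.chrom,
                "n_oligos": len(r.oligo_ids),
                "density_per_kb": density,
                "flagged": density < min_density,
            }
        )
    return regions, report


def regions_bed9(regions, path=None) -> str:
    """BED9 with itemRgb encoding the color (255,0,0 red / 0,255,0 green)."""
    from .io import write_bed

    rgb = {"RED": "255,0,0", "GREEN": "0,255,0"}
    rows = [
        (r.chrom, r.start, r.end, r.label, 0, "+", r.start, r.end, rgb[r.color])
        for r in regions
    ]
    return write_bed(rows, path)
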