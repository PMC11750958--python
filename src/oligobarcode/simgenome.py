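"""Deterministic synthetic genomes with planted features and truth tables.

This module stands in for the real plant genome assemblies and resequencing
data the probe-design workflow normally consumes.  It produces:

* multi-chromosome FASTA genomes with i.i.d. random background sequence,
  planted dispersed-repeat families, tandem 35S rDNA arrays (head-to-tail
  copies of a composite 18S-ITS1-5.8S-ITS2-25S-IGS unit) and centromere
  annotations, together with machine-readable truth tables;
* derived "sister species" genomes with seeded SNPs, inversions and
  translocations, emulating divergence between closely related species;
* simulated sequencing-read k-mer count tables (multiplicity x depth with
  Poisson noise) standing in for Illumina repeat-depth evidence.

Every operation is a pure function of its inputs and an explicit integer
seed: regenerating with the same seed is byte-identical.  Coordinates are
0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import decode, encode, kmer_codes, revcomp
from .io import write_bed, write_fasta

# Subunit lengths of the synthetic composite rDNA unit (bp).  Scaled-down but
# rank-realistic: the 18S and 25S dominate, spacers are short.
RDNA_SUBUNIT_LENGTHS = {
    "18S": 1000,
    "ITS1": 180,
    "5.8S": 150,
    "ITS2": 200,
    "25S": 900,
    "IGS": 500,
}
RDNA_SUBUNIT_ORDER = ("18S", "ITS1", "5.8S", "ITS2", "25S", "IGS")


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def synthetic_rdna_subunits(seed: int = 101) -> dict:
    """Deterministic synthetic subunit sequences for the composite rDNA unit."""
    rng = np.random.default_rng(seed)
    return {
        name: decode(_random_seq(rng, RDNA_SUBUNIT_LENGTHS[name]))
        for name in RDNA_SUBUNIT_ORDER
    }


def rdna_unit_sequence(subunits: dict) -> str:
    return "".join(subunits[name] for name in RDNA_SUBUNIT_ORDER)


@dataclass
class RepeatFamily:
    """A dispersed repeat family planted at explicit loci."""

    family: str
    length: int
    loci: list  # list of (chrom, start)
    identity: float = 1.0  # per-copy identity to the family consensus


@dataclass
class RdnaArraySpec:
    """A tandem rDNA array planted at an explicit locus.

    ``truncated_flags[i]`` marks copy i as an edge-truncated unit retaining
    only the leading ``truncation_fraction`` of its 18S (the remainder of the
    unit is deleted), as seen at real array margins.  ``divergence`` applies
    per-copy random substitutions at that rate.
    """

    chrom: str
    start: int
    unit_count: int
    truncated_flags: list = None
    truncation_fraction: float = 0.7
    divergence: float = 0.0

    def __post_init__(self):
        if self.truncated_flags is None:
            self.truncated_flags = [False] * self.unit_count
        if len(self.truncated_flags) != self.unit_count:
            raise ValueError("truncated_flags length must equal unit_count")
        if self.unit_count < 0:
            raise ValueError("unit_count must be >= 0")


@dataclass
class GenomeTruth:
    """Ground truth for one synthetic genome."""

    chrom_lengths: dict
    repeat_intervals: list = field(default_factory=list)  # (chrom, start, end, family)
    rdna_arrays: list = field(default_factory=list)  # realized array records
    centromeres: dict = field(default_factory=dict)
    seed: int = 0

    def repeats_bed(self, path=None) -> str:
        rows = [(c, s, e, f) for c, s, e, f in self.repeat_intervals]
        return write_bed(rows, path)

    def rdna_bed(self, path=None) -> str:
        rows = [
            (a["chrom"], a["start"], a["end"],
             f"rdna;units={a['unit_count']};truncated={sum(a['truncated_flags'])}")
            for a in self.rdna_arrays
        ]
        return write_bed(rows, path)

    def centromeres_bed(self, path=None) -> str:
        rows = [(c, p, p + 1, "centromere") for c, p in self.centromeres.items()]
        return write_bed(rows, path)


def _mutate_copy(rng: np.random.Generator, arr: np.ndarray, n_subs: int) -> np.ndarray:
    out = arr.copy()
    if n_subs <= 0:
        return out
    pos = rng.choice(arr.size, size=min(n_subs, arr.size), replace=False)
    shift = rng.integers(1, 4, size=pos.size).astype(np.uint8)
    out[pos] = (out[pos] + shift) % 4
    return out


def make_genome(
    chrom_lengths: dict,
    seed: int,
    *,
    repeats=(),
    rdna_arrays=(),
    centromeres: dict = None,
    gc: float = 0.5,
    rdna_subunits: dict = None,
):
    """Generate a synthetic genome and its truth tables.

    Returns ``(genome, truth)`` where ``genome`` maps chromosome id to its
    plus-strand sequence.  Planted features must be disjoint; a collision
    raises ``ValueError`` naming the offending intervals.
    """
    for name, length in chrom_lengths.items():
        if length < 10_000:
            raise ValueError(f"chromosome {name} shorter than 10 kb")

    rng = np.random.default_rng(seed)
    arrays = {
        name: _random_seq(rng, length, gc) for name, length in chrom_lengths.items()
    }

    if centromeres is None:
        centromeres = {n: int(0.4 * length) for n, length in chrom_lengths.items()}
    for name, pos in centromeres.items():
        if not (0 < pos < chrom_lengths[name]):
            raise ValueError(f"centromere of {name} outside (0, length)")

    subunits = rdna_subunits or synthetic_rdna_subunits()
    unit = encode(rdna_unit_sequence(subunits))
    len18 = len(subunits["18S"])

    planted = []  # (chrom, start, end, label) for collision checking
    truth = GenomeTruth(chrom_lengths=dict(chrom_lengths), centromeres=dict(centromeres),
                        seed=seed)

    for fam in repeats:
        consensus = _random_seq(rng, fam.length, gc)
        n_subs = int(round((1.0 - fam.identity) * fam.length))
        for chrom, start in fam.loci:
            end = start + fam.length
            if chrom not in arrays or not (0 <= start and end <= chrom_lengths[chrom]):
                raise ValueError(
                    f"repeat {fam.family} at {chrom}:{start}-{end} outside chromosome"
                )
            copy = _mutate_copy(rng, consensus, n_subs)
            arrays[chrom][start:end] = copy
            planted.append((chrom, start, end, f"repeat:{fam.family}"))
            truth.repeat_intervals.append((chrom, start, end, fam.family))

    for spec in rdna_arrays:
        pos = spec.start
        unit_meta = []
        for i in range(spec.unit_count):
            if spec.truncated_flags[i]:
                kept = int(round(spec.truncation_fraction * len18))
                copy = unit[:kept]
            else:
                copy = unit
            n_subs = int(round(spec.divergence * copy.size))
            copy = _mutate_copy(rng, copy, n_subs)
            end = pos + copy.size
            if end > chrom_lengths[spec.chrom]:
                raise ValueError(
                    f"rDNA array at {spec.chrom}:{spec.start} overruns chromosome"
                )
            arrays[spec.chrom][pos:end] = copy
            unit_meta.append((pos, end))
            pos = end
        planted.append((spec.chrom, spec.start, pos, "rdna"))
        truth.rdna_arrays.append(
            {
                "chrom": spec.chrom,
                "start": spec.start,
                "end": pos,
                "unit_count": spec.unit_count,
                "truncated_flags": list(spec.truncated_flags),
                "truncation_fraction": spec.truncation_fraction,
                "unit_intervals": unit_meta,
            }
        )

    # collision check over all planted features
    by_chrom = {}
    for item in planted:
        by_chrom.setdefault(item[0], []).append(item)
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: t[1])
        for a, b in zip(items, items[1:]):
            if b[1] < a[2]:
                raise ValueError(
                    f"planted features collide on {chrom}: "
                    f"{a[3]} [{a[1]},{a[2]}) overlaps {b[3]} [{b[1]},{b[2]})"
                )

    genome = {name: decode(arr) for name, arr in arrays.items()}
    return genome, truth


@dataclass
class RearrangementMap:
    """Edits converting a source genome into a diverged sister genome."""

    snp_rate: float = 0.0
    inversions: list = field(default_factory=list)  # (chrom, start, end)
    translocations: list = field(default_factory=list)  # (src, start, end, dst, dst_pos)
    ortholog_map: dict = field(default_factory=dict)  # source chrom -> target chrom
    snp_counts: dict = field(default_factory=dict)  # realized, per chromosome

    def __post_init__(self):
        if not (0.0 <= self.snp_rate <= 0.25):
            raise ValueError("snp_rate must be in [0, 0.25]")
        by_chrom = {}
        for chrom, s, e in self.inversions:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, s, e, *_ in self.translocations:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"rearranged intervals overlap on {chrom}")


def mutate_genome(genome: dict, rmap: RearrangementMap, seed: int):
    """Apply inversions, translocations and SNPs; return (genome, realized map).

    Inversions and translocations are interpreted in input coordinates and
    applied first; SNPs are then sampled per base at ``snp_rate`` over the
    rearranged genome.  The realized map records per-chromosome SNP counts.
    """
    rng = np.random.default_rng(seed)
    arrays = {name: encode(seq) for name, seq in genome.items()}

    for chrom, start, end in rmap.inversions:
        arr = arrays.get(chrom)
        if arr is None or not (0 <= start < end <= arr.size):
            raise ValueError(f"inversion interval {chrom}:{start}-{end} invalid")
        comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
        arrays[chrom] = np.concatenate(
            [arr[:start], comp[arr[start:end]][::-1], arr[end:]]
        )

    for src, start, end, dst, dst_pos in rmap.translocations:
        if src == dst:
            raise ValueError("translocation source and destination must differ")
        sarr = arrays.get(src)
        darr = arrays.get(dst)
        if sarr is None or darr is None or not (0 <= start < end <= sarr.size):
            raise ValueError(f"translocation interval {src}:{start}-{end} invalid")
        if not (0 <= dst_pos <= darr.size):
            raise ValueError(f"translocation destination {dst}:{dst_pos} invalid")
        segment = sarr[start:end].copy()
        arrays[src] = np.concatenate([sarr[:start], sarr[end:]])
        arrays[dst] = np.concatenate([darr[:dst_pos], segment, darr[dst_pos:]])

    snp_counts = {}
    if rmap.snp_rate > 0:
        for name in arrays:
            arr = arrays[name]
            hits = np.nonzero(rng.random(arr.size) < rmap.snp_rate)[0]
            hits = hits[arr[hits] < 4]
            shift = rng.integers(1, 4, size=hits.size).astype(np.uint8)
            arr[hits] = (arr[hits] + shift) % 4
            snp_counts[name] = int(hits.size)
    else:
        snp_counts = {name: 0 for name in arrays}

    realized = RearrangementMap(
        snp_rate=rmap.snp_rate,
        inversions=list(rmap.inversions),
        translocations=list(rmap.translocations),
        ortholog_map=dict(rmap.ortholog_map) or {n: n for n in genome},
        snp_counts=snp_counts,
    )
    return {name: decode(arr) for name, arr in arrays.items()}, realized


class KmerTable:
    """Canonical k-mer -> simulated read depth, as a sorted code array."""

    def __init__(self, k: int, codes: np.ndarray, counts: np.ndarray):
        self.k = k
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.counts = counts[order]

    def __len__(self):
        return self.codes.size

    def lookup_codes(self, query: np.ndarray) -> np.ndarray:
        """Depth of each query canonical code; absent k-mers count 0."""
        idx = np.searchsorted(self.codes, query)
        idx = np.clip(idx, 0, max(len(self) - 1, 0))
        if len(self) == 0:
            return np.zeros(query.size, dtype=np.int64)
        hit = self.codes[idx] == query
        out = np.zeros(query.size, dtype=np.int64)
        out[hit] = self.counts[idx[hit]]
        return out

    def to_tsv(self, path=None) -> str:
        shifts = np.arange(2 * (self.k - 1), -1, -2, dtype=np.uint64)
        sym = np.frombuffer(b"ACGT", dtype=np.uint8)
        chars = sym[((self.codes[:, None] >> shifts[None, :]) & np.uint64(3)).astype(np.uint8)]
        lines = [
            chars[i].tobytes().decode("ascii") + "\t" + str(int(self.counts[i]))
            for i in range(len(self))
        ]
        text = "\n".join(lines) + ("\n" if lines else "")
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, path) -> "KmerTable":
        from pathlib import Path

        kmers, counts = [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            kmer, cnt = line.split("\t")
            kmers.append(kmer)
            counts.append(int(cnt))
        if not kmers:
            return cls(0, np.empty(0, np.uint64), np.empty(0, np.int64))
        k = len(kmers[0])
        codes = _codes_from_strings(kmers, k)
        return cls(k, codes, np.array(counts, dtype=np.int64))


def _codes_from_strings(kmers, k) -> np.ndarray:
    enc = np.stack([encode(s) for s in kmers])
    codes = np.zeros(len(kmers), dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | enc[:, j].astype(np.uint64)
    return codes


def canonical_codes(arr: np.ndarray, k: int):
    """Canonical (min of strand pair) codes of all valid k-mers of ``arr``."""
    fwd, valid = kmer_codes(arr, k)
    rc_all, _ = kmer_codes(np.array([3, 2, 1, 0, 4], dtype=np.uint8)[arr][::-1], k)
    rc = rc_all[::-1]
    canon = np.minimum(fwd, rc)
    return canon[valid]


def make_kmer_table(genome: dict, k: int, depth: float, seed: int) -> KmerTable:
    """Simulated read-depth table: Poisson(multiplicity x depth) per k-mer."""
    if not (15 <= k <= 31):
        raise ValueError("k must be in [15, 31]")
    shortest = min(len(s) for s in genome.values())
    if k > shortest:
        raise ValueError("k longer than shortest sequence")
    rng = np.random.default_rng(seed)
    parts = [canonical_codes(encode(seq), k) for seq in genome.values()]
    allc = np.concatenate(parts) if parts else np.empty(0, np.uint64)
    codes, mult = np.unique(allc, return_counts=True)
    if depth == 0:
        counts = np.zeros(codes.size, dtype=np.int64)
    else:
        counts = rng.poisson(mult * float(depth)).astype(np.int64)
    return KmerTable(k, codes, counts)


# ---------------------------------------------------------------------------
# Barcode-design fixture: a valid, signature-unique region spec for a
# synthetic genome (the real workflow chooses regions manually).
# ---------------------------------------------------------------------------

_CLASS_ORDER = ("terminal-p", "interstitial-p", "pericentromeric",
                "interstitial-q", "terminal-q")


def _class_midpoint(cls: str, cen: int, length: int) -> int:
    q = length - cen
    return {
        "terminal-p": int(0.075 * cen),
        "interstitial-p": int(0.55 * cen),
        "pericentromeric": cen,
        "interstitial-q": cen + int(0.55 * q),
        "terminal-q": length - int(0.075 * q),
    }[cls]


def make_barcode_spec(chrom_lengths: dict, centromeres: dict, region_width: int = 80_000):
    """Deterministic barcode design with pairwise-distinct signatures.

    Chromosome i receives the i-th pattern from a fixed enumeration of
    (position-class, color) band patterns; bands are placed at canonical
    class midpoints so downstream classification recovers the pattern.
    Patterns are same-color multi-band combinations ordered by decreasing
    band separation, so each chromosome's color group spans distant loci and
    admits 200-kb-separated oligo pairs.  Returns a list of region dicts
    suitable for ``barcodedesign.load_design``.
    """
    from itertools import combinations

    colors = ("RED", "GREEN")
    # canonical midpoint fractions for a 0.4 centromere (enumeration order only)
    frac = {"terminal-p": 0.03, "interstitial-p": 0.22, "pericentromeric": 0.40,
            "interstitial-q": 0.73, "terminal-q": 0.955}
    two = sorted(combinations(_CLASS_ORDER, 2), key=lambda p: -(frac[p[1]] - frac[p[0]]))
    three = sorted(combinations(_CLASS_ORDER, 3), key=lambda p: -(frac[p[2]] - frac[p[0]]))
    patterns = []
    for combo in list(two) + list(three):
        for col in colors:
            patterns.append([(cls, col) for cls in combo])

    regions = []
    for i, (chrom, length) in enumerate(sorted(chrom_lengths.items())):
        cen = centromeres[chrom]
        pattern = patterns[i % len(patterns)]
        for j, (cls, col) in enumerate(pattern, start=1):
            mid = _class_midpoint(cls, cen, length)
            half = min(region_width, int(0.12 * length)) // 2
            start = max(0, mid - half)
            end = min(length, mid + half)
            regions.append(
                {"label": f"{chrom}.{j}", "chrom": chrom, "start": start,
                 "end": end, "color": col}
            )
    return regions


def write_genome(genome: dict, path) -> str:
    return write_fasta(genome, path)
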