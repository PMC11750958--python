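"""Synthesis-pool assembly: oligo pairing, primer design, in-silico PCR.

The cost-halving idea: two selected 50-mers from the same amplification
group are merged into one orderable 100-nt insert, flanked by a forward
primer site and a nested reverse cassette.  Pairing requires a genomic
separation of at least 200 kb so the two probes cannot compete for
neighboring hybridization targets; within a group the pairing is a
maximum-cardinality matching under that constraint.

Primer scheme (three primers per unit):

* ``FORWARD_COLOR`` — one forward primer per color pool; carries the dye.
* ``REVERSE_GROUP`` — nested inner reverse site, one per chromosome group;
  with a color forward it amplifies one chromosome's units of that color.
* ``REVERSE_POOL``  — outer reverse site shared by the whole pool; with a
  color forward it amplifies the entire color pool.

``insilico_pcr`` verifies this selectivity computationally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from ._seq import encode, gc_fraction, kmer_codes, revcomp
from .config import DesignConfig

FORWARD_COLOR = "FORWARD_COLOR"
REVERSE_POOL = "REVERSE_POOL"
REVERSE_GROUP = "REVERSE_GROUP"


@dataclass(frozen=True)
class PrimerSet:
    primer_id: str
    sequence: str
    scope: str
    tm: float
    gc: float


@dataclass
class SynthesisUnit:
    unit_id: str
    oligoA: object  # OligoCandidate
    oligoB: object
    chrom: str
    color: str
    group: str
    genomic_separation: int
    fwd_primer_id: str
    rev_group_primer_id: str
    rev_pool_primer_id: str
    full_sequence: str

    @property
    def insert(self) -> str:
        return self.oligoA.sequence + self.oligoB.sequence


# ---------------------------------------------------------------------------
# Distance-constrained pairing
# ---------------------------------------------------------------------------

def pair_oligos(group_oligos, cfg: DesignConfig):
    """Maximum-cardinality pairing with a minimum genomic separation.

    All oligos must belong to one amplification group (same chromosome and
    color).  Returns ``(pairs, unpaired)`` where each pair ``(a, b)``
    satisfies ``b.start - a.start >= cfg.min_pair_separation`` and every
    oligo is used at most once.  The optimum is found by binary search on
    the pair count m: pairing the i-th smallest position with the
    (n-m+i)-th smallest is feasible iff a size-m matching exists.
    """
    oligos = sorted(group_oligos, key=lambda o: o.start)
    n = len(oligos)
    if n < 2:
        return [], list(oligos)
    pos = [o.start for o in oligos]
    if len(set(pos)) != n:
        raise ValueError("oligo positions within a group must be distinct")
    D = cfg.min_pair_separation

    def feasible(m: int) -> bool:
        return all(pos[n - m + i] - pos[i] >= D for i in range(m))

    lo, hi = 0, n // 2
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if feasible(mid):
            lo = mid
        else:
            hi = mid - 1
    m = lo
    pairs = [(oligos[i], oligos[n - m + i]) for i in range(m)]
    unpaired = oligos[m : n - m]
    return pairs, unpaired


# ---------------------------------------------------------------------------
# Primer design
# ---------------------------------------------------------------------------

def melting_temperature(seq: str) -> float:
    """Nearest-neighbor Tm (SantaLucia & Hicks 2004 unified parameters,
    Biopython ``Tm_NN`` defaults: 50 nM primer, 50 mM Na+)."""
    return float(_mt.Tm_NN(seq))


def has_hairpin(seq: str, stem: int = 6, min_loop: int = 3) -> bool:
    """True if the primer can fold back on itself with a stem >= ``stem``."""
    n = len(seq)
    for i in range(n - 2 * stem - min_loop + 1):
        probe = revcomp(seq[i : i + stem])
        j0 = i + stem + min_loop
        if probe in seq[j0:]:
            return True
    return False


def three_prime_complementarity(a: str, b: str) -> int:
    """Length of the longest mutually annealing 3'-end duplex of two primers."""
    lmax = min(len(a), len(b))
    best = 0
    for l in range(1, lmax + 1):
        if a[-l:] == revcomp(b[-l:]):
            best = l
    return best


def _genome_code_set(genome: dict, k: int) -> np.ndarray:
    parts = []
    for seq in genome.values():
        codes, valid = kmer_codes(encode(seq), k)
        parts.append(codes[valid])
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def _shares_kmer(seq: str, sorted_codes: np.ndarray, k: int) -> bool:
    if len(seq) < k or sorted_codes.size == 0:
        return False
    for s in (seq, revcomp(seq)):
        codes, valid = kmer_codes(encode(s), k)
        codes = codes[valid]
        idx = np.searchsorted(sorted_codes, codes)
        idx = np.clip(idx, 0, sorted_codes.size - 1)
        if np.any(sorted_codes[idx] == codes):
            return True
    return False


def design_primer_sets(
    n_forward: int,
    n_reverse_group: int,
    n_reverse_pool: int,
    genome: dict,
    seed: int,
    *,
    length: int = 20,
    target_tm: float = 55.0,
    tm_tolerance: float = 2.0,
    gc_range=(0.40, 0.60),
    genome_match_k: int = 15,
    max_dimer: int = 3,
    hairpin_stem: int = 6,
    max_iterations: int = None,
) -> list:
    """Seeded rejection sampling of a mutually orthogonal primer battery.

    Every primer satisfies GC in ``gc_range``, Tm within ``tm_tolerance`` of
    ``target_tm``, no self-hairpin stem >= ``hairpin_stem``, pairwise 3'-end
    complementarity <= ``max_dimer`` (including against itself), and no
    perfect >= ``genome_match_k``-nt match to the target genome on either
    strand.  Raises ``RuntimeError`` with rejection statistics if the budget
    is exhausted.
    """
    wanted = (
        [(FORWARD_COLOR, f"A{i+1}") for i in range(n_forward)]
        + [(REVERSE_GROUP, f"C{i+1}") for i in range(n_reverse_group)]
        + [(REVERSE_POOL, f"B{i+1}") for i in range(n_reverse_pool)]
    )
    if not wanted:
        return []
    if max_iterations is None:
        max_iterations = 4000 * len(wanted)
    rng = np.random.default_rng(seed)
    gcodes = _genome_code_set(genome, genome_match_k) if genome else np.empty(0, np.uint64)

    accepted: list[PrimerSet] = []
    rejections = {"gc": 0, "tm": 0, "hairpin": 0, "dimer": 0, "genome": 0, "dup": 0}
    bases = "ACGT"
    iters = 0
    for scope, pid in wanted:
        ok = False
        while iters < max_iterations:
            iters += 1
            seq = "".join(bases[i] for i in rng.integers(0, 4, size=length))
            gc = gc_fraction(seq)
            if not (gc_range[0] <= gc <= gc_range[1]):
                rejections["gc"] += 1
                continue
            tm = melting_temperature(seq)
            if abs(tm - target_tm) > tm_tolerance:
                rejections["tm"] += 1
                continue
            if length >= 2 * hairpin_stem + 3 and has_hairpin(seq, hairpin_stem):
                rejections["hairpin"] += 1
                continue
            if three_prime_complementarity(seq, seq) > max_dimer:
                rejections["dimer"] += 1
                continue
            if any(
                three_prime_complementarity(seq, p.sequence) > max_dimer
                or three_prime_complementarity(p.sequence, seq) > max_dimer
                for p in accepted
            ):
                rejections["dimer"] += 1
                continue
            if any(p.sequence == seq for p in accepted):
                rejections["dup"] += 1
                continue
            if _shares_kmer(seq, gcodes, genome_match_k):
                rejections["genome"] += 1
                continue
            accepted.append(PrimerSet(pid, seq, scope, round(tm, 2), round(gc, 3)))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"primer design unsatisfiable within {max_iterations} draws "
                f"(needed {len(wanted)}, got {len(accepted)}; rejections {rejections})"
            )
    return accepted


def primer_table(primers, path=None) -> str:
    from .io import write_bed

    rows = [("primer_id", "scope", "sequence", "tm", "gc")]
    rows += [(p.primer_id, p.scope, p.sequence, p.tm, p.gc) for p in primers]
    return write_bed(rows, path)


# ---------------------------------------------------------------------------
# Unit assembly and in-silico PCR
# ---------------------------------------------------------------------------

def _exact_shared_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[j : j + k] in kmers for j in range(len(b) - k + 1))


def build_unit(
    pair,
    fwd: PrimerSet,
    rev_group: PrimerSet,
    rev_pool: PrimerSet,
    *,
    unit_id: str = "U000000",
    color: str = "NA",
    group: str = None,
    ambiguity_k: int = 15,
) -> SynthesisUnit:
    """Assemble one synthesis unit.

    Layout: ``fwd + oligoA + oligoB + revcomp(rev_group) + revcomp(rev_pool)``
    (group site inner, pool site outer).  Any primer with a >= 15-nt perfect
    match inside the genomic insert (either strand) would make amplification
    ambiguous and raises ``ValueError``.  Primers may be ``None`` (testing
    mode: that cassette element is omitted).
    """
    a, b = pair
    if a.chrom != b.chrom:
        raise ValueError("paired oligos must come from one chromosome")
    if a.start >= b.start:
        a, b = b, a
    insert = a.sequence + b.sequence
    parts = []
    for p in (fwd, rev_group, rev_pool):
        if p is None:
            continue
        for s in (p.sequence, revcomp(p.sequence)):
            if _exact_shared_kmer(insert, s, ambiguity_k):
                raise ValueError(
                    f"primer {p.primer_id} has a >= {ambiguity_k}-nt match inside "
                    f"the genomic insert of {unit_id}: ambiguous amplification"
                )
    full = (
        (fwd.sequence if fwd else "")
        + insert
        + (revcomp(rev_group.sequence) if rev_group else "")
        + (revcomp(rev_pool.sequence) if rev_pool else "")
    )
    return SynthesisUnit(
        unit_id=unit_id,
        oligoA=a,
        oligoB=b,
        chrom=a.chrom,
        color=color,
        group=group if group is not None else a.chrom,
        genomic_separation=b.start - a.start,
        fwd_primer_id=fwd.primer_id if fwd else "",
        rev_group_primer_id=rev_group.primer_id if rev_group else "",
        rev_pool_primer_id=rev_pool.primer_id if rev_pool else "",
        full_sequence=full,
    )


def _site_matches(site: str, template: str, max_mismatches: int) -> bool:
    """Does ``site`` occur in ``template`` with at most ``max_mismatches``?"""
    n, m = len(template), len(site)
    if m == 0 or m > n:
        return False
    t = encode(template)
    s = encode(site)
    for off in range(n - m + 1):
        if int((t[off : off + m] != s).sum()) <= max_mismatches:
            return True
    return False


def insilico_pcr(pool, fwd: PrimerSet, rev: PrimerSet, max_mismatches: int = 0) -> list:
    """Unit ids amplified by a (forward, reverse) primer pair.

    A unit amplifies iff the forward primer matches its 5' site and the
    reverse primer matches (as reverse complement) a site in its reverse
    cassette, both within ``max_mismatches``.
    """
    out = []
    rc_site = revcomp(rev.sequence)
    for u in pool:
        flen = len(fwd.sequence)
        prefix = u.full_sequence[:flen]
        if len(prefix) < flen:
            continue
        mm = sum(1 for x, y in zip(prefix, fwd.sequence) if x != y)
        if mm > max_mismatches:
            continue
        cassette = u.full_sequence[flen + len(u.insert):]
        if _site_matches(rc_site, cassette, max_mismatches):
            out.append(u.unit_id)
    return out


# ---------------------------------------------------------------------------
# Order file
# ---------------------------------------------------------------------------

ORDER_COLUMNS = (
    "unit_id", "full_sequence", "chrom", "color", "group",
    "oligoA_locus", "oligoB_locus", "separation",
)


def emit_order_file(pool, path=None) -> str:
    """Vendor hand-off TSV, one row per synthesis unit."""
    if not pool:
        raise ValueError("empty pool")
    seen_ids = set()
    seqs = {}
    lines = ["\t".join(ORDER_COLUMNS)]
    for u in pool:
        if u.unit_id in seen_ids:
            raise ValueError(f"duplicate unit_id {u.unit_id}")
        seen_ids.add(u.unit_id)
        if u.full_sequence in seqs:
            warnings.warn(
                f"units {seqs[u.full_sequence]} and {u.unit_id} share a full "
                "sequence (synthesis collision)", stacklevel=2,
            )
        else:
            seqs[u.full_sequence] = u.unit_id
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    u.unit_id, u.full_sequence, u.chrom, u.color, u.group,
                    f"{u.oligoA.chrom}:{u.oligoA.start}",
                    f"{u.oligoB.chrom}:{u.oligoB.start}",
                    u.genomic_separation,
                )
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return text


def read_order_file(path_or_text):
    """Parse an order file back into a list of per-unit dicts."""
    from pathlib import Path

    text = path_or_text
    if "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if tuple(header) != ORDER_COLUMNS:
        raise ValueError("unexpected order-file header")
    out = []
    for ln in lines[1:]:
        fields = dict(zip(ORDER_COLUMNS, ln.split("\t")))
        fields["separation"] = int(fields["separation"])
        out.append(fields)
    return out
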