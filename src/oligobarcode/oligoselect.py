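"""Single-copy oligo selection: extraction, homology, depth and density filters.

A candidate is a plus-strand genomic 50-mer (length configurable) taken every
``step`` bp.  Three filters reduce candidates to hybridization-safe,
evenly spread probes:

1. ``filter_homology`` removes any candidate with a full-length ungapped
   off-target match at identity >= ``homology_threshold`` anywhere else in
   the genome (either strand).
2. ``filter_kmer_depth`` removes candidates whose mean simulated read depth
   falls outside the [q, p] quantile band of all candidate scores, or that
   contain a single k-mer deeper than ``d`` times the median score — the
   repeat/dropout screen normally driven by Illumina read k-mer counts.
3. ``cap_density`` thins each 1-Mb tile to at most ``density_cap`` oligos
   (2.5/kb at defaults), keeping the subset whose minimum inter-oligo gap
   is maximal.

Each filter returns a subset of its input and never alters candidate
coordinates, so the pipeline is monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._seq import KmerIndex, encode, revcomp
from .config import DesignConfig


@dataclass(frozen=True)
class OligoCandidate:
    """A candidate probe: a plus-strand genomic window with evidence fields."""

    chrom: str
    start: int
    length: int
    sequence: str
    kmer_score: float = float("nan")
    max_offtarget_identity: float = float("nan")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}"


def extract_candidates(genome: dict, cfg: DesignConfig) -> list:
    """All plus-strand windows at positions 0, step, 2*step, ... per chromosome.

    Windows containing non-ACGT characters are dropped.
    """
    if not genome:
        raise ValueError("empty genome")
    L, step = cfg.oligo_length, cfg.step
    out = []
    for chrom in genome:
        seq = genome[chrom]
        if len(seq) < L:
            raise ValueError(f"chromosome {chrom} shorter than oligo_length")
        arr = encode(seq)
        bad = np.concatenate([[0], np.cumsum(arr >= 4)])
        for start in range(0, len(seq) - L + 1, step):
            if bad[start + L] - bad[start] == 0:
                out.append(OligoCandidate(chrom, start, L, seq[start : start + L]))
    return out


# ---------------------------------------------------------------------------
# Homology screening
# ---------------------------------------------------------------------------

def _encode_matrix(cands) -> np.ndarray:
    return np.stack([encode(c.sequence) for c in cands])


def _exact_best_matches(cands, genome: dict, L: int) -> np.ndarray:
    """Exhaustive ungapped scan: best off-target match count per candidate.

    Compares every candidate against every full-length window of every
    chromosome on both strands, excluding only the candidate's own origin
    locus (plus strand, identical coordinates).
    """
    M = len(cands)
    C = _encode_matrix(cands)
    best = np.zeros(M, dtype=np.int16)
    own = {}
    for i, c in enumerate(cands):
        own.setdefault(c.chrom, []).append((c.start, i))
    chunk = max(4096, (1 << 25) // max(M, 1))
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    for chrom, seq in genome.items():
        g = encode(seq)
        for strand in "+-":
            garr = g if strand == "+" else comp[g][::-1]
            n_pos = garr.size - L + 1
            if n_pos <= 0:
                continue
            for a in range(0, n_pos, chunk):
                b = min(a + chunk, n_pos)
                acc = np.zeros((M, b - a), dtype=np.uint8)
                for i in range(L):
                    acc += C[:, i : i + 1] == garr[a + i : b + i]
                if strand == "+":
                    for start, ci in own.get(chrom, ()):
                        if a <= start < b:
                            acc[ci, start - a] = 0
                np.maximum(best, acc.max(axis=1), out=best)
    return best


def _row_kmer_codes(C: np.ndarray, k: int) -> np.ndarray:
    """(M, L-k+1) rolling 2-bit codes for each row of an encoded matrix."""
    M, L = C.shape
    n = L - k + 1
    codes = np.zeros((M, n), dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | C[:, j : j + n].astype(np.uint64)
    return codes


def _seeded_best_matches(cands, genome: dict, L: int, seed_k: int) -> np.ndarray:
    """Seed-and-extend scan: best verified off-target match count per candidate.

    Exact k-mer seeds (length ``seed_k``) are looked up in a genome index and
    every seeded locus is verified by a full-length ungapped comparison.
    Sensitivity is guaranteed for off-targets with at most
    ``floor(L/seed_k) - 1`` mismatches (a clean seed must survive); lower
    identities are found only when a seed happens to be conserved.
    """
    M = len(cands)
    C = _encode_matrix(cands)
    enc_chroms = {name: encode(seq) for name, seq in genome.items()}
    index = KmerIndex(enc_chroms, seed_k)
    best = np.zeros(M, dtype=np.int16)
    offs = np.arange(L)
    own_global = np.array(
        [index.offsets[c.chrom] + c.start for c in cands], dtype=np.int64
    )
    bounds = index._bounds

    for orient in (0, 1):
        S = C if orient == 0 else np.stack(
            [encode(revcomp(c.sequence)) for c in cands]
        )
        codes = _row_kmer_codes(S, seed_k)
        n_off = codes.shape[1]
        flat = codes.ravel()
        lo, hi = index.find_many(flat)
        lens = hi - lo
        nz = np.nonzero(lens)[0]
        if nz.size == 0:
            continue
        pos_idx = np.concatenate(
            [np.arange(lo[i], hi[i]) for i in nz]
        )
        reps = lens[nz]
        cand_of = np.repeat(nz // n_off, reps)
        off_of = np.repeat(nz % n_off, reps)
        gstart = index.sorted_pos[pos_idx] - off_of
        # keep windows fully inside one chromosome
        ci = np.searchsorted(bounds, gstart, side="right") - 1
        lo_b = bounds[np.clip(ci, 0, len(bounds) - 1)]
        lengths = np.array(
            [index.chrom_length(n) for n in index.chrom_names], dtype=np.int64
        )
        ok = (gstart >= lo_b) & (gstart + L <= lo_b + lengths[np.clip(ci, 0, len(lengths) - 1)])
        if orient == 0:
            ok &= gstart != own_global[cand_of]
        cand_of, gstart = cand_of[ok], gstart[ok]
        if cand_of.size == 0:
            continue
        pairs = np.unique(np.stack([cand_of, gstart]), axis=1)
        cand_of, gstart = pairs[0], pairs[1]
        windows = index.concat[gstart[:, None] + offs[None, :]]
        matches = (windows == S[cand_of]).sum(axis=1).astype(np.int16)
        np.maximum.at(best, cand_of, matches)
    return best


def filter_homology(cands, genome: dict, cfg: DesignConfig, mode: str = "auto"):
    """Drop candidates with a full-length off-target at identity >= threshold.

    ``mode``: ``"exact"`` (exhaustive scan, verdicts guaranteed),
    ``"seeded"`` (k-mer seeding + ungapped extension, fast at genome scale),
    or ``"auto"`` (exact below ``cfg.exact_homology_max_bases``).
    Retained candidates carry ``max_offtarget_identity`` (in seeded mode the
    maximum over seed-verified loci, 0 if none was examined).
    """
    if not cands:
        return []
    L = cfg.oligo_length
    if mode == "auto":
        total = sum(len(s) for s in genome.values())
        mode = "exact" if total <= cfg.exact_homology_max_bases else "seeded"
    if mode == "exact":
        best = _exact_best_matches(cands, genome, L)
    elif mode == "seeded":
        best = _seeded_best_matches(cands, genome, L, cfg.homology_seed_k)
    else:
        raise ValueError(f"unknown homology mode {mode!r}")
    thresh = cfg.homology_threshold
    out = []
    for c, b in zip(cands, best):
        ident = float(b) / L
        if ident < thresh:
            out.append(replace(c, max_offtarget_identity=ident))
    return out


def brute_force_offtarget_identity(cand, genome: dict, L: int) -> float:
    """Independent oracle: max off-target identity by direct sliding comparison.

    Naive per-candidate scan over all windows of both strands, excluding the
    candidate's own plus-strand origin.  Quadratic; for small genomes only.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    q = encode(cand.sequence)
    best = 0
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    for chrom, seq in genome.items():
        g = encode(seq)
        for strand in "+-":
            garr = g if strand == "+" else comp[g][::-1]
            if garr.size < L:
                continue
            win = sliding_window_view(garr, L)
            m = (win == q).sum(axis=1)
            if strand == "+" and chrom == cand.chrom:
                m[cand.start] = 0
            best = max(best, int(m.max()))
    return best / L


# ---------------------------------------------------------------------------
# k-mer depth filter
# ---------------------------------------------------------------------------

def _candidate_kmer_depths(cands, table) -> tuple[np.ndarray, np.ndarray]:
    k = table.k
    C = _encode_matrix(cands)
    fwd = _row_kmer_codes(C, k)
    Crc = np.stack([encode(revcomp(c.sequence)) for c in cands])
    rc = _row_kmer_codes(Crc, k)[:, ::-1]
    canon = np.minimum(fwd, rc)
    depths = table.lookup_codes(canon.ravel()).reshape(canon.shape)
    return depths.mean(axis=1), depths.max(axis=1)


def filter_kmer_depth(cands, table, cfg: DesignConfig):
    """Quantile-band + per-k-mer-cap depth filter.

    Scores each candidate by the mean depth of its constituent canonical
    k-mers; retains candidates whose score lies inside the inclusive
    [kmer_q, kmer_p] quantile band of all candidate scores and whose deepest
    single k-mer does not exceed ``kmer_d`` times the median score.
    """
    if not cands:
        return []
    if table is None or len(table) == 0:
        warnings.warn("empty k-mer table: depth filter skipped", stacklevel=2)
        return [replace(c, kmer_score=0.0) for c in cands]
    scores, maxima = _candidate_kmer_depths(cands, table)
    lo = np.quantile(scores, cfg.kmer_q)
    hi = np.quantile(scores, cfg.kmer_p)
    med = np.median(scores)
    keep = (scores >= lo) & (scores <= hi) & (maxima <= cfg.kmer_d * med)
    return [
        replace(c, kmer_score=float(s))
        for c, s, k in zip(cands, scores, keep)
        if k
    ]


# ---------------------------------------------------------------------------
# Density capping
# ---------------------------------------------------------------------------

def _max_min_gap_subset(positions: np.ndarray, cap: int) -> np.ndarray:
    """Indices of the size-``cap`` subset maximizing the minimum pairwise gap.

    Binary search on the gap, greedy left-to-right feasibility check;
    deterministic and position-based.
    """
    n = positions.size

    def greedy_count(g: int) -> int:
        count, last = 1, positions[0]
        for p in positions[1:]:
            if p - last >= g:
                count += 1
                last = p
        return count

    lo_g, hi_g = 0, int(positions[-1] - positions[0])
    while lo_g < hi_g:  # largest g with greedy_count(g) >= cap
        mid = (lo_g + hi_g + 1) // 2
        if greedy_count(mid) >= cap:
            lo_g = mid
        else:
            hi_g = mid - 1
    g = lo_g
    chosen = [0]
    last = positions[0]
    for i in range(1, n):
        if len(chosen) == cap:
            break
        if positions[i] - last >= g:
            chosen.append(i)
            last = positions[i]
    return np.array(chosen[:cap], dtype=np.int64)


def cap_density(cands, cfg: DesignConfig):
    """Thin each density window to at most ``density_cap`` oligos.

    Windows tile each chromosome at ``density_step`` (window == step at
    defaults).  Over-cap windows keep the evenest subset (maximum minimum
    gap).  Idempotent.
    """
    if not cands:
        return []
    order = sorted(range(len(cands)), key=lambda i: (cands[i].chrom, cands[i].start))
    by_chrom = {}
    for i in order:
        by_chrom.setdefault(cands[i].chrom, []).append(i)
    kept = []
    for chrom, idxs in by_chrom.items():
        starts = np.array([cands[i].start for i in idxs], dtype=np.int64)
        max_start = int(starts.max())
        w, step = cfg.density_window, cfg.density_step
        t = 0
        while t <= max_start:
            in_w = np.nonzero((starts >= t) & (starts < t + w))[0]
            if in_w.size > cfg.density_cap:
                sel = _max_min_gap_subset(starts[in_w], cfg.density_cap)
                in_w = in_w[sel]
            kept.extend(idxs[j] for j in in_w)
            t += step
    kept.sort()
    return [cands[i] for i in kept]


def write_oligos_bed(cands, path=None) -> str:
    """BED6 of retained oligos; score = 1000 * kmer_score / median score."""
    from .io import write_bed

    scores = np.array([c.kmer_score for c in cands], dtype=float)
    med = np.nanmedian(scores) if cands else float("nan")
    rows = []
    for i, c in enumerate(cands):
        s = 0 if not np.isfinite(c.kmer_score) or not med or not np.isfinite(med) \
            else int(round(1000 * c.kmer_score / med))
        rows.append((c.chrom, c.start, c.end, f"oligo_{i:06d}", s, "+"))
    return write_bed(rows, path)
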