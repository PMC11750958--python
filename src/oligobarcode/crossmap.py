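"""Cross-species oligo mapping and orthology classification.

Maps designed oligos onto a second genome by ungapped best-identity
placement, classifies placements as orthologous or not under a chromosome
orthology map, and bins placements into tiling windows (100 kb default) for
downstream plotting.

Mapping uses exact k-mer seeding with disjoint seed windows sized so that
any placement at identity >= ``min_identity`` must contain one clean seed
(pigeonhole over mismatches); seeded loci are verified by full-length
comparison, so the reported best placement is exact despite the heuristic
flavor.  Only ungapped alignment is modeled.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._seq import KmerIndex, encode, revcomp

UNMAPPED = "UNMAPPED"

_PLACEMENT_COLUMNS = (
    "oligo_id", "source_chrom", "target_chrom", "target_start",
    "strand", "identity", "multi_mapping",
)


def _as_pairs(oligos):
    """Normalize input to (oligo_id, source_chrom, sequence) triples."""
    out = []
    for o in oligos:
        if hasattr(o, "sequence"):
            out.append((o.id, o.chrom, o.sequence))
        else:
            oid, seq = o
            out.append((oid, oid.split(":")[0] if ":" in oid else "", seq))
    return out


def map_oligos(oligos, target: dict, min_identity: float = 0.9) -> pd.DataFrame:
    """Best ungapped placement of each oligo in the target genome.

    Returns one row per oligo; ``target_chrom`` is ``"UNMAPPED"`` when the
    best identity over both strands falls below ``min_identity``.  Ties on
    identity are broken by (chromosome id, position, strand) lexicographic
    order and flagged in ``multi_mapping``.
    """
    triples = _as_pairs(oligos)
    rows = {
        oid: [oid, src, UNMAPPED, -1, ".", 0.0, False]
        for oid, src, _ in triples
    }
    if target and triples:
        enc = {name: encode(seq) for name, seq in target.items()}
        by_len = {}
        for oid, src, seq in triples:
            if not (30 <= len(seq) <= 100):
                raise ValueError(f"oligo {oid}: length must be 30-100 nt")
            by_len.setdefault(len(seq), []).append((oid, seq))
        for L, group in by_len.items():
            mm_max = int((1.0 - min_identity) * L)
            k = min(31, max(4, L // (mm_max + 1)))
            index = KmerIndex(enc, k)
            _map_group(group, index, L, k, mm_max, min_identity, rows)
    df = pd.DataFrame(list(rows.values()), columns=_PLACEMENT_COLUMNS)
    return df


def _map_group(group, index: KmerIndex, L, k, mm_max, min_identity, rows):
    chrom_names = index.chrom_names
    bounds = index._bounds
    lengths = np.array([index.chrom_length(n) for n in chrom_names], dtype=np.int64)
    seed_offs = np.arange(0, (mm_max + 1) * k, k, dtype=np.int64)
    offs = np.arange(L)
    order_rank = {n: i for i, n in enumerate(sorted(chrom_names))}

    best = {}  # oligo_id -> (identity, rank, pos, strand_pref, chrom, start, strand)
    counts = {}

    for orient, strand in ((0, "+"), (1, "-")):
        seqs = [s if orient == 0 else revcomp(s) for _, s in group]
        S = np.stack([encode(s) for s in seqs])
        codes = np.zeros((len(group), seed_offs.size), dtype=np.uint64)
        for si, off in enumerate(seed_offs):
            c = np.zeros(len(group), dtype=np.uint64)
            for j in range(k):
                c = (c << np.uint64(2)) | S[:, off + j].astype(np.uint64)
            codes[:, si] = c
        flat = codes.ravel()
        lo, hi = index.find_many(flat)
        lens = hi - lo
        nz = np.nonzero(lens)[0]
        if nz.size == 0:
            continue
        pos_idx = np.concatenate([np.arange(lo[i], hi[i]) for i in nz])
        reps = lens[nz]
        oligo_of = np.repeat(nz // seed_offs.size, reps)
        off_of = np.repeat(seed_offs[nz % seed_offs.size], reps)
        gstart = index.sorted_pos[pos_idx] - off_of
        ci = np.clip(np.searchsorted(bounds, gstart, side="right") - 1, 0, len(chrom_names) - 1)
        lo_b = bounds[ci]
        ok = (gstart >= lo_b) & (gstart + L <= lo_b + lengths[ci])
        oligo_of, gstart, ci = oligo_of[ok], gstart[ok], ci[ok]
        if oligo_of.size == 0:
            continue
        pairs = np.unique(np.stack([oligo_of, gstart]), axis=1)
        oligo_of, gstart = pairs[0], pairs[1]
        ci = np.clip(np.searchsorted(bounds, gstart, side="right") - 1, 0, len(chrom_names) - 1)
        windows = index.concat[gstart[:, None] + offs[None, :]]
        matches = (windows == S[oligo_of]).sum(axis=1)
        ident = matches / L
        good = ident >= min_identity
        for oi, gs, c, idv in zip(
            oligo_of[good], gstart[good], ci[good], ident[good]
        ):
            oid = group[oi][0]
            chrom = chrom_names[c]
            # minus-strand placements are reported in plus-strand coordinates
            local = int(gs) - index.offsets[chrom]
            key = (-idv, order_rank[chrom], local, 0 if strand == "+" else 1)
            cur = best.get(oid)
            if cur is None or key < cur[0]:
                best[oid] = (key, chrom, local, strand, float(idv))
            counts.setdefault(oid, []).append(round(float(idv), 9))

    for oid, (key, chrom, local, strand, idv) in best.items():
        top = max(counts[oid])
        multi = counts[oid].count(top) > 1
        rows[oid] = [oid, rows[oid][1], chrom, local, strand, idv, multi]


def classify_orthology(placements: pd.DataFrame, ortholog_map: dict) -> dict:
    """Mapping and non-orthologous placement rates.

    ``non_orthologous_fraction_of_mapped`` uses the mapped count as the
    denominator (matching how the published 4.95% relates to its counts);
    ``non_orthologous_fraction_of_total`` uses all designed oligos, as the
    headline mapped fraction does.  Placements whose source chromosome is
    absent from the map are counted as NA and reported.
    """
    df = placements
    total = len(df)
    if total == 0:
        warnings.warn("no placements to classify", stacklevel=2)
        return {
            "total": 0, "mapped": 0, "mapped_fraction": 0.0,
            "non_orthologous": 0, "non_orthologous_fraction_of_mapped": 0.0,
            "non_orthologous_fraction_of_total": 0.0, "na": 0,
            "per_chromosome": pd.DataFrame(),
        }
    mapped = df["target_chrom"] != UNMAPPED
    has_map = df["source_chrom"].isin(ortholog_map)
    na_mask = mapped & ~has_map
    if na_mask.any():
        warnings.warn(
            f"{int(na_mask.sum())} placements from chromosomes absent from the "
            "ortholog map counted as NA", stacklevel=2,
        )
    expected = df["source_chrom"].map(ortholog_map)
    non_orth = mapped & has_map & (df["target_chrom"] != expected)

    per = (
        df.assign(mapped=mapped, non_orth=non_orth)
        .groupby("source_chrom", sort=True)
        .agg(total=("oligo_id", "size"), mapped=("mapped", "sum"),
             non_orthologous=("non_orth", "sum"))
        .reset_index()
    )
    per["mapped_fraction"] = per["mapped"] / per["total"]
    per["non_orthologous_fraction_of_mapped"] = np.where(
        per["mapped"] > 0, per["non_orthologous"] / per["mapped"], 0.0
    )

    n_mapped = int(mapped.sum())
    n_non = int(non_orth.sum())
    return {
        "total": total,
        "mapped": n_mapped,
        "mapped_fraction": n_mapped / total,
        "non_orthologous": n_non,
        "non_orthologous_fraction_of_mapped": (n_non / n_mapped) if n_mapped else 0.0,
        "non_orthologous_fraction_of_total": n_non / total,
        "na": int(na_mask.sum()),
        "per_chromosome": per,
    }


def window_counts(
    placements: pd.DataFrame, target_chrom_lengths: dict, window: int = 100_000
) -> pd.DataFrame:
    """Placement counts in tiling windows per target chromosome (BED4-style).

    A placement falls in the window containing its start; totals conserve
    the number of mapped placements on known chromosomes.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mapped = placements[placements["target_chrom"] != UNMAPPED]
    rows = []
    for chrom in sorted(target_chrom_lengths):
        L = target_chrom_lengths[chrom]
        starts = mapped.loc[mapped["target_chrom"] == chrom, "target_start"].to_numpy()
        for w in range(0, max(L, 1), window):
            end = min(w + window, L)
            n = int(((starts >= w) & (starts < end)).sum())
            rows.append((chrom, w, end, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
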