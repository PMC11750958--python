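"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by enumeration or direct
scanning, independent of the library's optimized paths, so tests compare
two routes to the same answer.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

import numpy as np
import pytest
import yaml

from oligobarcode import simgenome as sg
from oligobarcode.config import DesignConfig
from oligobarcode.io import write_fasta
from oligobarcode.pipeline import RunConfig, run_pipeline


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def exhaustive_max_matching(positions, min_sep: int) -> int:
    """Maximum number of disjoint pairs with separation >= min_sep, by
    exhaustive recursion over all matchings (n <= ~12)."""
    pos = tuple(sorted(positions))

    @lru_cache(maxsize=None)
    def best(remaining: frozenset) -> int:
        if len(remaining) < 2:
            return 0
        items = sorted(remaining)
        first = items[0]
        rest = frozenset(items[1:])
        result = best(rest)  # leave first unmatched
        for j in items[1:]:
            if pos[j] - pos[first] >= min_sep:
                result = max(result, 1 + best(rest - {j}))
        return result

    n = len(pos)
    out = best(frozenset(range(n)))
    best.cache_clear()
    return out


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_max_offtarget(seq: str, genome: dict, own: tuple) -> float:
    """Max full-length ungapped off-target identity by direct string scan."""
    L = len(seq)
    best = 0
    for chrom, g in genome.items():
        for strand, text in (("+", g), ("-", naive_revcomp(g))):
            for p in range(len(text) - L + 1):
                if strand == "+" and (chrom, p) == own:
                    continue
                m = sum(1 for a, b in zip(seq, text[p : p + L]) if a == b)
                if m > best:
                    best = m
    return best / L


def naive_max_offtarget_fast(seq: str, genome: dict, own: tuple) -> float:
    """Same oracle vectorized with a sliding-window view (still exhaustive)."""
    from numpy.lib.stride_tricks import sliding_window_view

    from oligobarcode._seq import encode

    L = len(seq)
    q = encode(seq)
    qrc = encode(naive_revcomp(seq))
    best = 0
    for chrom, g in genome.items():
        garr = encode(g)
        if garr.size < L:
            continue
        win = sliding_window_view(garr, L)
        m = (win == q).sum(axis=1)
        if chrom == own[0]:
            m[own[1]] = 0
        best = max(best, int(m.max()))
        # minus strand: candidate reverse-complement against plus strand
        m2 = (win == qrc).sum(axis=1)
        best = max(best, int(m2.max()))
    return best / L


def naive_best_placement(seq: str, genome: dict):
    """Best ungapped placement by direct scan: (identity, chrom, pos, strand)."""
    from numpy.lib.stride_tricks import sliding_window_view

    from oligobarcode._seq import encode

    L = len(seq)
    best_key, best = None, (0.0, "", -1, ".")
    for chrom in sorted(genome):
        garr = encode(genome[chrom])
        if garr.size < L:
            continue
        win = sliding_window_view(garr, L)
        for srank, (strand, q) in enumerate(
            (("+", encode(seq)), ("-", encode(naive_revcomp(seq))))
        ):
            m = (win == q).sum(axis=1)
            for p in np.nonzero(m == m.max())[0]:
                key = (-m[p] / L, chrom, int(p), srank)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (m[p] / L, chrom, int(p), strand)
    return best


# ---------------------------------------------------------------------------
# Toy pipeline fixture (session-scoped; reused by several acceptance tests)
# ---------------------------------------------------------------------------

def build_toy_inputs(root: Path, seed: int = 17):
    """Synthesize the toy study genome + all pipeline inputs under ``root``."""
    root.mkdir(parents=True, exist_ok=True)
    repeat = sg.RepeatFamily(
        "LTR1", 3000,
        [("chr1", 150_000), ("chr1", 450_000), ("chr2", 220_000)],
        identity=0.98,
    )
    genome, truth = sg.make_genome(
        {"chr1": 600_000, "chr2": 600_000}, seed=seed, repeats=[repeat]
    )
    write_fasta(genome, root / "genome.fa")
    truth.centromeres_bed(root / "centromeres.bed")
    table = sg.make_kmer_table(genome, 21, 50, seed=seed + 1)
    table.to_tsv(root / "kmers.tsv")
    regions = sg.make_barcode_spec(truth.chrom_lengths, truth.centromeres)
    (root / "design.yaml").write_text(yaml.safe_dump({"regions": regions}))
    return genome, truth


def toy_run_config(root: Path, out_dir: Path, seed: int = 99) -> RunConfig:
    return RunConfig(
        genome_path=str(root / "genome.fa"),
        design_spec_path=str(root / "design.yaml"),
        centromeres_path=str(root / "centromeres.bed"),
        kmer_table_path=str(root / "kmers.tsv"),
        out_dir=str(out_dir),
        seed=seed,
        design=DesignConfig(step=100),
    )


@pytest.fixture(scope="session")
def toy_inputs(tmp_path_factory):
    root = tmp_path_factory.mktemp("toy_inputs")
    genome, truth = build_toy_inputs(root)
    return {"root": root, "genome": genome, "truth": truth}


@pytest.fixture(scope="session")
def toy_run(toy_inputs, tmp_path_factory):
    out = tmp_path_factory.mktemp("toy_run")
    cfg = toy_run_config(toy_inputs["root"], out)
    report = run_pipeline(cfg)
    return {**toy_inputs, "cfg": cfg, "report": report, "out": out}
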