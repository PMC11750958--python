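"""Synthetic-genome generator: determinism, truth consistency, mutation model."""

import numpy as np
import pytest
from scipy import stats

from oligobarcode import simgenome as sg
from oligobarcode.io import write_fasta


def test_lengths_and_byte_determinism():
    g1, t1 = sg.make_genome({"chrA": 500_000, "chrB": 500_000}, seed=7)
    g2, t2 = sg.make_genome({"chrA": 500_000, "chrB": 500_000}, seed=7)
    assert {k: len(v) for k, v in g1.items()} == {"chrA": 500_000, "chrB": 500_000}
    assert write_fasta(g1) == write_fasta(g2)
    assert t1.chrom_lengths == t2.chrom_lengths
    g3, _ = sg.make_genome({"chrA": 500_000, "chrB": 500_000}, seed=8)
    assert g3 != g1


def test_truth_fasta_consistency_for_planted_repeats():
    fam = sg.RepeatFamily("fam1", 1200, [("c1", 5_000), ("c1", 20_000)], identity=1.0)
    g, truth = sg.make_genome({"c1": 40_000}, seed=3, repeats=[fam])
    (c, s1, e1, _), (_, s2, e2, _) = truth.repeat_intervals
    assert g["c1"][s1:e1] == g["c1"][s2:e2]  # exact family: identical copies


def test_partial_identity_copies_match_at_configured_rate():
    fam = sg.RepeatFamily("fam", 1000, [("c1", 5_000), ("c1", 20_000)], identity=0.9)
    g, truth = sg.make_genome({"c1": 40_000}, seed=5, repeats=[fam])
    a = g["c1"][5_000:6_000]
    b = g["c1"][20_000:21_000]
    ident = sum(x == y for x, y in zip(a, b)) / 1000
    # each copy carries 100 substitutions vs consensus; pairwise ~0.81-0.86
    assert 0.78 <= ident < 0.95


def test_rdna_array_head_to_tail_and_unit_count():
    spec = sg.RdnaArraySpec("c1", 10_000, 7)
    g, truth = sg.make_genome({"c1": 60_000}, seed=11, rdna_arrays=[spec])
    rec = truth.rdna_arrays[0]
    assert rec["unit_count"] == 7
    ivs = rec["unit_intervals"]
    assert len(ivs) == 7
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        assert s2 == e1  # head-to-tail
    unit = sg.rdna_unit_sequence(sg.synthetic_rdna_subunits())
    assert g["c1"][ivs[0][0] : ivs[0][1]] == unit


def test_overlapping_planted_features_rejected_with_names():
    fam = sg.RepeatFamily("famX", 2000, [("c1", 5_000), ("c1", 6_000)])
    with pytest.raises(ValueError, match="famX"):
        sg.make_genome({"c1": 40_000}, seed=1, repeats=[fam])


def test_mutate_identity_case_and_inversion():
    g, _ = sg.make_genome({"c1": 30_000}, seed=2)
    out, realized = sg.mutate_genome(g, sg.RearrangementMap(), seed=5)
    assert out == g
    inv = sg.RearrangementMap(inversions=[("c1", 10_000, 20_000)])
    out2, _ = sg.mutate_genome(g, inv, seed=5)
    from oligobarcode._seq import revcomp

    assert out2["c1"][10_000:20_000] == revcomp(g["c1"][10_000:20_000])
    assert out2["c1"][:10_000] == g["c1"][:10_000]
    # reverse complement conserves length and the A+T / C+G totals
    assert len(out2["c1"]) == len(g["c1"])
    for pair in ("AT", "CG"):
        assert sum(out2["c1"].count(b) for b in pair) == sum(
            g["c1"].count(b) for b in pair
        )


def test_snp_count_within_binomial_99_interval():
    n, rate = 100_000, 0.02
    g, _ = sg.make_genome({"c1": n}, seed=4)
    out, realized = sg.mutate_genome(g, sg.RearrangementMap(snp_rate=rate), seed=9)
    observed = sum(a != b for a, b in zip(g["c1"], out["c1"]))
    assert observed == realized.snp_counts["c1"]
    lo = stats.binom.ppf(0.005, n, rate)
    hi = stats.binom.ppf(0.995, n, rate)
    assert lo <= observed <= hi


def test_translocation_conserves_total_length():
    g, _ = sg.make_genome({"c1": 30_000, "c2": 30_000}, seed=6)
    tl = sg.RearrangementMap(translocations=[("c1", 2_000, 7_000, "c2", 10_000)])
    out, _ = sg.mutate_genome(g, tl, seed=1)
    assert len(out["c1"]) + len(out["c2"]) == 60_000
    assert out["c2"][10_000:15_000] == g["c1"][2_000:7_000]


def test_bad_intervals_rejected():
    g, _ = sg.make_genome({"c1": 30_000}, seed=6)
    with pytest.raises(ValueError):
        sg.mutate_genome(g, sg.RearrangementMap(inversions=[("c1", 10, 40_000)]), seed=1)
    with pytest.raises(ValueError):
        sg.RearrangementMap(snp_rate=0.5)


def test_kmer_table_depth_zero_and_unique_region_depths():
    g, _ = sg.make_genome({"c1": 50_000}, seed=12)
    t0 = sg.make_kmer_table(g, 21, 0, seed=1)
    assert int(t0.counts.sum()) == 0

    depth = 50
    table = sg.make_kmer_table(g, 21, depth, seed=1)
    from oligobarcode._seq import encode

    codes = sg.canonical_codes(encode(g["c1"][1_000:1_050]), 21)
    counts = table.lookup_codes(codes)
    lo = stats.poisson.ppf(0.005, depth)
    hi = stats.poisson.ppf(0.995, depth)
    assert np.all(counts >= lo) and np.all(counts <= hi)


def test_kmer_table_repeat_multiplicity():
    fam = sg.RepeatFamily("r", 500, [("c1", p) for p in range(2_000, 22_000, 2_000)])
    g, _ = sg.make_genome({"c1": 50_000}, seed=13, repeats=[fam])
    table = sg.make_kmer_table(g, 21, 50, seed=2)
    from oligobarcode._seq import encode

    rep_codes = sg.canonical_codes(encode(g["c1"][2_100:2_300]), 21)
    rep_depth = table.lookup_codes(rep_codes).mean()
    uniq_codes = sg.canonical_codes(encode(g["c1"][30_000:30_200]), 21)
    uniq_depth = table.lookup_codes(uniq_codes).mean()
    assert 8 <= rep_depth / uniq_depth <= 12  # 10 planted copies


def test_kmer_table_k_longer_than_sequence_errors():
    with pytest.raises(ValueError):
        sg.make_kmer_table({"c1": "ACGT" * 5}, 21, 10, seed=0)
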