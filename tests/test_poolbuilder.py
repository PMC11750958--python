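"""Pairing, primer battery, unit assembly, in-silico PCR, order file."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligobarcode import poolbuilder as pb
from oligobarcode.config import DesignConfig
from oligobarcode.oligoselect import OligoCandidate
from oligobarcode._seq import revcomp

from conftest import exhaustive_max_matching

CFG = DesignConfig()


def _oligo(start, chrom="c1", seq=None, rng=None):
    if seq is None:
        seq = "".join("ACGT"[i] for i in (rng or np.random.default_rng(start)).integers(0, 4, 50))
    return OligoCandidate(chrom, start, 50, seq)


# ----------------------------------------------------------------- pairing

@pytest.mark.parametrize(
    "positions,expected",
    [
        ([0, 250_000], 1),
        ([0, 100_000], 0),
        ([0, 100_000, 300_000, 420_000], 2),
        ([], 0),
        ([5], 0),
    ],
)
def test_pairing_examples(positions, expected):
    pairs, unpaired = pb.pair_oligos([_oligo(p) for p in positions], CFG)
    assert len(pairs) == expected
    assert len(pairs) * 2 + len(unpaired) == len(positions)
    for a, b in pairs:
        assert b.start - a.start >= CFG.min_pair_separation


def test_pairing_specific_optimal_matching():
    pairs, _ = pb.pair_oligos([_oligo(p) for p in [0, 100_000, 300_000, 420_000]], CFG)
    assert [(a.start, b.start) for a, b in pairs] == [(0, 300_000), (100_000, 420_000)]


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    st.lists(st.integers(0, 1_200_000), min_size=0, max_size=12, unique=True),
    st.integers(1, 400_000),
)
def test_pairing_cardinality_equals_exhaustive_matching(positions, min_sep):
    cfg = DesignConfig(min_pair_separation=min_sep)
    pairs, unpaired = pb.pair_oligos([_oligo(p) for p in positions], cfg)
    assert len(pairs) == exhaustive_max_matching(positions, min_sep)
    used = [a.start for a, _ in pairs] + [b.start for _, b in pairs] + [
        u.start for u in unpaired
    ]
    assert sorted(used) == sorted(positions)  # each oligo used at most once


# ----------------------------------------------------------------- primers

@pytest.fixture(scope="module")
def primer_battery():
    from oligobarcode import simgenome as sg

    genome, _ = sg.make_genome({"c1": 40_000}, seed=30)
    return genome, pb.design_primer_sets(2, 21, 1, genome, seed=31)


def test_primer_battery_satisfies_all_invariants(primer_battery):
    genome, primers = primer_battery
    assert len(primers) == 24
    scopes = [p.scope for p in primers]
    assert scopes.count(pb.FORWARD_COLOR) == 2
    assert scopes.count(pb.REVERSE_GROUP) == 21
    assert scopes.count(pb.REVERSE_POOL) == 1
    for p in primers:
        assert 0.40 <= p.gc <= 0.60
        assert abs(p.tm - 55.0) <= 2.0
        assert not pb.has_hairpin(p.sequence)
        assert p.tm == pytest.approx(pb.melting_temperature(p.sequence), abs=0.01)
    for i, a in enumerate(primers):
        for b in primers[i:]:
            assert pb.three_prime_complementarity(a.sequence, b.sequence) <= 3
    # no perfect >= 15-nt genome match on either strand
    text = genome["c1"]
    for p in primers:
        for s in (p.sequence, revcomp(p.sequence)):
            for j in range(len(s) - 14):
                assert s[j : j + 15] not in text


def test_primer_requests_zero_and_unsatisfiable():
    assert pb.design_primer_sets(0, 0, 0, {}, seed=1) == []
    with pytest.raises(RuntimeError, match="unsatisfiable"):
        pb.design_primer_sets(10_000, 0, 0, {}, seed=1, length=6, max_iterations=5_000)


def test_three_prime_complementarity_detects_dimer():
    a = "ACGTACGTACGTACGTAAGG"  # 3' ...AAGG
    b = "TTTTTTTTTTTTTTTTCCTT"  # 3' ...CCTT; revcomp(CCTT)=AAGG
    assert pb.three_prime_complementarity(a, b) >= 4


def test_hairpin_detection():
    stem = "ACGTGC"
    seq = stem + "AAAA" + revcomp(stem) + "ACGT"
    assert pb.has_hairpin(seq)
    # A/C-only sequences cannot form any complementary stem
    assert not pb.has_hairpin("AAAAAAAAAACCCCCCCCCC")


# ----------------------------------------------------------------- units

def test_unit_layout_and_length(primer_battery):
    _, primers = primer_battery
    fwd = [p for p in primers if p.scope == pb.FORWARD_COLOR][0]
    grp = [p for p in primers if p.scope == pb.REVERSE_GROUP][0]
    pool = [p for p in primers if p.scope == pb.REVERSE_POOL][0]
    rng = np.random.default_rng(40)
    a, b = _oligo(0, rng=rng), _oligo(300_000, rng=rng)
    u = pb.build_unit((a, b), fwd, grp, pool, unit_id="U1", color="RED")
    assert len(u.full_sequence) == 100 + 20 + 20 + 20
    assert u.full_sequence == (
        fwd.sequence + a.sequence + b.sequence
        + revcomp(grp.sequence) + revcomp(pool.sequence)
    )
    assert u.genomic_separation == 300_000
    assert u.insert == a.sequence + b.sequence

    bare = pb.build_unit((a, b), None, None, None, unit_id="U2")
    assert len(bare.full_sequence) == 100


def test_unit_rejects_primer_inside_insert(primer_battery):
    _, primers = primer_battery
    fwd = primers[0]
    rng = np.random.default_rng(41)
    a = _oligo(0, seq=fwd.sequence + "".join("ACGT"[i] for i in rng.integers(0, 4, 30)))
    b = _oligo(300_000, rng=rng)
    with pytest.raises(ValueError, match="ambiguous"):
        pb.build_unit((a, b), fwd, None, None)


def test_pcr_selectivity_one_pool(primer_battery):
    _, primers = primer_battery
    fwds = [p for p in primers if p.scope == pb.FORWARD_COLOR]
    grps = [p for p in primers if p.scope == pb.REVERSE_GROUP][:3]
    poolp = [p for p in primers if p.scope == pb.REVERSE_POOL][0]
    rng = np.random.default_rng(42)
    pool = []
    for color, fwd in zip(("RED", "GREEN"), fwds):
        for gi, grp in enumerate(grps):
            for k in range(2):
                a = _oligo(0, chrom=f"chr{gi}", rng=rng)
                b = _oligo(300_000, chrom=f"chr{gi}", rng=rng)
                pool.append(
                    pb.build_unit(
                        (a, b), fwd, grp, poolp,
                        unit_id=f"U{len(pool):03d}", color=color, group=f"chr{gi}",
                    )
                )
    for color, fwd in zip(("RED", "GREEN"), fwds):
        got = set(pb.insilico_pcr(pool, fwd, poolp))
        assert got == {u.unit_id for u in pool if u.color == color}
        for gi, grp in enumerate(grps):
            got_g = set(pb.insilico_pcr(pool, fwd, grp))
            assert got_g == {
                u.unit_id for u in pool if u.color == color and u.group == f"chr{gi}"
            }
    unused = pb.PrimerSet("X", "ACGTACGTACGTACGTACGT", pb.REVERSE_GROUP, 50.0, 0.5)
    assert pb.insilico_pcr(pool, fwds[0], unused) == []


# ----------------------------------------------------------------- order file

def test_order_file_roundtrip_and_errors(primer_battery):
    _, primers = primer_battery
    fwd = primers[0]
    grp = [p for p in primers if p.scope == pb.REVERSE_GROUP][0]
    poolp = [p for p in primers if p.scope == pb.REVERSE_POOL][0]
    rng = np.random.default_rng(43)
    pool = [
        pb.build_unit(
            (_oligo(i * 10, rng=rng), _oligo(300_000 + i * 10, rng=rng)),
            fwd, grp, poolp, unit_id=f"U{i}", color="RED",
        )
        for i in range(3)
    ]
    text = pb.emit_order_file(pool)
    rows = pb.read_order_file(text)
    assert len(rows) == 3
    for u, r in zip(pool, rows):
        assert r["unit_id"] == u.unit_id
        assert r["full_sequence"] == u.full_sequence
        assert r["separation"] == u.genomic_separation

    with pytest.raises(ValueError, match="duplicate unit_id"):
        pb.emit_order_file([pool[0], pool[0]])

    import dataclasses

    clone = dataclasses.replace(pool[1], unit_id="U9")
    with pytest.warns(UserWarning, match="synthesis collision"):
        pb.emit_order_file([pool[1], clone])

    with pytest.raises(ValueError, match="empty pool"):
        pb.emit_order_file([])
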