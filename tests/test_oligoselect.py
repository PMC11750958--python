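"""Candidate extraction and the homology / depth / density filters."""

import numpy as np
import pytest

from oligobarcode import oligoselect as osel
from oligobarcode import simgenome as sg
from oligobarcode.config import DesignConfig

from conftest import naive_max_offtarget_fast


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_extraction_grid_and_boundaries():
    rng = np.random.default_rng(0)
    cfg = DesignConfig()
    g = {"c1": _random_seq(rng, 100)}
    cands = osel.extract_candidates(g, cfg)
    assert [c.start for c in cands] == list(range(0, 51, 5))
    assert all(c.sequence == g["c1"][c.start : c.start + 50] for c in cands)

    exact = {"c1": _random_seq(rng, 50)}
    assert len(osel.extract_candidates(exact, cfg)) == 1

    with pytest.raises(ValueError):
        osel.extract_candidates({}, cfg)


def test_windows_containing_n_are_dropped():
    rng = np.random.default_rng(1)
    seq = _random_seq(rng, 200)
    seq = seq[:100] + "N" + seq[101:]
    cands = osel.extract_candidates({"c1": seq}, DesignConfig())
    starts = {c.start for c in cands}
    # windows covering position 100 are absent
    assert all(not (s <= 100 < s + 50) for s in starts)
    assert 0 in starts and 150 in starts


@pytest.mark.parametrize("mode", ["exact", "seeded"])
def test_verbatim_duplicate_removed(mode):
    rng = np.random.default_rng(2)
    seq = _random_seq(rng, 4_000)
    seq = seq[:2_000] + seq[100:150] + seq[2_050:]  # copy of window at 100
    g = {"c1": seq}
    cfg = DesignConfig(step=100)
    cands = [c for c in osel.extract_candidates(g, cfg)]
    kept = osel.filter_homology(cands, g, cfg, mode=mode)
    kept_ids = {c.id for c in kept}
    assert "c1:100" not in kept_ids
    assert "c1:2000" not in kept_ids


def test_threshold_sharpness_37_vs_38_matches():
    """A second copy at 37/50 (0.74) is retained; at 38/50 (0.76) removed."""
    rng = np.random.default_rng(3)
    base = _random_seq(rng, 20_000)
    src = base[100:150]

    def plant(n_mismatch, at):
        copy = list(src)
        pos = rng.choice(50, size=n_mismatch, replace=False)
        for p in pos:
            copy[p] = "ACGT"[("ACGT".index(copy[p]) + 1) % 4]
        return base[:at] + "".join(copy) + base[at + 50 :]

    cfg = DesignConfig()
    for n_mm, expect_removed in ((13, False), (12, True)):
        g = {"c1": plant(n_mm, 10_000)}
        cand = osel.OligoCandidate("c1", 100, 50, g["c1"][100:150])
        kept = osel.filter_homology([cand], g, cfg, mode="exact")
        removed = not kept
        assert removed == expect_removed
        if kept:
            assert kept[0].max_offtarget_identity == pytest.approx((50 - n_mm) / 50)


def test_exact_mode_agrees_with_naive_scan_on_random_genome():
    rng = np.random.default_rng(4)
    fam = sg.RepeatFamily("f", 800, [("c1", 3_000), ("c1", 12_000)], identity=0.98)
    g, _ = sg.make_genome({"c1": 30_000}, seed=21, repeats=[fam])
    cfg = DesignConfig(step=300)
    cands = osel.extract_candidates(g, cfg)
    kept = {c.id for c in osel.filter_homology(cands, g, cfg, mode="exact")}
    for c in cands:
        oracle = naive_max_offtarget_fast(c.sequence, g, (c.chrom, c.start))
        assert (oracle < cfg.homology_threshold) == (c.id in kept)


def test_homology_empty_input():
    assert osel.filter_homology([], {"c1": "ACGT" * 100}, DesignConfig()) == []


def test_kmer_filter_degenerate_equal_scores_keeps_all():
    rng = np.random.default_rng(5)
    g = {"c1": _random_seq(rng, 30_000)}
    cfg = DesignConfig(step=500)
    cands = osel.extract_candidates(g, cfg)
    table = sg.make_kmer_table(g, 21, 0, seed=1)  # all counts zero: all equal
    kept = osel.filter_kmer_depth(cands, table, cfg)
    assert len(kept) == len(cands)


def test_kmer_filter_removes_repeat_depth_and_dropout():
    # 10 exact copies occupying ~5% of the genome (repeats must be a
    # minority for the quantile band to isolate them, as in real data)
    fam = sg.RepeatFamily("r", 1_000, [("c1", p) for p in range(3_000, 43_000, 4_000)])
    g, _ = sg.make_genome({"c1": 200_000}, seed=22, repeats=[fam])
    cfg = DesignConfig(step=200)
    cands = osel.extract_candidates(g, cfg)
    table = sg.make_kmer_table(g, 21, 50, seed=3)

    # dropout: zero the counts of k-mers from a unique region
    from oligobarcode._seq import encode

    gap_codes = sg.canonical_codes(encode(g["c1"][50_000:51_000]), 21)
    zero = np.isin(table.codes, gap_codes)
    table.counts[zero] = 0

    kept = {c.id for c in osel.filter_kmer_depth(cands, table, cfg)}
    in_repeat = [c for c in cands if any(
        s <= c.start and c.end <= e for _, s, e, _ in _repeat_ivs(g)
    )]
    in_gap = [c for c in cands if 50_000 <= c.start and c.end <= 51_000]
    assert in_repeat and in_gap
    assert all(c.id not in kept for c in in_repeat)  # 10x depth: above p-quantile
    assert all(c.id not in kept for c in in_gap)  # zero depth: below q-quantile


def _repeat_ivs(g):
    # the fixture plants 10 copies of length 1000 every 4000 bp from 3000
    return [("c1", p, p + 1_000, "r") for p in range(3_000, 43_000, 4_000)]


def test_kmer_filter_empty_table_warns_and_passes_through():
    rng = np.random.default_rng(6)
    g = {"c1": _random_seq(rng, 5_000)}
    cfg = DesignConfig(step=500)
    cands = osel.extract_candidates(g, cfg)
    empty = sg.KmerTable(21, np.empty(0, np.uint64), np.empty(0, np.int64))
    with pytest.warns(UserWarning, match="empty k-mer table"):
        kept = osel.filter_kmer_depth(cands, empty, cfg)
    assert [c.id for c in kept] == [c.id for c in cands]


def test_cap_density_caps_and_is_idempotent():
    rng = np.random.default_rng(7)
    starts = np.sort(rng.choice(1_000_000, size=3_000, replace=False))
    cands = [osel.OligoCandidate("c1", int(s), 50, "A" * 50) for s in starts]
    cfg = DesignConfig()
    once = osel.cap_density(cands, cfg)
    assert len(once) == 2_500
    twice = osel.cap_density(once, cfg)
    assert [c.id for c in twice] == [c.id for c in once]

    few = cands[:2_000]
    assert [c.id for c in osel.cap_density(few, cfg)] == [c.id for c in few]


def test_cap_density_thins_toward_even_spacing():
    # dense cluster + sparse tail: the retained subset spreads out
    starts = list(range(0, 5_000, 10)) + list(range(600_000, 650_000, 5_000))
    cands = [osel.OligoCandidate("c1", s, 50, "A" * 50) for s in starts]
    cfg = DesignConfig(density_cap=50)
    kept = osel.cap_density(cands, cfg)
    assert len(kept) == 50
    gaps = np.diff([c.start for c in kept])
    assert gaps.min() >= 100  # far above the 10-bp input spacing


def test_filters_return_subsets_preserving_order_and_identity():
    rng = np.random.default_rng(8)
    g = {"c1": _random_seq(rng, 40_000)}
    cfg = DesignConfig(step=200)
    cands = osel.extract_candidates(g, cfg)
    table = sg.make_kmer_table(g, 21, 50, seed=4)
    ids = [c.id for c in cands]
    step1 = osel.filter_homology(cands, g, cfg, mode="exact")
    step2 = osel.filter_kmer_depth(step1, table, cfg)
    step3 = osel.cap_density(step2, cfg)
    for stage in (step1, step2, step3):
        stage_ids = [c.id for c in stage]
        assert set(stage_ids) <= set(ids)
        assert stage_ids == [i for i in ids if i in set(stage_ids)]
    assert len(cands) >= len(step1) >= len(step2) >= len(step3)
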