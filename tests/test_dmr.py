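import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methylsynergy import (DMC, DMRTile, filter_ambiguous, intersect_dmr_sets,
                           summarize_dmrs, tile_dmcs)


def mk_dmc(pos, diff=-40.0, chrom="chr1"):
    return DMC(chrom, pos, diff, 1e-6, 1e-5,
               "hyper" if diff > 0 else "hypo")


# ----------------------------------------------------------------- tiling

def test_tiling_spec_layout():
    tiles = tile_dmcs([mk_dmc(1000), mk_dmc(1400), mk_dmc(2100)],
                      merge_gap=500, min_tile_width=100)
    assert len(tiles) == 2
    wide, single = tiles
    # span 1000..1400 inclusive = width 401, no extension
    assert (wide.start, wide.end, wide.width) == (999, 1400, 401)
    # singleton padded to 100 bp: 1-based 2051..2150
    assert (single.start, single.end, single.width) == (2050, 2150, 100)
    assert single.n_dmcs == 1 and wide.n_dmcs == 2


def test_gap_of_exactly_500_merges():
    tiles = tile_dmcs([mk_dmc(1000), mk_dmc(1500)], merge_gap=500)
    assert len(tiles) == 1
    tiles = tile_dmcs([mk_dmc(1000), mk_dmc(1501)], merge_gap=500)
    assert len(tiles) == 2


def test_wide_tile_not_extended():
    tiles = tile_dmcs([mk_dmc(1000), mk_dmc(1150)], min_tile_width=100)
    assert tiles[0].width == 151
    assert (tiles[0].start, tiles[0].end) == (999, 1150)


def test_extension_clips_at_chromosome_start():
    tiles = tile_dmcs([mk_dmc(3)], min_tile_width=100)
    assert tiles[0].start == 0
    assert tiles[0].end == 53   # right side keeps its padding


def test_empty_input():
    assert tile_dmcs([]) == []


def _oracle_tiles(positions, merge_gap, min_width):
    """Brute-force single-linkage chaining over all gap partitions."""
    groups = []
    for p in sorted(positions):
        if groups and p - groups[-1][-1] <= merge_gap:
            groups[-1].append(p)
        else:
            groups.append([p])
    spans = []
    for g in groups:
        start, end = g[0] - 1, g[-1]
        width = end - start
        if width < min_width:
            pad = min_width - width
            start = max(0, start - pad // 2)
            end = end + (pad - pad // 2)
        spans.append((start, end))
    return spans


@settings(max_examples=100, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=20_000),
                min_size=1, max_size=50, unique=True),
       st.sampled_from([100, 500, 1000]))
def test_tiling_matches_bruteforce_oracle(positions, gap):
    tiles = tile_dmcs([mk_dmc(p) for p in positions], merge_gap=gap)
    assert [(t.start, t.end) for t in tiles] == _oracle_tiles(positions, gap, 100)
    # every DMC in exactly one tile; members inside span
    total = sum(t.n_dmcs for t in tiles)
    assert total == len(positions)
    for t in tiles:
        for m in t.member_dmcs:
            assert t.start <= m.pos - 1 < t.end
    # no two tiles' member sets within merge_gap
    for a, b in zip(tiles, tiles[1:]):
        assert b.member_dmcs[0].pos - a.member_dmcs[-1].pos > gap


def test_tiling_idempotent_and_order_invariant(rng):
    positions = sorted(rng.choice(50_000, size=40, replace=False) + 1)
    dmcs = [mk_dmc(int(p)) for p in positions]
    tiles = tile_dmcs(dmcs)
    shuffled = list(dmcs)
    rng.shuffle(shuffled)
    tiles2 = tile_dmcs(shuffled)
    assert [(t.start, t.end) for t in tiles] == [(t.start, t.end) for t in tiles2]
    for t in tiles:
        again = tile_dmcs(t.member_dmcs)
        assert len(again) == 1
        raw_start, raw_end = t.member_dmcs[0].pos - 1, t.member_dmcs[-1].pos
        if raw_end - raw_start >= 100:
            assert (again[0].start, again[0].end) == (t.start, t.end)


# ------------------------------------------------------- ambiguity and mean

def test_mixed_direction_tiles_removed():
    tiles = tile_dmcs([mk_dmc(1000, +40), mk_dmc(1100, -40),
                       mk_dmc(5000, -40), mk_dmc(9000, -36), mk_dmc(9100, -40),
                       mk_dmc(20000, 50)])
    clean, frac = filter_ambiguous(tiles)
    assert frac == pytest.approx(0.25)       # 1 mixed of 4 tiles
    assert all(t.direction in ("hyper", "hypo") for t in clean)


def test_summarize_mean_is_unweighted():
    tiles = tile_dmcs([mk_dmc(1000, -40), mk_dmc(1100, -60)])
    out = summarize_dmrs(tiles)
    assert out[0].mean_diff == pytest.approx(-50.0)
    single = summarize_dmrs(tile_dmcs([mk_dmc(5000, -35)]))
    assert single[0].mean_diff == pytest.approx(-35.0)


def test_summarize_random_matches_recomputation(rng):
    diffs = rng.uniform(-80, -35, size=10)
    dmcs = [mk_dmc(1000 + 10 * i, float(d)) for i, d in enumerate(diffs)]
    out = summarize_dmrs(tile_dmcs(dmcs))
    assert out[0].mean_diff == pytest.approx(float(np.mean(diffs)))


def test_summarize_rejects_ambiguous():
    tiles = tile_dmcs([mk_dmc(1000, 40), mk_dmc(1100, -40)])
    with pytest.raises(ValueError):
        summarize_dmrs(tiles)


# ------------------------------------------------------------------- Venn

def _tile(chrom, start, end, direction="hypo"):
    return DMRTile(chrom, start, end, [], -40.0, direction)


def test_venn_all_shared_and_disjoint():
    shared = intersect_dmr_sets({
        "A": [_tile("chr1", 0, 100)], "B": [_tile("chr1", 50, 150)],
        "C": [_tile("chr1", 90, 200)]})
    assert shared.counts == {("A", "B", "C"): 1}
    disjoint = intersect_dmr_sets({
        "A": [_tile("chr1", 0, 100)], "B": [_tile("chr1", 200, 300)],
        "C": [_tile("chr1", 400, 500)]})
    assert disjoint.counts == {("A",): 1, ("B",): 1, ("C",): 1}
    assert disjoint.total == 3


def test_venn_chained_overlap_is_one_component():
    # A overlaps B, B overlaps C, A disjoint from C -> single {A,B,C} component
    venn = intersect_dmr_sets({
        "A": [_tile("chr1", 0, 100)], "B": [_tile("chr1", 90, 210)],
        "C": [_tile("chr1", 200, 300)]})
    assert venn.counts == {("A", "B", "C"): 1}


def test_venn_matches_union_find_oracle(rng):
    sets = {}
    for name in "ABC":
        starts = rng.choice(5_000, size=15, replace=False)
        sets[name] = [_tile("chr1", int(s), int(s) + int(rng.integers(20, 120)))
                      for s in starts]
    venn = intersect_dmr_sets(sets)
    # oracle: union-find over all tiles under pairwise overlap
    tiles = [(t.start, t.end, name) for name, ts in sets.items() for t in ts]
    parent = list(range(len(tiles)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(tiles)):
        for j in range(i + 1, len(tiles)):
            if tiles[i][0] < tiles[j][1] and tiles[j][0] < tiles[i][1]:
                parent[find(i)] = find(j)
    comps = {}
    for i, (_, _, name) in enumerate(tiles):
        comps.setdefault(find(i), set()).add(name)
    expected = {}
    for members in comps.values():
        key = tuple(sorted(members))
        expected[key] = expected.get(key, 0) + 1
    assert venn.counts == expected


def test_venn_rejects_mixed_directions():
    with pytest.raises(ValueError):
        intersect_dmr_sets({"A": [_tile("chr1", 0, 100, "hypo")],
                            "B": [_tile("chr1", 0, 100, "hyper")]})
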