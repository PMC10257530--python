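import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylsynergy import (ContingencyResult, FeatureTrack, TSSTable,
                           build_promoters, complement_intervals,
                           cpg_region_contingency, fisher_exact_two_sided,
                           odds_ratio_test, tss_distance_enrichment)
from methylsynergy.methylation_io import flatten_track


def _tss(rows):
    return TSSTable(pd.DataFrame(rows, columns=["gene_id", "chrom",
                                                "tss_pos", "strand"]))


# -------------------------------------------------------------- promoters

def test_promoter_construction_by_strand():
    tss = _tss([("g1", "chr1", 10000, "+"), ("g2", "chr1", 10000, "-"),
                ("g3", "chr1", 1000, "+")])
    track = build_promoters(tss)
    spans = list(track.intervals[["start", "end"]].itertuples(index=False, name=None))
    assert spans[0] == (8000, 10500)
    assert spans[1] == (9500, 12000)
    assert spans[2] == (0, 1500)     # clipped at chromosome start
    assert list(track.intervals["label"]) == ["g1", "g2", "g3"]


def test_promoter_clipped_at_chrom_length():
    tss = _tss([("g1", "chr1", 9900, "+")])
    track = build_promoters(tss, chrom_sizes={"chr1": 10000})
    assert list(track.intervals[["start", "end"]].iloc[0]) == [7900, 10000]


# ------------------------------------------------------------- complement

def test_complement_basic_and_identity():
    uni = FeatureTrack.from_spans("u", [("chr1", 0, 1000)])
    cov = FeatureTrack.from_spans("c", [("chr1", 200, 300)])
    out = complement_intervals(uni, cov)
    assert list(out.intervals[["start", "end"]].itertuples(index=False, name=None)) \
        == [(0, 200), (300, 1000)]
    empty = FeatureTrack.from_spans("c", [])
    same = complement_intervals(uni, empty)
    assert list(same.intervals[["start", "end"]].itertuples(index=False, name=None)) \
        == [(0, 1000)]


def test_complement_matches_per_bp_oracle(rng):
    uni = FeatureTrack.from_spans("u", [("chr1", 0, 5000), ("chr1", 6000, 10000)])
    spans = [("chr1", int(s), int(s + rng.integers(1, 400)))
             for s in rng.integers(0, 9800, size=25)]
    cov = FeatureTrack.from_spans("c", spans)
    out = complement_intervals(uni, cov)
    member = np.zeros(10_000, dtype=bool)
    for _, s, e in spans:
        member[s:min(e, 10_000)] = True
    universe = np.zeros(10_000, dtype=bool)
    universe[0:5000] = True
    universe[6000:10000] = True
    expected = universe & ~member
    got = np.zeros(10_000, dtype=bool)
    for r in out.intervals.itertuples():
        got[r.start:r.end] = True
    assert (got == expected).all()


# ---------------------------------------------------------- contingency/OR

def _universe(n, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": np.arange(1, n + 1) * 10})


def test_contingency_partition_arithmetic():
    # 1000 CpGs at pos 10..10000; DMRs cover first 100; feature covers
    # CpGs 71..270 (so 30 of them are inside DMRs)
    uni = _universe(1000)
    dmrs = FeatureTrack.from_spans("d", [("chr1", 0, 1000)])          # CpGs 1..100
    feat = FeatureTrack.from_spans("f", [("chr1", 700, 2700)])        # CpGs 71..270
    res = cpg_region_contingency(uni, dmrs, feat)
    assert (res.a, res.b, res.c, res.d) == (30, 70, 170, 730)
    res = odds_ratio_test(res)
    assert res.odds_ratio == pytest.approx((30 * 730) / (70 * 170))
    assert res.odds_ratio == pytest.approx(1.8403, abs=2e-4)
    assert res.log_or == pytest.approx(math.log(res.odds_ratio))


def test_contingency_feature_covering_everything():
    uni = _universe(50)
    dmrs = FeatureTrack.from_spans("d", [("chr1", 0, 100)])
    feat = FeatureTrack.from_spans("f", [("chr1", 0, 10_000)])
    res = cpg_region_contingency(uni, dmrs, feat)
    assert res.b == 0 and res.d == 0
    res = odds_ratio_test(res)
    assert res.undefined


def test_contingency_matches_per_cpg_bruteforce(rng):
    uni = _universe(300)
    dmr_spans = [("chr1", int(s), int(s + rng.integers(5, 200)))
                 for s in rng.integers(0, 2900, size=8)]
    feat_spans = [("chr1", int(s), int(s + rng.integers(5, 300)))
                  for s in rng.integers(0, 2900, size=8)]
    dmrs = FeatureTrack.from_spans("d", dmr_spans)
    feat = FeatureTrack.from_spans("f", feat_spans)
    res = cpg_region_contingency(uni, dmrs, feat)

    def member(p0, spans):
        return any(s <= p0 < e for _, s, e in spans)

    a = b = c = d = 0
    for pos in uni["pos"]:
        p0 = pos - 1
        in_d, in_f = member(p0, dmr_spans), member(p0, feat_spans)
        a += in_d and in_f
        b += in_d and not in_f
        c += in_f and not in_d
        d += not in_d and not in_f
    assert (res.a, res.b, res.c, res.d) == (a, b, c, d)
    # fragmentation invariance: splitting a feature interval changes nothing
    split = []
    for chrom, s, e in feat_spans:
        mid = (s + e) // 2
        if mid > s:
            split += [(chrom, s, mid), (chrom, mid, e)]
        else:
            split.append((chrom, s, e))
    res2 = cpg_region_contingency(uni, dmrs, FeatureTrack.from_spans("f2", split))
    assert (res2.a, res2.b, res2.c, res2.d) == (a, b, c, d)


def test_or_one_for_balanced_table():
    res = odds_ratio_test(ContingencyResult(25, 25, 25, 25))
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.log_or == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_fisher_implementation_matches_scipy(rng):
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
        ours = fisher_exact_two_sided(a, b, c, d)
        ref = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12), (a, b, c, d)


def test_fisher_example_table():
    assert fisher_exact_two_sided(8, 2, 2, 8) == pytest.approx(0.0230, abs=5e-5)


def test_permuted_dmr_labels_center_or_at_one(rng):
    """Randomly relabelling which CpGs are 'in DMRs' gives OR ~ 1."""
    uni = _universe(2000)
    feat = FeatureTrack.from_spans("f", [("chr1", 0, 6000)])
    ors = []
    for _ in range(300):
        pick = rng.choice(2000, size=200, replace=False)
        spans = [("chr1", int(uni["pos"][i] - 1), int(uni["pos"][i]))
                 for i in pick]
        res = odds_ratio_test(cpg_region_contingency(
            uni, FeatureTrack.from_spans("d", spans), feat))
        ors.append(res.odds_ratio)
    med = float(np.median(ors))
    assert 0.85 < med < 1.18


# ------------------------------------------------------------ TSS distance

def test_tss_distance_bins_constructed_layout():
    # DMR CpGs all within 1 kb of a TSS; far CpGs outside DMRs
    tss = _tss([("g1", "chr1", 100_000, "+")])
    uni = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.r_[100_000 + np.arange(-400, 400, 20),     # near, in DMR
                     np.arange(1, 50_001, 500)]})            # far, outside
    dmrs = FeatureTrack.from_spans("d", [("chr1", 99_500, 100_500)])
    results = tss_distance_enrichment(dmrs, tss, uni)
    first, last = results[0], results[-1]
    assert first.odds_ratio > 1
    assert last.a == 0          # no DMR CpGs at >=100 kb
    # CpG exactly at the TSS lands in the first bin
    exact = pd.DataFrame({"chrom": ["chr1"], "pos": [100_001]})
    res = tss_distance_enrichment(dmrs, tss, exact)
    assert res[0].a + res[0].c == 1


def test_tss_empty_bin_flagged():
    tss = _tss([("g1", "chr1", 0, "+")])
    uni = pd.DataFrame({"chrom": ["chr1"], "pos": [1]})
    dmrs = FeatureTrack.from_spans("d", [("chr1", 0, 10)])
    results = tss_distance_enrichment(dmrs, tss, uni)
    empty = results[2]
    assert empty.a == 0 and empty.c == 0
    assert empty.p_value is None


def test_tss_bins_must_be_disjoint():
    tss = _tss([("g1", "chr1", 0, "+")])
    uni = pd.DataFrame({"chrom": ["chr1"], "pos": [1]})
    with pytest.raises(ValueError):
        tss_distance_enrichment(FeatureTrack.from_spans("d", [("chr1", 0, 5)]),
                                tss, uni, bins=[(0, 100), (50, 200)])
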