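import gzip

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylsynergy import (CallFileError, FeatureTrack, MethylationCallSet,
                           flatten_track, merge_strands, points_in_track,
                           read_cytosine_calls, unite_groups,
                           write_cytosine_calls)
from methylsynergy.methylation_io import read_bed, write_bed


# ---------------------------------------------------------------------- IO

def test_cytosine_report_parsing_and_coverage_filter(tmp_path):
    p = tmp_path / "calls.tsv"
    p.write_text("chr1\t100\t+\t5\t5\tCpG\tCGA\n"
                 "chr1\t200\t+\t2\t2\tCpG\tCGT\n")
    calls = read_cytosine_calls(p, "cytosine_report", min_coverage=5)
    assert len(calls) == 1   # coverage 4 dropped, coverage 10 kept
    rec = calls.records.iloc[0]
    assert (rec.chrom, rec.pos, rec.strand, rec.n_meth, rec.n_unmeth) == \
        ("chr1", 100, "+", 5, 5)
    at_threshold = read_cytosine_calls(p, "cytosine_report")
    assert len(at_threshold) == 2   # no filter requested


def test_empty_file_gives_empty_callset(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    assert len(read_cytosine_calls(p)) == 0


def test_malformed_line_reports_line_number(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("chr1\t100\t+\t5\t5\tCpG\tCGA\n"
                 "chr1\tnotanumber\t+\t5\t5\tCpG\tCGA\n")
    with pytest.raises(CallFileError, match="line 2"):
        read_cytosine_calls(p)


def test_negative_counts_rejected(tmp_path):
    p = tmp_path / "neg.tsv"
    p.write_text("chr1\t100\t+\t-3\t5\tCpG\tCGA\n")
    with pytest.raises(CallFileError, match="negative"):
        read_cytosine_calls(p)


@pytest.mark.parametrize("dialect", ["cytosine_report", "coverage"])
def test_round_trip_is_lossless(tmp_path, dialect, toy_calls):
    calls = toy_calls
    if dialect == "coverage":
        calls = MethylationCallSet("toy", toy_calls.records.assign(strand="."))
    p = tmp_path / "out.tsv"
    write_cytosine_calls(calls, p, dialect)
    back = read_cytosine_calls(p, dialect, sample_id="toy")
    a = calls.records.sort_values(["chrom", "pos"]).reset_index(drop=True)
    b = back.records.sort_values(["chrom", "pos"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_gzip_transparent(tmp_path, toy_calls):
    p = tmp_path / "calls.tsv.gz"
    body = "chr1\t100\t+\t5\t5\tCpG\tCGA\n"
    with gzip.open(p, "wt") as fh:
        fh.write(body)
    assert len(read_cytosine_calls(p)) == 1


# -------------------------------------------------------------- merge_strands

def test_merge_strands_pairs_and_orphans(toy_calls):
    merged = merge_strands(toy_calls)
    got = {(r.chrom, r.pos): (r.n_meth, r.n_unmeth)
           for r in merged.records.itertuples()}
    assert got[("chr1", 100)] == (8, 12)
    # orphan '-' at 301 re-keys to 300 on '+'
    assert got[("chr1", 300)] == (2, 8)
    # orphan '+' unchanged
    assert got[("chr1", 500)] == (10, 0)
    assert set(merged.records["strand"]) == {"+"}


def test_merge_strands_identity_on_plus_only():
    calls = MethylationCallSet.from_records("s", [("chr1", 100, "+", 5, 5)])
    merged = merge_strands(calls)
    pd.testing.assert_frame_equal(merged.records, calls.records)


def _brute_force_merge(records):
    """Oracle: pair each '-' at p with '+' at p-1 by exhaustive search."""
    out = {}
    for chrom, pos, strand, m, u in records:
        key = (chrom, pos if strand == "+" else pos - 1)
        a, b = out.get(key, (0, 0))
        out[key] = (a + m, b + u)
    return out


@settings(max_examples=50, deadline=None)
@given(st.lists(
    st.tuples(st.sampled_from(["chr1", "chr2"]),
              st.integers(min_value=1, max_value=30),
              st.integers(min_value=0, max_value=20),
              st.integers(min_value=0, max_value=20)),
    max_size=15))
def test_merge_strands_matches_pairing_oracle(raw):
    # sites at even 1-based positions: '+' at 2k, '-' partner at 2k+1
    records = []
    seen = set()
    for chrom, site, m, u in raw:
        strand = "+" if m % 2 == 0 else "-"
        pos = 2 * site + (0 if strand == "+" else 1)
        if (chrom, pos, strand) in seen:
            continue
        seen.add((chrom, pos, strand))
        records.append((chrom, pos, strand, m, u))
    calls = MethylationCallSet.from_records("s", records)
    merged = merge_strands(calls)
    oracle = _brute_force_merge(records)
    got = {(r.chrom, r.pos): (r.n_meth, r.n_unmeth)
           for r in merged.records.itertuples()}
    assert got == oracle
    # conservation of totals
    assert merged.records["n_meth"].sum() == sum(r[3] for r in records)
    assert merged.records["n_unmeth"].sum() == sum(r[4] for r in records)


def test_merge_strands_rejects_duplicate_plus():
    with pytest.raises(ValueError):
        MethylationCallSet.from_records(
            "s", [("chr1", 100, "+", 1, 1), ("chr1", 100, "+", 2, 2)])


# -------------------------------------------------------------- unite_groups

def _mk(sample_id, triples):
    return MethylationCallSet.from_records(
        sample_id, [(c, p, "+", m, u) for c, p, m, u in triples])


def test_unite_two_of_three_rule():
    s1 = _mk("s1", [("chr1", 10, 3, 3), ("chr1", 20, 9, 1)])
    s2 = _mk("s2", [("chr1", 10, 4, 2), ("chr1", 20, 1, 1)])
    s3 = _mk("s3", [("chr1", 20, 2, 2)])
    united = unite_groups([s1, s2, s3], min_coverage=5, min_per_group=2)
    # chr1:10 at >=5x in s1,s2 -> kept; chr1:20 at >=5x only in s1 -> dropped
    assert list(united.keys.itertuples(index=False, name=None)) == [("chr1", 10)]
    assert united.present[0].tolist() == [True, True, False]


def test_unite_strict_equals_intersection_oracle(rng):
    sites = [("chr1", p) for p in range(10, 200, 10)]
    samples = []
    for i in range(3):
        chosen = [s for s in sites if rng.random() < 0.7]
        samples.append(_mk(f"s{i}", [(c, p, 5, 5) for c, p in chosen]))
    united = unite_groups(samples, min_coverage=5, min_per_group=3)
    oracle = set.intersection(*(
        set(map(tuple, s.records[["chrom", "pos"]].to_numpy())) for s in samples))
    assert set(united.keys.itertuples(index=False, name=None)) == oracle


def test_unite_invariant_to_sample_order():
    s1 = _mk("a", [("chr1", 10, 3, 3), ("chr2", 7, 8, 0)])
    s2 = _mk("b", [("chr1", 10, 4, 2)])
    s3 = _mk("c", [("chr2", 7, 2, 4), ("chr1", 10, 1, 5)])
    u1 = unite_groups([s1, s2, s3], 5, 2)
    u2 = unite_groups([s3, s1, s2], 5, 2)
    pd.testing.assert_frame_equal(u1.to_frame(), u2.to_frame())


def test_unite_min_per_group_validation():
    s = _mk("s", [("chr1", 10, 5, 5)])
    with pytest.raises(ValueError):
        unite_groups([s], min_coverage=5, min_per_group=2)


# ---------------------------------------------------------------- intervals

def test_bed_round_trip(tmp_path):
    track = FeatureTrack("t", pd.DataFrame({
        "chrom": ["chr1", "chr2"], "start": [10, 0], "end": [50, 9],
        "strand": ["+", "-"], "label": ["a", "b"]}))
    p = tmp_path / "t.bed"
    write_bed(track, p)
    back = read_bed(p, "t")
    pd.testing.assert_frame_equal(track.intervals, back.intervals)


def test_points_in_track_matches_per_bp_oracle(rng):
    spans = [("chr1", int(s), int(s + rng.integers(1, 30)))
             for s in rng.integers(0, 300, size=10)]
    track = FeatureTrack.from_spans("t", spans)
    pos = np.arange(0, 350)
    chroms = np.array(["chr1"] * len(pos))
    got = points_in_track(chroms, pos, track)
    member = np.zeros(350, dtype=bool)
    for _, s, e in spans:
        member[s:e] = True
    assert (got == member).all()


def test_flatten_merges_overlaps():
    track = FeatureTrack.from_spans("t", [("chr1", 0, 10), ("chr1", 5, 20),
                                          ("chr1", 30, 40)])
    flat = flatten_track(track)
    assert list(flat.intervals[["start", "end"]].itertuples(index=False, name=None)) \
        == [(0, 20), (30, 40)]
    assert track.total_length() == 30
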