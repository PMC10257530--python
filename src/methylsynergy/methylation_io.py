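"""Reading, writing and assembly of per-cytosine bisulfite methylation calls.

Two on-disk dialects are supported, both plain TSV (gzip transparent):

* ``cytosine_report`` — Bismark cytosine-report style: chrom, 1-based position,
  strand, methylated count, unmethylated count, context, trinucleotide.
* ``coverage`` — Bismark coverage style: chrom, 1-based start, end,
  methylation percentage, methylated count, unmethylated count (no strand).

Genomic interval tracks (promoters, exons, chromatin states, ...) are consumed
as BED6, half-open 0-based.  Cytosine positions are 1-based throughout; the
interval helpers below take 0-based point coordinates, and converters are
explicit at every call site (``pos - 1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("methylsynergy")

CALL_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth"]

_CYTOSINE_REPORT_COLS = ["chrom", "pos", "strand", "n_meth", "n_unmeth",
                         "context", "trinucleotide"]
_COVERAGE_COLS = ["chrom", "start", "end", "meth_pct", "n_meth", "n_unmeth"]


class CallFileError(ValueError):
    """A call file failed to parse or validate (carries a line number)."""


# ---------------------------------------------------------------------------
# MethylationCallSet
# ---------------------------------------------------------------------------

@dataclass
class MethylationCallSet:
    """Per-sample per-CpG methylated/unmethylated read counts.

    ``records`` is a DataFrame with columns chrom, pos (1-based), strand
    ('+'/'-'/'.'), n_meth, n_unmeth.  (chrom, pos, strand) is unique, counts
    are non-negative and positions are >= 1.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=CALL_COLUMNS).reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)
        df["n_meth"] = df["n_meth"].astype(np.int64)
        df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
        if len(df):
            if (df["pos"] < 1).any():
                raise ValueError("positions must be 1-based (>= 1)")
            if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
                raise ValueError("negative methylation counts")
            if df.duplicated(["chrom", "pos", "strand"]).any():
                raise ValueError("duplicate (chrom, pos, strand) records")
        self.records = df

    @classmethod
    def from_records(cls, sample_id: str, records) -> "MethylationCallSet":
        return cls(sample_id, pd.DataFrame(list(records), columns=CALL_COLUMNS))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def coverage(self) -> pd.Series:
        return self.records["n_meth"] + self.records["n_unmeth"]

    @property
    def ratio(self) -> pd.Series:
        """Methylation ratio n_meth / coverage per record (NaN at coverage 0)."""
        cov = self.coverage
        return self.records["n_meth"] / cov.where(cov > 0)

    def filter_coverage(self, min_coverage: int) -> "MethylationCallSet":
        keep = self.coverage >= min_coverage
        return MethylationCallSet(self.sample_id, self.records[keep])

    def sort(self) -> "MethylationCallSet":
        df = self.records.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        return MethylationCallSet(self.sample_id, df)


def read_cytosine_calls(path, dialect: str = "cytosine_report",
                        min_coverage: int | None = None,
                        sample_id: str | None = None) -> MethylationCallSet:
    """Read a per-cytosine call file into a :class:`MethylationCallSet`.

    ``min_coverage`` (optional) drops records with ``n_meth + n_unmeth`` below
    the threshold at read time.  Malformed lines raise :class:`CallFileError`
    with the offending 1-based line number.
    """
    if min_coverage is not None and min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    sample_id = sample_id if sample_id is not None else str(path)
    if dialect == "cytosine_report":
        cols, dtypes = _CYTOSINE_REPORT_COLS, {"pos": np.int64}
    elif dialect == "coverage":
        cols, dtypes = _COVERAGE_COLS, {"start": np.int64, "end": np.int64}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        raw = pd.read_csv(path, sep="\t", header=None, names=cols,
                          comment="#", compression="infer", dtype=str)
    except pd.errors.EmptyDataError:
        return MethylationCallSet(sample_id, pd.DataFrame(columns=CALL_COLUMNS))
    # validate numerics ourselves so errors carry line numbers
    for col in ("pos", "start", "end", "n_meth", "n_unmeth"):
        if col not in raw.columns:
            continue
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise CallFileError(f"{path}: malformed {col} field at line {line}")
        if (coerced < 0).any() and col in ("n_meth", "n_unmeth"):
            line = int(np.flatnonzero((coerced < 0).to_numpy())[0]) + 1
            raise CallFileError(f"{path}: negative count at line {line}")
        raw[col] = coerced.astype(np.int64)
    if raw.isna().any().any():
        line = int(np.flatnonzero(raw.isna().any(axis=1).to_numpy())[0]) + 1
        raise CallFileError(f"{path}: missing field at line {line}")
    if dialect == "cytosine_report":
        df = raw[CALL_COLUMNS].copy()
    else:
        df = pd.DataFrame({"chrom": raw["chrom"], "pos": raw["start"],
                           "strand": ".", "n_meth": raw["n_meth"],
                           "n_unmeth": raw["n_unmeth"]})
    calls = MethylationCallSet(sample_id, df)
    if min_coverage is not None:
        calls = calls.filter_coverage(min_coverage)
    return calls


def write_cytosine_calls(calls: MethylationCallSet, path,
                         dialect: str = "cytosine_report") -> None:
    df = calls.records
    if dialect == "cytosine_report":
        out = df.assign(context="CpG", trinucleotide="CGG")
        out = out[_CYTOSINE_REPORT_COLS]
    elif dialect == "coverage":
        cov = (df["n_meth"] + df["n_unmeth"]).to_numpy()
        pct = np.where(cov > 0, 100.0 * df["n_meth"].to_numpy() / np.maximum(cov, 1), 0.0)
        out = pd.DataFrame({"chrom": df["chrom"], "start": df["pos"],
                            "end": df["pos"], "meth_pct": np.round(pct, 6),
                            "n_meth": df["n_meth"], "n_unmeth": df["n_unmeth"]})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Strand merging
# ---------------------------------------------------------------------------

def merge_strands(calls: MethylationCallSet) -> MethylationCallSet:
    """Combine the two strands of each CpG dinucleotide into one record.

    CpG methylation is symmetric: the '-' strand cytosine sits one base
    downstream of the '+' strand cytosine, so a '-' record at position p+1 is
    summed into the '+' record at p.  Orphan '-' records are re-keyed to their
    '+' strand position p-1.  Output is keyed on the '+' strand, sorted.
    """
    df = calls.records
    if len(df) == 0:
        return MethylationCallSet(calls.sample_id, df)
    strands = set(df["strand"].unique())
    if not strands <= {"+", "-"}:
        raise ValueError(f"strand must be '+' or '-' on every record, got {strands}")
    plus = df[df["strand"] == "+"].copy()
    minus = df[df["strand"] == "-"].copy()
    if plus.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate '+' strand records at the same position")
    minus["pos"] = minus["pos"] - 1
    if (minus["pos"] < 1).any():
        raise ValueError("'-' strand record at position 1 has no valid '+' position")
    merged = (
        pd.concat([plus, minus.assign(strand="+")])
        .groupby(["chrom", "pos"], as_index=False, sort=True)[["n_meth", "n_unmeth"]]
        .sum()
        .assign(strand="+")
    )
    return MethylationCallSet(calls.sample_id, merged[CALL_COLUMNS])


# ---------------------------------------------------------------------------
# UnitedMatrix
# ---------------------------------------------------------------------------

@dataclass
class UnitedMatrix:
    """Cross-sample filtered CpG count matrix for one experimental group.

    A CpG is retained when it is covered at >= ``min_coverage`` reads in at
    least ``min_per_group`` samples of the group.  ``meth``/``cov`` are
    (n_cpgs, n_samples) arrays with zeros where a sample did not capture the
    site; ``present`` marks capture at threshold coverage.
    """

    group_id: str
    sample_ids: list[str]
    keys: pd.DataFrame            # columns chrom, pos — sorted
    meth: np.ndarray
    cov: np.ndarray
    min_coverage: int
    min_per_group: int
    present: np.ndarray = field(default=None)  # bool (n_cpgs, n_samples)

    def __post_init__(self) -> None:
        if self.present is None:
            self.present = self.cov >= self.min_coverage

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def pooled_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Coverage-pooled (meth, cov) over present samples, per CpG."""
        m = np.where(self.present, self.meth, 0).sum(axis=1)
        c = np.where(self.present, self.cov, 0).sum(axis=1)
        return m, c

    def to_frame(self) -> pd.DataFrame:
        df = self.keys.copy()
        for j, sid in enumerate(self.sample_ids):
            df[f"meth_{sid}"] = self.meth[:, j]
            df[f"cov_{sid}"] = self.cov[:, j]
        return df


def unite_groups(samples: list[MethylationCallSet], min_coverage: int = 5,
                 min_per_group: int = 2, group_id: str = "group") -> UnitedMatrix:
    """Unite replicate call sets of one group into a filtered CpG matrix.

    Coverage filtering is applied per sample first; a CpG is kept when it
    survives that filter in at least ``min_per_group`` samples.  The output is
    sorted by (chrom, pos) and invariant to sample input order.
    """
    if not samples:
        raise ValueError("unite_groups needs at least one sample")
    if not (1 <= min_per_group <= len(samples)):
        raise ValueError(
            f"min_per_group={min_per_group} out of range for {len(samples)} samples")
    order = np.argsort([s.sample_id for s in samples], kind="stable")
    samples = [samples[i] for i in order]
    frames = []
    for s in samples:
        df = s.records[(s.records.n_meth + s.records.n_unmeth) >= min_coverage]
        frames.append(df.groupby(["chrom", "pos"], as_index=True)[["n_meth", "n_unmeth"]]
                        .sum())
    merged = pd.concat(frames, axis=1, keys=range(len(frames)), join="outer").sort_index()
    meth = np.column_stack([
        merged[(j, "n_meth")].fillna(0).to_numpy(np.int64) for j in range(len(frames))])
    unmeth = np.column_stack([
        merged[(j, "n_unmeth")].fillna(0).to_numpy(np.int64) for j in range(len(frames))])
    cov = meth + unmeth
    captured = np.column_stack([
        merged[(j, "n_meth")].notna().to_numpy() for j in range(len(frames))])
    present = captured & (cov >= min_coverage)
    keep = present.sum(axis=1) >= min_per_group
    keys = merged.index.to_frame(index=False)
    keys.columns = ["chrom", "pos"]
    keys = keys[keep].reset_index(drop=True)
    logger.info("unite %s: %d/%d CpGs kept (>=%dx in >=%d of %d samples)",
                group_id, int(keep.sum()), len(merged), min_coverage,
                min_per_group, len(samples))
    return UnitedMatrix(group_id, [s.sample_id for s in samples], keys,
                        meth[keep], cov[keep], min_coverage, min_per_group,
                        present=present[keep])


def write_united(united: UnitedMatrix, path) -> None:
    df = united.to_frame()
    df.insert(0, "group_id", united.group_id)
    df.to_csv(path, sep="\t", index=False)


def read_united(path, min_coverage: int = 5, min_per_group: int = 2) -> UnitedMatrix:
    df = pd.read_csv(path, sep="\t")
    group_id = str(df["group_id"].iloc[0]) if len(df) else "group"
    sample_ids = [c[5:] for c in df.columns if c.startswith("meth_")]
    meth = df[[f"meth_{s}" for s in sample_ids]].to_numpy(np.int64)
    cov = df[[f"cov_{s}" for s in sample_ids]].to_numpy(np.int64)
    return UnitedMatrix(group_id, sample_ids, df[["chrom", "pos"]].copy(),
                        meth, cov, min_coverage, min_per_group)


# ---------------------------------------------------------------------------
# FeatureTrack and interval arithmetic (half-open, 0-based)
# ---------------------------------------------------------------------------

@dataclass
class FeatureTrack:
    """Named set of genomic intervals, half-open 0-based (BED convention)."""

    name: str
    intervals: pd.DataFrame   # chrom, start, end [, strand, label]

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals).reset_index(drop=True)
        for col, default in (("strand", "."), ("label", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[["chrom", "start", "end", "strand", "label"]]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError(f"track {self.name!r}: empty or inverted interval")
        if len(df) and (df["start"] < 0).any():
            raise ValueError(f"track {self.name!r}: negative start")
        self.intervals = df

    @classmethod
    def from_spans(cls, name: str, spans) -> "FeatureTrack":
        return cls(name, pd.DataFrame(
            [tuple(s) for s in spans], columns=["chrom", "start", "end"]))

    def __len__(self) -> int:
        return len(self.intervals)

    def total_length(self) -> int:
        flat = flatten_track(self)
        iv = flat.intervals
        return int((iv["end"] - iv["start"]).sum())

    def sort(self) -> "FeatureTrack":
        df = self.intervals.sort_values(["chrom", "start", "end"], kind="mergesort")
        return FeatureTrack(self.name, df)


def read_bed(path, name: str | None = None) -> FeatureTrack:
    """Read a BED3-6 file (gzip transparent) into a FeatureTrack."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         compression="infer", dtype=str)
    except pd.errors.EmptyDataError:
        return FeatureTrack(name or str(path),
                            pd.DataFrame(columns=["chrom", "start", "end"]))
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "label", "score", "strand"][: df.shape[1]]
    out = pd.DataFrame({"chrom": df["chrom"],
                        "start": pd.to_numeric(df["start"]).astype(np.int64),
                        "end": pd.to_numeric(df["end"]).astype(np.int64)})
    out["strand"] = df["strand"] if "strand" in df else "."
    out["label"] = df["label"] if "label" in df else "."
    return FeatureTrack(name or str(path), out)


def write_bed(track: FeatureTrack, path) -> None:
    iv = track.intervals
    bed = pd.DataFrame({"chrom": iv["chrom"], "start": iv["start"], "end": iv["end"],
                        "name": iv["label"], "score": 0, "strand": iv["strand"]})
    bed.to_csv(path, sep="\t", header=False, index=False)


def flatten_track(track: FeatureTrack) -> FeatureTrack:
    """Merge overlapping/adjacent-overlapping intervals per chromosome."""
    iv = track.intervals.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    for chrom, grp in iv.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:            # strict overlap merges; abutting stays split
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return FeatureTrack.from_spans(track.name, rows)


def points_in_track(chroms: np.ndarray, pos0: np.ndarray,
                    track: FeatureTrack) -> np.ndarray:
    """Boolean membership of 0-based points in a track (flattened internally)."""
    chroms = np.asarray(chroms)
    pos0 = np.asarray(pos0, dtype=np.int64)
    member = np.zeros(len(pos0), dtype=bool)
    flat = flatten_track(track)
    for chrom, grp in flat.intervals.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, pos0[sel], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(sel.sum(), dtype=bool)
        hit[ok] = pos0[sel][ok] < ends[idx[ok]]
        member[sel] = hit
    return member
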