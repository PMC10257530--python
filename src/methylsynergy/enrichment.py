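"""CpG-level odds-ratio enrichment of DMRs against genomic features.

Every CpG of a background universe (by default the united, coverage-filtered
CpG set) is cross-classified by DMR membership and feature membership:

    a = in DMR and in feature        b = in DMR, outside feature
    c = in feature, outside DMRs     d = outside both

OR = (a/c)/(b/d) = ad/bc, reported with its natural log and a two-sided
Fisher exact p-value computed by hypergeometric enumeration (sum of all
table probabilities not exceeding that of the observed table).  Zero cells
are flagged (OR infinite or undefined), never corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import DMRTile
from .methylation_io import FeatureTrack, flatten_track, points_in_track


@dataclass
class ContingencyResult:
    """A 2x2 CpG cross-classification with optional OR/p annotation.

    ``odds_ratio`` is math.inf when b*c = 0 with a*d > 0 and NaN when both
    products vanish; ``undefined`` flags either case.
    """

    a: int
    b: int
    c: int
    d: int
    feature_name: str = ""
    dmr_set_name: str = ""
    odds_ratio: float | None = None
    log_or: float | None = None
    p_value: float | None = None

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def undefined(self) -> bool:
        return self.odds_ratio is not None and not math.isfinite(self.odds_ratio)


@dataclass
class TSSTable:
    """Gene transcription start sites (0-based point coordinates)."""

    sites: pd.DataFrame   # gene_id, chrom, tss_pos, strand

    def __post_init__(self):
        df = pd.DataFrame(self.sites)[["gene_id", "chrom", "tss_pos", "strand"]]
        df = df.reset_index(drop=True)
        df["tss_pos"] = df["tss_pos"].astype(np.int64)
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("TSS strand must be '+' or '-'")
        self.sites = df

    def __len__(self) -> int:
        return len(self.sites)


def build_promoters(tss: TSSTable, upstream: int = 2000, downstream: int = 500,
                    chrom_sizes: dict[str, int] | None = None) -> FeatureTrack:
    """Promoter intervals: ``upstream`` bp before to ``downstream`` bp after
    each TSS, strand-aware, clipped to [0, chromosome length)."""
    df = tss.sites
    plus = df["strand"].to_numpy() == "+"
    t = df["tss_pos"].to_numpy()
    start = np.where(plus, t - upstream, t - downstream)
    end = np.where(plus, t + downstream, t + upstream)
    start = np.maximum(start, 0)
    if chrom_sizes:
        size = df["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, size)
    out = pd.DataFrame({"chrom": df["chrom"], "start": start, "end": end,
                        "strand": df["strand"], "label": df["gene_id"]})
    out = out[out["start"] < out["end"]]
    return FeatureTrack("promoters", out)


def complement_intervals(universe: FeatureTrack,
                         covered: FeatureTrack) -> FeatureTrack:
    """Set difference universe \\ covered (covered is flattened first)."""
    uni = universe.sort().intervals
    if len(uni):
        for chrom, grp in uni.groupby("chrom"):
            e = grp["end"].to_numpy()[:-1]
            s = grp["start"].to_numpy()[1:]
            if len(s) and (s < e).any():
                raise ValueError("universe intervals must be non-overlapping")
    cov = flatten_track(covered).intervals
    rows = []
    for r in uni.itertuples():
        sub = cov[(cov["chrom"] == r.chrom) &
                  (cov["end"] > r.start) & (cov["start"] < r.end)]
        cursor = r.start
        for c in sub.itertuples():
            if c.start > cursor:
                rows.append((r.chrom, cursor, min(c.start, r.end)))
            cursor = max(cursor, c.end)
            if cursor >= r.end:
                break
        if cursor < r.end:
            rows.append((r.chrom, cursor, r.end))
    name = f"{universe.name}_minus_{covered.name}"
    return FeatureTrack.from_spans(name, rows)


def _dmr_track(dmrs, name: str = "dmrs") -> FeatureTrack:
    if isinstance(dmrs, FeatureTrack):
        return dmrs
    return FeatureTrack.from_spans(
        name, [(t.chrom, t.start, t.end) for t in dmrs])


def cpg_region_contingency(cpg_universe: pd.DataFrame,
                           dmrs: list[DMRTile] | FeatureTrack,
                           feature: FeatureTrack,
                           dmr_set_name: str = "dmrs") -> ContingencyResult:
    """Count the 2x2 classification of universe CpGs (counts only).

    ``cpg_universe`` holds 1-based CpG coordinates (columns chrom, pos), the
    convention of the united matrices it normally comes from.
    """
    if len(cpg_universe) == 0:
        raise ValueError("empty CpG universe")
    chroms = cpg_universe["chrom"].to_numpy()
    pos0 = cpg_universe["pos"].to_numpy(np.int64) - 1
    in_dmr = points_in_track(chroms, pos0, _dmr_track(dmrs, dmr_set_name))
    in_feat = points_in_track(chroms, pos0, feature)
    a = int((in_dmr & in_feat).sum())
    b = int((in_dmr & ~in_feat).sum())
    c = int((~in_dmr & in_feat).sum())
    d = int((~in_dmr & ~in_feat).sum())
    return ContingencyResult(a, b, c, d, feature.name, dmr_set_name)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums P(X = x) over the support of X ~ Hypergeom(N=a+b+c+d, K=a+b, n=a+c)
    for every x whose probability does not exceed that of the observed table
    (relative tie tolerance 1e-7, the conventional guard against float ties).
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("negative contingency count")
    n_total, k_dmr, n_feat = a + b + c + d, a + b, a + c
    if n_total == 0:
        return 1.0
    lo = max(0, k_dmr + n_feat - n_total)
    hi = min(k_dmr, n_feat)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n_total, k_dmr, n_feat)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def odds_ratio_test(result: ContingencyResult) -> ContingencyResult:
    """Annotate a contingency table with OR = ad/bc, ln(OR) and Fisher p."""
    a, b, c, d = result.a, result.b, result.c, result.d
    if b * c > 0:
        orr = (a * d) / (b * c)
        log_or = math.log(orr) if orr > 0 else -math.inf
    elif a * d > 0:
        orr, log_or = math.inf, math.inf
    else:
        orr, log_or = math.nan, math.nan
    result.odds_ratio = orr
    result.log_or = log_or
    result.p_value = fisher_exact_two_sided(a, b, c, d)
    return result


DEFAULT_TSS_BINS: list[tuple[float, float]] = [
    (0, 1_000), (1_000, 5_000), (5_000, 10_000),
    (10_000, 50_000), (50_000, 100_000), (100_000, math.inf),
]


def tss_distance_enrichment(dmrs, tss: TSSTable,
                            cpg_universe: pd.DataFrame,
                            bins: list[tuple[float, float]] | None = None,
                            dmr_set_name: str = "dmrs") -> list[ContingencyResult]:
    """OR of DMR membership per unsigned-distance-to-nearest-TSS bin.

    Distances are strand-blind.  CpGs on chromosomes with no TSS have
    undefined distance and are left out of every bin.  An empty bin yields a
    counts-only result (a = c = 0, no OR/p annotation).
    """
    bins = bins if bins is not None else DEFAULT_TSS_BINS
    for (lo1, hi1), (lo2, _) in zip(bins, bins[1:]):
        if hi1 > lo2:
            raise ValueError("bins must be disjoint and ordered")
    chroms = cpg_universe["chrom"].to_numpy()
    pos0 = cpg_universe["pos"].to_numpy(np.int64) - 1
    dist = np.full(len(pos0), np.inf)
    for chrom, grp in tss.sites.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        sites = np.sort(grp["tss_pos"].to_numpy(np.int64))
        idx = np.searchsorted(sites, pos0[sel])
        left = np.abs(pos0[sel] - sites[np.clip(idx - 1, 0, len(sites) - 1)])
        right = np.abs(sites[np.clip(idx, 0, len(sites) - 1)] - pos0[sel])
        dist[sel] = np.minimum(left, right)
    in_dmr = points_in_track(chroms, pos0, _dmr_track(dmrs, dmr_set_name))
    results = []
    for lo, hi in bins:
        in_bin = (dist >= lo) & (dist < hi) & np.isfinite(dist)
        a = int((in_dmr & in_bin).sum())
        b = int((in_dmr & ~in_bin).sum())
        c = int((~in_dmr & in_bin).sum())
        d = int((~in_dmr & ~in_bin).sum())
        res = ContingencyResult(a, b, c, d, f"tss_{lo:g}_{hi:g}", dmr_set_name)
        if a + c > 0:
            res = odds_ratio_test(res)
        results.append(res)
    return results


def enrichment_report(results: list[ContingencyResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": r.feature_name, "dmr_set": r.dmr_set_name,
        "a": r.a, "b": r.b, "c": r.c, "d": r.d,
        "odds_ratio": r.odds_ratio, "log_or": r.log_or, "p_value": r.p_value,
    } for r in results])
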