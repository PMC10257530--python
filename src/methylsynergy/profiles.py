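"""Global methylation summaries and feature-centered methylation curves.

The global summary is the coverage-weighted mean methylation percentage,
100 * sum(methylated reads) / sum(reads), over all retained CpGs and samples
of a group; the distribution summary reports a histogram with the fractions
below 5% and above 95% methylation as a bimodality proxy (somatic methylomes
concentrate near the two extremes).

Feature-centered profiles average methylation in fixed-width offset bins of
a window (default 5 kb) centered on each feature's midpoint, flipping minus-
strand features so negative offsets always point upstream; a cubic smoothing
spline over the bin means provides the presentation-layer curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .methylation_io import FeatureTrack, MethylationCallSet, UnitedMatrix

logger = logging.getLogger("methylsynergy")


@dataclass
class MethylationProfile:
    """Binned methylation around feature centers (offsets in bp)."""

    feature_name: str
    group_id: str
    bin_centers: np.ndarray    # window offsets, negative = upstream
    bin_means: np.ndarray      # percent, NaN where no coverage
    bin_counts: np.ndarray     # CpG observations per bin
    smoothed: np.ndarray       # percent on ``grid``
    grid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.bin_centers,
                             "mean": self.bin_means,
                             "n_cpgs": self.bin_counts})


def weighted_mean_methylation(united: UnitedMatrix, group: str | None = None) -> float:
    """Coverage-weighted mean methylation percent over the united matrix."""
    if group is not None and group != united.group_id:
        raise ValueError(f"matrix holds group {united.group_id!r}, not {group!r}")
    if len(united) == 0:
        raise ValueError("empty united matrix")
    m = np.where(united.present, united.meth, 0).sum()
    c = np.where(united.present, united.cov, 0).sum()
    return float(100.0 * m / c)


def methylation_histogram(per_cpg_percent, bin_width: float = 10.0,
                          low: float = 5.0, high: float = 95.0):
    """Histogram of per-CpG methylation percentages on [0, 100].

    Returns (counts, summary) where summary reports the fractions strictly
    below ``low`` and strictly above ``high`` percent methylation; their sum
    is the bimodality proxy.
    """
    vals = np.asarray(per_cpg_percent, dtype=float)
    if len(vals) and (vals.min() < 0 or vals.max() > 100):
        raise ValueError("methylation percentages must lie in [0, 100]")
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    counts, _ = np.histogram(vals, bins=edges)
    n = len(vals)
    summary = {
        "n": n,
        "fraction_below_low": float((vals < low).sum() / n) if n else np.nan,
        "fraction_above_high": float((vals > high).sum() / n) if n else np.nan,
    }
    if n:
        summary["bimodality"] = (summary["fraction_below_low"]
                                 + summary["fraction_above_high"])
    return counts, summary


def _per_cpg_counts(calls) -> pd.DataFrame:
    """Pool any supported container to per-CpG (chrom, pos, meth, cov)."""
    if isinstance(calls, UnitedMatrix):
        m, c = calls.pooled_counts()
        df = calls.keys.assign(meth=m, cov=c)
    elif isinstance(calls, MethylationCallSet):
        df = calls.records.assign(cov=calls.coverage)
        df = (df.groupby(["chrom", "pos"], as_index=False)
                .agg(meth=("n_meth", "sum"), cov=("cov", "sum")))
    elif isinstance(calls, pd.DataFrame):
        df = calls[["chrom", "pos", "meth", "cov"]].copy()
    else:
        raise TypeError(f"unsupported calls container {type(calls).__name__}")
    return df[df["cov"] > 0]


def feature_centered_profile(calls, features: FeatureTrack, window: int = 5000,
                             n_bins: int = 50, group_id: str = "",
                             grid_points: int = 201) -> MethylationProfile:
    """Coverage-weighted methylation by offset bin around feature midpoints.

    Offsets run over [-window/2, window/2); minus-strand features are flipped
    so that negative offsets are upstream of the feature.  Returns an empty
    profile (all-NaN means) with a warning when no CpG falls in any window.
    """
    half = window // 2
    bin_w = window / n_bins
    df = _per_cpg_counts(calls)
    meth_sum = np.zeros(n_bins)
    cov_sum = np.zeros(n_bins)
    n_obs = np.zeros(n_bins, dtype=np.int64)
    by_chrom = {chrom: grp for chrom, grp in df.groupby("chrom")}
    for f in features.intervals.itertuples():
        grp = by_chrom.get(f.chrom)
        if grp is None:
            continue
        center = (f.start + f.end) // 2
        pos0 = grp["pos"].to_numpy(np.int64) - 1
        off = pos0 - center
        if f.strand == "-":
            off = -off
        sel = (off >= -half) & (off < -half + n_bins * bin_w)
        if not sel.any():
            continue
        idx = ((off[sel] + half) / bin_w).astype(np.int64)
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(meth_sum, idx, grp["meth"].to_numpy(float)[sel])
        np.add.at(cov_sum, idx, grp["cov"].to_numpy(float)[sel])
        np.add.at(n_obs, idx, 1)
    centers = -half + (np.arange(n_bins) + 0.5) * bin_w
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cov_sum > 0, 100.0 * meth_sum / np.maximum(cov_sum, 1), np.nan)
    grid = np.linspace(-half, half, grid_points)
    ok = np.isfinite(means)
    if ok.sum() == 0:
        logger.warning("feature_centered_profile: no CpGs in any window of %s",
                       features.name)
        smoothed = np.full(grid_points, np.nan)
    elif ok.sum() < 4:
        smoothed = np.interp(grid, centers[ok], means[ok])
    else:
        spline = make_smoothing_spline(centers[ok], means[ok])
        smoothed = spline(grid)
    return MethylationProfile(features.name, group_id, centers, means,
                              n_obs, smoothed, grid)


def profile_to_tsv(profile: MethylationProfile, path) -> None:
    df = profile.to_frame()
    fine = pd.DataFrame({"offset": profile.grid, "smoothed": profile.smoothed})
    out = df.merge(fine, on="offset", how="outer").sort_values("offset")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
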