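"""Per-CpG differential methylation testing and DMC calling.

The effect size at each CpG is the difference of coverage-pooled group
methylation proportions, in percentage points (treatment minus control).
Significance comes from one of two tests on the per-sample
(methylated, unmethylated) counts:

* ``logistic_lrt`` (default) — likelihood-ratio test (1 df) between binomial
  logit models with and without a group term.  With the group indicator as
  the only covariate the MLE of each model is attained at the pooled group
  (resp. overall) proportion, so the statistic reduces in closed form to the
  pooled G-test; that identity is what the vectorised implementation uses.
* ``fisher_pooled`` — two-sided Fisher exact test on the pooled 2x2 table,
  for 1-vs-1 designs without replicates.

q-values are Benjamini-Hochberg over all tested CpGs.  A CpG is a DMC when
|difference| >= ``diff_cutoff`` (inclusive) and q < ``q_cutoff``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylation_io import UnitedMatrix

logger = logging.getLogger("methylsynergy")

HYPER = "hyper"
HYPO = "hypo"

DMC_COLUMNS = ["chrom", "pos", "strand", "p_value", "q_value", "meth_diff", "direction"]


@dataclass(frozen=True)
class DMC:
    """A differentially methylated cytosine (treatment vs control)."""

    chrom: str
    pos: int                  # 1-based
    meth_diff: float          # percentage points, treatment - control
    p_value: float
    q_value: float
    direction: str            # hyper iff meth_diff > 0

    def __post_init__(self):
        expected = HYPER if self.meth_diff > 0 else HYPO
        if self.direction != expected:
            raise ValueError(f"direction {self.direction!r} inconsistent with "
                             f"meth_diff {self.meth_diff}")


@dataclass
class AnalysisConfig:
    """Thresholds and choices for the DMC/DMR workflow.

    Defaults: >=5x coverage per sample, capture in >=2 replicates per group,
    |difference| >= 35 percentage points (inclusive), q < 0.01, DMCs within
    500 bp merged into tiles, tiles padded to 100 bp.
    """

    min_coverage: int = 5
    min_per_group: int = 2
    diff_cutoff: float = 35.0
    q_cutoff: float = 0.01
    merge_gap: int = 500
    min_tile_width: int = 100
    test: str = "logistic_lrt"

    def __post_init__(self):
        if min(self.min_coverage, self.min_per_group, self.diff_cutoff,
               self.merge_gap, self.min_tile_width) <= 0:
            raise ValueError("all thresholds must be positive")
        if not (0 < self.q_cutoff < 1):
            raise ValueError("q_cutoff must lie in (0, 1)")
        if self.test not in ("logistic_lrt", "fisher_pooled"):
            raise ValueError(f"unknown test {self.test!r}")


def _pool(counts) -> tuple[int, int]:
    """Sum an iterable of (n_meth, n_unmeth) pairs."""
    arr = np.asarray(list(counts), dtype=np.int64).reshape(-1, 2)
    return int(arr[:, 0].sum()), int(arr[:, 1].sum())


def pooled_methylation_difference(treatment_counts, control_counts) -> float:
    """Difference of pooled methylation proportions, in percentage points."""
    mt, ut = _pool(treatment_counts)
    mc, uc = _pool(control_counts)
    if mt + ut == 0 or mc + uc == 0:
        raise ValueError("zero pooled coverage in one group")
    return 100.0 * (mt / (mt + ut) - mc / (mc + uc))


def _g_statistic(mt, ct, mc, cc):
    """Vectorised pooled G statistic (= logistic LRT with a group term)."""
    mt = np.asarray(mt, dtype=float); ct = np.asarray(ct, dtype=float)
    mc = np.asarray(mc, dtype=float); cc = np.asarray(cc, dtype=float)

    def _ll(m, c, p):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(m > 0, m * np.log(p), 0.0)
            t2 = np.where(c - m > 0, (c - m) * np.log1p(-p), 0.0)
        return t1 + t2

    pt = np.divide(mt, ct, out=np.zeros_like(mt), where=ct > 0)
    pc = np.divide(mc, cc, out=np.zeros_like(mc), where=cc > 0)
    p0 = (mt + mc) / (ct + cc)
    g = 2.0 * (_ll(mt, ct, pt) + _ll(mc, cc, pc)
               - _ll(mt, ct, p0) - _ll(mc, cc, p0))
    return np.maximum(g, 0.0)


def dmc_test(treatment_counts_per_sample, control_counts_per_sample,
             method: str = "logistic_lrt") -> float:
    """p-value for a group effect at one CpG from per-sample counts."""
    mt, ut = _pool(treatment_counts_per_sample)
    mc, uc = _pool(control_counts_per_sample)
    if mt + ut == 0 and mc + uc == 0:
        raise ValueError("all-zero coverage at CpG")
    if method == "logistic_lrt":
        g = _g_statistic(mt, mt + ut, mc, mc + uc)
        return float(stats.chi2.sf(g, df=1))
    if method == "fisher_pooled":
        return float(stats.fisher_exact([[mt, ut], [mc, uc]])[1])
    raise ValueError(f"unknown test {method!r}")


def dmc_table(united_treatment: UnitedMatrix, united_control: UnitedMatrix,
              config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Test every CpG shared by the two united matrices.

    Returns a DataFrame (chrom, pos, meth_diff, p_value, q_value) over the
    coordinate intersection; CpGs with zero pooled coverage in either group
    are skipped with a log notice.
    """
    config = config or AnalysisConfig()
    mt, ct = united_treatment.pooled_counts()
    mc, cc = united_control.pooled_counts()
    t = united_treatment.keys.assign(mt=mt, ct=ct)
    c = united_control.keys.assign(mc=mc, cc=cc)
    both = t.merge(c, on=["chrom", "pos"], how="inner")
    if len(both) == 0:
        logger.warning("dmc_table: empty CpG intersection between %s and %s",
                       united_treatment.group_id, united_control.group_id)
        return pd.DataFrame(columns=["chrom", "pos", "meth_diff", "p_value", "q_value"])
    ok = (both["ct"] > 0) & (both["cc"] > 0)
    if (~ok).any():
        logger.info("dmc_table: skipping %d CpGs with zero pooled coverage",
                    int((~ok).sum()))
        both = both[ok].reset_index(drop=True)
    mt = both["mt"].to_numpy(float); ct = both["ct"].to_numpy(float)
    mc = both["mc"].to_numpy(float); cc = both["cc"].to_numpy(float)
    diff = 100.0 * (mt / ct - mc / cc)
    if config.test == "logistic_lrt":
        p = stats.chi2.sf(_g_statistic(mt, ct, mc, cc), df=1)
    else:
        p = np.array([stats.fisher_exact([[int(a), int(b - a)], [int(x), int(y - x)]])[1]
                      for a, b, x, y in zip(mt, ct, mc, cc)])
    q = multipletests(p, method="fdr_bh")[1] if len(p) else p
    out = both[["chrom", "pos"]].copy()
    out["meth_diff"] = diff
    out["p_value"] = p
    out["q_value"] = q
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def call_dmcs(united_treatment: UnitedMatrix, united_control: UnitedMatrix,
              config: AnalysisConfig | None = None,
              table: pd.DataFrame | None = None) -> list[DMC]:
    """Call DMCs: |diff| >= diff_cutoff (inclusive) and q < q_cutoff.

    Pass a precomputed ``table`` (from :func:`dmc_table`) to avoid re-testing.
    """
    config = config or AnalysisConfig()
    if table is None:
        table = dmc_table(united_treatment, united_control, config)
    hit = (table["meth_diff"].abs() >= config.diff_cutoff) & \
          (table["q_value"] < config.q_cutoff)
    sub = table[hit]
    return [DMC(str(r.chrom), int(r.pos), float(r.meth_diff), float(r.p_value),
                float(r.q_value), HYPER if r.meth_diff > 0 else HYPO)
            for r in sub.itertuples()]


def dmcs_to_frame(dmcs: list[DMC]) -> pd.DataFrame:
    df = pd.DataFrame([{"chrom": d.chrom, "pos": d.pos, "strand": "+",
                        "p_value": d.p_value, "q_value": d.q_value,
                        "meth_diff": d.meth_diff, "direction": d.direction}
                       for d in dmcs], columns=DMC_COLUMNS)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_dmcs(dmcs: list[DMC], path) -> None:
    dmcs_to_frame(dmcs).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dmcs(path) -> list[DMC]:
    df = pd.read_csv(path, sep="\t")
    return [DMC(str(r.chrom), int(r.pos), float(r.meth_diff), float(r.p_value),
                float(r.q_value), str(r.direction)) for r in df.itertuples()]
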