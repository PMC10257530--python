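"""Synthetic bisulfite cohorts, genome annotations and viability plates.

The generator emulates the structure of an RRBS drug-treatment study so
every pipeline stage can be exercised against known ground truth:

* cohort design: one control group and three treatment groups, three
  replicates each (4 x 3);
* baseline methylome: per-CpG methylation levels drawn from a two-component
  beta mixture (weights 0.45/0.55, modes Beta(0.5, 10) near 0 and
  Beta(10, 0.5) near 1), the bimodal shape typical of somatic methylomes;
* planted differential regions: non-overlapping intervals where treatment
  groups are shifted by a signed effect (percentage points, clamped to
  [0, 100]); hypomethylated regions draw their baseline from the high mode
  and hypermethylated ones from the low mode, so the shift is expressible;
* sequencing: per-sample, per-strand read depth from a negative binomial
  (mean 30, dispersion 5 — typical post-filter RRBS depth) with Bernoulli
  site dropout, methylated counts binomial at the site's level;
* viability plates: multiplicative-independence combination viability with
  optional planted synergy epsilon and Gaussian noise.

All generators are pure functions of (seed, parameters); independent
substreams are derived per generator so the annotation, the methylome and
the plate do not share randomness.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import TSSTable, build_promoters, complement_intervals
from .genes import GeneModel
from .methylation_io import FeatureTrack, MethylationCallSet
from .synergy import ViabilityTable

DEFAULT_GROUPS = ("control", "treat_a", "treat_b", "treat_c")


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start: int            # half-open, 0-based
    end: int
    effect: float         # signed percentage points applied to treatment groups
    groups: tuple[str, ...] | None = None   # None = every non-control group

    @property
    def direction(self) -> str:
        return "hyper" if self.effect > 0 else "hypo"


@dataclass
class SimulationTruth:
    """Ground truth and parameters for one synthetic cohort."""

    seed: int
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_cpgs: int = 50_000
    groups: tuple[str, ...] = DEFAULT_GROUPS
    control_group: str = "control"
    n_replicates: int = 3
    mixture_weights: tuple[float, float] = (0.45, 0.55)
    low_mode: tuple[float, float] = (0.5, 10.0)
    high_mode: tuple[float, float] = (10.0, 0.5)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    dropout: float = 0.05
    planted_dmrs: list[PlantedRegion] = field(default_factory=list)
    cpgs_per_planted: int = 8
    stranded: bool = True
    # viability truth
    v_a: float = 0.6
    v_b: float = 0.5
    synergy_eps: float = 0.0
    viability_noise_sd: float = 0.05

    def __post_init__(self):
        if any(abs(r.effect) > 100 for r in self.planted_dmrs):
            raise ValueError("planted effects must lie in [-100, 100]")
        spans = sorted((r.chrom, r.start, r.end) for r in self.planted_dmrs)
        for (c1, s1, e1), (c2, s2, _) in zip(spans, spans[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("planted regions must not overlap")
        if self.control_group not in self.groups:
            raise ValueError("control_group must be one of groups")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True, default=list)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_dmrs"] = [
            PlantedRegion(r["chrom"], r["start"], r["end"], r["effect"],
                          tuple(r["groups"]) if r.get("groups") else None)
            for r in d.get("planted_dmrs", [])]
        d["groups"] = tuple(d["groups"])
        for k in ("mixture_weights", "low_mode", "high_mode"):
            d[k] = tuple(d[k])
        return cls(**d)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def plant_regions(seed: int, n_hypo: int, n_hyper: int = 0,
                  effect_range: tuple[float, float] = (40.0, 60.0),
                  width: int = 1000, n_chrom: int = 2,
                  chrom_length: int = 5_000_000,
                  groups: tuple[str, ...] | None = None) -> list[PlantedRegion]:
    """Draw non-overlapping planted regions on an even genome grid."""
    rng = _rng(seed, 11)
    n_total = n_hypo + n_hyper
    per_chrom = int(np.ceil(n_total / n_chrom))
    slots = []
    for c in range(n_chrom):
        gap = chrom_length // (per_chrom + 1)
        if gap <= width:
            raise ValueError("too many planted regions for the genome size")
        for k in range(per_chrom):
            start = (k + 1) * gap + int(rng.integers(0, gap - width))
            slots.append((f"chr{c + 1}", start, start + width))
    rng.shuffle(slots)
    lo, hi = effect_range
    regions = []
    for i in range(n_total):
        chrom, start, end = slots[i]
        mag = float(rng.uniform(lo, hi))
        effect = -mag if i < n_hypo else mag
        regions.append(PlantedRegion(chrom, start, end, effect, groups))
    return sorted(regions, key=lambda r: (r.chrom, r.start))


# ---------------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------------

def generate_feature_annotation(seed: int, n_chrom: int = 2,
                                chrom_length: int = 5_000_000,
                                feature_spec: dict | None = None):
    """Deterministic gene models plus derived interval tracks.

    Returns (tracks, tss_table, genes) where ``tracks`` maps name ->
    FeatureTrack for gene_bodies, promoters, exons, introns, intergenic and
    cpg_islands, all mutually consistent with the gene models (promoters are
    produced by :func:`~methylsynergy.enrichment.build_promoters`).
    """
    spec = {"n_genes_per_chrom": 60, "gene_length": (5_000, 50_000),
            "exons_per_gene": (2, 8), "exon_length": (100, 300),
            "island_fraction": 0.6, "island_length": (300, 1_500)}
    spec.update(feature_spec or {})
    rng = _rng(seed, 23)
    genes: list[GeneModel] = []
    exon_rows, island_rows, body_rows = [], [], []
    chrom_sizes = {f"chr{i + 1}": chrom_length for i in range(n_chrom)}
    gid = 0
    for chrom in chrom_sizes:
        n_genes = spec["n_genes_per_chrom"]
        if n_genes == 0:
            continue
        slot = chrom_length // (n_genes + 1)
        for k in range(n_genes):
            glen = int(rng.integers(*spec["gene_length"]))
            glen = min(glen, slot - 1000)
            start = (k + 1) * slot - glen // 2
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            gid += 1
            gene = GeneModel(f"gene{gid:04d}", chrom, tss, strand, (start, end))
            genes.append(gene)
            body_rows.append((chrom, start, end, strand, gene.gene_id))
            n_ex = int(rng.integers(*spec["exons_per_gene"]))
            ex_starts = np.sort(rng.choice(
                np.arange(start, end - spec["exon_length"][1]),
                size=n_ex, replace=False))
            last_end = start
            for es in ex_starts:
                if es < last_end:
                    continue
                ee = es + int(rng.integers(*spec["exon_length"]))
                ee = min(ee, end)
                exon_rows.append((chrom, int(es), int(ee), strand, gene.gene_id))
                last_end = ee
            if rng.random() < spec["island_fraction"]:
                ilen = int(rng.integers(*spec["island_length"]))
                icenter = tss
                island_rows.append((chrom, max(0, icenter - ilen // 2),
                                    icenter + ilen // 2, ".", "."))
    def _track(name, rows):
        return FeatureTrack(name, pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "label"]))

    bodies = _track("gene_bodies", body_rows)
    exons = _track("exons", exon_rows)
    islands = _track("cpg_islands", island_rows)
    tss_table = TSSTable(pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss_pos, g.strand) for g in genes],
        columns=["gene_id", "chrom", "tss_pos", "strand"]))
    promoters = build_promoters(tss_table, chrom_sizes=chrom_sizes)
    whole = FeatureTrack.from_spans(
        "genome", [(c, 0, L) for c, L in chrom_sizes.items()])
    intergenic = complement_intervals(whole, bodies)
    intergenic.name = "intergenic"
    introns = complement_intervals(bodies.sort(), exons) if len(bodies) else \
        FeatureTrack.from_spans("introns", [])
    introns.name = "introns"
    tracks = {"gene_bodies": bodies, "promoters": promoters, "exons": exons,
              "introns": introns, "intergenic": intergenic,
              "cpg_islands": islands}
    return tracks, tss_table, genes


# ---------------------------------------------------------------------------
# Methylome cohort
# ---------------------------------------------------------------------------

def _place_cpgs(truth: SimulationTruth, rng: np.random.Generator):
    """CpG site positions: uniform background plus density in planted regions.

    Positions are odd 1-based coordinates (so the '-' strand partner at
    pos+1 never collides with the next site).
    """
    chroms, positions = [], []
    per_chrom = truth.n_cpgs // truth.n_chrom
    for chrom in truth.chrom_names:
        grid = np.arange(1, truth.chrom_length - 2, 2, dtype=np.int64)
        take = rng.choice(len(grid), size=min(per_chrom, len(grid)), replace=False)
        pos = grid[np.sort(take)]
        chroms.append(np.full(len(pos), chrom, dtype=object))
        positions.append(pos)
    extra_c, extra_p = [], []
    for r in truth.planted_dmrs:
        grid = np.arange(r.start + 1 + (r.start % 2), r.end, 2, dtype=np.int64)
        k = min(truth.cpgs_per_planted, len(grid))
        take = rng.choice(len(grid), size=k, replace=False)
        extra_c.append(np.full(k, r.chrom, dtype=object))
        extra_p.append(grid[np.sort(take)])
    chroms = np.concatenate(chroms + extra_c)
    positions = np.concatenate(positions + extra_p)
    df = pd.DataFrame({"chrom": chroms, "pos": positions})
    df = df.drop_duplicates(["chrom", "pos"]).sort_values(
        ["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def _baseline_levels(truth: SimulationTruth, site_df: pd.DataFrame,
                     rng: np.random.Generator) -> np.ndarray:
    n = len(site_df)
    w_low, w_high = truth.mixture_weights
    high = rng.random(n) < w_high / (w_low + w_high)
    level = np.where(high,
                     rng.beta(*truth.high_mode, size=n),
                     rng.beta(*truth.low_mode, size=n))
    # planted regions draw from the direction-compatible mode
    for r in truth.planted_dmrs:
        sel = ((site_df["chrom"] == r.chrom) &
               (site_df["pos"] - 1 >= r.start) & (site_df["pos"] - 1 < r.end))
        idx = np.flatnonzero(sel.to_numpy())
        if len(idx) == 0:
            continue
        mode = truth.high_mode if r.effect < 0 else truth.low_mode
        level[idx] = rng.beta(*mode, size=len(idx))
    return level


def generate_methylome_cohort(truth: SimulationTruth
                              ) -> tuple[dict[str, list[MethylationCallSet]],
                                         SimulationTruth]:
    """Simulate per-sample call sets for every group of the design.

    Returns ({group: [MethylationCallSet, ...]}, truth).  When
    ``truth.stranded`` the two strands of each CpG are emitted as separate
    records (the '-' strand at pos+1), splitting the site's depth
    binomially; strand-merging then restores the site totals exactly.
    """
    rng = _rng(truth.seed, 37)
    sites = _place_cpgs(truth, rng)
    base = _baseline_levels(truth, sites, rng)
    levels = {g: base.copy() for g in truth.groups}
    for r in truth.planted_dmrs:
        sel = ((sites["chrom"] == r.chrom) &
               (sites["pos"] - 1 >= r.start) & (sites["pos"] - 1 < r.end))
        idx = np.flatnonzero(sel.to_numpy())
        affected = r.groups if r.groups is not None else \
            tuple(g for g in truth.groups if g != truth.control_group)
        for g in affected:
            if g == truth.control_group:
                continue
            levels[g][idx] = np.clip(base[idx] + r.effect / 100.0, 0.0, 1.0)
    n = len(sites)
    r_disp = truth.coverage_dispersion
    p_nb = r_disp / (r_disp + truth.coverage_mean)
    cohort: dict[str, list[MethylationCallSet]] = {}
    for g in truth.groups:
        cohort[g] = []
        for rep in range(truth.n_replicates):
            cov = rng.negative_binomial(r_disp, p_nb, size=n)
            cov[rng.random(n) < truth.dropout] = 0
            if truth.stranded:
                cov_plus = rng.binomial(cov, 0.5)
                cov_minus = cov - cov_plus
                meth_plus = rng.binomial(cov_plus, levels[g])
                meth_minus = rng.binomial(cov_minus, levels[g])
                frames = []
                for strand, c_arr, m_arr, shift in (
                        ("+", cov_plus, meth_plus, 0),
                        ("-", cov_minus, meth_minus, 1)):
                    keep = c_arr > 0
                    frames.append(pd.DataFrame({
                        "chrom": sites["chrom"].to_numpy()[keep],
                        "pos": sites["pos"].to_numpy()[keep] + shift,
                        "strand": strand,
                        "n_meth": m_arr[keep],
                        "n_unmeth": c_arr[keep] - m_arr[keep]}))
                df = pd.concat(frames, ignore_index=True)
            else:
                meth = rng.binomial(cov, levels[g])
                keep = cov > 0
                df = pd.DataFrame({
                    "chrom": sites["chrom"].to_numpy()[keep],
                    "pos": sites["pos"].to_numpy()[keep],
                    "strand": "+",
                    "n_meth": meth[keep],
                    "n_unmeth": cov[keep] - meth[keep]})
            df = df.sort_values(["chrom", "pos"], kind="mergesort")
            cohort[g].append(MethylationCallSet(f"{g}_rep{rep + 1}", df))
    return cohort, truth


# ---------------------------------------------------------------------------
# Viability plates
# ---------------------------------------------------------------------------

def generate_viability_table(truth: SimulationTruth, n_replicates: int = 3,
                             n_control_outliers: int = 0,
                             outlier_sd_multiple: float = 5.0
                             ) -> tuple[ViabilityTable, SimulationTruth]:
    """Simulate a replicate x treatment viability plate.

    Observed combination viability is v_a*v_b - synergy_eps plus Gaussian
    noise (floored at 0); singles and controls are noised the same way.
    ``n_control_outliers`` replicate sets get their control displaced by
    ``outlier_sd_multiple`` noise SDs (requires a positive noise SD).
    """
    if not (0.0 <= truth.v_a <= 1.0 and 0.0 <= truth.v_b <= 1.0):
        raise ValueError("single-agent viabilities must lie in [0, 1]")
    if truth.viability_noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    rng = _rng(truth.seed, 53)
    sd = truth.viability_noise_sd
    n = n_replicates

    def noised(mean):
        return np.maximum(0.0, mean + rng.normal(0.0, sd, size=n)) if sd > 0 \
            else np.full(n, max(0.0, mean))

    df = pd.DataFrame({
        "drug_a": noised(truth.v_a),
        "drug_b": noised(truth.v_b),
        "combination": noised(truth.v_a * truth.v_b - truth.synergy_eps),
        "control": noised(1.0),
    })
    if n_control_outliers:
        if sd <= 0:
            raise ValueError("control outliers need a positive noise SD")
        rows = rng.choice(n, size=n_control_outliers, replace=False)
        df.loc[rows, "control"] = 1.0 + outlier_sd_multiple * sd
    return ViabilityTable(df), truth


def write_plate_csv(table: ViabilityTable, path) -> None:
    long = table.values.reset_index(names="replicate_id").melt(
        id_vars="replicate_id", var_name="treatment", value_name="viability")
    long.sort_values(["replicate_id", "treatment"]).to_csv(path, index=False)
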