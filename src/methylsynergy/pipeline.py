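"""End-to-end pipeline orchestration from a YAML config.

Stages communicate through plain TSV/JSON artifacts in the output
directory, so each stage can be run (and re-run) independently:

    simulate -> unite -> dmc -> dmr -> venn -> enrich -> profile -> genes
    (+ synergy)

Outputs are a pure function of (inputs, config); a run manifest records the
config snapshot, input checksums, stage timings and every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import AnalysisConfig, call_dmcs, dmc_table, read_dmcs, write_dmcs
from .dmr import (dmrs_to_frame, filter_ambiguous, intersect_dmr_sets, read_dmrs,
                  summarize_dmrs, tile_dmcs, write_dmrs)
from .enrichment import (TSSTable, build_promoters, cpg_region_contingency,
                         enrichment_report, odds_ratio_test,
                         tss_distance_enrichment)
from .genes import (associate_regions_to_genes, classify_cancer_roles,
                    promoter_partition, select_top_hypomethylated)
from .methylation_io import (merge_strands, read_bed, read_cytosine_calls,
                             read_united, unite_groups, write_bed,
                             write_cytosine_calls, write_united)
from .profiles import (feature_centered_profile, methylation_histogram,
                       profile_to_tsv, weighted_mean_methylation)
from .simulate import (SimulationTruth, generate_feature_annotation,
                       generate_methylome_cohort, generate_viability_table,
                       plant_regions, write_plate_csv)
from .synergy import read_plate_csv, synergy_score, write_synergy_report

logger = logging.getLogger("methylsynergy")

STAGES = ["simulate", "unite", "dmc", "dmr", "venn", "enrich", "profile",
          "genes", "synergy"]


class ConfigError(ValueError):
    pass


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


DEFAULT_CONFIG = {
    "seed": 7,
    "simulate": {
        "n_chrom": 2, "chrom_length": 2_000_000, "n_cpgs": 20_000,
        "n_planted_hypo": 30, "n_planted_hyper": 10,
        "effect_range": [40.0, 60.0], "region_width": 1000,
        "coverage_mean": 30.0, "coverage_dispersion": 5.0, "dropout": 0.05,
        "n_genes_per_chrom": 40,
    },
    "analysis": {
        "min_coverage": 5, "min_per_group": 2, "diff_cutoff": 35.0,
        "q_cutoff": 0.01, "merge_gap": 500, "min_tile_width": 100,
        "test": "logistic_lrt",
    },
    "groups": ["control", "treat_a", "treat_b", "treat_c"],
    "control_group": "control",
    "n_replicates": 3,
    "synergy": {"enabled": True, "n_replicates": 6, "v_a": 0.6, "v_b": 0.5,
                "synergy_eps": 0.15, "noise_sd": 0.05},
    "top_n_hypo": 8000,
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config must be a YAML mapping")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if key in cfg and isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    bad = [k for k in ("seed", "groups", "control_group") if k not in cfg]
    if bad:
        raise ConfigError(f"config missing required fields: {bad}")
    # validates threshold ranges
    AnalysisConfig(**cfg["analysis"])
    return cfg


def analysis_config(cfg: dict) -> AnalysisConfig:
    return AnalysisConfig(**cfg["analysis"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _truth_from_config(cfg: dict) -> SimulationTruth:
    sim = cfg["simulate"]
    planted = plant_regions(
        cfg["seed"], sim["n_planted_hypo"], sim["n_planted_hyper"],
        tuple(sim["effect_range"]), sim["region_width"],
        sim["n_chrom"], sim["chrom_length"])
    syn = cfg["synergy"]
    return SimulationTruth(
        seed=cfg["seed"], n_chrom=sim["n_chrom"],
        chrom_length=sim["chrom_length"], n_cpgs=sim["n_cpgs"],
        groups=tuple(cfg["groups"]), control_group=cfg["control_group"],
        n_replicates=cfg["n_replicates"],
        coverage_mean=sim["coverage_mean"],
        coverage_dispersion=sim["coverage_dispersion"], dropout=sim["dropout"],
        planted_dmrs=planted, v_a=syn["v_a"], v_b=syn["v_b"],
        synergy_eps=syn["synergy_eps"], viability_noise_sd=syn["noise_sd"])


def _comparisons(cfg: dict) -> list[str]:
    return [g for g in cfg["groups"] if g != cfg["control_group"]]


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    truth = _truth_from_config(cfg)
    tracks, tss, _genes = generate_feature_annotation(
        cfg["seed"], truth.n_chrom, truth.chrom_length,
        {"n_genes_per_chrom": cfg["simulate"]["n_genes_per_chrom"]})
    cohort, truth = generate_methylome_cohort(truth)
    out = []
    calls_dir = outdir / "calls"
    calls_dir.mkdir(parents=True, exist_ok=True)
    for group, reps in cohort.items():
        for calls in reps:
            p = calls_dir / f"{calls.sample_id}.cov.tsv"
            write_cytosine_calls(calls, p, dialect="cytosine_report")
            out.append(p)
    for name, track in tracks.items():
        p = outdir / f"track_{name}.bed"
        write_bed(track, p)
        out.append(p)
    tss_path = outdir / "tss.tsv"
    tss.sites.to_csv(tss_path, sep="\t", index=False)
    out.append(tss_path)
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    out.append(truth_path)
    if cfg["synergy"].get("enabled", True):
        plate, _ = generate_viability_table(
            truth, n_replicates=cfg["synergy"]["n_replicates"])
        p = outdir / "plate.csv"
        write_plate_csv(plate, p)
        out.append(p)
    # synthetic gene<->citation table for the cancer-role stage
    rng = np.random.default_rng([cfg["seed"] % (2**31), 71])
    cit = pd.DataFrame({
        "gene_id": tss.sites["gene_id"],
        "oncogene_citations": rng.poisson(1.0, len(tss.sites)),
        "tsg_citations": rng.poisson(1.0, len(tss.sites))})
    p = outdir / "citations.tsv"
    cit.to_csv(p, sep="\t", index=False)
    out.append(p)
    return out


def stage_unite(cfg: dict, outdir: Path) -> list[Path]:
    acfg = analysis_config(cfg)
    out = []
    for group in cfg["groups"]:
        samples = []
        for rep in range(1, cfg["n_replicates"] + 1):
            p = outdir / "calls" / f"{group}_rep{rep}.cov.tsv"
            if not p.exists():
                raise FileNotFoundError(f"missing input call file: {p}")
            calls = read_cytosine_calls(p, "cytosine_report",
                                        sample_id=f"{group}_rep{rep}")
            samples.append(merge_strands(calls))
        united = unite_groups(samples, acfg.min_coverage, acfg.min_per_group,
                              group_id=group)
        p = outdir / f"united_{group}.tsv"
        write_united(united, p)
        out.append(p)
    return out


def stage_dmc(cfg: dict, outdir: Path) -> list[Path]:
    acfg = analysis_config(cfg)
    control = read_united(outdir / f"united_{cfg['control_group']}.tsv",
                          acfg.min_coverage, acfg.min_per_group)
    out = []
    for group in _comparisons(cfg):
        treat = read_united(outdir / f"united_{group}.tsv",
                            acfg.min_coverage, acfg.min_per_group)
        table = dmc_table(treat, control, acfg)
        table.to_csv(outdir / f"dmc_table_{group}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        dmcs = call_dmcs(treat, control, acfg, table=table)
        p = outdir / f"dmc_{group}.tsv"
        write_dmcs(dmcs, p)
        out.extend([outdir / f"dmc_table_{group}.tsv", p])
    return out


def stage_dmr(cfg: dict, outdir: Path) -> list[Path]:
    acfg = analysis_config(cfg)
    out = []
    for group in _comparisons(cfg):
        dmcs = read_dmcs(outdir / f"dmc_{group}.tsv")
        tiles = tile_dmcs(dmcs, acfg.merge_gap, acfg.min_tile_width)
        clean, frac = filter_ambiguous(tiles)
        clean = summarize_dmrs(clean)
        logger.info("dmr %s: %d tiles, %.3g%% ambiguous removed",
                    group, len(tiles), 100 * frac)
        for direction in ("hypo", "hyper"):
            sub = [t for t in clean if t.direction == direction]
            p = outdir / f"dmr_{direction}_{group}.tsv"
            write_dmrs(sub, p)
            out.append(p)
    return out


def stage_venn(cfg: dict, outdir: Path) -> list[Path]:
    out = []
    for direction in ("hypo", "hyper"):
        sets = {}
        for group in _comparisons(cfg):
            tiles = read_dmrs(outdir / f"dmr_{direction}_{group}.tsv")
            sets[group] = tiles
        if len(sets) < 2:
            continue
        venn = intersect_dmr_sets(sets)
        p = outdir / f"venn_{direction}.json"
        with open(p, "w") as fh:
            json.dump(venn.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        out.append(p)
    return out


_ENRICH_TRACKS = ["promoters", "exons", "introns", "intergenic", "cpg_islands"]


def stage_enrich(cfg: dict, outdir: Path) -> list[Path]:
    acfg = analysis_config(cfg)
    universe = _cpg_universe(cfg, outdir, acfg)
    tss = TSSTable(pd.read_csv(outdir / "tss.tsv", sep="\t"))
    results = []
    for group in _comparisons(cfg):
        for direction in ("hypo", "hyper"):
            dmrs = read_dmrs(outdir / f"dmr_{direction}_{group}.tsv")
            if not dmrs:
                continue
            name = f"{direction}_{group}"
            for track_name in _ENRICH_TRACKS:
                track = read_bed(outdir / f"track_{track_name}.bed", track_name)
                res = cpg_region_contingency(universe, dmrs, track, name)
                results.append(odds_ratio_test(res))
            results.extend(tss_distance_enrichment(dmrs, tss, universe,
                                                   dmr_set_name=name))
    report = enrichment_report(results)
    p = outdir / "enrichment.tsv"
    report.to_csv(p, sep="\t", index=False, float_format="%.6g")
    return [p]


def _cpg_universe(cfg: dict, outdir: Path, acfg: AnalysisConfig) -> pd.DataFrame:
    frames = []
    for group in cfg["groups"]:
        united = read_united(outdir / f"united_{group}.tsv",
                             acfg.min_coverage, acfg.min_per_group)
        frames.append(united.keys)
    return (pd.concat(frames).drop_duplicates(["chrom", "pos"])
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True))


def stage_profile(cfg: dict, outdir: Path) -> list[Path]:
    acfg = analysis_config(cfg)
    out = []
    summary_rows = []
    for group in cfg["groups"]:
        united = read_united(outdir / f"united_{group}.tsv",
                             acfg.min_coverage, acfg.min_per_group)
        mean = weighted_mean_methylation(united)
        m, c = united.pooled_counts()
        pct = 100.0 * m[c > 0] / c[c > 0]
        _, hist = methylation_histogram(pct)
        summary_rows.append({"group": group, "n_cpgs": len(united),
                             "weighted_mean_pct": mean, **{
                                 k: v for k, v in hist.items() if k != "n"}})
        for track_name in ("promoters", "cpg_islands"):
            track = read_bed(outdir / f"track_{track_name}.bed", track_name)
            if len(track) == 0:
                continue
            prof = feature_centered_profile(united, track, group_id=group)
            p = outdir / f"profile_{track_name}_{group}.tsv"
            profile_to_tsv(prof, p)
            out.append(p)
    p = outdir / "global_methylation.tsv"
    pd.DataFrame(summary_rows).to_csv(p, sep="\t", index=False,
                                      float_format="%.6g")
    out.append(p)
    return out


def stage_genes(cfg: dict, outdir: Path) -> list[Path]:
    from .genes import GeneModel
    tss = pd.read_csv(outdir / "tss.tsv", sep="\t")
    genes = [GeneModel(str(r.gene_id), str(r.chrom), int(r.tss_pos),
                       str(r.strand)) for r in tss.itertuples()]
    promoters = read_bed(outdir / "track_promoters.bed", "promoters")
    # re-attach gene labels (BED round trip keeps them in the name column)
    citations = pd.read_csv(outdir / "citations.tsv", sep="\t")
    out = []
    for group in _comparisons(cfg):
        dmrs = read_dmrs(outdir / f"dmr_hypo_{group}.tsv")
        top = select_top_hypomethylated(dmrs, cfg["top_n_hypo"]) if dmrs else []
        assoc = associate_regions_to_genes(top, genes)
        partition = promoter_partition(assoc, top, promoters)
        rows = [{"gene_id": g, "n_dmrs": len(ix)} for g, ix in
                sorted(assoc.items()) if ix]
        assoc_df = pd.DataFrame(rows, columns=["gene_id", "n_dmrs"])
        assoc_df["promoter_class"] = assoc_df["gene_id"].map(
            partition["labels"])
        assoc_df = assoc_df.merge(citations, on="gene_id", how="left")
        assoc_df[["oncogene_citations", "tsg_citations"]] = \
            assoc_df[["oncogene_citations", "tsg_citations"]].fillna(0).astype(int)
        roles = classify_cancer_roles(assoc_df) if len(assoc_df) else \
            assoc_df.assign(role=pd.Series(dtype=str))
        p = outdir / f"gene_assoc_{group}.tsv"
        roles.to_csv(p, sep="\t", index=False)
        out.append(p)
        pj = outdir / f"promoter_partition_{group}.json"
        with open(pj, "w") as fh:
            json.dump({k: v for k, v in partition.items() if k != "labels"},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
        out.append(pj)
    return out


def stage_synergy(cfg: dict, outdir: Path) -> list[Path]:
    if not cfg["synergy"].get("enabled", True):
        return []
    plate_path = outdir / "plate.csv"
    if not plate_path.exists():
        raise FileNotFoundError(f"missing input plate file: {plate_path}")
    table = read_plate_csv(plate_path)
    result = synergy_score(table)
    p = outdir / "synergy.json"
    write_synergy_report(result, p)
    return [p]


_STAGE_FUNCS = {
    "simulate": stage_simulate, "unite": stage_unite, "dmc": stage_dmc,
    "dmr": stage_dmr, "venn": stage_venn, "enrich": stage_enrich,
    "profile": stage_profile, "genes": stage_genes, "synergy": stage_synergy,
}


def run_stage(name: str, cfg: dict, outdir: Path) -> list[Path]:
    if name not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {name!r}")
    return _STAGE_FUNCS[name](cfg, Path(outdir))


def run_pipeline(config_path, outdir, stages: list[str] | None = None
                 ) -> RunManifest:
    """Run the configured stages in order and write a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    cfg = load_config(config_path)
    manifest = RunManifest(config=cfg)
    manifest.input_checksums[str(config_path)] = _sha256(Path(config_path))
    for stage in (stages or STAGES):
        t0 = time.perf_counter()
        logger.info("=== stage %s ===", stage)
        written = run_stage(stage, cfg, outdir)
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        manifest.outputs.extend(sorted(str(p) for p in written))
        logger.info("stage %s wrote %d files", stage, len(written))
    manifest.write(outdir / "manifest.json")
    return manifest


def _setup_logging(outdir: Path) -> None:
    root = logging.getLogger("methylsynergy")
    root.setLevel(logging.INFO)
    have = {getattr(h, "_msy_tag", None) for h in root.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h._msy_tag = "stderr"
        h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        root.addHandler(h)
    logpath = str(outdir / "run.log")
    for h in list(root.handlers):
        if getattr(h, "_msy_tag", None) == "file" and \
                getattr(h, "baseFilename", None) != logpath:
            root.removeHandler(h)
            h.close()
    if not any(getattr(h, "_msy_tag", None) == "file" for h in root.handlers):
        fh = logging.FileHandler(logpath)
        fh._msy_tag = "file"
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        root.addHandler(fh)
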