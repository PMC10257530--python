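"""Region-to-gene association and downstream gene-level summaries.

Genes receive a *basal regulatory domain* (default 5 kb upstream and 1 kb
downstream of the TSS, strand-aware) that is then extended in both
directions up to ``max_extension`` (default 1 Mb) or until it reaches the
nearest neighbouring gene's basal domain, whichever comes first — the
basal-plus-extension rule of the standard region-enrichment association
tool, at its documented defaults.  A region is associated with every gene
whose regulatory domain it overlaps by at least 1 bp (regions between two
genes may therefore map to both).

Also here: the promoter-overlap partition of associated genes, selection of
the most hypomethylated regions, and the literature-citation rule that
labels genes as oncogene and/or tumor suppressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmr import DMRTile
from .methylation_io import FeatureTrack

ONCOGENE = "Oncogene"
TSG = "Tumor Suppressor Gene"
DUAL = "Oncogene/Tumor Suppressor Gene"
NEITHER = "Neither"


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss_pos: int              # 0-based
    strand: str
    body: tuple[int, int] | None = None   # half-open gene body, optional

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        if self.body is not None:
            s, e = self.body
            if not (s <= self.tss_pos < e):
                raise ValueError(f"TSS of {self.gene_id} outside gene body")


@dataclass(frozen=True)
class CancerRoleRecord:
    gene_id: str
    oncogene_citations: int
    tsg_citations: int


def regulatory_domains(genes: list[GeneModel], basal_up: int = 5000,
                       basal_down: int = 1000,
                       max_extension: int = 1_000_000) -> pd.DataFrame:
    """Basal-plus-extension regulatory domain per gene (half-open, 0-based).

    Extension on each side stops at the nearest other gene's basal domain
    (never shrinking the gene's own basal domain) or at ``max_extension``
    from the basal edge.
    """
    rows = []
    for g in genes:
        if g.strand == "+":
            bs, be = g.tss_pos - basal_up, g.tss_pos + basal_down
        else:
            bs, be = g.tss_pos - basal_down, g.tss_pos + basal_up
        rows.append((g.gene_id, g.chrom, max(0, bs), be))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "basal_start", "basal_end"])
    df = df.sort_values(["chrom", "basal_start", "basal_end"], kind="mergesort")
    starts = np.full(len(df), 0, dtype=np.int64)
    ends = np.full(len(df), np.iinfo(np.int64).max, dtype=np.int64)
    df = df.reset_index(drop=True)
    for chrom, grp in df.groupby("chrom"):
        bs = grp["basal_start"].to_numpy()
        be = grp["basal_end"].to_numpy()
        idx = grp.index.to_numpy()
        # nearest basal end of any *other* gene at or left of this basal start
        prev_end = np.maximum.accumulate(np.concatenate([[0], be[:-1]]))
        nxt = np.concatenate([bs[1:], [np.iinfo(np.int64).max]])
        next_start = np.minimum.accumulate(nxt[::-1])[::-1]
        ext_start = np.maximum(bs - max_extension, np.minimum(prev_end, bs))
        ext_end = np.minimum(be + max_extension, np.maximum(next_start, be))
        starts[idx] = np.maximum(ext_start, 0)
        ends[idx] = ext_end
    out = df[["gene_id", "chrom", "basal_start", "basal_end"]].copy()
    out["start"] = starts
    out["end"] = ends
    return out


def associate_regions_to_genes(dmrs: list[DMRTile], genes: list[GeneModel],
                               basal_up: int = 5000, basal_down: int = 1000,
                               max_extension: int = 1_000_000) -> dict[str, list[int]]:
    """Map gene_id -> indices of DMRs overlapping its regulatory domain."""
    domains = regulatory_domains(genes, basal_up, basal_down, max_extension)
    assoc: dict[str, list[int]] = {g.gene_id: [] for g in genes}
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, t in enumerate(dmrs):
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end, i))
    for dom in domains.itertuples():
        for start, end, i in by_chrom.get(dom.chrom, ()):
            if start < dom.end and dom.start < end:
                assoc[dom.gene_id].append(i)
    return {g: sorted(ix) for g, ix in assoc.items()}


def promoter_partition(associations: dict[str, list[int]],
                       dmrs: list[DMRTile],
                       promoters: FeatureTrack) -> dict:
    """Partition associated genes by promoter overlap of their DMRs.

    A gene counts as "within" when at least one of its associated DMRs
    overlaps that gene's own promoter interval (matched by the promoter
    track's label) by >= 1 bp.  Genes with no associated DMR are ignored.
    """
    promo = {}
    for p in promoters.intervals.itertuples():
        promo.setdefault(p.label, []).append((p.chrom, p.start, p.end))
    within = outside = 0
    labels = {}
    for gene_id, idxs in associations.items():
        if not idxs:
            continue
        hit = False
        for chrom, ps, pe in promo.get(gene_id, ()):
            for i in idxs:
                t = dmrs[i]
                if t.chrom == chrom and t.start < pe and ps < t.end:
                    hit = True
                    break
            if hit:
                break
        labels[gene_id] = "within" if hit else "outside"
        within += hit
        outside += not hit
    total = within + outside
    return {"within": within, "outside": outside,
            "prop_within": within / total if total else np.nan,
            "prop_outside": outside / total if total else np.nan,
            "labels": labels}


def select_top_hypomethylated(dmrs: list[DMRTile], n: int = 8000) -> list[DMRTile]:
    """The ``n`` most hypomethylated DMRs (most negative mean difference).

    Ties on the mean difference break by (chrom, start).  All inputs must be
    hypo-direction with a summarised mean difference.
    """
    for t in dmrs:
        if t.direction != "hypo":
            raise ValueError("select_top_hypomethylated expects hypo DMRs only")
        if t.mean_diff is None:
            raise ValueError("DMRs must be summarised (mean_diff set)")
    ordered = sorted(dmrs, key=lambda t: (t.mean_diff, t.chrom, t.start))
    return ordered[: min(n, len(ordered))]


def classify_cancer_role(record: CancerRoleRecord) -> str:
    """Citation-majority cancer-role label for a gene.

    More oncogene than tumor-suppressor citations -> Oncogene; the converse
    -> Tumor Suppressor Gene; equal and nonzero -> the dual label; no
    citations at all -> Neither.
    """
    onc, tsg = record.oncogene_citations, record.tsg_citations
    if onc < 0 or tsg < 0:
        raise ValueError("citation counts must be >= 0")
    if onc > tsg:
        return ONCOGENE
    if tsg > onc:
        return TSG
    if onc == tsg > 0:
        return DUAL
    return NEITHER


def classify_cancer_roles(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorised role labels for a gene/citation-count table."""
    out = table.copy()
    out["role"] = [
        classify_cancer_role(CancerRoleRecord(str(r.gene_id),
                                              int(r.oncogene_citations),
                                              int(r.tsg_citations)))
        for r in table.itertuples()]
    return out
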