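"""DMC-to-DMR tiling, ambiguity filtering and cross-comparison intersection.

DMRs are built by single-linkage chaining: consecutive DMCs on the same
chromosome whose positions lie within ``merge_gap`` bp (inclusive) of one
another join a tile.  A raw tile spans its member cytosines inclusively
(width = max - min + 1 bp); tiles narrower than ``min_tile_width`` are padded
symmetrically to that width, with an odd remainder going to the right and the
left edge clipped at the start of the chromosome.  Tiles whose members mix
hyper- and hypomethylation are ambiguous and removed before downstream use;
the per-tile effect is the unweighted mean of member differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .differential import DMC, HYPER, HYPO

AMBIGUOUS = "ambiguous"


@dataclass
class DMRTile:
    """A differentially methylated region (half-open, 0-based)."""

    chrom: str
    start: int
    end: int
    member_dmcs: list[DMC] = field(default_factory=list)
    mean_diff: float | None = None
    direction: str = AMBIGUOUS

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def n_dmcs(self) -> int:
        return len(self.member_dmcs)


@dataclass
class VennPartition:
    """Counts of overlap-connected DMR components by set-membership pattern."""

    counts: dict[tuple[str, ...], int]
    regions: dict[tuple[str, ...], list[tuple[str, int, int]]]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_json_dict(self) -> dict:
        return {"&".join(k): {"count": v,
                              "regions": [list(r) for r in self.regions[k]]}
                for k, v in sorted(self.counts.items())}


def tile_dmcs(dmcs: list[DMC], merge_gap: int = 500,
              min_tile_width: int = 100) -> list[DMRTile]:
    """Chain DMCs into tiles and pad short tiles to ``min_tile_width``."""
    if not dmcs:
        return []
    ordered = sorted(dmcs, key=lambda d: (d.chrom, d.pos))
    tiles: list[DMRTile] = []
    members: list[DMC] = [ordered[0]]
    for d in ordered[1:]:
        prev = members[-1]
        if d.chrom == prev.chrom and d.pos - prev.pos <= merge_gap:
            members.append(d)
        else:
            tiles.append(_make_tile(members, min_tile_width))
            members = [d]
    tiles.append(_make_tile(members, min_tile_width))
    return tiles


def _make_tile(members: list[DMC], min_tile_width: int) -> DMRTile:
    pmin, pmax = members[0].pos, members[-1].pos
    start, end = pmin - 1, pmax        # 1-based inclusive span -> 0-based half-open
    width = end - start
    if width < min_tile_width:
        pad = min_tile_width - width
        left, right = pad // 2, pad - pad // 2   # odd remainder extends right
        start = max(0, start - left)
        end = end + right
    dirs = {m.direction for m in members}
    direction = dirs.pop() if len(dirs) == 1 else AMBIGUOUS
    return DMRTile(members[0].chrom, start, end, list(members), None, direction)


def filter_ambiguous(tiles: list[DMRTile]) -> tuple[list[DMRTile], float]:
    """Drop tiles mixing hyper- and hypomethylated members.

    Returns the clean tiles and the removed fraction over all input tiles
    (0.0 for empty input).
    """
    clean = [t for t in tiles if t.direction != AMBIGUOUS]
    frac = (len(tiles) - len(clean)) / len(tiles) if tiles else 0.0
    return clean, frac


def summarize_dmrs(tiles: list[DMRTile]) -> list[DMRTile]:
    """Attach the unweighted mean member difference to each (unambiguous) tile."""
    out = []
    for t in tiles:
        if t.direction == AMBIGUOUS:
            raise ValueError("summarize_dmrs expects unambiguous tiles")
        mean = float(np.mean([m.meth_diff for m in t.member_dmcs]))
        out.append(replace(t, mean_diff=mean))
    return out


def intersect_dmr_sets(sets: dict[str, list[DMRTile]]) -> VennPartition:
    """Partition the union of 2-3 same-direction DMR sets by shared overlap.

    Tiles from all sets are pooled; components are formed under >=1 bp
    overlap (single linkage); each component is counted once under the
    pattern of set names contributing at least one tile to it.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("intersect_dmr_sets takes 2-3 named sets")
    dirs = {t.direction for tiles in sets.values() for t in tiles}
    if len(dirs) > 1:
        raise ValueError(f"mixed DMR directions across sets: {dirs}")
    rows = [(t.chrom, t.start, t.end, name)
            for name, tiles in sets.items() for t in tiles]
    counts: dict[tuple[str, ...], int] = {}
    regions: dict[tuple[str, ...], list[tuple[str, int, int]]] = {}
    if rows:
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "set"])
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        cur = None  # (chrom, start, end, members)
        components = []
        for r in df.itertuples():
            if cur is not None and r.chrom == cur[0] and r.start < cur[2]:
                cur = (cur[0], cur[1], max(cur[2], r.end), cur[3] | {r.set})
            else:
                if cur is not None:
                    components.append(cur)
                cur = (r.chrom, r.start, r.end, {r.set})
        components.append(cur)
        for chrom, start, end, members in components:
            key = tuple(sorted(members))
            counts[key] = counts.get(key, 0) + 1
            regions.setdefault(key, []).append((chrom, int(start), int(end)))
    return VennPartition(counts, regions)


def dmrs_to_frame(tiles: list[DMRTile]) -> pd.DataFrame:
    df = pd.DataFrame([{"chrom": t.chrom, "start": t.start, "end": t.end,
                        "mean_diff": t.mean_diff, "direction": t.direction,
                        "n_dmcs": t.n_dmcs} for t in tiles],
                      columns=["chrom", "start", "end", "mean_diff",
                               "direction", "n_dmcs"])
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_dmrs(tiles: list[DMRTile], path) -> None:
    dmrs_to_frame(tiles).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dmrs(path) -> list[DMRTile]:
    df = pd.read_csv(path, sep="\t")
    return [DMRTile(str(r.chrom), int(r.start), int(r.end), [],
                    None if pd.isna(r.mean_diff) else float(r.mean_diff),
                    str(r.direction))
            for r in df.itertuples()]
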