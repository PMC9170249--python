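"""Genomic interval algebra and plain-text genomics I/O.

Every coordinate inside the package is 0-based, half-open (the BED
convention): an interval ``[start, end)`` covers ``end - start`` bases.
Inputs in 1-based conventions are converted at the boundary and never
propagate inward.

Interval *sets* are plain :class:`pandas.DataFrame` objects with at least
``chrom``, ``start`` and ``end`` columns (optionally ``name``, ``score``,
``strand`` and arbitrary extra columns).  Single intervals are the
lightweight :class:`GenomicInterval`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BED_CORE = ["chrom", "start", "end"]
BED6 = BED_CORE + ["name", "score", "strand"]
BED12 = BED6 + [
    "thick_start",
    "thick_end",
    "item_rgb",
    "block_count",
    "block_sizes",
    "block_starts",
]


class BedFormatError(ValueError):
    """Raised for malformed BED / site-table lines; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval.

    ``strand`` is one of ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """Ordered chromosome sizes plus optional cytosine-site registries.

    ``cg_sites`` maps chromosome name to a sorted array of CG-dinucleotide
    positions.  CG sites are registered once per dinucleotide (the two
    symmetric strands collapsed onto the forward-strand C position), while
    CH sites are registered per strand because CH methylation is
    asymmetric; ``ch_strands`` holds the matching strand array.
    """

    chrom_sizes: dict[str, int]
    cg_sites: dict[str, np.ndarray] = field(default_factory=dict)
    ch_sites: dict[str, np.ndarray] = field(default_factory=dict)
    ch_strands: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        for registry in (self.cg_sites, self.ch_sites):
            for chrom, pos in registry.items():
                if chrom not in self.chrom_sizes:
                    raise ValueError(f"registry chromosome {chrom} not in genome")
                if len(pos) and pos.max() >= self.chrom_sizes[chrom]:
                    raise ValueError(f"site beyond end of {chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def n_cg(self) -> int:
        return int(sum(len(v) for v in self.cg_sites.values()))

    def n_ch(self) -> int:
        return int(sum(len(v) for v in self.ch_sites.values()))


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the intersection of two intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def sort_intervals(frame: pd.DataFrame) -> pd.DataFrame:
    """Sort an interval set by (chrom, start, end), resetting the index."""
    return frame.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def _validate_intervals(frame: pd.DataFrame) -> None:
    if len(frame) == 0:
        return
    bad = frame["start"] >= frame["end"]
    if bad.any():
        row = frame[bad].iloc[0]
        raise ValueError(
            f"invalid interval {row['chrom']}:{row['start']}-{row['end']}"
        )
    if (frame["start"] < 0).any():
        raise ValueError("negative interval start")


def merge_intervals(frame: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Merge intervals whose gap is at most ``max_gap`` bp.

    Adjacent-but-not-overlapping intervals ([0,5) and [5,9)) have gap 0 and
    merge at ``max_gap=0``.  Output is sorted and non-overlapping; the union
    of covered bases is preserved (and extended across merged gaps).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    _validate_intervals(frame)
    if len(frame) == 0:
        return pd.DataFrame(columns=BED_CORE)
    frame = sort_intervals(frame[BED_CORE])
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, sub in frame.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= max_gap:
                cur_e = max(cur_e, int(e))
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return sort_intervals(
        pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})
    )


def _merged_lookup(reference: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chrom (starts, ends) arrays of the merged reference set."""
    merged = merge_intervals(reference, max_gap=0) if len(reference) else reference
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in merged.groupby("chrom", sort=False):
        out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    return out


def covered_bp_single(
    chrom: str, start: int, end: int, lookup: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> int:
    """bp of [start,end) covered by a merged per-chrom lookup."""
    if chrom not in lookup:
        return 0
    starts, ends = lookup[chrom]
    i = int(np.searchsorted(ends, start, side="right"))
    j = int(np.searchsorted(starts, end, side="left"))
    if i >= j:
        return 0
    ov = np.minimum(ends[i:j], end) - np.maximum(starts[i:j], start)
    return int(ov[ov > 0].sum())


def fraction_overlap(
    query: pd.DataFrame, reference: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Per-query overlap with a reference set.

    Returns a copy of ``query`` with three added columns — ``any_overlap``
    (>= 1 bp intersection), ``covered_bp`` and ``fraction`` (covered bp over
    query length) — plus the aggregate count of queries with any overlap.
    """
    _validate_intervals(query)
    _validate_intervals(reference)
    lookup = _merged_lookup(reference)
    covered = np.array(
        [
            covered_bp_single(c, int(s), int(e), lookup)
            for c, s, e in zip(query["chrom"], query["start"], query["end"])
        ],
        dtype=np.int64,
    ) if len(query) else np.array([], dtype=np.int64)
    out = query.copy()
    out["covered_bp"] = covered
    lengths = (out["end"] - out["start"]).to_numpy() if len(out) else np.array([])
    out["fraction"] = covered / lengths if len(out) else covered.astype(float)
    out["any_overlap"] = covered > 0
    return out, int((covered > 0).sum())


def points_in_intervals(
    chrom: str, positions: np.ndarray, lookup: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Boolean membership of point positions in a merged interval lookup."""
    if chrom not in lookup or len(positions) == 0:
        return np.zeros(len(positions), dtype=bool)
    starts, ends = lookup[chrom]
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(positions), dtype=bool)
    inside[ok] = positions[ok] < ends[idx[ok]]
    return inside


def intervals_overlapping_point_counts(
    query: pd.DataFrame, positions_by_chrom: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Number of registry points falling in each query interval."""
    counts = np.zeros(len(query), dtype=np.int64)
    for i, (c, s, e) in enumerate(zip(query["chrom"], query["start"], query["end"])):
        pos = positions_by_chrom.get(c)
        if pos is None:
            continue
        counts[i] = int(
            np.searchsorted(pos, e, side="left") - np.searchsorted(pos, s, side="left")
        )
    return counts


def reciprocal_overlap_match(
    predicted: pd.DataFrame, truth: pd.DataFrame, min_frac: float = 0.5
) -> pd.DataFrame:
    """Greedy 1:1 matching of predicted to truth intervals.

    A pair matches when the intersection covers at least ``min_frac`` of
    *both* intervals (reciprocal overlap).  Returns a table with one row per
    matched pair: indices into both frames and the Jaccard index.
    """
    pairs = []
    for ti, trow in truth.iterrows():
        for pi, prow in predicted.iterrows():
            if prow["chrom"] != trow["chrom"]:
                continue
            inter = min(prow["end"], trow["end"]) - max(prow["start"], trow["start"])
            if inter <= 0:
                continue
            lp = prow["end"] - prow["start"]
            lt = trow["end"] - trow["start"]
            if inter >= min_frac * lp and inter >= min_frac * lt:
                union = lp + lt - inter
                pairs.append((pi, ti, inter / union))
    pairs.sort(key=lambda t: -t[2])
    used_p: set[int] = set()
    used_t: set[int] = set()
    rows = []
    for pi, ti, jac in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        rows.append({"pred_index": pi, "truth_index": ti, "jaccard": jac})
    return pd.DataFrame(rows, columns=["pred_index", "truth_index", "jaccard"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> Genome:
    """Read a two-column chrom.sizes TSV into a :class:`Genome`."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedFormatError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return Genome(chrom_sizes=sizes)


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(
    path: str | Path, one_based: bool = False, genome: Genome | None = None
) -> pd.DataFrame:
    """Read BED3/BED6/BED12 into an interval DataFrame.

    ``one_based=True`` declares the input start coordinates 1-based
    inclusive; they are shifted to the internal 0-based half-open
    convention on the way in.
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 columns")
            if ncols is None:
                ncols = len(parts)
            try:
                start = int(parts[1])
                end = int(parts[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if one_based:
                start -= 1
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}:{lineno}: invalid interval start={start} end={end}"
                )
            if genome is not None:
                if parts[0] not in genome.chrom_sizes:
                    raise BedFormatError(f"{path}:{lineno}: unknown chrom {parts[0]}")
                if end > genome.chrom_sizes[parts[0]]:
                    raise BedFormatError(f"{path}:{lineno}: interval beyond chrom end")
            rows.append([parts[0], start, end] + parts[3:])
    n = ncols or 3
    if n <= 6:
        columns = BED_CORE + BED6[3:n]
    else:
        columns = BED12[:n]
    frame = pd.DataFrame(rows, columns=columns)
    if len(frame):
        frame["start"] = frame["start"].astype(np.int64)
        frame["end"] = frame["end"].astype(np.int64)
        if "score" in frame.columns:
            frame["score"] = pd.to_numeric(frame["score"], errors="coerce")
    return frame


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an interval DataFrame as BED (columns beyond chrom/start/end kept)."""
    cols = [c for c in BED12 if c in frame.columns]
    extra = [c for c in frame.columns if c not in cols]
    frame[cols + extra].to_csv(path, sep="\t", header=False, index=False)


SITE_COLUMNS = ["chrom", "pos", "strand", "context", "m", "h"]


def read_site_table(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read an allc-style per-cytosine TSV.

    Columns: chrom, position, strand, context (CG/CH), methylated basecalls
    ``m``, total basecalls ``h``.  ``one_based`` converts positions to the
    internal 0-based convention.
    """
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=SITE_COLUMNS,
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "context": str,
                "m": np.int64,
                "h": np.int64,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise BedFormatError(f"{path}: malformed site table: {exc}") from exc
    if one_based:
        frame["pos"] -= 1
    if len(frame):
        if (frame["pos"] < 0).any():
            raise BedFormatError(f"{path}: negative position after conversion")
        if ((frame["m"] < 0) | (frame["m"] > frame["h"])).any():
            bad = frame[(frame["m"] < 0) | (frame["m"] > frame["h"])].index[0]
            raise BedFormatError(f"{path}: line {bad + 1}: require 0 <= m <= h")
    return frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_site_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame[SITE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a table with header, tab-separated."""
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return frame


def write_bedgraph(frame: pd.DataFrame, path: str | Path) -> None:
    frame[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )
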