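"""Windowed MeDIP-seq comparison: binning, RPKM, input subtraction,
multi-scale channel correlation, CpG-island enrichment and Hilbert-curve
rendering.

The comparison asks whether two immunoprecipitation channels (an anti-5mC
pulldown and an anti-RFP pulldown of a methyl-CpG-binding probe) read out
the same underlying methylation landscape.  The machinery is generic: any
two genomic read sets over a shared chromosome partition can be compared.

Conventions: 0-based half-open coordinates (BED); windows ``[i*w, (i+1)*w)``
tiling each chromosome left to right, last window truncated at the
chromosome end; reads assigned to windows by their midpoint (keeps the
count-conservation identity exact), coverage (bedGraph) apportioned by
overlap length; strand ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ranktests

__all__ = [
    "GenomicTrack",
    "HilbertImage",
    "IslandEnrichment",
    "read_chrom_sizes",
    "read_bed",
    "read_bedgraph",
    "write_bedgraph",
    "bin_counts",
    "rpkm",
    "subtract_input",
    "window_correlation",
    "island_enrichment",
    "hilbert_d2xy",
    "hilbert_xy2d",
    "hilbert_render",
]


# ---------------------------------------------------------------------------
# containers and plain-text I/O

@dataclass
class GenomicTrack:
    """Per-window counts (and optionally RPKM) over tiled chromosomes.

    ``windows`` holds columns ``chrom, start, end, count`` and, after
    :func:`rpkm`, a ``rpkm`` column.  ``total_mapped`` is the library size
    used for depth normalization.
    """

    windows: pd.DataFrame
    window_size: int
    total_mapped: int

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "count"}
        if not required.issubset(self.windows.columns):
            raise ValueError(f"track windows need columns {sorted(required)}")
        if (self.windows["count"] < 0).any():
            raise ValueError("window counts must be non-negative")

    def same_grid(self, other: "GenomicTrack") -> bool:
        a, b = self.windows, other.windows
        return (
            self.window_size == other.window_size
            and len(a) == len(b)
            and (a["chrom"].values == b["chrom"].values).all()
            and (a["start"].values == b["start"].values).all()
            and (a["end"].values == b["end"].values).all()
        )

    def chrom_values(self, chrom: str, column: str = "count") -> np.ndarray:
        sel = self.windows[self.windows["chrom"] == chrom]
        if sel.empty:
            raise ValueError(f"no windows for chromosome {chrom!r}")
        return sel.sort_values("start")[column].to_numpy()


@dataclass
class HilbertImage:
    """A 1D window track folded onto a 2D grid along a Hilbert curve.

    ``matrix`` is ``2**order x 2**order``; cells beyond the track length
    are NaN and flagged False in ``assigned`` (distinct from a zero
    signal).
    """

    order: int
    matrix: np.ndarray
    chrom: str
    assigned: np.ndarray


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file; extra columns beyond chrom/start/end are kept.

    A 7th column, when present, is interpreted as a methylation level
    (BED6+1 islands dialect).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand", "level"]
    df.columns = names[: df.shape[1]]
    return df


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path, value_col: str = "value") -> None:
    out = df[["chrom", "start", "end", value_col]]
    out.to_csv(path, sep="\t", header=False, index=False)


def _check_bounds(df: pd.DataFrame, chrom_sizes: Mapping[str, int]) -> None:
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            raise ValueError(f"chromosome {chrom!r} absent from chrom sizes")
        bad = sub[(sub["start"] < 0) | (sub["end"] > chrom_sizes[chrom])]
        if not bad.empty:
            rec = bad.iloc[0]
            raise ValueError(
                f"interval beyond chromosome bounds: {rec['chrom']}:"
                f"{rec['start']}-{rec['end']} (size {chrom_sizes[chrom]})"
            )


def _window_grid(chrom_sizes: Mapping[str, int], window: int) -> pd.DataFrame:
    rows = []
    for chrom, size in chrom_sizes.items():
        n = -(-size // window)  # ceil
        starts = np.arange(n, dtype=np.int64) * window
        ends = np.minimum(starts + window, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# binning and normalization

def bin_counts(
    intervals: pd.DataFrame | str | Path,
    chrom_sizes: Mapping[str, int] | str | Path,
    window: int,
) -> GenomicTrack:
    """Bin reads or coverage into fixed-size windows.

    Three-column input (BED intervals, e.g. aligned fragments) is counted
    by the midpoint rule: each record adds 1 to the window containing its
    midpoint, so window counts sum exactly to the record count.
    Four-column input (bedGraph coverage) is apportioned to windows in
    proportion to overlap length.
    """
    if window < 1:
        raise ValueError("window must be >= 1 bp")
    if not isinstance(chrom_sizes, Mapping):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    if not isinstance(intervals, pd.DataFrame):
        path = Path(intervals)
        probe = pd.read_csv(path, sep="\t", header=None, comment="#", nrows=1)
        intervals = read_bedgraph(path) if probe.shape[1] >= 4 else read_bed(path)
    if window > max(chrom_sizes.values()):
        raise ValueError("window larger than every chromosome")

    grid = _window_grid(chrom_sizes, window)
    counts = np.zeros(len(grid), dtype=float)
    offsets = {}
    pos = 0
    for chrom, size in chrom_sizes.items():
        offsets[chrom] = pos
        pos += -(-size // window)

    has_value = "value" in intervals.columns
    if not intervals.empty:
        _check_bounds(intervals, chrom_sizes)
        for chrom, sub in intervals.groupby("chrom", sort=False):
            off = offsets[chrom]
            n_win = -(-chrom_sizes[chrom] // window)
            start = sub["start"].to_numpy(np.int64)
            end = sub["end"].to_numpy(np.int64)
            if not has_value:
                mid = (start + end) // 2
                idx = np.clip(mid // window, 0, n_win - 1)
                counts[off:off + n_win] += np.bincount(idx, minlength=n_win)
            else:
                val = sub["value"].to_numpy(float)
                for s, e, v in zip(start, end, val):
                    w0, w1 = s // window, (e - 1) // window
                    for w in range(w0, w1 + 1):
                        lo = max(s, w * window)
                        hi = min(e, (w + 1) * window)
                        counts[off + w] += v * (hi - lo)

    grid = grid.copy()
    grid["count"] = counts
    if has_value:
        total = int(round(counts.sum()))
    else:
        total = int(len(intervals))
    return GenomicTrack(grid, window, max(total, 0))


def rpkm(track: GenomicTrack) -> GenomicTrack:
    """Depth- and length-normalize counts to reads/kb/million mapped.

    RPKM = count / (window length in kb x total mapped reads in millions);
    truncated terminal windows use their true length.
    """
    if track.total_mapped <= 0:
        raise ValueError("total_mapped must be positive for RPKM")
    df = track.windows.copy()
    len_kb = (df["end"] - df["start"]) / 1000.0
    df["rpkm"] = df["count"] / (len_kb * (track.total_mapped / 1e6))
    return GenomicTrack(df, track.window_size, track.total_mapped)


def subtract_input(signal: GenomicTrack, input_track: GenomicTrack) -> pd.DataFrame:
    """Per-window RPKM(signal) - RPKM(input); values may be negative.

    Returns a bedGraph-style frame (chrom, start, end, value) suitable for
    :func:`write_bedgraph` and :func:`hilbert_render`.
    """
    if not signal.same_grid(input_track):
        raise ValueError("signal and input tracks are on different window grids")
    sig = signal if "rpkm" in signal.windows.columns else rpkm(signal)
    inp = input_track if "rpkm" in input_track.windows.columns else rpkm(input_track)
    out = sig.windows[["chrom", "start", "end"]].copy()
    out["value"] = sig.windows["rpkm"].values - inp.windows["rpkm"].values
    return out


# ---------------------------------------------------------------------------
# channel comparison

def window_correlation(
    reads_a: pd.DataFrame,
    reads_b: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    windows: Sequence[int] = (2000, 5000, 10000),
    include_zero: bool = True,
) -> pd.DataFrame:
    """Genome-wide Pearson correlation of per-window RPKMs per window size.

    Re-bins both read sets at every requested size.  ``include_zero=False``
    drops windows with zero counts in both channels before correlating
    (exposed because published pipelines differ; default keeps all
    windows).
    """
    rows = []
    for w in windows:
        ta = rpkm(bin_counts(reads_a, chrom_sizes, w))
        tb = rpkm(bin_counts(reads_b, chrom_sizes, w))
        x = ta.windows["rpkm"].to_numpy()
        y = tb.windows["rpkm"].to_numpy()
        if not include_zero:
            keep = (ta.windows["count"].to_numpy() > 0) | (
                tb.windows["count"].to_numpy() > 0
            )
            x, y = x[keep], y[keep]
        if x.size < 2:
            raise ValueError(f"fewer than 2 windows at size {w}")
        rows.append({"window_bp": w, "n_windows": x.size,
                     "pearson_r": ranktests.pearson(x, y)})
    return pd.DataFrame(rows)


@dataclass
class IslandEnrichment:
    """Per-island RPKMs with heavy/light classification and t-tests.

    ``tests`` maps channel name to a :class:`~chromodyn.ranktests.TestResult`
    comparing heavy vs light islands, or None (with ``note`` set) when only
    one group is present.
    """

    records: pd.DataFrame
    tests: dict[str, "ranktests.TestResult | None"]
    note: str = ""


HEAVY_METHYLATION_THRESHOLD = 0.8  # heavy iff level >= 80%


def _count_overlapping(reads: pd.DataFrame, islands: pd.DataFrame) -> np.ndarray:
    """Reads overlapping each island by any amount (full-overlap counting)."""
    counts = np.zeros(len(islands), dtype=np.int64)
    for chrom, sub in reads.groupby("chrom", sort=False):
        starts = np.sort(sub["start"].to_numpy(np.int64))
        ends = np.sort(sub["end"].to_numpy(np.int64))
        mask = islands["chrom"] == chrom
        if not mask.any():
            continue
        isl = islands[mask]
        # overlap iff read.start < island.end and read.end > island.start
        n_start_before_end = np.searchsorted(starts, isl["end"].to_numpy(), "left")
        n_end_before_start = np.searchsorted(ends, isl["start"].to_numpy(), "right")
        counts[np.flatnonzero(mask.to_numpy())] = n_start_before_end - n_end_before_start
    return counts


def island_enrichment(
    reads_by_channel: Mapping[str, pd.DataFrame],
    islands: pd.DataFrame,
    total_mapped: Mapping[str, int] | None = None,
    level_col: str = "level",
) -> IslandEnrichment:
    """Quantify channel enrichment over CpG islands and test heavy vs light.

    Islands with methylation level >= 0.8 are classified heavy, below 0.8
    light.  Per island and channel, RPKM is computed from reads overlapping
    the island (any overlap) and the island length.  A two-sample Student's
    t test compares heavy vs light RPKMs per channel; with a single group
    present the test is refused and flagged in ``note``.
    """
    if islands.empty:
        raise ValueError("empty island set")
    if level_col not in islands.columns:
        raise ValueError(f"islands need a {level_col!r} column")
    rec = islands[["chrom", "start", "end"]].copy()
    rec["level"] = islands[level_col].astype(float).values
    rec["group"] = np.where(
        rec["level"] >= HEAVY_METHYLATION_THRESHOLD, "heavy", "light"
    )
    len_kb = (rec["end"] - rec["start"]) / 1000.0
    for channel, reads in reads_by_channel.items():
        total = (
            total_mapped[channel]
            if total_mapped is not None
            else len(reads)
        )
        if total <= 0:
            raise ValueError(f"channel {channel!r} has no mapped reads")
        counts = _count_overlapping(reads, rec)
        rec[f"rpkm_{channel}"] = counts / (len_kb * (total / 1e6))

    tests: dict[str, ranktests.TestResult | None] = {}
    note = ""
    heavy = rec["group"] == "heavy"
    if heavy.all() or (~heavy).all():
        note = "single methylation group: heavy/light t-test refused"
        tests = {channel: None for channel in reads_by_channel}
    elif heavy.sum() < 2 or (~heavy).sum() < 2:
        note = "fewer than 2 islands in a group: heavy/light t-test refused"
        tests = {channel: None for channel in reads_by_channel}
    else:
        for channel in reads_by_channel:
            col = rec[f"rpkm_{channel}"]
            t, p = ranktests.student_t(col[heavy], col[~heavy])
            tests[channel] = ranktests.TestResult(("heavy", "light"), t, p)
    return IslandEnrichment(rec, tests, note)


# ---------------------------------------------------------------------------
# Hilbert-curve rendering

def hilbert_d2xy(order: int, d: int) -> tuple[int, int]:
    """Position of step ``d`` along the order-``order`` Hilbert curve."""
    n = 1 << order
    x = y = 0
    t = d
    s = 1
    while s < n:
        rx = 1 & (t // 2)
        ry = 1 & (t ^ rx)
        if ry == 0:
            if rx == 1:
                x, y = s - 1 - x, s - 1 - y
            x, y = y, x
        x += s * rx
        y += s * ry
        t //= 4
        s *= 2
    return x, y


def hilbert_xy2d(order: int, x: int, y: int) -> int:
    """Inverse of :func:`hilbert_d2xy`."""
    d = 0
    s = (1 << order) // 2
    while s > 0:
        rx = 1 if (x & s) > 0 else 0
        ry = 1 if (y & s) > 0 else 0
        d += s * s * ((3 * rx) ^ ry)
        if ry == 0:
            if rx == 1:
                x, y = s - 1 - x, s - 1 - y
            x, y = y, x
        s //= 2
    return d


def hilbert_render(
    track: GenomicTrack | pd.DataFrame,
    chrom: str | None = None,
    value_col: str | None = None,
) -> HilbertImage:
    """Fold one chromosome's window values onto a 2D Hilbert-curve grid.

    The curve order is the smallest ``k`` with ``4**k >=`` the number of
    windows; window ``i`` lands on the ``i``-th cell of the curve (standard
    d2xy orientation).  Unassigned trailing cells are NaN and masked.
    Locality preservation makes large-scale enrichment patterns visually
    comparable between channels.
    """
    if isinstance(track, GenomicTrack):
        df = track.windows
        value_col = value_col or ("rpkm" if "rpkm" in df.columns else "count")
    else:
        df = track
        value_col = value_col or "value"
    if chrom is None:
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("track spans multiple chromosomes; pass chrom=")
        chrom = chroms[0]
    sel = df[df["chrom"] == chrom].sort_values("start")
    values = sel[value_col].to_numpy(float)
    n = values.size
    if n == 0:
        raise ValueError(f"empty track for chromosome {chrom!r}")
    order = max(1, math.ceil(math.log(n, 4)))
    side = 1 << order
    matrix = np.full((side, side), np.nan)
    assigned = np.zeros((side, side), dtype=bool)
    for i in range(n):
        x, y = hilbert_d2xy(order, i)
        matrix[y, x] = values[i]
        assigned[y, x] = True
    return HilbertImage(order, matrix, chrom, assigned)
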