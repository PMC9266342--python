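"""Depth-of-coverage copy-number analysis.

The chain is: per-base depth from alignments -> within-sample normalization
by the geometric mean of positive per-base depths -> mean depth in
non-overlapping windows (default 1 kb), log2-transformed -> circular binary
segmentation (CBS) with permutation-calibrated split acceptance -> segments
above a log2 threshold called duplicated.

The CBS here is a from-scratch implementation of the circular-split
permutation-test family: for each current arc the pair of breakpoints
maximizing a scaled mean-difference statistic is found, and the split is
accepted when its permutation p-value (1 + b) / (nperm + 1) falls at or
below alpha.  The statistic |mean_in - mean_out| / sqrt(1/k + 1/(n-k)) is
the two-sample t numerator with pooled scale held fixed, which leaves the
permutation ranking unchanged while keeping every permutation O(n^2) in
vectorized form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import GenomeSequence, Region
from .seqio_align import AlignmentRecord


class DepthTrack:
    """Per-base depth per chromosome (raw counts or normalized reals)."""

    def __init__(self, depths: Dict[str, np.ndarray]):
        self.depths = depths

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.depths[chrom]

    def chroms(self) -> List[str]:
        return list(self.depths)

    def chrom_means(self) -> Dict[str, float]:
        return {c: float(d.mean()) for c, d in self.depths.items()}


@dataclass
class Window:
    region: Region
    mean_depth: float
    log2: Optional[float]  # None marks a zero-mean window, excluded from CBS


class WindowTrack:
    def __init__(self, window_size: int, windows: Dict[str, List[Window]]):
        self.window_size = window_size
        self.windows = windows

    def values(self, chrom: str) -> np.ndarray:
        """log2 values with NaN at zero-mean windows."""
        return np.array(
            [w.log2 if w.log2 is not None else np.nan for w in self.windows[chrom]]
        )


@dataclass
class Segment:
    chrom: str
    start_window: int  # inclusive window index
    end_window: int  # exclusive window index
    mean: float
    call: str = "neutral"  # duplicated | deleted | neutral


def per_base_depth(
    records: Sequence[AlignmentRecord],
    genome: GenomeSequence,
    min_mapq: int = 0,
) -> DepthTrack:
    """Count, for every reference base, the records whose aligned span covers
    it.  Unmapped and sub-min_mapq records are ignored; soft-clipped bases do
    not count."""
    diffs = {c: np.zeros(genome.length(c) + 1, dtype=np.int64) for c in genome.names()}
    for rec in records:
        if rec.is_unmapped or rec.mapq < min_mapq:
            continue
        if rec.ref_name not in diffs:
            raise ValueError(f"record references unknown chromosome {rec.ref_name!r}")
        d = diffs[rec.ref_name]
        for start, end in rec.aligned_blocks():
            if start >= d.size - 1:
                continue
            d[max(0, start)] += 1
            d[min(end, d.size - 1)] -= 1
    return DepthTrack({c: np.cumsum(d[:-1]) for c, d in diffs.items()})


def normalize_geometric(track: DepthTrack) -> DepthTrack:
    """Divide every depth by the genome-wide geometric mean of the positive
    per-base depths.  Zero positions stay zero (log of zero is undefined, so
    they cannot enter the mean)."""
    all_depths = np.concatenate([track[c] for c in track.chroms()])
    positive = all_depths[all_depths > 0]
    if positive.size == 0:
        raise ValueError("all-zero depth track cannot be normalized")
    gm = np.exp(np.mean(np.log(positive.astype(float))))
    return DepthTrack({c: track[c] / gm for c in track.chroms()})


def window_log2(track: DepthTrack, window: int = 1000) -> WindowTrack:
    """Mean normalized depth in non-overlapping windows, log2-transformed.

    A terminal partial window is kept and averaged over its actual length —
    subtelomeric signal lives there.  Zero-mean windows carry no log2 value
    and are excluded from segmentation.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out: Dict[str, List[Window]] = {}
    for chrom in track.chroms():
        depth = track[chrom]
        wins: List[Window] = []
        for start in range(0, depth.size, window):
            end = min(start + window, depth.size)
            mean = float(depth[start:end].mean())
            wins.append(
                Window(
                    Region(chrom, start, end),
                    mean,
                    float(np.log2(mean)) if mean > 0 else None,
                )
            )
        out[chrom] = wins
    return WindowTrack(window, out)


# ---------------------------------------------------------------------------
# circular binary segmentation


def _max_circular_stat(x: np.ndarray) -> Tuple[float, int, int]:
    """Maximum over arcs (i, j], 0 <= i < j <= n (proper subsets), of
    |mean_in - mean_out| / sqrt(1/k + 1/(n-k)).  Ties break toward the
    lexicographically smallest (i, j)."""
    n = x.size
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[-1]
    best = (-1.0, 0, 0)
    for span in range(1, n):  # arc length
        inner = s[span:] - s[: n - span + 1]  # sums of arcs (i, i+span]
        mean_in = inner / span
        mean_out = (total - inner) / (n - span)
        stat = np.abs(mean_in - mean_out) / np.sqrt(1.0 / span + 1.0 / (n - span))
        i = int(np.argmax(stat))
        if stat[i] > best[0] + 1e-12:
            best = (float(stat[i]), i, i + span)
    return best


def _perm_max_stats(
    x: np.ndarray, nperm: int, rng: np.random.Generator, obs: float, alpha: float
) -> int:
    """Count permutations whose max circular statistic reaches obs.

    Early-stops once the count can no longer yield p <= alpha.
    """
    n = x.size
    limit = int(np.floor(alpha * (nperm + 1))) - 1  # max b with (1+b)/(nperm+1) <= alpha
    exceed = 0
    chunk = max(1, min(nperm, 200))
    done = 0
    while done < nperm:
        m = min(chunk, nperm - done)
        perms = np.empty((m, n))
        for r in range(m):
            perms[r] = rng.permutation(x)
        s = np.concatenate(
            [np.zeros((m, 1)), np.cumsum(perms, axis=1)], axis=1
        )
        total = s[:, -1:]
        mx = np.zeros(m)
        for span in range(1, n):
            inner = s[:, span:] - s[:, : n - span + 1]
            scale = np.sqrt(1.0 / span + 1.0 / (n - span))
            stat = np.abs(inner / span - (total - inner) / (n - span)) / scale
            np.maximum(mx, stat.max(axis=1), out=mx)
        exceed += int((mx >= obs - 1e-12).sum())
        done += m
        if exceed > limit:
            return exceed
    return exceed


def _segment_interval(
    x: np.ndarray,
    lo: int,
    alpha: float,
    nperm: int,
    rng: np.random.Generator,
    boundaries: List[int],
) -> None:
    n = x.size
    if n < 2 or np.ptp(x) == 0:
        return
    stat, i, j = _max_circular_stat(x)
    if stat <= 0:
        return
    b = _perm_max_stats(x, nperm, rng, stat, alpha)
    if (1 + b) / (nperm + 1) > alpha:
        return
    cuts = sorted({i, j} - {0, n})
    pieces = []
    prev = 0
    for c in cuts + [n]:
        pieces.append((prev, c))
        prev = c
    for a, bnd in pieces:
        if bnd < n:
            boundaries.append(lo + bnd)
        _segment_interval(x[a:bnd], lo + a, alpha, nperm, rng, boundaries)


def cbs_segment(
    wt: WindowTrack,
    alpha: float = 0.01,
    nperm: int = 1000,
    seed: int = 0,
    merge_tol: float = 0.05,
) -> List[Segment]:
    """Segment every chromosome's windowed log2 track with circular binary
    segmentation; adjacent segments whose means differ by less than
    ``merge_tol`` log2 units are merged back.  Deterministic per seed.

    Zero-mean (missing) windows are excluded from the statistic but are
    assigned to the segment covering their position so that the output
    partitions every window exactly once.
    """
    if nperm < 100:
        raise ValueError("nperm < 100 makes the permutation quantile unreliable")
    rng = np.random.default_rng(seed)
    segments: List[Segment] = []
    for chrom in wt.windows:
        vals = wt.values(chrom)
        n = vals.size
        present = ~np.isnan(vals)
        idx = np.nonzero(present)[0]
        if idx.size < 2:
            mean = float(np.nanmean(vals)) if idx.size else 0.0
            segments.append(Segment(chrom, 0, n, mean))
            continue
        x = vals[idx]
        boundaries: List[int] = []
        _segment_interval(x, 0, alpha, nperm, rng, boundaries)
        # boundaries are indices into the non-missing subsequence; map back
        cutpoints = sorted(set(boundaries))
        starts = [0] + [int(idx[c]) for c in cutpoints]
        ends = [int(idx[c]) for c in cutpoints] + [n]
        chrom_segs = []
        for s0, e0 in zip(starts, ends):
            sel = present[s0:e0]
            mean = float(vals[s0:e0][sel].mean()) if sel.any() else 0.0
            chrom_segs.append(Segment(chrom, s0, e0, mean))
        segments.extend(_merge_adjacent(chrom_segs, vals, present, merge_tol))
    return segments


def _merge_adjacent(
    segs: List[Segment], vals: np.ndarray, present: np.ndarray, tol: float
) -> List[Segment]:
    out = [segs[0]]
    for seg in segs[1:]:
        prev = out[-1]
        if abs(seg.mean - prev.mean) < tol:
            s0, e0 = prev.start_window, seg.end_window
            sel = present[s0:e0]
            mean = float(vals[s0:e0][sel].mean()) if sel.any() else 0.0
            out[-1] = Segment(seg.chrom, s0, e0, mean)
        else:
            out.append(seg)
    return out


def call_duplication(
    segments: Sequence[Segment],
    wt: WindowTrack,
    dup_log2: float = 0.3,
    del_log2: float = -0.5,
) -> List[Region]:
    """Label segments by mean log2 and return the duplicated ones as base-pair
    regions."""
    regions: List[Region] = []
    for seg in segments:
        if seg.mean >= dup_log2:
            seg.call = "duplicated"
        elif seg.mean <= del_log2:
            seg.call = "deleted"
        else:
            seg.call = "neutral"
        if seg.call == "duplicated":
            wins = wt.windows[seg.chrom]
            regions.append(
                Region(
                    seg.chrom,
                    wins[seg.start_window].region.start,
                    wins[seg.end_window - 1].region.end,
                )
            )
    return regions


def write_bedgraph(track: DepthTrack, path: str) -> None:
    """Run-length-collapsed bedGraph of a depth track."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            d = track[chrom]
            change = np.nonzero(np.diff(d))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [d.size]])
            for s, e in zip(starts.tolist(), ends.tolist()):
                fh.write(f"{chrom}\t{s}\t{e}\t{d[s]:g}\n")


def write_regions_bed(regions: Sequence[Region], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def write_regions_tsv(regions: Sequence[Region], path: str) -> None:
    """1-based inclusive report."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlength\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start + 1}\t{r.end}\t{len(r)}\n")
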