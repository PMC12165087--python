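"""Segment calling from window statistics.

Candidate windows come from the top quantile of positive rIBD values and are
confirmed by a positive f_d (after the D < 0 zeroing rule).  Flow direction
is inferred by comparing the f_d of the two population arrangements.  The
end-to-end caller grows segments as maximal runs of windows with sustained
positive rIBD — the "regions where rIBD > 0" reading of the scan — anchored
by a confirmed candidate or by a long enough run, with interval utilities
for bidirectional intersection, genome fractions and truth-tract recovery
scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ArgumentError, ContractError, InsufficientDataError
from .genio import GenomicWindow
from .ibdscan import RibdWindow

DIR_1 = "dir1"
DIR_2 = "dir2"
AMBIGUOUS = "ambiguous"


@dataclass
class IntrogressedSegment:
    chrom: str
    start: int
    end: int
    direction: str
    mean_ribd: float
    mean_fd: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ContractError("empty segment")


# ---------------------------------------------------------------------------
# window gates
# ---------------------------------------------------------------------------


def top_quantile_threshold(
    ribd_values: np.ndarray, q: float = 0.01, min_windows: int = 100
) -> float:
    """Nearest-rank (1 - q) quantile of the positive rIBD values.

    Candidate windows are those strictly above the threshold (and therefore
    strictly positive).  With no positive values the threshold is +inf.
    """
    if not 0 < q < 1:
        raise ArgumentError("q must be in (0, 1)")
    vals = np.asarray(ribd_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < min_windows:
        raise InsufficientDataError(
            f"need >= {min_windows} non-missing windows, got {vals.size}"
        )
    pos = np.sort(vals[vals > 0])
    if pos.size == 0:
        return math.inf
    # nearest-rank: the top ceil(q * n) values sit strictly above the cut
    k = math.ceil(q * pos.size)
    if k >= pos.size:
        return float(np.nextafter(pos[0], -math.inf))
    return float(pos[pos.size - k - 1])


def _check_grid(windows_a: list[GenomicWindow], windows_b: list[GenomicWindow]) -> None:
    if len(windows_a) != len(windows_b) or any(
        (a.chrom, a.start, a.end) != (b.chrom, b.start, b.end)
        for a, b in zip(windows_a, windows_b)
    ):
        raise AlignmentError("window grids do not align")


def confirm_with_fd(
    candidates: list[bool], fd_values: np.ndarray, fd_min: float = 0.0
) -> list[bool]:
    """A candidate window is confirmed iff its (zero-adjusted) f_d exceeds
    ``fd_min``; missing f_d rejects."""
    fd = np.asarray(fd_values, dtype=float)
    if len(candidates) != fd.size:
        raise AlignmentError("candidate flags do not align with f_d values")
    return [bool(c) and not np.isnan(f) and f > fd_min for c, f in zip(candidates, fd)]


def infer_direction(
    fd_arr1: float, fd_arr2: float, delta: float = 0.0
) -> str:
    """Direction label for one window from the two arrangement f_d values.

    ``dir1`` when arrangement 1 exceeds arrangement 2 by more than ``delta``
    (flow toward arrangement 1's recipient), ``dir2`` for the converse,
    otherwise ``ambiguous``.  A missing value on either side is ambiguous.
    """
    if np.isnan(fd_arr1) or np.isnan(fd_arr2):
        return AMBIGUOUS
    if fd_arr1 - fd_arr2 > delta:
        return DIR_1
    if fd_arr2 - fd_arr1 > delta:
        return DIR_2
    return AMBIGUOUS


# ---------------------------------------------------------------------------
# merging and interval algebra
# ---------------------------------------------------------------------------


def merge_segments(
    windows: list[GenomicWindow],
    directions: list[str],
    ribd: np.ndarray,
    fd: np.ndarray,
    gap: int = 0,
) -> list[IntrogressedSegment]:
    """Merge overlapping or book-ended (within ``gap`` bp) windows of the
    same direction into segments; segment statistics are window means
    weighted by window length."""
    order = sorted(range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].start))
    segments: list[IntrogressedSegment] = []
    cur: list[int] = []

    def flush() -> None:
        if not cur:
            return
        lengths = np.array([windows[i].length for i in cur], dtype=float)
        r = np.array([ribd[i] for i in cur], dtype=float)
        f = np.array([fd[i] for i in cur], dtype=float)
        segments.append(
            IntrogressedSegment(
                chrom=windows[cur[0]].chrom,
                start=windows[cur[0]].start,
                end=max(windows[i].end for i in cur),
                direction=directions[cur[0]],
                mean_ribd=float(np.average(r, weights=lengths)),
                mean_fd=float(np.average(f, weights=lengths)),
                n_windows=len(cur),
            )
        )

    for i in order:
        w = windows[i]
        if cur:
            prev_end = max(windows[j].end for j in cur)
            same = (
                windows[cur[0]].chrom == w.chrom
                and directions[cur[0]] == directions[i]
                and w.start - prev_end <= gap
            )
            if same:
                cur.append(i)
                continue
            flush()
            cur = []
        cur.append(i)
    flush()
    return segments


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def intersect_bidirectional(
    segments_dir_a: list, segments_dir_b: list
) -> list[tuple[int, int]]:
    """Maximal intervals covered by at least one segment from each set."""
    a = _union([(s.start, s.end) if hasattr(s, "start") else tuple(s) for s in segments_dir_a])
    b = _union([(s.start, s.end) if hasattr(s, "start") else tuple(s) for s in segments_dir_b])
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def genome_fraction(segments: list, genome_length: int) -> float:
    """Fraction of the genome covered by the union of segments."""
    spans = [(s.start, s.end) if hasattr(s, "start") else tuple(s) for s in segments]
    for s, e in spans:
        if s < 0 or e > genome_length:
            raise ContractError(f"segment [{s}, {e}) outside [0, {genome_length})")
    return sum(e - s for s, e in _union(spans)) / genome_length


def evaluate_recovery(
    segments: list, truth_intervals: list
) -> tuple[float, float, float]:
    """Base-level (precision, recall, F1) of segment calls against truth.

    ``truth_intervals`` may be TruthTract objects or (start, end) pairs; the
    union footprint is used on both sides.  With no segments precision is
    NaN and recall 0; with empty truth recall is NaN.
    """
    seg_u = _union([(s.start, s.end) if hasattr(s, "start") else tuple(s) for s in segments])
    truth_u = _union(
        [(t.start, t.end) if hasattr(t, "start") else tuple(t) for t in truth_intervals]
    )
    seg_bases = sum(e - s for s, e in seg_u)
    truth_bases = sum(e - s for s, e in truth_u)
    overlap = sum(hi - lo for lo, hi in intersect_bidirectional(seg_u, truth_u))
    precision = overlap / seg_bases if seg_bases else float("nan")
    recall = overlap / truth_bases if truth_bases else float("nan")
    if not seg_bases:
        recall = 0.0 if truth_bases else float("nan")
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = float("nan") if math.isnan(precision) or math.isnan(recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


# ---------------------------------------------------------------------------
# the directional caller
# ---------------------------------------------------------------------------


def call_segments(
    ribd_windows: list[RibdWindow],
    fd_same: np.ndarray,
    fd_opp: np.ndarray,
    direction_label: str,
    q: float = 0.01,
    fd_min: float = 0.0,
    delta: float = 0.0,
    gap: int = 0,
    extend: bool = True,
    min_windows: int = 100,
    min_run_windows: int = 8,
    veto_margin: float = 0.05,
    member_floor: float = 0.0,
) -> list[IntrogressedSegment]:
    """Call introgressed segments for one donor-to-recipient direction.

    ``fd_same`` is the f_d track of the arrangement matching this direction,
    ``fd_opp`` the opposite arrangement's.  Candidate seeds are top-quantile
    rIBD windows confirmed by f_d; with ``extend`` segments are maximal runs
    of positive-rIBD windows that either contain a seed or span at least
    ``min_run_windows`` windows (sustained sharing no isolated noise window
    produces).  A run whose length-weighted f_d vote favours the opposite
    arrangement by more than ``veto_margin`` is suppressed; direction is
    otherwise adjudicated by the opposing scan's own rIBD track.
    """
    windows = [r.window for r in ribd_windows]
    ribd = np.array([r.ribd for r in ribd_windows], dtype=float)
    fd_same = np.asarray(fd_same, dtype=float)
    fd_opp = np.asarray(fd_opp, dtype=float)
    if fd_same.size != len(windows) or fd_opp.size != len(windows):
        raise AlignmentError("f_d tracks do not align with the rIBD window grid")
    threshold = top_quantile_threshold(ribd, q=q, min_windows=min_windows)
    with np.errstate(invalid="ignore"):
        positive = (~np.isnan(ribd)) & (ribd > max(member_floor, 0.0))
        topq = positive & (ribd > threshold)
    confirmed = np.array(confirm_with_fd(list(topq), fd_same, fd_min=fd_min))
    seed = topq & confirmed
    member = positive if extend else seed

    # maximal runs of member windows; a run is emitted when it contains a
    # confirmed seed and its length-weighted f_d vote matches the direction
    order = sorted(range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].start))
    segments: list[IntrogressedSegment] = []
    run: list[int] = []

    def flush() -> None:
        if not run:
            return
        if not any(seed[i] for i in run) and len(run) < min_run_windows:
            return
        lengths = np.array([windows[i].length for i in run], dtype=float)
        fs, fo = fd_same[run], fd_opp[run]
        ok = ~np.isnan(fs) & ~np.isnan(fo)
        if ok.any():
            opposed = infer_direction(
                float(np.average(fs[ok], weights=lengths[ok])),
                float(np.average(fo[ok], weights=lengths[ok])),
                delta=veto_margin,
            ) == DIR_2
            if opposed:
                return
        segments.append(
            IntrogressedSegment(
                chrom=windows[run[0]].chrom,
                start=windows[run[0]].start,
                end=max(windows[i].end for i in run),
                direction=direction_label,
                mean_ribd=float(np.average(ribd[run], weights=lengths)),
                mean_fd=float(np.nansum(fd_same[run] * lengths) / lengths.sum()),
                n_windows=len(run),
            )
        )

    for i in order:
        if not member[i]:
            continue
        if run:
            prev_end = max(windows[j].end for j in run)
            if windows[run[0]].chrom != windows[i].chrom or windows[i].start - prev_end > gap:
                flush()
                run = []
        run.append(i)
    flush()
    return segments


def segment_table(segments: list[IntrogressedSegment]):
    import pandas as pd

    return pd.DataFrame(
        [
            (s.chrom, s.start, s.end, s.direction, s.mean_ribd, s.mean_fd, s.n_windows)
            for s in segments
        ],
        columns=["chrom", "start", "end", "direction", "mean_ribd", "mean_fd", "n_windows"],
    )
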