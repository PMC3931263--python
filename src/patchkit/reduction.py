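"""Min-max trace reduction for display.

Drawing n samples into w pixel columns naively costs n-1 line segments.
Because every segment inside one pixel column only ever lights pixels
between the column's vertical minimum and maximum, the column can be drawn
as a single min-max vertical line plus one connector to the next column:
2w-1 segments in total, with pixel coverage identical to the naive drawing.
Reduction only pays off for n > 2w + 2; shorter inputs are returned as the
plain polyline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SegmentList", "reduce_trace", "column_extrema", "column_bounds"]

Point = tuple[float, float]


@dataclass
class SegmentList:
    """Ordered drawable segments in data coordinates (x = sample index)."""

    segments: list[tuple[Point, Point]]
    width: int
    reduced: bool

    def __len__(self) -> int:
        return len(self.segments)


def column_bounds(n: int, width_px: int) -> np.ndarray:
    """Sample-index boundaries of the near-equal column partition.

    Column k covers samples [floor(k*n/w), floor((k+1)*n/w)); sizes differ
    by at most one.
    """
    k = np.arange(width_px + 1, dtype=np.int64)
    return (k * n) // width_px


def column_extrema(samples: np.ndarray, width_px: int) -> list[tuple[float, float]]:
    """Exact (min, max) of each pixel column's samples."""
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 2:
        raise ValueError("need at least two samples")
    if width_px < 1:
        raise ValueError("width must be >= 1")
    bounds = column_bounds(n, width_px)
    return [(float(np.min(samples[a:b])), float(np.max(samples[a:b])))
            for a, b in zip(bounds[:-1], bounds[1:])]


def reduce_trace(samples: np.ndarray, width_px: int) -> SegmentList:
    """Min-max reduction of a sample vector to 2w-1 drawable segments.

    For n <= 2w + 2 the unreduced polyline (n-1 segments) is returned.
    Each reduced column contributes one vertical segment between its min
    and max (drawn from whichever extremum occurs first in the column, for
    determinism) and one connector from the column's last sample to the
    next column's first sample.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 2:
        raise ValueError("need at least two samples")
    if width_px < 1:
        raise ValueError("width must be >= 1")
    if n <= 2 * width_px + 2:
        segs = [((float(i), float(samples[i])), (float(i + 1), float(samples[i + 1])))
                for i in range(n - 1)]
        return SegmentList(segs, width_px, reduced=False)
    bounds = column_bounds(n, width_px)
    segs: list[tuple[Point, Point]] = []
    for k in range(width_px):
        a, b = int(bounds[k]), int(bounds[k + 1])
        col = samples[a:b]
        imin = a + int(np.argmin(col))
        imax = a + int(np.argmax(col))
        x = 0.5 * (a + b - 1)
        lo, hi = float(samples[imin]), float(samples[imax])
        if imin <= imax:
            segs.append(((x, lo), (x, hi)))
        else:
            segs.append(((x, hi), (x, lo)))
        if k + 1 < width_px:
            nxt = int(bounds[k + 1])
            segs.append(((float(b - 1), float(samples[b - 1])),
                         (float(nxt), float(samples[nxt]))))
    assert len(segs) == 2 * width_px - 1
    return SegmentList(segs, width_px, reduced=True)
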