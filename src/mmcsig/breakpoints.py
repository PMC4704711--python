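"""Balancer rearrangement boundaries from binned read depth.

A reciprocal-translocation balancer changes copy number of the flanking
material in strains carrying it, so its boundary shows up as a persistent
step ("major drop") in mean coverage when a chromosome is laid out in fixed
5- or 10-kb bins.  Detection here is deliberately simple and robust: compare
the median of a short run of bins on either side of each candidate boundary.
Base-pair refinement from soft-clipped reads is out of scope (it needs the
alignments themselves); calls are reported at bin-edge resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DepthTrack", "BreakpointCall", "bin_depth", "detect_coverage_drop"]


@dataclass
class DepthTrack:
    """Ordered fixed-width bins of mean coverage for one chromosome."""

    chrom: str
    bin_width: int
    means: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        self.means = np.asarray(self.means, dtype=float)
        if (self.means < 0).any():
            raise ValueError("bin means must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.means.size)

    def bin_start(self, index: int) -> int:
        """1-based start position of a bin."""
        return index * self.bin_width + 1


@dataclass(frozen=True)
class BreakpointCall:
    """A candidate rearrangement boundary at a bin edge.

    ``boundary_bin`` is the first bin of the dropped region; ``boundary_pos``
    the corresponding 1-based bin-edge coordinate.  ``pre_mean`` and
    ``post_mean`` are the robust (median) depths of the flanking runs and
    ``ratio = post_mean / pre_mean``.
    """

    chrom: str
    boundary_bin: int
    boundary_pos: int
    pre_mean: float
    post_mean: float

    @property
    def ratio(self) -> float:
        return self.post_mean / self.pre_mean if self.pre_mean > 0 else float("nan")


def bin_depth(
    positions,
    depths,
    bin_width: int = 5000,
    chrom: str = "chrI",
    chrom_length: int | None = None,
) -> DepthTrack:
    """Average per-position depth into fixed-width bins.

    ``positions`` are 1-based; each bin's mean is taken over the positions it
    actually contains, so a final partial bin is averaged over its actual
    width.  Positions need not be sorted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    pos = np.asarray(positions, dtype=np.int64)
    dep = np.asarray(depths, dtype=float)
    if pos.size != dep.size:
        raise ValueError("positions and depths differ in length")
    if pos.size == 0:
        raise ValueError("no positions supplied")
    idx = (pos - 1) // bin_width
    n_bins = int(idx.max()) + 1
    if chrom_length is not None:
        n_bins = max(n_bins, int(np.ceil(chrom_length / bin_width)))
    sums = np.bincount(idx, weights=dep, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return DepthTrack(chrom=chrom, bin_width=bin_width, means=means)


def detect_coverage_drop(
    track: DepthTrack,
    drop_ratio: float = 0.6,
    min_run: int = 3,
    search_interval: tuple[int, int] | None = None,
) -> list[BreakpointCall]:
    """Locate persistent drops in a binned coverage track.

    A candidate boundary before bin ``i`` qualifies when the median of bins
    ``[i, i+min_run)`` falls below ``drop_ratio`` times the median of bins
    ``[i-min_run, i)``.  Runs of consecutive qualifying boundaries are merged
    to the single boundary with the most extreme post/pre ratio (leftmost on
    ties).  ``search_interval`` restricts scanning to a bin range (inclusive),
    mirroring a search "at the previously mapped genetic locations".  Medians
    rather than means are used so a single dropped-out bin cannot fake or
    mask a boundary.
    """
    if not 0 < drop_ratio < 1:
        raise ValueError("drop_ratio must be in (0, 1)")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    n = track.n_bins
    if n < 2 * min_run:
        raise ValueError(f"track has {n} bins; need at least {2 * min_run}")

    lo, hi = min_run, n - min_run
    if search_interval is not None:
        lo = max(lo, int(search_interval[0]))
        hi = min(hi, int(search_interval[1]) + 1)

    qualifying: list[tuple[int, float, float]] = []  # (boundary, pre, post)
    for i in range(lo, hi):
        pre = float(np.median(track.means[i - min_run: i]))
        post = float(np.median(track.means[i: i + min_run]))
        if pre > 0 and post < drop_ratio * pre:
            qualifying.append((i, pre, post))

    calls: list[BreakpointCall] = []
    group: list[tuple[int, float, float]] = []

    def flush() -> None:
        if not group:
            return
        # most extreme ratio first; exact ties (noiseless steps) resolved by
        # the sharpest single-bin step, then leftmost
        best_ratio = min(t[2] / t[1] for t in group)
        tied = [t for t in group if t[2] / t[1] <= best_ratio + 1e-9]
        best = max(tied, key=lambda t: (track.means[t[0] - 1] - track.means[t[0]], -t[0]))
        i, pre, post = best
        calls.append(
            BreakpointCall(
                chrom=track.chrom,
                boundary_bin=i,
                boundary_pos=track.bin_start(i),
                pre_mean=pre,
                post_mean=post,
            )
        )

    for item in qualifying:
        if group and item[0] == group[-1][0] + 1:
            group.append(item)
        else:
            flush()
            group = [item]
    flush()
    return calls
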