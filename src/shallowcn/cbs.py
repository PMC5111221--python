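"""Circular binary segmentation of per-bin log2 ratio tracks.

Per chromosome, the marker sequence is treated as a circle and the arc
maximizing the standardized mean difference between inside and outside is
located; the split is accepted when its permutation p-value falls below
``alpha``, and the procedure recurses on the resulting pieces.  Because
the statistic is symmetric between an arc and its complement, scanning
all linear windows covers every circular arc.  Adjacent segments whose
means differ by less than a pruning tolerance are merged afterwards.

The scale estimate entering the statistic is a constant per chromosome
(robustly derived from successive differences), so it cancels in the
permutation comparison; significance is fully permutation-calibrated.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError

_PERM_BLOCK = 128


def _arc_stats_single(x: np.ndarray, min_bins: int):
    """Max standardized arc statistic and its (i, j) arc for one sequence.

    Returns (stat, i, j) where the arc is x[i:j]; stat is
    |mean_in - mean_out| / sqrt(1/k + 1/(n-k)) (scale-free up to the
    constant sigma, which cancels in permutation comparisons).
    """
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    tot = S[-1]
    best, bi, bj = -1.0, 0, n
    for k in range(min_bins, n - min_bins + 1):
        d = S[k:] - S[: n + 1 - k]
        stat = np.abs(d / k - (tot - d) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        i = int(np.argmax(stat))
        if stat[i] > best:
            best, bi, bj = float(stat[i]), i, i + k
    return best, bi, bj


def _arc_stats_block(xs: np.ndarray, min_bins: int) -> np.ndarray:
    """Max arc statistic per row of a (B, n) matrix of permuted sequences."""
    B, n = xs.shape
    S = np.concatenate([np.zeros((B, 1)), np.cumsum(xs, axis=1)], axis=1)
    tot = S[:, -1:]
    best = np.zeros(B)
    for k in range(min_bins, n - min_bins + 1):
        d = S[:, k:] - S[:, : n + 1 - k]
        stat = np.abs(d / k - (tot - d) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        np.maximum(best, stat.max(axis=1), out=best)
    return best


def _split_significant(
    x: np.ndarray,
    alpha: float,
    n_permutations: int,
    min_bins: int,
    rng: np.random.Generator,
):
    """Best arc for x and whether it passes the permutation test.

    The permutation loop stops early once enough permuted maxima exceed
    the observed one to rule out significance at level ``alpha``.
    """
    n = len(x)
    if n < 2 * min_bins or np.ptp(x) < 1e-12:
        return None
    obs, i, j = _arc_stats_single(x, min_bins)
    # significant iff (exceed + 1) / (n_perm + 1) < alpha
    max_exceed = int(np.ceil(alpha * (n_permutations + 1))) - 2
    if max_exceed < 0:
        return None
    exceed = 0
    done = 0
    while done < n_permutations:
        b = min(_PERM_BLOCK, n_permutations - done)
        perms = rng.permuted(np.tile(x, (b, 1)), axis=1)
        exceed += int(np.sum(_arc_stats_block(perms, min_bins) >= obs))
        done += b
        if exceed > max_exceed:
            return None
    return i, j


def _segment_values(
    x: np.ndarray,
    alpha: float,
    n_permutations: int,
    min_bins: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Recursive CBS on a 1-D value array; returns (start, stop) index pairs."""
    pieces: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        hit = _split_significant(x[lo:hi], alpha, n_permutations, min_bins, rng)
        if hit is None:
            pieces.append((lo, hi))
            continue
        i, j = hit
        cuts = [lo, *(lo + c for c in (i, j) if 0 < c < hi - lo), hi]
        for a, b in zip(cuts[:-1], cuts[1:]):
            stack.append((a, b))
    return sorted(pieces)


def _prune(pieces: list[tuple[int, int]], x: np.ndarray, tol: float):
    """Merge adjacent pieces whose means differ by < tol, closest first."""
    pieces = list(pieces)
    while len(pieces) > 1:
        means = [x[a:b].mean() for a, b in pieces]
        diffs = [abs(means[i + 1] - means[i]) for i in range(len(means) - 1)]
        i = int(np.argmin(diffs))
        if diffs[i] >= tol:
            break
        pieces[i] = (pieces[i][0], pieces[i + 1][1])
        del pieces[i + 1]
    return pieces


def segment_cbs(
    track,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_bins_per_segment: int = 3,
    prune_tol: float = 0.05,
    max_gap: int = 10,
    seed: int = 0,
):
    """Segment a ratio track into maximal constant-mean segments.

    Missing bins are skipped; runs of missing bins longer than ``max_gap``
    bins (centromere-scale masked gaps) break segments, so no segment
    bridges such a gap.  Segment extents span from the first member bin's
    start to the last member bin's end, and each segment's mean is the
    exact mean of its member bins.  Calls are left unset.
    """
    from .profiling import Segment  # deferred: profiling imports this module

    grid = track.grid
    finite = np.isfinite(track.values)
    if not finite.any():
        raise DegenerateInputError("all bins are missing")
    rng = np.random.default_rng(seed)
    segments = []
    for chrom in grid.chrom_names():
        sl = grid.chrom_slice(chrom)
        idx = np.nonzero(finite[sl.start : sl.stop])[0] + sl.start
        if len(idx) == 0:
            continue
        # split into runs separated by > max_gap missing bins
        breaks = np.nonzero(np.diff(idx) > max_gap + 1)[0]
        for run in np.split(idx, breaks + 1):
            x = track.values[run]
            pieces = _segment_values(x, alpha, n_permutations, min_bins_per_segment, rng)
            pieces = _prune(pieces, x, prune_tol)
            for a, b in pieces:
                bins = run[a:b]
                segments.append(
                    Segment(
                        chrom=chrom,
                        start=int(grid.start[bins[0]]),
                        end=int(grid.end[bins[-1]]),
                        n_bins=len(bins),
                        mean=float(x[a:b].mean()),
                    )
                )
    return segments
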