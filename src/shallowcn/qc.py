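"""Sample-level noise and coverage quality metrics.

The central metric is MAPD, the median absolute pairwise difference of
position-ordered per-marker log2 ratios: median(|x_{i+1} - x_i|).  It
measures sample noise while being largely insensitive to true copy-number
structure, since a CN breakpoint contributes only one large difference
per segment boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError
from .profiling import RatioTrack
from .simulate import BinCounts


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    mapd: float | None
    n_markers_used: int
    masked_fraction: float
    covered_bin_fraction: float
    mean_count: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def compute_mapd(track: RatioTrack, pairing: str = "skip") -> tuple[float, int]:
    """MAPD of a ratio track, with its usable marker count.

    Markers are taken in genomic order; pairs spanning a chromosome
    boundary are excluded (a cross-chromosome difference is not a
    biological adjacency).  ``pairing='skip'`` (default) takes
    differences between consecutive non-missing markers within each
    chromosome; ``pairing='strict'`` keeps only pairs of adjacent bins
    that are both non-missing.  The genome-wide median uses the even-count
    midpoint convention.
    """
    if pairing not in ("skip", "strict"):
        raise ConfigurationError(f"unknown pairing mode {pairing!r}")
    diffs: list[np.ndarray] = []
    n_markers = 0
    for chrom in track.grid.chrom_names():
        sl = track.grid.chrom_slice(chrom)
        x = track.values[sl]
        if pairing == "skip":
            x = x[np.isfinite(x)]
            n_markers += len(x)
            if len(x) >= 2:
                diffs.append(np.abs(np.diff(x)))
        else:
            ok = np.isfinite(x)
            n_markers += int(ok.sum())
            pair = ok[:-1] & ok[1:]
            if pair.any():
                diffs.append(np.abs(x[1:][pair] - x[:-1][pair]))
    if n_markers < 2 or not diffs:
        raise DegenerateInputError("MAPD needs >= 2 usable markers")
    all_diffs = np.concatenate(diffs)
    if len(all_diffs) == 0:
        raise DegenerateInputError("MAPD needs >= 1 adjacent marker pair")
    return float(np.median(all_diffs)), n_markers


def qc_report(counts: BinCounts, track: RatioTrack, pairing: str = "skip") -> QCReport:
    """Aggregate per-sample QC: MAPD, masking and bin-level coverage.

    ``covered_bin_fraction`` is the fraction of bins with at least one
    read — the bin-resolution analog of the fraction of target bases at
    >= 1-fold coverage.
    """
    if not counts.grid.same_grid(track.grid):
        raise ConfigurationError("counts and track are on different grids")
    try:
        mapd, n_markers = compute_mapd(track, pairing=pairing)
    except DegenerateInputError:
        mapd, n_markers = None, int(np.isfinite(track.values).sum())
    return QCReport(
        sample_id=counts.sample_id,
        mapd=mapd,
        n_markers_used=n_markers,
        masked_fraction=track.masked_fraction,
        covered_bin_fraction=float(np.mean(counts.counts >= 1)),
        mean_count=float(np.mean(counts.counts)),
    )
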