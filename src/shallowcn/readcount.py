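"""Adapter from coordinate-sorted alignment files to per-bin counts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam

from .errors import ConfigurationError, FormatError
from .grid import BinGrid
from .simulate import BinCounts


def count_reads_in_bins(
    alignment_source,
    grid: BinGrid,
    min_mapq: int = 0,
    exclude_duplicates: bool = True,
    sample_id: str | None = None,
) -> BinCounts:
    """Count primary mapped reads per grid bin from a SAM/BAM file.

    Each filter-passing read is assigned to exactly one bin by its
    leftmost aligned position.  Reads that are unmapped, secondary,
    supplementary, below ``min_mapq``, or duplicate-flagged (when
    ``exclude_duplicates``) are skipped; reads on chromosomes absent
    from the grid are ignored but tallied (``discarded_reads`` in the
    result's metadata is exposed via the returned object's attribute).
    The input must be coordinate-sorted.
    """
    path = str(alignment_source)
    if sample_id is None:
        sample_id = Path(path).stem
    counts = [0] * grid.n_bins
    grid_names = set(grid.chrom_names())
    discarded = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        refs = set(fh.references or ())
        if not refs & grid_names:
            raise ConfigurationError(
                "no chromosome overlap between alignment file and grid"
            )
        last = (-1, -1)
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            key = (read.reference_id, read.reference_start)
            if key < last:
                raise FormatError(f"{path} is not coordinate-sorted")
            last = key
            if read.mapping_quality < min_mapq:
                continue
            if exclude_duplicates and read.is_duplicate:
                continue
            chrom = read.reference_name
            if chrom not in grid_names:
                discarded += 1
                continue
            counts[grid.bin_at(chrom, read.reference_start)] += 1
    result = BinCounts(grid, np.array(counts, dtype=np.int64), sample_id=sample_id)
    object.__setattr__(result, "discarded_reads", discarded)
    return result
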