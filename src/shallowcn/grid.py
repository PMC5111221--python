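"""Fixed genomic bin grids.

A :class:`BinGrid` is the ordered partition of a genome into fixed-width
windows (50 kb by default) that every count track, ratio track and segment
in this package aligns to.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

DEFAULT_BIN_SIZE = 50_000


@dataclass(frozen=True)
class BinGrid:
    """An ordered tiling of chromosomes into bins with per-bin GC fraction.

    Bins tile each chromosome without gaps or overlaps; the terminal bin of
    a chromosome may be shorter than ``bin_size``.  Bins are sorted by
    (chromosome order, start).
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    chrom: np.ndarray  # str per bin
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    gc: np.ndarray  # float64 in [0, 1]
    _slices: dict[str, slice] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ConfigurationError("bin_size must be positive")
        if not (len(self.chrom) == len(self.start) == len(self.end) == len(self.gc)):
            raise ConfigurationError("grid columns must have equal length")
        if np.any(self.gc < 0) or np.any(self.gc > 1):
            raise ConfigurationError("gc_fraction must lie in [0, 1]")
        lengths = dict(self.chromosomes)
        slices: dict[str, slice] = {}
        pos = 0
        for name, length in self.chromosomes:
            n = int(np.sum(self.chrom == name))
            sl = slice(pos, pos + n)
            slices[name] = sl
            s, e = self.start[sl], self.end[sl]
            if n == 0:
                raise ConfigurationError(f"chromosome {name} has no bins")
            if s[0] != 0 or e[-1] != lengths[name]:
                raise ConfigurationError(f"bins do not span chromosome {name}")
            if np.any(s[1:] != e[:-1]):
                raise ConfigurationError(f"bins have gaps/overlaps on {name}")
            pos += n
        if pos != len(self.chrom):
            raise ConfigurationError("bins out of chromosome order")
        object.__setattr__(self, "_slices", slices)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def widths(self) -> np.ndarray:
        return self.end - self.start

    def chrom_slice(self, name: str) -> slice:
        return self._slices[name]

    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def bin_at(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing base ``pos`` on ``chrom``."""
        sl = self._slices[chrom]
        i = int(np.searchsorted(self.end[sl], pos, side="right"))
        if i >= sl.stop - sl.start or pos < 0:
            raise ConfigurationError(f"position {chrom}:{pos} outside grid")
        return sl.start + i

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end,
             "gc_fraction": self.gc}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, bin_size: int | None = None) -> "BinGrid":
        chrom = df["chrom"].to_numpy(dtype=object)
        start = df["start"].to_numpy(dtype=np.int64)
        end = df["end"].to_numpy(dtype=np.int64)
        gc = df["gc_fraction"].to_numpy(dtype=float)
        names = list(dict.fromkeys(chrom))
        chromosomes = tuple(
            (n, int(end[chrom == n].max())) for n in names
        )
        if bin_size is None:
            bin_size = int(np.max(end - start))
        return cls(chromosomes, bin_size, chrom, start, end, gc)

    def same_grid(self, other: "BinGrid") -> bool:
        return (
            self.chromosomes == other.chromosomes
            and self.bin_size == other.bin_size
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
        )


def build_grid(
    chromosomes: list[tuple[str, int]], bin_size: int, gc: np.ndarray
) -> BinGrid:
    """Assemble a :class:`BinGrid` by tiling each chromosome with bins.

    ``gc`` supplies one GC fraction per bin in grid order.
    """
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name, length in chromosomes:
        if length < bin_size:
            raise ConfigurationError(
                f"chromosome {name} shorter than one bin ({length} < {bin_size})"
            )
        edges = list(range(0, length, bin_size)) + [length]
        if edges[-1] == edges[-2]:
            edges.pop(-2)
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(name)
            starts.append(s)
            ends.append(e)
    gc = np.asarray(gc, dtype=float)
    if len(gc) != len(chroms):
        raise ConfigurationError(
            f"expected {len(chroms)} gc values, got {len(gc)}"
        )
    return BinGrid(
        tuple(chromosomes),
        bin_size,
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        gc,
    )
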