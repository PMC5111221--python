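"""Per-bin counts to a masked, segmented three-state copy-number profile.

The stages mirror a standard read-depth CN pipeline for low-coverage WGS:
GC-normalize counts to log2(CN/2) ratios assuming a diploid baseline and no
matched normal, mask blacklisted regions, segment with circular binary
segmentation, and call each segment gain/neutral/loss against fixed log2
thresholds (+0.15 / -0.15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .cbs import segment_cbs
from .errors import ConfigurationError, DegenerateInputError, FitError
from .grid import BinGrid
from .simulate import BinCounts

logger = logging.getLogger("shallowcn")

GAIN_THRESHOLD = 0.15
LOSS_THRESHOLD = -0.15

MASK_BLACKLIST = "blacklist"
MASK_ZERO = "zero-count"
MASK_USER = "user"


@dataclass(frozen=True)
class BlacklistRegions:
    """Sorted, merged genomic intervals excluded from CN estimation.

    Typically centromeric / highly repetitive regions where read-depth
    copy number cannot be measured.  0-based half-open.
    """

    regions: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_intervals(cls, intervals) -> "BlacklistRegions":
        """Canonicalize arbitrary (chrom, start, end) intervals."""
        by_chrom: dict[str, list[list[int]]] = {}
        for chrom, s, e in intervals:
            if e <= s:
                raise ConfigurationError(f"empty blacklist interval {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append([s, e])
        merged: list[tuple[str, int, int]] = []
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom])
            cur = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur[1]:
                    cur[1] = max(cur[1], e)
                else:
                    merged.append((chrom, cur[0], cur[1]))
                    cur = [s, e]
            merged.append((chrom, cur[0], cur[1]))
        return cls(tuple(merged))

    def __len__(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class RatioTrack:
    """Per-bin log2(CN/2) ratios with mask provenance.

    ``values`` holds NaN for missing (masked or zero-count) bins;
    ``mask_reason`` records why each missing bin is missing.  The
    pre-masking values are retained in ``raw_values`` for audit.
    """

    grid: BinGrid
    values: np.ndarray  # float64, NaN = missing
    mask_reason: np.ndarray  # object: None | reason string
    sample_id: str = "sample"
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.values) != self.grid.n_bins:
            raise ConfigurationError("track length does not match grid")
        if self.raw_values is None:
            object.__setattr__(self, "raw_values", self.values.copy())

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def masked_fraction(self) -> float:
        return float(np.mean(self.missing))


@dataclass(frozen=True)
class Segment:
    """A maximal run of bins with a common mean log2 ratio."""

    chrom: str
    start: int
    end: int
    n_bins: int
    mean: float
    call: str | None = None  # 'loss' | 'neutral' | 'gain'

    def __post_init__(self) -> None:
        if self.end <= self.start or self.n_bins < 1:
            raise ConfigurationError("invalid segment extent")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CNProfile:
    """A called copy-number profile: ordered segments plus the thresholds used."""

    sample_id: str
    segments: tuple[Segment, ...]
    gain_thr: float = GAIN_THRESHOLD
    loss_thr: float = LOSS_THRESHOLD
    provenance: dict = field(default_factory=dict, compare=False)

    def called(self, call: str) -> list[Segment]:
        return [s for s in self.segments if s.call == call]

    def cna_intervals(self) -> dict[str, list[tuple[str, int, int]]]:
        """Called gain/loss intervals keyed by event type."""
        out: dict[str, list[tuple[str, int, int]]] = {"gain": [], "loss": []}
        for s in self.segments:
            if s.call in out:
                out[s.call].append((s.chrom, s.start, s.end))
        return out


def gc_normalize(
    counts: BinCounts,
    grid: BinGrid | None = None,
    fit: str = "poly2",
    min_nonzero_bins: int = 200,
) -> RatioTrack:
    """GC-normalize counts into median-centred log2 ratios.

    Expected count as a function of GC is fitted on non-zero bins within
    the 5th-95th count percentiles — a degree-2 polynomial by default, or
    a running median over GC deciles (``fit='decile-median'``).  Ratios
    are divided by their genome-wide median so that the majority (diploid)
    state maps to log2 ratio 0; no matched normal is used.  Zero-count
    bins become missing with reason ``zero-count``.
    """
    grid = grid if grid is not None else counts.grid
    if not counts.grid.same_grid(grid):
        raise ConfigurationError("counts grid does not match supplied grid")
    c = counts.counts.astype(float)
    nz = c > 0
    if int(nz.sum()) < min_nonzero_bins:
        raise DegenerateInputError(
            f"need >= {min_nonzero_bins} non-zero bins, got {int(nz.sum())}"
        )
    gc = grid.gc
    if fit == "poly2":
        if np.ptp(gc[nz]) < 1e-9:
            expected = np.full(grid.n_bins, c[nz].mean())
            train = nz
        else:
            # initial fit on all non-zero bins, then trim the 5-95 percentile
            # band of relative residuals and refit: robust to CNA outliers
            # without discarding whole GC strata.
            coefs = np.polynomial.polynomial.polyfit(gc[nz], c[nz], 2)
            fit0 = np.clip(np.polynomial.polynomial.polyval(gc, coefs), 1e-9, None)
            rel = np.where(nz, c / fit0, np.nan)
            lo, hi = np.nanpercentile(rel, [5, 95])
            train = nz & (rel >= lo) & (rel <= hi)
            if train.sum() < 3:
                train = nz
            coefs = np.polynomial.polynomial.polyfit(gc[train], c[train], 2)
            expected = np.polynomial.polynomial.polyval(gc, coefs)
    elif fit == "decile-median":
        train = nz  # per-decile medians are already outlier-robust
        edges = np.quantile(gc[train], np.linspace(0, 1, 11))
        edges[0], edges[-1] = -np.inf, np.inf
        centers, medians = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            sel = train & (gc >= a) & (gc < b)
            if sel.any():
                centers.append(gc[sel].mean())
                medians.append(np.median(c[sel]))
        expected = np.interp(gc, centers, medians)
    else:
        raise ConfigurationError(f"unknown fit method {fit!r}")
    if not np.all(np.isfinite(expected)):
        raise FitError("GC fit produced non-finite expected counts")
    expected = np.clip(expected, 1e-9, None)
    ratio = np.where(nz, c / expected, np.nan)
    med = np.nanmedian(ratio)
    if not np.isfinite(med) or med <= 0:
        raise FitError("degenerate ratio median")
    values = np.log2(ratio / med)
    reason = np.full(grid.n_bins, None, dtype=object)
    reason[~nz] = MASK_ZERO
    return RatioTrack(grid, values, reason, sample_id=counts.sample_id)


def apply_blacklist(track: RatioTrack, blacklist: BlacklistRegions) -> RatioTrack:
    """Mask every bin overlapping a blacklist interval by >= 1 bp."""
    values = track.values.copy()
    reason = track.mask_reason.copy()
    for chrom, s, e in blacklist.regions:
        if chrom not in track.grid._slices:
            continue
        sl = track.grid.chrom_slice(chrom)
        starts = track.grid.start[sl]
        ends = track.grid.end[sl]
        hit = (starts < e) & (ends > s)
        idx = np.nonzero(hit)[0] + sl.start
        values[idx] = np.nan
        reason[idx] = MASK_BLACKLIST
    return replace(
        track, values=values, mask_reason=reason, raw_values=track.raw_values
    )


def call_segments(
    segments,
    gain_thr: float = GAIN_THRESHOLD,
    loss_thr: float = LOSS_THRESHOLD,
    sample_id: str = "sample",
) -> CNProfile:
    """Three-state call per segment with strict threshold inequalities.

    A segment is a gain iff its mean log2 ratio is strictly above
    ``gain_thr``, a loss iff strictly below ``loss_thr``; boundary values
    are neutral.
    """
    if not gain_thr > loss_thr:
        raise ConfigurationError("gain_thr must exceed loss_thr")
    called = []
    for s in segments:
        if s.mean > gain_thr:
            call = "gain"
        elif s.mean < loss_thr:
            call = "loss"
        else:
            call = "neutral"
        called.append(replace(s, call=call))
    return CNProfile(sample_id, tuple(called), gain_thr=gain_thr, loss_thr=loss_thr)


def run_profile(
    counts: BinCounts,
    grid: BinGrid | None = None,
    blacklist: BlacklistRegions | None = None,
    gain_thr: float = GAIN_THRESHOLD,
    loss_thr: float = LOSS_THRESHOLD,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_bins_per_segment: int = 3,
    prune_tol: float = 0.05,
    max_gap: int = 10,
    seed: int = 0,
    fit: str = "poly2",
) -> tuple[CNProfile, RatioTrack]:
    """Full per-sample pipeline: normalize, mask, segment, call.

    Returns the called profile together with the masked ratio track it
    was segmented from.
    """
    track = gc_normalize(counts, grid, fit=fit)
    if blacklist is not None:
        track = apply_blacklist(track, blacklist)
    segments = segment_cbs(
        track,
        alpha=alpha,
        n_permutations=n_permutations,
        min_bins_per_segment=min_bins_per_segment,
        prune_tol=prune_tol,
        max_gap=max_gap,
        seed=seed,
    )
    profile = call_segments(
        segments, gain_thr=gain_thr, loss_thr=loss_thr, sample_id=counts.sample_id
    )
    from .qc import compute_mapd  # local import to avoid a cycle

    try:
        mapd, _ = compute_mapd(track)
    except DegenerateInputError:
        mapd = float("nan")
    logger.info(
        "stage=profile sample=%s masked_fraction=%.4f n_segments=%d mapd=%.4f",
        counts.sample_id,
        track.masked_fraction,
        len(profile.segments),
        mapd,
    )
    profile.provenance.update(
        masked_fraction=track.masked_fraction,
        n_segments=len(profile.segments),
        mapd=mapd,
        seed=seed,
    )
    return profile, track
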