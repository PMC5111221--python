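"""Base-pair-resolution comparison of copy-number profiles.

Provides pairwise concordance (fraction of compared base pairs with the
same loss/neutral/gain state), decomposition of the genome into regions
shared by subsets of samples per event type, the shared-CN-neutral
accounting identity, and correlation clustering of normalized bin values
restricted to CNA regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import AccountingError, ConfigurationError, DegenerateInputError
from .grid import BinGrid
from .profiling import BlacklistRegions, CNProfile, RatioTrack

# state codes
LOSS, NEUTRAL, GAIN, MASKED = -1, 0, 1, -9
_STATE_NAME = {LOSS: "loss", NEUTRAL: "neutral", GAIN: "gain", MASKED: "masked"}
_STATE_CODE = {v: k for k, v in _STATE_NAME.items()}


@dataclass(frozen=True)
class StateTrack:
    """Per-bin three-state call (or masked) derived from a profile."""

    grid: BinGrid
    states: np.ndarray  # int8 codes
    sample_id: str = "sample"

    @property
    def is_cna(self) -> np.ndarray:
        return (self.states == GAIN) | (self.states == LOSS)


@dataclass(frozen=True)
class ConcordanceResult:
    """Base-pair accounting of agreement between two state tracks.

    ``per_class`` maps each CNA class to (shared_bp, a_only_bp,
    b_only_bp): base pairs where both samples carry the event, and where
    only one does.  ``shared_cnv_fraction`` is shared CNA bp over all bp
    where at least one sample carries a CNA.

    The five fields ``shared_cna_bp``, ``a_only_cna_bp``, ``b_only_cna_bp``,
    ``conflict_cna_bp`` (opposite event types at the same bin) and
    ``shared_neutral_bp`` partition ``total_compared_bp`` exactly.
    """

    sample_a: str
    sample_b: str
    total_compared_bp: int
    shared_bp: int
    discordant_bp: int
    shared_neutral_bp: int
    shared_cna_bp: int
    a_only_cna_bp: int
    b_only_cna_bp: int
    conflict_cna_bp: int
    per_class: dict[str, tuple[int, int, int]]
    shared_fraction: float
    shared_cnv_fraction: float

    def to_row(self) -> dict:
        row = {
            "sample_a": self.sample_a,
            "sample_b": self.sample_b,
            "total_compared_bp": self.total_compared_bp,
            "shared_bp": self.shared_bp,
            "discordant_bp": self.discordant_bp,
            "shared_neutral_bp": self.shared_neutral_bp,
            "shared_cna_bp": self.shared_cna_bp,
            "a_only_cna_bp": self.a_only_cna_bp,
            "b_only_cna_bp": self.b_only_cna_bp,
            "conflict_cna_bp": self.conflict_cna_bp,
            "shared_fraction": self.shared_fraction,
            "shared_cnv_fraction": self.shared_cnv_fraction,
        }
        for cls, (s, a, b) in self.per_class.items():
            row[f"shared_{cls}_bp"] = s
            row[f"a_only_{cls}_bp"] = a
            row[f"b_only_{cls}_bp"] = b
        return row


@dataclass(frozen=True)
class OverlapRegion:
    chrom: str
    start: int
    end: int
    event_type: str  # 'gain' | 'loss'
    samples: frozenset[str]

    @property
    def shared(self) -> bool:
        return len(self.samples) >= 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionOverlap:
    """Maximal regions labeled by the exact sample subset carrying each event."""

    regions: tuple[OverlapRegion, ...]
    samples: tuple[str, ...]

    def shared_bp(self) -> int:
        return sum(r.length for r in self.regions if r.shared)

    def sample_only_bp(self) -> int:
        return sum(r.length for r in self.regions if not r.shared)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "event_type": r.event_type,
                    "n_samples": len(r.samples),
                    "samples": ",".join(sorted(r.samples)),
                    "shared": r.shared,
                }
                for r in self.regions
            ]
        )


def truth_to_profile(
    truth,
    grid: BinGrid,
    gain_thr: float = 0.15,
    loss_thr: float = -0.15,
    sample_id: str = "truth",
) -> CNProfile:
    """Called profile implied by a ground-truth CN partition.

    Each truth region becomes a segment whose mean is its expected log2
    ratio at the truth's purity, then the standard thresholds are applied;
    used as the reference profile in recovery experiments.
    """
    from .profiling import Segment, call_segments

    segments = []
    for chrom, s, e, cn in truth.canonicalized().regions:
        sl = grid.chrom_slice(chrom)
        n_bins = int(np.sum((grid.start[sl] >= s) & (grid.start[sl] < e)))
        segments.append(
            Segment(chrom=chrom, start=s, end=e, n_bins=max(n_bins, 1),
                    mean=truth.expected_log2(cn))
        )
    return call_segments(segments, gain_thr=gain_thr, loss_thr=loss_thr,
                         sample_id=sample_id)


def profile_to_states(profile: CNProfile, grid: BinGrid) -> StateTrack:
    """Map a segment-level profile onto grid bins by bin midpoint.

    A bin takes the call of the segment containing its midpoint; bins
    whose midpoint falls in no segment (masked gaps) are masked.
    """
    seg_chroms = {s.chrom for s in profile.segments}
    grid_chroms = set(grid.chrom_names())
    if not seg_chroms <= grid_chroms:
        raise ConfigurationError(
            f"profile chromosomes {sorted(seg_chroms - grid_chroms)} absent from grid"
        )
    states = np.full(grid.n_bins, MASKED, dtype=np.int8)
    mid = (grid.start + grid.end) // 2
    for s in profile.segments:
        if s.call is None:
            raise ConfigurationError("profile has uncalled segments")
        sl = grid.chrom_slice(s.chrom)
        hit = (mid[sl] >= s.start) & (mid[sl] < s.end)
        states[sl.start : sl.stop][hit] = _STATE_CODE[s.call]
    return StateTrack(grid, states, sample_id=profile.sample_id)


def concordance(a: StateTrack, b: StateTrack) -> ConcordanceResult:
    """Bin-quantized base-pair concordance between two state tracks.

    Bins masked in either sample are excluded from the denominator.
    Symmetric in (a, b) up to swapping the a_only/b_only fields.
    """
    if not a.grid.same_grid(b.grid):
        raise ConfigurationError("state tracks are on different grids")
    w = a.grid.widths
    both = (a.states != MASKED) & (b.states != MASKED)
    total = int(w[both].sum())
    equal = both & (a.states == b.states)
    shared = int(w[equal].sum())
    per_class = {}
    for code, name in ((GAIN, "gain"), (LOSS, "loss")):
        sa, sb = (a.states == code) & both, (b.states == code) & both
        per_class[name] = (
            int(w[sa & sb].sum()),
            int(w[sa & ~sb].sum()),
            int(w[~sa & sb].sum()),
        )
    shared_neutral = int(w[equal & (a.states == NEUTRAL)].sum())
    any_cna = both & (a.is_cna | b.is_cna)
    shared_cna = int(w[equal & a.is_cna].sum())
    a_only_cna = int(w[both & a.is_cna & (b.states == NEUTRAL)].sum())
    b_only_cna = int(w[both & b.is_cna & (a.states == NEUTRAL)].sum())
    conflict = int(w[both & a.is_cna & b.is_cna & (a.states != b.states)].sum())
    den = int(w[any_cna].sum())
    return ConcordanceResult(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        total_compared_bp=total,
        shared_bp=shared,
        discordant_bp=total - shared,
        shared_neutral_bp=shared_neutral,
        shared_cna_bp=shared_cna,
        a_only_cna_bp=a_only_cna,
        b_only_cna_bp=b_only_cna,
        conflict_cna_bp=conflict,
        per_class=per_class,
        shared_fraction=shared / total if total else float("nan"),
        shared_cnv_fraction=shared_cna / den if den else float("nan"),
    )


def shared_regions(profiles: list[CNProfile], grid: BinGrid) -> RegionOverlap:
    """Decompose called CNAs into maximal sample-subset regions.

    For each event type independently, every genomic interval is labeled
    with the exact subset of samples calling that event there; intervals
    carried by >= 2 samples are shared, by exactly 1 sample-only.
    Computed at base-pair resolution by interval sweep over segment
    boundaries.
    """
    if len(profiles) < 2:
        raise ConfigurationError("shared_regions needs >= 2 profiles")
    names = [p.sample_id for p in profiles]
    if len(set(names)) != len(names):
        raise ConfigurationError("profiles must have distinct sample_ids")
    out: list[OverlapRegion] = []
    for event in ("gain", "loss"):
        per_sample = {
            p.sample_id: {} for p in profiles
        }  # sample -> chrom -> list[(s, e)]
        chroms: set[str] = set()
        for p in profiles:
            for chrom, s, e in p.cna_intervals()[event]:
                per_sample[p.sample_id].setdefault(chrom, []).append((s, e))
                chroms.add(chrom)
        for chrom in sorted(chroms, key=grid.chrom_names().index):
            edges = sorted(
                {x for ivs in per_sample.values() for s, e in ivs.get(chrom, []) for x in (s, e)}
            )
            current: list[tuple[int, int, frozenset]] = []
            for s, e in zip(edges[:-1], edges[1:]):
                members = frozenset(
                    name
                    for name, ivs in per_sample.items()
                    if any(a <= s and e <= b for a, b in ivs.get(chrom, []))
                )
                if not members:
                    continue
                if current and current[-1][1] == s and current[-1][2] == members:
                    current[-1] = (current[-1][0], e, members)
                else:
                    current.append((s, e, members))
            out.extend(
                OverlapRegion(chrom, s, e, event, m) for s, e, m in current
            )
    return RegionOverlap(tuple(out), tuple(names))


def shared_neutral_bp(
    total_covered_bp: int, shared_cna_bp: int, sample_only_cna_bp: int
) -> int:
    """Shared copy-neutral base pairs: total minus shared and sample-only CNA."""
    if min(total_covered_bp, shared_cna_bp, sample_only_cna_bp) < 0:
        raise ConfigurationError("base-pair arguments must be non-negative")
    result = total_covered_bp - shared_cna_bp - sample_only_cna_bp
    if result < 0:
        raise AccountingError(
            "CNA base pairs exceed total covered base pairs — inconsistent inputs"
        )
    return result


@dataclass(frozen=True)
class CorrelationClustering:
    """Pairwise Pearson correlations over CNA bins plus their dendrogram."""

    correlation: pd.DataFrame
    linkage: np.ndarray
    labels: tuple[str, ...]
    n_bins_used: int

    def first_merge(self) -> frozenset[str]:
        """The pair of original samples merged first (lowest join height)."""
        for a, b in self.linkage[:, :2].astype(int):
            if a < len(self.labels) and b < len(self.labels):
                return frozenset((self.labels[a], self.labels[b]))
        raise RuntimeError("no leaf-leaf merge in dendrogram")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist):
            bl = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{bl:.6g}"
            return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{bl:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def cna_bin_correlation(
    tracks: list[RatioTrack],
    profiles: list[CNProfile],
    filter_regions: BlacklistRegions | None = None,
    linkage_method: str = "complete",
) -> CorrelationClustering:
    """Correlate samples over bins called as CNA in at least one profile.

    Normalized per-bin values are extracted from bins inside the union of
    gain/loss calls across ``profiles``, excluding bins overlapping
    ``filter_regions``; pairwise-complete Pearson correlations are
    clustered by Euclidean distance between correlation-matrix rows
    (complete linkage by default).
    """
    if len(tracks) < 2:
        raise ConfigurationError("need >= 2 samples to correlate")
    grid = tracks[0].grid
    for t in tracks[1:]:
        if not t.grid.same_grid(grid):
            raise ConfigurationError("tracks are on different grids")
    select = np.zeros(grid.n_bins, dtype=bool)
    for p in profiles:
        select |= profile_to_states(p, grid).is_cna
    if filter_regions is not None:
        for chrom, s, e in filter_regions.regions:
            if chrom not in grid._slices:
                continue
            sl = grid.chrom_slice(chrom)
            hit = (grid.start[sl] < e) & (grid.end[sl] > s)
            select[sl.start : sl.stop][hit] = False
    if int(select.sum()) < 2:
        raise DegenerateInputError("fewer than 2 usable CNA bins")
    df = pd.DataFrame(
        {t.sample_id: t.values[select] for t in tracks}
    )
    corr = df.corr(method="pearson", min_periods=2)
    Z = hierarchy.linkage(corr.to_numpy(), method=linkage_method, metric="euclidean")
    return CorrelationClustering(
        correlation=corr,
        linkage=Z,
        labels=tuple(corr.columns),
        n_bins_used=int(select.sum()),
    )
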