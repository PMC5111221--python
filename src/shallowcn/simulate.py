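"""Synthetic low-coverage read-depth data with known copy-number truth.

Counts are simulated at bin level, not read level: each bin's read count is
a negative-binomial draw whose mean reflects fold-coverage, local copy
number, tumor purity and a unimodal GC response.  This mirrors what a
read-depth CN caller consumes, and lets every downstream stage be tested
against exact ground truth.  Degradation operators emulate the two
artifact regimes of archival-tissue sequencing: whole-genome-amplification
style dropout/overdispersion and plain coverage down-sampling.

Calibration: at fold-coverage ``c`` the expected count of a full-width bin
is ``c * bin_size / read_length`` (read length defaults to 75 bp,
single-end equivalents of 75 bp paired-end reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, PlacementError
from .grid import DEFAULT_BIN_SIZE, BinGrid, build_grid

DEFAULT_READ_LENGTH = 75
# GC response is quadratic in (gc - optimum) scaled by half the plausible
# GC range, so gc_bias_strength ~ fractional depth loss at the range edge.
GC_OPTIMUM = 0.45
GC_HALF_RANGE = 0.25


@dataclass(frozen=True)
class TruthProfile:
    """Ground-truth integer copy number over a grid, with tumor purity.

    ``regions`` is an ordered partition of the genome into
    (chrom, start, end, copy_number) records; the baseline (non-event)
    copy number is 2.  The expected log2 ratio of a region with copy
    number ``c`` at purity ``p`` is ``log2((p*c + (1-p)*2) / 2)``.
    """

    regions: tuple[tuple[str, int, int, int], ...]
    purity: float = 1.0
    baseline: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ConfigurationError("purity must lie in (0, 1]")
        for _, s, e, cn in self.regions:
            if e <= s or cn < 0:
                raise ConfigurationError("invalid truth region")

    def expected_log2(self, cn: int) -> float:
        return math.log2((self.purity * cn + (1 - self.purity) * self.baseline) / 2.0)

    def canonicalized(self) -> "TruthProfile":
        """Merge adjacent same-chromosome regions with equal copy number."""
        merged: list[list] = []
        for chrom, s, e, cn in self.regions:
            if merged and merged[-1][0] == chrom and merged[-1][2] == s and merged[-1][3] == cn:
                merged[-1][2] = e
            else:
                merged.append([chrom, s, e, cn])
        return TruthProfile(tuple(tuple(r) for r in merged), self.purity, self.baseline)

    def cn_per_bin(self, grid: BinGrid) -> np.ndarray:
        """Copy number of each grid bin (by bin midpoint)."""
        cn = np.full(grid.n_bins, self.baseline, dtype=np.int64)
        mid = (grid.start + grid.end) // 2
        for chrom, s, e, c in self.regions:
            sl = grid.chrom_slice(chrom)
            hit = (mid[sl] >= s) & (mid[sl] < e)
            cn[sl.start : sl.stop][hit] = c
        return cn

    def expected_log2_per_bin(self, grid: BinGrid) -> np.ndarray:
        cn = self.cn_per_bin(grid)
        return np.log2((self.purity * cn + (1 - self.purity) * self.baseline) / 2.0)

    def event_regions(self) -> list[tuple[str, int, int, int]]:
        return [r for r in self.regions if r[3] != self.baseline]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the count simulator.

    mean_coverage
        Genome-wide fold coverage of the diploid baseline.
    dispersion
        Negative-binomial size parameter; variance is mu + mu^2/dispersion,
        so large values approach Poisson counting noise.  The default of
        100 adds ~10% extra-Poisson coefficient of variation per bin,
        reproducing the bin-to-bin noise (MAPD ~ 0.15) of acceptable
        FFPE shallow-WGS libraries at ~1-2x coverage.
    gc_bias_strength
        Amplitude of the unimodal (inverted-quadratic) GC response; 0
        disables GC bias.
    dropout_fraction
        Fraction of bins independently forced to zero count, emulating
        amplification dropout.
    read_length
        Base pairs per read used to convert fold coverage to counts.
    """

    mean_coverage: float = 1.3
    dispersion: float = 100.0
    gc_bias_strength: float = 0.0
    dropout_fraction: float = 0.0
    read_length: int = DEFAULT_READ_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ConfigurationError("mean_coverage must be > 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if not (0 <= self.dropout_fraction < 1):
            raise ConfigurationError("dropout_fraction must lie in [0, 1)")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be > 0")


@dataclass(frozen=True)
class BinCounts:
    """Raw per-bin read counts for one sample on a grid."""

    grid: BinGrid
    counts: np.ndarray  # int64, >= 0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if len(self.counts) != self.grid.n_bins:
            raise ConfigurationError("counts length does not match grid")
        if np.any(self.counts < 0):
            raise ConfigurationError("counts must be non-negative")

    @property
    def mean_coverage(self) -> float:
        """Realized fold coverage implied by the default read length."""
        return float(self.counts.sum() * DEFAULT_READ_LENGTH / self.grid.widths.sum())


def simulate_grid(
    n_chromosomes: int,
    chromosome_length_bp: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    gc_profile_seed: int = 0,
) -> BinGrid:
    """Build a grid of equal-length chromosomes with a smooth GC landscape.

    GC fractions follow a stationary AR(1) process (lag-1 correlation 0.9)
    mapped to [0.3, 0.7], giving the long-range GC autocorrelation real
    genomes show at 50 kb resolution.
    """
    if n_chromosomes < 1:
        raise ConfigurationError("n_chromosomes must be >= 1")
    if bin_size <= 0 or chromosome_length_bp < bin_size:
        raise ConfigurationError("chromosome length must be >= bin_size > 0")
    chromosomes = [(f"chr{i+1}", chromosome_length_bp) for i in range(n_chromosomes)]
    n_per = -(-chromosome_length_bp // bin_size)  # ceil
    rng = np.random.default_rng(gc_profile_seed)
    rho = 0.9
    gc_parts = []
    for _ in range(n_chromosomes):
        z = np.empty(n_per)
        z[0] = rng.standard_normal()
        eps = rng.standard_normal(n_per - 1) if n_per > 1 else np.empty(0)
        for t in range(1, n_per):
            z[t] = rho * z[t - 1] + math.sqrt(1 - rho**2) * eps[t - 1]
        gc_parts.append(np.clip(0.5 + 0.08 * z, 0.3, 0.7))
    return build_grid(chromosomes, bin_size, np.concatenate(gc_parts))


def simulate_truth(
    grid: BinGrid,
    n_events: int,
    event_size_range_bp: tuple[int, int],
    cn_states: tuple[int, ...] = (1, 3),
    purity: float = 1.0,
    seed: int = 0,
    max_retries: int = 1000,
) -> TruthProfile:
    """Place non-overlapping integer-CN events on a diploid background.

    Events are snapped to bin boundaries (the native resolution of the
    pipeline) and drawn uniformly over chromosomes weighted by length.
    """
    states = tuple(sorted(set(int(c) for c in cn_states)))
    if not states or any(c < 0 for c in states) or 2 in states:
        raise ConfigurationError("cn_states must be non-negative integers != 2")
    lo, hi = event_size_range_bp
    if lo < grid.bin_size or hi < lo:
        raise ConfigurationError("event sizes must span >= 1 bin and lo <= hi")
    rng = np.random.default_rng(seed)
    lengths = np.array([l for _, l in grid.chromosomes], dtype=float)
    names = grid.chrom_names()
    placed: dict[str, list[tuple[int, int, int]]] = {n: [] for n in names}
    bs = grid.bin_size
    for _ in range(n_events):
        ok = False
        for _attempt in range(max_retries):
            ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
            chrom, clen = grid.chromosomes[ci]
            size = bs * max(1, int(round(rng.uniform(lo, hi) / bs)))
            if size > clen:
                continue
            start = bs * int(rng.integers(0, (clen - size) // bs + 1))
            end = min(start + size, clen)
            if any(s < end and start < e for s, e, _ in placed[chrom]):
                continue
            cn = int(states[rng.integers(len(states))])
            placed[chrom].append((start, end, cn))
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place {n_events} non-overlapping events"
            )
    regions: list[tuple[str, int, int, int]] = []
    for chrom, clen in grid.chromosomes:
        pos = 0
        for s, e, cn in sorted(placed[chrom]):
            if s > pos:
                regions.append((chrom, pos, s, 2))
            regions.append((chrom, s, e, cn))
            pos = e
        if pos < clen:
            regions.append((chrom, pos, clen, 2))
    return TruthProfile(tuple(regions), purity=purity).canonicalized()


def gc_response(gc: np.ndarray, strength: float) -> np.ndarray:
    """Unimodal (inverted quadratic) GC depth response, normalized to mean 1."""
    raw = 1.0 - strength * ((np.asarray(gc, dtype=float) - GC_OPTIMUM) / GC_HALF_RANGE) ** 2
    raw = np.clip(raw, 0.05, None)
    return raw / raw.mean()


def simulate_counts(
    grid: BinGrid, truth: TruthProfile, config: SimulationConfig,
    sample_id: str = "sim",
) -> BinCounts:
    """Draw negative-binomial per-bin counts under a truth profile.

    The per-bin mean is
    ``r * width/bin_size * (purity*CN + (1-purity)*2)/2 * g(gc)``
    with ``r = mean_coverage * bin_size / read_length`` and ``g`` the
    mean-1 GC response; then ``dropout_fraction`` of bins are zeroed.
    """
    rng = np.random.default_rng(config.seed)
    r = config.mean_coverage * grid.bin_size / config.read_length
    cn = truth.cn_per_bin(grid)
    tumor_factor = (truth.purity * cn + (1 - truth.purity) * truth.baseline) / 2.0
    g = gc_response(grid.gc, config.gc_bias_strength)
    mu = r * (grid.widths / grid.bin_size) * tumor_factor * g
    counts = _nb_draw(rng, mu, config.dispersion)
    if config.dropout_fraction > 0:
        counts[rng.random(grid.n_bins) < config.dropout_fraction] = 0
    return BinCounts(grid, counts, sample_id=sample_id)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean=mu, size=dispersion) draws; mu=0 bins stay 0."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(len(mu), dtype=np.int64)
    pos = mu > 0
    p = dispersion / (dispersion + mu[pos])
    out[pos] = rng.negative_binomial(dispersion, p)
    return out


def degrade_wga(
    counts: BinCounts,
    extra_dispersion_factor: float = 4.0,
    dropout_fraction: float = 0.85,
    seed: int = 0,
) -> BinCounts:
    """Emulate whole-genome-amplification damage on a count track.

    Each bin count c is resampled as Poisson(c * m) with a mean-1 gamma
    multiplier m of variance (factor - 1), inflating the conditional
    variance to c + (factor - 1) c^2 while preserving the marginal mean;
    then ``dropout_fraction`` of bins are zeroed.  A factor of exactly 1
    with zero dropout is the identity.
    """
    if extra_dispersion_factor < 1:
        raise ConfigurationError("extra_dispersion_factor must be >= 1")
    if not (0 <= dropout_fraction < 1):
        raise ConfigurationError("dropout_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    c = counts.counts.astype(float)
    if extra_dispersion_factor > 1:
        var = extra_dispersion_factor - 1.0
        m = rng.gamma(shape=1.0 / var, scale=var, size=len(c))
        new = rng.poisson(c * m).astype(np.int64)
    else:
        new = counts.counts.copy()
    if dropout_fraction > 0:
        new[rng.random(len(new)) < dropout_fraction] = 0
    return replace(counts, counts=new, sample_id=counts.sample_id + "-wga")


def downsample_counts(counts: BinCounts, fraction: float, seed: int = 0) -> BinCounts:
    """Thin each bin count binomially, emulating read down-sampling."""
    if not (0 < fraction <= 1):
        raise ConfigurationError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    new = rng.binomial(counts.counts, fraction).astype(np.int64)
    return replace(
        counts, counts=new, sample_id=f"{counts.sample_id}-ds{fraction:g}"
    )


def write_fixture_sam(
    path,
    grid: BinGrid,
    reads: list[tuple[str, int, int, bool]],
    read_length: int = DEFAULT_READ_LENGTH,
) -> None:
    """Write a minimal coordinate-sorted single-end SAM for adapter tests.

    ``reads`` are (chrom, 0-based position, mapq, is_duplicate) records;
    they are sorted into coordinate order before writing.
    """
    order = {name: i for i, name in enumerate(grid.chrom_names())}
    reads = sorted(reads, key=lambda r: (order[r[0]], r[1]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in grid.chromosomes:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for i, (chrom, pos, mapq, dup) in enumerate(reads):
            flag = 1024 if dup else 0
            seq = "A" * read_length
            qual = "I" * read_length
            fh.write(
                f"read{i}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t{read_length}M\t"
                f"*\t0\t0\t{seq}\t{qual}\n"
            )
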