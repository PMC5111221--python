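"""Simulation experiments validating the pipeline end to end.

Each function mirrors one of the study designs the pipeline is meant for —
input-titration/down-sampling recovery, WGA degradation contrast,
profile-overlap accounting, replicate clustering — run on synthetic data
with known truth, plus oracle cross-checks of the MAPD and CBS primitives.
All randomness derives from a single seed via fixed offsets.

Problem sizes default to desk scale (a few thousand 50 kb bins, tens of
replicates); every knob is exposed so larger runs are one call away.
"""

from __future__ import annotations

import numpy as np

from .cbs import segment_cbs
from .compare import cna_bin_correlation, concordance, profile_to_states, truth_to_profile
from .errors import DegenerateInputError
from .grid import build_grid
from .profiling import RatioTrack, gc_normalize, run_profile
from .qc import compute_mapd
from .simulate import (
    SimulationConfig,
    degrade_wga,
    downsample_counts,
    simulate_counts,
    simulate_grid,
    simulate_truth,
)


def _track_from_values(values_by_chrom, sample_id="t") -> RatioTrack:
    values_by_chrom = [v for v in values_by_chrom if len(v)] or [[0.0]]
    chroms = [(f"chr{i+1}", len(v) * 50_000)
              for i, v in enumerate(values_by_chrom)]
    values = np.concatenate([np.asarray(v, float) for v in values_by_chrom])
    grid = build_grid(chroms, 50_000, np.full(len(values), 0.5))
    reason = np.full(len(values), None, dtype=object)
    reason[~np.isfinite(values)] = "user"
    return RatioTrack(grid, values, reason, sample_id=sample_id)


def mapd_bruteforce(values_by_chrom) -> float:
    """Brute-force MAPD: explicit per-chromosome |x_{i+1}-x_i| list, explicit
    even-count-midpoint median.  Raises ValueError when no pair exists."""
    diffs: list[float] = []
    for vals in values_by_chrom:
        vals = [v for v in vals if np.isfinite(v)]
        diffs.extend(abs(b - a) for a, b in zip(vals, vals[1:]))
    if not diffs:
        raise ValueError("no usable marker pair")
    diffs.sort()
    n = len(diffs)
    return diffs[n // 2] if n % 2 else 0.5 * (diffs[n // 2 - 1] + diffs[n // 2])


def random_marker_tracks(seed: int, n_tracks: int = 1000):
    """Random multi-chromosome marker tracks with missing values, as
    per-chromosome value lists (lengths 2-10,000 markers in total)."""
    rng = np.random.default_rng(seed)
    for _ in range(n_tracks):
        # log-uniform marker totals in [2, 10000]
        total = max(2, int(np.exp(rng.uniform(np.log(2), np.log(10_000)))))
        n_chrom = int(rng.integers(1, 5))
        sizes = rng.multinomial(total, np.ones(n_chrom) / n_chrom)
        track = []
        for size in sizes:
            vals = rng.normal(0, 1, size)
            vals[rng.random(size) < rng.uniform(0, 0.3)] = np.nan
            track.append(vals)
        yield track


def mapd_oracle_agreement(seed: int, n_tracks: int = 1000) -> dict:
    """Fraction of random tracks where compute_mapd equals brute force exactly."""
    agree = total = 0
    for values in random_marker_tracks(seed, n_tracks):
        track = _track_from_values(values)
        try:
            expected = mapd_bruteforce(values)
        except ValueError:
            try:
                compute_mapd(track)
            except DegenerateInputError:
                agree += 1
            total += 1
            continue
        got, _ = compute_mapd(track)
        agree += got == expected
        total += 1
    return {"agreement_fraction": agree / total, "n": total}


def exhaustive_split_t(x: np.ndarray, min_bins: int = 3) -> int | None:
    """Oracle: argmax split of the two-sample pooled-variance t statistic."""
    n = len(x)
    best_t, best_c = -np.inf, None
    for c in range(min_bins, n - min_bins + 1):
        a, b = x[:c], x[c:]
        va = a.var(ddof=1) if len(a) > 1 else 0.0
        vb = b.var(ddof=1) if len(b) > 1 else 0.0
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / (n - 2)
        if sp2 <= 0:
            continue
        t = abs(a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        if t > best_t:
            best_t, best_c = t, c
    return best_c


def cbs_breakpoint_accuracy(seed: int, n_cases: int = 200) -> dict:
    """Single-changepoint chromosomes (<=120 bins, step >= 5x noise sd):
    fraction where the CBS breakpoint is within +-1 bin of the exhaustive
    max-t oracle; constant chromosomes must return one segment."""
    rng = np.random.default_rng(seed)
    hits = 0
    for case in range(n_cases):
        n = int(rng.integers(30, 121))
        cut = int(rng.integers(8, n - 8))
        sd = rng.uniform(0.05, 0.2)
        step = rng.uniform(5 * sd, 10 * sd) * rng.choice([-1, 1])
        x = rng.normal(0, sd, n)
        x[cut:] += step
        track = _track_from_values([x])
        segs = sorted(segment_cbs(track, seed=seed + case),
                      key=lambda s: s.start)
        oracle = exhaustive_split_t(x)
        got = {s.start // 50_000 for s in segs[1:]}
        hits += any(abs(g - oracle) <= 1 for g in got)
    # noiseless constant chromosomes always give one segment
    flat = _track_from_values([np.zeros(100)])
    constant_ok = len(segment_cbs(flat, seed=seed)) == 1
    return {"within_1bin_fraction": hits / n_cases, "n": n_cases,
            "constant_single_segment": constant_ok}


def _standard_genome(seed: int):
    grid = simulate_grid(6, 12_000_000, 50_000, gc_profile_seed=seed)
    truth = simulate_truth(grid, 8, (2_500_000, 3_500_000),
                           cn_states=(1, 3, 4), seed=seed + 10_000)
    return grid, truth


def _truth_concordance(profile, truth, grid) -> float:
    ref = profile_to_states(truth_to_profile(truth, grid), grid)
    return concordance(profile_to_states(profile, grid), ref).shared_fraction


def titration_experiment(seed: int, n_seeds: int = 10,
                         coverages=(2.2, 1.3, 0.6)) -> dict:
    """Profile at high coverage, down-sample to lower depths, re-profile.

    Reports mean bin-level three-state concordance of each down-sampled
    profile against the full-depth profile, and of every profile against
    truth."""
    full_cov = coverages[0]
    vs_full = {c: [] for c in coverages[1:]}
    vs_truth = {c: [] for c in coverages}
    for rep in range(n_seeds):
        grid, truth = _standard_genome(seed + rep)
        counts = simulate_counts(
            grid, truth,
            SimulationConfig(mean_coverage=full_cov, gc_bias_strength=0.3,
                             seed=seed + 20_000 + rep))
        prof_full, _ = run_profile(counts, seed=seed + 30_000 + rep)
        states_full = profile_to_states(prof_full, grid)
        vs_truth[full_cov].append(_truth_concordance(prof_full, truth, grid))
        for cov in coverages[1:]:
            thinned = downsample_counts(counts, cov / full_cov,
                                        seed=seed + 40_000 + rep)
            prof, _ = run_profile(thinned, seed=seed + 50_000 + rep)
            vs_full[cov].append(
                concordance(profile_to_states(prof, grid),
                            states_full).shared_fraction)
            vs_truth[cov].append(_truth_concordance(prof, truth, grid))
    return {
        "mean_concordance_vs_full": {c: float(np.mean(v))
                                     for c, v in vs_full.items()},
        "mean_concordance_vs_truth": {c: float(np.mean(v))
                                      for c, v in vs_truth.items()},
        "n": n_seeds,
    }


def wga_contrast(seed: int, n_pairs: int = 20,
                 extra_dispersion_factor: float = 4.0,
                 dropout_fraction: float = 0.85) -> dict:
    """Paired unamplified vs WGA-degraded simulations.

    Reports in how many pairs the degraded sample has strictly higher
    MAPD, and the mean drop in truth concordance caused by degradation."""
    mapd_higher = 0
    drops = []
    for rep in range(n_pairs):
        # larger genome than the titration runs: with 85% dropout the
        # degraded sample must still clear the GC-fit's non-zero-bin floor
        grid = simulate_grid(8, 15_000_000, 50_000,
                             gc_profile_seed=seed + 500 + rep)
        truth = simulate_truth(grid, 8, (2_500_000, 3_500_000),
                               cn_states=(1, 3, 4), seed=seed + 10_500 + rep)
        counts = simulate_counts(
            grid, truth,
            SimulationConfig(mean_coverage=2.2, gc_bias_strength=0.3,
                             seed=seed + 60_000 + rep))
        wga = degrade_wga(counts, extra_dispersion_factor, dropout_fraction,
                          seed=seed + 70_000 + rep)
        m0, _ = compute_mapd(gc_normalize(counts))
        m1, _ = compute_mapd(gc_normalize(wga))
        mapd_higher += m1 > m0
        prof0, _ = run_profile(counts, seed=seed + 80_000 + rep)
        prof1, _ = run_profile(wga, seed=seed + 90_000 + rep)
        drops.append(_truth_concordance(prof0, truth, grid)
                     - _truth_concordance(prof1, truth, grid))
    return {"mapd_higher_pairs": mapd_higher, "n": n_pairs,
            "mean_truth_concordance_drop": float(np.mean(drops))}


def accounting_identity_check(seed: int, n_pairs: int = 50) -> dict:
    """Random truth-profile pairs: shared + a-only + b-only + shared-neutral
    base pairs must reproduce the compared total exactly, and concordance
    must be symmetric."""
    holds = symmetric = 0
    for rep in range(n_pairs):
        grid = simulate_grid(3, 15_000_000, 50_000, gc_profile_seed=seed + rep)
        ta = simulate_truth(grid, 4, (1_000_000, 3_000_000),
                            cn_states=(1, 3, 4), seed=seed + 1000 + rep)
        tb = simulate_truth(grid, 4, (1_000_000, 3_000_000),
                            cn_states=(1, 3, 4), seed=seed + 2000 + rep)
        a = profile_to_states(truth_to_profile(ta, grid, sample_id="a"), grid)
        b = profile_to_states(truth_to_profile(tb, grid, sample_id="b"), grid)
        res, rev = concordance(a, b), concordance(b, a)
        holds += (
            res.shared_cna_bp + res.a_only_cna_bp + res.b_only_cna_bp
            + res.conflict_cna_bp + res.shared_neutral_bp
            == res.total_compared_bp
        )
        symmetric += (
            res.shared_fraction == rev.shared_fraction
            and res.total_compared_bp == rev.total_compared_bp
            and res.conflict_cna_bp == rev.conflict_cna_bp
            and res.a_only_cna_bp == rev.b_only_cna_bp
            and res.b_only_cna_bp == rev.a_only_cna_bp
            and all(res.per_class[c][0] == rev.per_class[c][0]
                    for c in ("gain", "loss"))
        )
    return {"identity_holds": holds, "symmetric": symmetric, "n": n_pairs}


def clustering_sanity(seed: int, n_trials: int = 20) -> dict:
    """Two same-truth replicates vs one different-truth sample: in how many
    trials do the replicates merge first in the dendrogram."""
    first = 0
    for rep in range(n_trials):
        grid = simulate_grid(3, 10_000_000, 50_000, gc_profile_seed=seed + rep)
        truth = simulate_truth(grid, 3, (1_500_000, 3_000_000),
                               cn_states=(1, 3, 4), seed=seed + 3000 + rep)
        other = simulate_truth(grid, 3, (1_500_000, 3_000_000),
                               cn_states=(1, 3, 4), seed=seed + 4000 + rep)
        tracks, profiles = [], []
        for name, t, s in (("rep1", truth, 1), ("rep2", truth, 2),
                           ("other", other, 3)):
            counts = simulate_counts(
                grid, t,
                SimulationConfig(mean_coverage=1.3, gc_bias_strength=0.3,
                                 seed=seed + 5000 + 10 * rep + s),
                sample_id=name)
            prof, track = run_profile(counts, seed=seed + 6000 + 10 * rep + s)
            tracks.append(track)
            profiles.append(prof)
        result = cna_bin_correlation(tracks, profiles)
        first += result.first_merge() == frozenset({"rep1", "rep2"})
    return {"replicates_merge_first": first, "n": n_trials}
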