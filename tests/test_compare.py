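"""Concordance, shared/unique region decomposition and correlation clustering."""

import numpy as np
import pytest

import shallowcn as sc
from shallowcn.errors import (
    AccountingError,
    ConfigurationError,
    DegenerateInputError,
)

from conftest import make_track, uniform_profile


def profile_from_calls(grid, calls, sample_id="p"):
    """Build a called profile from a per-bin call list on a one-chrom grid."""
    segs = []
    i = 0
    while i < len(calls):
        j = i
        while j < len(calls) and calls[j] == calls[i]:
            j += 1
        mean = {"gain": 0.5, "loss": -0.5, "neutral": 0.0}[calls[i]]
        segs.append(sc.Segment("chr1", i * 50_000, j * 50_000, j - i, mean))
        i = j
    return sc.call_segments(segs, sample_id=sample_id)


class TestProfileToStates:
    def test_all_neutral(self, small_grid):
        prof = uniform_profile(small_grid, 0.0)
        st = sc.profile_to_states(prof, small_grid)
        assert np.all(st.states == 0)

    def test_direct_mapping(self, small_grid):
        prof = profile_from_calls(small_grid, ["gain"] * 5 + ["neutral"] * 5)
        st = sc.profile_to_states(prof, small_grid)
        assert list(st.states) == [1] * 5 + [0] * 5

    def test_midpoint_in_gap_is_masked(self, small_grid):
        segs = [sc.Segment("chr1", 0, 250_000, 5, 0.0),
                sc.Segment("chr1", 300_000, 500_000, 4, 0.0)]
        prof = sc.call_segments(segs)
        st = sc.profile_to_states(prof, small_grid)
        assert st.states[5] == -9  # bin [250k,300k) midpoint uncovered
        assert np.sum(st.states == -9) == 1

    def test_unknown_chromosome_rejected(self, small_grid):
        prof = sc.call_segments([sc.Segment("chrZ", 0, 100_000, 2, 0.0)])
        with pytest.raises(ConfigurationError):
            sc.profile_to_states(prof, small_grid)


class TestConcordance:
    def test_self_concordance_is_one(self, small_grid):
        prof = profile_from_calls(small_grid, ["gain"] * 3 + ["neutral"] * 7)
        st = sc.profile_to_states(prof, small_grid)
        res = sc.concordance(st, st)
        assert res.shared_fraction == 1.0
        assert res.shared_cnv_fraction == 1.0

    def test_enumerated_example(self, small_grid):
        # a: gain bins 0-4; b: gain bins 0-1; rest neutral
        a = sc.profile_to_states(
            profile_from_calls(small_grid, ["gain"] * 5 + ["neutral"] * 5, "a"),
            small_grid)
        b = sc.profile_to_states(
            profile_from_calls(small_grid, ["gain"] * 2 + ["neutral"] * 8, "b"),
            small_grid)
        res = sc.concordance(a, b)
        assert res.shared_fraction == pytest.approx(7 / 10)
        assert res.shared_cnv_fraction == pytest.approx(2 / 5)

    def test_total_discordance(self, small_grid):
        a = sc.profile_to_states(uniform_profile(small_grid, 0.5, "a"), small_grid)
        b = sc.profile_to_states(uniform_profile(small_grid, -0.5, "b"), small_grid)
        res = sc.concordance(a, b)
        assert res.shared_fraction == 0.0

    def test_symmetry(self, small_grid):
        a = sc.profile_to_states(
            profile_from_calls(small_grid,
                               ["gain"] * 3 + ["loss"] * 2 + ["neutral"] * 5, "a"),
            small_grid)
        b = sc.profile_to_states(
            profile_from_calls(small_grid,
                               ["neutral"] * 4 + ["loss"] * 3 + ["gain"] * 3, "b"),
            small_grid)
        ab, ba = sc.concordance(a, b), sc.concordance(b, a)
        assert ab.shared_fraction == ba.shared_fraction
        assert ab.shared_cnv_fraction == ba.shared_cnv_fraction
        assert ab.total_compared_bp == ba.total_compared_bp
        for cls in ("gain", "loss"):
            s1, a1, b1 = ab.per_class[cls]
            s2, a2, b2 = ba.per_class[cls]
            assert (s1, a1, b1) == (s2, b2, a2)

    def test_masked_bins_excluded_from_denominator(self, small_grid):
        segs = [sc.Segment("chr1", 0, 400_000, 8, 0.0)]  # last 2 bins uncovered
        a = sc.profile_to_states(sc.call_segments(segs, sample_id="a"), small_grid)
        b = sc.profile_to_states(uniform_profile(small_grid, 0.0, "b"), small_grid)
        res = sc.concordance(a, b)
        assert res.total_compared_bp == 400_000

    def test_accounting_identity(self, small_grid):
        a = sc.profile_to_states(
            profile_from_calls(small_grid,
                               ["gain"] * 4 + ["loss"] * 2 + ["neutral"] * 4, "a"),
            small_grid)
        b = sc.profile_to_states(
            profile_from_calls(small_grid,
                               ["gain"] * 2 + ["neutral"] * 6 + ["loss"] * 2, "b"),
            small_grid)
        res = sc.concordance(a, b)
        only_cna = res.a_only_cna_bp + res.b_only_cna_bp + res.conflict_cna_bp
        neutral = sc.shared_neutral_bp(
            res.total_compared_bp, res.shared_cna_bp, only_cna)
        # bins counted once each: shared CNA + unique CNA + neutral = total
        assert res.shared_cna_bp + only_cna + neutral == res.total_compared_bp
        assert neutral == res.shared_neutral_bp


class TestSharedRegions:
    def test_identical_profiles_single_shared_region(self, small_grid):
        a = profile_from_calls(small_grid, ["gain"] * 4 + ["neutral"] * 6, "a")
        b = profile_from_calls(small_grid, ["gain"] * 4 + ["neutral"] * 6, "b")
        ov = sc.shared_regions([a, b], small_grid)
        assert len(ov.regions) == 1
        r = ov.regions[0]
        assert (r.chrom, r.start, r.end, r.event_type) == ("chr1", 0, 200_000, "gain")
        assert r.shared and ov.sample_only_bp() == 0

    def test_partial_overlap_decomposition(self, small_grid):
        # gains A:[0,300kb), B:[200kb,500kb)
        a = profile_from_calls(small_grid, ["gain"] * 6 + ["neutral"] * 4, "a")
        b = profile_from_calls(small_grid,
                               ["neutral"] * 4 + ["gain"] * 6, "b")
        ov = sc.shared_regions([a, b], small_grid)
        got = {(r.start, r.end, frozenset(r.samples)) for r in ov.regions}
        assert got == {
            (0, 200_000, frozenset({"a"})),
            (200_000, 300_000, frozenset({"a", "b"})),
            (300_000, 500_000, frozenset({"b"})),
        }

    def test_event_type_must_match(self, small_grid):
        a = profile_from_calls(small_grid, ["gain"] * 5 + ["neutral"] * 5, "a")
        b = profile_from_calls(small_grid, ["loss"] * 5 + ["neutral"] * 5, "b")
        ov = sc.shared_regions([a, b], small_grid)
        assert all(not r.shared for r in ov.regions)
        assert len(ov.regions) == 2

    def test_fewer_than_two_profiles_rejected(self, small_grid):
        a = profile_from_calls(small_grid, ["gain"] * 5 + ["neutral"] * 5, "a")
        with pytest.raises(ConfigurationError):
            sc.shared_regions([a], small_grid)

    def test_conservation_against_concordance(self):
        # interval accounting agrees with bin-level concordance accounting
        grid = sc.simulate_grid(2, 20_000_000, 50_000, gc_profile_seed=5)
        for seed in range(5):
            ta = sc.simulate_truth(grid, 3, (1_000_000, 3_000_000), seed=seed)
            tb = sc.simulate_truth(grid, 3, (1_000_000, 3_000_000), seed=50 + seed)
            pa = sc.truth_to_profile(ta, grid, sample_id="a")
            pb = sc.truth_to_profile(tb, grid, sample_id="b")
            ov = sc.shared_regions([pa, pb], grid)
            res = sc.concordance(sc.profile_to_states(pa, grid),
                                 sc.profile_to_states(pb, grid))
            shared_cna = sum(res.per_class[c][0] for c in ("gain", "loss"))
            only_cna = sum(res.per_class[c][1] + res.per_class[c][2]
                           for c in ("gain", "loss"))
            gg = ov.to_frame()
            both = gg[gg.n_samples >= 2]
            # shared-region bp where both carry the same event type
            assert int((both.end - both.start).sum()) == shared_cna
            assert ov.shared_bp() + ov.sample_only_bp() >= shared_cna + only_cna


class TestSharedNeutralBp:
    def test_stated_arithmetic(self):
        assert sc.shared_neutral_bp(100, 30, 15) == 55

    def test_no_cna(self):
        assert sc.shared_neutral_bp(100, 0, 0) == 100

    def test_negative_result_is_accounting_error(self):
        with pytest.raises(AccountingError):
            sc.shared_neutral_bp(100, 80, 30)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ConfigurationError):
            sc.shared_neutral_bp(-1, 0, 0)


class TestCnaBinCorrelation:
    def _tracks_profiles(self, grid, seeds, truths):
        tracks, profiles = [], []
        for seed, truth in zip(seeds, truths):
            counts = sc.simulate_counts(
                grid, truth,
                sc.SimulationConfig(mean_coverage=1.3, seed=seed),
                sample_id=f"s{seed}")
            prof, track = sc.run_profile(counts, seed=seed + 1)
            tracks.append(track)
            profiles.append(prof)
        return tracks, profiles

    def test_duplicated_sample_merges_first(self):
        grid = sc.simulate_grid(3, 15_000_000, 50_000, gc_profile_seed=6)
        truth = sc.simulate_truth(grid, 3, (1_500_000, 3_000_000), seed=7)
        other = sc.simulate_truth(grid, 3, (1_500_000, 3_000_000), seed=77)
        tracks, profiles = self._tracks_profiles(grid, [1, 2], [truth, other])
        dup = sc.RatioTrack(grid, tracks[0].values.copy(),
                            tracks[0].mask_reason.copy(), sample_id="dup")
        result = sc.cna_bin_correlation(tracks + [dup], profiles)
        assert result.correlation.loc["s1", "dup"] == pytest.approx(1.0)
        assert result.first_merge() == frozenset({"s1", "dup"})

    def test_anticorrelated_tracks(self, small_grid):
        prof = profile_from_calls(small_grid, ["gain"] * 10, "a")
        x = np.linspace(-1, 1, 10)
        a = make_track(small_grid, x, "a")
        b = make_track(small_grid, -x, "b")
        result = sc.cna_bin_correlation([a, b], [prof])
        assert result.correlation.loc["a", "b"] <= -0.99

    def test_correlation_matrix_properties(self):
        grid = sc.simulate_grid(2, 15_000_000, 50_000, gc_profile_seed=8)
        truths = [sc.simulate_truth(grid, 2, (1_500_000, 3_000_000), seed=s)
                  for s in (1, 2, 3)]
        tracks, profiles = self._tracks_profiles(grid, [11, 12, 13], truths)
        res = sc.cna_bin_correlation(tracks, profiles)
        m = res.correlation.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        # clustering invariant to sample order
        res2 = sc.cna_bin_correlation(tracks[::-1], profiles)
        assert res.first_merge() == res2.first_merge()

    def test_filter_regions_and_degenerate(self, small_grid):
        prof = profile_from_calls(small_grid, ["gain"] * 2 + ["neutral"] * 8, "a")
        a = make_track(small_grid, np.arange(10.0), "a")
        b = make_track(small_grid, np.arange(10.0), "b")
        bl = sc.BlacklistRegions.from_intervals([("chr1", 0, 100_000)])
        with pytest.raises(DegenerateInputError):
            sc.cna_bin_correlation([a, b], [prof], filter_regions=bl)

    def test_newick_output_contains_all_labels(self):
        grid = sc.simulate_grid(2, 15_000_000, 50_000, gc_profile_seed=9)
        truths = [sc.simulate_truth(grid, 2, (1_500_000, 3_000_000), seed=s)
                  for s in (4, 5, 6)]
        tracks, profiles = self._tracks_profiles(grid, [21, 22, 23], truths)
        res = sc.cna_bin_correlation(tracks, profiles)
        nwk = res.to_newick()
        assert nwk.endswith(";")
        for label in res.labels:
            assert label in nwk
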