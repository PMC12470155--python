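"""Anchor-centered environment profiles: masking, weighting, truth recovery."""

import numpy as np
import pytest

from dnascape import (AnchorFlankSpec, GenomeSpec, Interval, count_dinucleotides,
                      generate_genome, place_anchors, profile, profile_tracks)
from dnascape.profiles import EnvironmentProfile, ProfileConfig
from dnascape.tracks import BinnedTrack
from dnascape._seq import DINUCLEOTIDES


class TestProfileBasics:
    def test_constant_track_gives_constant_profile(self):
        track = BinnedTrack("c1", 1000, np.full(200, 7.0))
        anchors = [Interval("c1", p, p + 10) for p in (50_000, 100_000, 150_000)]
        prof = profile(track, anchors, ProfileConfig(half_width=20_000))
        ok = prof.weight > 0
        np.testing.assert_allclose(prof.mean[ok], 7.0)
        two = ok & (prof.n_anchors >= 2)
        np.testing.assert_allclose(prof.variance[two], 0.0, atol=1e-18)

    def test_distances_grid(self):
        track = BinnedTrack("c1", 1000, np.zeros(100))
        prof = profile(track, [Interval("c1", 50_000, 50_010)],
                       ProfileConfig(half_width=10_000))
        assert prof.distances[0] == -10_000
        assert prof.distances[-1] == 10_000
        assert prof.distances[prof.center_index] == 0

    def test_half_width_must_be_multiple_of_resolution(self):
        track = BinnedTrack("c1", 1000, np.zeros(100))
        with pytest.raises(ValueError, match="multiple"):
            profile(track, [Interval("c1", 50_000, 50_010)],
                    ProfileConfig(half_width=10_500))

    def test_no_usable_anchors_rejected(self):
        track = BinnedTrack("c1", 1000, np.zeros(100))
        with pytest.raises(ValueError, match="chromosome"):
            profile(track, [Interval("c9", 50_000, 50_010)],
                    ProfileConfig(half_width=10_000))

    def test_half_width_beyond_chromosome_warns_and_truncates(self):
        track = BinnedTrack("c1", 1000, np.arange(50.0))
        with pytest.warns(UserWarning, match="half-width"):
            prof = profile(track, [Interval("c1", 25_000, 25_010)],
                           ProfileConfig(half_width=60_000))
        far = np.abs(prof.distances) > 30_000
        assert np.all(prof.weight[far] == 0)


class TestInteriorMasking:
    def make_case(self):
        # value = bin index, so every contribution is identifiable
        track = BinnedTrack("c1", 1000, np.arange(40.0))
        # two anchors 10 kbp apart, each filling its whole bin
        anchors = [Interval("c1", 5000, 6000), Interval("c1", 15_000, 16_000)]
        return track, anchors

    def test_neighbor_interior_excluded_when_masked(self):
        track, anchors = self.make_case()
        cfg_on = ProfileConfig(half_width=12_000, mask_anchors=True)
        prof_on = profile(track, anchors, cfg_on)
        # at +10 kbp, anchor 1 would land on anchor 2's interior (bin 15):
        # masked -> only anchor 2 contributes, its +10 kbp bin is 25
        i = prof_on.index_of(10_000)
        assert prof_on.mean[i] == pytest.approx(25.0)
        assert prof_on.n_anchors[i] == 1

    def test_neighbor_included_when_mask_off(self):
        track, anchors = self.make_case()
        cfg_off = ProfileConfig(half_width=12_000, mask_anchors=False)
        prof_off = profile(track, anchors, cfg_off)
        i = prof_off.index_of(10_000)
        assert prof_off.mean[i] == pytest.approx((15.0 + 25.0) / 2)
        assert prof_off.n_anchors[i] == 2

    def test_masked_and_unmasked_agree_away_from_interiors(self):
        track, anchors = self.make_case()
        p_on = profile(track, anchors, ProfileConfig(half_width=12_000))
        p_off = profile(track, anchors,
                        ProfileConfig(half_width=12_000, mask_anchors=False))
        for d in (-3000, -2000, 2000, 3000):
            i = p_on.index_of(d)
            assert p_on.mean[i] == pytest.approx(p_off.mean[i])

    def test_partial_mask_weights(self):
        # a mask interval covering 30% of one bin down-weights it, while a
        # bin masked > 50% is discarded entirely
        track = BinnedTrack("c1", 1000, np.full(40, 1.0))
        anchors = [Interval("c1", 20_000, 20_010)]
        mask = [Interval("c1", 25_000, 25_300),    # 30% of bin 25
                Interval("c1", 27_000, 27_600)]    # 60% of bin 27
        cfg = ProfileConfig(half_width=10_000, mask_anchors=False)
        prof = profile(track, anchors, cfg, mask=mask)
        assert prof.weight[prof.index_of(5000)] == pytest.approx(0.7)
        assert prof.weight[prof.index_of(7000)] == 0.0


class TestDeclustering:
    def test_clustered_anchors_do_not_bias_masked_profile(self, rng):
        """Artificial anchor clusters on an i.i.d. genome: the masked profile
        stays flat (no distance deviates from the global mean by > 4 SE)."""
        n_fail = 0
        for seed in range(5):
            g, _ = generate_genome(GenomeSpec({"c1": 400_000}, seed=seed))
            ts = count_dinucleotides(g.chromosomes["c1"], 1000, "c1")
            track = ts.track("GC")
            # clusters of 3 anchors spaced 2 kbp, cluster centers well apart
            anchors = []
            for c in range(30_000, 380_000, 35_000):
                anchors += [Interval("c1", c + k * 2000, c + k * 2000 + 500)
                            for k in range(3)]
            prof = profile(track, anchors, ProfileConfig(half_width=20_000))
            ok = (prof.weight > 0) & np.isfinite(prof.se) & (prof.se > 0)
            z = (prof.mean[ok] - np.nanmean(track.values)) / prof.se[ok]
            n_fail += np.sum(np.abs(z) > 4)
        assert n_fail == 0

    def test_anchor_count_conservation(self):
        track = BinnedTrack("c1", 1000, np.ones(100))
        anchors = [Interval("c1", p, p + 10) for p in (30_000, 60_000)]
        prof = profile(track, anchors, ProfileConfig(half_width=10_000))
        assert prof.n_anchors[prof.center_index] <= len(anchors)


class TestSharedWeights:
    def test_linear_combination_profiles_exactly(self, rng):
        """profile(a*x + b*y) == a*profile(x) + b*profile(y) when profiled
        together (shared weights) — the basis of the influence decomposition."""
        vals_x = rng.normal(size=300)
        vals_y = rng.normal(size=300)
        a, b = 2.5, -1.25
        tx = BinnedTrack("c1", 1000, vals_x)
        ty = BinnedTrack("c1", 1000, vals_y)
        tz = BinnedTrack("c1", 1000, a * vals_x + b * vals_y)
        anchors = [Interval("c1", int(p), int(p) + 20)
                   for p in rng.integers(40_000, 260_000, size=12)]
        profs = profile_tracks({"x": tx, "y": ty, "z": tz}, anchors,
                               ProfileConfig(half_width=30_000))
        ok = profs["x"].weight > 0
        np.testing.assert_allclose(
            profs["z"].mean[ok],
            a * profs["x"].mean[ok] + b * profs["y"].mean[ok], rtol=1e-10)


class TestEnrichmentRecovery:
    def test_cc_flank_enrichment_recovered(self):
        """The CC environment profile around enriched anchors matches the
        generator's analytic truth within 3 SE and decays beyond support."""
        g, _ = generate_genome(GenomeSpec({"c1": 1_200_000}, seed=21,
                                          resolution=200))
        spec = AnchorFlankSpec(50, 10, 5000, enrichment={"CC": 1.5, "GG": 1.5})
        g, anchors, truth = place_anchors(g, spec, 22, truth_resolution=200)
        ts = count_dinucleotides(g.chromosomes["c1"], 200, "c1")
        prof = profile(ts.track("CC"), anchors, ProfileConfig(half_width=20_000))
        ef = np.array(truth["expected_dinucleotide_frequencies"])
        offsets = np.array(truth["bin_start_offsets"])
        j = DINUCLEOTIDES.index("CC")
        bg = truth["background_dinucleotide_frequencies"][j]
        for k in (0, len(offsets) // 2, len(offsets) - 1):
            d = int(offsets[k]) + 100   # bin midpoint offset
            i = int(np.argmin(np.abs(prof.distances - d)))
            expected_count = ef[k, j] * 200
            assert abs(prof.mean[i] - expected_count) <= 3 * prof.se[i] + 1e-9
        far = np.abs(prof.distances) > 6000
        near_center = prof.mean[prof.center_index]
        assert near_center > np.nanmean(prof.mean[far]) + 4 * prof.se[prof.center_index]

    def test_left_right_symmetry(self):
        g, _ = generate_genome(GenomeSpec({"c1": 1_200_000}, seed=31,
                                          resolution=200))
        spec = AnchorFlankSpec(50, 10, 5000, enrichment={"CC": 1.4, "GG": 1.4})
        g, anchors, _ = place_anchors(g, spec, 32, truth_resolution=200)
        ts = count_dinucleotides(g.chromosomes["c1"], 200, "c1")
        prof = profile(ts.track("GC"), anchors, ProfileConfig(half_width=10_000))
        c = prof.center_index
        left = prof.mean[c - 25:c][::-1]
        right = prof.mean[c + 1:c + 26]
        se = np.sqrt(prof.se[c - 25:c][::-1] ** 2 + prof.se[c + 1:c + 26] ** 2)
        assert np.all(np.abs(left - right) < 4 * se)
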