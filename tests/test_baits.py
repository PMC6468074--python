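"""Depth-anomaly masking and 2x bait tiling."""

import numpy as np
import pytest

from capmark.baits import (
    Bait,
    MaskedLocus,
    combine_profiles,
    detect_anomalies,
    mask_and_segment,
    refine_locus,
    tile_baits,
)
from capmark.io import DepthProfile, LocusSequence
from capmark.simulate import simulate_depth


def _profile(depths):
    return DepthProfile("L", np.asarray(depths))


class TestDetectAnomalies:
    def test_uniform_depth_has_no_anomalies(self):
        assert detect_anomalies(_profile([10] * 500)) == []

    def test_200x_plateau_recovered_exactly(self):
        d = np.full(500, 10)
        d[200:250] = 2000
        assert detect_anomalies(_profile(d)) == [(200, 250)]

    def test_99x_plateau_below_ratio_not_flagged(self):
        d = np.full(500, 10)
        d[200:250] = 990
        assert detect_anomalies(_profile(d)) == []

    def test_100x_boundary_is_inclusive(self):
        d = np.full(500, 10)
        d[200:250] = 1000
        assert detect_anomalies(_profile(d)) == [(200, 250)]

    def test_plateau_wider_than_window_fully_masked(self):
        d = np.full(800, 10)
        d[200:600] = 5000
        assert detect_anomalies(_profile(d), flank_window=100) == [(200, 600)]

    def test_invariant_to_depth_scaling(self, rng):
        base = rng.poisson(20, 400) + 5
        base[100:140] = 20 * 250
        spans = detect_anomalies(_profile(base))
        scaled = detect_anomalies(_profile(base * 7))
        assert spans == scaled == [(100, 140)]

    def test_simulated_injections_recovered(self, rng):
        lengths = {f"L{i}": 400 for i in range(10)}
        profiles, truth = simulate_depth(
            rng, lengths, mean_depth=30, anomaly_prob=0.5, anomaly_fold=200
        )
        for p in profiles:
            spans = detect_anomalies(p)
            if p.locus_id in truth:
                assert spans == [truth[p.locus_id]]
            else:
                assert spans == []

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            detect_anomalies(_profile([1, 2, 3]), flank_window=0)


class TestMaskAndSegment:
    def test_segment_arithmetic_around_anomaly(self):
        # 400 nt with anomaly [100,150): left run 100 nt < 120 dropped,
        # right run 250 nt kept
        seq = LocusSequence(locus_id="L", sequence="A" * 400)
        m = mask_and_segment(seq, [(100, 150)])
        assert m.segments == [(150, 400)]
        assert m.sequence[100:150] == "a" * 50
        assert m.sequence[:100] == "A" * 100

    def test_short_locus_discarded(self):
        seq = LocusSequence(locus_id="L", sequence="A" * 100)
        assert mask_and_segment(seq, []) is None

    def test_clean_locus_single_segment(self):
        seq = LocusSequence(locus_id="L", sequence="A" * 300)
        m = mask_and_segment(seq, [])
        assert m.segments == [(0, 300)]

    def test_overlapping_anomalies_merged(self):
        seq = LocusSequence(locus_id="L", sequence="A" * 400)
        m = mask_and_segment(seq, [(100, 160), (140, 200)])
        assert m.sequence[100:200].islower()
        assert m.segments == [(200, 400)]

    def test_idempotent_on_already_masked_input(self):
        seq = LocusSequence(locus_id="L", sequence="A" * 400)
        first = mask_and_segment(seq, [(100, 150)])
        again = mask_and_segment(
            LocusSequence(locus_id="L", sequence=first.sequence), []
        )
        assert again.sequence == first.sequence
        assert again.segments == first.segments


class TestTileBaits:
    def test_240nt_segment_three_baits_exact_double_interior_coverage(self):
        m = MaskedLocus("L", "A" * 240, segments=[(0, 240)])
        baits = tile_baits(m)
        assert [b.offset for b in baits] == [0, 60, 120]
        coverage = np.zeros(240, dtype=int)
        for b in baits:
            coverage[b.offset: b.offset + 120] += 1
        assert (coverage[60:180] == 2).all()
        assert (coverage >= 1).all()

    def test_exact_120nt_single_unpadded_bait(self):
        m = MaskedLocus("L", "A" * 120, segments=[(0, 120)])
        (b,) = tile_baits(m)
        assert b.offset == 0 and b.pad_len == 0 and len(b.sequence) == 120

    def test_legacy_100nt_padded_with_20_ts(self):
        m = MaskedLocus("L", "A" * 100, segments=[(0, 100)])
        (b,) = tile_baits(m, allow_short=True)
        assert b.pad_len == 20
        assert b.sequence == "A" * 100 + "T" * 20

    def test_sub_100nt_span_skipped_even_in_legacy_mode(self):
        m = MaskedLocus("L", "A" * 99, segments=[(0, 99)])
        assert tile_baits(m, allow_short=True) == []

    def test_final_bait_right_aligned(self):
        m = MaskedLocus("L", "A" * 250, segments=[(0, 250)])
        baits = tile_baits(m)
        assert [b.offset for b in baits] == [0, 60, 120, 130]
        coverage = np.zeros(250, dtype=int)
        for b in baits:
            coverage[b.offset: b.offset + 120] += 1
        assert (coverage >= 1).all()

    def test_padding_must_be_ts(self):
        with pytest.raises(ValueError):
            Bait(locus_id="L", segment_index=0, offset=0,
                 sequence="A" * 120, pad_len=5)

    def test_no_bait_contains_masked_characters(self, rng):
        for _ in range(20):
            length = int(rng.integers(150, 800))
            seq = LocusSequence(locus_id="L", sequence="ACGT" * (length // 4 + 1))
            seq = LocusSequence(locus_id="L", sequence=seq.sequence[:length])
            n_anom = int(rng.integers(0, 3))
            spans = []
            for _ in range(n_anom):
                s = int(rng.integers(0, length - 10))
                spans.append((s, min(length, s + int(rng.integers(5, 80)))))
            m = mask_and_segment(seq, spans)
            if m is None:
                continue
            for b in tile_baits(m):
                source = b.sequence[: len(b.sequence) - b.pad_len]
                assert source.isupper()


class TestRefineLocus:
    def test_combined_max_masks_region_anomalous_in_any_sample(self):
        d1 = np.full(400, 10)
        d2 = np.full(400, 10)
        d2[50:100] = 4000
        combined = combine_profiles(
            [DepthProfile("L", d1, "s1"), DepthProfile("L", d2, "s2")], how="max"
        )
        seq = LocusSequence(locus_id="L", sequence="G" * 400)
        masked, baits = refine_locus(seq, combined)
        assert masked.sequence[50:100].islower()
        assert all(b.sequence.isupper() for b in baits)

    def test_length_mismatch_rejected(self):
        seq = LocusSequence(locus_id="L", sequence="A" * 100)
        with pytest.raises(ValueError):
            refine_locus(seq, _profile([10] * 99))
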