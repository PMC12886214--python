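import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_clusters, brute_force_detectable

from introskim.calling import IntrogressionEvent, SegmentCall
from introskim.panels import (
    JunctionRecord,
    MarkerPanel,
    cluster_junctions,
    marker_spacing_stats,
    predict_detectability,
    predict_kasp_calls,
    propose_markers,
)

MB = 1_000_000


def _panel(positions_by_chrom):
    rows = [
        {"marker_id": f"K{c}_{i}", "chrom": c, "position": p}
        for c, ps in positions_by_chrom.items()
        for i, p in enumerate(ps)
    ]
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "position"])
    return MarkerPanel(markers=df)


def _j(chrom, pos_mb, line, bc1):
    return JunctionRecord(chrom=chrom, position=pos_mb * MB, line_id=line, bc1_id=bc1)


class TestClusterJunctions:
    def test_nearby_junctions_from_different_bc1_form_hotspot(self, full_spec):
        js = [_j("3T", 10, "L1", "BC1"), _j("3T", 12, "L2", "BC2")]
        clusters = cluster_junctions(js, full_spec, tolerance=5 * MB)
        assert len(clusters) == 1
        assert clusters[0].is_hotspot
        assert clusters[0].n_independent == 2

    def test_same_bc1_cluster_is_not_a_hotspot(self, full_spec):
        js = [_j("3T", 10, "L1", "BC1"), _j("3T", 12, "L2", "BC1")]
        clusters = cluster_junctions(js, full_spec, tolerance=5 * MB)
        assert len(clusters) == 1
        assert not clusters[0].is_hotspot

    def test_distant_junctions_stay_singletons(self, full_spec):
        js = [_j("3T", 5, "L1", "BC1"), _j("3T", 95, "L2", "BC2")]
        clusters = cluster_junctions(js, full_spec, tolerance=10 * MB)
        assert len(clusters) == 2
        assert not any(c.is_hotspot for c in clusters)

    def test_unknown_chromosome_rejected(self, full_spec):
        with pytest.raises(KeyError):
            cluster_junctions([_j("9Z", 10, "L1", "BC1")], full_spec)

    def test_order_invariance_and_bruteforce_equivalence(self, full_spec):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 15))
            pos = sorted(int(p) for p in rng.integers(0, 100 * MB, n))
            tol = int(rng.integers(1, 20)) * MB
            js = [_j("1T", 0, f"L{i}", f"BC{i % 4}") for i in range(n)]
            js = [
                JunctionRecord("1T", p, j.line_id, j.bc1_id)
                for p, j in zip(pos, js)
            ]
            perm = rng.permutation(n)
            shuffled = [js[i] for i in perm]
            clusters = cluster_junctions(shuffled, full_spec, tolerance=tol)
            got = sorted(tuple(sorted(c.positions)) for c in clusters)
            comps = brute_force_clusters(pos, tol)
            expected = sorted(tuple(sorted(pos[i] for i in comp)) for comp in comps)
            assert got == expected

    def test_hotspots_plus_further_sites_cover_all_clusters(self, full_spec):
        js = [
            _j("3T", 10, "L1", "BC1"),
            _j("3T", 12, "L2", "BC2"),
            _j("3T", 60, "L3", "BC1"),
            _j("5T", 40, "L4", "BC3"),
        ]
        clusters = cluster_junctions(js, full_spec, tolerance=5 * MB)
        n_hot = sum(1 for c in clusters if c.is_hotspot)
        n_further = sum(1 for c in clusters if not c.is_hotspot)
        assert n_hot + n_further == len(clusters) == 3


class TestMarkerSpacing:
    def test_adjacent_gap_stats(self, full_spec):
        panel = _panel({"1A": [0, 10 * MB, 30 * MB]})
        mean_gap, n_over, table = marker_spacing_stats(panel, full_spec)
        assert mean_gap == pytest.approx(15 * MB)
        assert n_over == 0
        assert table.iloc[0]["n_gaps"] == 2

    def test_single_marker_chromosomes_contribute_no_gaps(self, full_spec):
        panel = _panel({"1A": [5 * MB], "2A": [7 * MB, 90 * MB]})
        mean_gap, n_over, table = marker_spacing_stats(panel, full_spec)
        assert mean_gap == pytest.approx(83 * MB)
        assert n_over == 1  # 83 Mb > 70 Mb

    def test_empty_panel_is_an_error(self, full_spec):
        panel = _panel({})
        with pytest.raises(ValueError):
            marker_spacing_stats(panel, full_spec)

    def test_random_panels_match_bruteforce_adjacent_difference(self, full_spec):
        rng = np.random.default_rng(9)
        for _ in range(100):
            pos = sorted(set(int(p) for p in rng.integers(0, 100 * MB, rng.integers(2, 12))))
            panel = _panel({"1A": pos})
            mean_gap, n_over, _ = marker_spacing_stats(panel, full_spec)
            gaps = [b - a for a, b in zip(pos, pos[1:])]
            assert mean_gap == pytest.approx(float(np.mean(gaps)))
            assert n_over == sum(g > 70 * MB for g in gaps)


class TestDetectability:
    def test_small_segment_between_flanking_markers_invisible_to_both(self):
        panel = _panel({"5D": [80 * MB, 99 * MB]})
        kasp, gish = predict_detectability("5D", 81 * MB, 94 * MB, panel)
        assert (kasp, gish) == (False, False)  # 13 Mb, no marker inside

    def test_large_segment_with_markers_seen_by_both(self):
        panel = _panel({"5D": [10 * MB, 40 * MB]})
        kasp, gish = predict_detectability("5D", 0, 60 * MB, panel)
        assert (kasp, gish) == (True, True)

    def test_flags_match_bruteforce_containment_on_enumerated_segments(self):
        rng = np.random.default_rng(21)
        pos = sorted(int(p) for p in rng.integers(0, 100 * MB, 6))
        panel = _panel({"2D": pos})
        for start_mb in range(0, 95, 5):
            for end_mb in range(start_mb + 5, 100, 5):
                kasp, _ = predict_detectability("2D", start_mb * MB, end_mb * MB, panel)
                assert kasp == brute_force_detectable(start_mb * MB, end_mb * MB, pos)


class TestKaspCalls:
    def _sub(self, line, alien, wheat, start_mb, end_mb, zyg):
        gain = SegmentCall(line, alien, start_mb * MB, end_mb * MB, "alien_gain", 0.9,
                           end_mb - start_mb)
        loss = SegmentCall(line, wheat, start_mb * MB, end_mb * MB, "wheat_loss",
                           0.02 if zyg == "hom" else 0.5, end_mb - start_mb, zygosity=zyg)
        return IntrogressionEvent(line, "homoeologous_substitution", alien_segment=gain,
                                  wheat_partner=loss, zygosity=zyg)

    def test_marker_inside_hom_substitution_calls_alien_hom(self, full_spec):
        panel = _panel({"2D": [70 * MB], "2A": [10 * MB]})
        events = [self._sub("L", "2T", "2D", 60, 100, "hom")]
        calls = predict_kasp_calls(events, panel, full_spec)
        assert calls.set_index("marker_id")["call"]["K2D_0"] == "alien_hom"
        assert calls.set_index("marker_id")["call"]["K2A_0"] == "wheat_hom"

    def test_het_substitution_calls_het(self, full_spec):
        panel = _panel({"2D": [70 * MB]})
        events = [self._sub("L", "2T", "2D", 60, 100, "het")]
        calls = predict_kasp_calls(events, panel, full_spec)
        assert calls["call"].iloc[0] == "het"

    def test_addition_makes_every_group_marker_het(self, full_spec):
        panel = _panel({"7A": [10 * MB], "7D": [80 * MB], "3A": [10 * MB]})
        gain = SegmentCall("L", "7T", 0, 100 * MB, "alien_gain", 0.9, 100)
        events = [IntrogressionEvent("L", "whole_chromosome_addition", alien_segment=gain)]
        calls = predict_kasp_calls(events, panel, full_spec).set_index("marker_id")["call"]
        assert calls["K7A_0"] == "het"
        assert calls["K7D_0"] == "het"
        assert calls["K3A_0"] == "wheat_hom"

    def test_random_event_sets_match_bruteforce_containment(self, full_spec):
        rng = np.random.default_rng(17)
        for _ in range(50):
            pos = sorted(int(p) for p in rng.integers(0, 100 * MB, 8))
            panel = _panel({"4D": pos})
            s = int(rng.integers(0, 60))
            e = int(rng.integers(s + 5, 100))
            zyg = "hom" if rng.random() < 0.5 else "het"
            events = [self._sub("L", "4T", "4D", s, e, zyg)]
            calls = predict_kasp_calls(events, panel, full_spec)
            for row in calls.itertuples(index=False):
                inside = s * MB <= row.position < e * MB
                expected = ("alien_hom" if zyg == "hom" else "het") if inside else "wheat_hom"
                assert row.call == expected


class TestProposeMarkers:
    def test_midpoint_for_undetectable_segment(self, full_spec):
        panel = _panel({"5D": [80 * MB, 99 * MB]})
        proposals = propose_markers([("5D", 100 * MB, 113 * MB)], panel, full_spec)
        mid = proposals[proposals["reason"].str.startswith("undetected")]
        assert list(mid["position"]) == [(100 + 113) * MB // 2]

    def test_wide_gap_filled_at_thirds(self, full_spec):
        panel = _panel({"1A": [0, 120 * MB]})
        proposals = propose_markers([], panel, full_spec, target_density=50 * MB)
        fills = proposals[proposals["reason"].str.startswith("gap_fill")]
        assert list(fills["position"]) == [40 * MB, 80 * MB]

    def test_fully_covered_panel_proposes_nothing(self, full_spec):
        panel = _panel({"1A": [0, 40 * MB, 80 * MB]})
        proposals = propose_markers([], panel, full_spec)
        assert len(proposals) == 0

    def test_after_proposals_every_segment_is_detectable(self, full_spec):
        rng = np.random.default_rng(5)
        panel = _panel({"6D": sorted(int(p) for p in rng.integers(0, 100 * MB, 3))})
        segments = []
        for _ in range(20):
            s = int(rng.integers(0, 90)) * MB
            e = s + int(rng.integers(2, 10)) * MB
            segments.append(("6D", s, e))
        undetected = [
            seg for seg in segments if not predict_detectability(*seg, panel)[0]
        ]
        proposals = propose_markers(undetected, panel, full_spec)
        merged = pd.concat([panel.markers, proposals.assign(marker_id="new")],
                           ignore_index=True)
        augmented = MarkerPanel(markers=merged[["marker_id", "chrom", "position"]])
        for seg in segments:
            assert predict_detectability(*seg, augmented)[0]
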