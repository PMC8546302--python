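import pytest

from mqtlkit.errors import InvalidInputError
from mqtlkit.map_projection import (
    GeneticMap,
    MarkerLocus,
    ProjectionStatus,
    build_consensus_map,
    project_all,
    project_qtl,
)


class TestConsensusMap:
    def test_empty_component_list_is_identity(self, dense_map):
        consensus, report = build_consensus_map(dense_map, [])
        assert report.empty
        assert consensus.to_dataframe().drop(columns=[]).equals(
            dense_map.to_dataframe()
        )

    def test_component_only_marker_interpolated(self, two_anchor_maps):
        component, reference = two_anchor_maps
        comp2 = GeneticMap(
            "c2",
            [MarkerLocus("A", "1A", 10.0), MarkerLocus("N", "1A", 15.0),
             MarkerLocus("B", "1A", 20.0)],
        )
        consensus, report = build_consensus_map(reference, [comp2])
        assert consensus.position_of("N", "1A") == pytest.approx(30.0)
        assert report.empty

    def test_consistent_placements_are_averaged(self, two_anchor_maps):
        _, reference = two_anchor_maps
        c1 = GeneticMap("c1", [MarkerLocus("A", "1A", 10.0), MarkerLocus("N", "1A", 15.0),
                               MarkerLocus("B", "1A", 20.0)])
        # same marker, slightly different interpolated position (31 on consensus)
        c2 = GeneticMap("c2", [MarkerLocus("A", "1A", 10.0), MarkerLocus("N", "1A", 15.5),
                               MarkerLocus("B", "1A", 20.0)])
        consensus, _ = build_consensus_map(reference, [c1, c2])
        assert consensus.position_of("N", "1A") == pytest.approx((30.0 + 31.0) / 2)

    def test_conflicting_placements_left_unplaced(self, two_anchor_maps):
        _, reference = two_anchor_maps
        c1 = GeneticMap("c1", [MarkerLocus("A", "1A", 10.0), MarkerLocus("N", "1A", 11.0),
                               MarkerLocus("B", "1A", 20.0)])
        c2 = GeneticMap("c2", [MarkerLocus("A", "1A", 10.0), MarkerLocus("N", "1A", 19.0),
                               MarkerLocus("B", "1A", 20.0)])
        consensus, report = build_consensus_map(reference, [c1, c2])
        assert consensus.position_of("N", "1A") is None
        assert (report["reason"] == "conflicting_placements").any()

    def test_marker_outside_anchor_span_reported(self, two_anchor_maps):
        _, reference = two_anchor_maps
        comp = GeneticMap("c", [MarkerLocus("A", "1A", 10.0), MarkerLocus("B", "1A", 20.0),
                                MarkerLocus("N", "1A", 25.0)])
        consensus, report = build_consensus_map(reference, [comp])
        assert consensus.position_of("N", "1A") is None
        assert (report["reason"] == "outside_anchors").any()

    def test_group_with_single_shared_anchor_skipped(self, two_anchor_maps):
        _, reference = two_anchor_maps
        comp = GeneticMap("c", [MarkerLocus("A", "1A", 10.0), MarkerLocus("X", "1A", 30.0)])
        _, report = build_consensus_map(reference, [comp])
        assert (report["reason"] == ProjectionStatus.NO_ANCHORS).any()


class TestProjectQtl:
    def test_identity_when_maps_coincide(self, dense_map, make_qtl):
        q = make_qtl(chrom="2B", peak=35.0, ci=(31.0, 39.0))
        p = project_qtl(q, dense_map, dense_map)
        assert p.status == ProjectionStatus.PROJECTED
        assert p.consensus_peak == pytest.approx(35.0)
        assert (p.consensus_ci_lo, p.consensus_ci_hi) == (pytest.approx(31.0), pytest.approx(39.0))

    def test_hand_computed_linear_rescaling(self, two_anchor_maps, make_qtl):
        component, consensus = two_anchor_maps
        p = project_qtl(make_qtl(peak=15.0, ci=(12.0, 18.0)), component, consensus)
        assert p.status == ProjectionStatus.PROJECTED
        assert p.consensus_peak == pytest.approx(30.0)
        assert p.consensus_ci_lo == pytest.approx(24.0)
        assert p.consensus_ci_hi == pytest.approx(36.0)
        assert (p.left_anchor, p.right_anchor) == ("A", "B")

    def test_ci_width_scales_by_local_anchor_ratio(self, two_anchor_maps, make_qtl):
        component, consensus = two_anchor_maps
        p = project_qtl(make_qtl(peak=15.0, ci=(12.0, 18.0)), component, consensus)
        assert p.consensus_ci_hi - p.consensus_ci_lo == pytest.approx(6.0 * 2.0)

    def test_point_outside_anchors_not_extrapolated(self, two_anchor_maps, make_qtl):
        component, consensus = two_anchor_maps
        p = project_qtl(make_qtl(peak=5.0, ci=(4.0, 6.0)), component, consensus)
        assert p.status == ProjectionStatus.OUTSIDE_ANCHORS
        assert p.consensus_peak is None

    def test_peak_on_shared_anchor_lands_exactly(self, two_anchor_maps, make_qtl):
        component, consensus = two_anchor_maps
        p = project_qtl(make_qtl(peak=10.0, ci=(10.0, 10.0)), component, consensus)
        assert p.consensus_peak == pytest.approx(20.0, abs=0)

    def test_inverted_anchor_order_flagged(self, make_qtl):
        component = GeneticMap("c", [MarkerLocus("A", "1A", 10.0), MarkerLocus("B", "1A", 20.0)])
        consensus = GeneticMap("r", [MarkerLocus("B", "1A", 20.0), MarkerLocus("A", "1A", 40.0)])
        p = project_qtl(make_qtl(peak=15.0, ci=(14.0, 16.0)), component, consensus)
        assert p.status == ProjectionStatus.INVERTED_ANCHOR_ORDER

    def test_fewer_than_two_shared_anchors(self, make_qtl):
        component = GeneticMap("c", [MarkerLocus("A", "1A", 10.0), MarkerLocus("Z", "1A", 20.0)])
        consensus = GeneticMap("r", [MarkerLocus("A", "1A", 20.0), MarkerLocus("Y", "1A", 40.0)])
        p = project_qtl(make_qtl(peak=15.0, ci=(14.0, 16.0)), component, consensus)
        assert p.status == ProjectionStatus.NO_ANCHORS

    def test_unknown_linkage_group_raises(self, two_anchor_maps, make_qtl):
        component, consensus = two_anchor_maps
        with pytest.raises(InvalidInputError):
            project_qtl(make_qtl(chrom="5D", peak=15.0, ci=(14.0, 16.0)), component, consensus)

    def test_projection_preserves_order(self, dense_map, make_qtl):
        # order-preserving through a stretched component map
        component = GeneticMap(
            "c", [MarkerLocus(f"M{i:02d}", "2B", float(8 * i)) for i in range(11)]
        )
        peaks = [3.0, 17.0, 33.0, 61.0, 77.0]
        mapped = [
            project_qtl(make_qtl(chrom="2B", peak=p, ci=(p, p)), component, dense_map).consensus_peak
            for p in peaks
        ]
        assert mapped == sorted(mapped)


class TestProjectAll:
    def test_empty_input(self, dense_map):
        out, summary = project_all([], {}, dense_map)
        assert out == [] and sum(summary.values()) == 0

    def test_identical_maps_project_everything(self, dense_map, make_qtl):
        qtls = [make_qtl(f"Q{i}", chrom="2B", peak=10.0 * i + 5, ci=(10.0 * i + 4, 10.0 * i + 6))
                for i in range(5)]
        out, summary = project_all(qtls, {"POP01": dense_map}, dense_map)
        assert summary[ProjectionStatus.PROJECTED] == 5

    def test_unknown_map_counted_as_no_map(self, dense_map, make_qtl):
        out, summary = project_all([make_qtl(chrom="2B", peak=5.0, ci=(4.0, 6.0))], {}, dense_map)
        assert summary[ProjectionStatus.NO_MAP] == 1
        assert out[0].status == ProjectionStatus.NO_MAP
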