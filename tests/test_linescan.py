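"""Boundary tracing, arc-length ROI placement, spot assignment, comparisons."""

import math

import numpy as np
import pytest

from conftest import make_quiet, make_smooth
from oculims.images import compute_tic, extract_ion_image
from oculims.imzml import MSIDataset, Spectrum
from oculims.linescan import (
    BoundaryPath,
    assign_spots,
    compare_symmetric_positions,
    place_rois,
    set_origin,
    trace_boundary,
)
from oculims.masses import MassWindow
from oculims.pipeline import PipelineConfig, run_pipeline


def disk_mask(radius_um, pitch_um, pad=3):
    n = int(2 * radius_um / pitch_um) + 2 * pad + 1
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    return ((xx - c) ** 2 + (yy - c) ** 2) * pitch_um**2 <= radius_um**2, c * pitch_um


class TestTraceBoundary:
    def test_rectangle_perimeter(self):
        mask = np.zeros((16, 26), dtype=bool)
        mask[3:13, 3:23] = True  # 10 x 20 pixels at 100 μm
        path = trace_boundary(mask, 100.0)
        assert path.total_length == pytest.approx(6000.0, rel=0.05)

    def test_disk_perimeter_close_to_circle(self):
        mask, _ = disk_mask(2000.0, 100.0)
        path = trace_boundary(mask, 100.0)
        assert path.total_length == pytest.approx(2 * math.pi * 2000.0, rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            trace_boundary(np.zeros((5, 5), dtype=bool), 100.0)

    def test_ambiguous_components_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True  # two equal 3x3 blobs
        with pytest.raises(ValueError, match="components"):
            trace_boundary(mask, 100.0)

    def test_largest_component_wins(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:12, 2:12] = True
        mask[15:17, 15:17] = True  # small satellite ignored
        path = trace_boundary(mask, 100.0)
        assert path.total_length == pytest.approx(4000.0, rel=0.06)


class TestSetOrigin:
    def test_apex_becomes_arc_zero(self):
        mask, c = disk_mask(2000.0, 100.0)
        path = trace_boundary(mask, 100.0)
        apex = (c + 2000.0, c)
        out = set_origin(path, apex, superior_hint_xy=(c, c - 2000.0))
        origin = out.point_at_branch_arc(0.0, "apex")
        assert np.linalg.norm(origin - np.array(apex)) < 120.0

    def test_far_apex_rejected(self):
        mask, c = disk_mask(2000.0, 100.0)
        path = trace_boundary(mask, 100.0)
        with pytest.raises(ValueError, match="apex"):
            set_origin(path, (c, c), (c, c - 2000.0))

    def test_symmetric_arcs_mirror_on_disk(self):
        """|arc| positions land on mirror-image points for a symmetric shape."""
        mask, c = disk_mask(2000.0, 100.0)
        path = trace_boundary(mask, 100.0)
        out = set_origin(path, (c + 2000.0, c), (c, c - 2000.0))
        # agreement is limited by the simplified polyline's segment length
        tol = 300.0
        for arc in (500.0, 1500.0, 2500.0):
            p_sup = out.point_at_branch_arc(arc, "superior")
            p_inf = out.point_at_branch_arc(arc, "inferior")
            assert p_sup[0] == pytest.approx(p_inf[0], abs=tol)
            assert (p_sup[1] - c) == pytest.approx(-(p_inf[1] - c), abs=tol)
            assert p_sup[1] < c  # superior is up

    def test_phantom_branch_labels_match_ground_truth(self, small_quiet_phantom):
        ds, gt = small_quiet_phantom
        path = trace_boundary(ds.occupancy_mask(), ds.pitch_um)
        out = set_origin(path, gt.apex_xy, gt.superior_hint_xy)
        p_sup = out.point_at_branch_arc(1000.0, "superior")
        iy = int(round(p_sup[1] / ds.pitch_um))
        # superior branch of the traced contour lies in the +1 half of the GT map
        assert gt.branch[iy, int(round(p_sup[0] / ds.pitch_um))] == 1


class TestPlaceROIs:
    def line_path(self):
        pts = np.column_stack([np.linspace(0.0, 2000.0, 41), np.zeros(41)])
        return BoundaryPath(
            points=pts, pitch_um=50.0, closed=False, origin_set=True,
            superior_sign=1, origin_arc_um=1000.0,
        )

    def test_straight_path_centers(self):
        series = place_rois(self.line_path(), 200.0, 400.0, max_arc_um=2000.0)
        got = sorted(
            (r.branch, r.arc_um, round(r.center_xy[0], 6)) for r in series.rois
        )
        assert len(series) == 5  # 0, ±400, ±800 with the origin counted once
        xs = sorted(x for _, _, x in got)
        assert xs == [200.0, 600.0, 1000.0, 1400.0, 1800.0]

    def test_no_overlap_when_spacing_exceeds_diameter(self):
        series = place_rois(self.line_path(), 200.0, 400.0, max_arc_um=2000.0)
        centers = np.array([r.center_xy for r in series.rois])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() > series.diameter_um

    def test_circular_path_chord_vs_arc(self):
        mask, c = disk_mask(2000.0, 100.0)
        path = trace_boundary(mask, 100.0)
        path = set_origin(path, (c + 2000.0, c), (c, c - 2000.0))
        series = place_rois(path, 200.0, 400.0, max_arc_um=4000.0)
        sup = sorted(series.branch("superior"), key=lambda r: r.arc_um)
        r_eff = path.total_length / (2 * math.pi)
        expected_chord = 2 * r_eff * math.sin(400.0 / (2 * r_eff))
        for a, b in zip(sup[:-1], sup[1:]):
            assert b.arc_um - a.arc_um == pytest.approx(400.0)
            chord = math.dist(a.center_xy, b.center_xy)
            assert chord <= 400.0 + 1e-6
            assert chord == pytest.approx(expected_chord, rel=0.05)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            place_rois(self.line_path(), 200.0, 0.0)


def grid_dataset(values, pitch=100.0):
    """values: 2-D array -> dataset with one peak of that intensity per pixel."""
    spectra = {}
    for iy, ix in np.ndindex(values.shape):
        spectra[(ix + 1, iy + 1)] = Spectrum([250.0], [float(values[iy, ix])])
    return MSIDataset(spectra, mz_range=(200.0, 310.0), pitch_um=pitch)


class TestAssignSpots:
    def test_mean_of_member_spots(self):
        ds = grid_dataset(np.array([[2.0, 4.0]]))  # pixels at x=0 and 100 μm
        tic = {c: 10.0 for c in ds.spectra}
        ion = extract_ion_image(ds, MassWindow(250.0, 1.0), tic)
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]])
        path = BoundaryPath(pts, pitch_um=100.0, closed=False, origin_set=True,
                            origin_arc_um=0.0)
        series = place_rois(path, diameter_um=250.0, spacing_um=400.0,
                            max_arc_um=0.0)
        out = assign_spots(series, ds, ion)
        assert len(out) == 1
        assert out.rois[0].n_spots == 2
        assert out.rois[0].mean_intensity == pytest.approx(0.3)

    def test_roi_over_unscanned_region_dropped(self):
        ds = grid_dataset(np.ones((1, 3)))
        ion = extract_ion_image(ds, MassWindow(250.0, 1.0))
        pts = np.column_stack([np.linspace(0, 4000.0, 41), np.zeros(41)])
        path = BoundaryPath(pts, pitch_um=100.0, closed=False, origin_set=True,
                            origin_arc_um=0.0)
        series = place_rois(path, 200.0, 400.0, max_arc_um=4000.0)
        out = assign_spots(series, ds, ion)
        kept_arcs = {r.arc_um for r in out.rois}
        assert kept_arcs == {0.0}  # only the ROI over the 3 scanned pixels

    def test_spot_counts_match_brute_force(self, small_quiet_phantom):
        """Membership (pixel center in disk) agrees with an explicit loop."""
        ds, gt = small_quiet_phantom
        tic = compute_tic(ds)
        ion = extract_ion_image(ds, MassWindow(gt.config.target_mz, 0.0009), tic)
        path = set_origin(
            trace_boundary(ds.occupancy_mask(), ds.pitch_um),
            gt.apex_xy, gt.superior_hint_xy,
        )
        series = assign_spots(place_rois(path, 200.0, 400.0, 3000.0), ds, ion)
        assert len(series) > 5
        for roi in series.rois:
            brute = [
                c
                for c in ds.spectra
                if math.dist(ds.physical_xy(c), roi.center_xy) <= 100.0
            ]
            assert sorted(brute) == sorted(roi.spots)
            assert 1 <= roi.n_spots <= 11


class TestComparisons:
    def build_series(self, sup_values, inf_values, arc=400.0):
        from oculims.linescan import ROI, ROISeries

        rois = [
            ROI((0, 0), 200.0, "superior", arc, spots=[(1, 1)] * len(sup_values),
                values=np.array(sup_values, dtype=float)),
            ROI((0, 1), 200.0, "inferior", arc, spots=[(1, 2)] * len(inf_values),
                values=np.array(inf_values, dtype=float)),
        ]
        return ROISeries(rois, 200.0, 400.0)

    def test_identical_spots_not_significant(self):
        res = compare_symmetric_positions(self.build_series([1, 1, 1], [1, 1, 1]))
        (pos,) = [p for p in res.positions if p.tested]
        assert pos.p_two_sided == 1.0 and pos.tier == "none" and pos.direction == ""

    def test_small_samples_use_exact_method(self):
        from oculims.linescan import mann_whitney_u

        assert mann_whitney_u([0.1, 0.2], [0.3, 0.4]).method == "exact"

    def test_direction_follows_means(self):
        res = compare_symmetric_positions(
            self.build_series([5, 6, 7, 8], [1, 2, 3, 4])
        )
        (pos,) = [p for p in res.positions if p.tested]
        assert pos.direction == "superior"
        assert pos.p_two_sided == pytest.approx(2 / 70, abs=1e-12)
        assert pos.tier == "0.05"

    def test_one_branch_positions_reported_untested(self):
        from oculims.linescan import ROI, ROISeries

        series = ROISeries(
            [ROI((0, 0), 200.0, "superior", 800.0, spots=[(1, 1)],
                 values=np.array([1.0]))],
            200.0, 400.0,
        )
        res = compare_symmetric_positions(series)
        assert len(res.positions) == 1 and not res.positions[0].tested

    def test_monotone_profile_on_smooth_noise_free_phantom(self, small_config):
        """Strictly decaying field ⇒ strictly decreasing ROI means, both branches."""
        cfg = make_smooth(make_quiet(small_config))
        res = run_pipeline(PipelineConfig(phantom=cfg, seed=cfg.seed,
                                          max_arc_um=3600.0))
        df = res.linescan.to_frame()
        for branch in ("superior", "inferior"):
            means = (
                df[df.branch == branch]
                .sort_values("arc_position_um")
                .mean_norm_intensity.to_numpy()
            )
            assert len(means) >= 5
            assert np.all(np.diff(means) < 0)
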