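"""spotNorm pipeline: assignment, drift, normalization, filter, histogram."""

import numpy as np
import pandas as pd
import pytest

from rodspt import (CellGeometry, SimConfig, assign_spots,
                    build_xnorm_histogram, cylinder_filter, estimate_drift,
                    normalize_movie, normalize_spot, normalize_spots,
                    simulate_cells, simulate_tracks)
from rodspt.geometry import AmbiguousCellsError, GeometryError, apply_drift


def spots_df(xy, movie_id=0, track_id=0):
    xy = np.atleast_2d(xy)
    return pd.DataFrame({"movie_id": movie_id, "track_id": track_id,
                         "frame": np.arange(len(xy)),
                         "x_px": xy[:, 0], "y_px": xy[:, 1]})


class TestCellGeometry:
    def test_rejects_degenerate_centerline(self):
        with pytest.raises(GeometryError, match="zero-length"):
            CellGeometry(cell_id=0, movie_id=0,
                         outline=[[0, 0], [10, 0], [10, 4], [0, 4]],
                         centerline=[[2, 2], [2, 2], [8, 2]],
                         length_px=10, width_px=4)

    def test_rejects_bad_aspect(self):
        with pytest.raises(GeometryError, match="L > 2R"):
            CellGeometry(cell_id=0, movie_id=0,
                         outline=[[0, 0], [4, 0], [4, 10], [0, 10]],
                         centerline=[[2, 1], [2, 9]],
                         length_px=4, width_px=10)


class TestAssign:
    def test_centroid_spot_assigned(self, rect_cell):
        out = assign_spots(spots_df([[10.0, 3.0]] * 4), [rect_cell])
        assert len(out) == 4
        assert (out["cell_id"] == 0).all()

    def test_outside_spot_dropped(self, rect_cell):
        out = assign_spots(spots_df([[50.0, 50.0]] * 4), [rect_cell])
        assert len(out) == 0

    def test_overlapping_cells_raise(self, rect_cell):
        other = CellGeometry(cell_id=1, movie_id=0,
                             outline=rect_cell.outline + [5.0, 0.0],
                             centerline=rect_cell.centerline + [5.0, 0.0],
                             length_px=19.0, width_px=6.0)
        with pytest.raises(AmbiguousCellsError):
            assign_spots(spots_df([[10.0, 3.0]]), [rect_cell, other])

    def test_generator_round_trip(self, small_config, straight_cells):
        # noise-free spots generated inside known cells map back to them
        cfg = SimConfig(n_cells=20, spots_per_cell=100, seed=42,
                        sigma_loc=0.0)
        tracks, gt = simulate_tracks(straight_cells, cfg)
        assigned = assign_spots(tracks, straight_cells)
        assert len(assigned) == len(tracks)
        pos = gt.positions[gt.positions.track_id >= 0]
        truth = gt.molecules.set_index("molecule_id")["cell_id"]
        mol_of_track = pos.groupby("track_id")["molecule_id"].first()
        expect = truth.loc[mol_of_track.loc[assigned["track_id"]].values].values
        assert (assigned["cell_id"].values == expect).all()


class TestDrift:
    def _centered_spots(self, cell, n=60, seed=0):
        rng = np.random.default_rng(seed)
        c = np.asarray(cell.polygon.centroid.coords[0])
        xy = c + rng.normal(0, 0.5, size=(n, 2))
        df = spots_df(xy)
        df["track_id"] = np.arange(n) // 4
        return df

    def test_no_drift_when_centered(self, rect_cell):
        df = self._centered_spots(rect_cell)
        assigned = assign_spots(df, [rect_cell])
        shifts = estimate_drift(assigned, [rect_cell])
        np.testing.assert_allclose(shifts[0], [0.0, 0.0])

    def test_injected_offset_recovered(self, rect_cell):
        df = self._centered_spots(rect_cell)
        df["x_px"] -= 2.0
        df["y_px"] += 1.0
        assigned = assign_spots(df, [rect_cell])
        shifts = estimate_drift(assigned, [rect_cell])
        np.testing.assert_allclose(shifts[0], [2.0, -1.0], atol=0.3)
        corrected = apply_drift(df, shifts)
        assert corrected["x_px"].mean() > df["x_px"].mean()

    def test_small_shift_not_applied(self, rect_cell):
        df = self._centered_spots(rect_cell)
        df["x_px"] -= 0.1
        assigned = assign_spots(df, [rect_cell])
        shifts = estimate_drift(assigned, [rect_cell], threshold_px=0.5)
        np.testing.assert_allclose(shifts[0], [0.0, 0.0])


class TestNormalize:
    def test_centerline_spot_is_zero(self, rect_cell):
        xn, yn = normalize_spot(rect_cell, 10.0, 3.0)
        assert xn == pytest.approx(0.0, abs=1e-12)

    def test_edge_spot_sign_convention(self, rect_cell):
        # centerline runs toward +x; "left" of it is +y, so a spot on the
        # +y membrane edge at mid-cell has xNorm = +1
        mid_x = 0.5 * (rect_cell.centerline[0, 0] + rect_cell.centerline[1, 0])
        xn, yn = normalize_spot(rect_cell, mid_x, 3.0 + rect_cell.R)
        assert xn == pytest.approx(1.0)
        assert yn == pytest.approx(0.5)
        xn_neg, _ = normalize_spot(rect_cell, mid_x, 3.0 - rect_cell.R)
        assert xn_neg == pytest.approx(-1.0)

    def test_out_of_range_rejected_not_clipped(self, rect_cell):
        assert normalize_spot(rect_cell, 10.0, 3.0 + 1.5 * rect_cell.R) is None

    def test_round_trip_on_straight_cell(self, rect_cell):
        rng = np.random.default_rng(0)
        xy = np.column_stack([rng.uniform(1, 19, 50), rng.uniform(0.5, 5.5, 50)])
        df = assign_spots(spots_df(xy), [rect_cell])
        norm, _ = normalize_spots(df, [rect_cell])
        # invert: x = x0 + yNorm*L along the axis, y = yc + xNorm*R
        x_back = rect_cell.centerline[0, 0] + norm["yNorm"] * rect_cell.L
        y_back = 3.0 + norm["xNorm"] * rect_cell.R
        np.testing.assert_allclose(x_back, df["x_px"], atol=1e-9)
        np.testing.assert_allclose(y_back, df["y_px"], atol=1e-9)

    def test_membrane_marginal_is_arcsine(self):
        # noise-free membrane spots projected to |xNorm| follow the arcsine
        # law with CDF (2/pi)*arcsin(x)
        from scipy.stats import kstest
        cfg = SimConfig(n_cells=60, m_true=1.0, sigma_loc=0.0, n_sub=1,
                        spots_per_cell=2000, seed=2, f_depth=1.0,
                        p_bleach=0.5, dilF_true=1.0)
        cells = simulate_cells(cfg)
        tracks, _ = simulate_tracks(cells, cfg)
        norm, _ = normalize_movie(tracks, cells)
        x = np.abs(norm[norm.in_cylinder]["xNorm"].to_numpy())
        assert len(x) > 1e5
        stat = kstest(x, lambda v: 2 / np.pi * np.arcsin(v)).statistic
        assert stat < 0.01


class TestCylinderFilter:
    def test_open_interval(self, rect_cell):
        df = assign_spots(spots_df([[10.0, 3.0], [0.5 + rect_cell.R / 2, 3.0]],
                                   track_id=0), [rect_cell])
        norm, _ = normalize_spots(df, [rect_cell])
        out = cylinder_filter(norm, [rect_cell])
        flags = out.sort_values("frame")["in_cylinder"].tolist()
        assert flags == [True, False]

    def test_uniform_axial_kept_fraction(self):
        # L = 4R: cylindrical fraction (L-2R)/L = 1/2
        cell = CellGeometry(cell_id=0, movie_id=0,
                            outline=[[0, 0], [40, 0], [40, 20], [0, 20]],
                            centerline=[[0, 10], [40, 10]],
                            length_px=40, width_px=20)
        rng = np.random.default_rng(1)
        n = 20000
        df = spots_df(np.column_stack([rng.uniform(0, 40, n),
                                       np.full(n, 10.0)]))
        df["track_id"] = np.arange(n)
        assigned = assign_spots(df, [cell])
        norm, _ = normalize_spots(assigned, [cell])
        out = cylinder_filter(norm, [cell])
        frac = out["in_cylinder"].mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)


class TestHistogram:
    def _norm_df(self, xnorm, track_id=None):
        n = len(xnorm)
        return pd.DataFrame({
            "movie_id": 0, "cell_id": 0,
            "track_id": np.zeros(n, int) if track_id is None else track_id,
            "frame": np.arange(n), "xNorm": xnorm, "yNorm": 0.5,
            "in_cylinder": True})

    def test_single_track_single_bin(self):
        hist = build_xnorm_histogram(self._norm_df([0.5] * 4), n_boot=0)
        assert hist.prob.max() == pytest.approx(1.0)
        assert hist.n_spots == 4

    def test_zero_bootstrap_gives_zero_sem(self):
        hist = build_xnorm_histogram(self._norm_df([0.5] * 4), n_boot=0)
        np.testing.assert_array_equal(hist.sem, 0.0)

    def test_fold_preserves_mass_and_halves_support(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 4000)
        tid = np.arange(4000) // 4
        signed = build_xnorm_histogram(self._norm_df(x, tid), n_boot=0,
                                       absolute=False)
        folded = build_xnorm_histogram(self._norm_df(x, tid), n_boot=0,
                                       absolute=True)
        assert signed.prob.sum() == pytest.approx(1.0)
        assert folded.prob.sum() == pytest.approx(1.0)
        assert len(folded.prob) == len(signed.prob) // 2
        # fold identity bin by bin
        np.testing.assert_allclose(
            folded.prob, signed.prob[25:] + signed.prob[:25][::-1], atol=1e-12)

    def test_semicircle_for_cytoplasm_only(self):
        # no imaging effects: |xNorm| of volume molecules follows the
        # semicircle law 2*sqrt(1-x^2)/pi per bin
        cfg = SimConfig(n_cells=40, m_true=0.0, sigma_loc=0.0, n_sub=1,
                        spots_per_cell=1500, seed=4, f_depth=1.0,
                        dilF_true=1.0)
        cells = simulate_cells(cfg)
        tracks, _ = simulate_tracks(cells, cfg)
        norm, _ = normalize_movie(tracks, cells)
        hist = build_xnorm_histogram(norm, n_boot=50, seed=0)
        from rodspt.mbmodel import _semicircle_cdf
        expected = np.diff(2 * _semicircle_cdf(hist.edges, 1.0) - 1)
        dev = np.abs(hist.prob - expected)
        tol = 3 * np.maximum(hist.sem, 1e-4)
        assert (dev < tol + 0.003).all()

    def test_min_track_length_enforced(self):
        df = pd.concat([self._norm_df([0.1] * 2), self._norm_df([0.9] * 4)])
        df.loc[df.xNorm == 0.9, "track_id"] = 1
        hist = build_xnorm_histogram(df, n_boot=0)
        # the 2-spot track is discarded entirely
        assert hist.n_spots == 4
        assert hist.prob[22] == pytest.approx(1.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_xnorm_histogram(self._norm_df([]))
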