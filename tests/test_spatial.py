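"""Spatial state space: grids, subdetector counts, assignment, retention."""

import numpy as np
import pandas as pd
import pytest

from opscr.spatial import (
    AsciiRaster, ConfigurationError, DomainCoverageError,
    build_habitat_grid, build_detector_grid, assign_detections,
    retain_within_radius, read_ascii_raster, write_ascii_raster,
    standardize_covariates,
)
from conftest import make_raster


class TestHabitatGrid:
    def test_cell_counts_with_and_without_buffer(self):
        extent = (0.0, 0.0, 100.0, 100.0)
        raster = make_raster((-60.0, -60.0, 160.0, 160.0))
        assert build_habitat_grid(extent, 20.0, raster, 0.0).n_cells == 25
        # (100 + 2*60) / 20 = 11 cells per side
        assert build_habitat_grid(extent, 20.0, raster, 60.0).n_cells == 121

    def test_constant_raster_resamples_to_constant(self):
        extent = (0.0, 0.0, 100.0, 100.0)
        hab = build_habitat_grid(extent, 20.0, make_raster(extent, 3.7), 0.0)
        assert np.allclose(hab.X, 3.7)

    def test_area_weighted_mean_on_split_cell(self):
        # raster cells of 10 km with values 1 (left half) and 3 (right half):
        # each 20 km habitat cell averages to 2 exactly
        extent = (0.0, 0.0, 40.0, 40.0)
        arr = np.tile([1.0, 3.0, 1.0, 3.0], (4, 1))
        hab = build_habitat_grid(extent, 20.0, make_raster(extent, array=arr), 0.0)
        assert np.allclose(hab.X, 2.0)

    def test_raster_must_cover_buffered_extent(self):
        extent = (0.0, 0.0, 100.0, 100.0)
        with pytest.raises(DomainCoverageError):
            build_habitat_grid(extent, 20.0, make_raster(extent), buffer_width=20.0)

    def test_buffer_rule_warns_below_six_sigma(self, habitat_3x3):
        with pytest.warns(UserWarning, match="6"):
            assert not habitat_3x3.validate_buffer(sigma_max=10.0)

    def test_row_major_indexing_from_lower_left(self, habitat_3x3):
        assert np.allclose(habitat_3x3.cell_centres[0], [10.0, 10.0])
        assert np.allclose(habitat_3x3.cell_centres[1], [30.0, 10.0])
        assert np.allclose(habitat_3x3.cell_centres[3], [10.0, 30.0])


class TestDetectorGrid:
    def test_fully_covered_detector_has_25_subdetectors(self, grids_small):
        _, detectors = grids_small
        assert detectors.n_detectors == 16
        assert np.all(detectors.K == 25)

    def test_detectors_outside_habitat_are_dropped(self):
        # habitat only over the left half of the detector extent
        raster = make_raster((0.0, 0.0, 40.0, 80.0))
        habitat = build_habitat_grid((0.0, 0.0, 40.0, 80.0), 20.0, raster, 0.0)
        detectors = build_detector_grid((0.0, 0.0, 80.0, 80.0), 10.0, 2.0, habitat)
        assert detectors.n_detectors == 32          # right-half detectors gone
        assert np.all(detectors.detector_centres[:, 0] < 40.0)

    def test_half_covered_detector_K_matches_brute_force(self):
        # habitat edge cuts straight through the detector centre at x = 40
        raster = make_raster((0.0, 0.0, 40.0, 40.0))
        habitat = build_habitat_grid((0.0, 0.0, 40.0, 40.0), 20.0, raster, 0.0)
        detectors = build_detector_grid((30.0, 10.0, 40.0, 20.0), 10.0, 2.0, habitat)
        j = 0
        subs = detectors.subdetector_centres(j)
        brute = sum(
            1 for (x, y) in subs
            if 0.0 <= x <= 40.0 and 0.0 <= y <= 40.0
        )
        assert detectors.K[j] == brute == 25  # centres at 31..39 all inside

        # edge through the detector centre at x = 40: 3 of 5 centre columns
        # remain inside (boundary centres count as overlapping)
        detectors2 = build_detector_grid((35.0, 10.0, 45.0, 20.0), 10.0, 2.0, habitat)
        subs2 = detectors2.subdetector_centres(0)
        brute2 = sum(1 for (x, y) in subs2 if x <= 40.0)
        assert detectors2.K[0] == brute2 == 15

    def test_K_conservation_over_all_detectors(self, grids_small):
        habitat, detectors = grids_small
        total = 0
        for j in range(detectors.n_detectors):
            for c in detectors.subdetector_centres(j):
                if habitat.cell_of(c)[0] >= 0:
                    total += 1
        assert total == detectors.K.sum()

    def test_non_divisible_sizes_rejected(self, habitat_3x3):
        with pytest.raises(ConfigurationError):
            build_detector_grid((0.0, 0.0, 60.0, 60.0), 10.0, 3.0, habitat_3x3)


class TestAssignDetections:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["individual_id", "season", "x", "y"])

    def test_same_subdetector_counts_once(self, grids_small):
        _, detectors = grids_small
        rec = self._records([("a", 1, 3.1, 3.2), ("a", 1, 3.3, 3.4),
                             ("a", 1, 3.0, 3.0)])
        out = assign_detections(rec, detectors)
        assert len(out) == 1 and out["y"].iloc[0] == 1

    def test_distinct_subdetectors_counted(self, grids_small):
        _, detectors = grids_small
        rec = self._records([("a", 1, 1.0, 1.0), ("a", 1, 5.0, 5.0),
                             ("a", 1, 9.0, 9.0)])
        out = assign_detections(rec, detectors)
        assert out["y"].iloc[0] == 3

    def test_equidistant_tie_goes_to_lowest_index(self, grids_small):
        _, detectors = grids_small
        # point exactly between detector centres 0 (5,5) and 1 (15,5)
        rec = self._records([("a", 1, 10.0, 5.0)])
        out = assign_detections(rec, detectors)
        d2 = ((detectors.detector_centres - [10.0, 5.0]) ** 2).sum(axis=1)
        ties = np.where(np.isclose(d2, d2.min()))[0]
        assert len(ties) >= 2                        # genuinely equidistant
        assert out["detector"].iloc[0] == ties.min()

    def test_records_outside_all_detectors_excluded(self, grids_small):
        _, detectors = grids_small
        rec = self._records([("a", 1, 200.0, 200.0), ("a", 1, 3.0, 3.0)])
        out = assign_detections(rec, detectors)
        assert len(out) == 1 and out["y"].iloc[0] == 1

    def test_every_retained_record_maps_to_one_detector(self, small_synthetic_study):
        st = small_synthetic_study
        out = assign_detections(st.detections, st.detectors)
        assert (out["y"] >= 1).all()
        assert (out["y"] <= st.detectors.K[out["detector"]]).all()
        # total distinct-subdetector hits can never exceed record count
        assert out["y"].sum() <= len(st.detections)


class TestRetentionFilter:
    def test_boundary_inclusion(self):
        rec = pd.DataFrame({"individual_id": ["a", "b"], "season": [1, 1],
                            "x": [69.9, 70.1], "y": [0.0, 0.0]})
        out = retain_within_radius(rec, np.array([[0.0, 0.0]]), 70.0)
        assert list(out["individual_id"]) == ["a"]

    def test_matches_brute_force_on_mixed_set(self):
        rng = np.random.default_rng(5)
        rec = pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(10)],
            "season": np.ones(10, dtype=int),
            "x": rng.uniform(0, 200, 10), "y": rng.uniform(0, 200, 10),
        })
        refs = rng.uniform(0, 200, (4, 2))
        out = retain_within_radius(rec, refs, 70.0)
        xy = rec[["x", "y"]].to_numpy()
        brute = {
            rec["individual_id"].iloc[k]
            for k in range(10)
            if min(np.hypot(*(xy[k] - r)) for r in refs) <= 70.0
        }
        assert set(out["individual_id"]) == brute

    def test_empty_reference_set_is_an_error(self):
        rec = pd.DataFrame({"individual_id": ["a"], "season": [1],
                            "x": [0.0], "y": [0.0]})
        with pytest.raises(ConfigurationError):
            retain_within_radius(rec, np.zeros((0, 2)), 70.0)


class TestRasterIO:
    def test_round_trip(self, tmp_path):
        r = make_raster((0.0, 0.0, 40.0, 30.0), array=np.arange(12.0).reshape(3, 4))
        write_ascii_raster(tmp_path / "x.asc", r)
        back = read_ascii_raster(tmp_path / "x.asc")
        assert np.allclose(back.values, r.values)
        assert back.cellsize == r.cellsize
        assert back.extent == r.extent


def test_covariate_standardization_stores_constants(grids_small):
    _, detectors = grids_small
    rng = np.random.default_rng(0)
    raw = {"tracks": rng.gamma(2, 3, size=(detectors.n_detectors, 3))}
    standardize_covariates(detectors, raw)
    z = detectors.covariates["tracks"]
    mu, sd = detectors.cov_constants["tracks"]
    assert abs(z.mean()) < 1e-12 and abs(z.std() - 1) < 1e-12
    assert np.allclose(z * sd + mu, raw["tracks"])
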