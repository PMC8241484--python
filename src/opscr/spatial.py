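"""Discrete spatial state space for spatial capture-recapture.

Builds the habitat grid (the state space of activity centres, including the
buffer that lets individuals move in and out of the searched area), the
detector grid with its subdetector structure, and performs the spatial data
preparation steps: assigning raw detection records to detectors/subdetectors
and the distance-based sample retention filter.

All coordinates are planar kilometres in an equal-area projection; the
package never handles lon/lat. Cell and detector indexing is 0-based,
row-major from the lower-left corner.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger("opscr")

__all__ = [
    "AsciiRaster",
    "HabitatGrid",
    "DetectorGrid",
    "DomainCoverageError",
    "ConfigurationError",
    "DataConsistencyError",
    "read_ascii_raster",
    "write_ascii_raster",
    "build_habitat_grid",
    "build_detector_grid",
    "assign_detections",
    "retain_within_radius",
    "standardize_covariates",
]

DETECTION_COLUMNS = ["individual_id", "season", "x", "y", "county_id"]


class DomainCoverageError(ValueError):
    """A raster or grid does not cover the spatial domain it must."""


class ConfigurationError(ValueError):
    """Inconsistent grid/size configuration."""


class DataConsistencyError(ValueError):
    """Input tables contradict each other (e.g. detection after death)."""


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text raster; km units in the header)
# ---------------------------------------------------------------------------

@dataclass
class AsciiRaster:
    """A regular raster; ``values[0, :]`` is the *top* row (ESRI convention)."""

    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.ncols * self.cellsize,
            self.yllcorner + self.nrows * self.cellsize,
        )


def read_ascii_raster(path) -> AsciiRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.loadtxt(lines[i:], dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise DomainCoverageError(
            f"raster body {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return AsciiRaster(
        values=values,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_raster(path, raster: AsciiRaster) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner:.6f}\n")
        fh.write(f"yllcorner {raster.yllcorner:.6f}\n")
        fh.write(f"cellsize {raster.cellsize:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:.6f}\n")
        np.savetxt(fh, raster.values, fmt="%.8g")


# ---------------------------------------------------------------------------
# Habitat grid
# ---------------------------------------------------------------------------

@dataclass
class HabitatGrid:
    """Regular lattice of habitat cells holding the density covariate X.

    The grid covers the detector (core) extent expanded by ``buffer_width``,
    so activity centres can sit outside the searched area. ``region_id``
    partitions cells into disjoint regions; movement is confined within a
    region.
    """

    cell_centres: np.ndarray          # (nc, 2) km
    cell_size: float
    X: np.ndarray                     # (nc,) density covariate
    region_id: np.ndarray             # (nc,) int
    buffer_width: float
    core_extent: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        self.cell_centres = np.asarray(self.cell_centres, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.region_id = np.asarray(self.region_id, dtype=int)
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.buffer_width < 0:
            raise ConfigurationError("buffer_width must be non-negative")
        if not np.all(np.isfinite(self.X)):
            raise ConfigurationError("habitat covariate X must be finite in every cell")
        # regular-lattice check: constant spacing relative to the grid origin
        offs = (self.cell_centres - self.cell_centres.min(axis=0)) / self.cell_size
        if not np.allclose(offs, np.round(offs), atol=1e-8):
            raise ConfigurationError("cell centres do not lie on a regular lattice")

    @property
    def n_cells(self) -> int:
        return self.cell_centres.shape[0]

    @property
    def n_regions(self) -> int:
        return int(self.region_id.max()) + 1 if self.n_cells else 0

    def cell_of(self, xy: np.ndarray) -> np.ndarray:
        """Index of the habitat cell containing each point (-1 if none)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        tree = cKDTree(self.cell_centres)
        dist, idx = tree.query(xy)
        half = self.cell_size / 2.0
        inside = np.all(np.abs(xy - self.cell_centres[idx]) <= half + 1e-9, axis=1)
        out = np.where(inside, idx, -1)
        return out

    def validate_buffer(self, sigma_max: float) -> bool:
        """Warn unless the buffer is at least 6 times the largest admissible
        detection scale (the half-normal kernel is negligible beyond that)."""
        ok = self.buffer_width >= 6.0 * sigma_max
        if not ok:
            warnings.warn(
                f"buffer width {self.buffer_width} km is below 6*sigma_max "
                f"({6.0 * sigma_max} km); activity centres near the edge may "
                "be truncated",
                stacklevel=2,
            )
        return ok


def _lattice_centres(extent, size) -> tuple[np.ndarray, int, int]:
    """Row-major (from lower-left) centres of a lattice covering extent."""
    xmin, ymin, xmax, ymax = extent
    nx = int(round((xmax - xmin) / size))
    ny = int(round((ymax - ymin) / size))
    if nx <= 0 or ny <= 0 or not (
        np.isclose(xmin + nx * size, xmax) and np.isclose(ymin + ny * size, ymax)
    ):
        raise ConfigurationError(
            f"extent {extent} is not an integer multiple of size {size}"
        )
    xs = xmin + size * (np.arange(nx) + 0.5)
    ys = ymin + size * (np.arange(ny) + 0.5)
    gx, gy = np.meshgrid(xs, ys)          # row-major: y varies slowest
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    return centres, nx, ny


def _area_weighted_resample(raster: AsciiRaster, centres: np.ndarray, cell_size: float) -> np.ndarray:
    """Area-weighted mean of raster values over each square target cell."""
    half = cell_size / 2.0
    rx0, ry0 = raster.xllcorner, raster.yllcorner
    cs = raster.cellsize
    # raster row 0 is the top row -> flip so row index increases with y
    vals = raster.values[::-1, :]
    out = np.empty(centres.shape[0])
    for k, (cx, cy) in enumerate(centres):
        x0, x1 = cx - half, cx + half
        y0, y1 = cy - half, cy + half
        i0 = int(np.floor((x0 - rx0) / cs + 1e-9))
        i1 = int(np.ceil((x1 - rx0) / cs - 1e-9))
        j0 = int(np.floor((y0 - ry0) / cs + 1e-9))
        j1 = int(np.ceil((y1 - ry0) / cs - 1e-9))
        if i0 < 0 or j0 < 0 or i1 > raster.ncols or j1 > raster.nrows:
            raise DomainCoverageError(
                "covariate raster does not cover the buffered habitat extent"
            )
        ii = np.arange(i0, i1)
        jj = np.arange(j0, j1)
        wx = np.minimum(x1, rx0 + (ii + 1) * cs) - np.maximum(x0, rx0 + ii * cs)
        wy = np.minimum(y1, ry0 + (jj + 1) * cs) - np.maximum(y0, ry0 + jj * cs)
        w = np.outer(wy, wx)
        block = vals[np.ix_(jj, ii)]
        out[k] = float((w * block).sum() / w.sum())
    return out


def build_habitat_grid(
    extent,
    cell_size: float,
    covariate_raster: AsciiRaster,
    buffer_width: float = 0.0,
    n_regions: int = 1,
) -> HabitatGrid:
    """Lay a regular habitat lattice over ``extent`` expanded by the buffer.

    ``extent`` is the core (detector) extent ``(xmin, ymin, xmax, ymax)`` in
    km. The density covariate is resampled to cell resolution by
    area-weighted mean. ``n_regions > 1`` splits the grid into vertical bands
    of cells with distinct ``region_id`` (disjoint movement state spaces).
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ConfigurationError("extent is degenerate")
    if cell_size <= 0:
        raise ConfigurationError("cell_size must be positive")
    buffered = (xmin - buffer_width, ymin - buffer_width,
                xmax + buffer_width, ymax + buffer_width)
    centres, nx, ny = _lattice_centres(buffered, cell_size)
    rext = covariate_raster.extent
    if (rext[0] > buffered[0] + 1e-9 or rext[1] > buffered[1] + 1e-9
            or rext[2] < buffered[2] - 1e-9 or rext[3] < buffered[3] - 1e-9):
        raise DomainCoverageError(
            f"covariate raster extent {rext} does not cover the buffered "
            f"habitat extent {buffered}"
        )
    X = _area_weighted_resample(covariate_raster, centres, cell_size)
    # vertical bands by x coordinate
    edges = np.linspace(buffered[0], buffered[2], n_regions + 1)
    region = np.clip(np.searchsorted(edges, centres[:, 0], side="right") - 1,
                     0, n_regions - 1)
    return HabitatGrid(
        cell_centres=centres,
        cell_size=cell_size,
        X=X,
        region_id=region,
        buffer_width=buffer_width,
        core_extent=tuple(extent),
    )


# ---------------------------------------------------------------------------
# Detector grid
# ---------------------------------------------------------------------------

@dataclass
class DetectorGrid:
    """Main detectors with their habitat-overlapping subdetector counts K.

    Each detector is the centre of a ``detector_size`` cell, subdivided into
    ``(detector_size/subdetector_size)**2`` subdetectors; ``K[j]`` counts the
    subdetector centres that fall inside a habitat cell and is the binomial
    sample size of the observation model. Detector covariates are stored
    z-scored with their standardization constants.
    """

    detector_centres: np.ndarray      # (nd, 2)
    detector_size: float
    subdetector_size: float
    K: np.ndarray                     # (nd,) int
    county_id: np.ndarray             # (nd,) int
    covariates: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (nd, T)
    cov_constants: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.detector_centres = np.asarray(self.detector_centres, dtype=float)
        self.K = np.asarray(self.K, dtype=int)
        self.county_id = np.asarray(self.county_id, dtype=int)
        nsub = int(round(self.detector_size / self.subdetector_size)) ** 2
        if np.any(self.K < 1) or np.any(self.K > nsub):
            raise ConfigurationError("K must satisfy 1 <= K_j <= (detector/sub)^2")
        for name, arr in self.covariates.items():
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"covariate {name!r} has non-finite values")

    @property
    def n_detectors(self) -> int:
        return self.detector_centres.shape[0]

    @property
    def n_counties(self) -> int:
        return int(self.county_id.max()) + 1 if self.n_detectors else 0

    def subdetector_centres(self, j: int) -> np.ndarray:
        """Centres of all subdetectors of detector j (habitat overlap ignored)."""
        m = int(round(self.detector_size / self.subdetector_size))
        off = self.subdetector_size * (np.arange(m) + 0.5) - self.detector_size / 2.0
        gx, gy = np.meshgrid(off, off)
        return self.detector_centres[j] + np.column_stack([gx.ravel(), gy.ravel()])


def build_detector_grid(
    extent,
    detector_size: float,
    subdetector_size: float,
    habitat: HabitatGrid,
    n_counties: int = 1,
) -> DetectorGrid:
    """Detector lattice over the core extent, with K from habitat overlap.

    A subdetector overlaps the habitat when its centre point falls inside a
    habitat cell; detectors with no overlapping subdetectors are dropped.
    Counties are vertical bands over the detector extent.
    """
    ratio = detector_size / subdetector_size
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigurationError(
            "detector_size must be an integer multiple of subdetector_size"
        )
    centres, nx, ny = _lattice_centres(extent, detector_size)
    m = int(round(ratio))
    off = subdetector_size * (np.arange(m) + 0.5) - detector_size / 2.0
    gx, gy = np.meshgrid(off, off)
    offsets = np.column_stack([gx.ravel(), gy.ravel()])   # (m*m, 2)
    subs = centres[:, None, :] + offsets[None, :, :]      # (nd, m*m, 2)
    inside = habitat.cell_of(subs.reshape(-1, 2)).reshape(subs.shape[:2]) >= 0
    K = inside.sum(axis=1)
    keep = K > 0
    centres = centres[keep]
    K = K[keep]
    edges = np.linspace(extent[0], extent[2], n_counties + 1)
    county = np.clip(np.searchsorted(edges, centres[:, 0], side="right") - 1,
                     0, n_counties - 1)
    return DetectorGrid(
        detector_centres=centres,
        detector_size=detector_size,
        subdetector_size=subdetector_size,
        K=K,
        county_id=county,
    )


def standardize_covariates(
    detectors: DetectorGrid, raw: dict[str, np.ndarray]
) -> DetectorGrid:
    """Z-score each detector covariate over detectors x seasons, storing the
    (mean, sd) constants on the grid so linear predictors are reproducible."""
    for name, arr in raw.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] != detectors.n_detectors:
            raise ConfigurationError(
                f"covariate {name!r} first axis must index detectors"
            )
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError(f"covariate {name!r} has missing values")
        mu = float(arr.mean())
        sd = float(arr.std())
        if sd == 0.0:
            sd = 1.0
        detectors.covariates[name] = (arr - mu) / sd
        detectors.cov_constants[name] = (mu, sd)
    return detectors


# ---------------------------------------------------------------------------
# Detection assignment and retention filter
# ---------------------------------------------------------------------------

def assign_detections(records: pd.DataFrame, detectors: DetectorGrid) -> pd.DataFrame:
    """Aggregate raw detection records to subdetector counts y.

    Each record is mapped to the nearest detector centre and then to the
    nearest subdetector centre of that detector (ties broken by lowest
    index). Returns a sparse table with one row per (individual_id, detector,
    season) holding ``y`` = the number of distinct subdetectors with at least
    one detection; 0 <= y <= K_j. Records beyond the footprint of every
    detector are excluded with a logged count.
    """
    req = {"individual_id", "season", "x", "y"}
    missing = req - set(records.columns)
    if missing:
        raise DataConsistencyError(f"detection table misses columns {sorted(missing)}")
    if len(records) == 0:
        return pd.DataFrame(columns=["individual_id", "detector", "season", "y"])
    xy = records[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise DataConsistencyError("detection coordinates must be finite")
    # exhaustive distances; lowest index wins ties exactly
    d2 = ((xy[:, None, :] - detectors.detector_centres[None, :, :]) ** 2).sum(axis=2)
    jmin = np.argmin(d2, axis=1)   # argmin returns the first (lowest) index on ties
    half = detectors.detector_size / 2.0
    inside = np.all(
        np.abs(xy - detectors.detector_centres[jmin]) <= half + 1e-9, axis=1
    )
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning("excluded %d detection record(s) outside all detectors", n_dropped)
    sub_idx = np.full(len(records), -1, dtype=int)
    for j in np.unique(jmin[inside]):
        rows = np.where(inside & (jmin == j))[0]
        sc = detectors.subdetector_centres(int(j))
        sd2 = ((xy[rows, None, :] - sc[None, :, :]) ** 2).sum(axis=2)
        sub_idx[rows] = np.argmin(sd2, axis=1)
    kept = records.loc[inside].copy()
    kept["detector"] = jmin[inside]
    kept["subdetector"] = sub_idx[inside]
    grouped = (
        kept.groupby(["individual_id", "detector", "season"])["subdetector"]
        .nunique()
        .rename("y")
        .reset_index()
    )
    ymax = detectors.K[grouped["detector"].to_numpy()]
    # distinct subdetectors hit can never exceed the subdivision count;
    # exceeding K would mean detections on non-habitat subdetectors
    if np.any(grouped["y"].to_numpy() > ymax):
        logger.warning("some detectors recorded hits on non-habitat subdetectors")
        grouped["y"] = np.minimum(grouped["y"].to_numpy(), ymax)
    return grouped


def retain_within_radius(
    records: pd.DataFrame, reference_points: np.ndarray, radius: float
) -> pd.DataFrame:
    """Keep records whose minimum distance to any reference point is <= radius.

    This is the spatial retention filter used to restrict the analysis to the
    neighbourhood of the collared individuals' samples.
    """
    if radius <= 0:
        raise ConfigurationError("radius must be positive")
    reference_points = np.atleast_2d(np.asarray(reference_points, dtype=float))
    if reference_points.size == 0:
        raise ConfigurationError("retention filter needs at least one reference point")
    if len(records) == 0:
        return records.copy()
    xy = records[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(reference_points)
    dmin, _ = tree.query(xy)
    return records.loc[dmin <= radius].copy()


# ---------------------------------------------------------------------------
# Geometry export
# ---------------------------------------------------------------------------

def export_geometry(habitat: HabitatGrid, detectors: DetectorGrid, prefix) -> None:
    """Write cell/detector centres as CSV plus a JSON metadata sidecar."""
    prefix = str(prefix)
    pd.DataFrame({
        "cell": np.arange(habitat.n_cells),
        "x": habitat.cell_centres[:, 0],
        "y": habitat.cell_centres[:, 1],
        "X": habitat.X,
        "region_id": habitat.region_id,
    }).to_csv(prefix + "_habitat.csv", index=False)
    pd.DataFrame({
        "detector": np.arange(detectors.n_detectors),
        "x": detectors.detector_centres[:, 0],
        "y": detectors.detector_centres[:, 1],
        "K": detectors.K,
        "county_id": detectors.county_id,
    }).to_csv(prefix + "_detectors.csv", index=False)
    meta = {
        "cell_size": habitat.cell_size,
        "buffer_width": habitat.buffer_width,
        "core_extent": list(habitat.core_extent),
        "detector_size": detectors.detector_size,
        "subdetector_size": detectors.subdetector_size,
        "cov_constants": {k: list(v) for k, v in detectors.cov_constants.items()},
    }
    with open(prefix + "_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
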