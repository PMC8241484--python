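"""Synthetic OPSCR studies with the full statistical structure of the model.

The generator composes the three forward processes — multistate demography
with collar-dependent hazards, covariate-weighted random-walk movement of
activity centres, and half-normal subdetector detection — and emits exactly
the tables and rasters the data-preparation layer consumes: detection
records, a collar table, dead recoveries, a density-covariate raster and a
truth manifest for parameter-recovery tests.

Conventions
-----------
* Collars are assigned at the start of each season to previously uncollared
  individuals alive in that season, topping the collared share up to
  ``collar_fraction`` of the living; a collar stays on for
  ``collar_duration`` seasons (never re-fitted). The hazards for the
  interval (t, t+1] and the detectability in season t both use the collar
  status of season t, so generator and likelihood share one covariate table.
* All legal-culling deaths are recovered; other-cause deaths are recovered
  with probability ``other_recovery_prob`` (cryptic mortality).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spatial import (
    AsciiRaster, HabitatGrid, DetectorGrid,
    build_habitat_grid, build_detector_grid, standardize_covariates,
    write_ascii_raster, read_ascii_raster, export_geometry,
)
from .demography import DemographicParams, State
from .movement import MovementParams, initial_ac_distribution, movement_kernel_matrix
from .detection import DetectionParams, COVARIATE_NAMES, _p_matrix

__all__ = ["StudyConfig", "SyntheticStudy", "generate_study", "assign_collars",
           "flagship_config"]

_LOGIT = lambda p: float(np.log(p / (1.0 - p)))


@dataclass
class StudyConfig:
    """Generator settings; defaults emulate the wolverine monitoring design
    (20 km habitat cells, 10 km detectors with 2 km subdetectors, 60 km
    buffer, eight seasons) with the reported cause-specific mortality of
    non-collared individuals (h = 0.10, w = 0.25) and the reported
    logit-scale collar effects (-0.37 on legal culling, -1.08 on other
    mortality) as generating truth."""

    core_extent: tuple = (0.0, 0.0, 240.0, 240.0)
    cell_size: float = 20.0
    detector_size: float = 10.0
    subdetector_size: float = 2.0
    buffer_width: float = 60.0
    n_regions: int = 2
    n_sexes: int = 2
    n_counties: int = 2
    T: int = 8
    M: int = 600
    # demography (probability scale for intercept-type truths)
    psi: float = 0.35
    gamma: float = 0.15
    h: float = 0.10
    w: float = 0.25
    beta_h_gps: float = -0.37
    beta_w_gps: float = -1.08
    # movement
    tau: float = 10.0
    b_dens: float = 0.5
    # detection
    p0: float = 0.02
    sigma: float = 8.0
    beta_tracks: float = 0.25
    beta_roads: float = -0.2
    beta_snow: float = 0.2
    beta_prevdet: float = 0.4
    beta_gps_det: float = -0.3
    # collaring and recoveries
    collar_fraction: float = 0.05
    collar_duration: int = 2
    other_recovery_prob: float = 0.03
    # non-random collaring (sensitivity mode): log-odds tilt of collar
    # assignment toward individuals recruited in the current season,
    # emulating over-representation of young animals among captures
    collar_recruit_bias: float = 0.0

    @property
    def n_groups(self) -> int:
        return self.n_regions * self.n_sexes

    def region_of_group(self, g: int) -> int:
        return g // self.n_sexes

    def demographic_truth(self) -> DemographicParams:
        G, T = self.n_groups, self.T
        return DemographicParams(
            psi=np.full(G, self.psi),
            gamma=np.full((G, T - 1), self.gamma),
            h0=np.full((G, T - 1), _LOGIT(self.h)),
            w0=np.full((G, T - 1), _LOGIT(self.w)),
            beta_h_gps=self.beta_h_gps,
            beta_w_gps=self.beta_w_gps,
        )

    def movement_truth(self) -> MovementParams:
        return MovementParams(tau=self.tau, b_dens=self.b_dens)

    def detection_truth(self) -> DetectionParams:
        return DetectionParams(
            p0_intercept=np.full((self.n_counties, self.T), _LOGIT(self.p0)),
            sigma=self.sigma,
            beta_tracks=self.beta_tracks,
            beta_roads=self.beta_roads,
            beta_snow=self.beta_snow,
            beta_prevdet=self.beta_prevdet,
            beta_gps=self.beta_gps_det,
        )

    def validate(self) -> None:
        for gps in (0, 1):
            h = 1 / (1 + np.exp(-(_LOGIT(self.h) + self.beta_h_gps * gps)))
            w = 1 / (1 + np.exp(-(_LOGIT(self.w) + self.beta_w_gps * gps)))
            if h + w >= 1.0:
                raise ValueError(
                    f"infeasible truth: h + w = {h + w:.3f} >= 1 for gps={gps}"
                )
        if not 0.0 <= self.collar_fraction <= 1.0:
            raise ValueError("collar_fraction must be in [0, 1]")
        if self.collar_duration < 1:
            raise ValueError("collar_duration must be >= 1")


def flagship_config(**overrides) -> StudyConfig:
    """Scaled-down single-group study used by the recovery experiments:
    100 x 100 km searched area, 40 km buffer (6 x the 6.5 km admissible
    upper bound on sigma, rounded up to whole habitat cells), five seasons,
    M = 300, ~20% of living individuals collared, detection scale
    sigma = 5 km. Baseline detectability is raised relative to the
    full-scale defaults so the reduced detector array retains enough
    information per individual."""
    base = dict(
        core_extent=(0.0, 0.0, 100.0, 100.0),
        cell_size=20.0,
        detector_size=10.0,
        subdetector_size=2.0,
        buffer_width=40.0,
        n_regions=1, n_sexes=1, n_counties=1,
        T=5, M=300,
        psi=0.30, gamma=0.12,
        tau=10.0, b_dens=0.5,
        p0=0.12, sigma=5.0,
        collar_fraction=0.20, collar_duration=2,
    )
    base.update(overrides)
    return StudyConfig(**base)


@dataclass
class SyntheticStudy:
    """A complete simulated study plus its generating truth."""

    config: StudyConfig
    seed: int
    habitat: HabitatGrid
    detectors: DetectorGrid
    covariate_raster: AsciiRaster
    individuals: pd.DataFrame       # individual_id, group, sex, region (all M)
    detections: pd.DataFrame        # individual_id, season, x, y, county_id
    collar: pd.DataFrame            # individual_id, season, gps
    recoveries: pd.DataFrame        # individual_id, season, cause, x, y
    truth: dict                     # parameters, z, s, summary counts

    def gps_matrix(self) -> np.ndarray:
        M, T = self.config.M, self.config.T
        gps = np.zeros((M, T), dtype=int)
        idx = {iid: i for i, iid in enumerate(self.individuals["individual_id"])}
        for _, r in self.collar.iterrows():
            gps[idx[r["individual_id"]], int(r["season"]) - 1] = int(r["gps"])
        return gps

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_ascii_raster(path / "density_covariate.asc", self.covariate_raster)
        self.individuals.to_csv(path / "individuals.csv", index=False)
        self.detections.to_csv(path / "detections.csv", index=False)
        self.collar.to_csv(path / "collar.csv", index=False)
        self.recoveries.to_csv(path / "recoveries.csv", index=False)
        for name in COVARIATE_NAMES:
            raw = (self.detectors.covariates[name]
                   * self.detectors.cov_constants[name][1]
                   + self.detectors.cov_constants[name][0])
            pd.DataFrame(raw).to_csv(path / f"cov_{name}.csv", index=False)
        export_geometry(self.habitat, self.detectors, path / "geometry")
        cfg = asdict(self.config)
        cfg["core_extent"] = list(cfg["core_extent"])
        with open(path / "config.yaml", "w") as fh:
            yaml.safe_dump({"config": cfg, "seed": self.seed}, fh)
        truth = dict(self.truth)
        with open(path / "truth.json", "w") as fh:
            import json
            json.dump(truth, fh, indent=1)

    @classmethod
    def from_dir(cls, path) -> "SyntheticStudy":
        path = Path(path)
        with open(path / "config.yaml") as fh:
            blob = yaml.safe_load(fh)
        cfg = blob["config"]
        cfg["core_extent"] = tuple(cfg["core_extent"])
        config = StudyConfig(**cfg)
        raster = read_ascii_raster(path / "density_covariate.asc")
        habitat = build_habitat_grid(config.core_extent, config.cell_size, raster,
                                     config.buffer_width, config.n_regions)
        detectors = build_detector_grid(config.core_extent, config.detector_size,
                                        config.subdetector_size, habitat,
                                        config.n_counties)
        raw = {name: pd.read_csv(path / f"cov_{name}.csv").to_numpy()
               for name in COVARIATE_NAMES}
        standardize_covariates(detectors, raw)
        import json
        with open(path / "truth.json") as fh:
            truth = json.load(fh)
        return cls(
            config=config, seed=int(blob["seed"]), habitat=habitat,
            detectors=detectors, covariate_raster=raster,
            individuals=pd.read_csv(path / "individuals.csv"),
            detections=pd.read_csv(path / "detections.csv"),
            collar=pd.read_csv(path / "collar.csv"),
            recoveries=pd.read_csv(path / "recoveries.csv"),
            truth=truth,
        )


# ---------------------------------------------------------------------------
# Collar assignment
# ---------------------------------------------------------------------------

def assign_collars(
    alive: np.ndarray,
    fraction: float,
    duration_seasons: int,
    rng: np.random.Generator,
    recruit_bias: float = 0.0,
    recruited: np.ndarray | None = None,
) -> np.ndarray:
    """Season-by-season collar assignment over an alive matrix (n, T).

    At each season the collared share of living individuals is topped up to
    ``fraction`` by sampling previously uncollared living individuals;
    collars stay on for ``duration_seasons`` seasons and are never re-fitted.
    ``recruit_bias`` tilts the sampling log-odds toward individuals whose
    first alive season is the current one (non-random capture mode).
    Returns the binary GPS matrix (n, T).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if duration_seasons < 1:
        raise ValueError("duration_seasons must be >= 1")
    alive = np.asarray(alive, dtype=bool)
    n, T = alive.shape
    gps = np.zeros((n, T), dtype=int)
    ever = np.zeros(n, dtype=bool)
    for t in range(T):
        living = np.where(alive[:, t])[0]
        if living.size == 0:
            continue
        target = int(round(fraction * living.size))
        current = int((gps[living, t] == 1).sum())
        need = target - current
        pool = living[(gps[living, t] == 0) & (~ever[living])]
        if need <= 0 or pool.size == 0:
            continue
        need = min(need, pool.size)
        if recruit_bias != 0.0 and recruited is not None:
            logw = recruit_bias * recruited[pool, t].astype(float)
            w = np.exp(logw - logw.max())
            w /= w.sum()
            chosen = rng.choice(pool, size=need, replace=False, p=w)
        else:
            chosen = rng.choice(pool, size=need, replace=False)
        ever[chosen] = True
        gps[chosen, t:t + duration_seasons] = 1
    return gps


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------

def _synthesize_density_raster(extent, rng, cellsize=10.0, n_bumps=6) -> AsciiRaster:
    """Smooth positive field (sum of Gaussian bumps), roughly unit-scale."""
    xmin, ymin, xmax, ymax = extent
    ncols = int(np.ceil((xmax - xmin) / cellsize))
    nrows = int(np.ceil((ymax - ymin) / cellsize))
    xs = xmin + cellsize * (np.arange(ncols) + 0.5)
    ys = ymin + cellsize * (np.arange(nrows) + 0.5)
    gx, gy = np.meshgrid(xs, ys)
    field_vals = np.zeros_like(gx)
    span = max(xmax - xmin, ymax - ymin)
    for _ in range(n_bumps):
        cx = rng.uniform(xmin, xmax)
        cy = rng.uniform(ymin, ymax)
        scale = rng.uniform(0.1, 0.3) * span
        amp = rng.uniform(0.5, 1.5)
        field_vals += amp * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * scale ** 2))
    field_vals = (field_vals - field_vals.mean()) / (field_vals.std() + 1e-12)
    return AsciiRaster(values=field_vals[::-1, :], xllcorner=xmin, yllcorner=ymin,
                       cellsize=cellsize)


def generate_study(config: StudyConfig, seed: int) -> SyntheticStudy:
    """Simulate a complete study; deterministic under ``seed``."""
    config.validate()
    rng = np.random.default_rng(seed)
    buffered = (config.core_extent[0] - config.buffer_width,
                config.core_extent[1] - config.buffer_width,
                config.core_extent[2] + config.buffer_width,
                config.core_extent[3] + config.buffer_width)
    raster = _synthesize_density_raster(buffered, rng)
    habitat = build_habitat_grid(config.core_extent, config.cell_size, raster,
                                 config.buffer_width, config.n_regions)
    detectors = build_detector_grid(config.core_extent, config.detector_size,
                                    config.subdetector_size, habitat,
                                    config.n_counties)
    T, M, G = config.T, config.M, config.n_groups
    nd = detectors.n_detectors
    raw_cov = {
        "tracks": rng.gamma(4.0, 5.0, size=(nd, T)),          # km searched
        "roads": np.repeat(rng.exponential(5.0, size=(nd, 1)), T, axis=1),
        "snow": np.clip(rng.normal(0.6, 0.25, size=(nd, T)), 0, 1),
    }
    standardize_covariates(detectors, raw_cov)

    demo = config.demographic_truth()
    mov = config.movement_truth()
    det = config.detection_truth()

    group = np.arange(M) % G
    region = np.array([config.region_of_group(g) for g in group])
    sex = group % config.n_sexes
    ids = np.array([f"id{i:04d}" for i in range(M)])

    # per-region movement machinery
    init_p = [initial_ac_distribution(habitat, mov, r) for r in range(config.n_regions)]
    kern_cum = []
    for r in range(config.n_regions):
        P = np.exp(movement_kernel_matrix(habitat, mov, r))
        P[~np.isfinite(P)] = 0.0
        kern_cum.append(np.cumsum(P, axis=1))
    init_cum = [np.cumsum(p) for p in init_p]

    # subdetector geometry: which subdetectors of each detector overlap habitat
    overlap_subs = []
    for j in range(nd):
        sc = detectors.subdetector_centres(j)
        overlap_subs.append(np.where(habitat.cell_of(sc) >= 0)[0])

    z = np.zeros((M, T), dtype=int)
    s = np.zeros((M, T), dtype=int)
    gps = np.zeros((M, T), dtype=int)
    prev = np.zeros((M, T), dtype=int)
    detected_before = np.zeros(M, dtype=bool)
    ever_collared = np.zeros(M, dtype=bool)
    recruited = np.zeros((M, T), dtype=bool)
    records: list[tuple] = []
    recov_rows: list[tuple] = []

    # season 1 states and ACs
    z[:, 0] = np.where(rng.random(M) < demo.psi[group], State.ALIVE, State.UNBORN)
    recruited[:, 0] = z[:, 0] == State.ALIVE
    u = rng.random(M)
    for r in range(config.n_regions):
        m = region == r
        s[m, 0] = np.searchsorted(init_cum[r], u[m])

    half_sub = config.subdetector_size / 2.0

    def top_up_collars(t0: int) -> None:
        living = np.where(z[:, t0] == State.ALIVE)[0]
        if living.size == 0 or config.collar_fraction == 0.0:
            return
        target = int(round(config.collar_fraction * living.size))
        need = target - int((gps[living, t0] == 1).sum())
        pool = living[(gps[living, t0] == 0) & (~ever_collared[living])]
        if need <= 0 or pool.size == 0:
            return
        need = min(need, pool.size)
        if config.collar_recruit_bias != 0.0:
            logw = config.collar_recruit_bias * recruited[pool, t0].astype(float)
            w = np.exp(logw - logw.max())
            chosen = rng.choice(pool, size=need, replace=False, p=w / w.sum())
        else:
            chosen = rng.choice(pool, size=need, replace=False)
        ever_collared[chosen] = True
        gps[chosen, t0:t0 + config.collar_duration] = 1

    def detect_season(t0: int) -> None:
        prev[:, t0] = detected_before.astype(int)
        alive = np.where(z[:, t0] == State.ALIVE)[0]
        if alive.size == 0:
            return
        p, _ = _p_matrix(det, detectors, habitat, t0 + 1,
                         gps[alive, t0], prev[alive, t0], s[alive, t0])
        y = rng.binomial(np.broadcast_to(detectors.K, p.shape), p)
        ii, jj = np.nonzero(y)
        for a, j in zip(ii, jj):
            i = alive[a]
            subs = rng.choice(overlap_subs[j], size=y[a, j], replace=False)
            sc = detectors.subdetector_centres(j)[subs]
            jit = rng.uniform(-half_sub, half_sub, size=sc.shape)
            for (px, py) in sc + jit:
                records.append((ids[i], t0 + 1, px, py,
                                int(detectors.county_id[j])))
            detected_before[i] = True

    top_up_collars(0)
    detect_season(0)

    for t in range(1, T):
        # transitions into season t use collar status of season t-1
        uz = rng.random(M)
        for g in range(G):
            for gv in (0, 1):
                m = (group == g) & (gps[:, t - 1] == gv)
                if not m.any():
                    continue
                h = 1 / (1 + np.exp(-(demo.h0[g, t - 1] + demo.beta_h_gps * gv)))
                w = 1 / (1 + np.exp(-(demo.w0[g, t - 1] + demo.beta_w_gps * gv)))
                gam = demo.gamma[g, t - 1]
                prev_z = z[m, t - 1]
                out = np.full(prev_z.shape, State.DEAD_OTHER, dtype=int)
                un = prev_z == State.UNBORN
                out[un] = np.where(uz[m][un] < gam, State.ALIVE, State.UNBORN)
                al = prev_z == State.ALIVE
                ua = uz[m][al]
                out[al] = np.select(
                    [ua < 1 - h - w, ua < 1 - w], [State.ALIVE, State.DEAD_LEGAL],
                    State.DEAD_OTHER,
                )
                z[m, t] = out
        recruited[:, t] = (z[:, t] == State.ALIVE) & (z[:, t - 1] == State.UNBORN)
        # AC movement (paths persist after death; harmless, unobserved)
        us = rng.random(M)
        for r in range(config.n_regions):
            m = region == r
            rows = kern_cum[r][s[m, t - 1]]
            s[m, t] = (rows < us[m][:, None]).sum(axis=1)
        # dead recoveries
        died_legal = np.where((z[:, t - 1] == State.ALIVE) & (z[:, t] == State.DEAD_LEGAL))[0]
        died_other = np.where((z[:, t - 1] == State.ALIVE) & (z[:, t] == State.DEAD_OTHER))[0]
        for i in died_legal:
            cx, cy = habitat.cell_centres[s[i, t]]
            jx, jy = rng.uniform(-habitat.cell_size / 2, habitat.cell_size / 2, 2)
            recov_rows.append((ids[i], t + 1, "legal", cx + jx, cy + jy))
        for i in died_other:
            if rng.random() < config.other_recovery_prob:
                cx, cy = habitat.cell_centres[s[i, t]]
                jx, jy = rng.uniform(-habitat.cell_size / 2, habitat.cell_size / 2, 2)
                recov_rows.append((ids[i], t + 1, "other", cx + jx, cy + jy))
        top_up_collars(t)
        detect_season(t)

    detections = pd.DataFrame(
        records, columns=["individual_id", "season", "x", "y", "county_id"]
    )
    recoveries = pd.DataFrame(
        recov_rows, columns=["individual_id", "season", "cause", "x", "y"]
    )
    collar_rows = [(ids[i], t + 1, int(gps[i, t]))
                   for i in range(M) for t in range(T) if gps[i, t]]
    collar = pd.DataFrame(collar_rows, columns=["individual_id", "season", "gps"])
    individuals = pd.DataFrame({
        "individual_id": ids, "group": group, "sex": sex, "region": region,
    })
    ever_alive = (z == State.ALIVE).any(axis=1)
    truth = {
        "seed": seed,
        "params": {
            "psi": config.psi, "gamma": config.gamma,
            "h": config.h, "w": config.w,
            "h0_logit": _LOGIT(config.h), "w0_logit": _LOGIT(config.w),
            "beta_h_gps": config.beta_h_gps, "beta_w_gps": config.beta_w_gps,
            "tau": config.tau, "b_dens": config.b_dens,
            "sigma": config.sigma, "p0": config.p0,
            "p0_logit": _LOGIT(config.p0),
            "beta_tracks": config.beta_tracks, "beta_roads": config.beta_roads,
            "beta_snow": config.beta_snow, "beta_prevdet": config.beta_prevdet,
            "beta_gps_det": config.beta_gps_det,
        },
        "z": z.tolist(), "s": s.tolist(), "gps": gps.tolist(),
        "n_ever_alive": int(ever_alive.sum()),
        "n_detected": int(detections["individual_id"].nunique()),
        "n_collared": int(ever_collared.sum()),
        "n_recoveries_legal": int((recoveries["cause"] == "legal").sum())
        if len(recoveries) else 0,
        "n_recoveries_other": int((recoveries["cause"] == "other").sum())
        if len(recoveries) else 0,
    }
    return SyntheticStudy(
        config=config, seed=seed, habitat=habitat, detectors=detectors,
        covariate_raster=raster, individuals=individuals, detections=detections,
        collar=collar, recoveries=recoveries, truth=truth,
    )
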