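"""Bayesian fitting of the open-population SCR model by MCMC.

The posterior couples three processes: the four-state demographic chain with
collar-dependent cause-specific hazards, the covariate-weighted random walk
of activity centres over the discrete habitat, and half-normal subdetector
detection. Sampling is Metropolis-within-Gibbs:

* activity-centre cells are updated by exact single-site Gibbs draws (the
  latent state chain is marginalized on the fly by forward-backward
  messages, so AC updates never condition on a particular z);
* the latent states z are either sampled explicitly by forward-filtering
  backward-sampling (``mode="latent"``, the default, mirroring the
  categorical formulation) or marginalized out of every likelihood by the
  forward algorithm (``mode="marginal"``, a faster-mixing option that the
  tests also use as an exactness cross-check);
* scalar parameters move by adaptive random-walk Metropolis on transformed
  scales (logit for probabilities), with proposal scales tuned only during
  burn-in.

Readable reference implementations (:func:`joint_loglik`,
:func:`marginal_loglik_forward`) stand apart from the vectorized sampler and
serve as oracles in the test-suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit, logsumexp

from .spatial import HabitatGrid, DetectorGrid, DataConsistencyError
from .demography import (
    DemographicParams, State, InfeasibleHazardError,
    initial_distribution, transition_matrix, state_constraints_from_recoveries,
)
from .movement import (
    MovementParams, initial_ac_distribution, movement_kernel_matrix,
)
from .detection import DetectionParams, binom_log_coeff, observation_loglik

__all__ = [
    "StudyData", "ModelParameters", "Priors", "MCMCConfig", "PosteriorResult",
    "prepare_study_data", "prepare_from_synthetic",
    "joint_loglik", "marginal_loglik_forward", "params_from_vector",
    "run_mcmc", "gelman_rubin", "derive_collar_contrasts",
    "InitializationError",
]

_NEG_INF = -np.inf


try:
    from numba import njit as _njit
except ImportError:                                    # pragma: no cover
    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=True)
def _forward_nb(loginit, logT, group, gps, e, marg, alphas, want_alpha):
    """Forward algorithm over every individual's 4-state chain.

    This is the sampler's innermost loop (it runs once per Metropolis
    proposal on demographic or detection parameters), hence the explicit
    compiled loops rather than vectorized numpy.
    """
    M = e.shape[0]
    T = e.shape[1]
    lp = np.empty(4)
    tmp = np.empty(4)
    for i in range(M):
        g = group[i]
        for z in range(4):
            lp[z] = loginit[g, z] + e[i, 0, z]
        if want_alpha:
            for z in range(4):
                alphas[i, 0, z] = lp[z]
        for k in range(T - 1):
            gv = gps[i, k]
            for z2 in range(4):
                mx = -np.inf
                for z1 in range(4):
                    v = lp[z1] + logT[g, k, gv, z1, z2]
                    if v > mx:
                        mx = v
                if mx == -np.inf:
                    tmp[z2] = -np.inf
                else:
                    s = 0.0
                    for z1 in range(4):
                        v = lp[z1] + logT[g, k, gv, z1, z2]
                        if v > -np.inf:
                            s += np.exp(v - mx)
                    tmp[z2] = mx + np.log(s) + e[i, k + 1, z2]
            for z in range(4):
                lp[z] = tmp[z]
            if want_alpha:
                for z in range(4):
                    alphas[i, k + 1, z] = lp[z]
        mx = -np.inf
        for z in range(4):
            if lp[z] > mx:
                mx = lp[z]
        if mx == -np.inf:
            marg[i] = -np.inf
        else:
            s = 0.0
            for z in range(4):
                if lp[z] > -np.inf:
                    s += np.exp(lp[z] - mx)
            marg[i] = mx + np.log(s)


def _lse(x: np.ndarray, axis: int) -> np.ndarray:
    """Low-overhead log-sum-exp along one axis; all-(-inf) slices give -inf.

    The sampler's inner loops call this thousands of times per iteration on
    small arrays, where the generic scipy implementation's dispatch overhead
    dominates the arithmetic.
    """
    m = np.max(x, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        return np.squeeze(m, axis=axis) + np.log(np.exp(x - m).sum(axis=axis))


class InitializationError(RuntimeError):
    """The chain could not be started at a finite log-posterior."""


# ---------------------------------------------------------------------------
# Fit-ready data container
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Everything the likelihood needs, with augmented pseudo-individuals.

    Individuals 0..n_detected-1 were genetically identified (detected,
    collared or recovered); the remainder up to M are augmentation slots
    with all-zero collar covariate and no detections.
    """

    habitat: HabitatGrid
    detectors: DetectorGrid
    T: int
    M: int
    individual_ids: list
    n_detected: int
    group: np.ndarray            # (M,)
    region_of_group: np.ndarray  # (G,)
    gps: np.ndarray              # (M, T) binary
    prev: np.ndarray             # (M, T) binary, any detection strictly before t
    masks: np.ndarray            # (M, T, 4) admissible states
    y_ind: np.ndarray            # (R,) individual index of positive counts
    y_det: np.ndarray            # (R,)
    y_season: np.ndarray         # (R,) 1-based
    y_count: np.ndarray          # (R,)

    @property
    def n_groups(self) -> int:
        return len(self.region_of_group)

    @property
    def n_counties(self) -> int:
        return self.detectors.n_counties

    def y_rows(self) -> np.ndarray:
        """(R, 4) array of (individual, detector, season, y)."""
        return np.column_stack([self.y_ind, self.y_det, self.y_season, self.y_count])


def prepare_study_data(
    habitat: HabitatGrid,
    detectors: DetectorGrid,
    y_table: pd.DataFrame,
    collar: pd.DataFrame,
    recoveries: pd.DataFrame,
    M: int,
    T: int,
    groups: dict | None = None,
    n_groups: int = 1,
    region_of_group=None,
) -> StudyData:
    """Assemble the augmented likelihood inputs from prepared tables.

    ``y_table`` is the output of :func:`opscr.spatial.assign_detections`;
    ``groups`` maps detected individual_id -> group index (sex x region);
    augmented slots are spread evenly over groups.
    """
    ids = set()
    for df, col in ((y_table, "individual_id"), (collar, "individual_id"),
                    (recoveries, "individual_id")):
        if df is not None and len(df):
            ids |= set(df[col])
    detected_ids = sorted(ids)
    n_det = len(detected_ids)
    if M < n_det:
        raise DataConsistencyError(
            f"augmented size M={M} below number of identified individuals {n_det}"
        )
    all_ids = detected_ids + [f"aug{i:04d}" for i in range(M - n_det)]
    idx = {iid: i for i, iid in enumerate(all_ids)}

    group = np.zeros(M, dtype=int)
    if groups:
        for iid, g in groups.items():
            if iid in idx:
                group[idx[iid]] = int(g)
    if n_groups > 1:
        group[n_det:] = np.arange(M - n_det) % n_groups
    if region_of_group is None:
        region_of_group = np.zeros(n_groups, dtype=int)
    region_of_group = np.asarray(region_of_group, dtype=int)

    gps = np.zeros((M, T), dtype=int)
    if collar is not None and len(collar):
        for _, r in collar.iterrows():
            t = int(r["season"])
            if not 1 <= t <= T:
                raise DataConsistencyError(f"collar season {t} outside horizon")
            gps[idx[r["individual_id"]], t - 1] = int(r["gps"])

    if y_table is not None and len(y_table):
        y_ind = y_table["individual_id"].map(idx).to_numpy(dtype=int)
        y_det = y_table["detector"].to_numpy(dtype=int)
        y_season = y_table["season"].to_numpy(dtype=int)
        y_count = y_table["y"].to_numpy(dtype=int)
        keep = y_count > 0
        y_ind, y_det, y_season, y_count = (
            a[keep] for a in (y_ind, y_det, y_season, y_count))
    else:
        y_ind = y_det = y_season = y_count = np.zeros(0, dtype=int)
    if np.any(y_count > detectors.K[y_det]):
        raise DataConsistencyError("y exceeds the subdetector count K")

    prev = np.zeros((M, T), dtype=int)
    for i in np.unique(y_ind):
        first = int(y_season[y_ind == i].min())
        prev[i, first:] = 1       # seasons strictly after the first detection

    det_ev = pd.DataFrame({
        "individual_id": [all_ids[i] for i in y_ind], "season": y_season,
    })
    masks = state_constraints_from_recoveries(recoveries, T, all_ids, det_ev)
    return StudyData(
        habitat=habitat, detectors=detectors, T=T, M=M,
        individual_ids=all_ids, n_detected=n_det, group=group,
        region_of_group=region_of_group, gps=gps, prev=prev, masks=masks,
        y_ind=y_ind, y_det=y_det, y_season=y_season, y_count=y_count,
    )


def prepare_from_synthetic(
    study, M: int | None = None, augment_factor: float | None = None
) -> StudyData:
    """Run a synthetic study through the real data-preparation path.

    ``M`` sets the augmented size directly (default: the generator's own
    superpopulation bound). ``augment_factor`` instead scales the number of
    genetically identified individuals (3 is the recommended default for
    fitting, so the posterior population size has headroom below M).
    """
    from .spatial import assign_detections

    cfg = study.config
    if augment_factor is not None:
        ids = set(study.detections["individual_id"]) if len(study.detections) \
            else set()
        ids |= set(study.collar["individual_id"]) if len(study.collar) else set()
        ids |= set(study.recoveries["individual_id"]) if len(study.recoveries) \
            else set()
        M = max(int(np.ceil(augment_factor * len(ids))), M or 0)
    y_table = assign_detections(study.detections, study.detectors)
    groups = dict(zip(study.individuals["individual_id"], study.individuals["group"]))
    region_of_group = np.array(
        [cfg.region_of_group(g) for g in range(cfg.n_groups)], dtype=int
    )
    return prepare_study_data(
        study.habitat, study.detectors, y_table, study.collar, study.recoveries,
        M=M or cfg.M, T=cfg.T, groups=groups,
        n_groups=cfg.n_groups, region_of_group=region_of_group,
    )


# ---------------------------------------------------------------------------
# Reference likelihoods (oracles; readable, not fast)
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """Joint parameter bundle: demography plus per-group movement/detection
    (detection intercepts and slopes are shared; sigma may vary by group)."""

    demographic: DemographicParams
    movement: list
    detection: list

    def __post_init__(self) -> None:
        if isinstance(self.movement, MovementParams):
            self.movement = [self.movement]
        if isinstance(self.detection, DetectionParams):
            self.detection = [self.detection]


def params_from_vector(pv: dict, data: StudyData) -> ModelParameters:
    """Bundle a sampler-style parameter dict into :class:`ModelParameters`."""
    demographic = DemographicParams(
        psi=expit(pv["psi_l"]), gamma=expit(pv["gamma_l"]),
        h0=pv["h0"], w0=pv["w0"],
        beta_h_gps=float(pv["beta_h_gps"][0]),
        beta_w_gps=float(pv["beta_w_gps"][0]),
    )
    movement = [MovementParams(tau=float(pv["tau"][g]),
                               b_dens=float(pv["b_dens"][g]))
                for g in range(data.n_groups)]
    detection = [DetectionParams(
        p0_intercept=pv["p0_int"], sigma=float(pv["sigma"][g]),
        beta_tracks=float(pv["beta_tracks"][0]),
        beta_roads=float(pv["beta_roads"][0]),
        beta_snow=float(pv["beta_snow"][0]),
        beta_prevdet=float(pv["beta_prevdet"][0]),
        beta_gps=float(pv["beta_gps"][0]),
    ) for g in range(data.n_groups)]
    return ModelParameters(demographic=demographic, movement=movement,
                           detection=detection)


def _obs_loglik_by_group(params, ac, z, data: StudyData, local_radius):
    total = 0.0
    rows = data.y_rows()
    for g in range(data.n_groups):
        members = np.where(data.group == g)[0]
        remap = -np.ones(data.M, dtype=int)
        remap[members] = np.arange(members.size)
        sub = rows[np.isin(rows[:, 0], members)]
        sub = np.column_stack([remap[sub[:, 0]], sub[:, 1], sub[:, 2], sub[:, 3]]) \
            if len(sub) else np.zeros((0, 4), dtype=int)
        total += observation_loglik(
            sub, ac[members], z[members], params.detection[g], data.detectors,
            data.habitat, data.gps[members], data.prev[members],
            local_radius=local_radius,
        )
        if not np.isfinite(total):
            return _NEG_INF
    return total


def joint_loglik(
    params: ModelParameters,
    z: np.ndarray,
    ac: np.ndarray,
    data: StudyData,
    local_radius: float | None = None,
) -> float:
    """Log p(y, z, s | params): demographic transitions (with recovery-state
    constraints), movement prior of the AC paths, and the observation model.
    Constraint violations return -inf rather than raising."""
    M, T = z.shape
    # evidence masks
    for i in range(M):
        for t in range(T):
            if not data.masks[i, t, z[i, t] - 1]:
                return _NEG_INF
    total = 0.0
    try:
        with np.errstate(divide="ignore"):
            for i in range(M):
                g = data.group[i]
                total += np.log(
                    initial_distribution(params.demographic, g)[z[i, 0] - 1])
                for t in range(1, T):
                    tm = transition_matrix(params.demographic, t + 1,
                                           int(data.gps[i, t - 1]), g)
                    total += np.log(tm[z[i, t - 1] - 1, z[i, t] - 1])
    except InfeasibleHazardError:
        return _NEG_INF
    if not np.isfinite(total):
        return _NEG_INF
    with np.errstate(divide="ignore"):
        for i in range(M):
            g = data.group[i]
            r = data.region_of_group[g]
            mp = params.movement[g]
            p1 = initial_ac_distribution(data.habitat, mp, r)
            total += np.log(p1[ac[i, 0]])
            logK = movement_kernel_matrix(data.habitat, mp, r)
            for t in range(1, T):
                total += logK[ac[i, t - 1], ac[i, t]]
    if not np.isfinite(total):
        return _NEG_INF
    total += _obs_loglik_by_group(params, ac, z, data, local_radius)
    return float(total)


def marginal_loglik_forward(
    params: ModelParameters,
    ac: np.ndarray,
    data: StudyData,
    local_radius: float | None = None,
) -> float:
    """log sum_z exp(joint_loglik) for fixed AC paths, by the forward
    algorithm over each individual's 4-state chain with recovery and
    detection evidence."""
    M, T = ac.shape
    total = 0.0
    # detection evidence per (individual, season) for the alive state
    A = np.zeros((M, T))
    rows = data.y_rows()
    for i in range(M):
        g = data.group[i]
        for t in range(1, T + 1):
            zloc = np.full((1, T), State.DEAD_OTHER, dtype=int)
            zloc[0, t - 1] = State.ALIVE
            sub = rows[(rows[:, 0] == i) & (rows[:, 2] == t)]
            sub = np.column_stack([np.zeros(len(sub), dtype=int), sub[:, 1],
                                   sub[:, 2], sub[:, 3]]) \
                if len(sub) else np.zeros((0, 4), dtype=int)
            A[i, t - 1] = observation_loglik(
                sub, ac[i:i + 1], zloc, params.detection[g], data.detectors,
                data.habitat, data.gps[i:i + 1], data.prev[i:i + 1],
                local_radius=local_radius,
            )
    haspos = np.zeros((M, T), dtype=bool)
    for i, j, t, c in rows:
        haspos[i, t - 1] = True
    with np.errstate(divide="ignore"):
        mlog = np.where(data.masks, 0.0, _NEG_INF)
    try:
        for i in range(M):
            g = data.group[i]
            e = np.zeros((T, 4))
            for t in range(T):
                e[t] = mlog[i, t]
                e[t, State.ALIVE - 1] += A[i, t]
                if haspos[i, t]:
                    for zz in (State.UNBORN, State.DEAD_LEGAL, State.DEAD_OTHER):
                        e[t, zz - 1] = _NEG_INF
            with np.errstate(divide="ignore"):
                lp = np.log(initial_distribution(params.demographic, g)) + e[0]
                for t in range(1, T):
                    tm = transition_matrix(params.demographic, t + 1,
                                           int(data.gps[i, t - 1]), g)
                    lp = logsumexp(lp[:, None] + np.log(tm), axis=0) + e[t]
            total += logsumexp(lp)
    except InfeasibleHazardError:
        return _NEG_INF
    # movement prior (constant in z)
    for i in range(M):
        g = data.group[i]
        mp = params.movement[g]
        r = data.region_of_group[g]
        total += np.log(initial_ac_distribution(data.habitat, mp, r)[ac[i, 0]])
        logK = movement_kernel_matrix(data.habitat, mp, r)
        for t in range(1, T):
            total += logK[ac[i, t - 1], ac[i, t]]
    return float(total)


# ---------------------------------------------------------------------------
# Priors and MCMC configuration
# ---------------------------------------------------------------------------

@dataclass
class Priors:
    """Weakly informative defaults: Normal(0, sd^2) on logit-scale intercepts
    and slopes, Uniform(0,1) on psi and gamma, Uniform(0, max) on the spatial
    scales. sigma_max interacts with the buffer rule (buffer >= 6 sigma)."""

    intercept_sd: float = 2.0
    slope_sd: float = 2.0
    sigma_max: float = 10.0
    tau_max: float = 100.0


@dataclass
class MCMCConfig:
    n_chains: int = 4
    n_iterations: int = 42_500
    burn_in: int = 12_500
    thinning: int = 1
    mode: str = "latent"                 # "latent" (explicit z) or "marginal"
    local_radius_factor: float | None = 6.0   # None -> exact full evaluation
    adapt_interval: int = 50
    seed: int = 0
    checkpoint_dir: str | None = None
    save_ac: bool = False                # keep activity-centre draws (memory!)

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.mode not in ("latent", "marginal"):
            raise ValueError("mode must be 'latent' or 'marginal'")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

_AL = State.ALIVE - 1      # index of the alive state in 0-based state axes
_OTHER_STATES = [0, 2, 3]


class _Sampler:
    """One chain of Metropolis-within-Gibbs. Internal, but stable enough for
    the test-suite to cross-check its cached likelihoods against the
    reference implementations."""

    def __init__(self, data: StudyData, priors: Priors, config: MCMCConfig,
                 rng: np.random.Generator):
        self.d = data
        self.priors = priors
        self.cfg = config
        self.rng = rng
        d = data
        self.G = d.n_groups
        self.T = d.T
        self.M = d.M
        self.nc = d.habitat.n_cells
        self.nd = d.detectors.n_detectors
        self.C = d.detectors.n_counties
        cc = d.habitat.cell_centres
        dc = d.detectors.detector_centres
        self.d2_cd = ((cc[:, None, :] - dc[None, :, :]) ** 2).sum(axis=2)
        self.Kf = d.detectors.K.astype(float)
        self.combo = 2 * d.gps + d.prev                     # (M, T) in 0..3
        with np.errstate(divide="ignore"):
            self.mlog = np.where(d.masks, 0.0, _NEG_INF)    # (M, T, 4)
        # positive-count rows
        self.r_i = d.y_ind
        self.r_j = d.y_det
        self.r_t = d.y_season
        self.r_y = d.y_count.astype(float)
        self.r_K = self.Kf[d.y_det]
        self.r_logC = binom_log_coeff(self.r_K, self.r_y)
        self.r_combo = self.combo[self.r_i, self.r_t - 1]
        self.r_g = d.group[self.r_i]
        # covariate design per season: (T, nd) pieces
        self.cov = {name: d.detectors.covariates.get(name)
                    for name in ("tracks", "roads", "snow")}
        # feasibility needs checking only for collar states that occur
        self.realized_gps = np.zeros((self.G, 2), dtype=bool)
        for g in range(self.G):
            vals = np.unique(d.gps[d.group == g])
            self.realized_gps[g, vals] = True
            self.realized_gps[g, 0] = True
        self.region_cells = [np.where(d.habitat.region_id == r)[0]
                             for r in range(d.habitat.n_regions)]
        self._gps_nb = np.ascontiguousarray(d.gps, dtype=np.int64)
        self.und = np.setdiff1d(np.arange(self.M), np.unique(d.y_ind))
        self._init_params()
        self._init_latents()
        self._build_blocks()
        self._refresh_all(initial=True)

    # -- parameter vector ---------------------------------------------------

    def _init_params(self) -> None:
        G, T, C = self.G, self.T, self.C
        rng = self.rng
        jit = lambda shape, s=0.3: rng.normal(0.0, s, size=shape)
        self.pv = {
            "psi_l": logit(0.3) + jit(G),
            "gamma_l": logit(0.15) + jit((G, T - 1)),
            "h0": logit(0.1) + jit((G, T - 1)),
            "w0": logit(0.2) + jit((G, T - 1)),
            "beta_h_gps": jit(1, 0.2),
            "beta_w_gps": jit(1, 0.2),
            "tau": np.clip(self.d.habitat.cell_size * np.exp(jit(G, 0.2)),
                           1e-2, self.priors.tau_max * 0.99),
            "b_dens": jit(G, 0.2),
            "sigma": np.clip(self.d.detectors.detector_size / 2.0 * np.exp(jit(G, 0.2)),
                             1e-2, self.priors.sigma_max * 0.99),
            "p0_int": logit(0.05) + jit((C, T)),
            "beta_tracks": jit(1, 0.2),
            "beta_roads": jit(1, 0.2),
            "beta_snow": jit(1, 0.2),
            "beta_prevdet": jit(1, 0.2),
            "beta_gps": jit(1, 0.2),
        }

    def log_prior(self, pv) -> float:
        pr = self.priors
        lp = 0.0
        for key in ("psi_l", "gamma_l"):
            v = pv[key]
            lp += float(np.sum(np.log(expit(v)) + np.log(expit(-v))))
        for key in ("h0", "w0", "p0_int"):
            lp += float(-0.5 * np.sum(pv[key] ** 2) / pr.intercept_sd ** 2)
        for key in ("beta_h_gps", "beta_w_gps", "b_dens", "beta_tracks",
                    "beta_roads", "beta_snow", "beta_prevdet", "beta_gps"):
            lp += float(-0.5 * np.sum(pv[key] ** 2) / pr.slope_sd ** 2)
        if np.any(pv["sigma"] <= 0) or np.any(pv["sigma"] >= pr.sigma_max):
            return _NEG_INF
        if np.any(pv["tau"] <= 0) or np.any(pv["tau"] >= pr.tau_max):
            return _NEG_INF
        return lp

    # -- caches -------------------------------------------------------------

    def _build_trans(self, pv):
        """loginit (G, 4) and logT (G, T-1, 2, 4, 4); None if infeasible."""
        G, T = self.G, self.T
        psi = expit(pv["psi_l"])
        gam = expit(pv["gamma_l"])
        h = expit(pv["h0"][:, :, None] + pv["beta_h_gps"][0] * np.array([0, 1]))
        w = expit(pv["w0"][:, :, None] + pv["beta_w_gps"][0] * np.array([0, 1]))
        phi = 1.0 - h - w                                  # (G, T-1, 2)
        for g in range(G):
            for gv in range(2):
                if self.realized_gps[g, gv] and np.any(phi[g, :, gv] <= 0.0):
                    return None
        loginit = np.full((G, 4), _NEG_INF)
        loginit[:, 0] = np.log1p(-psi)
        loginit[:, 1] = np.log(psi)
        logT = np.full((G, T - 1, 2, 4, 4), _NEG_INF)
        with np.errstate(divide="ignore", invalid="ignore"):
            logT[:, :, :, 0, 0] = np.log1p(-gam)[:, :, None]
            logT[:, :, :, 0, 1] = np.log(gam)[:, :, None]
            logT[:, :, :, 1, 1] = np.log(phi)
            logT[:, :, :, 1, 2] = np.log(h)
            logT[:, :, :, 1, 3] = np.log(w)
        logT[:, :, :, 2, 3] = 0.0
        logT[:, :, :, 3, 3] = 0.0
        logT[np.isnan(logT)] = _NEG_INF
        return loginit, logT

    def _build_move(self, pv):
        """log kernels (G, nc, nc) and initial AC log-probs (G, nc)."""
        G = self.G
        logK = np.full((G, self.nc, self.nc), _NEG_INF)
        loginit = np.full((G, self.nc), _NEG_INF)
        hab = self.d.habitat
        for g in range(G):
            mp = MovementParams(tau=float(pv["tau"][g]), b_dens=float(pv["b_dens"][g]))
            r = self.d.region_of_group[g]
            logK[g] = movement_kernel_matrix(hab, mp, r)
            with np.errstate(divide="ignore"):
                loginit[g] = np.log(initial_ac_distribution(hab, mp, r))
        return logK, loginit

    def _move_cum(self):
        """Cumulative movement distributions for prior-path proposals."""
        logK, loginit = self.move
        with np.errstate(over="ignore"):
            cumK = np.cumsum(np.exp(logK), axis=2)
            cuminit = np.cumsum(np.exp(loginit), axis=1)
        return cumK, cuminit

    def _lp0_base(self, pv, t):
        """Logit-scale baseline over detectors for season index t (0-based),
        before the individual-level (gps, prev) shifts."""
        lp = pv["p0_int"][self.d.detectors.county_id, t].copy()
        for name, key in (("tracks", "beta_tracks"), ("roads", "beta_roads"),
                          ("snow", "beta_snow")):
            if self.cov[name] is not None:
                lp += pv[key][0] * self.cov[name][:, t]
        return lp

    def _build_det(self, pv, old=None, seasons=None):
        """p0mat (4, T, nd), kern/kern_local/incl (G, nc, nd), Zg (G,4,T,nc).

        ``seasons`` restricts the rebuild to those season indices, reusing
        the kernel and the other seasons from ``old`` (valid only when sigma
        is unchanged)."""
        G, T = self.G, self.T
        shifts = np.array([0.0, pv["beta_prevdet"][0], pv["beta_gps"][0],
                           pv["beta_gps"][0] + pv["beta_prevdet"][0]])
        if old is not None and seasons is not None:
            p0mat = old["p0mat"].copy()
            Zg = old["Zg"].copy()
            kern, kern_local, incl = old["kern"], old["kern_local"], old["incl"]
            tlist = seasons
        else:
            p0mat = np.empty((4, T, self.nd))
            Zg = np.empty((G, 4, T, self.nc))
            kern = np.empty((G, self.nc, self.nd))
            incl = np.empty((G, self.nc, self.nd), dtype=bool)
            for g in range(G):
                s2 = pv["sigma"][g] ** 2
                kern[g] = np.exp(-self.d2_cd / (2.0 * s2))
                if self.cfg.local_radius_factor is None:
                    incl[g] = True
                else:
                    r2 = (self.cfg.local_radius_factor * pv["sigma"][g]) ** 2
                    incl[g] = self.d2_cd <= r2
            kern_local = kern * incl
            tlist = range(T)
        for t in tlist:
            base = self._lp0_base(pv, t)
            p0mat[:, t, :] = expit(base[None, :] + shifts[:, None])
            for g in range(G):
                # (4, nc): sum over detectors of K log(1 - p0 * kernel)
                pz = p0mat[:, t, None, :] * kern_local[g][None, :, :]
                Zg[g, :, t, :] = (self.Kf[None, None, :] * np.log1p(-pz)).sum(axis=2)
        return {"p0mat": p0mat, "kern": kern, "kern_local": kern_local,
                "incl": incl, "Zg": Zg}

    def _row_corr(self, det) -> np.ndarray:
        """Per-row exact-likelihood corrections at the current AC cells."""
        if len(self.r_i) == 0:
            return np.zeros(0)
        cells = self.s[self.r_i, self.r_t - 1]
        kf = det["kern"][self.r_g, cells, self.r_j]
        p = det["p0mat"][self.r_combo, self.r_t - 1, self.r_j] * kf
        inc = det["incl"][self.r_g, cells, self.r_j]
        with np.errstate(divide="ignore"):
            lp = np.log(p)
        return (self.r_y * lp + (self.r_K - self.r_y) * np.log1p(-p)
                + self.r_logC - self.r_K * np.log1p(-p * inc))

    def _compute_A(self, det) -> np.ndarray:
        tidx = np.arange(self.T)[None, :]
        A = det["Zg"][self.d.group[:, None], self.combo, tidx, self.s]
        if len(self.r_i):
            np.add.at(A, (self.r_i, self.r_t - 1), self._row_corr(det))
        return A

    def _compute_e(self, A) -> np.ndarray:
        e = self.mlog.copy()
        e[:, :, _AL] = e[:, :, _AL] + A
        return e

    def _ind_trans(self, logT, k) -> np.ndarray:
        """(M, 4, 4) transition log-probs for step k -> k+1."""
        return logT[self.d.group, k, self.d.gps[:, k]]

    def _forward(self, trans, e, return_alpha=False):
        loginit, logT = trans
        marg = np.empty(self.M)
        alphas = np.empty((self.M, self.T, 4)) if return_alpha \
            else np.empty((0, 0, 0))
        _forward_nb(loginit, logT, self.d.group, self._gps_nb, e, marg,
                    alphas, return_alpha)
        if return_alpha:
            return marg, alphas
        return marg

    def _mov_loglik(self, move) -> float:
        logK, loginit = move
        g = self.d.group
        total = float(loginit[g, self.s[:, 0]].sum())
        for t in range(1, self.T):
            total += float(logK[g, self.s[:, t - 1], self.s[:, t]].sum())
        return total

    # -- latent initialization ---------------------------------------------

    def _init_latents(self) -> None:
        d = self.d
        rng = self.rng
        self.s = np.empty((self.M, self.T), dtype=int)
        region = d.region_of_group[d.group]
        for i in range(self.M):
            cells = self.region_cells[region[i]]
            self.s[i] = rng.choice(cells, size=self.T)
        # detected individuals start at the cell nearest their detections
        if len(self.r_i):
            dcent = d.detectors.detector_centres
            for i in np.unique(self.r_i):
                m = self.r_i == i
                w = self.r_y[m]
                mean_all = (dcent[self.r_j[m]] * w[:, None]).sum(0) / w.sum()
                cells = self.region_cells[region[i]]
                home = cells[np.argmin(((d.habitat.cell_centres[cells] - mean_all) ** 2
                                        ).sum(1))]
                self.s[i] = home
                for t in np.unique(self.r_t[m]):
                    mt = m & (self.r_t == t)
                    wt = self.r_y[mt]
                    mu = (dcent[self.r_j[mt]] * wt[:, None]).sum(0) / wt.sum()
                    self.s[i, t - 1] = cells[np.argmin(
                        ((d.habitat.cell_centres[cells] - mu) ** 2).sum(1))]
        self.z = None   # sampled lazily in latent mode

    def _refresh_all(self, initial=False) -> None:
        self.trans = self._build_trans(self.pv)
        if self.trans is None:
            raise InitializationError("initial hazards infeasible (h + w >= 1)")
        self.move = self._build_move(self.pv)
        self.det = self._build_det(self.pv)
        self.A = self._compute_A(self.det)
        self.e = self._compute_e(self.A)
        marg, alphas = self._forward(self.trans, self.e, return_alpha=True)
        self.L_z = float(marg.sum())
        self.L_mov = self._mov_loglik(self.move)
        self.prior = self.log_prior(self.pv)
        if initial and not np.isfinite(self.L_z + self.L_mov + self.prior):
            bad = np.where(~np.isfinite(marg))[0][:10]
            raise InitializationError(
                f"non-finite initial log-posterior (L_z={self.L_z}, "
                f"L_mov={self.L_mov}, prior={self.prior}); first bad "
                f"individuals: {bad.tolist()}"
            )
        if self.cfg.mode == "latent":
            self.z = self._ffbs(alphas)
            self._refresh_latent_logliks()

    # -- FFBS over states ---------------------------------------------------

    def _gumbel_argmax(self, logw) -> np.ndarray:
        g = self.rng.gumbel(size=logw.shape)
        return np.argmax(np.where(np.isfinite(logw), logw + g, _NEG_INF), axis=-1)

    def _ffbs(self, alphas) -> np.ndarray:
        """Exact conditional draw of the state chain (0-based codes)."""
        _, logT = self.trans
        z = np.empty((self.M, self.T), dtype=int)
        z[:, -1] = self._gumbel_argmax(alphas[:, -1])
        rows = np.arange(self.M)
        for t in range(self.T - 2, -1, -1):
            Tk = self._ind_trans(logT, t)
            w = alphas[:, t] + Tk[rows, :, z[:, t + 1]]
            z[:, t] = self._gumbel_argmax(w)
        return z

    def _refresh_latent_logliks(self) -> None:
        self.L_demo = self._demo_loglik_given_z(self.trans)
        self.L_det = self._det_loglik_given_z()

    def _demo_loglik_given_z(self, trans) -> float:
        loginit, logT = trans
        g = self.d.group
        total = float(loginit[g, self.z[:, 0]].sum())
        for k in range(self.T - 1):
            Tk = self._ind_trans(logT, k)
            total += float(Tk[np.arange(self.M), self.z[:, k], self.z[:, k + 1]].sum())
        return total

    def _det_loglik_given_z(self) -> float:
        alive = self.z == _AL
        return float(self.A[alive].sum())

    # -- activity-centre Gibbs sweep ----------------------------------------

    def _acand(self, t, det) -> np.ndarray:
        """(M, nc) alive-state detection log-lik with season-t AC at each cell."""
        A = det["Zg"][self.d.group, self.combo[:, t], t]      # (M, nc)
        m = self.r_t - 1 == t
        if m.any():
            A = A.copy()
            rj, rg, rc = self.r_j[m], self.r_g[m], self.r_combo[m]
            ry, rK, rlc = self.r_y[m], self.r_K[m], self.r_logC[m]
            p = det["p0mat"][rc, t, rj][:, None] * det["kern"][rg, :, rj]
            inc = det["incl"][rg, :, rj]
            with np.errstate(divide="ignore"):
                lp = np.log(p)
            contrib = (ry[:, None] * lp + (rK - ry)[:, None] * np.log1p(-p)
                       + rlc[:, None] - rK[:, None] * np.log1p(-p * inc))
            np.add.at(A, self.r_i[m], contrib)
        return A

    def ac_sweep(self) -> None:
        d = self.d
        loginit, logT = self.trans
        logKm, loginit_ac = self.move
        g = d.group
        latent = self.cfg.mode == "latent"
        if not latent:
            # backward messages at current ACs
            bmsg = np.zeros((self.M, self.T, 4))
            for t in range(self.T - 2, -1, -1):
                Tk = self._ind_trans(logT, t)
                tmp = self.e[:, t + 1, :] + bmsg[:, t + 1, :]
                with np.errstate(invalid="ignore"):
                    bmsg[:, t] = _lse(Tk + tmp[:, None, :], axis=2)
        alpha_prev = None
        for t in range(self.T):
            Acand = self._acand(t, self.det)
            if t == 0:
                movp = loginit_ac[g]
            else:
                movp = logKm[g, self.s[:, t - 1], :]
            if t < self.T - 1:
                movn = logKm[g, :, self.s[:, t + 1]]
            else:
                movn = 0.0
            if latent:
                alive = (self.z[:, t] == _AL).astype(float)[:, None]
                logP = movp + movn + alive * np.where(
                    np.isfinite(Acand), Acand, -1e300)
            else:
                if t == 0:
                    pred = loginit[g]
                else:
                    Tk = self._ind_trans(logT, t - 1)
                    with np.errstate(invalid="ignore"):
                        pred = _lse(alpha_prev[:, :, None] + Tk, axis=1)
                v = pred + self.mlog[:, t, :] + bmsg[:, t, :]
                with np.errstate(invalid="ignore"):
                    const = _lse(v[:, _OTHER_STATES], axis=1)
                var = v[:, _AL]
                logP = movp + movn + np.logaddexp(
                    const[:, None], var[:, None] + Acand)
            self.s[:, t] = self._gumbel_argmax(logP)
            self.A[:, t] = Acand[np.arange(self.M), self.s[:, t]]
            self.e[:, t, _AL] = self.mlog[:, t, _AL] + self.A[:, t]
            if not latent:
                if t == 0:
                    alpha_prev = loginit[g] + self.e[:, 0, :]
                else:
                    alpha_prev = pred + self.e[:, t, :]
        self.L_mov = self._mov_loglik(self.move)
        if latent:
            self.L_det = self._det_loglik_given_z()
        else:
            self.L_z = float(self._forward(self.trans, self.e).sum())

    def _forward_subset(self, idx, e_sub):
        loginit, logT = self.trans
        marg = np.empty(idx.size)
        _forward_nb(loginit, logT, np.ascontiguousarray(self.d.group[idx]),
                    np.ascontiguousarray(self._gps_nb[idx]),
                    np.ascontiguousarray(e_sub), marg,
                    np.empty((0, 0, 0)), False)
        return marg

    def path_refresh(self) -> None:
        """Whole-path independence proposals from the movement prior for
        never-detected individuals.

        Single-site AC Gibbs moves whole paths slowly, which in turn slows
        the mixing of the density slope and the inclusion parameters through
        the many augmented individuals sitting in the buffer. Because the
        proposal is the movement prior itself, the acceptance ratio reduces
        to the ratio of state-marginal detection evidence, and paths of
        individuals far from the detectors are refreshed nearly freely.
        """
        und = self.und
        if und.size == 0:
            return
        cumK, cuminit = self._move_cum()
        g = self.d.group[und]
        s_new = np.empty((und.size, self.T), dtype=int)
        u = self.rng.random(und.size)
        s_new[:, 0] = (cuminit[g] < u[:, None]).sum(axis=1)
        for t in range(1, self.T):
            rows = cumK[g, s_new[:, t - 1]]
            s_new[:, t] = (rows < self.rng.random(und.size)[:, None]).sum(axis=1)
        tidx = np.arange(self.T)[None, :]
        A_new = self.det["Zg"][g[:, None], self.combo[und], tidx, s_new]
        if self.cfg.mode == "latent":
            alive = (self.z[und] == _AL)
            delta = ((A_new - self.A[und]) * alive).sum(axis=1)
        else:
            e_new = self.mlog[und].copy()
            e_new[:, :, _AL] += A_new
            marg_new = self._forward_subset(und, e_new)
            marg_old = self._forward_subset(und, self.e[und])
            delta = marg_new - marg_old
        acc = np.log(self.rng.random(und.size)) < delta
        if not acc.any():
            return
        rows = und[acc]
        self.s[rows] = s_new[acc]
        self.A[rows] = A_new[acc]
        self.e[rows, :, _AL] = self.mlog[rows, :, _AL] + self.A[rows]
        self.L_mov = self._mov_loglik(self.move)
        if self.cfg.mode == "latent":
            self.L_det = self._det_loglik_given_z()
        else:
            self.L_z = float(self._forward(self.trans, self.e).sum())

    # -- Metropolis blocks --------------------------------------------------

    def _build_blocks(self) -> None:
        G, T, C = self.G, self.T, self.C
        blocks = []
        for gi in range(G):
            blocks.append(dict(name=f"psi[{gi}]", kind="demo",
                               entries=[("psi_l", (gi,))], scale=0.4))
            for k in range(T - 1):
                blocks.append(dict(name=f"gamma[{gi},{k}]", kind="demo",
                                   entries=[("gamma_l", (gi, k))], scale=0.4))
                blocks.append(dict(name=f"h0[{gi},{k}]", kind="demo",
                                   entries=[("h0", (gi, k))], scale=0.4))
                blocks.append(dict(name=f"w0[{gi},{k}]", kind="demo",
                                   entries=[("w0", (gi, k))], scale=0.4))
            blocks.append(dict(name=f"tau[{gi}]", kind="move",
                               entries=[("tau", (gi,))], scale=1.0))
            blocks.append(dict(name=f"b_dens[{gi}]", kind="move",
                               entries=[("b_dens", (gi,))], scale=0.3))
            blocks.append(dict(name=f"sigma[{gi}]", kind="det",
                               entries=[("sigma", (gi,))], scale=0.3))
        blocks.append(dict(name="beta_h_gps", kind="demo",
                           entries=[("beta_h_gps", (0,))], scale=0.4))
        blocks.append(dict(name="beta_w_gps", kind="demo",
                           entries=[("beta_w_gps", (0,))], scale=0.4))
        for c in range(C):
            for t in range(T):
                blocks.append(dict(name=f"p0_int[{c},{t}]", kind="det",
                                   entries=[("p0_int", (c, t))], scale=0.3,
                                   seasons=[t]))
        blocks.append(dict(name="det_effort_slopes", kind="det", scale=0.15,
                           entries=[("beta_tracks", (0,)), ("beta_roads", (0,)),
                                    ("beta_snow", (0,))]))
        for nm in ("beta_prevdet", "beta_gps"):
            blocks.append(dict(name=nm, kind="det", entries=[(nm, (0,))],
                               scale=0.2))
        for b in blocks:
            b["acc"] = 0
            b["tries"] = 0
        self.blocks = blocks

    def _entry_logprior(self, pname, v) -> float:
        pr = self.priors
        if pname in ("psi_l", "gamma_l"):
            return float(np.log(expit(v)) + np.log(expit(-v)))
        if pname in ("h0", "w0", "p0_int"):
            return float(-0.5 * v * v / pr.intercept_sd ** 2)
        if pname == "sigma":
            return 0.0 if 0.0 < v < pr.sigma_max else _NEG_INF
        if pname == "tau":
            return 0.0 if 0.0 < v < pr.tau_max else _NEG_INF
        return float(-0.5 * v * v / pr.slope_sd ** 2)    # slopes, b_dens

    def _propose(self, block):
        saved = []
        delta = 0.0
        for pname, idx in block["entries"]:
            old = self.pv[pname][idx]
            saved.append((pname, idx, old))
            new = old + block["scale"] * self.rng.normal()
            self.pv[pname][idx] = new
            delta += self._entry_logprior(pname, new) \
                - self._entry_logprior(pname, old)
        return saved, delta

    def _restore(self, saved) -> None:
        for pname, idx, val in saved:
            self.pv[pname][idx] = val

    def param_updates(self) -> None:
        latent = self.cfg.mode == "latent"
        for block in self.blocks:
            block["tries"] += 1
            saved, prior_delta = self._propose(block)
            prior_new = self.prior + prior_delta
            if not np.isfinite(prior_new):
                self._restore(saved)
                continue
            kind = block["kind"]
            if kind == "demo":
                trans_new = self._build_trans(self.pv)
                if trans_new is None:
                    self._restore(saved)
                    continue
                if latent:
                    L_new = self._demo_loglik_given_z(trans_new)
                    L_old = self.L_demo
                else:
                    L_new = float(self._forward(trans_new, self.e).sum())
                    L_old = self.L_z
            elif kind == "move":
                move_new = self._build_move(self.pv)
                L_new = self._mov_loglik(move_new)
                L_old = self.L_mov
            else:
                seasons = block.get("seasons")
                det_new = self._build_det(self.pv, old=self.det, seasons=seasons) \
                    if seasons is not None else self._build_det(self.pv)
                A_new = self._compute_A(det_new)
                if latent:
                    alive = self.z == _AL
                    L_new = float(A_new[alive].sum())
                    L_old = self.L_det
                else:
                    e_new = self._compute_e(A_new)
                    L_new = float(self._forward(self.trans, e_new).sum())
                    L_old = self.L_z
            if np.log(self.rng.random()) < (L_new - L_old) + (prior_new - self.prior):
                block["acc"] += 1
                self.prior = prior_new
                if kind == "demo":
                    self.trans = trans_new
                    if latent:
                        self.L_demo = L_new
                    else:
                        self.L_z = L_new
                elif kind == "move":
                    self.move = move_new
                    self.L_mov = L_new
                else:
                    self.det = det_new
                    self.A = A_new
                    if latent:
                        self.L_det = L_new
                        self.e = self._compute_e(A_new)
                    else:
                        self.e = e_new
                        self.L_z = L_new
            else:
                self._restore(saved)

    def adapt(self) -> None:
        for block in self.blocks:
            if block["tries"] == 0:
                continue
            rate = block["acc"] / block["tries"]
            block["scale"] *= float(np.exp(np.clip(rate - 0.3, -0.5, 0.5)))
            block["scale"] = float(np.clip(block["scale"], 1e-3, 50.0))
            block["acc"] = 0
            block["tries"] = 0

    # -- iteration ----------------------------------------------------------

    def step(self, adapt_now: bool) -> None:
        if self.cfg.mode == "latent":
            _, alphas = self._forward(self.trans, self.e, return_alpha=True)
            self.z = self._ffbs((alphas))
            self._refresh_latent_logliks()
            self.ac_sweep()
        else:
            self.ac_sweep()
        self.path_refresh()
        self.param_updates()
        if adapt_now:
            self.adapt()

    def sample_population(self) -> tuple[int, np.ndarray]:
        """Draw z (if marginalized) and count individuals ever alive."""
        if self.cfg.mode == "latent":
            z = self.z
        else:
            _, alphas = self._forward(self.trans, self.e, return_alpha=True)
            z = self._ffbs(alphas)
        alive = z == _AL
        return int(alive.any(axis=1).sum()), alive.sum(axis=0)

    # -- reporting helpers ---------------------------------------------------

    _SCALAR_KEYS = ("beta_h_gps", "beta_w_gps", "beta_tracks", "beta_roads",
                    "beta_snow", "beta_prevdet", "beta_gps")

    def flat_names(self):
        names = []
        for key, arr in self.pv.items():
            label = {"psi_l": "psi", "gamma_l": "gamma"}.get(key, key)
            if key in self._SCALAR_KEYS:
                names.append(label)
            else:
                for idx in np.ndindex(arr.shape):
                    names.append(label + "[" + ",".join(map(str, idx)) + "]")
        return names

    def flat_values(self):
        vals = []
        for key, arr in self.pv.items():
            a = expit(arr) if key in ("psi_l", "gamma_l") else arr
            vals.extend(np.asarray(a).ravel().tolist())
        return vals

    def total_loglik(self) -> float:
        if self.cfg.mode == "latent":
            return self.L_demo + self.L_det + self.L_mov
        return self.L_z + self.L_mov


# ---------------------------------------------------------------------------
# Driver, diagnostics, derived quantities
# ---------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    """Posterior draws (chain x retained iteration per parameter), with the
    run configuration echoed for reproducibility."""

    draws: dict
    param_names: list
    config: dict
    acceptance: dict
    n_detected: int
    M: int
    ac_draws: np.ndarray | None = None   # (chains, n_save, M, T) cell indices

    def array(self, name) -> np.ndarray:
        return self.draws[name]

    def rhat(self) -> dict:
        return {n: gelman_rubin(self.draws[n]) for n in self.param_names}

    def max_rhat(self) -> float:
        return max(self.rhat().values())

    def summary(self) -> pd.DataFrame:
        rows = []
        rh = self.rhat()
        for n in self.param_names:
            x = self.draws[n].ravel()
            rows.append({
                "parameter": n, "median": np.median(x),
                "lo2.5": np.quantile(x, 0.025), "hi97.5": np.quantile(x, 0.975),
                "rhat": rh[n],
            })
        return pd.DataFrame(rows)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        recs = []
        for n, arr in self.draws.items():
            for c in range(arr.shape[0]):
                for it, v in enumerate(arr[c]):
                    recs.append((c, it, n, v))
        pd.DataFrame(recs, columns=["chain", "iteration", "parameter", "value"]) \
            .to_csv(out / "draws.csv", index=False)
        with open(out / "diagnostics.json", "w") as fh:
            json.dump({"rhat": self.rhat(), "acceptance": self.acceptance,
                       "n_detected": self.n_detected, "M": self.M}, fh, indent=1)
        with open(out / "run_config.json", "w") as fh:
            json.dump(self.config, fh, indent=1)
        self.summary().to_csv(out / "summary.csv", index=False)

    @classmethod
    def load(cls, out_dir) -> "PosteriorResult":
        out = Path(out_dir)
        df = pd.read_csv(out / "draws.csv")
        if not {"chain", "iteration", "parameter", "value"} <= set(df.columns):
            raise DataConsistencyError(
                "draws file must have columns chain, iteration, parameter, value"
            )
        draws = {}
        for n, sub in df.groupby("parameter", sort=False):
            piv = sub.pivot(index="chain", columns="iteration", values="value")
            draws[n] = piv.to_numpy()
        with open(out / "diagnostics.json") as fh:
            diag = json.load(fh)
        with open(out / "run_config.json") as fh:
            config = json.load(fh)
        names = [n for n in draws if n not in ("loglik", "N_super")
                 and not n.startswith("N_alive")]
        return cls(draws=draws, param_names=names, config=config,
                   acceptance=diag.get("acceptance", {}),
                   n_detected=diag.get("n_detected", 0), M=diag.get("M", 0))


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_iterations); each chain is split in
    half before computing the between/within variance ratio. The statistic
    is floored at 1: values below 1 arise only from the finite-sample
    (n-1)/n correction when the between-chain variance is negligible.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    n = chains.shape[1] // 2
    if n < 2:
        raise ValueError("chains too short to split")
    halves = np.concatenate([chains[:, :n], chains[:, chains.shape[1] - n:]], axis=0)
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W <= 1e-300:
        return 1.0 if B <= 1e-300 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(max(1.0, np.sqrt(var_hat / W)))


def run_mcmc(
    data: StudyData,
    config: MCMCConfig,
    priors: Priors | None = None,
) -> PosteriorResult:
    """Run independent chains and collect retained draws.

    Chains are seeded from ``config.seed`` and the chain index, so a run is
    reproducible and a checkpointed run (``config.checkpoint_dir``) resumes
    by skipping chains whose draws are already on disk — the resumed result
    is bit-identical to an uninterrupted one.
    """
    priors = priors or Priors()
    data.habitat.validate_buffer(priors.sigma_max)
    ckpt = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt:
        if config.save_ac:
            raise ValueError("save_ac cannot be combined with checkpointing")
        ckpt.mkdir(parents=True, exist_ok=True)
    n_save = (config.n_iterations - config.burn_in) // config.thinning
    all_chains = []
    all_ac = [] if config.save_ac else None
    names = None
    acceptance: dict = {}
    for chain in range(config.n_chains):
        cfile = ckpt / f"chain{chain}.npz" if ckpt else None
        if cfile is not None and cfile.exists():
            blob = np.load(cfile, allow_pickle=True)
            names = list(blob["names"])
            all_chains.append(blob["values"])
            continue
        rng = np.random.default_rng([config.seed % (2 ** 31), chain, 2021])
        smp = _Sampler(data, priors, config, rng)
        names = smp.flat_names() + ["N_super"] \
            + [f"N_alive[{t}]" for t in range(data.T)] + ["loglik"]
        values = np.empty((n_save, len(names)))
        ac_chain = np.empty((n_save, data.M, data.T), dtype=np.int32) \
            if config.save_ac else None
        row = 0
        for it in range(config.n_iterations):
            adapt_now = (it < config.burn_in
                         and (it + 1) % config.adapt_interval == 0)
            smp.step(adapt_now)
            if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
                if row < n_save:
                    nsuper, nalive = smp.sample_population()
                    values[row] = (smp.flat_values()
                                   + [float(nsuper)] + nalive.astype(float).tolist()
                                   + [smp.total_loglik()])
                    if ac_chain is not None:
                        ac_chain[row] = smp.s
                    row += 1
        for b in smp.blocks:
            acceptance[b["name"]] = acceptance.get(b["name"], 0.0) + (
                b["acc"] / max(b["tries"], 1)) / config.n_chains
        if cfile is not None:
            np.savez_compressed(cfile, names=np.array(names), values=values)
        all_chains.append(values)
        if all_ac is not None:
            all_ac.append(ac_chain)
    stacked = np.stack(all_chains)             # (chains, n_save, P)
    draws = {n: stacked[:, :, k] for k, n in enumerate(names)}
    nsuper = draws.get("N_super")
    if nsuper is not None and data.M > 0 and np.mean(nsuper >= data.M) > 0.01:
        raise RuntimeError(
            f"augmentation limit reached: {100 * np.mean(nsuper >= data.M):.1f}% "
            f"of population-size draws hit M={data.M}; increase M"
        )
    param_names = [n for n in names if n not in ("loglik", "N_super")
                   and not n.startswith("N_alive")]
    cfg_echo = asdict(config)
    return PosteriorResult(
        draws=draws, param_names=param_names, config=cfg_echo,
        acceptance=acceptance, n_detected=data.n_detected, M=data.M,
        ac_draws=np.stack(all_ac) if all_ac else None,
    )


def export_ac_draws(result: PosteriorResult, data: StudyData, path) -> None:
    """Write retained activity-centre draws as a long-format CSV
    (chain, iteration, individual, season, cell, x, y)."""
    if result.ac_draws is None:
        raise ValueError("run_mcmc was called without save_ac=True")
    ch, ns, M, T = result.ac_draws.shape
    cells = result.ac_draws.reshape(-1)
    idx = np.indices((ch, ns, M, T)).reshape(4, -1)
    pd.DataFrame({
        "chain": idx[0], "iteration": idx[1],
        "individual": [data.individual_ids[i] for i in idx[2]],
        "season": idx[3] + 1, "cell": cells,
        "x": data.habitat.cell_centres[cells, 0],
        "y": data.habitat.cell_centres[cells, 1],
    }).to_csv(path, index=False)


def derive_collar_contrasts(
    result: PosteriorResult, group: int = 0, season: int = 2
) -> dict:
    """Posterior mortality probabilities by collar status and their
    percentage-point differences (non-collared minus collared).

    ``season`` is the 1-based destination season of the transition (>= 2).
    Returns medians and equal-tailed 95% CrIs for h, w and overall mortality
    under gps = 0 and gps = 1, plus the three pp differences.
    """
    k = season - 2
    if k < 0:
        raise ValueError("season must be >= 2")
    h0n = f"h0[{group},{k}]"
    w0n = f"w0[{group},{k}]"
    for n in (h0n, w0n, "beta_h_gps", "beta_w_gps"):
        if n not in result.draws:
            raise KeyError(f"unknown group/season: missing draws for {n}")
    h0 = result.draws[h0n].ravel()
    w0 = result.draws[w0n].ravel()
    bh = result.draws["beta_h_gps"].ravel()
    bw = result.draws["beta_w_gps"].ravel()
    out: dict = {}
    h = {0: expit(h0), 1: expit(h0 + bh)}
    w = {0: expit(w0), 1: expit(w0 + bw)}
    o = {g: h[g] + w[g] for g in (0, 1)}
    for name, q in (("h", h), ("w", w), ("overall", o)):
        entry = {}
        for gv, label in ((0, "noncollared"), (1, "collared")):
            x = q[gv]
            entry[label] = {
                "median": float(np.median(x)),
                "lo": float(np.quantile(x, 0.025)),
                "hi": float(np.quantile(x, 0.975)),
            }
        diff = 100.0 * (q[0] - q[1])
        entry["diff_pp"] = {
            "median": float(np.median(diff)),
            "lo": float(np.quantile(diff, 0.025)),
            "hi": float(np.quantile(diff, 0.975)),
        }
        out[name] = entry
    return out


def effect_interval(result: PosteriorResult, name: str) -> tuple[float, float, float]:
    """(median, lo, hi) equal-tailed 95% interval of one parameter."""
    x = result.draws[name].ravel()
    return (float(np.median(x)), float(np.quantile(x, 0.025)),
            float(np.quantile(x, 0.975)))
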