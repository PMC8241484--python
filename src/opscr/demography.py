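"""Multistate population dynamics with cause-specific mortality.

Each individual's life history is a Markov chain over four states:
1 unborn (available for recruitment under data augmentation), 2 alive,
3 dead from legal culling (occupied for exactly one season), and 4 dead from
other causes / long dead (absorbing). Mortality hazards are logit-linear in
a binary GPS-collar covariate,

    logit(h_t) = h0_t + beta_h_gps * GPS,    (legal culling)
    logit(w_t) = w0_t + beta_w_gps * GPS,    (other causes)

with survival phi_t = 1 - h_t - w_t. Intercepts are season- and
group-specific (sex x region); the collar effects are shared across groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy.special import expit

from .spatial import DataConsistencyError

__all__ = [
    "State",
    "DemographicParams",
    "InfeasibleHazardError",
    "mortality_probs",
    "transition_distribution",
    "initial_distribution",
    "transition_matrix",
    "state_constraints_from_recoveries",
]


class State(IntEnum):
    UNBORN = 1
    ALIVE = 2
    DEAD_LEGAL = 3
    DEAD_OTHER = 4


class InfeasibleHazardError(ValueError):
    """h + w >= 1 for some realized covariate combination; the categorical
    transition distribution would not be a simplex. During MCMC this signals
    proposal rejection rather than an exception."""


@dataclass
class DemographicParams:
    """Parameters of the state model for G groups over T seasons.

    ``gamma``, ``h0`` and ``w0`` have shape (G, T-1): entry ``[g, t-2+1]``...
    entry ``[g, k]`` governs the transition into season ``k + 2`` (1-based).
    ``h0``/``w0`` are logit-scale intercepts for non-collared individuals;
    the two collar effects are scalars shared across groups.
    """

    psi: np.ndarray            # (G,) inclusion probability at t=1
    gamma: np.ndarray          # (G, T-1) recruitment probability
    h0: np.ndarray             # (G, T-1) logit-scale legal-culling intercept
    w0: np.ndarray             # (G, T-1) logit-scale other-mortality intercept
    beta_h_gps: float = 0.0
    beta_w_gps: float = 0.0

    def __post_init__(self) -> None:
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.h0 = np.atleast_2d(np.asarray(self.h0, dtype=float))
        self.w0 = np.atleast_2d(np.asarray(self.w0, dtype=float))
        if not (np.all(self.psi > 0) and np.all(self.psi < 1)):
            raise ValueError("psi must lie in (0, 1)")
        if not (np.all(self.gamma >= 0) and np.all(self.gamma <= 1)):
            raise ValueError("gamma must lie in [0, 1]")
        for name in ("h0", "w0"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} must be finite")
        if not (np.isfinite(self.beta_h_gps) and np.isfinite(self.beta_w_gps)):
            raise ValueError("collar effects must be finite")

    @property
    def n_groups(self) -> int:
        return self.psi.shape[0]

    @property
    def n_seasons(self) -> int:
        return self.gamma.shape[1] + 1


def mortality_probs(
    params: DemographicParams, season: int, gps: int, group: int = 0
) -> tuple[float, float, float]:
    """Cause-specific mortality (h, w) and survival phi for the transition
    into ``season`` (1-based, >= 2) under collar status ``gps``.

    Raises :class:`InfeasibleHazardError` when h + w >= 1.
    """
    if season < 2 or season > params.n_seasons:
        raise ValueError(f"season must be in [2, {params.n_seasons}]")
    k = season - 2
    h = float(expit(params.h0[group, k] + params.beta_h_gps * gps))
    w = float(expit(params.w0[group, k] + params.beta_w_gps * gps))
    if h + w >= 1.0:
        raise InfeasibleHazardError(
            f"h + w = {h + w:.4f} >= 1 at season {season}, gps={gps}"
        )
    return h, w, 1.0 - h - w


def initial_distribution(params: DemographicParams, group: int = 0) -> np.ndarray:
    """First-season state distribution (1-psi, psi, 0, 0)."""
    psi = params.psi[group]
    return np.array([1.0 - psi, psi, 0.0, 0.0])


def transition_distribution(
    current: int, params: DemographicParams, season: int, gps: int, group: int = 0
) -> np.ndarray:
    """Distribution of z_t given z_{t-1} = ``current`` (states coded 1..4)."""
    if season < 2:
        raise ValueError("transitions are defined for season >= 2")
    current = State(current)
    if current == State.UNBORN:
        g = params.gamma[group, season - 2]
        return np.array([1.0 - g, g, 0.0, 0.0])
    if current == State.ALIVE:
        h, w, phi = mortality_probs(params, season, gps, group)
        return np.array([0.0, phi, h, w])
    # both dead states move to (or stay in) the absorbing state
    return np.array([0.0, 0.0, 0.0, 1.0])


def transition_matrix(
    params: DemographicParams, season: int, gps: int, group: int = 0
) -> np.ndarray:
    """4x4 row-stochastic transition matrix for season-1 -> season."""
    return np.stack([
        transition_distribution(s, params, season, gps, group) for s in State
    ])


# ---------------------------------------------------------------------------
# Evidence masks from dead recoveries and detections
# ---------------------------------------------------------------------------

def _legal_transitions(T: int) -> np.ndarray:
    """(4, 4) boolean matrix of structurally possible transitions."""
    allowed = np.zeros((4, 4), dtype=bool)
    allowed[0, [0, 1]] = True          # unborn -> unborn / alive
    allowed[1, [1, 2, 3]] = True       # alive -> alive / dead-legal / dead-other
    allowed[2, 3] = True               # dead-legal -> absorbing
    allowed[3, 3] = True
    return allowed


def state_constraints_from_recoveries(
    recoveries: pd.DataFrame,
    horizon: int,
    individuals: list,
    detections: pd.DataFrame | None = None,
) -> np.ndarray:
    """Per-individual allowed-state masks implied by the data.

    A legal cull recorded at season t forces z_t = 3 and z = 4 afterwards; an
    "other"-cause recovery forces z_t = 4 with the individual alive at t-1.
    Seasons with at least one detection force z = 2. The masks are then
    tightened to the states reachable along structurally legal paths
    (forward-backward pruning), so e.g. the season before a death allows only
    the alive state.

    Returns a boolean array of shape (n_individuals, horizon, 4) where entry
    [i, t, s] says state s+1 is admissible for individual i in season t+1.
    A mask with an empty season raises :class:`DataConsistencyError`.
    """
    idx = {ind: i for i, ind in enumerate(individuals)}
    n = len(individuals)
    mask = np.ones((n, horizon, 4), dtype=bool)

    if recoveries is not None and len(recoveries):
        counts = recoveries["individual_id"].value_counts()
        if (counts > 1).any():
            bad = counts[counts > 1].index.tolist()
            raise DataConsistencyError(f"multiple recoveries for {bad}")
        for _, row in recoveries.iterrows():
            if row["individual_id"] not in idx:
                continue
            i = idx[row["individual_id"]]
            t = int(row["season"]) - 1
            if not (0 <= t < horizon):
                raise DataConsistencyError(
                    f"recovery season {t + 1} outside horizon {horizon}"
                )
            cause = str(row["cause"])
            if cause == "legal":
                mask[i, t, :] = [False, False, True, False]
            elif cause == "other":
                mask[i, t, :] = [False, False, False, True]
                if t >= 1:   # death in (t-1, t] requires being alive at t-1
                    mask[i, t - 1, :] &= [False, True, False, False]
            else:
                raise DataConsistencyError(f"unknown recovery cause {cause!r}")
            mask[i, t + 1:, :] &= [False, False, False, True]
            mask[i, :t, :] &= [True, True, False, False]

    if detections is not None and len(detections):
        col = "season"
        for ind, sub in detections.groupby("individual_id"):
            if ind not in idx:
                continue
            i = idx[ind]
            for t in (np.asarray(sub[col], dtype=int) - 1):
                if not (0 <= t < horizon):
                    raise DataConsistencyError(
                        f"detection season {t + 1} outside horizon {horizon}"
                    )
                mask[i, t, :] &= [False, True, False, False]
                if not mask[i, t].any():
                    raise DataConsistencyError(
                        f"individual {ind!r} detected in season {t + 1} but its "
                        f"recovery record excludes the alive state"
                    )

    # forward-backward pruning over legal transitions
    A = _legal_transitions(horizon)
    reach_fwd = np.empty_like(mask)
    reach_fwd[:, 0] = mask[:, 0] & np.array([True, True, False, False])
    for t in range(1, horizon):
        reach_fwd[:, t] = mask[:, t] & (reach_fwd[:, t - 1] @ A)
    out = np.empty_like(mask)
    out[:, -1] = reach_fwd[:, -1]
    for t in range(horizon - 2, -1, -1):
        out[:, t] = reach_fwd[:, t] & (out[:, t + 1] @ A.T)
    if not out.any(axis=2).all():
        bad = [individuals[i] for i in np.where(~out.any(axis=2).all(axis=1))[0]]
        raise DataConsistencyError(f"no legal state path for individuals {bad}")
    return out
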