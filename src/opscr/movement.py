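"""Activity-centre placement and between-season movement.

Activity centres (ACs) live on the centres of the discrete habitat cells.
The first-season AC follows an inhomogeneous point process with intensity
exp(b_dens * X(c)); later seasons follow an isotropic Gaussian random walk
of scale tau weighted by the same habitat covariate:

    P(s_t = c | s_{t-1}) propto exp(-||c - s_{t-1}||^2 / (2 tau^2) + b_dens X(c)),

normalized by summation over the habitat cells of the individual's region
(buffer cells included, so paths may leave the searched area without leaving
the state space).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .spatial import HabitatGrid

__all__ = [
    "MovementParams",
    "initial_ac_distribution",
    "movement_kernel",
    "movement_kernel_matrix",
    "sample_ac_path",
]


@dataclass
class MovementParams:
    """Random-walk scale tau (km) and density-covariate slope b_dens."""

    tau: float
    b_dens: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError("tau must be positive")
        if not np.isfinite(self.b_dens):
            raise ValueError("b_dens must be finite")


def _cells_of(habitat: HabitatGrid, region: int | None) -> np.ndarray:
    if region is None:
        return np.arange(habitat.n_cells)
    return np.where(habitat.region_id == region)[0]


def initial_ac_distribution(
    habitat: HabitatGrid, params: MovementParams, region: int | None = None
) -> np.ndarray:
    """First-season AC distribution over habitat cells, proportional to
    exp(b_dens * X). Computed in log space, so extreme slopes cannot
    overflow. Cells outside ``region`` (if given) get probability 0."""
    if habitat.n_cells == 0:
        raise ValueError("habitat is empty")
    cells = _cells_of(habitat, region)
    logw = np.full(habitat.n_cells, -np.inf)
    logw[cells] = params.b_dens * habitat.X[cells]
    return np.exp(logw - logsumexp(logw[cells]))


def movement_kernel(
    from_cell: int,
    habitat: HabitatGrid,
    params: MovementParams,
    region: int | None = None,
) -> np.ndarray:
    """One row of the between-season movement kernel (sums to 1)."""
    if not (0 <= from_cell < habitat.n_cells):
        raise ValueError(f"from_cell {from_cell} is not a valid habitat cell")
    cells = _cells_of(habitat, region)
    d2 = ((habitat.cell_centres[cells] - habitat.cell_centres[from_cell]) ** 2).sum(axis=1)
    logw_cells = -d2 / (2.0 * params.tau ** 2) + params.b_dens * habitat.X[cells]
    out = np.zeros(habitat.n_cells)
    out[cells] = np.exp(logw_cells - logsumexp(logw_cells))
    return out


def movement_kernel_matrix(
    habitat: HabitatGrid, params: MovementParams, region: int | None = None
) -> np.ndarray:
    """Log-kernel matrix L[a, b] = log P(s_t = b | s_{t-1} = a).

    Rows/columns outside ``region`` are -inf; each in-region row normalizes
    to 1 over the region's cells.
    """
    cells = _cells_of(habitat, region)
    cc = habitat.cell_centres[cells]
    d2 = ((cc[:, None, :] - cc[None, :, :]) ** 2).sum(axis=2)
    logw = -d2 / (2.0 * params.tau ** 2) + params.b_dens * habitat.X[cells][None, :]
    logw -= logsumexp(logw, axis=1, keepdims=True)
    out = np.full((habitat.n_cells, habitat.n_cells), -np.inf)
    out[np.ix_(cells, cells)] = logw
    return out


def sample_ac_path(
    habitat: HabitatGrid,
    params: MovementParams,
    T: int,
    rng: np.random.Generator,
    region: int | None = None,
) -> np.ndarray:
    """Forward-sample a T-season AC path (habitat-cell indices)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    path = np.empty(T, dtype=int)
    p = initial_ac_distribution(habitat, params, region)
    path[0] = rng.choice(habitat.n_cells, p=p)
    for t in range(1, T):
        p = movement_kernel(path[t - 1], habitat, params, region)
        path[t] = rng.choice(habitat.n_cells, p=p)
    return path
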