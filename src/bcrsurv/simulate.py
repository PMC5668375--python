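"""Fixed-step RK4 simulation of single cells and cohorts.

Each cell starts with ``bcr_level = bcr0``, no antibody bound, and a
survival signal equal to its initial BCR level.  The three state
variables are advanced on a fixed 0.01 h grid with the classical
fourth-order Runge–Kutta method; a cell dies (irreversibly) at the
first grid time where ``signal_on`` drops strictly below the
``deadline`` threshold.  Cohort viability at time t is simply the
fraction of cells whose death time exceeds t.

Notes on conventions (all deliberate, see the methods note):

* the death test uses strict ``<`` and is applied at t = 0 as well, so
  a cell whose initial signal already sits below the deadline counts as
  dead from the start and simulated t = 0 viability can be below 100%;
* query times are snapped to the nearest integration grid point, never
  interpolated;
* state variables are clamped to their invariant ranges after every
  step (bcr_bound additionally to ≤ bcr_level).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _kernel
from .model import CellState, ModelParameters, _derivatives

__all__ = [
    "Cohort",
    "ViabilityTable",
    "rk4_step",
    "simulate_cell",
    "CellTrajectory",
    "cohort_death_times",
    "simulate_cohort",
    "dose_time_surface",
]

DEFAULT_DT = 0.01  # hours


@dataclass(frozen=True)
class Cohort:
    """An ordered set of cells, identified by their initial BCR levels."""

    initial_bcr_levels: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.initial_bcr_levels, dtype=float)
        object.__setattr__(self, "initial_bcr_levels", levels)
        if levels.ndim != 1 or levels.size < 1:
            raise ValueError("cohort needs at least one cell")
        if np.any(levels <= 0) or np.any(levels > 1):
            raise ValueError("initial BCR levels must lie in (0, 1]")

    @property
    def size(self) -> int:
        return int(self.initial_bcr_levels.size)

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame({"bcr_level": self.initial_bcr_levels}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Cohort":
        from .io import read_cohort

        return read_cohort(path)


@dataclass
class ViabilityTable:
    """Viability fractions on a dose × time grid (tidy-CSV serializable)."""

    doses: np.ndarray
    times: np.ndarray
    viability: np.ndarray  # shape (n_doses, n_times)
    sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.shape != (self.doses.size, self.times.size):
            raise ValueError("viability must have shape (n_doses, n_times)")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any((self.viability < 0) | (self.viability > 1)):
            raise ValueError("viability values must lie in [0, 1]")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.viability.shape:
                raise ValueError("sd must match viability shape")

    def row(self, dose: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.doses - dose)))
        if not np.isclose(self.doses[idx], dose):
            raise KeyError(f"dose {dose} not in table")
        return self.viability[idx]

    def to_frame(self) -> pd.DataFrame:
        d, t = np.meshgrid(self.doses, self.times, indexing="ij")
        frame = pd.DataFrame(
            {
                "dose_ug_ml": d.ravel(),
                "time_h": t.ravel(),
                "viability": self.viability.ravel(),
            }
        )
        if self.sd is not None:
            frame["sd"] = self.sd.ravel()
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ViabilityTable":
        doses = np.sort(frame["dose_ug_ml"].unique())
        times = np.sort(frame["time_h"].unique())
        viab = np.full((doses.size, times.size), np.nan)
        sd = np.full_like(viab, np.nan) if "sd" in frame.columns else None
        for _, r in frame.iterrows():
            i = int(np.searchsorted(doses, r["dose_ug_ml"]))
            j = int(np.searchsorted(times, r["time_h"]))
            viab[i, j] = r["viability"]
            if sd is not None:
                sd[i, j] = r["sd"]
        if np.any(np.isnan(viab)):
            raise ValueError("viability table is missing (dose, time) combinations")
        return cls(doses=doses, times=times, viability=viab, sd=sd)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ViabilityTable":
        from .io import read_viability_table

        return read_viability_table(path)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _clamp(bcr_level: float, bcr_bound: float, signal_on: float):
    bcr_level = min(max(bcr_level, 0.0), 1.0)
    bcr_bound = min(max(bcr_bound, 0.0), bcr_level)
    signal_on = min(max(signal_on, 0.0), 1.0)
    return bcr_level, bcr_bound, signal_on


def rk4_step(state: CellState, anti_igm: float, params: ModelParameters, dt: float) -> CellState:
    """One classical fourth-order Runge–Kutta step of the combined model.

    Returns a new :class:`CellState` advanced by ``dt`` hours with the
    invariant clamps applied.  The ``alive`` flag is passed through
    unchanged; death bookkeeping belongs to :func:`simulate_cell`.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    y = (state.bcr_level, state.bcr_bound, state.signal_on)
    k1 = _derivatives(*y, anti_igm, params)
    y2 = tuple(a + 0.5 * dt * b for a, b in zip(y, k1))
    k2 = _derivatives(*y2, anti_igm, params)
    y3 = tuple(a + 0.5 * dt * b for a, b in zip(y, k2))
    k3 = _derivatives(*y3, anti_igm, params)
    y4 = tuple(a + dt * b for a, b in zip(y, k3))
    k4 = _derivatives(*y4, anti_igm, params)
    new = tuple(
        a + dt / 6.0 * (b1 + 2 * b2 + 2 * b3 + b4)
        for a, b1, b2, b3, b4 in zip(y, k1, k2, k3, k4)
    )
    bcr_level, bcr_bound, signal_on = _clamp(*new)
    return CellState(
        bcr_level=bcr_level,
        bcr_bound=bcr_bound,
        signal_on=signal_on,
        alive=state.alive,
        t=state.t + dt,
    )


@dataclass
class CellTrajectory:
    """Outcome of a single-cell simulation."""

    death_time: Optional[float]  # None if alive through t_end
    t_end: float
    trajectory: Optional[pd.DataFrame] = None

    @property
    def alive(self) -> bool:
        return self.death_time is None

    def alive_at(self, t: float) -> bool:
        return self.death_time is None or self.death_time > t


def simulate_cell(
    bcr0: float,
    anti_igm: float,
    params: ModelParameters,
    t_end: float = 72.0,
    dt: float = DEFAULT_DT,
    record_times: Optional[Sequence[float]] = None,
) -> CellTrajectory:
    """Integrate one cell and report its death time (if any).

    The cell starts at ``(bcr_level=bcr0, bcr_bound=0, signal_on=bcr0)``
    — the survival signal before culture is taken to track the initial
    BCR level.  Death is recorded at the first grid time where
    ``signal_on < deadline`` (checked at t = 0 too) and is absorbing.
    If ``record_times`` is given, the trajectory is sampled at the
    nearest grid points and returned as a DataFrame.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not 0.0 < bcr0 <= 1.0:
        raise ValueError("bcr0 must lie in (0, 1]")
    n_steps = int(round(t_end / dt))
    record_steps = None
    if record_times is not None:
        record_steps = {int(round(t / dt)) for t in record_times}
    rows = []
    state = CellState(bcr_level=bcr0, bcr_bound=0.0, signal_on=bcr0, alive=True, t=0.0)
    death_time: Optional[float] = None
    if state.signal_on < params.deadline:
        state.alive = False
        death_time = 0.0
    if record_steps is not None and 0 in record_steps:
        rows.append((0.0, state.bcr_level, state.bcr_bound, state.signal_on, state.alive))
    for step in range(n_steps):
        if death_time is not None and record_steps is None:
            break
        state = rk4_step(state, anti_igm, params, dt)
        state.t = (step + 1) * dt  # keep grid times exact
        if death_time is None and state.signal_on < params.deadline:
            state.alive = False
            death_time = state.t
        state.alive = death_time is None
        if record_steps is not None and (step + 1) in record_steps:
            rows.append((state.t, state.bcr_level, state.bcr_bound, state.signal_on, state.alive))
    trajectory = None
    if record_steps is not None:
        trajectory = pd.DataFrame(
            rows, columns=["t", "bcr_level", "bcr_bound", "signal_on", "alive"]
        )
    return CellTrajectory(death_time=death_time, t_end=t_end, trajectory=trajectory)


def _signal_stage_profile(
    anti_igm: float, params: ModelParameters, n_steps: int, dt: float
) -> np.ndarray:
    """Per-unit-BCR signal-generation rate at every RK4 stage.

    The receptor subsystem is linear and independent of the signal, so
    its stage values for a unit cell determine every cell's forcing:
    ``g = k1*(phi - psi) + k4*max(0, psi - offset*phi)``, scaled by the
    cell's initial level.
    """
    phi, psi = _kernel.unit_binding_stages(
        float(anti_igm), params.d1, params.k2, params.k3, n_steps, float(dt)
    )
    return params.k1 * (phi - psi) + params.k4 * np.maximum(
        0.0, psi - params.offset * phi
    )


def cohort_death_times(
    cohort: Cohort,
    anti_igm: float,
    params: ModelParameters,
    t_end: float = 72.0,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Death time per cell (inf for cells alive through ``t_end``)."""
    if anti_igm < 0:
        raise ValueError("anti_igm must be >= 0")
    n_steps = int(round(t_end / dt))
    g = _signal_stage_profile(anti_igm, params, n_steps, dt)
    steps = _kernel.death_steps_from_stages(
        np.ascontiguousarray(cohort.initial_bcr_levels, dtype=np.float64),
        g,
        params.d2,
        params.deadline,
        float(dt),
        n_steps,
    )
    return np.where(steps < 0, np.inf, steps * dt)


def simulate_cohort(
    cohort: Cohort,
    anti_igm: float,
    params: ModelParameters,
    times: Sequence[float],
    dt: float = DEFAULT_DT,
    t_end: Optional[float] = None,
) -> np.ndarray:
    """Fraction of the cohort alive at each requested time.

    Query times are snapped to the nearest grid point; viability is
    non-increasing in time because death is absorbing.

    A cell's fate under this model is monotone in its initial BCR
    level (the signal forcing and initial signal both scale with it),
    so the alive count at each query time is located by binary search
    over the sorted cohort, integrating only the probed cells; the
    result is identical to simulating every cell.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one query time")
    if t_end is None:
        t_end = float(times.max()) if times.max() > 0 else dt
    n_steps = int(round(t_end / dt))
    g = _signal_stage_profile(anti_igm, params, n_steps, dt)
    levels = np.sort(np.ascontiguousarray(cohort.initial_bcr_levels, dtype=np.float64))
    n = levels.size
    alive_sentinel = n_steps + 1
    cache: dict = {}

    def death_step(i: int) -> int:
        if i not in cache:
            s = int(
                _kernel.death_steps_from_stages(
                    levels[i : i + 1], g, params.d2, params.deadline, float(dt), n_steps
                )[0]
            )
            cache[i] = alive_sentinel if s < 0 else s
        return cache[i]

    query_steps = np.round(times / dt).astype(int)
    order = np.argsort(query_steps)
    viability = np.empty(times.size, dtype=float)
    lo = 0
    for pos in order:
        q = query_steps[pos]
        hi = n
        while lo < hi:  # first cell alive past step q; threshold rises with q
            mid = (lo + hi) // 2
            if death_step(mid) > q:
                hi = mid
            else:
                lo = mid + 1
        viability[pos] = (n - lo) / n
    return viability


def dose_time_surface(
    cohort: Cohort,
    doses: Sequence[float],
    times: Sequence[float],
    params: ModelParameters,
    dt: float = DEFAULT_DT,
) -> ViabilityTable:
    """Cohort viability over a dose × time grid (one simulation per dose)."""
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    times = np.asarray(times, dtype=float)
    viab = np.vstack(
        [simulate_cohort(cohort, float(a), params, times, dt=dt) for a in doses]
    )
    return ViabilityTable(doses=doses, times=times, viability=viab)
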