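"""Kinetic model of the B-cell survival signal.

The model tracks three per-cell state variables on a dimensionless [0, 1]
scale:

* ``bcr_level`` — total surface BCR (max-normalized MFI), decaying
  exponentially at rate ``d1`` during culture;
* ``bcr_bound`` — BCR crosslinked by anti-IgM antibody, governed by
  mass-action association/dissociation (``k2``, ``k3``) with the free
  receptor pool;
* ``signal_on`` — the survival signal.  Signal "on" and "off" pools sum
  to one; free BCR converts off→on at rate ``k1`` (tonic signal),
  crosslinked BCR above an activation threshold (``offset``) converts
  off→on at rate ``k4``, and the on pool is consumed at rate ``d2``.

A cell dies when ``signal_on`` falls below the ``deadline`` threshold.
Time is in hours, antibody dose in µg/ml throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "ModelParameters",
    "CellState",
    "StimulusSchedule",
    "bcr_level_at",
    "tonic_rhs",
    "tonic_steady_state",
    "binding_rhs",
    "equilibrium_occupancy",
    "occupancy_closed_form",
    "saturation_fraction",
    "effective_signal_input",
    "combined_rhs",
]

_PARAM_KEYS = ("d1", "k1", "k2", "k3", "k4", "d2", "offset", "deadline")


@dataclass(frozen=True)
class ModelParameters:
    """The eight rate/threshold constants of the survival-signal model.

    Parameters
    ----------
    d1 : float
        BCR degradation rate (/h).
    k1 : float
        Tonic signal generation rate per unit free BCR (/h).
    k2 : float
        Antibody–BCR association rate (ml/µg/h).
    k3 : float
        Antibody–BCR dissociation rate (/h).
    k4 : float
        Signal generation rate per unit effective crosslinked BCR (/h).
    d2 : float
        Signal consumption rate (/h).
    offset : float
        Activation threshold, as a fraction of total BCR that must be
        crosslinked before the antigen-triggered term contributes.
    deadline : float
        Survival-signal floor; a cell dies when ``signal_on`` drops
        below it.
    """

    d1: float
    k1: float
    k2: float
    k3: float
    k4: float
    d2: float
    offset: float
    deadline: float

    def __post_init__(self) -> None:
        for key in _PARAM_KEYS:
            value = getattr(self, key)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {key!r} must be finite and >= 0, got {value}")
        if not 0.0 <= self.offset <= 1.0:
            raise ValueError(f"offset must lie in [0, 1], got {self.offset}")
        if not 0.0 <= self.deadline <= 1.0:
            raise ValueError(f"deadline must lie in [0, 1], got {self.deadline}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        missing = [k for k in _PARAM_KEYS if k not in d]
        if missing:
            raise KeyError(f"missing parameter key(s): {', '.join(missing)}")
        return cls(**{k: float(d[k]) for k in _PARAM_KEYS})

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def published(cls) -> "ModelParameters":
        """The consensus (GA-averaged) parameter set shipped with the package."""
        return cls.from_dict(_load_fixture("consensus_fit.json"))

    @classmethod
    def tonic_fit(cls) -> "ModelParameters":
        """The tonic-only (unstimulated) fit: k4 disabled, offset saturated."""
        return cls.from_dict(_load_fixture("tonic_fit.json"))

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


def _load_fixture(name: str) -> dict:
    with resources.files("bcrsurv.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass
class CellState:
    """Instantaneous state of a single B cell.

    ``signal_off`` is not stored: it is by definition ``1 - signal_on``.
    Once ``alive`` is False it never reverts.
    """

    bcr_level: float
    bcr_bound: float
    signal_on: float
    alive: bool = True
    t: float = 0.0

    def validate(self) -> "CellState":
        if not 0.0 <= self.bcr_bound <= self.bcr_level <= 1.0:
            raise ValueError(
                f"invariant 0 <= bcr_bound <= bcr_level <= 1 violated: "
                f"bcr_bound={self.bcr_bound}, bcr_level={self.bcr_level}"
            )
        if not 0.0 <= self.signal_on <= 1.0:
            raise ValueError(f"signal_on must lie in [0, 1], got {self.signal_on}")
        return self

    @property
    def signal_off(self) -> float:
        return 1.0 - self.signal_on

    @property
    def bcr_free(self) -> float:
        return self.bcr_level - self.bcr_bound


@dataclass(frozen=True)
class StimulusSchedule:
    """Constant anti-IgM stimulation over the whole culture.

    The F(ab')2 anti-IgM dose (µg/ml) is held fixed from time 0 to
    ``t_end`` (no washout), matching the culture protocol the model was
    built for.
    """

    anti_igm: float
    t_end: float = 72.0

    def __post_init__(self) -> None:
        if self.anti_igm < 0:
            raise ValueError(f"anti_igm must be >= 0, got {self.anti_igm}")
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")


# ---------------------------------------------------------------------------
# Elementary model functions
# ---------------------------------------------------------------------------

def bcr_level_at(t, bcr0=1.0, d1=0.01435):
    """Surface BCR level after *t* hours of culture: ``bcr0 * exp(-d1 t)``.

    Net receptor turnover (synthesis, internalization, recycling,
    degradation) is collapsed into a single first-order loss at rate
    ``d1``.  Accepts scalars or arrays for ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if d1 < 0:
        raise ValueError("d1 must be >= 0")
    out = bcr0 * np.exp(-d1 * t)
    return out if out.ndim else float(out)


def tonic_rhs(signal_on, bcr_level, k1, d2):
    """d(signal_on)/dt for the tonic-only model.

    Free BCR converts the off pool (``1 - signal_on``) to the on pool at
    rate ``k1 * bcr_level``; the on pool is consumed at rate ``d2``.
    """
    return k1 * (1.0 - signal_on) * bcr_level - d2 * signal_on


def tonic_steady_state(bcr_level, k1, d2):
    """Fixed point of :func:`tonic_rhs` at a frozen BCR level.

    ``S* = k1 B / (k1 B + d2)`` — the signal level a cell relaxes to if
    its receptor level stopped changing.  Monotone increasing in
    ``bcr_level`` and ``k1``, decreasing in ``d2``.
    """
    denom = k1 * bcr_level + d2
    if np.any(np.asarray(denom) <= 0):
        raise ValueError("k1*bcr_level + d2 must be > 0")
    return k1 * bcr_level / denom


def binding_rhs(bcr_bound, bcr_level, anti_igm, k2, k3):
    """d(bcr_bound)/dt under mass-action antibody binding.

    ``k2 * A * (B - b) - k3 * b`` with dose ``A`` in µg/ml.
    """
    if np.any(np.asarray(bcr_bound) > np.asarray(bcr_level)):
        raise ValueError("bcr_bound must not exceed bcr_level")
    return k2 * anti_igm * (bcr_level - bcr_bound) - k3 * bcr_bound


def equilibrium_occupancy(anti_igm, k2, k3):
    """Equilibrium fraction of total BCR that is antibody-bound.

    ``A / (A + k3/k2)`` — the binding isotherm in dose units of µg/ml.
    """
    return k2 * np.asarray(anti_igm, dtype=float) / (k2 * np.asarray(anti_igm, dtype=float) + k3)


def occupancy_closed_form(anti_igm, t, k2, k3):
    """Fraction of total BCR bound after *t* hours at constant dose.

    Closed-form solution of :func:`binding_rhs` at constant total BCR
    (the staining/occupancy model, where receptor decay is negligible on
    the sub-hour binding timescale):

    ``k2 A (1 - exp(-(k2 A + k3) t)) / (k2 A + k3)``

    Tends to the :func:`equilibrium_occupancy` isotherm as t → ∞.
    """
    A = np.asarray(anti_igm, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(A < 0):
        raise ValueError("anti_igm and t must be >= 0")
    rate = k2 * A + k3
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(rate > 0, k2 * A * -np.expm1(-rate * t) / np.where(rate > 0, rate, 1.0), 0.0)
    return out if out.ndim else float(out)


def saturation_fraction(anti_igm, t, k2, k3):
    """Fraction of the *equilibrium* occupancy reached after *t* hours.

    ``1 - exp(-(k2 A + k3) t)`` — how close the binding reaction is to
    its plateau, regardless of where that plateau sits.  Monotone
    increasing in both ``t`` and ``anti_igm``.
    """
    A = np.asarray(anti_igm, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(A < 0):
        raise ValueError("anti_igm and t must be >= 0")
    out = -np.expm1(-(k2 * A + k3) * t)
    return out if out.ndim else float(out)


def effective_signal_input(bcr_bound, bcr_level, offset):
    """Crosslinked BCR in excess of the activation threshold.

    ``max(0, bcr_bound - bcr_level * offset)``: occupancy below the
    threshold fraction ``offset`` produces no antigen-triggered signal.
    """
    return np.maximum(0.0, np.asarray(bcr_bound, dtype=float) - np.asarray(bcr_level, dtype=float) * offset)


def _derivatives(bcr_level, bcr_bound, signal_on, anti_igm, p: ModelParameters):
    """Raw RHS of the combined model on plain floats/arrays (no checks)."""
    d_level = -p.d1 * bcr_level
    free = bcr_level - bcr_bound
    d_bound = p.k2 * anti_igm * free - p.k3 * bcr_bound
    f = np.maximum(0.0, bcr_bound - bcr_level * p.offset)
    off = 1.0 - signal_on
    d_signal = p.k1 * off * free + p.k4 * off * f - p.d2 * signal_on
    return d_level, d_bound, d_signal


def combined_rhs(state: CellState, anti_igm: float, params: ModelParameters):
    """Time derivatives ``(d bcr_level/dt, d bcr_bound/dt, d signal_on/dt)``
    of the integrated tonic + antigen-triggered model.

    The tonic term runs off *free* BCR, the antigen-triggered term off
    crosslinked BCR above the activation threshold; both draw on the
    shared off pool ``1 - signal_on``.  With ``anti_igm = 0`` and
    ``bcr_bound = 0`` the signal derivative reduces exactly to
    :func:`tonic_rhs`.
    """
    state.validate()
    if anti_igm < 0:
        raise ValueError("anti_igm must be >= 0")
    return _derivatives(state.bcr_level, state.bcr_bound, state.signal_on, anti_igm, params)
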