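"""CSV/JSON serialization of the package's tables.

All tables are plain tidy CSV; fractions are stored on [0, 1] (percent
formatting is a presentation concern).  Readers are tolerant: unknown
extra columns are preserved in the frame and logged, but missing or
non-numeric required columns raise a :class:`ParseError` naming the
offender.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .simulate import Cohort, ViabilityTable
from .synth import ObservationSet

__all__ = [
    "ParseError",
    "read_viability_table",
    "write_viability_table",
    "read_observation_set",
    "write_observation_set",
    "read_cohort",
    "write_cohort",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A table file is missing columns or holds non-numeric cells."""


def _read_csv(path: Union[str, Path], required: tuple, optional: tuple = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in required and c not in optional]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, ", ".join(extra))
    for col in required:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {bad[0]}")
        if coerced.isna().any():
            raise ParseError(f"{path}: missing value in column {col!r}")
        frame[col] = coerced
    return frame


def write_viability_table(table: ViabilityTable, path: Union[str, Path]) -> None:
    table.to_frame().to_csv(path, index=False)


def read_viability_table(path: Union[str, Path]) -> ViabilityTable:
    frame = _read_csv(path, ("dose_ug_ml", "time_h", "viability"), optional=("sd",))
    if "sd" in frame.columns:
        frame["sd"] = pd.to_numeric(frame["sd"], errors="raise")
    return ViabilityTable.from_frame(frame)


def write_observation_set(obs: ObservationSet, path: Union[str, Path]) -> None:
    frame = pd.DataFrame({"x": obs.x, "y": obs.y, "sd": obs.sd})
    frame["kind"] = obs.kind
    if obs.dose is not None:
        frame["dose_ug_ml"] = obs.dose
    if obs.anti_igm is not None:
        frame["anti_igm_ug_ml"] = obs.anti_igm
    frame.to_csv(path, index=False)


def read_observation_set(path: Union[str, Path]) -> ObservationSet:
    frame = _read_csv(path, ("x", "y", "sd"), optional=("kind", "dose_ug_ml", "anti_igm_ug_ml"))
    if "kind" not in frame.columns:
        raise ParseError(f"{path}: missing column(s) kind")
    kinds = frame["kind"].unique()
    if len(kinds) != 1:
        raise ParseError(f"{path}: mixed 'kind' values {kinds}")
    dose = float(frame["dose_ug_ml"].iloc[0]) if "dose_ug_ml" in frame.columns else None
    stim = float(frame["anti_igm_ug_ml"].iloc[0]) if "anti_igm_ug_ml" in frame.columns else None
    return ObservationSet(
        x=frame["x"].to_numpy(),
        y=frame["y"].to_numpy(),
        sd=frame["sd"].to_numpy(),
        kind=str(kinds[0]),
        dose=dose,
        anti_igm=stim,
    )


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    pd.DataFrame({"bcr_level": cohort.initial_bcr_levels}).to_csv(path, index=False)


def read_cohort(path: Union[str, Path]) -> Cohort:
    frame = _read_csv(path, ("bcr_level",))
    return Cohort(initial_bcr_levels=frame["bcr_level"].to_numpy())
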