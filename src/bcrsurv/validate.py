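"""Internal-consistency checks of a fitted parameter set.

Given a parameter JSON, recompute the analytic quantities the model
pins down — residual BCR after 72 h, the signal-strength ratio k4/k1,
the binding ratio k3/k2, the occupancy-saturation percentages at
reference (dose, time) points, and the BTK-inhibition tonic-rate
reduction — and compare each with its published value at the printed
rounding.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .model import ModelParameters, bcr_level_at, saturation_fraction

__all__ = ["validate_targets", "IBRUTINIB_K1"]

#: Tonic generation rate reproducing the viability decline seen under
#: 100 nM of the BTK inhibitor Ibrutinib (~40% of the unstimulated-fit k1).
IBRUTINIB_K1 = 0.009523


def validate_targets(params: Union[str, Path, dict, ModelParameters]) -> pd.DataFrame:
    """Evaluate every analytic consistency target from a parameter set.

    Returns a DataFrame with one row per target: the computed value,
    the expected value at its printed rounding, and a pass flag.
    """
    if isinstance(params, (str, Path)):
        params = json.loads(Path(params).read_text())
    if isinstance(params, dict):
        if not params:
            raise ValueError("empty parameter set")
        params = ModelParameters.from_dict(params)
    p = params

    tonic_k1 = ModelParameters.tonic_fit().k1
    # (name, computed, expected at its printed rounding, tolerance = one
    # unit in the last printed digit)
    rows = [
        ("residual_bcr_72h", bcr_level_at(72.0, 1.0, p.d1), 0.3558, 1e-4),
        ("k4_over_k1", p.k4 / p.k1, 4.3, 0.05),
        ("k3_over_k2", p.k3 / p.k2, 1.132, 5e-4),
        ("saturation_pct_1ug_30min", 100 * saturation_fraction(1.0, 0.5, p.k2, p.k3), 95, 0.5),
        ("saturation_pct_0p1ug_30min", 100 * saturation_fraction(0.1, 0.5, p.k2, p.k3), 82, 0.5),
        ("saturation_pct_10ug_9min", 100 * saturation_fraction(10.0, 0.15, p.k2, p.k3), 99, 0.5),
        ("btk_inhibited_k1_fraction", IBRUTINIB_K1 / tonic_k1, 0.40, 5e-3),
        ("btk_tonic_reduction_pct", 100 * (1 - IBRUTINIB_K1 / tonic_k1), 60, 0.5),
    ]
    frame = pd.DataFrame(rows, columns=["target", "computed", "expected", "tol"])
    frame["passed"] = (frame["computed"] - frame["expected"]).abs() <= frame["tol"]
    return frame
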