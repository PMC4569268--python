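"""Observed-vs-predicted comparison statistics.

The study it reproduces reports RMSE values that are exactly ten times
the conventional root-mean-square error of its printed columns (likely a
unit-scaling slip).  To keep comparisons unambiguous the report carries
both: ``rmse_standard`` = sqrt(mean squared error) in U/mL, and
``rmse_paper_scale`` = 10 x rmse_standard, the scale on which the study's
values (4.92 for the polynomial model, 4.1 for the network) live.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["ComparisonReport", "MAPEUndefinedError", "compare"]


class MAPEUndefinedError(ValueError):
    """MAPE is undefined because an observed value is zero."""


@dataclass(frozen=True)
class ComparisonReport:
    rmse_standard: float
    rmse_paper_scale: float
    mape_percent: float | None
    r_squared: float
    r: float
    n: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def compare(
    observed: Sequence[float] | np.ndarray,
    predicted: Sequence[float] | np.ndarray,
    require_mape: bool = True,
) -> ComparisonReport:
    """Error and agreement statistics between paired response vectors.

    mape_percent = 100 * mean(|obs - pred| / obs) requires strictly
    positive observed values; with ``require_mape=False`` a zero observed
    value yields ``mape_percent=None`` instead of an error.
    r_squared = 1 - SSE/SST, where SST is about the observed mean.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError(
            f"observed and predicted must be equal-length vectors, got "
            f"{obs.shape} and {pred.shape}"
        )
    if obs.size < 1:
        raise ValueError("need at least one observation")

    err = obs - pred
    rmse = float(np.sqrt(np.mean(err**2)))

    if np.any(obs == 0):
        if require_mape:
            raise MAPEUndefinedError(
                "observed vector contains zeros; MAPE is undefined"
            )
        mape = None
    else:
        mape = float(100.0 * np.mean(np.abs(err) / np.abs(obs)))

    sst = float(((obs - obs.mean()) ** 2).sum())
    sse = float((err**2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    corr = float(np.corrcoef(obs, pred)[0, 1]) if obs.size > 1 and np.std(pred) > 0 else 0.0

    return ComparisonReport(
        rmse_standard=rmse,
        rmse_paper_scale=10.0 * rmse,
        mape_percent=mape,
        r_squared=r2,
        r=corr,
        n=int(obs.size),
    )
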