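"""Information criteria and correct-model identification rates.

AIC = -2LL + 2q and BIC = -2LL + ln(N)q with N the number of level-1
records; smaller is better.  The crossed model is the generating (correct)
model throughout the study, so the identification rate is the percentage of
replications in which a criterion is strictly smaller for the crossed fit.
Ties count as incorrect (conservative; a probability-zero event here).
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .fit import FitResult

__all__ = ["aic", "bic", "identification_rate", "summarize_selection"]


def aic(deviance: float, q: int) -> float:
    """Akaike information criterion: deviance + 2q."""
    if q < 1:
        raise ValueError("q must be >= 1")
    return deviance + 2.0 * q


def bic(deviance: float, q: int, n_level1: int) -> float:
    """Bayesian information criterion: deviance + ln(N)q, N = level-1 count."""
    if q < 1:
        raise ValueError("q must be >= 1")
    if n_level1 < 2:
        raise ValueError("n_level1 must be >= 2")
    return deviance + math.log(n_level1) * q


def identification_rate(picks: Sequence[str]) -> float:
    """Percentage of picks equal to 'crossed'."""
    if not picks:
        raise ValueError("picks must be non-empty")
    return 100.0 * sum(p == "crossed" for p in picks) / len(picks)


def summarize_selection(
    pairs: Sequence[tuple[FitResult, FitResult]],
    condition_id: str = "",
) -> pd.DataFrame:
    """Per-replication criteria and aggregate hit rates for one condition.

    ``pairs`` holds (crossed fit, nested fit) per replication; replications
    where either fit failed to converge are dropped.
    """
    rows = []
    for r, (fc, fn) in enumerate(pairs):
        if not (fc.converged and fn.converged):
            continue
        ac, an = aic(fc.deviance, fc.q), aic(fn.deviance, fn.q)
        bc, bn = (
            bic(fc.deviance, fc.q, fc.n_level1),
            bic(fn.deviance, fn.q, fn.n_level1),
        )
        rows.append(
            {
                "condition_id": condition_id,
                "replication": r,
                "aic_crossed": ac,
                "aic_nested": an,
                "bic_crossed": bc,
                "bic_nested": bn,
                "aic_pick": "crossed" if ac < an else "nested",
                "bic_pick": "crossed" if bc < bn else "nested",
            }
        )
    return pd.DataFrame(rows)
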