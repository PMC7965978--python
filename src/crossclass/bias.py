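"""Relative bias metrics across Monte Carlo replications.

Parameter bias is (mean estimate - truth) / truth, acceptable within |0.05|;
SE bias is (mean model SE - empirical SD of estimates) / empirical SD,
acceptable within |0.10| (Hoogland-Boomsma thresholds).  The empirical SD
uses denominator R - 1 over the point estimates of the same model being
evaluated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import FIXED_NAMES, FitResult
from .grid import PopulationParameters

__all__ = [
    "PB_THRESHOLD",
    "SEB_THRESHOLD",
    "UndefinedBiasError",
    "parameter_relative_bias",
    "se_relative_bias",
    "summarize_condition",
]

PB_THRESHOLD = 0.05
SEB_THRESHOLD = 0.10


class UndefinedBiasError(ValueError):
    """Raised when a relative bias has a zero denominator."""


def parameter_relative_bias(mean_estimate: float, truth: float) -> float:
    """(mean estimate - truth) / truth."""
    if truth == 0:
        raise UndefinedBiasError(
            "relative parameter bias undefined for truth = 0; "
            "report the raw difference instead"
        )
    return (mean_estimate - truth) / truth


def se_relative_bias(mean_model_se: float, empirical_se: float) -> float:
    """(mean model SE - empirical SD of estimates) / empirical SD."""
    if empirical_se <= 0:
        raise UndefinedBiasError("empirical SE must be positive")
    return (mean_model_se - empirical_se) / empirical_se


def _truth_map(truth: PopulationParameters) -> dict[str, float]:
    return {
        "intercept": truth.intercept,
        "slope_x": truth.coeff_x,
        "slope_w": truth.coeff_w,
        "slope_z": truth.coeff_z,
    }


def summarize_condition(
    fits: list[FitResult],
    truth: PopulationParameters,
    condition_id: str = "",
    rho: float | None = None,
) -> pd.DataFrame:
    """Per-parameter bias rows for one condition and one model.

    All ``fits`` must share a model tag.  Fixed-effect rows always carry
    parameter and SE bias.  Variance-component rows carry parameter bias
    only when the level-2 residual correlation is zero (the population
    values are unknown otherwise); the raw mean/SD of the estimates is
    always reported, mirroring how the correlated conditions are tabulated.
    Non-converged replications are excluded.
    """
    used = [f for f in fits if f.converged]
    if len(used) < 2:
        raise ValueError("need >= 2 converged replications to summarize")
    tags = {f.model_tag for f in used}
    if len(tags) != 1:
        raise ValueError("fits mix model tags; summarize one model at a time")
    model_tag = tags.pop()
    if rho is None:
        rho = truth.rho_l2
    n = len(used)

    rows = []
    truths = _truth_map(truth)
    for name in FIXED_NAMES:
        est = np.array([f.fixed[name][0] for f in used])
        ses = np.array([f.fixed[name][1] for f in used])
        emp_sd = float(np.std(est, ddof=1))
        pb = parameter_relative_bias(float(est.mean()), truths[name])
        # degenerate replications (all estimates equal) leave the SE-bias ratio undefined
        seb = (
            se_relative_bias(float(ses.mean()), emp_sd)
            if emp_sd > 0
            else np.nan
        )
        rows.append(
            {
                "condition_id": condition_id,
                "model_tag": model_tag,
                "parameter": name,
                "kind": "fixed",
                "truth": truths[name],
                "mean_estimate": float(est.mean()),
                "empirical_sd": emp_sd,
                "mean_model_se": float(ses.mean()),
                "parameter_bias": pb,
                "se_bias": seb,
                "pb_flag": abs(pb) < PB_THRESHOLD,
                "seb_flag": abs(seb) < SEB_THRESHOLD if np.isfinite(seb) else np.nan,
                "n_reps_used": n,
            }
        )

    var_truths = {
        "sigma2_e": truth.sigma2_e,
        "tau_row": truth.tau_row,
        "tau_col": truth.tau_col,
    }
    var_names = list(used[0].variance)
    for name in var_names:
        est = np.array([f.variance[name] for f in used])
        row = {
            "condition_id": condition_id,
            "model_tag": model_tag,
            "parameter": name,
            "kind": "variance",
            "truth": var_truths[name] if rho == 0 else np.nan,
            "mean_estimate": float(est.mean()),
            "empirical_sd": float(np.std(est, ddof=1)),
            "mean_model_se": np.nan,
            "parameter_bias": np.nan,
            "se_bias": np.nan,
            "pb_flag": np.nan,
            "seb_flag": np.nan,
            "n_reps_used": n,
        }
        if rho == 0:
            pb = parameter_relative_bias(float(est.mean()), var_truths[name])
            row["parameter_bias"] = pb
            row["pb_flag"] = abs(pb) < PB_THRESHOLD
        rows.append(row)
    return pd.DataFrame(rows)
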