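"""Headline quantities of the misspecification study.

These helpers run the design grid (at a configurable replication count) and
reduce the per-condition summaries to the study's aggregate findings: mean
SE biases of the misspecified model's fixed effects, mean parameter biases
of its variance components, information-criterion hit rates by feeder count,
and the single-condition comparison of level-2 variance estimates between
the two models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import SimulationCondition
from .study import StudyConfig, StudyResult, run_condition, run_study

__all__ = [
    "full_grid_study",
    "headline_aggregates",
    "example_cell",
    "EXAMPLE_CONDITION",
]

#: the tabulated example condition: small coefficient, 30 groups of ~20,
#: moderate IUCC, correlated residuals, two feeders
EXAMPLE_CONDITION = SimulationCondition(
    coeff_magnitude=0.2,
    n_feeders=2,
    l2_residual_corr=0.4,
    n_groups=30,
    avg_group_size=20.0,
    iucc=0.15,
)


def full_grid_study(
    n_replications: int = 50,
    master_seed: int = 0,
    n_jobs: int = 1,
    output_dir=None,
) -> StudyResult:
    """Run every cell of the 144-condition grid."""
    cfg = StudyConfig(
        n_replications=n_replications,
        master_seed=master_seed,
        n_jobs=n_jobs,
        output_dir=output_dir,
    )
    return run_study(cfg)


def _mean_over_conditions(bias: pd.DataFrame, model_tag: str, parameter: str,
                          column: str, rho: float | None = None) -> float:
    sub = bias[(bias["model_tag"] == model_tag) & (bias["parameter"] == parameter)]
    if rho is not None:
        sub = sub[sub["l2_residual_corr"] == rho]
    return float(sub[column].mean())


def headline_aggregates(result: StudyResult) -> dict[str, float]:
    """Aggregate the study's headline numbers from a grid run.

    Means are taken across conditions (each condition contributing its
    across-replication summary), matching how the study reports them.
    """
    bias = result.bias
    sel = result.selection_summary
    out = {
        # fixed-effect SE biases of the misspecified model, all conditions
        "seb_intercept_hlm": _mean_over_conditions(
            bias, "nested", "intercept", "se_bias"
        ),
        "seb_slope_z_hlm": _mean_over_conditions(
            bias, "nested", "slope_z", "se_bias"
        ),
        "seb_slope_x_hlm": _mean_over_conditions(
            bias, "nested", "slope_x", "se_bias"
        ),
        "seb_intercept_ccrem": _mean_over_conditions(
            bias, "crossed", "intercept", "se_bias"
        ),
        # variance-component parameter biases, zero-correlation half-grid
        "pb_sigma2_hlm_rho0": _mean_over_conditions(
            bias, "nested", "sigma2_e", "parameter_bias", rho=0.0
        ),
        "pb_tau_hlm_rho0": _mean_over_conditions(
            bias, "nested", "tau_col", "parameter_bias", rho=0.0
        ),
        "pb_sigma2_ccrem_rho0": _mean_over_conditions(
            bias, "crossed", "sigma2_e", "parameter_bias", rho=0.0
        ),
        # raw level-1 variance estimates, correlated half-grid
        "sigma2_hlm_rho04": _mean_over_conditions(
            bias, "nested", "sigma2_e", "mean_estimate", rho=0.4
        ),
        "sigma2_ccrem_rho04": _mean_over_conditions(
            bias, "crossed", "sigma2_e", "mean_estimate", rho=0.4
        ),
    }
    for f in sorted(sel["n_feeders"].unique()):
        sub = sel[sel["n_feeders"] == f]
        out[f"aic_hit_f{int(f)}"] = float(sub["aic_hit_rate"].mean())
        out[f"bic_hit_f{int(f)}"] = float(sub["bic_hit_rate"].mean())
    out["aic_hit_overall"] = float(sel["aic_hit_rate"].mean())
    out["bic_hit_overall"] = float(sel["bic_hit_rate"].mean())
    return out


def example_cell(
    n_replications: int = 500, master_seed: int = 0
) -> dict[str, float]:
    """Mean level-2 variance estimates for the tabulated example condition.

    Returns the across-replication means of the misspecified model's single
    level-2 variance and of the correct model's retained-factor variance.
    """
    res = run_condition(EXAMPLE_CONDITION, n_replications, master_seed)
    hlm = np.array(
        [f.variance["tau_col"] for f in res.nested if f.converged]
    )
    ccrem = np.array(
        [f.variance["tau_col"] for f in res.crossed if f.converged]
    )
    return {
        "hlm_tau_mean": float(hlm.mean()),
        "hlm_tau_sd": float(hlm.std(ddof=1)),
        "ccrem_tau_mean": float(ccrem.mean()),
        "ccrem_tau_sd": float(ccrem.std(ddof=1)),
        "n_reps_used": int(len(hlm)),
    }
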