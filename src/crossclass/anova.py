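"""Factorial ANOVA screening of bias outcomes with partial eta-squared.

Bias metrics are screened by a balanced factorial ANOVA on the six design
factors, with interactions up to a configurable order (default 3) and the
remaining variation as error.  Effect sizes are partial eta-squared,
ss_effect / (ss_effect + ss_error), labelled with the conventional
0.010 / 0.059 / 0.138 cutpoints (small / medium / large; left-closed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AnovaResult",
    "factorial_anova",
    "partial_eta_squared",
    "classify_effect_size",
    "EFFECT_SIZE_CUTPOINTS",
]

EFFECT_SIZE_CUTPOINTS = (0.010, 0.059, 0.138)

DESIGN_FACTORS = (
    "coeff_magnitude",
    "n_feeders",
    "l2_residual_corr",
    "n_groups",
    "avg_group_size",
    "iucc",
)


@dataclass
class AnovaResult:
    """ANOVA table for one outcome: per-term SS, df, partial eta-squared."""

    outcome: str
    effects: pd.DataFrame  # columns: term, ss_effect, df, partial_eta_sq, size_label
    ss_error: float
    df_error: int

    @property
    def ss_total(self) -> float:
        return float(self.effects["ss_effect"].sum() + self.ss_error)

    def top_terms(self, k: int = 3) -> list[str]:
        return list(
            self.effects.sort_values("partial_eta_sq", ascending=False)
            .head(k)["term"]
        )


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """ss_effect / (ss_effect + ss_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("ss_effect and ss_error cannot both be zero")
    return ss_effect / (ss_effect + ss_error)


def classify_effect_size(eta: float) -> str:
    """Label a partial eta-squared: negligible / small / medium / large."""
    if not 0 <= eta <= 1:
        raise ValueError("partial eta-squared must lie in [0, 1]")
    small, medium, large = EFFECT_SIZE_CUTPOINTS
    if eta < small:
        return "negligible"
    if eta < medium:
        return "small"
    if eta < large:
        return "medium"
    return "large"


def _check_balanced(table: pd.DataFrame, factors: tuple[str, ...]) -> None:
    counts = table.groupby(list(factors), observed=True).size()
    expected = int(np.prod([table[f].nunique() for f in factors]))
    if len(counts) != expected:
        raise ValueError(
            f"design has missing cells: {len(counts)} of {expected} present"
        )
    if counts.nunique() != 1:
        raise ValueError("design is unbalanced: unequal cell counts")


def factorial_anova(
    table: pd.DataFrame,
    outcome: str,
    max_interaction_order: int = 3,
    factors: tuple[str, ...] = DESIGN_FACTORS,
) -> AnovaResult:
    """Balanced factorial ANOVA of ``outcome`` on the design factors.

    ``table`` holds one row per condition (or per replication, if screening
    at the replication level) with the factor columns and the outcome.  On
    a balanced design the term sums of squares are orthogonal, so the SS
    type is immaterial; sequential (Type I) SS are used.
    """
    if not 1 <= max_interaction_order <= 3:
        raise ValueError("max_interaction_order must be in 1..3")
    missing = [c for c in (*factors, outcome) if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks columns: {missing}")
    _check_balanced(table, factors)

    data = table[list(factors)].copy()
    data["_y"] = table[outcome].to_numpy(dtype=float)
    terms = [f"C({f}, Sum)" for f in factors]
    rhs = " + ".join(terms)
    if max_interaction_order > 1:
        rhs = f"({rhs}) ** {max_interaction_order}"
    model = smf.ols(f"_y ~ {rhs}", data=data).fit()
    tab = anova_lm(model, typ=1)

    ss_error = float(tab.loc["Residual", "sum_sq"])
    df_error = int(tab.loc["Residual", "df"])
    # wipe pure floating-point dust so a (near-)constant outcome yields
    # zero effects rather than 0/0 artifacts
    y = data["_y"].to_numpy()
    ss_total = float(np.sum((y - y.mean()) ** 2))
    tol = 1e-12 * max(ss_total, float(np.sum(y**2)), 1.0)
    if ss_error < tol:
        ss_error = 0.0
    rows = []
    for term, r in tab.iterrows():
        if term == "Residual":
            continue
        clean = ":".join(
            t.split("(")[1].split(",")[0] for t in term.split(":")
        )
        ss = max(float(r["sum_sq"]), 0.0)
        if ss < tol:
            ss = 0.0
        eta = partial_eta_squared(ss, ss_error) if ss + ss_error > 0 else 0.0
        rows.append(
            {
                "term": clean,
                "order": clean.count(":") + 1,
                "ss_effect": ss,
                "df": int(r["df"]),
                "partial_eta_sq": eta,
                "size_label": classify_effect_size(eta),
            }
        )
    effects = pd.DataFrame(rows)
    return AnovaResult(
        outcome=outcome, effects=effects, ss_error=ss_error, df_error=df_error
    )
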