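"""Cross-classified data generation with feeder-structured membership.

Individuals belong simultaneously to a receiver ("column") group j and a
feeder ("row") group k; each column group draws its members from a small set
of f feeder rows, which is what makes the classification crossed rather than
nested.  The outcome follows a two-way random-intercept model:

    Y_ijk = intercept + g*X_ijk + g*W_j + g*Z_k + b_j + c_k + e_ijk

with X (individual), W (receiver-level) and Z (feeder-level) predictors all
N(50, 10^2), b_j ~ N(0, tau_col), c_k ~ N(0, tau_row), e ~ N(0, sigma2_e).
The misspecified analysis downstream keeps the receiver factor as its only
level-2 structure, so W stays a cluster predictor while Z is demoted to the
individual level and the feeder grouping is ignored.

Correlation mechanism
---------------------
A non-zero correlation between the two sets of level-2 residuals only has
observable consequences if it runs along the membership links.  Two
mechanisms are provided:

* ``"aggregate"`` (default): each column group's residual is correlated with
  the standardized aggregate of its own feeders' residuals,
  ``b_j = rho * sum_{k in feeders(j)} c_k / sqrt(f) + sqrt(1-rho^2) * sqrt(tau_col) * eta_j``
  with ``c_k ~ N(0, tau_row)`` i.i.d.  Marginal variances are preserved and
  the correlation between ``b_j`` and the (standardized) combined residual
  of column j's feeders is exactly rho.  This is the linked-membership
  reading of the correlation (a school's unexplained effect tracks the joint
  effect of the neighborhoods that feed it) and it reproduces the
  characteristic overestimation pattern of the misspecified model.
* ``"matched"``: index-matched bivariate pairs (b_j, c_j) with correlation
  rho (requires J = K); the pairing is independent of the feeder map, so
  under random feeders the correlation is nearly invisible to either model.

With rho = 0 the two mechanisms coincide (independent draws).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import PopulationParameters, SimulationCondition, resolve_population_parameters

__all__ = [
    "FeederStructure",
    "CrossClassifiedDataset",
    "build_feeder_structure",
    "draw_group_sizes",
    "generate_level2_effects",
    "generate_dataset",
    "write_dataset_csv",
    "read_dataset_csv",
]


@dataclass(frozen=True)
class FeederStructure:
    """Feeder map: which row groups supply each column group."""

    n_col: int
    n_row: int
    feeders_of: dict[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        for j, rows in self.feeders_of.items():
            if len(set(rows)) != len(rows):
                raise ValueError(f"duplicate feeder rows for column {j}")
            if any(not (0 <= k < self.n_row) for k in rows):
                raise ValueError(f"feeder row out of range for column {j}")

    @property
    def n_feeders(self) -> int:
        return len(next(iter(self.feeders_of.values())))


@dataclass
class CrossClassifiedDataset:
    """Generated records plus the structure and truth that produced them.

    ``records`` has one row per individual with columns
    (i, j, k, x, z, w, y); j indexes column groups, k row groups (0-based).
    """

    records: pd.DataFrame
    structure: FeederStructure
    truth: PopulationParameters
    seed_info: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.records)


def build_feeder_structure(
    n_col: int,
    n_row: int,
    f: int,
    rng: np.random.Generator,
    link_matched: bool = False,
) -> FeederStructure:
    """Draw f distinct feeder rows for each of n_col column groups.

    By default all f feeders are drawn uniformly without replacement,
    independently across column groups.  With ``link_matched`` and J = K,
    column j always includes row j (a "home" feeder) and draws the remaining
    f - 1 uniformly from the other rows.
    """
    if not 1 <= f <= n_row:
        raise ValueError(f"need 1 <= f <= n_row, got f={f}, n_row={n_row}")
    matched = link_matched and n_col == n_row
    feeders: dict[int, tuple[int, ...]] = {}
    for j in range(n_col):
        if matched:
            others = np.delete(np.arange(n_row), j)
            extra = rng.choice(others, size=f - 1, replace=False)
            rows = np.concatenate(([j], extra))
        else:
            rows = rng.choice(n_row, size=f, replace=False)
        feeders[j] = tuple(int(k) for k in rows)
    return FeederStructure(n_col=n_col, n_row=n_row, feeders_of=feeders)


def draw_group_sizes(
    n_col: int, mean_size: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Column-group sizes: normal draws rounded to integers, floored at 1."""
    if mean_size <= 0:
        raise ValueError("mean_size must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    sizes = np.rint(rng.normal(mean_size, sd, size=n_col)).astype(int)
    return np.maximum(sizes, 1)


def generate_level2_effects(
    n_col: int,
    n_row: int,
    tau: float,
    rho: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Level-2 residuals b (columns) and c (rows), marginally N(0, tau).

    With rho != 0 the index-matched pairs (b_j, c_j) are bivariate normal
    with correlation rho, which requires J = K.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if rho != 0 and n_col != n_row:
        raise ValueError("correlated level-2 residuals require n_col == n_row")
    sd = float(np.sqrt(tau))
    u = rng.standard_normal(n_col)
    v = rng.standard_normal(n_row)
    b = sd * u
    if rho != 0:
        c = sd * (rho * u + np.sqrt(1.0 - rho**2) * v)
    else:
        c = sd * v
    return b, c


def _level2_feeder_aggregate(
    structure: FeederStructure,
    tau_col: float,
    tau_row: float,
    rho: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Feeder-aggregation residuals: b_j correlated rho with the
    standardized sum of column j's feeder residuals; marginals preserved."""
    J, K = structure.n_col, structure.n_row
    f = structure.n_feeders
    c = rng.normal(0.0, np.sqrt(tau_row), size=K)
    eta = rng.standard_normal(J)
    feeder_table = np.array([structure.feeders_of[j] for j in range(J)])
    if tau_row > 0:
        agg = c[feeder_table].sum(axis=1) / np.sqrt(f * tau_row)
    else:  # degenerate: nothing to correlate with, keep the marginal exact
        agg = rng.standard_normal(J)
    b = np.sqrt(tau_col) * (rho * agg + np.sqrt(1.0 - rho**2) * eta)
    return b, c


def generate_dataset(
    condition: SimulationCondition,
    params: PopulationParameters | None = None,
    rng: np.random.Generator | None = None,
    corr_mechanism: str = "aggregate",
    link_matched: bool = False,
    sigma2_override: float | None = None,
) -> CrossClassifiedDataset:
    """Generate one cross-classified dataset for a design cell.

    ``corr_mechanism`` selects how a non-zero level-2 residual correlation
    is realized ("aggregate" or "matched"; see the module docstring);
    irrelevant when the condition's correlation is zero.
    ``sigma2_override`` is a test hook that replaces the level-1 residual
    variance (e.g. 1e-12 for a noise-free check) without touching the
    recorded truth's level-2 structure.
    """
    if params is None:
        params = resolve_population_parameters(condition)
    if rng is None:
        rng = np.random.default_rng()
    if corr_mechanism not in ("aggregate", "matched"):
        raise ValueError("corr_mechanism must be 'aggregate' or 'matched'")
    sigma2 = params.sigma2_e if sigma2_override is None else sigma2_override

    J = K = condition.n_groups
    structure = build_feeder_structure(
        J, K, condition.n_feeders, rng, link_matched=link_matched
    )
    sizes = draw_group_sizes(
        J, condition.avg_group_size, params.groupsize_sd, rng
    )
    if corr_mechanism == "aggregate" or params.rho_l2 == 0:
        b, c = _level2_feeder_aggregate(
            structure, params.tau_col, params.tau_row, params.rho_l2, rng
        )
    else:
        # index-matched bivariate pairs, scaled per factor
        b, c = generate_level2_effects(J, K, 1.0, params.rho_l2, rng)
        b = np.sqrt(params.tau_col) * b
        c = np.sqrt(params.tau_row) * c

    n_total = int(sizes.sum())
    col = np.repeat(np.arange(J), sizes)
    # each individual picks one of its column's feeders uniformly
    feeder_table = np.array([structure.feeders_of[j] for j in range(J)])
    pick = rng.integers(0, condition.n_feeders, size=n_total)
    row = feeder_table[col, pick]

    mean, sd = params.predictor_mean, params.predictor_sd
    x = rng.normal(mean, sd, size=n_total)
    w_groups = rng.normal(mean, sd, size=J)   # receiver-level predictor W_j
    z_groups = rng.normal(mean, sd, size=K)   # feeder-level predictor Z_k
    e = rng.normal(0.0, np.sqrt(sigma2), size=n_total)

    y = (
        params.intercept
        + params.coeff_x * x
        + params.coeff_w * w_groups[col]
        + params.coeff_z * z_groups[row]
        + b[col]
        + c[row]
        + e
    )
    records = pd.DataFrame(
        {
            "i": np.arange(n_total),
            "j": col,
            "k": row,
            "x": x,
            "z": z_groups[row],
            "w": w_groups[col],
            "y": y,
        }
    )
    return CrossClassifiedDataset(
        records=records,
        structure=structure,
        truth=params,
        seed_info={"condition_id": condition.condition_id},
    )


def write_dataset_csv(dataset: CrossClassifiedDataset, path: str | Path) -> None:
    """Write records as CSV plus a JSON sidecar (structure, truth, seed)."""
    path = Path(path)
    dataset.records.to_csv(path, index=False)
    sidecar = {
        "structure": {
            "n_col": dataset.structure.n_col,
            "n_row": dataset.structure.n_row,
            "feeders_of": {
                str(j): list(v) for j, v in dataset.structure.feeders_of.items()
            },
        },
        "truth": dataset.truth.__dict__,
        "seed_info": dataset.seed_info,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_dataset_csv(path: str | Path) -> CrossClassifiedDataset:
    """Read a dataset written by :func:`write_dataset_csv`."""
    path = Path(path)
    records = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    structure = FeederStructure(
        n_col=sidecar["structure"]["n_col"],
        n_row=sidecar["structure"]["n_row"],
        feeders_of={
            int(j): tuple(v)
            for j, v in sidecar["structure"]["feeders_of"].items()
        },
    )
    truth = PopulationParameters(**sidecar["truth"])
    return CrossClassifiedDataset(
        records=records,
        structure=structure,
        truth=truth,
        seed_info=sidecar.get("seed_info", {}),
    )
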