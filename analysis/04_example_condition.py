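#!/usr/bin/env python
"""Replicate the tabulated single-condition comparison at 500 replications.

Reports the across-replication mean (SD) of the level-2 variance estimate
under both models for the condition MC 0.2 / 30 groups / size 20 /
IUCC 0.15 / rho 0.4 / 2 feeders, where the generating per-factor variance
is 0.2143.  The misspecified model absorbs much of the ignored factor's
variance (and its correlation with the retained factor) into its single
level-2 component.
"""

import json
from pathlib import Path

from crossclass.replicate import EXAMPLE_CONDITION, example_cell

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cell = example_cell(n_replications=500, master_seed=1)
    print(f"condition {EXAMPLE_CONDITION.condition_id} (truth tau = 0.2143)")
    print(
        f"crossed model:      {cell['ccrem_tau_mean']:.3f} "
        f"({cell['ccrem_tau_sd']:.3f})"
    )
    print(
        f"misspecified model: {cell['hlm_tau_mean']:.3f} "
        f"({cell['hlm_tau_sd']:.3f})"
    )
    (OUT / "example_cell.json").write_text(json.dumps(cell, indent=2))


if __name__ == "__main__":
    main()
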