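#!/usr/bin/env python
"""Relaxation study: identify the linear two-Maxwell transfer function from
step-relaxation records and read the time constants off its poles.

For each final strain (25%, 50%) a relaxation record is generated from the
published time-constant pairs, the second-order continuous-time transfer
function is estimated by the iterative instrumental-variable scheme, and
the recovered taus plus the pointwise model-vs-data error are tabulated.
The error trace staying below 0.01 N at 1% load noise mirrors the
behaviour reported for the real 50% tests.
"""

import argparse
from pathlib import Path

import pandas as pd

from gelsid.workflow import WorkflowConfig, run_relaxation_study


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    report = run_relaxation_study(WorkflowConfig(seed=args.seed))
    rows = []
    for label, row in report.items():
        rows.append({
            "test": label,
            "final_strain": row["target_strain"],
            "tau1_true_s": row["tau_true"][0], "tau2_true_s": row["tau_true"][1],
            "tau1_hat_s": round(row["tau_hat"][0], 3),
            "tau2_hat_s": round(row["tau_hat"][1], 3),
            "max_abs_error_N": row["max_abs_error"],
            "converged": row["converged"],
        })
    table = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    table.to_csv("results/relaxation_report.csv", index=False)
    print(table.to_string(index=False))
    worst = table["max_abs_error_N"].max()
    print(f"\nworst pointwise model-vs-data error: {worst:.4f} N "
          f"({'below' if worst < 0.01 else 'ABOVE'} the 0.01 N benchmark)")


if __name__ == "__main__":
    main()
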