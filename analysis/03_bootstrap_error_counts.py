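#!/usr/bin/env python
"""Bootstrap error-count null distributions for the two test conditions.

Resamples the 240 adapted-probe trials of each test condition of the
reconstructed cohort (with replacement; trial and participant units) and
summarizes the count distributions: mean, 5th/95th percentiles, and the
cross-condition tail probabilities in every convention.  Writes a summary
CSV and count-null histograms under results/.
"""

from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd

from orthillusion import (
    StudyDesign,
    bootstrap_error_counts,
    fit_control_reference,
    reconstruct_reported_counts,
)
from orthillusion.plots import plot_count_null

RESULTS = Path(__file__).resolve().parents[1] / "results"
REPORTED_COUNTS = {"test_200": 20, "test_33": 8}
N_ITERATIONS = 100_000
SEED = 101


def main() -> None:
    design = StudyDesign()
    trials = reconstruct_reported_counts(design, REPORTED_COUNTS, seed=SEED)
    reference = fit_control_reference(trials)
    adapted = set(design.adapted_labels)

    rows = []
    (RESULTS / "figures").mkdir(parents=True, exist_ok=True)
    for cond, observed in REPORTED_COUNTS.items():
        other = [v for k, v in REPORTED_COUNTS.items() if k != cond][0]
        sub = trials[(trials["condition"] == cond) & trials["probe_deg"].isin(adapted)]
        for unit in ("trial", "participant"):
            null = bootstrap_error_counts(
                sub, reference, n_iterations=N_ITERATIONS, unit=unit, seed=SEED
            )
            rows.append(
                {
                    "condition": cond,
                    "unit": unit,
                    "n_iterations": N_ITERATIONS,
                    "observed": null.observed_count,
                    "mean_count": null.mean_count,
                    "pct5": null.pct5,
                    "pct95": null.pct95,
                    "p_exact_other": null.p_exact(other),
                    "p_le_other": null.p_le(other),
                    "p_ge_other": null.p_ge(other),
                }
            )
            if unit == "trial":
                ax = plot_count_null(
                    null,
                    title=f"{cond}: bootstrap of {null.observed_count}/240 errors",
                    marks={"other condition": other},
                )
                fig_path = RESULTS / "figures" / f"count_null_{cond}.png"
                ax.figure.savefig(fig_path, dpi=150, bbox_inches="tight")
                plt.close(ax.figure)

    table = pd.DataFrame(rows)
    out = RESULTS / "bootstrap_counts.csv"
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    trial_rows = table[table["unit"] == "trial"].set_index("condition")
    print(
        f"\nbootstrap means reproduce the observed counts: "
        f"{trial_rows.at['test_200', 'mean_count']:.2f} ~ 20 (200 ms), "
        f"{trial_rows.at['test_33', 'mean_count']:.2f} ~ 8 (33 ms). "
        "Tail probabilities differ between trial and participant units because "
        "errors cluster within observers."
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
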