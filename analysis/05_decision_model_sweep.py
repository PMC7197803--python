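#!/usr/bin/env python
"""Illusion-rate sweep of the toy predictive-coding competition model.

Estimates the probability of reporting the removed (orthogonal) orientation
as a function of superposition duration, at the calibrated defaults.
Writes the sweep CSV and a rate-vs-duration figure under results/.
"""

from pathlib import Path

import matplotlib.pyplot as plt

from orthillusion import DecisionModelParams, rate_sweep

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 7
DURATIONS = [10, 33, 66, 100, 150, 200, 300, 500]


def main() -> None:
    params = DecisionModelParams()
    sweep = rate_sweep(DURATIONS, params, n_trials=200_000, seed=SEED)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "decision_model_sweep.csv"
    sweep.to_csv(out, index=False)
    print(sweep.to_string(index=False))

    at33 = sweep.set_index("duration_ms").at[33.0, "illusion_rate"]
    at200 = sweep.set_index("duration_ms").at[200.0, "illusion_rate"]
    print(
        f"\nillusion rate grows with switch time: {100 * at33:.1f}% at 33 ms vs "
        f"{100 * at200:.1f}% at 200 ms (observed: 3.3% and 8.3%) -- the "
        "orientation-tuned off response needs time to build up while the "
        "sustained representation adapts."
    )

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.errorbar(sweep["duration_ms"], sweep["illusion_rate"], yerr=sweep["se"],
                marker="o", capsize=3, color="crimson")
    for d, r in ((33, 0.033), (200, 0.083)):
        ax.plot(d, r, marker="s", color="k", ls="none")
    ax.set_xlabel("superposition duration (ms)")
    ax.set_ylabel("P(illusory orthogonal report)")
    ax.set_title("competition model (squares: observed rates)")
    fig_path = RESULTS / "figures" / "decision_model_sweep.png"
    fig_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(fig_path, dpi=150, bbox_inches="tight")
    print(f"wrote {out} and {fig_path}")


if __name__ == "__main__":
    main()
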