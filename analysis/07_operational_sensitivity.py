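"""Operational sensitivity analysis.

Maps the ICER versus TAU and the probability of cost-effectiveness at
λ = £20 000/QALY over the elicited plausible ranges of machine
throughput, sessions per course and minutes per session. Efficacy is
held fixed, so the surfaces vary only through the per-course
intervention cost; all cells share the base run's Monte Carlo draws.
"""

import argparse
from pathlib import Path

import numpy as np

from tmscea.bundle import make_base_case_bundle
from tmscea.psa import run_psa
from tmscea.report import write_csv
from tmscea.scenarios import operational_grid, throughput_crossing

OUT = Path(__file__).resolve().parents[1] / "results" / "osa"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-sims", type=int, default=2000)
    args = parser.parse_args()

    bundle = make_base_case_bundle()
    base = run_psa(bundle.spec, n_sims=args.n_sims, seed=args.seed)

    grid = operational_grid(
        bundle,
        throughputs=np.arange(5.0, 61.0, 5.0),
        sessions=np.array([20.0, 27.0, 30.0]),
        minutes=np.array([15.0, 30.0, 45.0, 60.0]),
        lam=20_000.0,
        base_result=base,
    )
    write_csv(grid.table, OUT / "operational_grid.csv")

    fine = operational_grid(
        bundle, np.arange(5.0, 44.0, 1.0), np.array([27.0]),
        np.array([30.0]), lam=20_000.0, base_result=base,
    )
    for arm in ("rtms", "itbs"):
        crossing = throughput_crossing(fine, arm, 30_000.0)
        print(f"{arm}: ICER vs TAU exceeds £30 000/QALY below "
              f"~{crossing:.0f} patients/year")

    t = grid.table
    best = t[(t.throughput == 60.0) & (t.sessions == 20.0) & (t.minutes == 15.0)]
    worst = t[(t.throughput == 5.0) & (t.sessions == 30.0) & (t.minutes == 60.0)]
    print(f"P(cost-effective at £20k), rTMS: "
          f"{100 * best['p_ce_rtms'].iloc[0]:.0f}% with high throughput and "
          f"prompt delivery vs {100 * worst['p_ce_rtms'].iloc[0]:.0f}% with "
          f"low throughput and prolonged delivery")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
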