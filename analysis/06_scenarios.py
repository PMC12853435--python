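"""Scenario analyses.

Reruns the probabilistic analysis under each named scenario —
maintenance best/worst cases, single-expert optimistic/pessimistic
maintenance, no mortality, alternative trial sources for utilities and
costs, the enhanced-care TAU trajectory, trial-observed delivery costs,
and the 16-26-week productivity/care window — and tabulates the pairwise
ICERs versus TAU.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tmscea.bundle import make_base_case_bundle
from tmscea.scenarios import SCENARIO_NAMES, run_scenario

OUT = Path(__file__).resolve().parents[1] / "results" / "scenarios"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-sims", type=int, default=2000)
    parser.add_argument("--name", choices=SCENARIO_NAMES, default=None,
                        help="run a single scenario instead of all")
    args = parser.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    bundle = make_base_case_bundle()
    names = [args.name] if args.name else list(SCENARIO_NAMES)
    rows = []
    for name in names:
        tbl, _ = run_scenario(name, bundle, n_sims=args.n_sims, seed=args.seed)
        pw = tbl[tbl["block"] == "pairwise"].set_index("arm")
        row = {"scenario": name}
        for arm in ("rtms", "itbs"):
            row[f"icer_{arm}"] = pw.loc[arm, "icer"]
            row[f"status_{arm}"] = pw.loc[arm, "status"]
        rows.append(row)
        print(f"{name:28s} rTMS {pw.loc['rtms', 'status']:>9s} "
              f"ICER {pw.loc['rtms', 'icer']:>9.0f}   "
              f"iTBS ICER {pw.loc['itbs', 'icer']:>9.0f}")
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "scenario_icers.csv", index=False, float_format="%.1f")
    below_30k = np.nanmax(frame[["icer_rtms", "icer_itbs"]].to_numpy())
    print(f"\nhighest scenario ICER: £{below_30k:.0f}/QALY")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
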