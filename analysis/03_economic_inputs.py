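"""Estimate state-attached economic inputs and the intervention costs.

Health-state costs: GEE panel regression (exchangeable working
correlation) on the specialist-care trial's per-cycle-scaled costs.
Utilities: OLS panel regression on the TMS trial's cross-walked EQ-5D-3L
scores. Productivity (human capital) and informal-care hours: stratified
means over the 0-16-week window. Intervention course costs: annuitised
equipment over throughput plus staff, training and imaging components.
"""

from pathlib import Path

import pandas as pd

import tmscea.econ as econ
from tmscea.bundle import default_intervention_costs, per_cycle_econ
from tmscea.econ import course_cost

DATA = Path(__file__).resolve().parents[1] / "results" / "trial_data"
OUT = Path(__file__).resolve().parents[1] / "results" / "economic_inputs"


def merged(*names: str) -> pd.DataFrame:
    frames = []
    for k, name in enumerate(names):
        df = pd.read_csv(DATA / f"econ_{name}.csv")
        frames.append(df.assign(subject_id=df["subject_id"] + 10_000 * k))
    return per_cycle_econ(pd.concat(frames, ignore_index=True))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    econ_bm = merged("rtms", "itbs")
    econ_smd = merged("tau", "sds")

    cost_est = econ.fit_state_costs(econ_smd)
    util_est = econ.fit_state_utilities(econ_bm)
    prod_est = econ.state_productivity(econ_bm, daily_earnings=120.0,
                                       window=(0.0, 16.0),
                                       employed_fraction=0.55)
    care_est = econ.state_informal_care(econ_bm, window=(0.0, 16.0))

    for name, est in (("state_costs_per_cycle", cost_est),
                      ("state_utilities", util_est),
                      ("state_productivity_per_cycle", prod_est),
                      ("state_informal_care_per_cycle", care_est)):
        est.to_frame().to_csv(OUT / f"{name}.csv", float_format="%.4f")
        print(f"{name}:")
        print(est.to_frame().round(3).to_string(), "\n")

    rows = []
    for arm, inputs in default_intervention_costs().items():
        rows.append({"arm": arm, "course_cost_gbp": round(course_cost(inputs), 2)})
        print(f"course cost {arm}: £{course_cost(inputs):.0f}")
    pd.DataFrame(rows).to_csv(OUT / "course_costs.csv", index=False)
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
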