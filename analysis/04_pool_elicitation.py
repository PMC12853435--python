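"""Pool the expert elicitation and fit the maintenance-of-effect curve.

Reconstructs each expert's judgment as a piecewise-linear CDF, pools
with equal weights, summarises between-expert spread, and fits the
Weibull retained-effect curve to the pooled medians of the 12- and
18-month retained fractions (anchored at 1 at 26 weeks).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tmscea.bundle import make_base_case_bundle
from tmscea.elicitation import (
    between_expert_spread,
    judgements_from_frame,
    linear_pool,
)
from tmscea.transitions import fit_weibull_maintenance

OUT = Path(__file__).resolve().parents[1] / "results" / "elicitation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = make_base_case_bundle()
    judgements = judgements_from_frame(bundle.expert_frame, bundle.expert_bounds)

    rows = []
    for quantity, js in sorted(judgements.items()):
        pool = linear_pool(js)
        spread = between_expert_spread(js)
        rows.append({
            "quantity": quantity, "n_experts": len(js),
            "pooled_median": pool.median, "pooled_mean": pool.mean,
            "pooled_sd": np.sqrt(pool.variance),
            "between_expert_sd": np.sqrt(spread["between_expert_variance"]),
            "most_optimistic": spread["most_optimistic"],
            "most_pessimistic": spread["most_pessimistic"],
        })
        print(f"{quantity}: {len(js)} experts, pooled median "
              f"{pool.median:.3g} (sd {np.sqrt(pool.variance):.3g})")
    pd.DataFrame(rows).to_csv(OUT / "pooled_summary.csv", index=False,
                              float_format="%.4f")

    p52 = linear_pool(judgements["retained_12m"])
    p78 = linear_pool(judgements["retained_18m"])
    maint = fit_weibull_maintenance([(52.0, p52.median), (78.0, p78.median)])
    print(f"maintenance Weibull: shape {maint.shape:.3f}, "
          f"scale {maint.scale_weeks:.1f} weeks; "
          f"retained at 12m {maint.weight(52.0):.2f}, "
          f"at 18m {maint.weight(78.0):.2f}")
    t = np.arange(26.0, 80.0, 2.0)
    pd.DataFrame({"weeks": t, "retained": np.asarray(maint.weight(t))}).to_csv(
        OUT / "maintenance_curve.csv", index=False, float_format="%.4f"
    )
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
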