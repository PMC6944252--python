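"""Bootstrap uncertainty: cost-effectiveness plane, CEAC and NMB.

1,000 stratified bootstrap resamples of the unadjusted complete-case data.
Writes ``results/bootstrap_cloud.csv``, ``results/ceac.csv`` and
``results/ce_plane.png``; prints the probability that the oral strategy is
cost saving and the probability it yields higher QALYs.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

import pandas as pd  # noqa: E402

from oviva_cea import reference  # noqa: E402
from oviva_cea.inference import bootstrap_ce, ceac_nmb  # noqa: E402
from oviva_cea.inference import assemble_analysis_frame  # noqa: E402
from oviva_cea.pipeline import DEFAULT_CEAC_THRESHOLDS, _complete_case_qalys  # noqa: E402
from oviva_cea.pipeline import render_ce_plane  # noqa: E402


def main():
    data = common.trial()
    frame = assemble_analysis_frame(data)
    cc = frame.dropna(subset=[f"u_{d}" for d in reference.VISIT_DAYS]
                      + ["total_cost"]).copy()
    cc["total_qaly"] = _complete_case_qalys(cc, "death_day")
    cloud = bootstrap_ce(cc, B=1000, seed=common.SEED)
    pd.DataFrame({"delta_qaly": cloud.delta_qaly,
                  "delta_cost": cloud.delta_cost}
                 ).to_csv(common.RESULTS / "bootstrap_cloud.csv", index=False)
    ceac = ceac_nmb(cloud, DEFAULT_CEAC_THRESHOLDS)
    ceac.to_csv(common.RESULTS / "ceac.csv", index=False)
    render_ce_plane(cloud, 30_000.0, common.RESULTS / "ce_plane.png")

    print(f"complete cases bootstrapped: {len(cc)}")
    print(f"p(oral cost saving)  = {cloud.p_cost_saving:.3f}")
    print(f"p(oral QALY gain)    = {cloud.p_qaly_gain:.3f}")
    print("quadrant shares:", {k: round(v, 3)
                               for k, v in cloud.quadrants.items()})
    at30k = ceac.loc[ceac["threshold"] == 30_000.0].iloc[0]
    print(f"p(oral cost-effective at £30,000/QALY) = "
          f"{at30k['p_oral_cost_effective']:.3f}")
    print(f"figure: {common.RESULTS / 'ce_plane.png'}")


if __name__ == "__main__":
    main()
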