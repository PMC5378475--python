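"""Generate the synthetic lifespan cohorts used by the survival analysis.

Emulates the grouped-male lifespan design: solitary males (n=40, mean
lifespan 12.0 d, SE 0.4) versus eight grouped males per plate (n=80, mean
7.7 d, SE 0.2). Gompertz hazards are calibrated so that both the group means
and the legend SEs are reproduced in expectation; records go to
results/cohorts.csv.

Run:  python analysis/01_simulate_cohorts.py [seed]
"""

import sys
from pathlib import Path

import numpy as np

from androdyn.io import write_survival_csv
from androdyn.synthetic import CohortSpec, calibrate_hazard, gen_survival_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")

# (group, n, target mean [d], Gompertz aging rate [1/d] matching legend SE)
COHORTS = [
    ("solitary_males", 40, 12.0, 0.5),
    ("grouped_males_8", 80, 7.7, 0.7),
]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    records = []
    for group, n, target, aging in COHORTS:
        hazard = calibrate_hazard(target, aging)
        cohort = gen_survival_cohort(CohortSpec(
            group_label=group, n=n, hazard=hazard,
            seed=int(rng.integers(0, 2**31 - 1))))
        days = [r.day for r in cohort]
        print(f"{group}: n={n}, target mean {target:.1f} d -> "
              f"sampled mean {np.mean(days):.2f} d "
              f"(hazard a={hazard.baseline_rate:.4g}/d, b={aging}/d)")
        records.extend(cohort)
    write_survival_csv(records, OUT / "cohorts.csv")
    print(f"wrote {len(records)} records to {OUT / 'cohorts.csv'}")


if __name__ == "__main__":
    main()
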