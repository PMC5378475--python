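"""Chemotaxis-index analysis on simulated plate assays.

Simulates two plate groups in the published design (12 plates, ~15 worms
placed per plate): males offered female supernatant versus buffer-only
control spots, aggregates the chemotaxis index as mean ± SEM over plates,
and compares the groups by unpaired t test and by exact label permutation.
Writes results/chemotaxis.json.

Run:  python analysis/05_chemotaxis.py [seed]
"""

import json
import sys
from pathlib import Path

import numpy as np

from androdyn.chemotaxis import aggregate_ci, compare_ci
from androdyn.synthetic import gen_chemotaxis_plate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")
N_PLATES = 12
N_WORMS = 15

# destination probabilities: attracted group vs symmetric null group
GROUPS = {
    "female_supernatant": dict(p_super=0.55, p_ctrl=0.15, p_origin=0.2),
    "buffer_only": dict(p_super=0.35, p_ctrl=0.35, p_origin=0.2),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    plates = {name: [gen_chemotaxis_plate(N_WORMS, seed=int(s), **p)
                     for s in rng.integers(0, 2**31 - 1, N_PLATES)]
              for name, p in GROUPS.items()}
    result = {"ci": {}}
    for name, group_plates in plates.items():
        res = aggregate_ci(group_plates)
        result["ci"][name] = {"mean": res.mean_ci, "sem": res.sem,
                              "n_plates": res.n_plates}
        print(f"{name}: CI = {res.mean_ci:.2f} ± {res.sem:.2f} "
              f"(mean ± SEM, n = {res.n_plates} plates)")
    p_t = compare_ci(plates["female_supernatant"], plates["buffer_only"],
                     method="t")
    p_perm = compare_ci(plates["female_supernatant"], plates["buffer_only"],
                        method="permutation", seed=SEED)
    result["comparison"] = {"t_p_value": p_t, "permutation_p_value": p_perm}
    print(f"unpaired t test p = {p_t:.4g}; permutation p = {p_perm:.4g}")
    (OUT / "chemotaxis.json").write_text(json.dumps(result, indent=2) + "\n")
    print(f"wrote {OUT / 'chemotaxis.json'}")


if __name__ == "__main__":
    main()
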