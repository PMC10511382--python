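#!/usr/bin/env python
"""Compare patients and controls on attention and questionnaire measures.

Reads results/cohort.csv (run 01_simulate_cohort.py first), applies
one-tailed Wilcoxon rank-sum tests with effect sizes r and BH-FDR, plus
bootstrapped kernel-density non-overlap for the attention parameters, and
writes results/group_tests.json.
"""

import json
from pathlib import Path

import numpy as np

from tva_arousal.io import read_cohort
from tva_arousal.stats_pipeline import (
    GROUP_TEST_DIRECTIONS,
    bh_fdr,
    distribution_nonoverlap,
    wilcoxon_rank_sum,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 4


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    pat = cohort[cohort["group"] == "patient"]
    con = cohort[cohort["group"] == "control"]
    tests = {}
    for var, direction in GROUP_TEST_DIRECTIONS.items():
        res = wilcoxon_rank_sum(
            con[var], pat[var],
            alternative="greater" if direction == "lower" else "less",
        )
        tests[var] = {"W": res.W, "z": round(res.z, 2), "r": round(res.r, 2),
                      "p": res.p, "patients": direction}
    adj, rej = bh_fdr([t["p"] for t in tests.values()])
    for (var, t), a, s in zip(tests.items(), adj, rej):
        t["p_fdr"] = float(a)
        t["significant"] = bool(s)
        print(f"{var:>15}: W={t['W']:7.1f} z={t['z']:6.2f} r={t['r']:.2f} "
              f"p_fdr={t['p_fdr']:.4f} {'*' if s else ''}")
    rng = np.random.default_rng(SEED)
    nonoverlap = {
        v: round(distribution_nonoverlap(
            con[v], pat[v], n_boot=1000, seed=int(rng.integers(0, 2**31 - 1))
        )["nonoverlap"], 3)
        for v in ("C", "K", "t0")
    }
    print("distribution non-overlap:", nonoverlap)
    (OUT / "group_tests.json").write_text(
        json.dumps({"tests": tests, "nonoverlap": nonoverlap}, indent=2) + "\n"
    )
    print(f"wrote {OUT / 'group_tests.json'}")


if __name__ == "__main__":
    main()
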