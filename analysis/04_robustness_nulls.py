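#!/usr/bin/env python
"""Run the random-signature and shuffled-label null batteries.

Two synthetic worlds are contrasted at 100 replicates each:

* signal — subtype labels drive a planted 50-gene signature; random
  size-matched gene sets can only pick up the purity gradient.
* confounded — no subtype effect; "subtypes" are contamination bins.

Reported per world: median CV accuracy per setting (real signature,
random signatures, shuffled labels), the real-minus-random median gap,
and the |SSMD| separating real-vs-random from random-vs-random
clustering ARIs. Outputs under results/robustness/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from sigrobust.scenarios import (
    confounded_scenario_config,
    run_robustness_scenario,
    signal_scenario_config,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "robustness"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--reps", type=int, default=100)
    parser.add_argument("--seed", type=int, default=20)
    args = parser.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for world, cfg in (("signal", signal_scenario_config(args.seed)),
                       ("confounded", confounded_scenario_config(args.seed))):
        res = run_robustness_scenario(cfg, n_reps=args.reps, seed=args.seed)
        pd.DataFrame(res["accuracy"]).to_csv(OUT / f"{world}_accuracy_null.tsv",
                                             sep="\t", index=False)
        pd.DataFrame({"ari_real_vs_random": res["ari_real_vs_random"]}).to_csv(
            OUT / f"{world}_ari_real_vs_random.tsv", sep="\t", index=False)
        pd.DataFrame({"ari_pairwise_random": res["ari_pairwise_random"]}).to_csv(
            OUT / f"{world}_ari_pairwise_random.tsv", sep="\t", index=False)
        summary[world] = {
            "accuracy_median": res["accuracy_median"],
            "real_minus_random_gap": res["real_minus_random_gap"],
            "majority_rate": res["majority_rate"],
            "clustering_ssmd_abs": abs(res["clustering_ssmd"]),
        }
        med = res["accuracy_median"]
        print(f"[{world}] real={med['real']:.3f} random={med['random_signature']:.3f} "
              f"shuffled={med['shuffled_labels']:.3f} gap={res['real_minus_random_gap']:+.3f} "
              f"clustering |SSMD|={abs(res['clustering_ssmd']):.2f}")
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print("A large gap and |SSMD| in the signal world, and their collapse in the "
          "confounded world, is the expected dichotomy: accuracy alone cannot "
          "certify that a signature measures subtype biology.")


if __name__ == "__main__":
    main()
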