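"""Calibration and recovery summary at reduced problem sizes.

Runs the null-calibration experiments (type-I error of the Bonferroni
route, realized SAM false-call rate at the delta targeting FDR 0.05) and a
small planted-recovery experiment, then writes results/evaluation.json.
The full-scale versions of these experiments (2000 genes, 100 null seeds,
20 recovery seeds) are what scripts/acceptance.py recomputes.
"""

import json
from pathlib import Path

from voxscreen.evaluation import (
    bonferroni_null_fraction,
    recovery_experiment,
    sam_null_false_call_fraction,
)
from voxscreen.synthetic_atlas import AtlasConfig

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}

    frac, n = bonferroni_null_fraction(n_genes=1000, seed=0)
    summary["bonferroni_null_significant_fraction"] = {"value": frac, "n": n}
    print(f"Bonferroni-significant fraction on {n} null genes: {frac:.4f}")

    fc, total = sam_null_false_call_fraction(n_seeds=20, n_genes=1000, seed=0)
    summary["sam_null_false_call_fraction"] = {"value": fc, "n": total}
    print(f"SAM false-call fraction at FDR target 0.05 ({total} null genes): {fc:.5f}")

    rec = recovery_experiment(
        n_seeds=5,
        atlas=AtlasConfig(grid_shape=(21, 10, 9), n_genes=300, n_posterior=8, n_anterior=8),
        seed=0,
    )
    summary["recovery"] = {
        "union_recovery": rec.union_recovery,
        "sensitivity": rec.sensitivity,
        "false_discovery_proportion": rec.false_discovery_proportion,
        "direction_agreement": rec.direction_agreement,
        "n_planted": rec.n_planted,
    }
    print(
        f"recovery over {rec.n_seeds} planted atlases: "
        f"union recovery {rec.union_recovery:.3f}, sensitivity {rec.sensitivity:.3f}, "
        f"FDP {rec.false_discovery_proportion:.3f}"
    )

    (OUT / "evaluation.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    print(f"summary written to {OUT / 'evaluation.json'}")


if __name__ == "__main__":
    main()
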