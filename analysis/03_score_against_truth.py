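"""Score the demo screen's candidates against the planted ground truth.

Joins results/demo/candidates.tsv with results/demo/truth.tsv and reports
sensitivity, false-discovery proportion and direction agreement of the
final candidate list, writing the merged table to results/demo/scored.tsv.
"""

from pathlib import Path

import pandas as pd

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"


def main() -> None:
    candidates = pd.read_csv(OUT / "candidates.tsv", sep="\t")
    # keep_default_na: the literal direction "null" must not become NaN
    truth = pd.read_csv(OUT / "truth.tsv", sep="\t", keep_default_na=False)
    merged = candidates.merge(truth[["gene_id", "direction"]], on="gene_id", how="left")
    merged["true_positive"] = merged["direction"] != "null"
    merged["direction_correct"] = merged["region"] == merged["direction"]
    merged.to_csv(OUT / "scored.tsv", sep="\t", index=False)

    n_planted = int((truth["direction"] != "null").sum())
    tp = int(merged["true_positive"].sum())
    sens = tp / n_planted if n_planted else float("nan")
    fdp = 1 - tp / len(merged) if len(merged) else 0.0
    agree = merged.loc[merged["true_positive"], "direction_correct"].mean()
    print(f"{len(merged)} candidates; {tp}/{n_planted} planted genes recovered")
    print(f"sensitivity = {sens:.3f}, false-discovery proportion = {fdp:.3f}")
    print(f"direction agreement among true positives = {agree:.3f}")
    print(f"scored table written to {OUT / 'scored.tsv'}")


if __name__ == "__main__":
    main()
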