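#!/usr/bin/env python
"""Score the proteome screen against the generator's ground truth.

Joins the strict-setting report from 03_mr_screen.py with the truth table and
reports empirical FDR among significant calls, power over truly causal
proteins, and precision/recall of the full causal-evidence call (significant
AND Steiger-correct AND colocalized). Also verifies the causal-evidence
conjunction row by row.
"""

from pathlib import Path

import pandas as pd

from protmr import evaluate_against_truth

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    results = pd.read_csv(OUT / "screen_strict" / "results.tsv", sep="\t")
    truth = pd.read_csv(OUT / "benchmark_truth.tsv", sep="\t")
    metrics = evaluate_against_truth(results, truth)
    implied = ((results["tier"] == "significant")
               & (results["steiger_direction"] == "correct")
               & results["colocalized"])
    assert (results["causal_evidence"] == implied).all(), "conjunction violated"
    df = pd.DataFrame(sorted(metrics.items()), columns=["metric", "value"])
    df.to_csv(OUT / "benchmark_evaluation.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\nevaluation -> {OUT / 'benchmark_evaluation.tsv'}")


if __name__ == "__main__":
    main()
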