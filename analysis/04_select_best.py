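"""Apply the model-selection rule to the sweep grid and report the winner.

Selection is lexicographic over the grid: highest pooled accuracy, then
highest sensitivity (a screening tool should not miss fallers), then the
smallest feature count N, then the fewest hidden units, then the smallest
K. Writes results/best_model.json.

Usage: python analysis/04_select_best.py [--grid results/grid.csv]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gaitfall.classify_eval import ConfusionMatrix, EvaluationReport, model_select
from gaitfall.io import write_best_report


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--grid", type=Path, default=Path("results/grid.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/best_model.json"))
    args = parser.parse_args()

    df = pd.read_csv(args.grid)
    reports = [
        EvaluationReport(
            cm=ConfusionMatrix(int(r.TP), int(r.FN), int(r.FP), int(r.TN)),
            accuracy=r.accuracy,
            sensitivity=r.sensitivity,
            specificity=r.specificity,
            auc=r.AUC,
            hidden_units=int(r.hidden_units),
            K=int(r.K),
            N=int(r.N),
        )
        for r in df.itertuples()
    ]
    best = model_select(reports)
    write_best_report(best, args.out)
    print(
        f"best configuration: K={best.K}, N={best.N}, "
        f"hidden={best.hidden_units}"
    )
    print(
        f"pooled 10-fold CV: accuracy {best.accuracy:.3f}, "
        f"sensitivity {best.sensitivity:.3f}, "
        f"specificity {best.specificity:.3f}, AUC {best.auc:.3f}"
    )
    print(f"confusion counts: TP={best.cm.tp} FN={best.cm.fn} FP={best.cm.fp} TN={best.cm.tn}")
    print(f"wrote {args.out}")
    print(json.dumps(best.as_row()))


if __name__ == "__main__":
    main()
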