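"""Run the ReliefF x MLP selection sweep over (K, N) and write the grid.

For each neighbor count K the features are re-weighted with ReliefF; for
each subset size N the top-N features are evaluated with a
single-hidden-layer MLP under stratified 10-fold cross-validation. Each
grid row records the pooled confusion counts and derived metrics, mirroring
the study's results-table layout.

The default hidden sweep here is the single size 50 (the full 10..200
sweep multiplies runtime by 20; pass --hidden 10:200:10 for it).

Usage: python analysis/03_selection_sweep.py [--features results/features.csv]
"""

import argparse
from pathlib import Path

from gaitfall.classify_eval import make_mlp_eval_fn
from gaitfall.cli import _parse_range
from gaitfall.feature_table import read_feature_table
from gaitfall.io import write_grid_csv
from gaitfall.relieff import SelectionSweepConfig, selection_sweep


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--features", type=Path, default=Path("results/features.csv"))
    parser.add_argument("--k-range", default="1:40")
    parser.add_argument("--n-range", default="5:40")
    parser.add_argument("--hidden", default="50")
    parser.add_argument("--folds", type=int, default=10)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/grid.csv"))
    args = parser.parse_args()

    matrix = read_feature_table(args.features)
    eval_fn = make_mlp_eval_fn(
        matrix,
        hidden_sweep=_parse_range(args.hidden),
        n_folds=args.folds,
        seed=args.seed,
    )
    cfg = SelectionSweepConfig(_parse_range(args.k_range), _parse_range(args.n_range))
    sweep = selection_sweep(matrix, cfg, eval_fn)
    write_grid_csv(sweep, args.out)
    print(
        f"{sweep.n_weightings} ReliefF weightings, "
        f"{sweep.n_cells} grid cells ({len(sweep.skipped)} skipped: "
        "K too large for a class)"
    )
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
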