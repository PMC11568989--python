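"""Extract the 168 gait features for every subject in the cohort.

Reads the manifest written by 01_simulate_cohort.py, runs preprocessing,
step detection and all feature blocks per subject, and writes the labeled
feature table to results/features.csv. Prints the class contrast on step
regularity — the quantity the faller/non-faller distinction rests on.

Usage: python analysis/02_extract_features.py [--manifest results/cohort/manifest.yaml]
"""

import argparse
from pathlib import Path

from gaitfall.feature_table import build_matrix, write_feature_table
from gaitfall.io import load_cohort


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument(
        "--manifest", type=Path, default=Path("results/cohort/manifest.yaml")
    )
    parser.add_argument("--out", type=Path, default=Path("results/features.csv"))
    args = parser.parse_args()

    matrix = build_matrix(load_cohort(args.manifest))
    write_feature_table(matrix, args.out)
    print(f"feature table: {matrix.X.shape[0]} subjects x {matrix.X.shape[1]} features")
    if matrix.exclusions:
        for sid, reason in matrix.exclusions:
            print(f"  excluded {sid}: {reason}")
    y = matrix.y()
    for name in ("StpReg_V", "StrReg_V", "cv_peak_V"):
        f = matrix.X[name]
        print(
            f"  {name}: fallers {f[y == 1].mean():.3f} "
            f"vs non-fallers {f[y == 0].mean():.3f}"
        )
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
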