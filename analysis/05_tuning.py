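"""Orientation selectivity and tuning width for every unit class.

Single-cell response classes (tuned / unspecific / interstim / untuned),
1 - CirVar selectivity with Hotelling significance, and bounded Gaussian
tuning-curve fits for ensembles, member groups, and single neurons.

    python analysis/05_tuning.py [--seed N]
"""

import argparse

import pandas as pd

from offsemble.config import PipelineConfig
from offsemble.pipeline import stage_tune


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--outdir", default="results/session")
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, outdir=args.outdir)
    out = stage_tune(cfg)
    tuning = pd.read_csv(out / "tuning.csv")
    classes = pd.read_csv(out / "cell_classes.csv")
    print("single-cell classes:")
    print(classes["cls"].value_counts().to_string())
    print("\nunit-group selectivity (significant units):")
    sig = tuning[tuning.significant]
    print(
        sig.groupby("unit_kind")[["osi", "sigma_deg"]]
        .mean()
        .round(3)
        .to_string()
    )


if __name__ == "__main__":
    main()
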