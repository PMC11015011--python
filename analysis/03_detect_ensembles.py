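"""Detect neuronal ensembles in the raster, with no stimulus information.

Functional-network filtering, Jaccard/Ward clustering of population vectors,
contrast-index selection of the cluster count, and the surrogate z-test.

    python analysis/03_detect_ensembles.py [--seed N]
"""

import argparse
import json

import pandas as pd

from offsemble.config import PipelineConfig
from offsemble.pipeline import stage_detect


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--outdir", default="results/session")
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, outdir=args.outdir)
    out = stage_detect(cfg)
    labels = pd.read_csv(out / "frame_labels.csv")
    pvals = json.loads((out / "ensemble_pvalues.json").read_text())
    n_sig = labels.loc[labels.is_ensemble, "cluster"].nunique()
    print(f"k* = {labels.cluster.max()} clusters; {n_sig} significant ensembles")
    for c, p in sorted(pvals.items(), key=lambda kv: int(kv[0])):
        print(f"  cluster {c}: p = {p:.3g}")


if __name__ == "__main__":
    main()
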