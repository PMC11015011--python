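"""Decode stimulus orientation from ensembles and from neuron quadruples.

Informedness-optimal thresholds, per-trial voting, 4x4 confusion matrices,
and the accuracy comparison between ensemble signals and randomly assembled
sets of four tuned neurons.

    python analysis/06_decoding.py [--seed N]
"""

import argparse
import json

from offsemble.config import PipelineConfig
from offsemble.pipeline import stage_decode


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--outdir", default="results/session")
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, outdir=args.outdir)
    out = stage_decode(cfg)
    summary = json.loads((out / "decode_summary.json").read_text())
    for key, value in summary.items():
        print(f"{key}: {value}")


if __name__ == "__main__":
    main()
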