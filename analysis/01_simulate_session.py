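"""Generate one synthetic imaging session and write its artifacts.

Produces the stimulus schedule (8 drifting-grating directions, 2 s each,
1-5 s blanks, >= 6 repetitions in 5 min), a planted population with
onsemble/offsemble structure, ground-truth spikes, GCaMP6s-like fluorescence,
and behavior traces, under results/session/.

    python analysis/01_simulate_session.py [--seed N] [--neurons N]
"""

import argparse

from offsemble.config import PipelineConfig
from offsemble.pipeline import stage_simulate


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--neurons", type=int, default=200)
    ap.add_argument("--outdir", default="results/session")
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, outdir=args.outdir,
                         population={"n_neurons": args.neurons})
    out = stage_simulate(cfg)
    print(f"session written to {out}: traces.h5, schedule.csv, behavior.csv, "
          f"ground_truth.json, true_raster.csv")


if __name__ == "__main__":
    main()
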