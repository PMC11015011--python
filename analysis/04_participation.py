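"""Classify onsemble / offsemble / nonparticipant neurons per ensemble.

Computes the Ensemble Participation Index for every (neuron, ensemble) pair,
tests it with the epoch t-test, and summarizes member counts and mean EPIs —
plus the still-vs-running EPI comparison using the behavior trace.

    python analysis/04_participation.py [--seed N]
"""

import argparse

import numpy as np
import pandas as pd

from offsemble import io as oio
from offsemble.config import PipelineConfig
from offsemble.participation import epi_by_locomotion
from offsemble.pipeline import stage_participate


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--outdir", default="results/session")
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, outdir=args.outdir)
    out = stage_participate(cfg)
    part = pd.read_csv(out / "participation.csv")
    summary = (
        part.groupby(["ensemble_id", "class"])
        .agg(n=("neuron_id", "size"), mean_epi=("epi", "mean"))
        .round(3)
    )
    print(summary)

    raster = oio.load_raster_csv(out / "raster.csv")
    behavior = oio.load_behavior(out / "behavior.csv")
    sig = pd.read_csv(out / "ensemble_signals.csv").drop(columns=["frame"])
    rows = []
    for col in sig.columns:
        loco = epi_by_locomotion(raster, sig[col].to_numpy(np.uint8),
                                 behavior.speed_cm_s)
        members = part[part.ensemble_id == int(col)]
        for cls in ("onsemble", "offsemble"):
            ids = members.loc[members["class"] == cls, "neuron_id"]
            sub = loco[loco.neuron_id.isin(ids)]
            rows.append({"ensemble_id": int(col), "class": cls,
                         "epi_still": sub.epi_still.mean(),
                         "epi_running": sub.epi_running.mean()})
    loco_df = pd.DataFrame(rows)
    loco_df.to_csv(out / "epi_locomotion.csv", index=False)
    print("\nstill vs running EPI (mean per class):")
    print(loco_df.groupby("class")[["epi_still", "epi_running"]].mean().round(3))


if __name__ == "__main__":
    main()
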