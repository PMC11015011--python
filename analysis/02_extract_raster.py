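"""Turn the session's fluorescence into a QC-filtered binary raster.

Neuropil correction, PSNR-based ROI selection (> 10 dB), median-min-max
smoothing, AR(1) sparse deconvolution, and PSNR-proportional binarization.

    python analysis/02_extract_raster.py [--seed N]
"""

import argparse

import pandas as pd

from offsemble.config import PipelineConfig
from offsemble.pipeline import stage_preprocess


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--outdir", default="results/session")
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, outdir=args.outdir)
    out = stage_preprocess(cfg)
    qc = pd.read_csv(out / "qc.csv")
    print(f"{int(qc.passed.sum())}/{len(qc)} ROIs passed QC "
          f"(PSNR {qc.psnr_db.min():.1f}-{qc.psnr_db.max():.1f} dB); "
          f"raster written to {out/'raster.csv'}")


if __name__ == "__main__":
    main()
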