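#!/usr/bin/env python
"""Segment and quantify every site stack: boutons.csv and sites.csv.

Reads the manifest written by 01_simulate_study.py (or any manifest of real
stacks with the same columns), runs exposure normalization, DoG enhancement,
iterative size-gated segmentation, the four exclusion filters, and per-site
summarization.

    python analysis/02_process_stacks.py --manifest results/study/metadata.csv \
        --out results
"""

import argparse
import json
import os

import pandas as pd

from boutonquant.config import RunConfig
from boutonquant.image_io import metadata_from_row, read_stack
from boutonquant.pipeline import process_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--manifest", default="results/study/metadata.csv")
    ap.add_argument("--out", default="results")
    ap.add_argument("--deconvolve", action="store_true",
                    help="enable Richardson-Lucy restoration before DoG")
    args = ap.parse_args()

    cfg = RunConfig()
    cfg.preprocess.deconv.skip = not args.deconvolve
    frame = pd.read_csv(args.manifest)
    stacks = [(read_stack(row["stack_path"], row), metadata_from_row(row))
              for _, row in frame.iterrows()]
    boutons, sites, counts = process_study(stacks, cfg)
    os.makedirs(args.out, exist_ok=True)
    boutons.to_csv(os.path.join(args.out, "boutons.csv"), index=False)
    sites.to_csv(os.path.join(args.out, "sites.csv"), index=False)
    with open(os.path.join(args.out, "counts.json"), "w") as fh:
        json.dump(counts, fh, indent=2)
    surv = boutons.surviving.sum()
    print(f"processed {len(stacks)} sites: {len(boutons)} segmented boutons, "
          f"{surv} surviving after filters -> {args.out}/sites.csv")


if __name__ == "__main__":
    main()
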