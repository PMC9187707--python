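#!/usr/bin/env python
"""Simulate the factorial CB1R study and write stacks + metadata to disk.

Generates one four-channel TIFF stack per sampled site for the
primate-calibrated design (2 subjects x 3 regions x 6 sites per layer),
together with the metadata CSV the processing step consumes and the
generator's planted per-site truth.

    python analysis/01_simulate_study.py --seed 1 --out results/study
"""

import argparse
import os

from boutonquant.image_io import metadata_to_frame, write_stack
from boutonquant.stacks import CHANNEL_ROLES
from boutonquant.synthetic import generate_study, reference_primate_design


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/study")
    ap.add_argument("--dense", action="store_true",
                    help="larger fields with more boutons per site")
    args = ap.parse_args()

    design = reference_primate_design(dense=args.dense)
    stacks, truth = generate_study(design, args.seed)
    os.makedirs(args.out, exist_ok=True)
    metas, paths = [], []
    for stack, meta in stacks:
        path = os.path.join(args.out, f"{meta.site_id}.tif")
        write_stack(stack, path, roles=list(CHANNEL_ROLES))
        metas.append(meta)
        paths.append(path)
    frame = metadata_to_frame(metas, exposures=stacks[0][0].exposure_ms)
    frame["stack_path"] = paths
    frame.to_csv(os.path.join(args.out, "metadata.csv"), index=False)
    truth.site_table.to_csv(os.path.join(args.out, "ground_truth_sites.csv"),
                            index=False)
    n_puncta = sum(len(v) for v in truth.puncta.values())
    print(f"wrote {len(stacks)} site stacks ({n_puncta} planted puncta) "
          f"and metadata.csv to {args.out}")


if __name__ == "__main__":
    main()
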