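#!/usr/bin/env python
"""Mixed-model ANOVA of per-site CB1R means, with Bonferroni post-hocs.

Fits, per species, mean CB1R intensity ~ region * cell type with a random
subject intercept on the sites.csv produced by 02_process_stacks.py, then
decomposes a significant interaction into simple effects and pairwise
region contrasts.

    python analysis/03_fit_mixed_model.py --sites results/sites.csv --out results
"""

import argparse
import json
import os

import pandas as pd

from boutonquant.config import RunConfig
from boutonquant.pipeline import analyze_sites


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sites", default="results/sites.csv")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    sites = pd.read_csv(args.sites)
    anova, posthoc, report = analyze_sites(sites, RunConfig())
    os.makedirs(args.out, exist_ok=True)
    with open(os.path.join(args.out, "anova.json"), "w") as fh:
        json.dump(anova, fh, indent=2)
    posthoc.to_csv(os.path.join(args.out, "posthoc.csv"), index=False)
    with open(os.path.join(args.out, "report.txt"), "w") as fh:
        fh.write(report + "\n")
    print(report)


if __name__ == "__main__":
    main()
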