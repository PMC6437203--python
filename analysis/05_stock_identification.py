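#!/usr/bin/env python
"""Genetic stock identification of the mixture sample.

Estimates the mixture composition over the baseline sources by
conditional-ML EM, decomposes the standard errors into mixture-sampling and
baseline-sampling components, adds percentile bootstrap intervals, and (for
the synthetic dataset) compares everything against the generator's truth.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from seabream import gsi
from seabream.io import read_genepop


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--mixture", type=Path, default=Path("results/data/mixture.gen"))
    ap.add_argument("--baselines", type=Path,
                    default=Path("results/data/baselines.gen"))
    ap.add_argument("--sources", default="P1,P2",
                    help="Baseline populations used as candidate sources.")
    ap.add_argument("--n-boot", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sources = args.sources.split(",")
    base_table = read_genepop(args.baselines).subset(sources)
    mixture = read_genepop(args.mixture)
    baselines = gsi.BaselineSet.from_genotypes(base_table)

    est = gsi.em_estimate(mixture, baselines, seed=args.seed)
    est = gsi.baseline_aware_se(est, mixture, baselines, seed=args.seed)
    ci = gsi.bootstrap_ci(mixture, baselines, n_boot=args.n_boot, seed=args.seed)

    report = pd.DataFrame({
        "proportion": est.proportions,
        "se_total": est.se_total,
        "se_mixture": est.se_information,
        "se_baseline": est.se_baseline,
        "ci_lower": ci["lower"],
        "ci_upper": ci["upper"],
    }).rename_axis("source")
    report.to_csv(args.outdir / "gsi_estimates.csv")
    gsi.assign_individuals(est).to_csv(args.outdir / "gsi_posteriors.csv")

    print(f"mixture of {est.n_mixture} fish over sources {sources} "
          f"({est.n_iterations} EM iterations, logL {est.log_likelihood:.1f})")
    truth_file = args.mixture.parent / "mixture_truth.json"
    truth = (json.loads(truth_file.read_text())["proportions"]
             if truth_file.exists() else {})
    for src in est.proportions.index:
        line = (f"  {src}: {100 * est.proportions[src]:.1f} "
                f"+/- {100 * est.se_total[src]:.1f}% "
                f"(95% CI {100 * ci.loc[src, 'lower']:.1f}-"
                f"{100 * ci.loc[src, 'upper']:.1f}%)")
        if src in truth:
            line += f"  [truth {100 * truth[src]:.1f}%]"
        print(line)


if __name__ == "__main__":
    main()
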