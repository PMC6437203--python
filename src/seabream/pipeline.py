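"""End-to-end orchestration of the monitoring analyses on synthetic data.

``run_demo`` wires every stage together — simulation, diversity statistics,
EB F_ST + UPGMA, stock identification, recapture decay + fitness conversion,
the replacement-model grid, and the recovery regression — and writes a
plain-text report comparing each estimate with the generator's truth, plus a
JSON manifest (seed, config hash, stage list, outputs) that makes a run
reproducible byte for byte.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import gsi, popgen, regression, simulate, stocking
from .io import tree_to_newick, write_genepop

STAGES = [
    "simulate",
    "diversity",
    "ebfst",
    "gsi",
    "decay",
    "replacement",
    "regression",
]


def _config_hash(config: simulate.SimulationConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_demo(seed: int, outdir: str | Path, scale: float = 1.0) -> Path:
    """Run the full synthetic pipeline and write ``report.txt`` + tables.

    ``scale`` shrinks sample sizes for quick smoke runs (1.0 = the default
    study-scale configuration).  Returns the report path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_pop = 6
    n_per_pop = max(int(60 * scale), 10)
    config = simulate.SimulationConfig(
        seed=seed,
        n_populations=n_pop,
        sample_sizes=(n_per_pop,) * n_pop,
        target_fst=0.05,
    )
    lines: list[str] = [
        f"seabream synthetic demo (seed={seed}, config={_config_hash(config)})",
        "",
    ]
    outputs: list[str] = []

    # --- simulate -----------------------------------------------------
    freqs = simulate.simulate_baseline_frequencies(config)
    genos = simulate.simulate_genotypes(freqs, list(config.sample_sizes), config.seed)
    write_genepop(genos, outdir / "baselines.gen", title="synthetic baselines")
    outputs.append("baselines.gen")
    two_pop = genos.subset(["P1", "P2"])
    mixture, origins = simulate.simulate_mixture(
        two_pop, config.mixture_proportions, n=max(int(167 * scale), 30),
        seed=config.seed,
    )
    cohorts = simulate.simulate_release_cohorts(config)
    covars = simulate.simulate_catch_covariates(config)
    lines += [
        "[simulate]",
        f"  populations={n_pop} x {n_per_pop} fish, {config.n_loci} loci, "
        f"target F_ST={config.target_fst}",
        f"  mixture n={mixture.n_individuals} with true proportions "
        f"{tuple(config.mixture_proportions)}",
        f"  cohorts={config.years} release years, decay={config.decay_rate}/yr",
        "",
    ]

    # --- diversity ----------------------------------------------------
    ft = popgen.allele_counts(genos)
    g = int(min(s.min() for s in ft.sample_sizes.values()))
    rich = popgen.allelic_richness(ft, g)
    het = popgen.expected_heterozygosity(ft)
    div = pd.DataFrame(
        {"allelic_richness": rich.mean(axis=0), "expected_het": het.mean(axis=0)}
    )
    div.to_csv(outdir / "diversity.csv")
    outputs.append("diversity.csv")
    lines += [
        "[diversity]",
        f"  rarefaction g={g} gene copies",
        f"  mean allelic richness across populations: "
        f"{rich.mean(axis=0).mean():.3f}",
        f"  mean expected heterozygosity: {het.mean(axis=0).mean():.4f}",
        "",
    ]

    # --- EB F_ST + UPGMA ---------------------------------------------
    dm = popgen.eb_fst_matrix(genos)
    dm.to_frame().to_csv(outdir / "ebfst.csv")
    tree = popgen.upgma(dm)
    (outdir / "upgma.nwk").write_text(tree_to_newick(tree) + "\n")
    outputs += ["ebfst.csv", "upgma.nwk"]
    off = dm.off_diagonal()
    lines += [
        "[ebfst]",
        f"  pairwise EB F_ST mean={off.mean():.5f} sd={off.std(ddof=1):.5f} "
        f"(generator target {config.target_fst})",
        f"  UPGMA tree: {tree_to_newick(tree)}",
        "",
    ]

    # --- GSI ----------------------------------------------------------
    baselines = gsi.BaselineSet.from_genotypes(two_pop)
    est = gsi.em_estimate(mixture, baselines, seed=seed)
    est = gsi.baseline_aware_se(est, mixture, baselines, n_resample=100, seed=seed)
    est.proportions.to_frame().assign(se=est.se_total).to_csv(outdir / "gsi.csv")
    outputs.append("gsi.csv")
    truth = dict(zip(two_pop.population_names(), config.mixture_proportions))
    lines += ["[gsi]"]
    for src in est.proportions.index:
        lines.append(
            f"  {src}: pi={est.proportions[src]:.4f} "
            f"+/- {est.se_total[src]:.4f} (truth {truth[src]:.3f})"
        )
    lines.append("")

    # --- decay + fitness ---------------------------------------------
    rates = stocking.cumulative_recapture_rate(cohorts, max_age=8)
    xs = np.arange(len(rates), dtype=float)
    fit = stocking.fit_exponential_decay(xs, rates.to_numpy())
    red = stocking.fitness_reduction_per_generation(fit.rate, 4.8, fit.se_rate)
    lines += [
        "[decay]",
        f"  fitted decline rate={fit.rate:.4f}/yr (se {fit.se_rate:.4f}; "
        f"truth {config.decay_rate})",
        f"  per-generation fitness reduction (G=4.8): {red.value:.3f} "
        f"+/- {red.se:.3f}",
        "",
    ]

    # --- replacement ---------------------------------------------------
    params = stocking.ReplacementParams(f=1.0, R=0.1)
    g50 = stocking.generations_to_threshold(params, 0.5)
    g99 = stocking.generations_to_threshold(params, 0.01)
    surface = stocking.equilibrium_surface(
        np.round(np.linspace(0, 1, 6), 2), np.round(np.linspace(0, 0.5, 6), 2)
    )
    surface.to_csv(outdir / "replacement_surface.csv")
    outputs.append("replacement_surface.csv")
    lines += [
        "[replacement]",
        f"  f=1, R=0.1: wild gene <50% at generation {g50}, <1% at {g99}",
        "  equilibrium wild-gene proportion over (f, R) grid written to "
        "replacement_surface.csv",
        "",
    ]

    # --- regression -----------------------------------------------------
    best, path = regression.stepwise_aic(
        covars["wild_catch"], covars[["hijiki", "effort", "sst", "ph"]]
    )
    lines += [
        "[regression]",
        f"  selected predictors: {best.selected} (R^2={best.r_squared:.3f}, "
        f"AIC={best.aic:.2f})",
        f"  search path: {[(a, c) for a, c, _ in path[1:]]}",
        "",
    ]

    report = outdir / "report.txt"
    report.write_text("\n".join(lines))
    manifest = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": STAGES,
        "outputs": sorted(outputs + ["report.txt"]),
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report


def run_stage(name: str, config: dict) -> object:
    """Run a single pipeline stage with keyword configuration.

    Unknown names raise with the list of valid stages.  This is the
    programmatic counterpart of the CLI subcommands.
    """
    dispatch = {
        "simulate": lambda c: simulate.simulate_baseline_frequencies(
            simulate.SimulationConfig(**c)
        ),
        "diversity": lambda c: popgen.allelic_richness(
            popgen.allele_counts(c["genotypes"]), c["g"]
        ),
        "ebfst": lambda c: popgen.eb_fst_matrix(c["genotypes"]),
        "gsi": lambda c: gsi.em_estimate(
            c["mixture"], c["baselines"], seed=c.get("seed", 0)
        ),
        "decay": lambda c: stocking.fit_exponential_decay(c["x"], c["y"]),
        "replacement": lambda c: stocking.generations_to_threshold(
            stocking.ReplacementParams(c["f"], c["R"]), c["threshold"]
        ),
        "regression": lambda c: regression.stepwise_aic(c["y"], c["X"]),
    }
    if name not in dispatch:
        raise ValueError(
            f"unknown stage {name!r}; valid stages: {', '.join(dispatch)}"
        )
    return dispatch[name](config)
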