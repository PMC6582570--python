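"""End-to-end analysis runner and publication-style outputs.

Ties the stages together: read pedigree and phenotypes, trace ancestors,
apply the half-sib informativeness filters, tabulate phenotype
frequencies, fit the threshold model with multiple chains, summarize the
h2 posterior, and write frequency/summary tables, the retained chains,
and a posterior-density figure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import matplotlib
import numpy as np
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pedigree import Pedigree, read_pedigree, trace_generations
from .phenotypes import (
    FilterConfig,
    apply_filters,
    build_halfsib_families,
    frequency_table,
    read_phenotypes,
)
from .threshold_gibbs import (
    GibbsChain,
    MCMCConfig,
    convergence_diagnostics,
    run_chains,
    summarize_posterior,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Defaults mirror the published protocol: pedigree depth 3 generations,
    minimum half-sib family size 20 (position) / 10 (number), monomorphic
    families dropped, 1,050,000 Gibbs iterations with 50,000 burn-in.
    """

    pedigree_path: str
    phenotype_path: str
    trait_name: str
    output_dir: str
    generations: int = 3
    filters: FilterConfig = field(default_factory=lambda: FilterConfig(
        min_family_size=20, drop_monomorphic_families=True))
    mcmc: MCMCConfig = field(default_factory=lambda: MCMCConfig(
        n_iterations=1_050_000, burn_in=50_000, thinning=10, n_chains=2))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filters = FilterConfig(**raw.pop("filters", {}))
        mcmc = MCMCConfig(**raw.pop("mcmc", {}))
        return cls(filters=filters, mcmc=mcmc, **raw)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the whole pipeline and write run artifacts.

    Writes table1.csv (phenotype frequencies before filtering), table2.csv
    and summary.json (posterior mode / mean +/- SD / 95% CI of h2, plus
    PSRF and ESS), chain.csv (retained samples of all chains), a
    posterior-density figure, and exclusions.log.  Any stage failure
    aborts with a stage-tagged message.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"[{name}] {exc}") from exc

    for label, path in (("pedigree", cfg.pedigree_path), ("phenotypes", cfg.phenotype_path)):
        if not Path(path).exists():
            raise StageError(f"[read] {label} file not found: {path}")

    ped = stage("read_pedigree", read_pedigree, cfg.pedigree_path)
    data = stage("read_phenotypes", read_phenotypes, cfg.phenotype_path, cfg.trait_name)
    ped = stage("trace_generations", trace_generations, ped, data.ids, cfg.generations)
    logger.info("pedigree truncated to %d generations: %d individuals",
                cfg.generations, len(ped))

    freq_raw = stage("frequency_table", frequency_table, data)
    freq_raw.to_frame().to_csv(out / "table1.csv", index=False)

    families = stage("build_families", build_halfsib_families, data, ped)
    data, exclusions = stage("apply_filters", apply_filters, data, families, cfg.filters)
    with open(out / "exclusions.log", "w") as fh:
        for rule, count in exclusions.as_dict().items():
            fh.write(f"{rule}: {count}\n")
            logger.info("exclusions %s: %d", rule, count)

    chains = stage("run_gibbs", run_chains, data, ped, cfg.mcmc)
    pooled = np.concatenate([c.h2 for c in chains])
    summary = stage("summarize_posterior", summarize_posterior, pooled)
    diag = stage("diagnostics", convergence_diagnostics, chains) \
        if len(chains) >= 2 else None

    frames = []
    for k, c in enumerate(chains):
        df = c.to_frame()
        df.insert(0, "iteration", cfg.mcmc.burn_in + 1
                  + np.arange(len(c)) * cfg.mcmc.thinning)
        df.insert(0, "chain", k)
        frames.append(df)
    import pandas as pd
    chain_df = pd.concat(frames, ignore_index=True)
    chain_df.to_csv(out / "chain.csv", index=False)

    table2 = pd.DataFrame([{
        "trait": cfg.trait_name, "mode": round(summary.mode, 3),
        "mean": round(summary.mean, 3), "sd": round(summary.sd, 3),
        "ci_low": round(summary.ci_low, 3), "ci_high": round(summary.ci_high, 3),
    }])
    table2.to_csv(out / "table2.csv", index=False)

    result = {"trait": cfg.trait_name, "n_observations": len(data),
              "n_pedigree": len(ped), "exclusions": exclusions.as_dict(),
              **summary.as_dict()}
    if diag is not None:
        result["psrf"] = diag.psrf
        result["ess"] = diag.ess
    with open(out / "summary.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)

    stage("plot", render_posterior_plot, chains, out / "posterior.png")
    return result


def render_posterior_plot(chains, path) -> Path:
    """Posterior-density figure of h2: heritability on the horizontal axis,
    posterior probability density on the vertical axis; one curve per chain."""
    from scipy.stats import gaussian_kde

    if isinstance(chains, GibbsChain):
        chains = [chains]
    if not chains or any(len(c) == 0 for c in chains):
        raise ValueError("cannot plot an empty chain")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    grid = np.linspace(0, 1, 512)
    for k, c in enumerate(chains):
        if np.ptp(c.h2) == 0:
            logger.warning("chain %d is degenerate (constant h2 = %.3f)", k, c.h2[0])
            ax.axvline(c.h2[0], label=f"chain {k}")
            continue
        dens = gaussian_kde(c.h2, bw_method="silverman")(grid)
        ax.plot(grid, dens, label=f"chain {k}")
    ax.set_xlabel("heritability ($h^2$)")
    ax.set_ylabel("posterior density")
    ax.set_xlim(0, 1)
    if len(chains) > 1:
        ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
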