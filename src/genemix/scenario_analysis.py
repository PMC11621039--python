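"""Scenario orchestration: every population as donor against one recipient.

Runs the mixing simulation for each candidate donor (including the recipient
as self-donor, the no-introduction reference), assembles the pairwise
differentiation metrics, and correlates the simulated heterozygosity outcome
with each metric — once for the full donor set and once with a caller-chosen
exclusion set (e.g. dropping taxonomically distinct outlier populations).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .divmetrics import metrics_table
from .genotype_io import GenotypeMatrix, PopulationMap
from .simintro import MixingSummary, ReplicateSet, SimConfig, run_replicates, summarize

logger = logging.getLogger(__name__)

#: metric columns correlated against the simulated outcome
METRIC_COLUMNS = ["fixed_diffs", "fst", "jost_d", "q0_beta",
                  "donor_variant_het", "donor_autosomal_het"]


@dataclass
class ScenarioResults:
    recipient: str
    baseline_het: float
    replicate_sets: dict[str, ReplicateSet]
    summaries: pd.DataFrame          # one row per scenario
    skipped: dict[str, str]          # population -> reason


def run_all_scenarios(matrix: GenotypeMatrix, popmap: PopulationMap, recipient: str,
                      config: SimConfig) -> ScenarioResults:
    """One mixing scenario per population, identical config throughout.

    The baseline is the self-donor scenario's mean generation-0
    heterozygosity; donors too small for the configured draw are skipped
    with a logged reason.
    """
    replicate_sets: dict[str, ReplicateSet] = {}
    skipped: dict[str, str] = {}
    for pop in popmap.populations:
        pool = [s for s in popmap.samples_in(pop) if s in matrix.sample_ids]
        if pop != recipient and len(pool) < config.n_donor:
            reason = f"{len(pool)} samples < n_donor={config.n_donor}"
            skipped[pop] = reason
            logger.info("scenario %s skipped: %s", pop, reason)
            continue
        replicate_sets[pop] = run_replicates(matrix, popmap, recipient, pop,
                                             config, scenario=pop)

    if recipient not in replicate_sets:
        raise ValueError(f"recipient {recipient!r} scenario could not run")
    baseline = float(replicate_sets[recipient].mean[0])

    summaries = pd.DataFrame.from_dict(
        {pop: asdict(summarize(rs, baseline)) for pop, rs in replicate_sets.items()},
        orient="index").drop(columns="scenario")
    return ScenarioResults(recipient=recipient, baseline_het=baseline,
                           replicate_sets=replicate_sets, summaries=summaries,
                           skipped=skipped)


def correlate_metrics(summaries: pd.DataFrame, metrics: pd.DataFrame,
                      recipient: str, exclude: Iterable[str] = (),
                      outcome: str = "final_het") -> pd.DataFrame:
    """Pearson correlation of the simulated outcome against each metric.

    The self-donor row is always excluded.  Returns one row per
    (metric, set) with set in {"full", "reduced"}; the reduced set applies
    the exclusion on top.  Fewer than 3 scenarios in a set withholds that
    set's correlations; a constant metric gives NaN, flagged ``degenerate``.
    """
    exclude = set(exclude)
    donors = [p for p in summaries.index if p != recipient and p in metrics.index]
    sets: dict[str, list[str]] = {"full": donors}
    if exclude:
        sets["reduced"] = [p for p in donors if p not in exclude]

    rows = []
    for set_name, members in sets.items():
        if len(members) < 3:
            logger.info("correlation set %s withheld: only %d scenarios",
                        set_name, len(members))
            continue
        y = summaries.loc[members, outcome].astype(float)
        for metric in METRIC_COLUMNS:
            if metric not in metrics.columns:
                continue
            x = metrics.loc[members, metric].astype(float)
            ok = x.notna() & y.notna()
            degenerate = (ok.sum() < 3 or np.ptp(x[ok].to_numpy()) == 0
                          or np.ptp(y[ok].to_numpy()) == 0)
            if degenerate:
                r = p = np.nan
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"set": set_name, "metric": metric, "n": int(ok.sum()),
                         "r": r, "p": p, "degenerate": bool(degenerate),
                         "excluded": ",".join(sorted(exclude)) if set_name == "reduced" else ""})
    return pd.DataFrame(rows)


def trajectories_frame(replicate_sets: Mapping[str, ReplicateSet]) -> pd.DataFrame:
    """Long-format per-replicate trajectories (scenario, replicate, generation,
    mean_het) plus cross-replicate mean and band."""
    rows = []
    for scenario, rs in replicate_sets.items():
        for t in rs.trajectories:
            for g, h in enumerate(t.mean_het):
                rows.append((scenario, t.replicate, g, h))
    df = pd.DataFrame(rows, columns=["scenario", "replicate", "generation", "mean_het"])
    return df


def render_report(results: ScenarioResults, correlations: pd.DataFrame,
                  out_dir: str | Path, config: SimConfig | None = None) -> dict[str, Path]:
    """Write trajectory/summary/correlation CSVs and the two figures.

    Figures: per-scenario mean trajectories with 95% ribbons and a dashed
    baseline; scatter panels of outcome vs each metric.  All numbers behind
    the figures are also emitted as CSV; a manifest records the config for
    reproducibility.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    traj = trajectories_frame(results.replicate_sets)
    paths["trajectories"] = out_dir / "trajectories.csv"
    traj.to_csv(paths["trajectories"], index=False)

    paths["summaries"] = out_dir / "scenario_summaries.csv"
    results.summaries.rename_axis("scenario").to_csv(paths["summaries"])

    paths["correlations"] = out_dir / "correlations.csv"
    correlations.to_csv(paths["correlations"], index=False)

    fig, ax = plt.subplots(figsize=(9, 5))
    gens = np.arange(len(next(iter(results.replicate_sets.values())).mean))
    for scenario, rs in results.replicate_sets.items():
        ax.plot(gens, rs.mean, label=scenario, lw=1.4)
        ax.fill_between(gens, rs.ci_low, rs.ci_high, alpha=0.2)
    ax.axhline(results.baseline_het, ls="--", color="k", lw=1,
               label="no-mixing baseline")
    ax.set_xlabel("generation")
    ax.set_ylabel("mean variant-site heterozygosity")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    paths["trajectory_plot"] = out_dir / "trajectories.png"
    fig.savefig(paths["trajectory_plot"], dpi=150)
    plt.close(fig)

    if len(correlations):
        metrics_present = correlations["metric"].unique()
        fig, axes = plt.subplots(1, len(metrics_present),
                                 figsize=(3 * len(metrics_present), 3), squeeze=False)
        for ax, metric in zip(axes[0], metrics_present):
            sub = correlations[correlations["metric"] == metric]
            ax.set_title(metric, fontsize=8)
            for _, row in sub.iterrows():
                ax.bar(row["set"], row["r"])
            ax.set_ylim(-1, 1)
            ax.set_ylabel("Pearson r")
        fig.tight_layout()
        paths["correlation_plot"] = out_dir / "correlations.png"
        fig.savefig(paths["correlation_plot"], dpi=150)
        plt.close(fig)

    manifest = {
        "recipient": results.recipient,
        "baseline_het": results.baseline_het,
        "skipped": results.skipped,
        "config": asdict(config) if config is not None else None,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["manifest"] = out_dir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths


def scenario_scatter(results: ScenarioResults, metrics: pd.DataFrame,
                     out_path: str | Path, outcome: str = "final_het") -> Path:
    """Scatter panels of the simulated outcome against each available metric."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    donors = [p for p in results.summaries.index
              if p != results.recipient and p in metrics.index]
    cols = [c for c in METRIC_COLUMNS if c in metrics.columns]
    fig, axes = plt.subplots(1, len(cols), figsize=(3 * len(cols), 3), squeeze=False)
    y = results.summaries.loc[donors, outcome]
    for ax, metric in zip(axes[0], cols):
        x = metrics.loc[donors, metric]
        ax.scatter(x, y, s=18)
        ax.set_xlabel(metric, fontsize=8)
        ax.set_ylabel(outcome, fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
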