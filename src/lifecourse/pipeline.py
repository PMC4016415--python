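"""End-to-end orchestration: synthesize -> estimate -> test -> simulate -> report.

Each stage reads and writes plain CSV artifacts in the output directory, so
a run is resumable per stage from its intermediates.  A line-oriented log
records seeds, row counts and warnings (zero-count rows, non-stationary
strata).  Any stage failure aborts with the stage name in the message.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import InitialMix, cohort_result
from .estimation import (
    count_transitions,
    estimate_cost_table,
    estimate_matrices,
    stationarity_report,
    stationarity_test,
    write_matrices,
)
from .montecarlo import simulate_collection, summarize_costs, summarize_years
from .panel import read_panel, write_panel
from .reporting import (
    aggregate_expectancy,
    compare_engines,
    cost_summary_table,
    expectancy_table,
    plot_cost_histogram,
    plot_occupancy,
    plot_yearly_cost,
)
from .states import DEFAULT_SCHEME, Gender, HealthState, N_TRANSIENT
from .synthetic import SynthConfig, generate_panel, make_ground_truth

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("lifecourse")


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: Path = Path("lifecourse_out")
    seed: int = 0
    n_individuals: int = 20_000
    years: tuple[int, ...] = (2004, 2005, 2006, 2007)
    cohort_size: int = 100_000
    n_per_gender: int = 10_000
    max_age: int = 110
    alpha: float = 0.05
    figures: bool = False
    panel_path: Path | None = None  # use an existing panel instead of synthesizing
    synth: dict = field(default_factory=dict)  # extra SynthConfig overrides

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in ("n_individuals", "cohort_size", "n_per_gender", "max_age"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        if raw.get("panel_path"):
            raw["panel_path"] = Path(raw["panel_path"])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out

        return wrapped

    return deco


def _initial_mix_from_panel(panel, year: int, min_n: int = 50) -> InitialMix | None:
    """Observed (gender x state) mix of the under-1 band in a reference year."""
    df = panel.df
    sel = df[(df["year"] == year) & (df["age"] == 0) & (df["state"] != "DEAD")]
    if len(sel) < min_n:
        return None
    shares = np.zeros((2, N_TRANSIENT))
    g = (sel["gender"] == "M").to_numpy().astype(int)
    s = sel["state"].map(lambda x: HealthState[x].value).to_numpy()
    np.add.at(shares, (g, s), 1)
    return InitialMix(shares=shares / shares.sum())


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole pipeline and return artifact paths plus headline numbers."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict = {"outdir": str(out)}
    try:
        log.info("lifecourse %s, seed %d", __version__, config.seed)

        @_stage("synth")
        def synth():
            cfg = SynthConfig(
                n_individuals=config.n_individuals,
                years=config.years,
                seed=config.seed,
                **config.synth,
            )
            truth = make_ground_truth(cfg)
            panel = generate_panel(truth, cfg)
            write_panel(panel, out / "panel.csv")
            write_matrices(truth.matrices, out / "true_matrices.csv")
            log.info("synthesized panel: %d records, %d persons",
                     len(panel), panel.report.n_persons)
            return truth, panel

        if config.panel_path is not None:
            panel = read_panel(config.panel_path)
            truth = None
            log.info("loaded panel %s: %d records", config.panel_path, len(panel))
        else:
            truth, panel = synth()
        artifacts["panel"] = str(out / "panel.csv")

        @_stage("estimate")
        def estimate():
            counts = count_transitions(panel, DEFAULT_SCHEME)
            mset = estimate_matrices(counts)
            write_matrices(mset, out / "matrices.csv")
            ctable = estimate_cost_table(panel, scheme=DEFAULT_SCHEME)
            ctable.write(out / "cost_table.csv")
            return counts, mset, ctable

        counts, mset, ctable = estimate()
        artifacts["matrices"] = str(out / "matrices.csv")
        artifacts["cost_table"] = str(out / "cost_table.csv")

        @_stage("test-stationarity")
        def stationarity():
            results = stationarity_test(counts, alpha=config.alpha)
            rep = stationarity_report(results)
            rep.to_csv(out / "stationarity.csv", index=False)
            for r in results:
                if not r.stationary:
                    log.warning("non-stationary stratum %s %s (p=%.4f); pooled "
                                "matrix used regardless", r.gender, r.age_group, r.p_value)
            return rep

        artifacts["stationarity"] = str(out / "stationarity.csv")
        stationarity()

        @_stage("cohort")
        def cohort():
            mix = _initial_mix_from_panel(panel, panel.years[-1])
            if mix is None:
                log.warning("under-1 band too small to estimate the initial mix; "
                            "using the default composition")
                mix = InitialMix.default()
            res = cohort_result(
                mset, mix, costs=ctable, size=config.cohort_size, max_age=config.max_age
            )
            res.occupancy.to_long_df().to_csv(out / "occupancy.csv", index=False)
            return mix, res

        mix, cres = cohort()
        artifacts["occupancy"] = str(out / "occupancy.csv")

        @_stage("mc")
        def mc():
            coll = simulate_collection(
                mset, mix, config.n_per_gender, ctable,
                seed=config.seed + 1, max_age=config.max_age,
            )
            return coll

        coll = mc()

        @_stage("report")
        def report():
            mc_years = summarize_years(coll)
            etab = expectancy_table(cres, mc_years)
            etab.to_csv(out / "expected_years.csv")
            summaries = {g.name: summarize_costs(coll, g) for g in Gender}
            cost_tab = cost_summary_table(summaries)
            cost_tab.to_csv(out / "lifetime_cost_distribution.csv")
            yearly = cres.yearly_mean_cost
            yearly.to_csv(out / "yearly_mean_cost.csv")

            headline = {}
            for g in Gender:
                agg = aggregate_expectancy(cres.expected_years[g.name].to_dict())
                gap = compare_engines(
                    float(cres.lifetime_mean_cost[g.name]), summaries[g.name].mean
                )
                headline[g.name] = {
                    "total_le": agg["total"],
                    "healthy_years": agg["healthy_years"],
                    "chronic_years": agg["chronic_years"],
                    "cohort_lifetime_cost": float(cres.lifetime_mean_cost[g.name]),
                    "mc_lifetime_cost": summaries[g.name].mean,
                    "engine_gap_pct": gap,
                }
                log.info("%s: LE %.2f, lifetime cost %.2f (cohort) vs %.2f (MC), gap %.3f%%",
                         g.name, agg["total"], cres.lifetime_mean_cost[g.name],
                         summaries[g.name].mean, gap)
            with open(out / "summary.json", "w") as fh:
                json.dump(headline, fh, indent=2)

            if config.figures:
                for g in Gender:
                    plot_occupancy(cres.occupancy, g, out / f"occupancy_{g.name}.png")
                    plot_cost_histogram(coll, g, out / f"cost_hist_{g.name}.png")
                plot_yearly_cost(yearly, out / "yearly_mean_cost.png")
            return headline

        artifacts["summary"] = str(out / "summary.json")
        artifacts["headline"] = report()
        return artifacts
    finally:
        log.removeHandler(handler)
        handler.close()
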