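"""Scenario runner for the three film-formation experiments.

Three scenarios probe the role of the metastable P3 ordering:

* ``p6_only``   — only the dense P6 crystal interactions are allowed,
* ``p6_p3``     — both P6 and the metastable P3 interactions are allowed,
* ``subsaturated`` — as ``p6_p3`` but half of the adsorption attempts find
  no protein available (``p_absent = 0.5``), modelling a protein
  concentration below surface saturation.

Each run starts from an empty lattice of ``cells`` x ``cells`` commensurate
14x14-site unit cells (the published system uses 40x40 cells), evolves under
the default couplings, and is summarised by its largest-cluster growth law
and percolation time.  Every run is exactly reproducible from the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .cluster_analysis import classify_growth, WindowPolicy
from .lattice import LatticeConfig
from .mc_engine import MCParams, TimeSeries, run_simulation
from .spin_model import ModelParams, bond_census, build_interaction_table

SCENARIO_NAMES = ("p6_only", "p6_p3", "subsaturated")

#: calibrated inverse temperature (kT^-1 units of the couplings).  The model
#: itself does not fix a temperature; it is tuned so that the film is both
#: fluid and ordering -- see analysis/00_calibrate_temperature.py, which
#: scans beta and picks the value maximizing the ordered-film size reached
#: in a fixed P6-only run (too cold: kinetic arrest; too hot: the film
#: never condenses).
DEFAULT_BETA = 0.08


@dataclass(frozen=True)
class Scenario:
    """One computational experiment: name, system size, schedule and model
    overrides.  ``cells`` counts 14x14-site unit cells per side (the
    published runs use 40; 10 is a desk-scale default)."""

    name: str
    cells: int = 40
    sweeps: int = 300
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    J0: float = 5.0
    J1: float = 2.0
    J2: float = 1.0
    Jsurf: float = 10.0
    beta: float = DEFAULT_BETA
    p_absent: float | None = None
    move_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"scenario name must be one of {SCENARIO_NAMES}")
        if self.cells < 2:
            raise ValueError("cells must be >= 2")
        if self.sweeps < 0:
            raise ValueError("sweeps must be nonnegative")
        if not self.seeds:
            raise ValueError("at least one seed is required")

    @property
    def p3_enabled(self) -> bool:
        return self.name != "p6_only"

    @property
    def effective_p_absent(self) -> float:
        if self.name == "subsaturated":
            return 0.5 if self.p_absent is None else self.p_absent
        return 0.0 if self.p_absent is None else self.p_absent

    def model_params(self) -> ModelParams:
        return ModelParams(J0=self.J0, J1=self.J1, J2=self.J2,
                           Jsurf=self.Jsurf, p3_enabled=self.p3_enabled,
                           p_absent=self.effective_p_absent)

    def mc_params(self, seed: int) -> MCParams:
        return MCParams(sweeps=self.sweeps, seed=seed, beta=self.beta,
                        move_mix=self.move_mix,
                        record_every=self.record_every)


@dataclass
class RunSummary:
    """Machine-readable summary of one run, consistent with its CSV."""

    scenario: str
    seed: int
    label: str
    slope: float
    rate: float
    delta_aicc: float
    window: tuple[int, int]
    percolation_sweep: int | None
    final_occupancy: float
    n_trimer: int
    n_p6: int
    n_p3: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_run(sc: Scenario, seed: int, series: TimeSeries,
                  final: LatticeConfig, table) -> RunSummary:
    fit = classify_growth(series)
    perc = series.data.loc[series.data["percolated"] > 0, "sweep"]
    nt, np6, np3, _, nocc = bond_census(final, table)
    return RunSummary(
        scenario=sc.name, seed=seed, label=fit.label, slope=fit.slope,
        rate=fit.rate, delta_aicc=fit.delta_aicc, window=fit.window,
        percolation_sweep=int(perc.iloc[0]) if len(perc) else None,
        final_occupancy=nocc / (final.width * final.height),
        n_trimer=nt, n_p6=np6, n_p3=np3)


def run_scenario(sc: Scenario, out_dir: str | Path | None = None,
                 ) -> list[RunSummary]:
    """Run the scenario for every seed; optionally write per-run artefacts.

    Per seed: ``<scenario>_<seed>.csv`` (time series),
    ``<scenario>_<seed>_final.tsv`` (snapshot), ``<scenario>_<seed>.json``
    (summary); plus a ``manifest.json`` recording all parameters.
    """
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    table = build_interaction_table(sc.p3_enabled)
    mp = sc.model_params()
    n = 14 * sc.cells
    summaries: list[RunSummary] = []
    for seed in sc.seeds:
        initial = LatticeConfig(n, n)
        series, final = run_simulation(initial, table, mp, sc.mc_params(seed))
        summary = summarize_run(sc, seed, series, final, table)
        summaries.append(summary)
        if out is not None:
            series.to_csv(out / f"{sc.name}_{seed}.csv")
            final.save_tsv(out / f"{sc.name}_{seed}_final.tsv")
            with open(out / f"{sc.name}_{seed}.json", "w") as fh:
                json.dump(summary.to_dict(), fh, indent=2)
    if out is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(dataclasses.asdict(sc), fh, indent=2)
    return summaries


@dataclass
class ComparisonReport:
    """Paired-seed comparison of two scenario runs (A vs. B)."""

    seeds: tuple[int, ...]
    percolation_diffs: list[float]      # A - B per seed (inf-aware)
    rate_diffs: list[float]
    median_percolation_diff: float
    sign_test_p: float                  # one-sided: A percolates earlier


def compare_runs(a: list[RunSummary], b: list[RunSummary]) -> ComparisonReport:
    """Per-seed paired differences between matched scenario runs.

    ``sign_test_p`` is the one-sided sign-test p-value for "A percolates
    earlier than B" (a run that never percolates counts as percolating at
    +infinity; ties are dropped, no-tie degenerate cases give p = 1).
    """
    seeds_a = tuple(s.seed for s in a)
    seeds_b = tuple(s.seed for s in b)
    if seeds_a != seeds_b:
        raise ValueError("seed lists must match for a paired comparison")

    def perc(s: RunSummary) -> float:
        return float("inf") if s.percolation_sweep is None \
            else float(s.percolation_sweep)

    pdiffs = []
    for ra, rb in zip(a, b):
        pa, pb = perc(ra), perc(rb)
        if np.isinf(pa) and np.isinf(pb):
            pdiffs.append(0.0)
        else:
            pdiffs.append(pa - pb)
    rdiffs = [ra.rate - rb.rate for ra, rb in zip(a, b)]
    n_neg = sum(1 for d in pdiffs if d < 0)
    n_pos = sum(1 for d in pdiffs if d > 0)
    if n_neg + n_pos == 0:
        p = 1.0
    else:
        p = float(stats.binomtest(n_neg, n_neg + n_pos, 0.5,
                                  alternative="greater").pvalue)
    finite = [d for d in pdiffs if np.isfinite(d)]
    median = float(np.median(finite)) if finite else float("nan")
    return ComparisonReport(seeds=seeds_a, percolation_diffs=pdiffs,
                            rate_diffs=rdiffs,
                            median_percolation_diff=median, sign_test_p=p)


# ---------------------------------------------------------------------------
# coarsening experiment
# ---------------------------------------------------------------------------


def coarsening_experiment(cells: int = 10, sweeps: int = 6000,
                          seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
                          beta: float = DEFAULT_BETA,
                          record_every: int = 20):
    """Domain-coarsening exponents of P6-only runs.

    Runs long P6-only simulations and fits the log-log slope of largest
    cluster size vs. sweep on the asymptotic window (the first tenth of the
    run is discarded as transient: the fill-in phase leaves a large size
    offset that would bias a power-law fit taken from time zero).
    Returns the list of :class:`~hydrofilm.cluster_analysis.CoarseningFit`.
    """
    from .cluster_analysis import estimate_coarsening_exponent

    table = build_interaction_table(False)
    mp = ModelParams(p3_enabled=False)
    n = 14 * cells
    policy = WindowPolicy(min_points=5, min_sweep=sweeps / 10)
    fits = []
    for seed in seeds:
        series, _ = run_simulation(
            LatticeConfig(n, n), table, mp,
            MCParams(sweeps=sweeps, seed=seed, beta=beta,
                     record_every=record_every))
        fits.append(estimate_coarsening_exponent(series, policy))
    return fits


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> Scenario:
    """Read a scenario config (YAML with scenario./lattice./mc./model. keys)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sc = raw.get("scenario", {})
    lat = raw.get("lattice", {})
    mc = raw.get("mc", {})
    model = raw.get("model", {})
    kwargs: dict = {"name": sc.get("name", "p6_p3")}
    if "cells" in lat:
        kwargs["cells"] = int(lat["cells"])
    if "sweeps" in mc:
        kwargs["sweeps"] = int(mc["sweeps"])
    if "seeds" in mc:
        kwargs["seeds"] = tuple(int(s) for s in mc["seeds"])
    if "beta" in mc:
        kwargs["beta"] = float(mc["beta"])
    if "record_every" in mc:
        kwargs["record_every"] = int(mc["record_every"])
    for key in ("J0", "J1", "J2", "Jsurf"):
        if key in model:
            kwargs[key] = float(model[key])
    if "p_absent" in model:
        kwargs["p_absent"] = float(model["p_absent"])
    return Scenario(**kwargs)
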