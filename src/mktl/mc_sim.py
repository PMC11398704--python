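"""Monte Carlo comparison of the twelve MKTL estimators.

For each sample size in the design, ``reps`` samples are drawn by inverse
transform and every requested method is fitted to the *same* samples
(common random numbers, so method comparisons are paired).  Results are
aggregated into the mean estimate and the mean squared error per
(method, parameter, n), and scenarios are compared by rank aggregation:
within each (scenario, n) the methods are ranked by eta-MSE and by
beta-MSE (1 = smallest, average ranks on ties) and the two ranks summed.

Fits warm-start at the true parameter values — the protocol under which
the reference simulation tables were produced (their initial values are
the truth) — which also keeps full-size runs affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .distribution import MKTLParams, quantile
from .estimation import METHODS, UnitSample, fit

__all__ = ["SimDesign", "SimTable", "RankTable", "run_simulation", "rank_methods"]

#: sample-size grid of the reference study
DEFAULT_N_GRID: tuple[int, ...] = (30, 150, 300, 500, 800)


@dataclass(frozen=True)
class SimDesign:
    """One simulation scenario: truth, sample sizes, replicates, methods, seed."""

    true_params: MKTLParams
    n_grid: Sequence[int] = DEFAULT_N_GRID
    reps: int = 1000
    methods: Sequence[str] = METHODS
    seed: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not len(self.n_grid):
            raise ValueError("n_grid must be non-empty")
        unknown = set(m.upper() for m in self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @property
    def scenario(self) -> str:
        if self.label is not None:
            return self.label
        return f"eta={self.true_params.eta:g},beta={self.true_params.beta:g}"


@dataclass(frozen=True)
class SimTable:
    """Tidy per-cell results: columns scenario, method, parameter, n, mean, mse,
    plus the per-(method, n) exclusion rate of failed fits."""

    cells: pd.DataFrame
    exclusions: pd.DataFrame
    design: SimDesign

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.cells.to_json(path, orient="records", indent=1)

    def cell(self, method: str, parameter: str, n: int) -> tuple[float, float]:
        """(mean, mse) for one method/parameter/sample-size cell."""
        c = self.cells
        row = c[(c.method == method.upper()) & (c.parameter == parameter) & (c.n == n)]
        if row.empty:
            raise KeyError((method, parameter, n))
        return float(row["mean"].iloc[0]), float(row["mse"].iloc[0])


@dataclass(frozen=True)
class RankTable:
    """Rank aggregation across scenarios: per (scenario, n) the summed
    eta-MSE and beta-MSE ranks per method, their totals and overall ranks."""

    per_cell: pd.DataFrame
    totals: pd.Series
    overall_ranks: pd.Series


def _replicate_rng(seed: int, n: int, rep: int) -> np.random.Generator:
    # independent, reproducible stream per (n, replicate); all methods of a
    # replicate share the sample (common random numbers)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(n, rep)))


def run_simulation(design: SimDesign, *, flag_threshold: float = 0.01) -> SimTable:
    """Run the Monte Carlo estimator comparison for one scenario.

    Replicates whose fit fails to converge are excluded from the aggregates
    and counted; an exclusion rate above ``flag_threshold`` for any
    (method, n) raises a warning-level flag in the exclusions table.
    """
    truth = design.true_params
    methods = [m.upper() for m in design.methods]
    rows = []
    excl = []
    for n in design.n_grid:
        n = int(n)
        estimates: dict[str, list[tuple[float, float]]] = {m: [] for m in methods}
        failed = dict.fromkeys(methods, 0)
        for rep in range(design.reps):
            rng = _replicate_rng(design.seed, n, rep)
            sample = UnitSample(quantile(rng.uniform(size=n), truth))
            for m in methods:
                res = fit(sample, m, starts=[truth.as_tuple()], compute_se=False)
                if res.converged:
                    estimates[m].append(res.params.as_tuple())
                else:
                    failed[m] += 1
        for m in methods:
            est = np.asarray(estimates[m])
            rate = failed[m] / design.reps
            excl.append(
                {"scenario": design.scenario, "method": m, "n": n,
                 "excluded": failed[m], "rate": rate, "flagged": rate > flag_threshold}
            )
            for j, par in enumerate(("eta", "beta")):
                tr = truth.as_tuple()[j]
                rows.append(
                    {
                        "scenario": design.scenario,
                        "method": m,
                        "parameter": par,
                        "n": n,
                        "mean": est[:, j].mean(),
                        "mse": np.mean((est[:, j] - tr) ** 2),
                    }
                )
    return SimTable(cells=pd.DataFrame(rows), exclusions=pd.DataFrame(excl), design=design)


def rank_methods(tables: Sequence[SimTable]) -> RankTable:
    """Aggregate MSE ranks over scenarios.

    For each (scenario, n): rank methods by eta-MSE and by beta-MSE
    (1 = smallest, ties get average ranks) and sum the two ranks, so cells
    range from 2 to 2M for M methods.  Totals over all (scenario, n) give
    the overall ranking (1 = best).
    """
    if not tables:
        raise ValueError("need at least one SimTable")
    methods = [m.upper() for m in tables[0].design.methods]
    for t in tables[1:]:
        if [m.upper() for m in t.design.methods] != methods:
            raise ValueError("all tables must share the same method set")
    recs = []
    for t in tables:
        c = t.cells
        for n in sorted(c.n.unique()):
            cell_ranks = np.zeros(len(methods))
            for par in ("eta", "beta"):
                sub = c[(c.n == n) & (c.parameter == par)].set_index("method")
                mse = sub.loc[methods, "mse"].to_numpy()
                cell_ranks += rankdata(mse, method="average")
            recs.append(
                {"scenario": t.design.scenario, "n": int(n),
                 **dict(zip(methods, cell_ranks))}
            )
    per_cell = pd.DataFrame(recs)
    totals = per_cell[methods].sum(axis=0)
    overall = pd.Series(rankdata(totals.to_numpy(), method="average"), index=methods)
    return RankTable(per_cell=per_cell, totals=totals, overall_ranks=overall)
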