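"""Monte Carlo harness: power and Type-I error of four interaction tests.

For each grid cell (total N, number of waves, effect size d) the harness
generates replicate panels from the growth model, analyses each panel
with every requested method, and records the proportion of replicates
whose group x session interaction p-value falls below alpha.  Cells with
d = 0 estimate Type-I error; d > 0 cells estimate power.

Methods
-------
``rANOVA``      uncorrected split-plot interaction F test
``GG-rANOVA``   the same F with Greenhouse-Geisser corrected df
``MLM-z``       mixed-model Wald z on the interaction (infinite df)
``MLM-F``       mixed-model F with between-within denominator df

Seeding: each cell derives a child seed from the master seed and its own
coordinates via ``numpy.random.SeedSequence`` spawn keys, and every
replicate derives its seed from the cell's sequence, so any single
replicate can be re-run in isolation and results are independent of
execution order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import lmm, ranova
from .datagen import (
    DEFAULT_MODEL,
    EffectSpec,
    GeneratingModel,
    StudyDesign,
    make_generating_model,
    simulate_dataset,
)

__all__ = [
    "METHODS",
    "GridSpec",
    "PowerCell",
    "run_replicate",
    "run_cell",
    "run_grid",
    "cell_seed_sequence",
    "replicate_seed",
    "plot_power_curves",
]

METHODS = ("rANOVA", "GG-rANOVA", "MLM-z", "MLM-F")
INTERACTION = "group:session"


@dataclass(frozen=True)
class GridSpec:
    """Full factorial simulation grid.

    Defaults are the study conditions of the comparison this package
    implements: total N in {6, 20, 30}, 3 or 6 waves, effect sizes
    d in {0.20, 0.50, 0.80, 1.00} plus the d = 0 null, alpha = 0.05,
    slope SD 2.00 behind the standardization.
    """

    sample_sizes: tuple[int, ...] = (6, 20, 30)
    waves: tuple[int, ...] = (3, 6)
    effects: tuple[float, ...] = (0.20, 0.50, 0.80, 1.00, 0.0)
    methods: tuple[str, ...] = METHODS
    n_reps: int = 2000
    alpha: float = 0.05
    master_seed: int = 0
    base_model: GeneratingModel = DEFAULT_MODEL

    def __post_init__(self) -> None:
        if any(n % 2 for n in self.sample_sizes):
            raise ValueError("total sample sizes must be even (equal split)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")


@dataclass(frozen=True)
class PowerCell:
    """Rejection summary for one (method, N, waves, d) cell."""

    method: str
    N: int
    waves: int
    d: float
    n_reps: int
    n_converged: int
    n_reject: int
    seed: int
    flagged: bool = False

    @property
    def rejection_rate(self) -> float:
        return self.n_reject / self.n_converged if self.n_converged else float("nan")

    @property
    def mc_se(self) -> float:
        if not self.n_converged:
            return float("nan")
        r = self.rejection_rate
        return math.sqrt(r * (1.0 - r) / self.n_converged)

    def as_record(self) -> dict:
        return {
            "method": self.method, "N": self.N, "waves": self.waves,
            "d": self.d, "n_reps": self.n_reps,
            "n_converged": self.n_converged,
            "rejection_rate": self.rejection_rate, "mc_se": self.mc_se,
            "seed": self.seed,
        }


def cell_seed_sequence(master_seed: int, N: int, waves: int, d: float) -> np.random.SeedSequence:
    """Deterministic per-cell seed stream keyed by the cell coordinates."""
    return np.random.SeedSequence(
        entropy=master_seed, spawn_key=(N, waves, int(round(1000 * d)))
    )


def replicate_seed(cell_ss: np.random.SeedSequence, rep: int) -> int:
    """Integer seed of replicate ``rep`` within a cell (stable, < 2^31)."""
    child = np.random.SeedSequence(
        entropy=cell_ss.entropy, spawn_key=cell_ss.spawn_key + (rep,)
    )
    return int(child.generate_state(1, np.uint32)[0] % (2**31))


def run_replicate(
    design: StudyDesign,
    model: GeneratingModel,
    methods: tuple[str, ...],
    seed: int,
) -> dict[str, tuple[float, bool]]:
    """Generate one panel and extract the interaction p-value per method.

    The same dataset feeds every method.  A failed mixed-model fit marks
    only the MLM methods as non-converged (p = nan); it never raises.
    """
    data = simulate_dataset(design, model, seed)
    out: dict[str, tuple[float, bool]] = {}

    if {"rANOVA", "GG-rANOVA"} & set(methods):
        table = ranova.ranova_mixed(ranova.to_wide(data))
        row = table.row("session:group")
        if "rANOVA" in methods:
            out["rANOVA"] = (row.p, True)
        if "GG-rANOVA" in methods:
            out["GG-rANOVA"] = (row.p_gg, True)

    if {"MLM-z", "MLM-F"} & set(methods):
        try:
            fit = lmm.fit_lmm(data)
        except Exception:
            fit = None
        ok = fit is not None and fit.converged
        for name, test in (("MLM-z", lmm.wald_z), ("MLM-F", lmm.wald_f)):
            if name not in methods:
                continue
            if ok:
                try:
                    out[name] = (test(fit, INTERACTION).p, True)
                except ValueError:
                    out[name] = (float("nan"), False)
            else:
                out[name] = (float("nan"), False)
    return out


def run_cell(
    N: int,
    waves: int,
    d: float,
    n_reps: int = 2000,
    methods: tuple[str, ...] = METHODS,
    alpha: float = 0.05,
    master_seed: int = 0,
    base_model: GeneratingModel = DEFAULT_MODEL,
) -> list[PowerCell]:
    """Estimate rejection rates for one grid cell, all methods at once.

    Non-converged replicates are dropped from that method's denominator;
    a cell whose convergence rate falls below 50% is flagged and a
    warning is emitted.
    """
    design = StudyDesign(n_per_group=N // 2, n_waves=waves)
    model = make_generating_model(EffectSpec(d), base_model)
    cell_ss = cell_seed_sequence(master_seed, N, waves, d)
    cell_seed = int(cell_ss.generate_state(1, np.uint32)[0] % (2**31))

    counts = {m: [0, 0] for m in methods}  # method -> [n_converged, n_reject]
    for rep in range(n_reps):
        res = run_replicate(design, model, methods, replicate_seed(cell_ss, rep))
        for m, (p, ok) in res.items():
            if ok and np.isfinite(p):
                counts[m][0] += 1
                counts[m][1] += int(p < alpha)

    cells = []
    for m in methods:
        n_conv, n_rej = counts[m]
        flagged = n_conv < 0.5 * n_reps
        if flagged:
            warnings.warn(
                f"cell (method={m}, N={N}, waves={waves}, d={d}): only "
                f"{n_conv}/{n_reps} replicates converged", stacklevel=2,
            )
        cells.append(
            PowerCell(
                method=m, N=N, waves=waves, d=d, n_reps=n_reps,
                n_converged=n_conv, n_reject=n_rej, seed=cell_seed,
                flagged=flagged,
            )
        )
    return cells


def run_grid(spec: GridSpec) -> pd.DataFrame:
    """Run the full factorial grid; deterministic given ``master_seed``.

    Returns a tidy frame with one row per (method, N, waves, d) cell and
    columns method, N, waves, d, n_reps, n_converged, rejection_rate,
    mc_se, seed.
    """
    records = []
    for N in spec.sample_sizes:
        for w in spec.waves:
            for d in spec.effects:
                for cell in run_cell(
                    N, w, d, n_reps=spec.n_reps, methods=spec.methods,
                    alpha=spec.alpha, master_seed=spec.master_seed,
                    base_model=spec.base_model,
                ):
                    records.append(cell.as_record())
    columns = ["method", "N", "waves", "d", "n_reps", "n_converged",
               "rejection_rate", "mc_se", "seed"]
    return pd.DataFrame(records, columns=columns)


def plot_power_curves(results: pd.DataFrame, out_dir) -> list[str]:
    """Write one power-curve panel per (waves, d) combination.

    x-axis total N, y-axis rejection rate, one line per method; the d = 0
    panels show Type-I error with the nominal alpha marked.
    """
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (waves, d), panel in results.groupby(["waves", "d"]):
        fig, ax = plt.subplots(figsize=(5, 4))
        for method, grp in panel.groupby("method"):
            grp = grp.sort_values("N")
            ax.errorbar(
                grp["N"], grp["rejection_rate"], yerr=2 * grp["mc_se"],
                marker="o", capsize=3, label=method,
            )
        kind = "Type I error" if d == 0 else f"Power, d = {d:g}"
        ax.set_title(f"{kind} ({waves} waves)")
        ax.set_xlabel("total N")
        ax.set_ylabel("rejection rate at alpha = 0.05")
        if d == 0:
            ax.axhline(0.05, color="grey", ls="--", lw=1)
        ax.legend(fontsize=8)
        fig.tight_layout()
        name = f"power_waves{waves}_d{int(round(100 * d)):03d}.png"
        fig.savefig(out_dir / name, dpi=120)
        plt.close(fig)
        written.append(str(out_dir / name))
    return written
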