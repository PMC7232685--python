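"""Monte-Carlo operating characteristics: type-I error and power.

Type-I error is the fraction of null datasets (no genotype has any effect)
in which a pre-designated SNP pair is selected as the best two-way model;
under SNP exchangeability every pair is selected with probability
1/C(p, 2), so the reference rate with 8 SNPs is 1/28 ≈ 0.03577.  Power is
the fraction of datasets in which the truly causal pair is selected.  All
methods under comparison are evaluated on identical datasets and identical
fold assignments (a paired design that removes between-dataset Monte-Carlo
noise from method contrasts).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import engine, simulate
from .errors import InvalidInputError, KmmdrError
from .simulate import SimulationConfig

__all__ = [
    "OperatingPoint",
    "NULL_REFERENCE_RATE",
    "estimate_type1",
    "estimate_power",
    "paper_grid",
    "enumerate_grid",
    "sweep",
]

#: Designated-pair selection rate under uniform selection among C(8,2) pairs.
NULL_REFERENCE_RATE = 1.0 / 28.0


@dataclass(frozen=True)
class OperatingPoint:
    """One Monte-Carlo estimate of a selection rate."""

    method: str
    survival_model: str
    maf: float
    censoring_fraction: float
    gamma: float
    n_datasets: int
    estimate: float
    h2: float | None = None
    model_seed: int | None = None
    n_failed: int = 0

    @property
    def mc_stderr(self) -> float:
        if self.n_datasets == 0:
            return float("nan")
        return float(
            np.sqrt(self.estimate * (1 - self.estimate) / self.n_datasets)
        )


def _dataset_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _selected_pair(report: engine.SearchReport) -> tuple[str, str] | None:
    for r in report.results:
        if not r.skipped:
            return r.snps
    return None


def _null_bound(cfg: SimulationConfig) -> float | None:
    """Censoring bound for the null (x ≡ 0) generator, computed once."""
    if cfg.censoring_fraction == 0:
        return None
    gen = simulate._cox_latent if cfg.survival_model == "cox" else simulate._aft_latent
    return simulate.calibrate_censoring(
        cfg.censoring_fraction,
        lambda r, size: gen(r, np.zeros(size), np.zeros(size), cfg),
        seed=cfg.seed,
    )


def estimate_type1(
    method: str,
    maf: float,
    censoring_fraction: float,
    n_datasets: int,
    seed: int,
    n: int = 400,
    p: int = 8,
    survival_model: str = "cox",
    k: int = 10,
    selection_order: str = "test_score_first",
) -> OperatingPoint:
    """Designated-pair selection rate over null datasets.

    Each dataset has ``p`` non-causal SNPs; the designated pair is
    (SNP1, SNP2).  Datasets where the search yields no usable model (e.g.
    the KM median is not estimable in most folds) are excluded, with the
    exclusion count reported.
    """
    if n_datasets < 1:
        raise InvalidInputError("n_datasets must be at least 1")
    base = SimulationConfig(
        survival_model=survival_model, n=n, p=p, causal_pair=None,
        maf=maf, censoring_fraction=censoring_fraction, seed=seed,
    )
    base = replace(base, censoring_bound=_null_bound(base))
    designated = ("SNP1", "SNP2")
    hits = failed = 0
    for ds_seed in _dataset_seeds(seed, n_datasets):
        cfg = replace(base, seed=ds_seed)
        genotypes, sample, _ = simulate.build_dataset(cfg)
        try:
            folds = engine.make_folds(sample, k=k, seed=ds_seed)
            report = engine.run_cv(
                sample, genotypes, 2, method, folds,
                selection_order=selection_order, keep_classifications=False,
            )
        except KmmdrError:
            failed += 1
            continue
        pair = _selected_pair(report)
        if pair is None:
            failed += 1
        elif pair == designated:
            hits += 1
    used = n_datasets - failed
    return OperatingPoint(
        method=method, survival_model=survival_model, maf=maf,
        censoring_fraction=censoring_fraction, gamma=0.0,
        n_datasets=used, estimate=hits / used if used else float("nan"),
        n_failed=failed,
    )


def estimate_power(
    methods,
    scenario: SimulationConfig,
    n_datasets: int,
    seed: int,
    model_seed: int = 0,
    k: int = 10,
    selection_order: str = "test_score_first",
) -> dict[str, OperatingPoint]:
    """Causal-pair selection rate per method, on shared datasets and folds.

    ``methods`` may be a single method name or a sequence; the paired
    design evaluates every method on the identical dataset/fold stream.
    The scenario's penetrance model is generated once from
    (maf, h2, model_seed) and reused for all datasets.
    """
    if isinstance(methods, str):
        methods = (methods,)
    if scenario.causal_pair is None:
        raise InvalidInputError("power scenarios need a causal pair")
    pen = scenario.penetrance
    if pen is None:
        pen = simulate.generate_penetrance(scenario.maf, scenario.h2, seed=model_seed)
    base = replace(scenario, penetrance=pen)
    base = replace(base, censoring_bound=_censored_bound_power(base))
    causal = tuple(f"SNP{i + 1}" for i in sorted(base.causal_pair))

    hits = {m: 0 for m in methods}
    failed = {m: 0 for m in methods}
    for ds_seed in _dataset_seeds(seed, n_datasets):
        cfg = replace(base, seed=ds_seed)
        genotypes, sample, _ = simulate.build_dataset(cfg)
        folds = engine.make_folds(sample, k=k, seed=ds_seed)
        for m in methods:
            try:
                report = engine.run_cv(
                    sample, genotypes, 2, m, folds,
                    selection_order=selection_order, keep_classifications=False,
                )
                pair = _selected_pair(report)
            except KmmdrError:
                pair = None
            if pair is None:
                failed[m] += 1
            elif pair == causal:
                hits[m] += 1
    out = {}
    for m in methods:
        used = n_datasets - failed[m]
        out[m] = OperatingPoint(
            method=m, survival_model=base.survival_model, maf=base.maf,
            censoring_fraction=base.censoring_fraction, gamma=base.gamma,
            n_datasets=used, estimate=hits[m] / used if used else float("nan"),
            h2=base.h2, model_seed=model_seed, n_failed=failed[m],
        )
    return out


def _censored_bound_power(cfg: SimulationConfig) -> float | None:
    if cfg.censoring_fraction == 0:
        return None
    gen = simulate._cox_latent if cfg.survival_model == "cox" else simulate._aft_latent

    def sampler(r, size):
        x = simulate._marginal_x(r, size, cfg)
        z = r.standard_normal(size) if cfg.gamma != 0 else np.zeros(size)
        return gen(r, x, z, cfg)

    return simulate.calibrate_censoring(cfg.censoring_fraction, sampler, seed=cfg.seed)


# ---------------------------------------------------------------------------
# sweeps over the full factorial design
# ---------------------------------------------------------------------------

PAPER_H2 = (0.01, 0.025, 0.05, 0.1, 0.2, 0.3, 0.4)
PAPER_MAF = (0.2, 0.4)
PAPER_MODELS_PER_CELL = 5
PAPER_SURVIVAL_MODELS = ("cox", "aft")
PAPER_GAMMA = (0.0, 1.0)
PAPER_CENSORING = (0.0, 0.1, 0.3, 0.5)


def paper_grid() -> dict:
    """The full factorial power design: 70 penetrance models × 2 survival
    models × 2 covariate effects × 4 censoring fractions = 1,120 cells."""
    return {
        "maf": PAPER_MAF,
        "h2": PAPER_H2,
        "model_seed": tuple(range(PAPER_MODELS_PER_CELL)),
        "survival_model": PAPER_SURVIVAL_MODELS,
        "gamma": PAPER_GAMMA,
        "censoring_fraction": PAPER_CENSORING,
    }


def enumerate_grid(grid: dict) -> list[dict]:
    """Materialize a grid specification into its list of cells (no
    simulation is executed)."""
    keys = list(grid)
    return [
        dict(zip(keys, values))
        for values in itertools.product(*(grid[kk] for kk in keys))
    ]


def sweep(
    grid: dict,
    reps: int,
    seed: int,
    methods=("km",),
    n: int = 400,
    p: int = 10,
    k: int = 10,
) -> pd.DataFrame:
    """Run :func:`estimate_power` over every grid cell.

    Per-cell seeds are derived deterministically from the master seed, so
    an identical call reproduces the identical table.  Cell failures are
    recorded (``error`` column) and the sweep continues.
    """
    cells = enumerate_grid(grid)
    cell_seeds = _dataset_seeds(seed, len(cells))
    rows = []
    for cell, cseed in zip(cells, cell_seeds):
        scenario = SimulationConfig(
            survival_model=cell.get("survival_model", "cox"),
            n=n, p=p, causal_pair=(0, 1),
            maf=cell["maf"], h2=cell["h2"],
            gamma=cell.get("gamma", 0.0),
            censoring_fraction=cell.get("censoring_fraction", 0.0),
        )
        try:
            points = estimate_power(
                methods, scenario, reps, seed=cseed,
                model_seed=cell.get("model_seed", 0), k=k,
            )
            for m, pt in points.items():
                rows.append(
                    {**cell, "method": m, "n_datasets": pt.n_datasets,
                     "estimate": pt.estimate, "mc_stderr": pt.mc_stderr,
                     "n_failed": pt.n_failed, "error": ""}
                )
        except KmmdrError as exc:
            for m in methods if not isinstance(methods, str) else (methods,):
                rows.append({**cell, "method": m, "n_datasets": 0,
                             "estimate": float("nan"), "mc_stderr": float("nan"),
                             "n_failed": reps, "error": str(exc)})
    return pd.DataFrame(rows)
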