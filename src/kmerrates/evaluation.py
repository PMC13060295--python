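"""Replicate benchmarking harness.

For a fixed source sequence s and condition (k, r), the harness draws n
independent mutated copies t_i, runs the requested estimators on each
pair (s, t_i), and summarizes each estimator's replicate distribution
of r-hat by its mean, variance, and average relative absolute error

    (1/n) * sum_i |r_hat_i - r| / r,

the single-number accuracy metric that folds bias and variance
together.  In the blow-up regime (k*r large, all r_hat = 1) the metric
saturates at (1 - r)/r.

Seeding: replicate i of grid cell (k-index, r-index) draws its
substream from SeedSequence([base_seed, k_index, r_index, i]), so any
cell or replicate can be re-run in isolation, bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .estimators import ESTIMATOR_NAMES, EstimateResult, estimate_all, observe
from .kmer_core import build_spectrum, d1_table
from .mutation import MutationParams, mutate
from .sketching import (
    q_cc_theta,
    q_pc_theta,
    q_pp_theta,
    sketch_spectrum,
    sketched_observations,
)

SKETCHED_NAMES = ("pp", "pc", "cc")

DEFAULT_R_GRID = tuple(round(0.001 + 0.02 * i, 3) for i in range(13))  # 0.001..0.241
DEFAULT_K_GRID = (12, 16, 20, 24, 28, 32)


@dataclass(frozen=True)
class ExperimentConfig:
    k_values: Sequence[int] = DEFAULT_K_GRID
    r_values: Sequence[float] = DEFAULT_R_GRID
    n_replicates: int = 100
    theta: float = 1.0
    base_seed: int = 0
    estimators: Sequence[str] = ESTIMATOR_NAMES

    def __post_init__(self) -> None:
        rv = list(self.r_values)
        if any(not 0.0 < r < 1.0 for r in rv):
            raise ValueError("r values must lie in (0, 1); r = 0 has no relative error")
        if rv != sorted(set(rv)):
            raise ValueError("r values must be strictly increasing")


@dataclass(frozen=True)
class GridCell:
    k: int
    r: float
    estimator: str
    mean_rel_abs_error: float
    mean_r_hat: float
    var_r_hat: float
    n: int


def replicate_seed(base_seed: int, *indices: int) -> int:
    """Derive an independent 32-bit substream seed from structured indices."""
    ss = np.random.SeedSequence([base_seed, *indices])
    return int(ss.generate_state(1)[0])


def run_replicates(
    s: str,
    k: int,
    r: float,
    n: int,
    base_seed: int,
    theta: float = 1.0,
    estimators: Sequence[str] = ESTIMATOR_NAMES,
    k_index: int = 0,
    r_index: int = 0,
) -> List[Dict[str, EstimateResult]]:
    """Estimates for n independent mutation replicates of one condition.

    With ``theta < 1`` both spectra are FracMinHash-sketched before
    observation, each replicate with its own hash seed (the estimator
    names then refer to the sketched variants; only pp/pc/cc exist
    sketched).  Fully reproducible from (base_seed, k_index, r_index).
    """
    if theta < 1.0 and not set(estimators) <= set(SKETCHED_NAMES):
        raise ValueError(f"sketched runs support only {SKETCHED_NAMES}")
    spec_s = build_spectrum(s, k)
    need_cc = "cc" in estimators
    d1sum = d1_table(spec_s) if need_cc else None
    out: List[Dict[str, EstimateResult]] = []
    for i in range(n):
        mseed = replicate_seed(base_seed, k_index, r_index, i)
        t = mutate(s, MutationParams(r, mseed))
        spec_t = build_spectrum(t, k)
        if theta >= 1.0:
            obs = observe(spec_s, spec_t)
            out.append(estimate_all(obs, d1sum, estimators))
        else:
            hseed = replicate_seed(base_seed, k_index, r_index, i, 1)
            sk_s = sketch_spectrum(spec_s, theta, hseed)
            sk_t = sketch_spectrum(spec_t, theta, hseed)
            obs_th = sketched_observations(sk_s, sk_t)
            res: Dict[str, EstimateResult] = {}
            if "pp" in estimators:
                res["pp"] = q_pp_theta(obs_th, theta)
            if "pc" in estimators:
                res["pc"] = q_pc_theta(obs_th, theta)
            if need_cc:
                res["cc"] = q_cc_theta(obs_th, theta, d1sum)
            out.append(res)
    return out


def error_grid(s: str, config: ExperimentConfig) -> List[GridCell]:
    """Average relative absolute error per (k, r, estimator) cell."""
    cells: List[GridCell] = []
    for ki, k in enumerate(config.k_values):
        for ri, r in enumerate(config.r_values):
            reps = run_replicates(
                s, k, r, config.n_replicates, config.base_seed,
                theta=config.theta, estimators=config.estimators,
                k_index=ki, r_index=ri,
            )
            for name in config.estimators:
                r_hats = np.array([rep[name].r_hat for rep in reps])
                cells.append(
                    GridCell(
                        k=k, r=r, estimator=name,
                        mean_rel_abs_error=float(np.mean(np.abs(r_hats - r) / r)),
                        mean_r_hat=float(r_hats.mean()),
                        var_r_hat=float(r_hats.var(ddof=1)) if len(r_hats) > 1 else 0.0,
                        n=config.n_replicates,
                    )
                )
    return cells


def cells_to_frame(cells: List[GridCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "estimator": c.estimator, "k": c.k, "r": c.r,
                "mean_rel_abs_error": c.mean_rel_abs_error,
                "mean_r_hat": c.mean_r_hat, "var_r_hat": c.var_r_hat, "n": c.n,
            }
            for c in cells
        ]
    )


def summarize(cells: List[GridCell]) -> pd.DataFrame:
    """Pivot cells into an estimator x (k, r) error table."""
    df = cells_to_frame(cells)
    if df.empty:
        return df
    return df.pivot_table(
        index="estimator", columns=["k", "r"], values="mean_rel_abs_error"
    )


def write_cells(cells: List[GridCell], path, fmt: str = "tsv") -> None:
    df = cells_to_frame(cells)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        df.to_json(path, orient="records", indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_cells(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
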