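"""Synthetic measurement tables for pipeline testing and parameter recovery.

Tables are generated from a known coefficient vector of the response
surface plus additive homoscedastic Gaussian noise in nA — the statistical
structure the calibration assumes. The default noise level (0.05 nA) is of
the same order as the residual scale of the reference calibration on the
measured runs.

The surface is not fully identifiable from coefficients alone: the offset
a0 trades off against the buffer power term (a3, a4), so two different
coefficient vectors can define near-identical surfaces over the measured
ranges. Recovery is therefore judged on predictions (surface RMSE on a
held-out grid), never on coefficient identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .calibrate import FitConfiguration, FitResult, fit
from .doe import build_l9, expand_full_factorial
from .model import CoefficientVector, OverflowSignal, evaluate_table

__all__ = [
    "SimulationSpecification",
    "RecoveryReport",
    "simulate_table",
    "recovery_experiment",
    "sample_generator_coefficients",
    "held_out_grid",
]

DesignName = Literal["l9", "factorial27"]


@dataclass(frozen=True)
class SimulationSpecification:
    """What to simulate: generator surface, design, noise, replication."""

    coefficients: CoefficientVector
    design: DesignName | pd.DataFrame = "l9"
    noise_sd: float = 0.05  # nA
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise standard deviation must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per condition")

    def conditions(self) -> pd.DataFrame:
        if isinstance(self.design, pd.DataFrame):
            cond = self.design[["ca_mM", "cb_mM", "ph"]].copy()
        elif self.design == "l9":
            cond = build_l9().realize()[["ca_mM", "cb_mM", "ph"]]
        elif self.design == "factorial27":
            cond = expand_full_factorial()
        else:
            raise ValueError(f"unknown design {self.design!r}")
        if np.any(cond["cb_mM"].to_numpy(dtype=float) <= 0) or np.any(
            cond["ph"].to_numpy(dtype=float) <= 0
        ):
            raise ValueError("all conditions need cb > 0 and ph > 0")
        return cond


def simulate_table(
    spec: SimulationSpecification, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate a measurement table: surface value + N(0, noise_sd) per replicate.

    ``test_id`` is sequential from 1. A generator vector that overflows at
    any design point is a specification error naming the point.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cond = spec.conditions()
    cond = pd.concat([cond] * spec.replicates, ignore_index=True)
    try:
        truth = evaluate_table(spec.coefficients, cond)
    except OverflowSignal as sig:
        raise ValueError(
            f"generator coefficients overflow on the design ({sig})"
        ) from sig
    noise = rng.normal(0.0, spec.noise_sd, size=len(cond)) if spec.noise_sd > 0 else 0.0
    table = cond.copy()
    table.insert(0, "test_id", np.arange(1, len(cond) + 1))
    table["ef_nA"] = truth + noise
    return table


def held_out_grid(resolution: int = 5) -> pd.DataFrame:
    """Evaluation grid for recovery: urea 0-10 mM, buffer 0.01-0.5 mM, pH 5-8."""
    ca = np.linspace(0.0, 10.0, resolution)
    cb = np.linspace(0.01, 0.5, resolution)
    ph = np.linspace(5.0, 8.0, resolution)
    ca_g, cb_g, ph_g = np.meshgrid(ca, cb, ph, indexing="ij")
    return pd.DataFrame({"ca_mM": ca_g.ravel(), "cb_mM": cb_g.ravel(), "ph": ph_g.ravel()})


@dataclass(frozen=True)
class RecoveryReport:
    """How well a fit to synthetic data recovered the generator surface."""

    surface_rmse: float  # nA, fitted vs generator on the held-out grid
    design_rmse: float  # nA, fitted vs generator on the design points
    coefficient_deltas: np.ndarray  # fitted - generator, reference only
    fit_result: FitResult = field(repr=False)
    table: pd.DataFrame = field(repr=False)


def recovery_experiment(
    spec: SimulationSpecification,
    fit_config: FitConfiguration | None = None,
    grid_resolution: int = 5,
) -> RecoveryReport:
    """Simulate, refit, and score surface agreement on a held-out grid."""
    table = simulate_table(spec)
    result = fit(table, fit_config)
    grid = held_out_grid(grid_resolution)
    truth = evaluate_table(spec.coefficients, grid)
    fitted = evaluate_table(result.coefficients, grid)
    truth_d = evaluate_table(spec.coefficients, table)
    fitted_d = evaluate_table(result.coefficients, table)
    return RecoveryReport(
        surface_rmse=float(np.sqrt(np.mean((fitted - truth) ** 2))),
        design_rmse=float(np.sqrt(np.mean((fitted_d - truth_d) ** 2))),
        coefficient_deltas=result.coefficients.as_array() - spec.coefficients.as_array(),
        fit_result=result,
        table=table,
    )


def sample_generator_coefficients(
    rng: np.random.Generator, max_abs_current: float = 10.0
) -> CoefficientVector:
    """Draw a random well-conditioned generator vector.

    Coefficients are sampled from moderate ranges (offset and term scales
    within a few nA, exponents within [-2, 2], urea slope within +-1
    nA/mM). A draw is accepted only if, over the held-out grid, the total
    surface and each individual term stay within ``max_abs_current``:
    measured biosensor currents are on the ~1 nA scale, and bounding the
    terms individually excludes surfaces built from huge mutually
    cancelling contributions that no measurement of this system could
    exhibit.
    """
    grid = held_out_grid(5)
    ca = grid["ca_mM"].to_numpy()
    cb = grid["cb_mM"].to_numpy()
    ph = grid["ph"].to_numpy()
    for _ in range(1000):
        a = np.array(
            [
                rng.uniform(-5, 5),
                rng.uniform(-3, 3),
                rng.uniform(-2, 2),
                rng.uniform(-5, 5),
                rng.uniform(-2, 2),
                rng.uniform(-1, 1),
            ]
        )
        coeffs = CoefficientVector.from_array(a)
        try:
            surf = evaluate_table(coeffs, grid)
        except OverflowSignal:
            continue
        term_ph = a[1] * ph ** a[2]
        term_cb = a[3] * cb ** a[4]
        if (
            np.max(np.abs(surf)) <= max_abs_current
            and np.max(np.abs(term_ph)) <= max_abs_current
            and np.max(np.abs(term_cb)) <= max_abs_current
        ):
            return coeffs
    raise RuntimeError("failed to draw a well-conditioned generator vector")
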