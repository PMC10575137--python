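"""Taguchi L9(3^3) design of experiments and main-effects analysis.

Three factors at three levels each would need 27 factorial runs; the L9
orthogonal array covers them with 9 runs in which every ordered pair of
levels of every pair of factors occurs exactly once. Main effects (factor
level means relative to the grand mean) are then estimable from the 9 runs,
and the 18 unrun factorial cells can be predicted additively.

The default factors are the calibration study's levels: urea 0.5/1/1.5 mM,
phosphate buffer 0.05/0.1/0.25 mM, pH 5.5/6/6.5.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "OrthogonalDesign",
    "MainEffects",
    "OrthogonalityReport",
    "BalanceError",
    "default_factors",
    "build_l9",
    "validate_orthogonality",
    "expand_full_factorial",
    "unrun_cells",
    "main_effects",
    "predict_additive",
]

#: Column names of a measurement table, by factor order (ca, cb, ph).
FACTOR_COLUMNS = ("ca_mM", "cb_mM", "ph")


@dataclass(frozen=True)
class FactorSpec:
    """A three-level experimental factor."""

    name: str
    unit: str
    levels: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError(f"factor {self.name!r} must have exactly 3 levels")
        lv = tuple(float(x) for x in self.levels)
        if not (lv[0] < lv[1] < lv[2]):
            raise ValueError(f"levels of {self.name!r} must be strictly increasing")
        object.__setattr__(self, "levels", lv)


def default_factors() -> tuple[FactorSpec, FactorSpec, FactorSpec]:
    """Factor levels of the urea biosensor calibration study."""
    return (
        FactorSpec("ca_mM", "mM", (0.5, 1.0, 1.5)),
        FactorSpec("cb_mM", "mM", (0.05, 0.1, 0.25)),
        FactorSpec("ph", "pH", (5.5, 6.0, 6.5)),
    )


@dataclass(frozen=True)
class OrthogonalDesign:
    """An L9 assignment of level indices (0..2) for three factors."""

    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    rows: tuple[tuple[int, int, int], ...]

    def realize(self) -> pd.DataFrame:
        """Map level indices to level values; adds 1-based ``test_id``."""
        data = {
            "test_id": np.arange(1, len(self.rows) + 1),
        }
        for j, f in enumerate(self.factors):
            data[f.name] = [f.levels[r[j]] for r in self.rows]
        return pd.DataFrame(data)

    def condition_triples(self) -> set[tuple[float, float, float]]:
        return {
            tuple(f.levels[r[j]] for j, f in enumerate(self.factors))
            for r in self.rows
        }


def build_l9(factors: Sequence[FactorSpec] | None = None) -> OrthogonalDesign:
    """Construct the L9(3^3) orthogonal array over three 3-level factors.

    The array is the affine lattice ``(i, j, (i + j + 1) mod 3)`` over
    GF(3), the realization whose runs coincide with the calibration study's
    measured design. Orthogonality holds by construction: for fixed values
    of any two coordinates the third is determined, so each ordered level
    pair of each column pair occurs exactly once.
    """
    if factors is None:
        factors = default_factors()
    factors = tuple(factors)
    if len(factors) != 3:
        raise ValueError(f"L9 requires exactly 3 factors, got {len(factors)}")
    for f in factors:
        if not isinstance(f, FactorSpec):
            raise TypeError("factors must be FactorSpec instances")
    rows = tuple(
        (i, j, (i + j + 1) % 3) for i, j in itertools.product(range(3), repeat=2)
    )
    return OrthogonalDesign(factors=factors, rows=rows)


@dataclass(frozen=True)
class OrthogonalityReport:
    """Per column pair, the count of each ordered level-index pair."""

    pair_counts: Mapping[tuple[int, int], Mapping[tuple[int, int], int]]
    passed: bool
    failures: tuple[str, ...] = ()


def validate_orthogonality(design: OrthogonalDesign) -> OrthogonalityReport:
    """Count level pairs per column pair; pass iff every count is exactly 1."""
    pair_counts: dict[tuple[int, int], dict[tuple[int, int], int]] = {}
    failures: list[str] = []
    for c1, c2 in itertools.combinations(range(3), 2):
        counts = {lp: 0 for lp in itertools.product(range(3), repeat=2)}
        for r in design.rows:
            counts[(r[c1], r[c2])] += 1
        pair_counts[(c1, c2)] = counts
        for lp, cnt in counts.items():
            if cnt != 1:
                failures.append(
                    f"columns ({c1},{c2}): level pair {lp} occurs {cnt} times (expected 1)"
                )
    return OrthogonalityReport(
        pair_counts=pair_counts, passed=not failures, failures=tuple(failures)
    )


def expand_full_factorial(factors: Sequence[FactorSpec] | None = None) -> pd.DataFrame:
    """All 27 factorial condition triples, ca outer, cb middle, ph inner."""
    if factors is None:
        factors = default_factors()
    factors = tuple(factors)
    if len(factors) != 3:
        raise ValueError(f"expected exactly 3 factors, got {len(factors)}")
    rows = list(itertools.product(*(f.levels for f in factors)))
    return pd.DataFrame(rows, columns=[f.name for f in factors])


def unrun_cells(design: OrthogonalDesign) -> pd.DataFrame:
    """The 18 factorial cells not covered by the design.

    ``test_id`` continues from the design (10..27), assigned in the
    deterministic factorial row order.
    """
    full = expand_full_factorial(design.factors)
    run = design.condition_triples()
    mask = [tuple(row) not in run for row in full.itertuples(index=False)]
    out = full[mask].reset_index(drop=True)
    out.insert(0, "test_id", np.arange(len(design.rows) + 1, len(design.rows) + 1 + len(out)))
    return out


@dataclass(frozen=True)
class MainEffects:
    """Grand mean and per-factor level means of the response (nA)."""

    grand_mean: float
    level_means: Mapping[str, Mapping[float, float]]
    factors: tuple[FactorSpec, ...] = field(default=())


class BalanceError(ValueError):
    """The measurement table is not a balanced L9 realization."""


def main_effects(
    table: pd.DataFrame, factors: Sequence[FactorSpec] | None = None
) -> MainEffects:
    """Grand mean and level means of ``ef_nA`` from a balanced L9 table.

    Each level of each factor must appear in exactly ``n/3`` rows; an
    unbalanced table raises :class:`BalanceError` naming the offending
    factor level.
    """
    if factors is None:
        factors = default_factors()
    factors = tuple(factors)
    ef = table["ef_nA"].to_numpy(dtype=float)
    per_level = len(table) / 3
    level_means: dict[str, dict[float, float]] = {}
    for f in factors:
        col = table[f.name].to_numpy(dtype=float)
        means: dict[float, float] = {}
        for level in f.levels:
            sel = col == level
            if int(sel.sum()) != per_level:
                raise BalanceError(
                    f"factor {f.name!r} level {level} appears {int(sel.sum())} times, "
                    f"expected {per_level:g}"
                )
        # second pass only after the whole factor is validated
        for level in f.levels:
            means[level] = float(ef[col == level].mean())
        level_means[f.name] = means
    return MainEffects(
        grand_mean=float(ef.mean()), level_means=level_means, factors=factors
    )


def predict_additive(
    effects: MainEffects, condition: Sequence[float]
) -> float:
    """Additive main-effects prediction at a factorial condition (nA).

    Returns ``grand_mean + sum_f (level_mean_f - grand_mean)``. The
    condition is (ca, cb, ph) and every value must be one of the factor's
    levels.
    """
    if len(condition) != len(effects.factors):
        raise ValueError("condition length must match number of factors")
    pred = effects.grand_mean
    for f, value in zip(effects.factors, condition):
        means = effects.level_means[f.name]
        if float(value) not in means:
            raise ValueError(
                f"{value!r} is not a level of factor {f.name!r} (levels: {f.levels})"
            )
        pred += means[float(value)] - effects.grand_mean
    return pred


def predict_additive_table(
    effects: MainEffects, conditions: pd.DataFrame
) -> pd.DataFrame:
    """Additive predictions for every row of a condition table."""
    out = conditions.copy()
    out["ef_nA"] = [
        predict_additive(effects, tuple(row))
        for row in conditions[[f.name for f in effects.factors]].itertuples(index=False)
    ]
    return out
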