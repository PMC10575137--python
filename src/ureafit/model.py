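"""Parametric response surface for urea biofuel-cell current.

The measured current ``EF`` (nA) of a urease-based biofuel cell is modelled
as a function of urea concentration ``Ca`` (mM), phosphate-buffer
concentration ``Cb`` (mM) and electrolyte pH::

    EF = a0 + a1 * pH**a2 + a3 * Cb**a4 + a5 * Ca

Urea enters linearly (a5, nA/mM); pH and buffer enter through power terms
whose exponents are free parameters. Because the fitted exponents may be
negative or fractional, ``Cb`` and ``pH`` must be strictly positive; urea
may be zero.

:data:`REFERENCE_COEFFS` is the published reference calibration of this
sensor system; it reproduces the measured calibration runs 1, 3 and 6 to
better than 0.005 nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "CoefficientVector",
    "ErrorReport",
    "OverflowSignal",
    "REFERENCE_COEFFS",
    "COEFF_BOUND",
    "evaluate",
    "evaluate_table",
    "evaluate_grid",
    "error_report",
]

#: Coefficient search range used throughout calibration: each of a0..a5 is
#: confined to [-COEFF_BOUND, COEFF_BOUND].
COEFF_BOUND = 100.0

#: Exponent magnitude beyond which exp() would overflow a float64.
_EXP_GUARD = 700.0


class OverflowSignal(FloatingPointError):
    """A power term's exponent ``|a * ln(base)|`` exceeded the float64 range.

    Carries ``exponent`` so fitting objectives can rank the violation.
    """

    def __init__(self, term: str, exponent: float):
        super().__init__(f"power term {term} overflows: |exponent| = {abs(exponent):.3g}")
        self.term = term
        self.exponent = exponent


class Condition(NamedTuple):
    """A single operating condition of the cell."""

    ca: float  #: urea concentration, mM (>= 0)
    cb: float  #: buffer concentration, mM (> 0)
    ph: float  #: electrolyte pH (> 0)

    def validate(self) -> "Condition":
        if not (self.ca >= 0):
            raise ValueError(f"urea concentration must be >= 0, got {self.ca}")
        if not (self.cb > 0):
            raise ValueError(f"buffer concentration must be > 0, got {self.cb}")
        if not (self.ph > 0):
            raise ValueError(f"pH must be > 0, got {self.ph}")
        return self


@dataclass(frozen=True)
class CoefficientVector:
    """The six response-surface coefficients a0..a5.

    a0 is the offset (nA); (a1, a2) scale and shape the pH power term;
    (a3, a4) the buffer power term; a5 is the urea slope (nA/mM).
    """

    a0: float
    a1: float
    a2: float
    a3: float
    a4: float
    a5: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("coefficients must all be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.a3, self.a4, self.a5], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "CoefficientVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (6,):
            raise ValueError(f"expected 6 coefficients, got shape {arr.shape}")
        return cls(*arr.tolist())

    def in_bounds(self, bound: float = COEFF_BOUND) -> bool:
        return bool(np.all(np.abs(self.as_array()) <= bound))

    def to_dict(self) -> dict:
        return {f"a{i}": v for i, v in enumerate(self.as_array())}

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientVector":
        return cls(*(float(d[f"a{i}"]) for i in range(6)))


#: Reference calibration of the sensor system (current in nA).
REFERENCE_COEFFS = CoefficientVector(
    2.43222, 0.30658, 0.866196, -3.3403528, 0.0580531, -0.044922
)


def evaluate(coeffs: CoefficientVector, condition: Condition) -> float:
    """Evaluate the response surface at one condition.

    Raises :class:`OverflowSignal` if a power term would overflow and
    ``ValueError`` for out-of-domain conditions (cb <= 0 or ph <= 0).
    """
    ca, cb, ph = Condition(*condition).validate()
    a = coeffs
    exp_ph = a.a2 * math.log(ph)
    if abs(exp_ph) > _EXP_GUARD:
        raise OverflowSignal("a1*pH^a2", exp_ph)
    exp_cb = a.a4 * math.log(cb)
    if abs(exp_cb) > _EXP_GUARD:
        raise OverflowSignal("a3*Cb^a4", exp_cb)
    return a.a0 + a.a1 * math.exp(exp_ph) + a.a3 * math.exp(exp_cb) + a.a5 * ca


def evaluate_table(coeffs: CoefficientVector, table: pd.DataFrame) -> np.ndarray:
    """Vectorized surface evaluation over a measurement table's conditions.

    ``table`` needs columns ``ca_mM``, ``cb_mM``, ``ph``. Domain and
    overflow rules match :func:`evaluate`.
    """
    ca = table["ca_mM"].to_numpy(dtype=float)
    cb = table["cb_mM"].to_numpy(dtype=float)
    ph = table["ph"].to_numpy(dtype=float)
    if np.any(ca < 0):
        raise ValueError("urea concentration must be >= 0")
    if np.any(cb <= 0):
        raise ValueError("buffer concentration must be > 0")
    if np.any(ph <= 0):
        raise ValueError("pH must be > 0")
    a = coeffs
    exp_ph = a.a2 * np.log(ph)
    exp_cb = a.a4 * np.log(cb)
    for name, e in (("a1*pH^a2", exp_ph), ("a3*Cb^a4", exp_cb)):
        bad = np.abs(e) > _EXP_GUARD
        if np.any(bad):
            raise OverflowSignal(name, float(e[bad][np.argmax(np.abs(e[bad]))]))
    return a.a0 + a.a1 * np.exp(exp_ph) + a.a3 * np.exp(exp_cb) + a.a5 * ca


def evaluate_grid(
    coeffs: CoefficientVector,
    ca_range: Iterable[float],
    cb_range: Iterable[float],
    ph_range: Iterable[float],
) -> pd.DataFrame:
    """Evaluate the surface on the Cartesian grid of the given axis values.

    Returns a DataFrame with columns ``ca_mM, cb_mM, ph, ef_nA``; row order
    is ca outer, cb middle, ph inner.
    """
    ca_v = np.asarray(list(ca_range), dtype=float)
    cb_v = np.asarray(list(cb_range), dtype=float)
    ph_v = np.asarray(list(ph_range), dtype=float)
    ca_g, cb_g, ph_g = np.meshgrid(ca_v, cb_v, ph_v, indexing="ij")
    grid = pd.DataFrame(
        {"ca_mM": ca_g.ravel(), "cb_mM": cb_g.ravel(), "ph": ph_g.ravel()}
    )
    grid["ef_nA"] = evaluate_table(coeffs, grid)
    return grid


@dataclass(frozen=True)
class ErrorReport:
    """Residual diagnostics of a coefficient vector against measured data.

    Residuals are model minus measurement, in nA.
    """

    residuals: np.ndarray
    rmse: float
    mae: float
    max_abs_error: float
    n: int

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))


def error_report(coeffs: CoefficientVector, table: pd.DataFrame) -> ErrorReport:
    """Residuals and summary error metrics of ``coeffs`` on a measurement table."""
    if len(table) == 0:
        raise ValueError("measurement table is empty")
    pred = evaluate_table(coeffs, table)
    resid = pred - table["ef_nA"].to_numpy(dtype=float)
    return ErrorReport(
        residuals=resid,
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        max_abs_error=float(np.max(np.abs(resid))),
        n=len(resid),
    )
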