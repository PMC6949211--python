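"""Orifice power-law pressure-loss model: prediction, fitting, scaling, units.

The loss across a severe lumen constriction behaves like an orifice plate:

    dP = 1/2 * rho * K * (Q / A_C)**n

with Q the volumetric flowrate, A_C the minimum (constriction) area, K a
dimensionless loss coefficient and n an exponent close to 2.  Because the
published loss data never state the air density, every fit also reports the
product K*rho, which is what the data actually constrain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UnknownUnitError

__all__ = [
    "PowerLawModel",
    "FitResult",
    "K_ORIFICE_REFERENCE",
    "predict_dp",
    "fit_powerlaw",
    "scale_loss",
    "scale_resistance",
    "convert_resistance",
    "area_ratio_exponent",
    "read_fit_pairs_csv",
]

#: Loss coefficient proposed by Brouns et al. (J. Biomech. 2007) as a single
#: reasonable fit across a range of idealized tracheal stenosis severities.
K_ORIFICE_REFERENCE = 1.2

_CMH2O_PA = 98.0665  # Pa per cm H2O
_ML_PER_L = 1000.0


@dataclass
class PowerLawModel:
    """dP = 1/2 rho K (Q/A_C)^n with A_C in mm**2, rho in kg/m**3."""

    K: float
    n: float
    A_C: float  # mm**2
    rho: float  # kg/m**3

    def __post_init__(self) -> None:
        if self.K < 0 or self.A_C <= 0 or self.rho <= 0:
            raise InvalidInputError("require K >= 0, A_C > 0, rho > 0")


@dataclass
class FitResult:
    model: PowerLawModel
    per_point_relative_error: np.ndarray = field(repr=False)
    max_relative_error: float = 0.0

    @property
    def K_rho(self) -> float:
        """The density/coefficient product actually constrained by the data."""
        return self.model.K * self.model.rho


def predict_dp(model: PowerLawModel, Q: float | np.ndarray) -> float | np.ndarray:
    """Predicted pressure loss (Pa) at flowrate Q (mL/s)."""
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise InvalidInputError("flowrate must be non-negative")
    # mL/s -> m**3/s and mm**2 -> m**2; the throat velocity Q/A_C is in m/s
    v_throat = (Q * 1e-6) / (model.A_C * 1e-6)
    dp = 0.5 * model.rho * model.K * v_throat**model.n
    return float(dp) if dp.ndim == 0 else dp


def fit_powerlaw(
    pairs: Sequence[tuple[float, float]],
    A_C: float,
    rho: float,
    fixed_n: float | None = None,
) -> FitResult:
    """Fit (K, n) or K alone to (Q [mL/s], dP [Pa]) pairs.

    With ``fixed_n`` the single remaining parameter K is obtained by
    relative-error least squares (minimising sum((pred/obs - 1)**2)), the
    natural criterion when quality is quoted as a percentage error across
    flowrates.  With n free, an ordinary least-squares line is fitted to
    log dP versus log Q.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError("pairs must be (Q, dP) tuples")
    Q, dp = arr[:, 0], arr[:, 1]
    if np.any(Q <= 0) or np.any(dp <= 0):
        raise InvalidInputError("flowrates and losses must be positive")
    min_pts = 2 if fixed_n is not None else 3
    if len(arr) < min_pts:
        raise InvalidInputError(f"need >= {min_pts} pairs")

    v = (Q * 1e-6) / (A_C * 1e-6)  # throat velocity, m/s
    if fixed_n is not None:
        c = 0.5 * rho * v**fixed_n  # dp = K * c
        r = c / dp
        K = float(np.sum(r) / np.sum(r**2))
        n = float(fixed_n)
    else:
        slope, intercept = np.polyfit(np.log(v), np.log(dp), 1)
        n = float(slope)
        K = float(np.exp(intercept) / (0.5 * rho))
    model = PowerLawModel(K=K, n=n, A_C=A_C, rho=rho)
    rel = np.abs(predict_dp(model, Q) / dp - 1.0)
    return FitResult(model=model, per_point_relative_error=rel,
                     max_relative_error=float(rel.max()))


def scale_loss(dp: float, Q_from: float, Q_to: float, n: float) -> float:
    """Scale a pressure loss to another flowrate: dp * (Q_to/Q_from)**n."""
    if Q_from <= 0 or Q_to <= 0:
        raise InvalidInputError("flowrates must be positive")
    return dp * (Q_to / Q_from) ** n


def scale_resistance(R: float, Q_from: float, Q_to: float, exponent: float) -> float:
    """Scale a resistance by the flowrate ratio raised to ``exponent``.

    This follows the published convention of applying the full orifice
    exponent (2 for a simple orifice plate) directly to R = dP/Q, not the
    R ~ Q**(n-1) relation the power law itself would imply.
    """
    if Q_from <= 0 or Q_to <= 0:
        raise InvalidInputError("flowrates must be positive")
    return R * (Q_to / Q_from) ** exponent


def convert_resistance(value: float, from_unit: str, to_unit: str) -> float:
    """Convert airway resistance between Pa.mL**-1.s and cmH2O.L**-1.s."""
    units = {"Pa/(mL/s)": 1.0, "cmH2O/(L/s)": _CMH2O_PA / _ML_PER_L}
    aliases = {
        "Pa/(mL/s)": "Pa/(mL/s)",
        "Pa.mL-1.s": "Pa/(mL/s)",
        "Pa mL-1 s": "Pa/(mL/s)",
        "cmH2O/(L/s)": "cmH2O/(L/s)",
        "cmH2O.L-1.s": "cmH2O/(L/s)",
        "cmH2O L-1 s": "cmH2O/(L/s)",
    }
    try:
        f = units[aliases[from_unit]]
        t = units[aliases[to_unit]]
    except KeyError as err:
        raise UnknownUnitError(f"unknown resistance unit {err.args[0]!r}") from None
    return value * f / t


def area_ratio_exponent(R_ratio: float, A_ratio: float) -> float:
    """Exponent m such that R_ratio = A_ratio**m, i.e. ln(R_ratio)/ln(A_ratio).

    Used to check how a resistance ratio scales with the reciprocal of a
    constriction area ratio (m = 2 for a pure orifice).
    """
    if R_ratio <= 0 or A_ratio <= 0:
        raise InvalidInputError("ratios must be positive")
    if A_ratio == 1.0:
        raise InvalidInputError("undefined exponent: area ratio is 1")
    return float(np.log(R_ratio) / np.log(A_ratio))


def read_fit_pairs_csv(path) -> list[tuple[float, float]]:
    """Read (Q, dP) fit input from CSV columns Q_Lmin,dP_Pa; Q returned in mL/s."""
    df = pd.read_csv(path)
    missing = {"Q_Lmin", "dP_Pa"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    q_mls = df["Q_Lmin"].to_numpy(float) * _ML_PER_L / 60.0
    return list(zip(q_mls.tolist(), df["dP_Pa"].to_numpy(float).tolist()))
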