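"""Station-wise energy flux, cumulative loss, and resistance profiles.

The mean energy flux through a plane is the surface integral of normal
velocity times total pressure (static plus dynamic).  Its streamwise
decrease from the inlet measures the accumulated viscous dissipation; no
pointwise dissipation field is needed, only plane samples.

Two averaging conventions are provided:

``mean_field``
    integral of the product of time-averaged total pressure and
    time-averaged normal velocity — the practical convention when only
    mean fields are stored;
``full_average``
    time mean of the instantaneous per-snapshot integrals.

They coincide exactly on steady fields; their difference on fluctuating
fields is the neglected turbulent transport term, exposed by
:func:`turbulent_transport_flux` rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConservationError, InvalidInputError
from .sampling import MeanPlaneField, PlaneSampleSeries, plane_flowrate, time_average

__all__ = [
    "EnergyFluxProfile",
    "ResistanceProfile",
    "energy_flux",
    "turbulent_transport_flux",
    "cumulative_loss",
    "resistance_profile",
    "mean_total_pressure",
    "write_energy_csv",
    "write_resistance_csv",
]

_MM2_TO_M2 = 1e-6  # plane integrals in mm**2 * (m/s) * Pa -> W


@dataclass
class EnergyFluxProfile:
    """Mean energy flux E_F (W) and cumulative loss E_F(inlet) - E_F(x) per station."""

    x: np.ndarray  # mm
    E_F: np.ndarray  # W
    cumulative_loss: np.ndarray  # W
    rho: float  # kg/m**3

    def __post_init__(self) -> None:
        if abs(self.cumulative_loss[0]) > 1e-12 * max(1.0, abs(self.E_F[0])):
            raise InvalidInputError("cumulative loss must vanish at the inlet")


@dataclass
class ResistanceProfile:
    """Resistance R(x) = (<P_tot>_inlet - <P_tot>_x) / Q in Pa.mL**-1.s."""

    x: np.ndarray  # mm
    R: np.ndarray  # Pa / (mL/s)
    Q: float  # mL/s
    pressure_convention: str = "area-averaged mean total pressure"


def _mean_field_flux(field: MeanPlaneField, rho: float) -> float:
    un = field.mean_velocity @ field.section.normal
    total_p = field.mean_pressure + 0.5 * rho * np.sum(field.mean_velocity**2, axis=1)
    return float(np.sum(field.weights * un * total_p) * _MM2_TO_M2)


def _snapshot_flux(snap, rho: float) -> float:
    un = snap.velocity @ snap.section.normal
    total_p = snap.pressure + 0.5 * rho * np.sum(snap.velocity**2, axis=1)
    return float(np.sum(snap.weights * un * total_p) * _MM2_TO_M2)


def energy_flux(
    field: MeanPlaneField | PlaneSampleSeries,
    rho: float,
    mode: str = "mean_field",
    discard_before: float = 0.0,
) -> float:
    """Mean energy flux through one plane, in watts.

    ``mean_field`` accepts either a :class:`MeanPlaneField` or a series
    (averaged internally); ``full_average`` needs the full series.
    """
    if rho <= 0:
        raise InvalidInputError("rho must be positive")
    if mode == "mean_field":
        if isinstance(field, PlaneSampleSeries):
            field = time_average(field, discard_before)
        return _mean_field_flux(field, rho)
    if mode == "full_average":
        if not isinstance(field, PlaneSampleSeries):
            raise InvalidInputError("full_average mode needs a PlaneSampleSeries")
        kept = [s for s in field.snapshots if s.time >= discard_before]
        if not kept:
            raise InvalidInputError("all snapshots discarded")
        return float(np.mean([_snapshot_flux(s, rho) for s in kept]))
    raise InvalidInputError(f"unknown energy-flux mode {mode!r}")


def turbulent_transport_flux(
    series: PlaneSampleSeries, rho: float, discard_before: float = 0.0
) -> float:
    """Energy flux carried by fluctuations: full_average minus mean_field (W)."""
    return energy_flux(series, rho, "full_average", discard_before) - energy_flux(
        series, rho, "mean_field", discard_before
    )


def _check_flowrates(fields: list[MeanPlaneField], tol: float) -> float:
    q = np.array([plane_flowrate(f) for f in fields])
    q_ref = float(np.mean(q))
    if q_ref == 0:
        raise InvalidInputError("zero mean flowrate")
    spread = float(np.max(np.abs(q - q_ref)) / abs(q_ref))
    if spread > tol:
        raise ConservationError(
            f"plane flowrates differ by {spread:.2%} (> {tol:.0%}): {q}"
        )
    return q_ref


def cumulative_loss(
    fields: list[MeanPlaneField],
    rho: float,
    mode: str = "mean_field",
    q_tol: float = 0.01,
) -> EnergyFluxProfile:
    """Energy-flux profile and cumulative loss from the first (inlet) station.

    Fields must share one flowrate within ``q_tol`` (mass conservation);
    the slope of the cumulative loss is the local mean dissipation rate.
    """
    if len(fields) < 2:
        raise InvalidInputError("need >= 2 stations")
    fields = sorted(fields, key=lambda f: f.section.station)
    _check_flowrates(fields, q_tol)
    x = np.array([f.section.station for f in fields])
    ef = np.array([energy_flux(f, rho, mode) for f in fields])
    return EnergyFluxProfile(x=x, E_F=ef, cumulative_loss=ef[0] - ef, rho=rho)


def mean_total_pressure(field: MeanPlaneField, rho: float) -> float:
    """Area-weighted mean of the time-mean total pressure on a plane (Pa)."""
    total_p = field.mean_pressure + 0.5 * rho * np.sum(field.mean_velocity**2, axis=1)
    return float(np.sum(field.weights * total_p) / np.sum(field.weights))


def resistance_profile(
    fields: list[MeanPlaneField],
    rho: float,
    Q: float | None = None,
) -> ResistanceProfile:
    """Resistance profile from area-averaged mean total pressure.

    R(x) = (<P_tot>(inlet) - <P_tot>(x)) / Q with Q in mL/s, so R is in
    Pa.mL**-1.s and R(inlet) = 0.  When the lumen expands downstream of a
    constriction the larger averaging area can make R appear to overshoot;
    that is a property of area averaging, not of the flow.
    """
    if not fields:
        raise InvalidInputError("need >= 1 station")
    fields = sorted(fields, key=lambda f: f.section.station)
    if Q is None:
        Q = float(np.mean([plane_flowrate(f) for f in fields]))
    if Q <= 0:
        raise InvalidInputError("flowrate must be positive")
    x = np.array([f.section.station for f in fields])
    p = np.array([mean_total_pressure(f, rho) for f in fields])
    return ResistanceProfile(x=x, R=(p[0] - p) / Q, Q=Q)


def write_energy_csv(path, profile: EnergyFluxProfile) -> None:
    pd.DataFrame(
        {"x_mm": profile.x, "E_F_W": profile.E_F, "cum_loss_W": profile.cumulative_loss}
    ).to_csv(path, index=False)


def write_resistance_csv(path, profile: ResistanceProfile) -> None:
    pd.DataFrame({"x_mm": profile.x, "R_Pa_per_mLs": profile.R}).to_csv(path, index=False)
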