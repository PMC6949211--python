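"""Time-resolved planar flow samples and their reductions.

A dataset is a set of centerline-normal planes; on each plane a fixed set
of sample points carries velocity (m/s) and static pressure (Pa) per
snapshot.  Point coordinates and quadrature weights stay in the geometric
units (mm, mm**2); because 1 mm**2 * 1 m/s = 1 mL/s, plane integrals of
velocity come out directly in mL/s, and energy fluxes need only a single
1e-6 factor to watts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .errors import EmptyWindowError, InvalidInputError
from .geometry import CrossSection

__all__ = [
    "PlaneSample",
    "PlaneSampleSeries",
    "MeanPlaneField",
    "quadrature_weights",
    "time_average",
    "plane_flowrate",
    "turbulence_intensity",
    "write_plane_series_csv",
    "read_plane_series_csv",
]


@dataclass
class PlaneSample:
    """One snapshot of velocity and pressure samples on a cross-section."""

    section: CrossSection
    points: np.ndarray  # (n, 3), mm
    weights: np.ndarray  # (n,), mm**2; sums to section.area
    velocity: np.ndarray  # (n, 3), m/s
    pressure: np.ndarray  # (n,), Pa
    time: float  # s

    def __post_init__(self) -> None:
        n = len(self.points)
        if not (len(self.weights) == len(self.velocity) == len(self.pressure) == n):
            raise InvalidInputError("inconsistent sample counts")
        wsum = float(np.sum(self.weights))
        if abs(wsum - self.section.area) > 5e-3 * self.section.area:
            raise InvalidInputError(
                f"quadrature weights sum {wsum:.4g} != section area "
                f"{self.section.area:.4g} (0.5% tolerance)"
            )


@dataclass
class PlaneSampleSeries:
    """Time-ordered snapshots sharing one point set and uniform step dt."""

    snapshots: list[PlaneSample]
    dt: float  # s

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise InvalidInputError("series needs >= 1 snapshot")
        times = np.array([s.time for s in self.snapshots])
        if len(times) > 1 and not np.allclose(np.diff(times), self.dt, rtol=1e-6):
            raise InvalidInputError("snapshot times are not uniformly spaced by dt")

    @property
    def section(self) -> CrossSection:
        return self.snapshots[0].section

    @property
    def points(self) -> np.ndarray:
        return self.snapshots[0].points

    @property
    def weights(self) -> np.ndarray:
        return self.snapshots[0].weights


@dataclass
class MeanPlaneField:
    """Time-averaged velocity/pressure on a plane, with fluctuation RMS.

    ``fluctuation_rms`` is the pointwise RMS of the velocity fluctuation
    magnitude |u - u_mean| over the averaging window.
    """

    section: CrossSection
    points: np.ndarray
    weights: np.ndarray  # mm**2
    mean_velocity: np.ndarray  # (n, 3), m/s
    mean_pressure: np.ndarray  # (n,), Pa
    fluctuation_rms: np.ndarray  # (n,), m/s
    n_averaged: int


def quadrature_weights(points2d: np.ndarray, area: float) -> np.ndarray:
    """Vertex quadrature weights from a Delaunay triangulation of plane points.

    Each point receives one third of the area of its incident triangles;
    the weights are then rescaled so they sum exactly to the section
    ``area`` (the triangulation covers only the convex hull of the points).
    """
    pts = np.asarray(points2d, dtype=float)
    if len(pts) < 3:
        raise InvalidInputError("need >= 3 points for quadrature")
    tri = Delaunay(pts)
    w = np.zeros(len(pts))
    simplices = tri.simplices
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    tri_area = 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    for k in range(3):
        np.add.at(w, simplices[:, k], tri_area / 3.0)
    total = w.sum()
    if total <= 0:
        raise InvalidInputError("degenerate point set: zero triangulated area")
    return w * (area / total)


def time_average(series: PlaneSampleSeries, discard_before: float = 0.0) -> MeanPlaneField:
    """Arithmetic time mean over snapshots at time >= ``discard_before``.

    Discarding an initial window drops start-up transients; the fluctuation
    RMS is computed about the retained-window mean.
    """
    kept = [s for s in series.snapshots if s.time >= discard_before]
    if not kept:
        raise EmptyWindowError(
            f"no snapshots at time >= {discard_before} s (series ends at "
            f"{series.snapshots[-1].time} s)"
        )
    vel = np.stack([s.velocity for s in kept])  # (t, n, 3)
    prs = np.stack([s.pressure for s in kept])  # (t, n)
    mean_v = vel.mean(axis=0)
    mean_p = prs.mean(axis=0)
    fluct = vel - mean_v
    rms = np.sqrt(np.mean(np.sum(fluct**2, axis=2), axis=0))
    first = kept[0]
    return MeanPlaneField(
        section=first.section,
        points=first.points,
        weights=first.weights,
        mean_velocity=mean_v,
        mean_pressure=mean_p,
        fluctuation_rms=rms,
        n_averaged=len(kept),
    )


def plane_flowrate(field: MeanPlaneField) -> float:
    """Volumetric flowrate Q = sum w * (u_mean . n) through the plane, mL/s.

    The sign follows the section normal orientation.
    """
    un = field.mean_velocity @ field.section.normal
    return float(np.sum(field.weights * un))  # mm**2 * m/s == mL/s


def turbulence_intensity(field: MeanPlaneField, u_ref: float) -> float:
    """Area-weighted mean fluctuation RMS divided by a reference velocity.

    ``u_ref`` is conventionally the bulk velocity at a named reference
    plane (e.g. the first tracheal ring), mirroring a "TI-ref" scalar.
    """
    if u_ref <= 0:
        raise InvalidInputError("reference velocity must be positive")
    w = field.weights
    return float(np.sum(w * field.fluctuation_rms) / np.sum(w) / u_ref)


# ---------------------------------------------------------------------------
# CSV interface (schema: station_mm,time_s,px,py,pz,u,v,w,p)
# ---------------------------------------------------------------------------


def write_plane_series_csv(path, series_list: list[PlaneSampleSeries]) -> None:
    """Write one dataset (all stations, all snapshots) to a single CSV."""
    frames = []
    for series in series_list:
        for snap in series.snapshots:
            frames.append(
                pd.DataFrame(
                    {
                        "station_mm": snap.section.station,
                        "time_s": snap.time,
                        "px": snap.points[:, 0],
                        "py": snap.points[:, 1],
                        "pz": snap.points[:, 2],
                        "u": snap.velocity[:, 0],
                        "v": snap.velocity[:, 1],
                        "w": snap.velocity[:, 2],
                        "p": snap.pressure,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_plane_series_csv(path, sections: list[CrossSection]) -> list[PlaneSampleSeries]:
    """Read a plane-sample dataset back, attaching the given cross-sections.

    Quadrature weights are rebuilt from a Delaunay triangulation of the
    in-plane point coordinates, normalised to each section's area.
    """
    df = pd.read_csv(path)
    required = {"station_mm", "time_s", "px", "py", "pz", "u", "v", "w", "p"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    by_station = {round(float(s.station), 6): s for s in sections}
    out: list[PlaneSampleSeries] = []
    for station, g in df.groupby("station_mm", sort=True):
        key = round(float(station), 6)
        if key not in by_station:
            raise InvalidInputError(f"{path}: no section for station {station} mm")
        sec = by_station[key]
        u_ax, v_ax = sec.basis()
        snaps = []
        times = sorted(g["time_s"].unique())
        weights = None
        for t in times:
            gt = g[g["time_s"] == t]
            pts = gt[["px", "py", "pz"]].to_numpy(float)
            if weights is None:
                rel = pts - sec.origin
                weights = quadrature_weights(
                    np.column_stack([rel @ u_ax, rel @ v_ax]), sec.area
                )
            snaps.append(
                PlaneSample(
                    section=sec,
                    points=pts,
                    weights=weights,
                    velocity=gt[["u", "v", "w"]].to_numpy(float),
                    pressure=gt["p"].to_numpy(float),
                    time=float(t),
                )
            )
        dt = times[1] - times[0] if len(times) > 1 else 0.0
        out.append(PlaneSampleSeries(snapshots=snaps, dt=float(dt)))
    return out
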