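"""Parametric stenosed-airway and flow-field generator with known ground truth.

Real datasets of this kind come from CT-segmented lumens and large-eddy
simulations, neither of which is portable.  This module generates the same
artefacts — watertight surface meshes, centerlines, and time-resolved
plane samples — from closed-form prescriptions, so that every downstream
operator can be checked against an analytic answer:

* the lumen is an elliptical tube whose *area* is modulated by a Gaussian
  dip, ``A(x) = A0 * (1 - c * exp(-(x - x0)**2 / (2 sigma**2)))``, giving a
  closed-form constriction ratio ``c`` and constricted length;
* velocity fields follow named profiles (plug, parabolic, orifice jet)
  scaled to a prescribed bulk flowrate, with white, seeded fluctuations of
  prescribed RMS;
* static pressure follows Bernoulli on the area change plus an imposed
  irreversible orifice loss ``1/2 rho K (Q/A_C)**n`` distributed over a
  mixing length downstream of the throat, so the exact injected loss is
  always recoverable.

Default shape parameters emulate a severely compressed adult trachea
(first-ring area ~117 mm**2, minimum area ~20.5 mm**2, constricted length
~33 mm) with 35 mm straight extrusions at both ends; the default flow is a
steady 392 mL/s inspiration in air.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import trimesh

from .errors import InvalidSpecError
from .geometry import AreaProfile, Centerline, CrossSection
from .sampling import PlaneSample, PlaneSampleSeries, quadrature_weights

__all__ = [
    "AirwayShapeSpec",
    "AnalyticFlowSpec",
    "OrificeLossLaw",
    "make_airway_surface",
    "analytic_sections",
    "sections_from_profile",
    "make_plane_samples",
    "make_orifice_pressure_field",
]


@dataclass(frozen=True)
class AirwayShapeSpec:
    """Shape of a synthetic stenosed airway.

    ``constriction_depth`` is the fractional *area* reduction at the dip
    centre; ``constriction_center`` is measured from the start of the
    imaged body (after the inlet extrusion).  ``ellipticity`` is the
    minor/major axis ratio; the axes are scaled so the area law above holds
    for any ellipticity.
    """

    length: float = 110.0  # mm, imaged body
    base_radius: float = 6.1  # mm, equivalent radius (A0 = pi r**2 ~ 117 mm**2)
    ellipticity: float = 0.8
    constriction_depth: float = 0.825
    constriction_center: float = 55.0  # mm from body inlet
    constriction_width: float = 12.5  # mm (Gaussian sigma)
    extrusion_length: float = 35.0  # mm, straight extensions at each end
    mesh_edge: float = 1.0  # mm, target surface edge length
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.constriction_depth < 1.0:
            raise InvalidSpecError("constriction depth must lie in [0, 1)")
        if self.constriction_width <= 0 or self.mesh_edge <= 0:
            raise InvalidSpecError("constriction_width and mesh_edge must be positive")
        if self.base_radius <= 0 or self.length <= 0 or self.ellipticity <= 0:
            raise InvalidSpecError("length, base_radius, ellipticity must be positive")

    @property
    def total_length(self) -> float:
        return self.length + 2.0 * self.extrusion_length

    @property
    def base_area(self) -> float:
        return math.pi * self.base_radius**2

    def area_scale(self, x: np.ndarray | float) -> np.ndarray | float:
        """Gaussian area modulation g(x) on the full (extruded) axis."""
        x0 = self.extrusion_length + self.constriction_center
        return 1.0 - self.constriction_depth * np.exp(
            -((np.asarray(x, dtype=float) - x0) ** 2)
            / (2.0 * self.constriction_width**2)
        )

    def analytic_area(self, x: np.ndarray | float) -> np.ndarray | float:
        """Closed-form lumen area A(x), mm**2."""
        return self.base_area * self.area_scale(x)


@dataclass(frozen=True)
class AnalyticFlowSpec:
    """Prescription for synthetic plane-sampled flow fields.

    ``fluctuation_rms`` is the RMS magnitude of the velocity fluctuation
    vector as a fraction of the local bulk velocity; fluctuations are
    white in time and space.  ``jet_area_mm2`` is only used by the
    ``orifice_jet`` profile (defaults to the full section area).
    """

    profile_kind: str = "plug"  # plug | parabolic | orifice_jet
    Q: float = 392.0  # mL/s (23.5 L/min steady inspiration)
    rho: float = 1.2  # kg/m**3
    mu: float = 1.8e-5  # Pa.s
    K_true: float = 1.2
    n_true: float = 2.0
    fluctuation_rms: float = 0.05
    n_snapshots: int = 40
    dt: float = 5e-3  # s
    seed: int = 0
    jet_area_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.Q <= 0 or self.rho <= 0:
            raise InvalidSpecError("Q and rho must be positive")
        if self.fluctuation_rms < 0:
            raise InvalidSpecError("fluctuation_rms must be non-negative")
        if self.n_snapshots < 1 or self.dt <= 0:
            raise InvalidSpecError("need n_snapshots >= 1 and dt > 0")
        if self.profile_kind not in ("plug", "parabolic", "orifice_jet"):
            raise InvalidSpecError(f"unknown profile_kind {self.profile_kind!r}")


@dataclass
class OrificeLossLaw:
    """Imposed station-wise pressure law and its exact injected loss."""

    x: np.ndarray  # mm
    p_static: np.ndarray  # Pa
    p_total: np.ndarray  # Pa
    dp_true: float  # Pa, irreversible total-pressure loss across the throat
    mixing_length: float  # mm
    rho: float


# ---------------------------------------------------------------------------
# surface mesh
# ---------------------------------------------------------------------------


def make_airway_surface(
    spec: AirwayShapeSpec,
) -> tuple[trimesh.Trimesh, Centerline, AreaProfile]:
    """Generate a watertight stenosed-tube mesh, its centerline, and A(x).

    The returned area profile is the analytic law on the raw arclength
    axis (0 at the inlet-extrusion start); carina alignment is a separate,
    later step.  Generation is fully deterministic.
    """
    a0 = spec.base_radius / math.sqrt(spec.ellipticity)  # major semi-axis
    b0 = spec.base_radius * math.sqrt(spec.ellipticity)  # minor semi-axis
    n_ax = max(2, int(round(spec.total_length / spec.mesh_edge))) + 1
    z = np.linspace(0.0, spec.total_length, n_ax)
    n_th = max(32, int(math.ceil(2.0 * math.pi * a0 / spec.mesh_edge)))
    theta = 2.0 * math.pi * np.arange(n_th) / n_th

    r_scale = np.sqrt(spec.area_scale(z))  # radius modulation -> area law exact
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    verts = np.empty((n_ax * n_th + 2, 3))
    for i in range(n_ax):
        ring = slice(i * n_th, (i + 1) * n_th)
        verts[ring, 0] = a0 * r_scale[i] * cos_t
        verts[ring, 1] = b0 * r_scale[i] * sin_t
        verts[ring, 2] = z[i]
    i_bot, i_top = n_ax * n_th, n_ax * n_th + 1
    verts[i_bot] = (0.0, 0.0, 0.0)
    verts[i_top] = (0.0, 0.0, spec.total_length)

    faces = []
    for i in range(n_ax - 1):
        for k in range(n_th):
            k1 = (k + 1) % n_th
            v00, v01 = i * n_th + k, i * n_th + k1
            v10, v11 = (i + 1) * n_th + k, (i + 1) * n_th + k1
            faces.append((v00, v01, v11))
            faces.append((v00, v11, v10))
    for k in range(n_th):  # end caps (fans), wound outward
        k1 = (k + 1) % n_th
        faces.append((i_bot, k1, k))
        base = (n_ax - 1) * n_th
        faces.append((i_top, base + k, base + k1))

    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()

    centerline = Centerline(
        points=np.column_stack([np.zeros(n_ax), np.zeros(n_ax), z]),
        arclength=z.copy(),
        landmarks={
            "carina_offset": spec.total_length,
            "first_ring_station": spec.extrusion_length,
        },
    )
    profile = AreaProfile(x=z.copy(), A=np.asarray(spec.analytic_area(z)))
    return mesh, centerline, profile


def analytic_sections(
    spec: AirwayShapeSpec, stations: Sequence[float], n_boundary: int = 48
) -> list[CrossSection]:
    """Exact elliptical cross-sections of the analytic lumen at given stations."""
    secs = []
    theta = 2.0 * math.pi * np.arange(n_boundary) / n_boundary
    a0 = spec.base_radius / math.sqrt(spec.ellipticity)
    b0 = spec.base_radius * math.sqrt(spec.ellipticity)
    for s in stations:
        scale = math.sqrt(float(spec.area_scale(s)))
        a, b = a0 * scale, b0 * scale
        loop = np.column_stack(
            [a * np.cos(theta), b * np.sin(theta), np.full(n_boundary, float(s))]
        )
        # exact ellipse area; perimeter from the boundary polygon
        per = float(np.sum(np.linalg.norm(np.diff(
            np.vstack([loop, loop[:1]]), axis=0), axis=1)))
        secs.append(
            CrossSection(
                station=float(s),
                origin=np.array([0.0, 0.0, float(s)]),
                normal=np.array([0.0, 0.0, 1.0]),
                loops=[loop],
                area=math.pi * a * b,
                perimeter=per,
            )
        )
    return secs


def sections_from_profile(profile: AreaProfile, n_boundary: int = 48) -> list[CrossSection]:
    """Circular-equivalent cross-sections reconstructed from an area profile.

    Stations become plane origins on a straight axis; each section is a
    circle of the profile's area.  Used when only A(x) is known (e.g. when
    re-reading a plane-sample CSV without the original mesh).
    """
    theta = 2.0 * math.pi * np.arange(n_boundary) / n_boundary
    secs = []
    for xi, area in zip(profile.x, profile.A):
        ri = math.sqrt(area / math.pi)
        loop = np.column_stack(
            [ri * np.cos(theta), ri * np.sin(theta), np.full(n_boundary, float(xi))]
        )
        secs.append(
            CrossSection(
                station=float(xi),
                origin=np.array([0.0, 0.0, float(xi)]),
                normal=np.array([0.0, 0.0, 1.0]),
                loops=[loop],
                area=float(area),
                perimeter=float(n_boundary * 2 * ri * math.sin(math.pi / n_boundary)),
            )
        )
    return secs


# ---------------------------------------------------------------------------
# plane-sampled flow fields
# ---------------------------------------------------------------------------


def _section_sample_points(
    section: CrossSection, n_rings: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample points (3D, mm), radial fractions t, and quadrature weights.

    Points are concentric scaled copies of the boundary loop plus the
    centroid, which keeps the outermost ring exactly on the lumen boundary
    (where no-slip profiles vanish).
    """
    u_ax, v_ax = section.basis()
    b2d = section.boundary2d()
    c2d = b2d.mean(axis=0)
    rel = b2d - c2d
    t_vals = np.arange(1, n_rings + 1) / n_rings
    pts2d = [c2d[None, :]]
    t_point = [np.zeros(1)]
    for t in t_vals:
        pts2d.append(c2d + t * rel)
        t_point.append(np.full(len(rel), t))
    pts2d = np.vstack(pts2d)
    t_point = np.concatenate(t_point)
    weights = quadrature_weights(pts2d, section.area)
    pts3d = (
        section.origin
        + pts2d[:, 0:1] * u_ax[None, :]
        + pts2d[:, 1:2] * v_ax[None, :]
    )
    return pts3d, t_point, weights


def _profile_speed(spec: AnalyticFlowSpec, section: CrossSection, t: np.ndarray) -> np.ndarray:
    """Axial speed per sample point for the named profile, bulk-scaled to Q."""
    u_bulk = spec.Q / section.area  # mL/s / mm**2 == m/s
    if spec.profile_kind == "plug":
        return np.full_like(t, u_bulk)
    if spec.profile_kind == "parabolic":
        # exact laminar solution on an ellipse: u = 2 U (1 - t**2)
        return 2.0 * u_bulk * (1.0 - t**2)
    # orifice_jet: top-hat core carrying the whole flowrate
    a_jet = spec.jet_area_mm2 if spec.jet_area_mm2 is not None else section.area
    if not 0.0 < a_jet <= section.area:
        raise InvalidSpecError("jet_area_mm2 must lie in (0, section area]")
    t_jet = math.sqrt(a_jet / section.area)
    u = np.zeros_like(t)
    u[t <= t_jet] = spec.Q / a_jet
    return u


def make_plane_samples(
    spec: AnalyticFlowSpec,
    sections: Sequence[CrossSection],
    pressures: Sequence[float] | None = None,
    n_rings: int = 16,
) -> list[PlaneSampleSeries]:
    """Time-resolved plane samples on each section, one series per plane.

    Pointwise velocities follow the named profile scaled to the bulk
    flowrate through each section; fluctuations are zero-mean white noise
    with the prescribed RMS magnitude, independent per point, component
    and snapshot, drawn from a generator seeded by ``spec.seed``.
    ``pressures`` supplies a uniform static pressure per section
    (default 0 Pa everywhere).
    """
    if pressures is None:
        pressures = np.zeros(len(sections))
    if len(pressures) != len(sections):
        raise InvalidSpecError("one pressure per section required")
    rng = np.random.default_rng(spec.seed)
    out: list[PlaneSampleSeries] = []
    for sec, p_s in zip(sections, pressures):
        pts, t_frac, w = _section_sample_points(sec, n_rings)
        speed = _profile_speed(spec, sec, t_frac)
        base_vel = speed[:, None] * sec.normal[None, :]
        u_bulk = spec.Q / sec.area
        # fluctuation-vector RMS = fraction * bulk  =>  per-component std / sqrt(3)
        sigma = spec.fluctuation_rms * u_bulk / math.sqrt(3.0)
        snaps = []
        for k in range(spec.n_snapshots):
            vel = base_vel
            if sigma > 0:
                vel = base_vel + rng.normal(0.0, sigma, size=base_vel.shape)
            snaps.append(
                PlaneSample(
                    section=sec,
                    points=pts,
                    weights=w,
                    velocity=vel,
                    pressure=np.full(len(pts), float(p_s)),
                    time=k * spec.dt,
                )
            )
        out.append(PlaneSampleSeries(snapshots=snaps, dt=spec.dt))
    return out


def make_orifice_pressure_field(
    spec: AnalyticFlowSpec,
    profile: AreaProfile,
    sections: Sequence[CrossSection] | None = None,
    mixing_diameters: float = 5.0,
    n_rings: int = 16,
) -> tuple[OrificeLossLaw, list[PlaneSampleSeries]]:
    """Plug-flow dataset with Bernoulli pressure plus an imposed orifice loss.

    Upstream of the area minimum the total pressure is constant (loss-free
    Bernoulli); across the throat an irreversible total-pressure drop of
    ``1/2 rho K_true (Q/A_C)**n_true`` is imposed, distributed smoothly
    over ``mixing_diameters`` hydraulic diameters downstream — emulating
    the gradual energy-flux decline of a breaking-up jet.  The injected
    loss is returned exactly in ``OrificeLossLaw.dp_true``.
    """
    A = profile.A
    i_min = int(np.argmin(A))
    if int(np.sum(A == A[i_min])) != 1:
        raise InvalidSpecError("area profile must have a unique minimum")
    x = profile.x
    a_c = float(A[i_min])
    v_throat = (spec.Q * 1e-6) / (a_c * 1e-6)  # m/s
    dp_true = 0.5 * spec.rho * spec.K_true * v_throat**spec.n_true

    d_h = 2.0 * math.sqrt(a_c / math.pi)  # mm, circular-equivalent at the throat
    l_mix = mixing_diameters * d_h
    s = np.clip((x - x[i_min]) / l_mix, 0.0, 1.0)
    ramp = 3.0 * s**2 - 2.0 * s**3  # smoothstep
    p_total = -dp_true * ramp
    u_bulk = (spec.Q * 1e-6) / (A * 1e-6)
    p_static = p_total - 0.5 * spec.rho * u_bulk**2

    if sections is None:
        sections = sections_from_profile(profile)
    elif len(sections) != len(x):
        raise InvalidSpecError("one section per profile station required")

    plug_spec = replace(spec, profile_kind="plug")
    series = make_plane_samples(plug_spec, sections, pressures=p_static, n_rings=n_rings)
    law = OrificeLossLaw(
        x=x.copy(),
        p_static=p_static,
        p_total=p_total,
        dp_true=float(dp_true),
        mixing_length=float(l_mix),
        rho=spec.rho,
    )
    return law, series
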