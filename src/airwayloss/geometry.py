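"""Lumen geometry: centerlines, plane slicing, area profiles, constriction metrics.

All geometric quantities are carried in millimetres (areas in mm**2), the
native unit of clinical surface reconstructions.  Station coordinates ``x``
are signed arclengths relative to a chosen origin (conventionally the
carina, with superior stations negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import EmptySectionError, InvalidInputError, TopologyError

__all__ = [
    "Centerline",
    "CrossSection",
    "AreaProfile",
    "ConstrictionMetrics",
    "resample_centerline",
    "frames_along",
    "slice_area",
    "area_profile",
    "local_minima",
    "constriction_metrics",
    "constriction_ratio",
    "align_profile",
    "plane_basis",
    "read_centerline_csv",
    "write_centerline_csv",
    "read_profile_csv",
    "write_profile_csv",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Centerline:
    """Ordered 3D polyline through the lumen, with cumulative arclength.

    Parameters
    ----------
    points : (n, 3) array, mm
    arclength : (n,) array, mm — cumulative distance along ``points``,
        strictly increasing from 0.
    landmarks : named stations (mm of arclength), e.g. ``carina_offset``,
        ``first_ring_station``, ``glottis_station``.
    """

    points: np.ndarray
    arclength: np.ndarray
    landmarks: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arclength = np.asarray(self.arclength, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise InvalidInputError("centerline needs >= 2 points of shape (n, 3)")
        if len(self.arclength) != len(self.points):
            raise InvalidInputError("arclength length mismatch")
        if not np.all(np.diff(self.arclength) > 0):
            raise InvalidInputError("arclength must be strictly increasing")
        total = self.arclength[-1]
        for name, s in self.landmarks.items():
            if not 0.0 <= s <= total:
                raise InvalidInputError(
                    f"landmark {name!r} at {s} mm outside [0, {total}] mm"
                )

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1])


@dataclass
class CrossSection:
    """A planar lumen cross-section: closed loop(s) cut by a centerline-normal plane."""

    station: float  # arclength s, mm
    origin: np.ndarray  # (3,), mm
    normal: np.ndarray  # (3,), unit
    loops: list[np.ndarray]  # each (m, 3), closed (first vertex not repeated)
    area: float  # mm**2
    perimeter: float  # mm

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise InvalidInputError("section normal must be unit length")
        if self.area <= 0:
            raise InvalidInputError("section area must be positive")

    @property
    def hydraulic_diameter(self) -> float:
        """4 * area / perimeter (mm)."""
        return 4.0 * self.area / self.perimeter

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-plane axes (u, v) completing ``normal``."""
        return plane_basis(self.normal)

    def boundary2d(self) -> np.ndarray:
        """Primary loop projected to in-plane coordinates, centred on ``origin``."""
        u, v = self.basis()
        rel = self.loops[0] - self.origin
        return np.column_stack([rel @ u, rel @ v])


@dataclass
class AreaProfile:
    """Lumen area versus signed station (negative = superior to the origin)."""

    x: np.ndarray  # mm
    A: np.ndarray  # mm**2

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.x.shape != self.A.shape or self.x.ndim != 1:
            raise InvalidInputError("x and A must be matching 1-d arrays")
        if not np.all(np.diff(self.x) > 0):
            raise InvalidInputError("profile stations must be strictly increasing")
        if not np.all(self.A > 0):
            raise InvalidInputError("all areas must be positive")


@dataclass
class ConstrictionMetrics:
    """Severity of a lumen constriction relative to a reference station.

    ``ratio`` is the fractional area reduction (A_ref - A_min) / A_ref and
    ``length`` the contiguous extent around the minimum where the area is
    reduced by at least ``threshold`` relative to A_ref.
    """

    A_ref: float  # mm**2
    A_min: float  # mm**2
    x_min: float  # mm
    ratio: float
    length: float  # mm
    threshold: float
    widened: bool = False  # A_min > A_ref (e.g. post-operative lumen)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def resample_centerline(points: np.ndarray, spacing: float) -> Centerline:
    """Resample a polyline to (near-)uniform arclength spacing.

    The number of segments is ``round(L / spacing)`` so the endpoints are
    preserved exactly and the achieved spacing is uniform.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise InvalidInputError("need >= 2 points of shape (n, 3)")
    if spacing <= 0:
        raise InvalidInputError("spacing must be positive")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise InvalidInputError("degenerate (zero-length) polyline")
    n_seg = max(1, int(round(total / spacing)))
    s_new = np.linspace(0.0, total, n_seg + 1)
    new_pts = np.column_stack([np.interp(s_new, s, pts[:, i]) for i in range(3)])
    return Centerline(points=new_pts, arclength=s_new)


def frames_along(centerline: Centerline) -> list[tuple[np.ndarray, np.ndarray]]:
    """Plane frames (origin, unit normal) at every centerline point.

    Normals are central-difference tangents (one-sided at the ends), the
    standard choice for slicing a tubular lumen normal to its axis.
    """
    pts = centerline.points
    tangents = np.gradient(pts, centerline.arclength, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise InvalidInputError("zero tangent on centerline")
    tangents = tangents / norms
    return [(pts[i].copy(), tangents[i]) for i in range(len(pts))]


def plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis (u, v) of the plane with unit ``normal``."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _loop_polygon(loop3d: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> Polygon:
    u, v = plane_basis(normal)
    rel = loop3d - origin
    return Polygon(np.column_stack([rel @ u, rel @ v]))


def slice_area(
    mesh,
    origin: np.ndarray,
    normal: np.ndarray,
    near_point: np.ndarray,
    station: float = float("nan"),
) -> CrossSection:
    """Intersect a watertight surface mesh with a plane and measure the lumen.

    Near branches a plane may cut several closed loops; only the loop whose
    centroid is nearest ``near_point`` (normally the centerline point) is
    kept.  Area is the planar polygon area of the 2D projection, perimeter
    the loop length.
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    path = mesh.section(plane_origin=origin, plane_normal=normal)
    if path is None or len(path.discrete) == 0:
        raise EmptySectionError(f"plane at station {station} does not cut the mesh")

    best = None
    for loop in path.discrete:
        closed = np.allclose(loop[0], loop[-1], atol=1e-8)
        if not closed:
            raise TopologyError(f"open intersection loop at station {station}")
        ring = loop[:-1]
        poly = _loop_polygon(ring, origin, normal)
        if not poly.is_valid or poly.area <= 0:
            raise TopologyError(f"degenerate intersection loop at station {station}")
        u, v = plane_basis(normal)
        c2d = np.array(poly.centroid.coords[0])
        centroid3d = origin + c2d[0] * u + c2d[1] * v
        d = float(np.linalg.norm(centroid3d - np.asarray(near_point, dtype=float)))
        if best is None or d < best[0]:
            best = (d, ring, poly)

    _, ring, poly = best
    return CrossSection(
        station=station,
        origin=origin,
        normal=normal,
        loops=[ring],
        area=float(poly.area),
        perimeter=float(poly.exterior.length),
    )


def area_profile(mesh, centerline: Centerline, carina_offset: float = 0.0) -> AreaProfile:
    """Area profile A(x) along a centerline, with x = arclength - carina_offset.

    With the carina at arclength ``carina_offset`` the most superior station
    is the most negative x and the carina sits at x = 0.
    """
    frames = frames_along(centerline)
    areas = np.empty(len(frames))
    for i, (origin, normal) in enumerate(frames):
        try:
            sec = slice_area(mesh, origin, normal, near_point=origin,
                             station=centerline.arclength[i])
        except (EmptySectionError, TopologyError) as err:
            raise type(err)(f"station index {i}: {err}") from err
        areas[i] = sec.area
    return AreaProfile(x=centerline.arclength - carina_offset, A=areas)


def local_minima(profile: AreaProfile, k: int) -> tuple[np.ndarray, np.ndarray]:
    """The k interior local minima with the smallest areas, sorted by station.

    Plateaus count once, reported at the midpoint of the flat run.  If fewer
    than k interior minima exist, all of them are returned.
    """
    if len(profile.x) < 3:
        raise InvalidInputError("profile needs >= 3 stations")
    x, A = profile.x, profile.A
    # compress equal-value runs so flat-bottomed dips count once
    runs: list[tuple[int, int]] = []  # [start, stop] inclusive
    start = 0
    for i in range(1, len(A)):
        if A[i] != A[start]:
            runs.append((start, i - 1))
            start = i
    runs.append((start, len(A) - 1))

    cands: list[tuple[float, float]] = []  # (area, station)
    for j, (lo, hi) in enumerate(runs):
        if j == 0 or j == len(runs) - 1:
            continue  # endpoints are not interior minima
        prev_val = A[runs[j - 1][1]]
        next_val = A[runs[j + 1][0]]
        if A[lo] < prev_val and A[lo] < next_val:
            cands.append((float(A[lo]), float(0.5 * (x[lo] + x[hi]))))

    cands.sort(key=lambda t: (t[0], t[1]))
    chosen = sorted(cands[:k], key=lambda t: t[1])
    stations = np.array([c[1] for c in chosen])
    areas = np.array([c[0] for c in chosen])
    return stations, areas


def constriction_ratio(A_ref: float, A_min: float) -> float:
    """Fractional area reduction (A_ref - A_min) / A_ref."""
    if A_ref <= 0:
        raise InvalidInputError("reference area must be positive")
    return (A_ref - A_min) / A_ref


def constriction_metrics(
    profile: AreaProfile,
    ref_station: float,
    threshold: float = 0.35,
    A_ref: float | None = None,
) -> ConstrictionMetrics:
    """Constriction severity relative to the area at ``ref_station``.

    The reference area is linearly interpolated at ``ref_station`` (the
    first-tracheal-ring station in clinical use) unless ``A_ref`` is given
    explicitly, e.g. when the reference plane was measured on a different
    scan.  The constricted length is the contiguous run containing the area
    minimum where ``A <= (1 - threshold) * A_ref``, with endpoints located
    by linear interpolation.  A negative ratio (lumen wider than the
    reference, as in post-operative airways) is reported with
    ``widened=True``.
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError("threshold must lie in (0, 1)")
    x, A = profile.x, profile.A
    if A_ref is None:
        if not x[0] <= ref_station <= x[-1]:
            raise InvalidInputError("ref_station outside the profile")
        A_ref = float(np.interp(ref_station, x, A))
    i_min = int(np.argmin(A))
    A_min = float(A[i_min])
    x_min = float(x[i_min])
    ratio = constriction_ratio(A_ref, A_min)

    level = (1.0 - threshold) * A_ref
    if A_min > level:
        length = 0.0
    else:
        lo = i_min
        while lo > 0 and A[lo - 1] <= level:
            lo -= 1
        hi = i_min
        while hi < len(A) - 1 and A[hi + 1] <= level:
            hi += 1
        # linear interpolation of the crossings just outside the run
        if lo > 0:
            t = (level - A[lo - 1]) / (A[lo] - A[lo - 1])
            x_lo = x[lo - 1] + t * (x[lo] - x[lo - 1])
        else:
            x_lo = x[0]
        if hi < len(A) - 1:
            t = (level - A[hi]) / (A[hi + 1] - A[hi])
            x_hi = x[hi] + t * (x[hi + 1] - x[hi])
        else:
            x_hi = x[-1]
        length = float(x_hi - x_lo)

    return ConstrictionMetrics(
        A_ref=A_ref,
        A_min=A_min,
        x_min=x_min,
        ratio=ratio,
        length=length,
        threshold=threshold,
        widened=ratio < 0,
    )


def align_profile(profile: AreaProfile, offset: float) -> AreaProfile:
    """Translate a profile along the station axis (areas untouched)."""
    return AreaProfile(x=profile.x + offset, A=profile.A.copy())


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def read_centerline_csv(path) -> np.ndarray:
    """Read an ordered centerline polyline from CSV with columns x,y,z (mm)."""
    df = pd.read_csv(path)
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing centerline columns {sorted(missing)}")
    return df[["x", "y", "z"]].to_numpy(dtype=float)


def write_centerline_csv(path, centerline: Centerline) -> None:
    pd.DataFrame(centerline.points, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_profile_csv(path) -> AreaProfile:
    """Read an area profile from CSV with columns x_mm,area_mm2."""
    df = pd.read_csv(path)
    missing = {"x_mm", "area_mm2"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing profile columns {sorted(missing)}")
    return AreaProfile(x=df["x_mm"].to_numpy(float), A=df["area_mm2"].to_numpy(float))


def write_profile_csv(path, profile: AreaProfile) -> None:
    pd.DataFrame({"x_mm": profile.x, "area_mm2": profile.A}).to_csv(path, index=False)
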