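"""Shared fixtures: generator airways and flow datasets reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from airwayloss import energy, geometry, sampling, synthetic


@pytest.fixture(scope="session")
def default_shape() -> synthetic.AirwayShapeSpec:
    """Severely constricted airway (82.5% area reduction), study-like defaults."""
    return synthetic.AirwayShapeSpec()


@pytest.fixture(scope="session")
def airway(default_shape):
    """(mesh, centerline, analytic profile) of the default airway."""
    return synthetic.make_airway_surface(default_shape)


@pytest.fixture(scope="session")
def flow_stations(default_shape) -> np.ndarray:
    """Plane stations covering the duct, including the throat exactly."""
    throat = default_shape.extrusion_length + default_shape.constriction_center
    grid = np.arange(10.0, default_shape.total_length - 5.0, 10.0)
    return np.unique(np.concatenate([grid, [throat]]))


@pytest.fixture(scope="session")
def orifice_dataset(default_shape, flow_stations):
    """Default orifice-loss dataset: (flow spec, loss law, series, mean fields)."""
    flow = synthetic.AnalyticFlowSpec()
    profile = geometry.AreaProfile(
        x=flow_stations, A=np.asarray(default_shape.analytic_area(flow_stations))
    )
    law, series = synthetic.make_orifice_pressure_field(flow, profile)
    fields = [sampling.time_average(s, discard_before=0.05) for s in series]
    return flow, law, series, fields


@pytest.fixture(scope="session")
def circle_section():
    """Factory for a circular cross-section normal to z at a given station."""

    def make(radius: float = 9.0, station: float = 0.0, n_boundary: int = 128):
        theta = 2.0 * np.pi * np.arange(n_boundary) / n_boundary
        loop = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.full(n_boundary, station)]
        )
        return geometry.CrossSection(
            station=station,
            origin=np.array([0.0, 0.0, station]),
            normal=np.array([0.0, 0.0, 1.0]),
            loops=[loop],
            area=float(np.pi * radius**2),
            perimeter=float(2 * n_boundary * radius * np.sin(np.pi / n_boundary)),
        )

    return make


@pytest.fixture()
def poiseuille_series(circle_section):
    """Factory for steady Poiseuille plane samples at uniform static pressure."""

    def make(radius=9.0, station=0.0, Q=392.0, pressure=0.0, n_rings=24):
        sec = circle_section(radius=radius, station=station)
        spec = synthetic.AnalyticFlowSpec(
            profile_kind="parabolic", Q=Q, fluctuation_rms=0.0, n_snapshots=1
        )
        return synthetic.make_plane_samples(
            spec, [sec], pressures=[pressure], n_rings=n_rings
        )[0]

    return make
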