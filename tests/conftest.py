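"""Shared fixtures and geometric helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
import shapely

from fretrack.boundary import Contour
from fretrack.synthetic import Scenario, Sector


def circle_contour(radius: float, center=(40.0, 40.0), n: int = 400, frame_index: int = 0) -> Contour:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)])
    return Contour(pts, frame_index)


def circle_with_exact_perimeter(perimeter: float, center=(40.0, 40.0), n: int = 2000) -> Contour:
    """Polygonal circle rescaled so its polygon perimeter equals ``perimeter``."""
    c = circle_contour(1.0, center=(0.0, 0.0), n=n)
    pts = c.points * (perimeter / c.perimeter)
    return Contour(pts + np.asarray(center))


def hausdorff(a: Contour, b: Contour, densify: float = 0.05) -> float:
    ga = shapely.linestrings(np.vstack([a.points, a.points[:1]]))
    gb = shapely.linestrings(np.vstack([b.points, b.points[:1]]))
    return float(shapely.hausdorff_distance(ga, gb, densify=densify))


# small image-level scenario: fast enough for end-to-end tests
MINI_POL = Scenario(
    name="MINI-POL", level="image", n_frames=8, frame_interval=2.0, release_index=2,
    sectors=(Sector(-0.55, 0.55, 12.0),),
    advance_midpoint=3.0, steepness=1.0, lead_time=4.0,
    shape_px=(128, 192), pixel_size=0.5,
    ellipse_axes=(25.0, 8.0), center=(45.0, 32.0),
    advance_duration=6.0,
)

MINI_NP = Scenario(
    name="MINI-NP", level="image", n_frames=8, frame_interval=2.0, release_index=2,
    sectors=(
        Sector(-0.45, 0.45, 10.0),
        Sector(2 * np.pi / 3 - 0.45, 2 * np.pi / 3 + 0.45, 10.0),
        Sector(4 * np.pi / 3 - 0.45, 4 * np.pi / 3 + 0.45, 10.0),
    ),
    advance_midpoint=3.0, steepness=1.0, lead_time=0.0,
    shape_px=(128, 192), pixel_size=0.5,
    ellipse_axes=(25.0, 8.0), center=(45.0, 32.0),
    advance_duration=6.0,
)


@pytest.fixture(scope="session")
def mini_pol_movie():
    from fretrack.synthetic import generate_movie

    return generate_movie(MINI_POL, seed=5)


@pytest.fixture(scope="session")
def mini_np_movie():
    from fretrack.synthetic import generate_movie

    return generate_movie(MINI_NP, seed=5)
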