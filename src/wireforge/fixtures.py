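"""Canonical study inputs.

Two preserved-region layouts cover the standard benchmark problems:
the eight corners of a cube (single-objective porosity study, 50 nm box)
and the six face centres of a parallelepiped (multi-objective studies
where the box dimensions themselves are design variables).
"""

from __future__ import annotations

import numpy as np

from .mesh import BoundingBox


def fixture_cube_corners(side: float) -> list[tuple[float, float, float]]:
    """Eight corner points of an axis-aligned cube with the given side (nm)."""
    if side <= 0:
        raise ValueError("cube side must be positive")
    s = float(side)
    return [(x, y, z) for x in (0.0, s) for y in (0.0, s) for z in (0.0, s)]


def fixture_parallelepiped_midfaces(
    a: float, b: float, c: float, gamma: float = 90.0
) -> list[tuple[float, float, float]]:
    """Six face-centre points of the (a, b, c, gamma) parallelepiped.

    The box is spanned from the origin by u = a*x_hat,
    v = b*(cos gamma, sin gamma, 0) and w = c*z_hat; the centres are
    (u+v)/2, (u+v)/2 + w, (u+w)/2, (u+w)/2 + v, (v+w)/2 and (v+w)/2 + u,
    so they always lie inside the (possibly sheared) box.
    """
    box = BoundingBox(a, b, c, gamma)  # validates dimensions
    u, v, w = box.basis().T
    centres = [
        (u + v) / 2,
        (u + v) / 2 + w,
        (u + w) / 2,
        (u + w) / 2 + v,
        (v + w) / 2,
        (v + w) / 2 + u,
    ]
    # snap away the ~1e-15 fuzz from cos(90 degrees)
    return [tuple(float(round(x, 9)) for x in p) for p in centres]
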