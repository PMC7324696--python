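"""Shared analytic fixtures: contour stacks with closed-form volumes."""

from __future__ import annotations

import math

import numpy as np
import pytest

from spacerselect.geometry import ContourSlice, ContourStack


def circle(cx, cy, r, n=180):
    th = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def square(cx, cy, half):
    return np.array(
        [
            [cx - half, cy - half],
            [cx + half, cy - half],
            [cx + half, cy + half],
            [cx - half, cy + half],
        ]
    )


def sphere_stack(radius, spacing=2.0, center=(0.0, 0.0, 0.0), name="sphere", n=180):
    """Sphere as circular cross-sections at slice centers."""
    cx, cy, cz = center
    k0 = math.floor((cz - radius) / spacing)
    k1 = math.ceil((cz + radius) / spacing)
    slices = []
    for k in range(k0, k1 + 1):
        z = k * spacing
        r2 = radius**2 - (z - cz) ** 2
        if r2 <= 0.25:  # skip sub-half-mm caps
            continue
        slices.append(ContourSlice(z, [circle(cx, cy, math.sqrt(r2), n)]))
    return ContourStack(name, slices, spacing)


def cylinder_stack(radius, height, spacing=2.0, center_xy=(0.0, 0.0), z0=0.0,
                   name="cylinder", n=180):
    nz = int(round(height / spacing))
    slices = [
        ContourSlice(z0 + (k + 0.5) * spacing, [circle(*center_xy, radius, n)])
        for k in range(nz)
    ]
    return ContourStack(name, slices, spacing)


def box_stack(size_xy, height, spacing=1.0, name="box"):
    nz = int(round(height / spacing))
    slices = [
        ContourSlice((k + 0.5) * spacing, [square(0.0, 0.0, size_xy / 2)])
        for k in range(nz)
    ]
    return ContourStack(name, slices, spacing)


def sphere_volume_cc(r_mm):
    return 4.0 / 3.0 * math.pi * r_mm**3 / 1000.0


@pytest.fixture(scope="session")
def sphere20():
    return sphere_stack(20.0, spacing=2.0)


@pytest.fixture(scope="session")
def published_registry():
    from spacerselect.decision import load_published_models

    return load_published_models()
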