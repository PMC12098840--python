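"""Independent reference implementations used as test oracles.

Everything here is deliberately brute force (direct quadrature, pixelwise
enumeration, textbook formulas evaluated term by term) and shares no code
with the package paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

MU_0 = 4.0e-7 * math.pi


def loop_field_quadrature(R, I, z0, r, z, n=100_000):
    """(B_r, B_z) of a circular loop by direct Biot-Savart line quadrature."""
    phi = (np.arange(n) + 0.5) / n * 2 * np.pi
    dl = 2 * np.pi * R / n
    sx, sy, sz = R * np.cos(phi), R * np.sin(phi), np.full(n, z0)
    tx, ty = -np.sin(phi), np.cos(phi)  # tangent (dz component 0)
    rx, ry, rz = r - sx, -sy, z - sz
    d3 = (rx * rx + ry * ry + rz * rz) ** 1.5
    bx = MU_0 * I / (4 * np.pi) * np.sum(ty * rz * dl / d3)
    bz = MU_0 * I / (4 * np.pi) * np.sum((tx * ry - ty * rx) * dl / d3)
    return bx, bz  # field point lies in the xz-plane, so B_r = B_x


def polyline_field_quadrature(vertices, I, point, n_per_seg=20_000):
    """B of a closed polygonal loop by segment-subdivided quadrature."""
    point = np.asarray(point, dtype=float)
    B = np.zeros(3)
    verts = np.asarray(vertices, dtype=float)
    for a, b in zip(verts, np.roll(verts, -1, axis=0)):
        ts = (np.arange(n_per_seg) + 0.5) / n_per_seg
        src = a[None, :] + ts[:, None] * (b - a)[None, :]
        dl = (b - a) / n_per_seg
        rv = point[None, :] - src
        d3 = np.linalg.norm(rv, axis=1) ** 3
        B += MU_0 * I / (4 * np.pi) * np.sum(np.cross(dl, rv) / d3[:, None], axis=0)
    return B


def median_threshold_bruteforce(image, kernel, threshold):
    """Median blur (replicated border) + binary threshold, pixel by pixel."""
    img = np.asarray(image, dtype=int)
    h, w = img.shape
    half = kernel // 2
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-half, half + 1):
                for dx in range(-half, half + 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    vals.append(img[yy, xx])
            vals.sort()
            med = vals[len(vals) // 2]
            out[y, x] = 255 if med > threshold else 0
    return out.astype(np.uint8)


def pearson_direct(xs, ys):
    """Pearson r straight from the definition."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / math.sqrt(np.sum(xm * xm) * np.sum(ym * ym)))


def thick_coil_center_field(inner_radius, radial_build, length, turns, current):
    """Closed-form |B| at the center of a thick solenoid (uniform J)."""
    a1 = inner_radius
    a2 = inner_radius + radial_build
    b = length / 2.0
    J = turns * current / (radial_build * length)
    return (
        MU_0
        * J
        * b
        * math.log((a2 + math.hypot(a2, b)) / (a1 + math.hypot(a1, b)))
    )


def disc_pixel_count(cx, cy, r, width, height):
    """Pixels (x, y) in a width x height grid with (x-cx)^2+(y-cy)^2 <= r^2."""
    count = 0
    for y in range(height):
        for x in range(width):
            if (x - cx) ** 2 + (y - cy) ** 2 <= r * r:
                count += 1
    return count
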