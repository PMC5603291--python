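"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's chord-length formulas: component
boundary crossings along a ray are found by fitting the (exact) quadratic
boundary function from three sampled points and taking its roots, and the
line integral is then the piecewise-constant sum of activity at interval
midpoints.  The chord through the image square is computed by polygon
clipping with shapely.
"""

import numpy as np
import shapely.geometry as sgeom


def _ray_point(angle_deg, offset, origin, t):
    th = np.deg2rad(angle_deg)
    ux, uy = np.cos(th), np.sin(th)
    vx, vy = -uy, ux
    return origin[0] + offset * ux + t * vx, origin[1] + offset * uy + t * vy


def _component_boundary_f(comp, angle_deg, offset, origin, t):
    """Quadratic-in-t boundary function: negative strictly inside."""
    x, y = _ray_point(angle_deg, offset, origin, t)
    dx, dy = x - comp.center[0], y - comp.center[1]
    phi = np.deg2rad(comp.rotation)
    c, s = np.cos(phi), np.sin(phi)
    xr = c * dx + s * dy
    yr = -s * dx + c * dy
    a, b = comp.semi_axes
    return (xr / a) ** 2 + (yr / b) ** 2 - 1.0


def line_integral_oracle(phantom, angle_deg, offset,
                         origin=(63.5, 63.5), t_span=400.0):
    """Activity integral along one ray, via quadratic root-finding.

    f(t) is an exact quadratic for every ellipse/disc, so its polynomial
    coefficients are recovered exactly from three samples and the entry/
    exit parameters are its real roots.
    """
    breakpoints = [-t_span, t_span]
    for comp in phantom.components:
        f = [_component_boundary_f(comp, angle_deg, offset, origin, t)
             for t in (-1.0, 0.0, 1.0)]
        # f(t) = c2 t^2 + c1 t + c0 from the three samples
        c2 = 0.5 * (f[0] + f[2]) - f[1]
        c1 = 0.5 * (f[2] - f[0])
        c0 = f[1]
        if c2 == 0.0:
            continue
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc > 0.0:
            r = np.sqrt(disc)
            breakpoints += [(-c1 - r) / (2 * c2), (-c1 + r) / (2 * c2)]
    ts = np.unique(np.clip(np.array(breakpoints), -t_span, t_span))
    total = 0.0
    for lo, hi in zip(ts[:-1], ts[1:]):
        if hi <= lo:
            continue
        tm = 0.5 * (lo + hi)
        x, y = _ray_point(angle_deg, offset, origin, tm)
        act = 0.0
        for comp in phantom.components:
            if _component_boundary_f(comp, angle_deg, offset, origin, tm) <= 0.0:
                act += comp.activity_delta
        total += act * (hi - lo)
    return total * phantom.amplitude


def square_chord_oracle(angle_deg, offset, origin, grid_size, t_span=400.0):
    """Chord length of a ray through the pixel square, by shapely clipping."""
    p0 = _ray_point(angle_deg, offset, origin, -t_span)
    p1 = _ray_point(angle_deg, offset, origin, t_span)
    square = sgeom.box(-0.5, -0.5, grid_size - 0.5, grid_size - 0.5)
    return sgeom.LineString([p0, p1]).intersection(square).length
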