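"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's optimised code paths: plain loops,
closed forms, and exhaustive scans, so they can certify the implementation.
"""

import math

import numpy as np
from scipy.optimize import minimize


def plain_cylinder_r(points, axis_point, axis_direction):
    """Eq-1 objective computed with plain Python loops (no shared code)."""
    u = [float(x) for x in axis_direction]
    norm = math.sqrt(sum(x * x for x in u))
    u = [x / norm for x in u]
    dists = []
    for p in np.asarray(points).reshape(-1, 3):
        d = [float(p[i]) - float(axis_point[i]) for i in range(3)]
        t = sum(d[i] * u[i] for i in range(3))
        perp = [d[i] - t * u[i] for i in range(3)]
        dists.append(math.sqrt(sum(x * x for x in perp)))
    dbar = sum(dists) / len(dists)
    return math.sqrt(sum((x - dbar) ** 2 for x in dists) / len(dists))


def grid_cylinder_oracle(points, step_deg=2.0, n_refine=30):
    """Best r over a hemisphere grid of axis directions (2-degree spacing),
    with per-direction optimal axis positioning.

    Directions are screened with a closed-form algebraic circle fit of the
    projected points; the best candidates get an exact inner 2-D position
    optimisation.  Returns the minimal r found on the grid.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    ctr = pts.mean(axis=0)

    dirs = []
    for th in np.radians(np.arange(0.0, 90.0 + step_deg, step_deg)):
        if th == 0.0:
            dirs.append([0.0, 0.0, 1.0])
            continue
        for ph in np.radians(np.arange(0.0, 360.0, step_deg)):
            dirs.append(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
            )
    dirs = np.asarray(dirs)

    def frame(u):
        e1 = np.array([1.0, 0.0, 0.0]) - u * u[0]
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.array([0.0, 1.0, 0.0]) - u * u[1]
        e1 /= np.linalg.norm(e1)
        return e1, np.cross(u, e1)

    def kasa(u):
        """Algebraic circle fit of the projection; returns (r, center2d, frame)."""
        e1, e2 = frame(u)
        d = pts - ctr
        x, y = d @ e1, d @ e2
        A = np.c_[2 * x, 2 * y, np.ones_like(x)]
        sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
        dist = np.hypot(x - sol[0], y - sol[1])
        return np.sqrt(np.mean((dist - dist.mean()) ** 2)), sol[:2], (e1, e2)

    screened = np.array([kasa(u)[0] for u in dirs])
    best = np.inf
    for i in np.argsort(screened)[:n_refine]:
        u = dirs[i]
        _, c0, (e1, e2) = kasa(u)

        def obj(p):
            origin = ctr + p[0] * e1 + p[1] * e2
            d = pts - origin
            t = d @ u
            dist = np.linalg.norm(d - np.outer(t, u), axis=1)
            return np.sqrt(np.mean((dist - dist.mean()) ** 2))

        res = minimize(
            obj, c0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}
        )
        best = min(best, res.fun)
    return float(best)


def window_max(values_by_column, center, half_width):
    """Max value within +-half_width columns of center, or None."""
    best = None
    for c, v in values_by_column.items():
        if abs(c - center) <= half_width and (best is None or v > best):
            best = v
    return best


def brute_smooth(values_by_column, window=3):
    """Window-max smoothing by exhaustive scan over all relevant columns."""
    if not values_by_column:
        return {}
    h = window // 2
    out = {}
    for c in range(min(values_by_column) - h, max(values_by_column) + h + 1):
        vals = [
            v for k, v in values_by_column.items() if abs(k - c) <= h
        ]
        if vals:
            out[c] = max(vals)
    return out


def brute_family_scan(smoothed_members, min_angles=5):
    """Most disrupted column by exhaustive scan (smallest column on ties)."""
    cols = sorted({c for m in smoothed_members for c in m})
    best_col, best_mean = None, None
    for c in cols:
        vals = [m[c] for m in smoothed_members if c in m]
        if len(vals) < min_angles:
            continue
        mean = sum(vals) / len(vals)
        if best_mean is None or mean > best_mean:
            best_col, best_mean = c, mean
    return best_col


def rank_spearman(x, y):
    """Spearman rho via explicit average ranks and Pearson on ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
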