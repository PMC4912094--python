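"""Cylinder fitting and per-site kink-angle measurement.

A kink angle at site ``s`` of a helix is the angle between the axes of two
cylinders fitted to the disjoint six-residue segments ``s-5..s`` (N-terminal)
and ``s+1..s+6`` (C-terminal).  Each cylinder is fitted to the 24 backbone
atoms (N, CA, C, O of six residues) by minimising

    r = sqrt( (1/m) * sum_i (d_i - dbar)^2 ),   m = 24,

where ``d_i`` is the distance of atom ``i`` from the axis line and ``dbar``
is the mean of the ``d_i`` (the fitted mean radius).  The angle is assigned
to the final residue of the first segment, so a helix of length ``L`` has
sites at 0-based indices ``5 .. L-7`` and must be at least 12 residues long.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, HelixTooShortError
from .structures import HelixBackbone

SEGMENT_RESIDUES = 6
SEGMENT_ATOMS = 24  # m: 6 residues x 4 backbone atoms


@dataclasses.dataclass
class CylinderFit:
    """Optimal cylinder axis for one six-residue segment.

    axis_point/axis_direction define the axis line; the direction is a unit
    vector oriented N->C along the segment.  ``r`` is the objective at the
    optimum and ``mean_radius`` the fitted mean atom-axis distance (both Å).
    """

    axis_point: np.ndarray
    axis_direction: np.ndarray
    mean_radius: float
    r: float
    segment_start_index: int = 0

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(self.axis_direction)
        if abs(norm - 1.0) > 1e-9:
            raise FitError(f"axis direction not unit (|u| = {norm})")
        if self.r < 0:
            raise FitError("negative fit residual")


def axis_distances(
    points: np.ndarray, axis_point: np.ndarray, axis_direction: np.ndarray
) -> np.ndarray:
    """Distances of points from the (infinite) axis line."""
    d = points - axis_point
    t = d @ axis_direction
    perp = d - np.outer(t, axis_direction)
    return np.linalg.norm(perp, axis=1)


def cylinder_r(
    points: np.ndarray, axis_point: np.ndarray, axis_direction: np.ndarray
) -> float:
    """The fit objective r (RMS deviation of distances from their mean)
    for an arbitrary, not necessarily optimal, axis.  The mean radius is
    re-estimated for the given axis."""
    dist = axis_distances(points, axis_point, axis_direction)
    return float(np.sqrt(np.mean((dist - dist.mean()) ** 2)))


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (u @ ref) * u
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def fit_cylinder(segment: np.ndarray, segment_start_index: int = 0) -> CylinderFit:
    """Fit the optimal cylinder axis to one six-residue segment.

    Parameters
    ----------
    segment : (6, 4, 3) or (24, 3) array
        Backbone atoms of six consecutive residues (N, CA, C, O each), Å.
        When flat, atoms are assumed grouped residue-by-residue so the
        N->C orientation can be recovered.

    The axis is parameterised as a perturbation of the principal axis of
    the 24 atoms through their centroid (direction tilt + in-plane offset,
    four parameters) and refined with a trust-region least-squares solver
    on the residual vector ``d_i - dbar``.  The returned direction is
    flipped, if needed, so that it points from the first residue's centroid
    towards the last residue's centroid.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.shape == (SEGMENT_RESIDUES, 4, 3):
        by_residue = segment
        pts = segment.reshape(-1, 3)
    elif segment.shape == (SEGMENT_ATOMS, 3):
        pts = segment
        by_residue = segment.reshape(SEGMENT_RESIDUES, 4, 3)
    else:
        raise FitError(
            f"segment must hold {SEGMENT_ATOMS} backbone atoms "
            f"(6 residues x N/CA/C/O), got shape {segment.shape}"
        )
    ctr = pts.mean(axis=0)
    centred = pts - ctr
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise FitError("degenerate segment geometry (collinear/coincident atoms)")
    u0 = vt[0]
    e1, e2 = _orthonormal_frame(u0)

    def residuals(params: np.ndarray) -> np.ndarray:
        a, b, ox, oy = params
        u = u0 + a * e1 + b * e2
        u = u / np.linalg.norm(u)
        origin = ctr + ox * e1 + oy * e2
        d = pts - origin
        t = d @ u
        dist = np.linalg.norm(d - np.outer(t, u), axis=1)
        return dist - dist.mean()

    sol = least_squares(
        residuals, np.zeros(4), xtol=1e-12, ftol=1e-12, gtol=1e-12, method="lm"
    )
    if not np.all(np.isfinite(sol.x)):
        raise FitError("cylinder fit did not converge")
    a, b, ox, oy = sol.x
    u = u0 + a * e1 + b * e2
    u = u / np.linalg.norm(u)
    origin = ctr + ox * e1 + oy * e2
    nc = by_residue[-1].mean(axis=0) - by_residue[0].mean(axis=0)
    if u @ nc < 0:
        u = -u
    dist = axis_distances(pts, origin, u)
    r = float(np.sqrt(np.mean((dist - dist.mean()) ** 2)))
    return CylinderFit(origin, u, float(dist.mean()), r, segment_start_index)


def axis_midpoint(fit: CylinderFit, points: np.ndarray) -> np.ndarray:
    """Midpoint of the axis segment spanned by the atoms' projections."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    t = (points - fit.axis_point) @ fit.axis_direction
    return fit.axis_point + 0.5 * (t.min() + t.max()) * fit.axis_direction


def angle_between_degrees(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two oriented unit vectors, degrees in [0, 180]."""
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


@dataclasses.dataclass
class KinkSite:
    """One measured site: the two flanking segments with their fitted cylinders."""

    site_index: int
    residue_id: str
    atoms_n: np.ndarray  # (6, 4, 3)
    atoms_c: np.ndarray
    fit_n: CylinderFit
    fit_c: CylinderFit

    @property
    def theta(self) -> float:
        return angle_between_degrees(self.fit_n.axis_direction, self.fit_c.axis_direction)

    @property
    def sum_r(self) -> float:
        return self.fit_n.r + self.fit_c.r


@dataclasses.dataclass
class AngleProfile:
    """Per-site kink angles of one helix.

    Arrays are aligned: ``theta[k]`` is the angle at 0-based helix residue
    index ``site_index[k]`` (author id ``residue_ids[k]``), with the two
    flanking fit residuals ``r_n[k]``/``r_c[k]`` and, once an error model is
    attached, the 95% confidence half-width ``epsilon[k]`` in degrees.
    """

    helix_id: str
    site_index: np.ndarray
    residue_ids: list[str]
    theta: np.ndarray
    r_n: np.ndarray
    r_c: np.ndarray
    epsilon: np.ndarray

    def __len__(self) -> int:
        return len(self.site_index)

    @property
    def max_theta(self) -> float:
        return float(self.theta.max())

    def attach_errors(self, model) -> "AngleProfile":
        self.epsilon = model.epsilon(self.r_n + self.r_c)
        return self

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "helix_id": self.helix_id,
                "site_index": self.site_index,
                "author_residue": self.residue_ids,
                "theta_deg": self.theta,
                "r_n": self.r_n,
                "r_c": self.r_c,
                "epsilon_deg": self.epsilon,
            }
        )

    @classmethod
    def from_frame(cls, df) -> "AngleProfile":
        helix_ids = df["helix_id"].unique()
        if len(helix_ids) != 1:
            raise ValueError(f"expected one helix per table, got {list(helix_ids)}")
        return cls(
            helix_id=str(helix_ids[0]),
            site_index=df["site_index"].to_numpy(dtype=int),
            residue_ids=[str(x) for x in df["author_residue"]],
            theta=df["theta_deg"].to_numpy(dtype=float),
            r_n=df["r_n"].to_numpy(dtype=float),
            r_c=df["r_c"].to_numpy(dtype=float),
            epsilon=df["epsilon_deg"].to_numpy(dtype=float)
            if "epsilon_deg" in df
            else np.full(len(df), np.nan),
        )


def site_range(n_residues: int) -> range:
    """0-based site indices measurable on a helix of the given length."""
    return range(5, n_residues - 6)


def measure_site(helix: HelixBackbone, site: int) -> KinkSite:
    """Fit the two flanking cylinders at one site and package the result."""
    if site not in site_range(helix.n_residues):
        raise IndexError(f"site {site} not measurable on length-{helix.n_residues} helix")
    atoms_n = helix.segment(site - 5)
    atoms_c = helix.segment(site + 1)
    fit_n = fit_cylinder(atoms_n, segment_start_index=site - 5)
    fit_c = fit_cylinder(atoms_c, segment_start_index=site + 1)
    return KinkSite(site, helix.residue_ids[site], atoms_n, atoms_c, fit_n, fit_c)


def measure_angles(helix: HelixBackbone, error_model=None) -> AngleProfile:
    """Measure the kink angle at every site of a helix.

    Raises :class:`HelixTooShortError` for helices under 12 residues; a
    12-residue helix yields exactly one site (index 5).
    """
    if not helix.is_analysable:
        raise HelixTooShortError(
            f"helix {helix.helix_id!r} has {helix.n_residues} residues; "
            "only helices 12 residues or longer can be analysed"
        )
    sites = list(site_range(helix.n_residues))
    theta = np.empty(len(sites))
    r_n = np.empty(len(sites))
    r_c = np.empty(len(sites))
    rids = []
    for k, s in enumerate(sites):
        ks = measure_site(helix, s)
        theta[k] = ks.theta
        r_n[k] = ks.fit_n.r
        r_c[k] = ks.fit_c.r
        rids.append(ks.residue_id)
    profile = AngleProfile(
        helix.helix_id,
        np.array(sites, dtype=int),
        rids,
        theta,
        r_n,
        r_c,
        np.full(len(sites), np.nan),
    )
    if error_model is not None:
        profile.attach_errors(error_model)
    return profile
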