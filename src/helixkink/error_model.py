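"""Heuristic confidence intervals on measured kink angles.

The half-width of the 95% confidence interval on a kink angle is predicted
from the quality of the two flanking cylinder fits,

    epsilon = a * ln(r_n + r_c - c) + b        (degrees),

with published defaults a = 6.349, b = 13.15, c = 0.2937 Å.  The model is
calibrated by a Monte-Carlo perturbation experiment: taking well-fitted
kinks, whose optimal axes are assumed to give the true angle, both cylinder
axes are rotated about their midpoints by random rotations; each perturbed
measurement yields an angle deviation ``alpha = theta - true_angle`` and a
degraded fit sum ``r_n + r_c``.  Binning |alpha| by r_n + r_c and taking the
95th percentile per bin gives per-bin epsilon values, to which the log curve
is fitted by least squares.

Because the log diverges as r_n + r_c -> c+, and a near-perfect helix can
legitimately have r_n + r_c below c, epsilon is clamped at a floor slightly
above c so the map is total.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .geometry import (
    KinkSite,
    angle_between_degrees,
    axis_midpoint,
    cylinder_r,
)

PUBLISHED_A = 6.349  # degrees
PUBLISHED_B = 13.15  # degrees
PUBLISHED_C = 0.2937  # Å
DEFAULT_FLOOR_MARGIN = 0.01  # Å above c
DEFAULT_MAX_TILT = 15.0  # degrees
DEFAULT_BIN_WIDTH = 0.05  # Å
MIN_SAMPLES_PER_BIN = 100
MIN_CALIBRATION_ANGLE = 10.0  # kinks at or under 10 degrees are excluded


@dataclasses.dataclass
class ErrorModel:
    """epsilon = a*ln(sum_r - c) + b, clamped below ``floor_sum_r``."""

    a: float = PUBLISHED_A
    b: float = PUBLISHED_B
    c: float = PUBLISHED_C
    floor_sum_r: float | None = None
    provenance: str = "published-default"

    def __post_init__(self) -> None:
        if self.floor_sum_r is None:
            self.floor_sum_r = self.c + DEFAULT_FLOOR_MARGIN
        if self.floor_sum_r <= self.c:
            raise ValueError("floor_sum_r must exceed c")

    def epsilon(self, sum_r):
        """Confidence half-width (degrees) for r_n + r_c (Å); vectorised."""
        x = np.maximum(np.asarray(sum_r, dtype=float), self.floor_sum_r)
        out = self.a * np.log(x - self.c) + self.b
        return out if out.ndim else float(out)

    @classmethod
    def published_default(cls) -> "ErrorModel":
        return cls()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "a": self.a,
                    "b": self.b,
                    "c": self.c,
                    "floor_sum_r": self.floor_sum_r,
                    "provenance": self.provenance,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ErrorModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def angles_differ(theta1: float, eps1: float, theta2: float, eps2: float) -> bool:
    """True iff the two confidence intervals do not overlap:
    |theta1 - theta2| > eps1 + eps2."""
    if min(eps1, eps2) < 0:
        raise ValueError("epsilon must be non-negative")
    return abs(theta1 - theta2) > eps1 + eps2


@dataclasses.dataclass
class PerturbationSample:
    """One Monte-Carlo perturbation of a kink measurement."""

    true_angle: float  # degrees
    measured_angle: float  # degrees
    alpha: float  # measured - true, degrees
    sum_r: float  # r_n + r_c against the perturbed axes, Å


def _random_rotations(n: int, max_tilt_deg: float, rng: np.random.Generator) -> np.ndarray:
    """(n, 3, 3) rotations: axis uniform on the sphere, angle uniform (0, max]."""
    axis = rng.normal(size=(n, 3))
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    ang = np.radians(rng.uniform(0.0, max_tilt_deg, size=n))
    # Avoid an exactly-zero rotation; the distribution is open at 0.
    ang = np.where(ang == 0.0, np.radians(max_tilt_deg) * 1e-12, ang)
    c, s = np.cos(ang), np.sin(ang)
    K = np.zeros((n, 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
    eye = np.eye(3)[None]
    return eye + s[:, None, None] * K + (1 - c)[:, None, None] * (K @ K)


def perturb_samples(
    site: KinkSite,
    n: int,
    max_tilt_deg: float = DEFAULT_MAX_TILT,
    rng: np.random.Generator | int | None = None,
) -> list[PerturbationSample]:
    """Draw ``n`` random-rotation perturbations of one kink measurement.

    Each of the two fitted cylinder axes is independently rotated about the
    midpoint of its own atom span (axis of rotation uniform on the sphere,
    rotation angle uniform in (0, max_tilt_deg]).  The angle between the
    rotated axes is the perturbed measurement; r_n and r_c are re-evaluated
    as the fit objective of each segment's atoms against its rotated axis,
    with the mean radius re-estimated per axis.
    """
    if max_tilt_deg <= 0:
        raise ValueError("max_tilt_deg must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    true_angle = site.theta
    pts_n = site.atoms_n.reshape(-1, 3)
    pts_c = site.atoms_c.reshape(-1, 3)
    mid_n = axis_midpoint(site.fit_n, pts_n)
    mid_c = axis_midpoint(site.fit_c, pts_c)
    rot_n = _random_rotations(n, max_tilt_deg, rng)
    rot_c = _random_rotations(n, max_tilt_deg, rng)
    u_n = rot_n @ site.fit_n.axis_direction
    u_c = rot_c @ site.fit_c.axis_direction
    cosang = np.clip(np.einsum("ij,ij->i", u_n, u_c), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    sum_r = _batch_r(pts_n, mid_n, u_n) + _batch_r(pts_c, mid_c, u_c)
    return [
        PerturbationSample(true_angle, float(t), float(t - true_angle), float(sr))
        for t, sr in zip(theta, sum_r)
    ]


def _batch_r(points: np.ndarray, origin: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Eq-1 objective of one segment against many axes through ``origin``."""
    d = points - origin  # (m, 3)
    t = d @ directions.T  # (m, n)
    perp2 = (d * d).sum(axis=1)[:, None] - t * t
    dist = np.sqrt(np.maximum(perp2, 0.0))
    return np.sqrt(((dist - dist.mean(axis=0)) ** 2).mean(axis=0))


def perturb_measurement(
    site: KinkSite,
    max_tilt_deg: float = DEFAULT_MAX_TILT,
    rng: np.random.Generator | int | None = None,
) -> PerturbationSample:
    """A single perturbation draw (see :func:`perturb_samples`)."""
    return perturb_samples(site, 1, max_tilt_deg, rng)[0]


@dataclasses.dataclass
class CalibrationResult:
    """Fitted model plus the per-bin statistics behind it."""

    model: ErrorModel
    bin_edges: np.ndarray  # (k+1,) Å, after merging underpopulated bins
    bin_mid: np.ndarray  # (k,) Å
    bin_epsilon: np.ndarray  # (k,) degrees: 95th percentile of |alpha| per bin
    bin_count: np.ndarray  # (k,)


def bin_samples(
    sum_r: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_per_bin: int = MIN_SAMPLES_PER_BIN,
) -> np.ndarray:
    """Bin edges over sum_r at the given width, with underpopulated leading
    runs merged left-to-right so each final bin holds >= min_per_bin samples
    (a trailing remainder is merged into the last bin)."""
    lo = np.floor(sum_r.min() / bin_width) * bin_width
    hi = sum_r.max()
    raw = lo + bin_width * np.arange(int(np.ceil((hi - lo) / bin_width)) + 1)
    if raw[-1] <= hi:
        raw = np.append(raw, raw[-1] + bin_width)
    counts, _ = np.histogram(sum_r, bins=raw)
    edges = [raw[0]]
    acc = 0
    for i, cnt in enumerate(counts):
        acc += cnt
        if acc >= min_per_bin:
            edges.append(raw[i + 1])
            acc = 0
    if acc > 0 and len(edges) > 1:
        edges[-1] = raw[-1]
    elif len(edges) == 1:
        edges.append(raw[-1])
    return np.asarray(edges)


def per_bin_percentile(
    alpha: np.ndarray, sum_r: np.ndarray, edges: np.ndarray, q: float = 95.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin q-th percentile of |alpha| (linear interpolation between order
    statistics); returns (bin midpoints, percentiles, counts)."""
    idx = np.clip(np.digitize(sum_r, edges) - 1, 0, len(edges) - 2)
    mids, eps, counts = [], [], []
    for k in range(len(edges) - 1):
        mask = idx == k
        n = int(mask.sum())
        if n == 0:
            continue
        mids.append(0.5 * (edges[k] + edges[k + 1]))
        eps.append(np.percentile(np.abs(alpha[mask]), q))
        counts.append(n)
    return np.asarray(mids), np.asarray(eps), np.asarray(counts)


def calibrate_error_model(
    samples: list[PerturbationSample],
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_per_bin: int = MIN_SAMPLES_PER_BIN,
    min_true_angle: float = MIN_CALIBRATION_ANGLE,
) -> CalibrationResult:
    """Fit epsilon = a*ln(x - c) + b to per-bin 95th percentiles of |alpha|.

    Samples from kinks with true angle <= ``min_true_angle`` (degrees) are
    excluded; at least five populated bins are required.
    """
    kept = [s for s in samples if s.true_angle > min_true_angle]
    if not kept:
        raise ValueError("no samples from kinks above the minimum true angle")
    alpha = np.array([s.alpha for s in kept])
    sum_r = np.array([s.sum_r for s in kept])
    edges = bin_samples(sum_r, bin_width, min_per_bin)
    mids, eps, counts = per_bin_percentile(alpha, sum_r, edges)
    if len(mids) < 5:
        raise ValueError(f"only {len(mids)} populated bins; need at least 5")

    def f(x, a, b, c):
        return a * np.log(x - c) + b

    cmax = mids.min() - 1e-6
    c0 = min(PUBLISHED_C, mids.min() - 0.05)
    lin = np.polyfit(np.log(mids - c0), eps, 1)
    p0 = (lin[0], lin[1], c0)
    popt, _ = curve_fit(
        f,
        mids,
        eps,
        p0=p0,
        bounds=([-np.inf, -np.inf, -np.inf], [np.inf, np.inf, cmax]),
        maxfev=20000,
    )
    a, b, c = (float(v) for v in popt)
    model = ErrorModel(a=a, b=b, c=c, provenance="recalibrated")
    return CalibrationResult(model, edges, mids, eps, counts)


def bin_coverage(
    edges: np.ndarray,
    bin_epsilon: np.ndarray,
    alpha: np.ndarray,
    sum_r: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of fresh samples per bin with |alpha| <= the bin's epsilon.

    Returns (per-bin coverage fractions, per-bin counts), for the bins of a
    previous calibration; fresh samples falling outside the calibrated range
    are assigned to the nearest edge bin.
    """
    idx = np.clip(np.digitize(sum_r, edges) - 1, 0, len(edges) - 2)
    k_present = np.arange(len(edges) - 1)
    eps_by_bin = np.full(len(edges) - 1, np.nan)
    # bin_epsilon corresponds to populated bins in order; rebuild mapping
    mids_all = 0.5 * (edges[:-1] + edges[1:])
    if len(bin_epsilon) == len(mids_all):
        eps_by_bin[:] = bin_epsilon
    else:  # pragma: no cover - only when some calibration bins were empty
        raise ValueError("bin_epsilon must align with edges")
    cov, cnt = [], []
    for k in k_present:
        mask = idx == k
        n = int(mask.sum())
        if n == 0 or np.isnan(eps_by_bin[k]):
            continue
        cov.append(float(np.mean(np.abs(alpha[mask]) <= eps_by_bin[k])))
        cnt.append(n)
    return np.asarray(cov), np.asarray(cnt)
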