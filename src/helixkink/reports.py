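"""Run configuration and per-site family summary tables.

The profile report gives, for every alignment column of a classified
family, the distribution of smoothed angles (n, min, quartiles, median,
max), the mean error, and a flag on the most disrupted site — the tabular
form of a per-site angle-distribution plot.  The subgroup split report
lists the angles of labelled member subsets at one column, for comparing
e.g. receptor subfamilies or ligand states.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .conservation import (
    DEFAULT_KINK_THRESHOLD,
    DEFAULT_MIN_ANGLES_PER_SITE,
    DEFAULT_MIN_FAMILY_SIZE,
    DEFAULT_PAIR_WINDOW,
    DEFAULT_SMOOTH_WINDOW,
    FamilyRecord,
)

logger = logging.getLogger("helixkink")


@dataclasses.dataclass
class RunConfig:
    """All tunable thresholds, echoed into every output header."""

    kink_threshold_deg: float = DEFAULT_KINK_THRESHOLD
    error_model: str = "published-default"
    smoothing_window: int = DEFAULT_SMOOTH_WINDOW
    pair_window: int = DEFAULT_PAIR_WINDOW
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE
    min_angles_per_site: int = DEFAULT_MIN_ANGLES_PER_SITE
    seed: int | None = None
    verbosity: str = "WARNING"

    def __post_init__(self) -> None:
        if (
            self.kink_threshold_deg <= 0
            or self.smoothing_window <= 0
            or self.pair_window <= 0
            or self.min_family_size <= 0
            or self.min_angles_per_site <= 0
        ):
            raise ValueError("all windows and thresholds must be positive")

    def header_lines(self) -> list[str]:
        return [
            "angles in degrees, distances in Å",
            f"kink_threshold_deg = {self.kink_threshold_deg}",
            f"error_model = {self.error_model}",
            f"smoothing_window = {self.smoothing_window}",
            f"pair_window = ±{self.pair_window}",
            f"min_family_size = {self.min_family_size}",
            f"min_angles_per_site = {self.min_angles_per_site}",
            f"seed = {self.seed}",
        ]

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def family_profile_report(family: FamilyRecord) -> pd.DataFrame:
    """Per-column distribution of smoothed angles for a classified family.

    One row per alignment column holding at least one smoothed angle:
    n, min, lower quartile, median, upper quartile, max (degrees), mean
    epsilon of the raw angles at that column, and a flag marking the most
    disrupted site.
    """
    columns = sorted({c for m in family.smoothed.values() for c in m})
    rows = []
    for c in columns:
        vals = np.array(
            [m[c] for m in family.smoothed.values() if c in m], dtype=float
        )
        eps = np.array(
            [e[c] for e in family.epsilons.values() if c in e], dtype=float
        )
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "column": c,
                "n": len(vals),
                "min_deg": vals.min(),
                "q1_deg": q1,
                "median_deg": med,
                "q3_deg": q3,
                "max_deg": vals.max(),
                "mean_epsilon_deg": eps.mean() if len(eps) else np.nan,
                "most_disrupted": c == family.most_disrupted_column,
            }
        )
    return pd.DataFrame(rows)


def family_header(family: FamilyRecord) -> list[str]:
    return [
        f"class = {family.kink_class.value}",
        f"most_disrupted_column = {family.most_disrupted_column}",
        f"theta_median = {family.theta_median:.3f} deg",
        f"sigma_theta = {family.sigma_theta:.3f} deg",
        f"mu_epsilon = {family.mu_eps:.3f} deg",
        f"n_members = {len(family.member_ids)}",
    ]


def subgroup_split_report(
    family: FamilyRecord,
    labels: Mapping[str, str],
    column: int | None = None,
) -> pd.DataFrame:
    """Angles per labelled subgroup at one alignment column.

    ``labels`` maps member id -> subgroup label; unknown members raise.
    One row per label with n, median angle and the semicolon-joined angle
    list, at the requested column (default: the most disrupted site).
    """
    unknown = set(labels) - set(family.member_ids)
    if unknown:
        raise ValueError(f"labels for unknown members: {sorted(unknown)}")
    col = family.most_disrupted_column if column is None else column
    rows = []
    for label in sorted(set(labels.values())):
        members = sorted(m for m, l in labels.items() if l == label)
        vals = [
            family.smoothed[m][col] for m in members if col in family.smoothed[m]
        ]
        rows.append(
            {
                "label": label,
                "column": col,
                "n": len(vals),
                "median_deg": float(np.median(vals)) if vals else np.nan,
                "angles_deg": ";".join(f"{v:.3f}" for v in vals),
            }
        )
    return pd.DataFrame(rows)
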