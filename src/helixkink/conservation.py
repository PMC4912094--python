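"""Kink-conservation classification for homologous helix pairs and families.

A pair of homologous helices is compared at the *most disrupted site*: the
site of the greatest angle in either helix.  That angle (theta_max) is
compared with the largest angle of the other helix within a window of +-4
alignment columns of the site (theta_min); pairs whose window holds no angle
(because of gaps) are removed.  With the per-angle confidence half-widths
eps1, eps2, pairs are classified:

    Conserved Straight   theta_max < 20 deg
    Conserved Kinked     theta_min > 20 deg and dtheta < eps1 + eps2
    Not Conserved        theta_max > 20 deg and dtheta > eps1 + eps2
    Other                everything else

Families (>= 5 aligned members) are classified analogously at the column
with the highest mean *smoothed* angle (each member's angle at a column is
replaced by the maximum over a three-column window, absorbing small
alignment errors; only columns with at least five smoothed angles are
eligible): the median angle, the standard deviation sigma_theta and the
mean error mu_eps at that column take the roles of the pair statistics,
with ties (sigma_theta = mu_eps) assigned to the conserved side.
"""

from __future__ import annotations

import dataclasses
import enum
import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .geometry import AngleProfile

DEFAULT_KINK_THRESHOLD = 20.0  # degrees
DEFAULT_PAIR_WINDOW = 4  # alignment columns either side of the kink site
DEFAULT_SMOOTH_WINDOW = 3  # columns
DEFAULT_MIN_FAMILY_SIZE = 5
DEFAULT_MIN_ANGLES_PER_SITE = 5
DEFAULT_CONTACT_CUTOFF = 4.0  # Å
PROLINE_FOLLOWING = 4  # residues after the site checked for proline


class KinkClass(str, enum.Enum):
    CONSERVED_STRAIGHT = "ConservedStraight"
    CONSERVED_KINKED = "ConservedKinked"
    NOT_CONSERVED = "NotConserved"
    OTHER = "Other"
    REMOVED = "Removed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# ---------------------------------------------------------------------------
# homology filters

@dataclasses.dataclass(frozen=True)
class HomologyCandidate:
    """A candidate homologous helix pair with its chain-level statistics."""

    chain_length_a: int
    chain_length_b: int
    tm_score: float
    sequence_identity: float  # fraction, gaps ignored
    helix_offset_n: int  # alignment offset of N-terminal helix ends, residues
    helix_offset_c: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.tm_score <= 1.0:
            raise ValueError("TM-score must be in [0, 1]")
        if not 0.0 <= self.sequence_identity <= 1.0:
            raise ValueError("sequence identity must be in [0, 1]")


def filter_homologous_pair(candidate: HomologyCandidate) -> bool:
    """Acceptance rule for a candidate homologous helix pair.

    Accept iff the longer chain is no more than 50% longer than the shorter,
    the structural alignment has TM-score strictly above 0.5, sequence
    identity (gaps ignored) is at least 10%, and both helix ends are offset
    by no more than four residues in the alignment.
    """
    lo = min(candidate.chain_length_a, candidate.chain_length_b)
    hi = max(candidate.chain_length_a, candidate.chain_length_b)
    return (
        hi <= 1.5 * lo
        and candidate.tm_score > 0.5
        and candidate.sequence_identity >= 0.10
        and abs(candidate.helix_offset_n) <= 4
        and abs(candidate.helix_offset_c) <= 4
    )


# ---------------------------------------------------------------------------
# alignment-column bookkeeping

def residue_columns(aligned_seq: str) -> list[int]:
    """Column index of each residue (non-gap position) of a gapped sequence."""
    return [c for c, ch in enumerate(aligned_seq) if ch != "-"]


def angles_by_column(profile: AngleProfile, aligned_seq: str) -> dict[int, float]:
    """Map each measured site of a helix to its alignment column.

    The k-th non-gap character of ``aligned_seq`` is residue k of the helix;
    sites index residues, so site s lands at the column of residue s.
    """
    cols = residue_columns(aligned_seq)
    n_res = len(cols)
    out: dict[int, float] = {}
    for s, theta in zip(profile.site_index, profile.theta):
        if s >= n_res:
            raise ValueError(
                f"profile site {s} beyond aligned sequence of {n_res} residues"
            )
        out[cols[s]] = float(theta)
    return out


def _values_by_column(profile: AngleProfile, aligned_seq: str, values) -> dict[int, float]:
    cols = residue_columns(aligned_seq)
    return {cols[s]: float(v) for s, v in zip(profile.site_index, values)}


# ---------------------------------------------------------------------------
# pair classification

@dataclasses.dataclass
class PairRecord:
    """Outcome of comparing one homologous helix pair."""

    helix_id_a: str
    helix_id_b: str
    kink_class: KinkClass
    most_disrupted_column: int | None = None
    theta_max: float | None = None
    theta_min: float | None = None
    eps1: float | None = None
    eps2: float | None = None
    proline_a: bool | None = None
    proline_b: bool | None = None


def pair_most_disrupted(
    angles_a: Mapping[int, float],
    angles_b: Mapping[int, float],
    window: int = DEFAULT_PAIR_WINDOW,
) -> tuple[int, float, int, float] | None:
    """Locate the most disrupted site of a pair.

    Returns (column of theta_max, theta_max, matched column, theta_min)
    where theta_min is the largest angle of the *other* helix within
    ``window`` columns of the theta_max column, or None (pair removed) if
    that window holds no angle because of gaps.
    """
    if not angles_a or not angles_b:
        return None
    best_a = max(angles_a, key=lambda c: (angles_a[c], -c))
    best_b = max(angles_b, key=lambda c: (angles_b[c], -c))
    if angles_a[best_a] >= angles_b[best_b]:
        col_max, theta_max, other = best_a, angles_a[best_a], angles_b
    else:
        col_max, theta_max, other = best_b, angles_b[best_b], angles_a
    in_window = {
        c: v for c, v in other.items() if abs(c - col_max) <= window
    }
    if not in_window:
        return None
    col_min = max(in_window, key=lambda c: (in_window[c], -c))
    return col_max, theta_max, col_min, in_window[col_min]


def classify_pair(
    theta_max: float,
    theta_min: float,
    eps1: float,
    eps2: float,
    kink_threshold: float = DEFAULT_KINK_THRESHOLD,
) -> KinkClass:
    """Classify a pair from its most-disrupted-site statistics (degrees)."""
    if theta_max < theta_min:
        raise ValueError("theta_max must be >= theta_min")
    if min(eps1, eps2) < 0:
        raise ValueError("epsilon must be non-negative")
    dtheta = theta_max - theta_min
    eps_sum = eps1 + eps2
    if theta_max < kink_threshold:
        return KinkClass.CONSERVED_STRAIGHT
    if theta_min > kink_threshold and dtheta < eps_sum:
        return KinkClass.CONSERVED_KINKED
    if theta_max > kink_threshold and dtheta > eps_sum:
        return KinkClass.NOT_CONSERVED
    return KinkClass.OTHER


def _proline_flag(aligned_seq: str, column: int, following: int = PROLINE_FOLLOWING) -> bool:
    """Proline at the site residue or the ``following`` residues after it,
    counted in the helix's own sequence (gaps skipped)."""
    cols = residue_columns(aligned_seq)
    try:
        idx = cols.index(column)
    except ValueError:
        # site column is a gap in this helix; start from the next residue
        later = [i for i, c in enumerate(cols) if c > column]
        if not later:
            return False
        idx = later[0]
    stretch = [aligned_seq[c] for c in cols[idx : idx + following + 1]]
    return "P" in stretch


def classify_pair_profiles(
    profile_a: AngleProfile,
    aligned_a: str,
    profile_b: AngleProfile,
    aligned_b: str,
    window: int = DEFAULT_PAIR_WINDOW,
    kink_threshold: float = DEFAULT_KINK_THRESHOLD,
) -> PairRecord:
    """Full pair pipeline: locate the most disrupted site, look up the two
    angles' errors, classify, and flag proline near the site in each helix.

    Both profiles must already carry epsilon values (an error model was
    attached during measurement)."""
    ang_a = angles_by_column(profile_a, aligned_a)
    ang_b = angles_by_column(profile_b, aligned_b)
    eps_a = _values_by_column(profile_a, aligned_a, profile_a.epsilon)
    eps_b = _values_by_column(profile_b, aligned_b, profile_b.epsilon)
    hit = pair_most_disrupted(ang_a, ang_b, window)
    if hit is None:
        return PairRecord(profile_a.helix_id, profile_b.helix_id, KinkClass.REMOVED)
    col_max, theta_max, col_min, theta_min = hit
    if col_max in ang_a and ang_a[col_max] == theta_max:
        e1, e2 = eps_a[col_max], eps_b[col_min]
    else:
        e1, e2 = eps_b[col_max], eps_a[col_min]
    if np.isnan(e1) or np.isnan(e2):
        raise ValueError("profiles lack epsilon values; attach an error model")
    cls = classify_pair(theta_max, theta_min, e1, e2, kink_threshold)
    return PairRecord(
        profile_a.helix_id,
        profile_b.helix_id,
        cls,
        most_disrupted_column=col_max,
        theta_max=theta_max,
        theta_min=theta_min,
        eps1=e1,
        eps2=e2,
        proline_a=_proline_flag(aligned_a, col_max),
        proline_b=_proline_flag(aligned_b, col_max),
    )


# ---------------------------------------------------------------------------
# family classification

def smooth_profile(
    angles: Mapping[int, float], window: int = DEFAULT_SMOOTH_WINDOW
) -> dict[int, float]:
    """Replace each column's angle by the maximum over a centred window.

    The smoothed value at column c is the maximum of the available angles at
    columns c-h .. c+h (h = window//2); it is defined wherever at least one
    angle falls in the window, so smoothing also extends one column beyond
    isolated angles.  Defined values never decrease.
    """
    if not angles:
        return {}
    h = window // 2
    out: dict[int, float] = {}
    lo, hi = min(angles), max(angles)
    for c in range(lo - h, hi + h + 1):
        vals = [angles[k] for k in range(c - h, c + h + 1) if k in angles]
        if vals:
            out[c] = max(vals)
    return out


def family_most_disrupted(
    smoothed: Sequence[Mapping[int, float]],
    min_angles: int = DEFAULT_MIN_ANGLES_PER_SITE,
) -> int:
    """Column with the highest mean smoothed angle among columns holding at
    least ``min_angles`` smoothed angles; ties go to the smallest column."""
    counts: dict[int, list[float]] = {}
    for member in smoothed:
        for c, v in member.items():
            counts.setdefault(c, []).append(v)
    eligible = {c: vals for c, vals in counts.items() if len(vals) >= min_angles}
    if not eligible:
        raise ValueError(
            f"no alignment column has at least {min_angles} smoothed angles"
        )
    return min(eligible, key=lambda c: (-float(np.mean(eligible[c])), c))


def classify_family(
    thetas: Sequence[float],
    epsilons: Sequence[float],
    kink_threshold: float = DEFAULT_KINK_THRESHOLD,
    min_members: int = DEFAULT_MIN_ANGLES_PER_SITE,
) -> tuple[KinkClass, float, float, float]:
    """Classify a family from the angles at its most disrupted column.

    Returns (class, theta_median, sigma_theta, mu_eps).  sigma_theta is the
    sample standard deviation (n-1 denominator); sigma_theta = mu_eps ties
    fall on the conserved side.
    """
    thetas = np.asarray(thetas, dtype=float)
    epsilons = np.asarray(epsilons, dtype=float)
    if len(thetas) < min_members:
        raise ValueError(f"need at least {min_members} angles, got {len(thetas)}")
    med = float(np.median(thetas))
    sigma = float(np.std(thetas, ddof=1))
    mu_eps = float(np.mean(epsilons))
    if sigma <= mu_eps:
        cls = (
            KinkClass.CONSERVED_STRAIGHT
            if med < kink_threshold
            else KinkClass.CONSERVED_KINKED
        )
    elif thetas.max() > kink_threshold:
        cls = KinkClass.NOT_CONSERVED
    else:
        cls = KinkClass.OTHER
    return cls, med, sigma, mu_eps


@dataclasses.dataclass
class FamilyRecord:
    """Outcome of classifying one aligned helix family."""

    member_ids: list[str]
    kink_class: KinkClass
    most_disrupted_column: int
    theta_median: float
    sigma_theta: float
    mu_eps: float
    smoothed: dict[str, dict[int, float]]
    raw_angles: dict[str, dict[int, float]]
    epsilons: dict[str, dict[int, float]]


def classify_family_profiles(
    profiles: Mapping[str, AngleProfile],
    aligned_seqs: Mapping[str, str],
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    kink_threshold: float = DEFAULT_KINK_THRESHOLD,
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
    min_angles_per_site: int = DEFAULT_MIN_ANGLES_PER_SITE,
) -> FamilyRecord:
    """Full family pipeline over aligned member profiles.

    ``profiles`` and ``aligned_seqs`` are keyed by member id; every profile
    must carry epsilon values.  The per-member mean error entering mu_eps is
    taken from each member's (unsmoothed) angle nearest the most disrupted
    column, matching how the smoothed angle at a column originates from a
    nearby raw measurement.
    """
    members = sorted(profiles)
    if len(members) < min_family_size:
        raise ValueError(
            f"family has {len(members)} members; need >= {min_family_size}"
        )
    missing = [m for m in members if m not in aligned_seqs]
    if missing:
        raise ValueError(f"members missing from alignment: {missing}")
    lengths = {len(aligned_seqs[m]) for m in members}
    if len(lengths) != 1:
        raise ValueError("aligned sequences have inconsistent lengths")
    raw = {m: angles_by_column(profiles[m], aligned_seqs[m]) for m in members}
    eps = {
        m: _values_by_column(profiles[m], aligned_seqs[m], profiles[m].epsilon)
        for m in members
    }
    smoothed = {m: smooth_profile(raw[m], smooth_window) for m in members}
    col = family_most_disrupted(
        [smoothed[m] for m in members], min_angles_per_site
    )
    h = smooth_window // 2
    thetas, errs = [], []
    for m in members:
        if col not in smoothed[m]:
            continue
        thetas.append(smoothed[m][col])
        # epsilon of the raw angle the smoothed value came from
        win = {c: raw[m][c] for c in range(col - h, col + h + 1) if c in raw[m]}
        src = max(win, key=lambda c: (win[c], -c))
        errs.append(eps[m][src])
    cls, med, sigma, mu_eps = classify_family(
        thetas, errs, kink_threshold, min_angles_per_site
    )
    return FamilyRecord(
        member_ids=members,
        kink_class=cls,
        most_disrupted_column=col,
        theta_median=med,
        sigma_theta=sigma,
        mu_eps=mu_eps,
        smoothed=smoothed,
        raw_angles=raw,
        epsilons=eps,
    )


# ---------------------------------------------------------------------------
# family membership pruning

def prune_family(
    members: Iterable[str],
    edges: Iterable[tuple[str, str]],
    min_connectivity: float = 0.9,
    min_size: int = DEFAULT_MIN_FAMILY_SIZE,
) -> list[str]:
    """Prune a candidate community to members connected to >90% of the rest.

    While any member is connected to ``min_connectivity`` or less of the
    other members, the member with the lowest connectivity is removed (ties:
    lexicographically smallest id) and connectivities are recomputed.
    Communities that end up below ``min_size`` members are discarded
    (empty list returned).  The result is independent of input order.
    """
    nodes = set(members)
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        if a in nodes and b in nodes and a != b:
            adj[a].add(b)
            adj[b].add(a)
    while len(nodes) > 1:
        conn = {n: len(adj[n] & nodes) / (len(nodes) - 1) for n in nodes}
        worst = min(nodes, key=lambda n: (conn[n], n))
        if conn[worst] > min_connectivity:
            break
        nodes.discard(worst)
    if len(nodes) < min_size:
        return []
    return sorted(nodes)


# ---------------------------------------------------------------------------
# sequence identity

def sequence_identity(
    aligned_a: str,
    aligned_b: str,
    columns: Iterable[int] | None = None,
) -> float | None:
    """Pairwise identity over columns where neither sequence is gapped,
    optionally restricted to a column subset.  None if no comparable columns."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    cols = range(len(aligned_a)) if columns is None else sorted(set(columns))
    match = total = 0
    for c in cols:
        x, y = aligned_a[c], aligned_b[c]
        if x == "-" or y == "-":
            continue
        total += 1
        match += x == y
    if total == 0:
        return None
    return match / total


def family_sequence_identity(
    aligned_seqs: Mapping[str, str], columns: Iterable[int] | None = None
) -> float | None:
    """Mean pairwise identity over all member pairs (gaps ignored)."""
    members = sorted(aligned_seqs)
    if len(members) < 2:
        raise ValueError("need at least two sequences")
    vals = [
        v
        for a, b in itertools.combinations(members, 2)
        if (v := sequence_identity(aligned_seqs[a], aligned_seqs[b], columns))
        is not None
    ]
    if not vals:
        return None
    return float(np.mean(vals))


def _chain_residue_data(model, chain_id: str):
    """Per-residue (author id, atom coordinate array) for one chain."""
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not found")
    out = []
    for res in chain:
        xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
        icode = res.seqid.icode.strip()
        out.append((f"{res.seqid.num}{icode}", xyz))
    return out


def _neighbour_residue_indices(
    residues, helix_start_idx: int, helix_end_idx: int, cutoff: float
) -> set[int]:
    helix_atoms = np.vstack(
        [xyz for _, xyz in residues[helix_start_idx : helix_end_idx + 1]]
    )
    tree = cKDTree(helix_atoms)
    neighbours: set[int] = set()
    for i, (_, xyz) in enumerate(residues):
        if helix_start_idx <= i <= helix_end_idx:
            continue
        if tree.query_ball_point(xyz, cutoff, return_length=True).sum() > 0:
            neighbours.add(i)
    return neighbours


def neighbouring_sequence_identity(
    model_a,
    chain_a: str,
    helix_range_a: tuple[int, int],
    aligned_chain_a: str,
    model_b,
    chain_b: str,
    helix_range_b: tuple[int, int],
    aligned_chain_b: str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> float | None:
    """Sequence identity among residues in spatial proximity to a helix pair.

    For each structure, the neighbour set is every residue of the chain
    outside the helix with at least one atom within ``cutoff`` (4 Å) of any
    helix atom.  Identity is computed over the alignment columns of the
    union of the two neighbour sets, skipping columns where either chain is
    gapped.  Helix ranges are 0-based residue indices (inclusive) within the
    chain.  Returns None (missing) when the union is empty.
    """
    res_a = _chain_residue_data(model_a[0] if hasattr(model_a, "__getitem__") else model_a, chain_a)
    res_b = _chain_residue_data(model_b[0] if hasattr(model_b, "__getitem__") else model_b, chain_b)
    cols_a = residue_columns(aligned_chain_a)
    cols_b = residue_columns(aligned_chain_b)
    if len(cols_a) != len(res_a) or len(cols_b) != len(res_b):
        raise ValueError("alignment does not match chain residue counts")
    nb_a = _neighbour_residue_indices(res_a, *helix_range_a, cutoff)
    nb_b = _neighbour_residue_indices(res_b, *helix_range_b, cutoff)
    columns = {cols_a[i] for i in nb_a} | {cols_b[i] for i in nb_b}
    if not columns:
        return None
    return sequence_identity(aligned_chain_a, aligned_chain_b, columns)


# ---------------------------------------------------------------------------
# per-site correlation

def correlate_sites(
    angles_i: Mapping[str, float],
    angles_j: Mapping[str, float],
    min_members: int = DEFAULT_MIN_ANGLES_PER_SITE,
) -> float:
    """Spearman rank correlation of family angles at two alignment columns,
    over members with an angle at both (average-rank tie handling)."""
    shared = sorted(set(angles_i) & set(angles_j))
    if len(shared) < min_members:
        raise ValueError(
            f"only {len(shared)} members have angles at both sites; "
            f"need >= {min_members}"
        )
    x = [angles_i[m] for m in shared]
    y = [angles_j[m] for m in shared]
    rho = spearmanr(x, y).statistic
    return float(rho)
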