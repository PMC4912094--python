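"""Parametric synthetic helices with known geometry.

Every atom of the canonical straight helix sits on a circular cylinder about
the z axis: residue ``i`` advances the phase by 100 deg and z by 1.5 Å
(canonical alpha-helical rise/twist), and each backbone atom type sits at a
fixed radius, phase offset and z offset relative to the CA of its residue.
Those per-atom constants were derived once from a helix built with standard
internal coordinates (phi = -57 deg, psi = -47 deg, omega = 180 deg,
standard bond lengths/angles) and are frozen below; they are this fixture's
definition of "ideal".

Kinked helices are two ideal arms sharing the junction residue, with the
C-terminal arm rigidly rotated by the requested kink angle about an axis
through the junction perpendicular to the N-arm axis.  Optional Gaussian
coordinate noise emulates imperfect real geometry.  All generation is
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .structures import (
    HelixAnnotation,
    HelixBackbone,
    write_annotations,
    write_backbone_pdb,
)

RISE_PER_RESIDUE = 1.5  # Å
TWIST_PER_RESIDUE = 100.0  # degrees

# (radius Å, phase offset deg vs CA, z offset Å vs CA) per backbone atom,
# derived from standard alpha-helix internal coordinates (phi=-57, psi=-47).
ATOM_CYLINDRICAL = {
    "N": (1.5514, -26.771, -0.9187),
    "CA": (2.2759, 0.0, 0.0),
    "C": (1.6661, 26.743, 1.0689),
    "O": (1.9208, 20.338, 2.2566),
}


@dataclasses.dataclass(frozen=True)
class HelixSpec:
    """Recipe for one synthetic helix."""

    n_residues: int
    kink_angle: float = 0.0  # degrees; 0 = straight
    kink_position: int = 0  # 0-based residue index of the junction
    coordinate_noise_sd: float = 0.0  # Å, isotropic Gaussian per coordinate
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if not 0.0 <= self.kink_angle < 180.0:
            raise ValueError("kink_angle must be in [0, 180)")
        if self.kink_angle > 0 and not (
            5 <= self.kink_position <= self.n_residues - 6
        ):
            raise ValueError(
                "kink_position must lie in [5, n_residues-6] for a kinked helix"
            )
        if self.coordinate_noise_sd < 0:
            raise ValueError("coordinate_noise_sd must be >= 0")


def _ideal_coords(n: int) -> np.ndarray:
    """(n, 4, 3) coordinates of the canonical straight helix about +z."""
    i = np.arange(n)
    coords = np.empty((n, 4, 3))
    for k, atom in enumerate(("N", "CA", "C", "O")):
        radius, dphase, dz = ATOM_CYLINDRICAL[atom]
        phase = np.radians(i * TWIST_PER_RESIDUE + dphase)
        coords[:, k, 0] = radius * np.cos(phase)
        coords[:, k, 1] = radius * np.sin(phase)
        coords[:, k, 2] = i * RISE_PER_RESIDUE + dz
    return coords


def generate_ideal_helix(
    n: int,
    helix_id: str = "ideal",
    chain_id: str = "A",
    residue_names: Sequence[str] | None = None,
) -> HelixBackbone:
    """Canonical straight alpha-helix of ``n`` residues (deterministic)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return HelixBackbone(
        helix_id,
        chain_id,
        [str(i + 1) for i in range(n)],
        _ideal_coords(n),
        residue_names,
    )


def generate_kinked_helix(
    spec: HelixSpec,
    helix_id: str = "synthetic",
    chain_id: str = "A",
    residue_names: Sequence[str] | None = None,
) -> HelixBackbone:
    """Two ideal arms joined at ``kink_position`` with the C-arm axis rotated
    by ``kink_angle`` about an in-plane axis through the junction.

    With ``kink_angle = 0`` the output is identical to
    :func:`generate_ideal_helix`.  The junction residue belongs to the
    N-terminal arm; residues after it are rotated rigidly, so no residues
    are deleted and the measured maximum angle tracks the construction angle.
    """
    coords = _ideal_coords(spec.n_residues)
    if spec.kink_angle > 0:
        k = spec.kink_position
        junction = np.array(
            [0.0, 0.0, (k + 0.5) * RISE_PER_RESIDUE]
        )  # on the N-arm axis between the junction residue and the next
        ang = np.radians(spec.kink_angle)
        # rotation about +x (perpendicular to the N-arm axis, +z)
        rot = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, np.cos(ang), -np.sin(ang)],
                [0.0, np.sin(ang), np.cos(ang)],
            ]
        )
        tail = coords[k + 1 :]
        coords[k + 1 :] = (tail - junction) @ rot.T + junction
    if spec.coordinate_noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        coords = coords + rng.normal(0.0, spec.coordinate_noise_sd, coords.shape)
    return HelixBackbone(
        helix_id,
        chain_id,
        [str(i + 1) for i in range(spec.n_residues)],
        coords,
        residue_names,
    )


@dataclasses.dataclass
class FamilyFixture:
    """A generated family: backbones, annotations and a gapped alignment."""

    backbones: dict[str, HelixBackbone]
    annotations: list[HelixAnnotation]
    aligned_sequences: dict[str, str]  # member id -> gapped one-letter sequence

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write one PDB per member, an annotation TSV and an aligned FASTA."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for member, bb in self.backbones.items():
            p = outdir / f"{member}.pdb"
            write_backbone_pdb(bb, p)
            paths[member] = p
        write_annotations(self.annotations, outdir / "helices.tsv")
        fasta = outdir / "family.fasta"
        with open(fasta, "w") as fh:
            for member, seq in self.aligned_sequences.items():
                fh.write(f">{member}\n{seq}\n")
        paths["annotations"] = outdir / "helices.tsv"
        paths["alignment"] = fasta
        return paths


def generate_family_fixture(
    kink_angles: Sequence[float],
    n_residues: int = 20,
    kink_position: int = 9,
    coordinate_noise_sd: float = 0.0,
    seed: int = 0,
    gap_columns: Mapping[str, Sequence[int]] | None = None,
) -> FamilyFixture:
    """Generate an aligned family of synthetic helices, one per kink angle.

    Members are named ``m00, m01, ...``.  By default the alignment is the
    identity (all members full length); ``gap_columns`` marks alignment
    columns at which a member is gapped, in which case that member's helix
    is generated with correspondingly fewer residues, which occupy the
    non-gap columns in order, keeping coordinates consistent with the
    alignment.
    """
    if len(kink_angles) < 1:
        raise ValueError("at least one member required")
    gap_columns = dict(gap_columns or {})
    backbones: dict[str, HelixBackbone] = {}
    annotations: list[HelixAnnotation] = []
    aligned: dict[str, str] = {}
    for j, angle in enumerate(kink_angles):
        member = f"m{j:02d}"
        gaps = sorted(set(gap_columns.get(member, ())))
        if any(g < 0 or g >= n_residues for g in gaps):
            raise ValueError(f"gap column out of range for member {member}")
        length = n_residues - len(gaps)
        spec = HelixSpec(
            n_residues=length,
            kink_angle=float(angle),
            kink_position=kink_position if angle > 0 else 0,
            coordinate_noise_sd=coordinate_noise_sd,
            rng_seed=seed + j,
        )
        bb = generate_kinked_helix(spec, helix_id=member, chain_id="A")
        backbones[member] = bb
        annotations.append(
            HelixAnnotation(chain_id="A", start=1, end=length, helix_id=member)
        )
        row = []
        res_iter = iter(bb.sequence)
        for col in range(n_residues):
            row.append("-" if col in gaps else next(res_iter))
        aligned[member] = "".join(row)
    return FamilyFixture(backbones, annotations, aligned)
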