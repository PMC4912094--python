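"""Coordinate I/O and helix extraction.

Reads PDB/mmCIF files (via gemmi), extracts helix backbones from sidecar
annotations, merges nearly-contiguous helical segments, and writes the
tabular outputs used throughout the package.

Helix boundaries are supplied as an annotation table (chain, start residue,
end residue in author numbering); this replaces the external secondary
structure annotation pipelines whose outputs this package consumes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    EmptyModelError,
    FormatError,
    MissingBackboneError,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def three_to_one(resname: str) -> str:
    return _AA3TO1.get(resname.upper(), "X")


@dataclasses.dataclass(frozen=True)
class HelixAnnotation:
    """A helix boundary annotation: chain + author residue number range."""

    chain_id: str
    start: int
    end: int
    helix_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise AnnotationError(
                f"annotation end {self.end} precedes start {self.start}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


class HelixBackbone:
    """Ordered backbone (N, CA, C, O) of one helix.

    Residues run strictly N-terminal to C-terminal.  Every residue must
    carry all four backbone atoms; residues missing any are rejected at
    construction.  Helices shorter than 12 residues can be constructed and
    round-tripped but cannot be angle-measured (see ``is_analysable``).

    Parameters
    ----------
    helix_id, chain_id : str
    residue_ids : sequence of str
        Author residue identifiers (number plus optional insertion code).
    coords : (L, 4, 3) array, Å
        Backbone coordinates in BACKBONE_ATOMS order (N, CA, C, O).
    residue_names : sequence of str, optional
        Three-letter residue names; defaults to ALA.
    """

    MIN_ANALYSABLE_LENGTH = 12

    def __init__(
        self,
        helix_id: str,
        chain_id: str,
        residue_ids: Sequence[str],
        coords: np.ndarray,
        residue_names: Sequence[str] | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        n = len(residue_ids)
        if coords.shape != (n, 4, 3):
            raise MissingBackboneError(
                f"expected coordinates of shape ({n}, 4, 3), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise MissingBackboneError("non-finite backbone coordinates")
        if len(set(residue_ids)) != n:
            raise AnnotationError("duplicate residue identifiers in helix")
        if residue_names is None:
            residue_names = ["ALA"] * n
        if len(residue_names) != n:
            raise AnnotationError("residue_names length mismatch")
        self.helix_id = helix_id
        self.chain_id = chain_id
        self.residue_ids = list(residue_ids)
        self.residue_names = list(residue_names)
        self.coords = coords

    def __len__(self) -> int:
        return len(self.residue_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def is_analysable(self) -> bool:
        """True if the helix meets the 12-residue minimum for angle measurement."""
        return self.n_residues >= self.MIN_ANALYSABLE_LENGTH

    @property
    def sequence(self) -> str:
        return "".join(three_to_one(r) for r in self.residue_names)

    def segment(self, start: int, length: int = 6) -> np.ndarray:
        """Backbone atoms of residues ``start .. start+length-1`` as (length, 4, 3)."""
        if start < 0 or start + length > self.n_residues:
            raise IndexError("segment outside helix")
        return self.coords[start : start + length]

    def reversed(self) -> "HelixBackbone":
        """Residue order reversed (atom order within residues preserved)."""
        return HelixBackbone(
            self.helix_id,
            self.chain_id,
            list(reversed(self.residue_ids)),
            self.coords[::-1].copy(),
            list(reversed(self.residue_names)),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "HelixBackbone":
        """Apply a rigid (or improper) transform x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new = self.coords @ rotation.T + translation
        return HelixBackbone(
            self.helix_id, self.chain_id, self.residue_ids, new, self.residue_names
        )

    def to_gemmi(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = self.helix_id or "helix"
        model = gemmi.Model("1")
        chain = gemmi.Chain(self.chain_id or "A")
        for rid, rname, atoms in zip(self.residue_ids, self.residue_names, self.coords):
            res = gemmi.Residue()
            res.name = rname
            num, icode = _split_resid(rid)
            res.seqid = gemmi.SeqId(num, icode)
            for aname, xyz in zip(BACKBONE_ATOMS, atoms):
                at = gemmi.Atom()
                at.name = aname
                at.element = gemmi.Element(aname[0])
                at.pos = gemmi.Position(*xyz)
                at.occ = 1.0
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        return st


def _split_resid(rid: str) -> tuple[int, str]:
    rid = str(rid).strip()
    if rid and not rid[-1].isdigit() and rid[-1] != "-":
        return int(rid[:-1]), rid[-1]
    return int(rid), " "


def _format_resid(seqid: gemmi.SeqId) -> str:
    icode = seqid.icode.strip()
    return f"{seqid.num}{icode}"


def read_structure(path: str | Path) -> gemmi.Structure:
    """Read a PDB or mmCIF file, keeping only the first model.

    Multi-model files (e.g. NMR ensembles) contribute their first model only.
    Raises :class:`FormatError` for unparseable files and
    :class:`EmptyModelError` when no chain with residues is present.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise EmptyModelError(f"{path} contains no residues")
    while len(st) > 1:
        del st[1]
    return st


def _pick_altloc(residue: gemmi.Residue, atom_name: str) -> gemmi.Atom | None:
    """Highest-occupancy conformer; ties broken by smallest altloc identifier."""
    best = None
    best_key = None
    for atom in residue:
        if atom.name != atom_name:
            continue
        key = (-atom.occ, atom.altloc or " ")
        if best is None or key < best_key:
            best, best_key = atom, key
    return best


def extract_helix(
    structure: gemmi.Structure | gemmi.Model,
    annotation: HelixAnnotation,
) -> HelixBackbone:
    """Extract a :class:`HelixBackbone` for the annotated residue range.

    The range is located on the author-numbered chain; every residue within
    it must carry complete N/CA/C/O backbone (an interior hole would corrupt
    segment indexing downstream), otherwise :class:`MissingBackboneError`.
    """
    model = structure[0] if isinstance(structure, gemmi.Structure) else structure
    chain = model.find_chain(annotation.chain_id)
    if chain is None:
        raise AnnotationError(f"chain {annotation.chain_id!r} not found")
    in_range = False
    ids, names, coords = [], [], []
    seen_end = False
    for res in chain:
        num = res.seqid.num
        if not in_range and num == annotation.start:
            in_range = True
        if in_range:
            atom_xyz = []
            for aname in BACKBONE_ATOMS:
                atom = _pick_altloc(res, aname)
                if atom is None:
                    raise MissingBackboneError(
                        f"residue {_format_resid(res.seqid)} in "
                        f"{annotation.chain_id} lacks backbone atom {aname}"
                    )
                atom_xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
            ids.append(_format_resid(res.seqid))
            names.append(res.name)
            coords.append(atom_xyz)
            if num == annotation.end:
                seen_end = True
                break
    if not in_range or not seen_end:
        raise AnnotationError(
            f"range {annotation.start}-{annotation.end} not found in chain "
            f"{annotation.chain_id!r}"
        )
    helix_id = annotation.helix_id or (
        f"{annotation.chain_id}_{annotation.start}_{annotation.end}"
    )
    return HelixBackbone(helix_id, annotation.chain_id, ids, np.array(coords), names)


def merge_annotations(
    annotations: Iterable[HelixAnnotation], max_gap: int = 2
) -> list[HelixAnnotation]:
    """Merge same-chain helix annotations separated by ``max_gap`` residues or fewer.

    Helical segments separated by only one or two residues are combined into
    a single spanning annotation; the rule is applied iteratively to a
    fixpoint (sorted by chain, then start).
    """
    by_chain: dict[str, list[HelixAnnotation]] = {}
    for ann in annotations:
        by_chain.setdefault(ann.chain_id, []).append(ann)
    out: list[HelixAnnotation] = []
    for chain_id in sorted(by_chain):
        anns = sorted(by_chain[chain_id], key=lambda a: (a.start, a.end))
        merged: list[HelixAnnotation] = []
        for ann in anns:
            if merged and ann.start - merged[-1].end - 1 <= max_gap:
                prev = merged.pop()
                merged.append(
                    HelixAnnotation(
                        chain_id,
                        prev.start,
                        max(prev.end, ann.end),
                        helix_id=prev.helix_id or ann.helix_id,
                        label=prev.label,
                    )
                )
            else:
                merged.append(ann)
        out.extend(merged)
    return out


def read_annotations(path: str | Path) -> list[HelixAnnotation]:
    """Read a helix annotation TSV: helix_id, chain, start_res, end_res."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"helix_id", "chain", "start_res", "end_res"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"annotation table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return [
        HelixAnnotation(
            chain_id=row["chain"],
            start=int(row["start_res"]),
            end=int(row["end_res"]),
            helix_id=row["helix_id"],
        )
        for _, row in df.iterrows()
    ]


def write_annotations(annotations: Iterable[HelixAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "helix_id": a.helix_id,
                "chain": a.chain_id,
                "start_res": a.start,
                "end_res": a.end,
            }
            for a in annotations
        ]
    )
    with open(path, "w") as fh:
        fh.write("# helix annotations (author residue numbering)\n")
        df.to_csv(fh, sep="\t", index=False)


def write_backbone_pdb(backbone: HelixBackbone, path: str | Path) -> None:
    backbone.to_gemmi().write_pdb(str(path))


def write_backbone_cif(backbone: HelixBackbone, path: str | Path) -> None:
    backbone.to_gemmi().make_mmcif_document().write_file(str(path))


def write_table(
    df: pd.DataFrame, path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Write a TSV with '#'-prefixed header comments (units, config echo)."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
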