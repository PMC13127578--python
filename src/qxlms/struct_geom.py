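"""Model-vs-model structural geometry.

Rigid-body superposition (Kabsch least squares), per-residue Calpha deviation
profiles after alignment on a reference region, relative rotation angles of a
segment between two conformations (e.g. the myosin lever between drug-bound
and drug-free motor models), single atom-pair distances, and polar-contact
enumeration across an interface.

Selections use a compact ``chain:start-end@atom`` syntax, comma-separated::

    A:3-710@CA           the motor body Calphas of chain A
    A:243@NH1            a single guanidinium nitrogen
    A:100-200,B:1-50     two residue ranges, all atoms

Residue numbers in selections are construct-space; each model translates
them with its own per-chain numbering offset (see
:class:`~qxlms.struct_map.StructureModel`).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from qxlms.struct_map import StructureModel

#: Rank-deficiency tolerance used to detect collinear selections.
_COLLINEAR_TOL = 1e-6

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class SelectionError(ValueError):
    """A selection is malformed or resolves to no usable atoms."""


@dataclass(frozen=True)
class SelectionPart:
    chain: str
    start: int
    end: int
    atom: Optional[str] = None  # None selects all atoms of the residues


_PART_RE = re.compile(r"^([^:]+):(\d+)(?:-(\d+))?(?:@([A-Za-z0-9']+))?$")


def parse_selection(text: str) -> tuple[SelectionPart, ...]:
    """Parse ``chain:start-end@atom`` selections (comma-separated parts)."""
    parts = []
    for token in str(text).split(","):
        token = token.strip()
        if not token:
            continue
        m = _PART_RE.match(token)
        if not m:
            raise SelectionError(
                f"unparseable selection {token!r} (expected chain:start-end@atom)"
            )
        chain, start, end, atom = m.groups()
        parts.append(
            SelectionPart(chain, int(start), int(end) if end else int(start), atom)
        )
    if not parts:
        raise SelectionError(f"empty selection {text!r}")
    return tuple(parts)


def _as_parts(selection) -> tuple[SelectionPart, ...]:
    if isinstance(selection, str):
        return parse_selection(selection)
    return tuple(selection)


def _selection_residues(model: StructureModel, selection) -> list[tuple[str, int]]:
    residues = []
    for part in _as_parts(selection):
        offset = model.chain_offset(part.chain)
        for number in range(part.start, part.end + 1):
            residues.append((part.chain, number + offset))
    return residues


def matched_ca_coordinates(
    model_a: StructureModel, model_b: StructureModel, selection
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Calpha coordinate pairs of selection residues present in both models.

    Residues are matched by (chain, construct residue number); each model
    applies its own offset.  Raises :class:`SelectionError` when no residue
    of the selection is present in both models.
    """
    coords_a, coords_b, matched = [], [], []
    for part in _as_parts(selection):
        off_a = model_a.chain_offset(part.chain)
        off_b = model_b.chain_offset(part.chain)
        for number in range(part.start, part.end + 1):
            if model_a.has_ca(part.chain, number + off_a) and model_b.has_ca(
                part.chain, number + off_b
            ):
                coords_a.append(
                    model_a.atom_position(part.chain, number + off_a, "CA")
                )
                coords_b.append(
                    model_b.atom_position(part.chain, number + off_b, "CA")
                )
                matched.append((part.chain, number))
    if not matched:
        raise SelectionError(
            f"selection resolves to no shared Calpha atoms "
            f"({model_a.model_id} vs {model_b.model_id})"
        )
    return np.array(coords_a), np.array(coords_b), matched


def _check_not_degenerate(coords: np.ndarray, what: str) -> None:
    if len(coords) < 3:
        raise SelectionError(f"{what} needs >=3 Calpha pairs, got {len(coords)}")
    centered = coords - coords.mean(axis=0)
    singular = np.linalg.svd(centered, compute_uv=False)
    if singular[1] <= _COLLINEAR_TOL * max(singular[0], 1.0):
        raise SelectionError(f"{what} atoms are (near-)collinear")


@dataclass
class Superposition:
    """Optimal least-squares rigid transform of mobile onto reference."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # Å
    rmsd: float  # Å over the alignment selection
    selection: str
    n_atoms: int

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rotation+translation carrying mobile onto reference."""
    centroid_m = mobile.mean(axis=0)
    centroid_r = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - centroid_r, mobile - centroid_m)
    matrix = rot.as_matrix()
    translation = centroid_r - matrix @ centroid_m
    rmsd = float(rssd / math.sqrt(len(mobile)))
    return matrix, translation, rmsd


def superpose(
    mobile: StructureModel, reference: StructureModel, selection
) -> Superposition:
    """Kabsch superposition of ``mobile`` onto ``reference`` over a selection.

    The selection must resolve to at least three non-collinear Calpha pairs
    present in both models.
    """
    coords_m, coords_r, _ = matched_ca_coordinates(mobile, reference, selection)
    _check_not_degenerate(coords_m, "alignment selection")
    matrix, translation, rmsd = _kabsch(coords_m, coords_r)
    return Superposition(
        rotation=matrix,
        translation=translation,
        rmsd=rmsd,
        selection=str(selection),
        n_atoms=len(coords_m),
    )


def per_residue_deviation(
    model_a: StructureModel,
    model_b: StructureModel,
    align_selection,
    compare_selection=None,
) -> pd.DataFrame:
    """Per-residue Calpha displacement after alignment on a reference region.

    Superposes ``model_a`` onto ``model_b`` over ``align_selection``, then
    reports, for every residue shared by both models (or restricted to
    ``compare_selection``), the displacement of its Calpha in Å.  Columns:
    ``chain``, ``residue`` (construct numbering), ``deviation``.
    """
    sup = superpose(model_a, model_b, align_selection)
    if compare_selection is None:
        shared = []
        for chain_name in model_a.chains():
            off_a = model_a.chain_offset(chain_name)
            off_b = model_b.chain_offset(chain_name)
            numbers = {
                num - off_a
                for (ch, num, atom) in model_a._index()
                if ch == chain_name and atom == "CA"
            }
            for number in sorted(numbers):
                if model_b.has_ca(chain_name, number + off_b):
                    shared.append((chain_name, number))
    else:
        shared = [
            (chain, num)
            for chain, num in _selection_residues(model_a, compare_selection)
        ]
    if not shared:
        raise SelectionError("models share no residues to compare")

    rows = []
    for chain_name, number in shared:
        off_a = model_a.chain_offset(chain_name)
        off_b = model_b.chain_offset(chain_name)
        try:
            pos_a = model_a.atom_position(chain_name, number + off_a, "CA")
            pos_b = model_b.atom_position(chain_name, number + off_b, "CA")
        except KeyError:
            continue
        moved = sup.transform(pos_a[None, :])[0]
        rows.append(
            {
                "chain": chain_name,
                "residue": number,
                "deviation": float(np.linalg.norm(moved - pos_b)),
            }
        )
    if not rows:
        raise SelectionError("models share no residues to compare")
    return pd.DataFrame(rows)


@dataclass
class SegmentRotation:
    """Relative rotation of a segment between two aligned conformations."""

    angle_deg: float  # in [0, 180]
    axis: Optional[np.ndarray]  # unit vector; None when angle ~ 0
    align_selection: str
    segment_selection: str


def segment_rotation_angle(
    model_a: StructureModel,
    model_b: StructureModel,
    align_selection,
    segment_selection,
) -> SegmentRotation:
    """Rotation angle of a segment after aligning models on a reference region.

    Superposes ``model_a`` onto ``model_b`` over ``align_selection``; the
    residual optimal rotation carrying the segment's Calphas of model_a onto
    those of model_b is reported as an axis-angle magnitude.  This is the
    standard way to quantify, e.g., a lever swing between two motor-domain
    conformations without defining a projection plane.
    """
    sup = superpose(model_a, model_b, align_selection)
    seg_a, seg_b, _ = matched_ca_coordinates(model_a, model_b, segment_selection)
    _check_not_degenerate(seg_a, "segment selection")
    moved = sup.transform(seg_a)
    matrix, _translation, _rmsd = _kabsch(moved, seg_b)
    rotvec = Rotation.from_matrix(matrix).as_rotvec()
    angle = math.degrees(float(np.linalg.norm(rotvec)))
    axis = rotvec / np.linalg.norm(rotvec) if angle > 1e-9 else None
    return SegmentRotation(
        angle_deg=angle,
        axis=axis,
        align_selection=str(align_selection),
        segment_selection=str(segment_selection),
    )


def atom_pair_distance(model: StructureModel, spec_a: str, spec_b: str) -> float:
    """Distance (Å) between two atoms given as ``chain:residue@atom`` specs."""
    positions = []
    for spec in (spec_a, spec_b):
        parts = _as_parts(spec)
        if len(parts) != 1 or parts[0].start != parts[0].end or parts[0].atom is None:
            raise SelectionError(
                f"atom spec {spec!r} must name exactly one atom (chain:resi@name)"
            )
        part = parts[0]
        offset = model.chain_offset(part.chain)
        try:
            positions.append(
                model.atom_position(part.chain, part.start + offset, part.atom)
            )
        except KeyError as exc:
            raise SelectionError(str(exc)) from exc
    return float(np.linalg.norm(positions[0] - positions[1]))


@dataclass(frozen=True)
class Contact:
    """A polar (N/O heavy-atom) contact across an interface."""

    chain_a: str
    residue_a: int
    atom_a: str
    chain_b: str
    residue_b: int
    atom_b: str
    distance: float

    @property
    def pair_key(self):
        a = (self.chain_a, self.residue_a, self.atom_a)
        b = (self.chain_b, self.residue_b, self.atom_b)
        return (a, b) if a <= b else (b, a)


def _polar_atoms(model: StructureModel, selection, sidechain_only: bool):
    atoms = []
    for chain, number in _selection_residues(model, selection):
        for name, pos, _resname in model.residue_atoms(chain, number):
            if not (name.startswith("N") or name.startswith("O")):
                continue
            if sidechain_only and name in _BACKBONE_ATOMS:
                continue
            atoms.append(((chain, number, name), pos))
    return atoms


def polar_contacts(
    model: StructureModel,
    selection_a,
    selection_b,
    cutoff: float = 3.5,
    sidechain_only: bool = False,
) -> list[Contact]:
    """All N/O atom pairs across two disjoint selections within ``cutoff`` Å.

    A plain heavy-atom distance criterion without an angular term — a
    deliberately simple hydrogen-bond proxy suitable for listing candidate
    interface contacts.  ``sidechain_only`` drops backbone N/O atoms.
    """
    residues_a = set(_selection_residues(model, selection_a))
    residues_b = set(_selection_residues(model, selection_b))
    overlap = residues_a & residues_b
    if overlap:
        raise SelectionError(f"selections overlap at residues {sorted(overlap)[:5]}")
    atoms_a = _polar_atoms(model, selection_a, sidechain_only)
    atoms_b = _polar_atoms(model, selection_b, sidechain_only)
    if not atoms_a or not atoms_b:
        raise SelectionError("a selection resolves to no polar atoms")

    tree = cKDTree(np.array([pos for _key, pos in atoms_b]))
    contacts = []
    for (key_a, pos_a) in atoms_a:
        for j in tree.query_ball_point(pos_a, cutoff):
            key_b, pos_b = atoms_b[j]
            contacts.append(
                Contact(
                    chain_a=key_a[0],
                    residue_a=key_a[1],
                    atom_a=key_a[2],
                    chain_b=key_b[0],
                    residue_b=key_b[1],
                    atom_b=key_b[2],
                    distance=float(np.linalg.norm(pos_a - pos_b)),
                )
            )
    contacts.sort(key=lambda c: (c.chain_a, c.residue_a, c.atom_a, c.distance))
    return contacts


def contact_difference(
    contacts_a: Iterable[Contact], contacts_b: Iterable[Contact]
) -> list[Contact]:
    """Contacts present in ``contacts_a`` but not ``contacts_b`` (by atom pair).

    Useful for listing interface hydrogen bonds unique to one model of a
    shared interface.
    """
    keys_b = {c.pair_key for c in contacts_b}
    return [c for c in contacts_a if c.pair_key not in keys_b]
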