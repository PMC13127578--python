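"""Mapping cross-links onto atomic models and classifying dynamics.

A cross-link is *within reach* of an amine/hydroxyl-reactive cross-linker
like DSBU when the Calpha-Calpha distance of its two attachment sites in a
model is at most 30 Å (boundary inclusive, configurable).  A quantified link
observed with a distance beyond reach is *exploratory*: the two side chains
must transiently sample conformations outside the modeled state to react.

Combining the direction of a significant intensity change with the reach
pattern across models gives the dynamics interpretation:

==========================  =================================================
category                    meaning
==========================  =================================================
stabilized_state            increase, within reach in the primary models —
                            increased sampling of the modeled conformation
alternate_state_sampling    increase, beyond reach in the primary models but
                            within reach in a declared alternate-conformation
                            model (e.g. a bent-lever, folded-back geometry)
increased_dynamics          increase, beyond reach everywhere — more time in
                            excursions outside any supplied model
lost_exploratory            decrease of a beyond-reach link — excursions
                            suppressed
redistribution              decrease of a within-reach link — signal moved to
                            competing reactions without a conformational loss
no_change                   not significant
unannotated                 a site falls outside every model's built regions
==========================  =================================================

Model files are PDB or mmCIF; per-model configuration maps each construct
protein to a chain and numbering offset (model residue number = construct
index + offset), and declares the model role (primary or alternate).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import yaml

from qxlms.xlink_io import LinkSpecies, ResidueRef

DEFAULT_REACH = 30.0

CATEGORIES = (
    "stabilized_state",
    "increased_dynamics",
    "alternate_state_sampling",
    "lost_exploratory",
    "redistribution",
    "no_change",
    "unannotated",
)


class ModelError(ValueError):
    """A structure file or model configuration problem."""


@dataclass
class StructureModel:
    """An atomic model with construct-to-chain mapping and numbering offsets.

    ``chain_map`` maps construct protein ids to chain names; ``offsets`` maps
    protein ids to the integer added to a construct residue index to obtain
    the model's residue number (0 when the model is numbered on the
    construct).
    """

    model_id: str
    structure: gemmi.Structure
    chain_map: dict[str, str] = field(default_factory=dict)
    offsets: dict[str, int] = field(default_factory=dict)
    role: str = "primary"
    _atom_index: Optional[dict] = field(default=None, repr=False, compare=False)

    def _index(self) -> dict:
        # (chain, residue number, atom name) -> position; altlocs resolved to
        # the highest-occupancy copy.
        if self._atom_index is None:
            index: dict[tuple[str, int, str], tuple[float, np.ndarray, str]] = {}
            for chain in self.structure[0]:
                for residue in chain:
                    for atom in residue:
                        key = (chain.name, residue.seqid.num, atom.name)
                        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                        if not np.all(np.isfinite(pos)):
                            raise ModelError(
                                f"non-finite coordinates at {key} in "
                                f"{self.model_id}"
                            )
                        previous = index.get(key)
                        if previous is None or atom.occ > previous[0]:
                            index[key] = (atom.occ, pos, residue.name)
            self._atom_index = index
        return self._atom_index

    # -- lookups -----------------------------------------------------------

    def chains(self) -> list[str]:
        return [chain.name for chain in self.structure[0]]

    def chain_offset(self, chain_name: str) -> int:
        for protein_id, mapped in self.chain_map.items():
            if mapped == chain_name:
                return self.offsets.get(protein_id, 0)
        return 0

    def resolve_residue(self, site: ResidueRef) -> tuple[str, int]:
        """Map a construct-space site to a (chain, residue number) address."""
        chain = self.chain_map.get(site.protein_id)
        if chain is None:
            raise KeyError(
                f"protein {site.protein_id!r} has no chain in model "
                f"{self.model_id!r}"
            )
        return chain, site.residue_index + self.offsets.get(site.protein_id, 0)

    def atom_position(self, chain: str, number: int, atom_name: str) -> np.ndarray:
        entry = self._index().get((chain, number, atom_name))
        if entry is None:
            raise KeyError(
                f"atom {chain}/{number}@{atom_name} absent from model "
                f"{self.model_id!r}"
            )
        return entry[1]

    def ca_position(self, site: ResidueRef) -> np.ndarray:
        chain, number = self.resolve_residue(site)
        return self.atom_position(chain, number, "CA")

    def has_ca(self, chain: str, number: int) -> bool:
        return (chain, number, "CA") in self._index()

    def residue_atoms(self, chain: str, number: int):
        """Yield (atom_name, position, residue_name) for one residue."""
        for (ch, num, name), (_occ, pos, resname) in self._index().items():
            if ch == chain and num == number:
                yield name, pos, resname


def read_structure(
    path,
    model_id: Optional[str] = None,
    chain_map: Optional[Mapping[str, str]] = None,
    offsets: Optional[Mapping[str, int]] = None,
    role: str = "primary",
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    The format is detected from the file contents/extension by gemmi.  Chains
    named in ``chain_map`` must exist in the file.
    """
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ModelError(f"cannot parse structure file {path}: {exc}") from exc
    if len(structure) == 0 or len(structure[0]) == 0:
        raise ModelError(f"structure file {path} contains no chains")
    structure.setup_entities()
    model = StructureModel(
        model_id=model_id or Path(str(path)).stem,
        structure=structure,
        chain_map=dict(chain_map or {}),
        offsets=dict(offsets or {}),
        role=role,
    )
    present = set(model.chains())
    for protein_id, chain in model.chain_map.items():
        if chain not in present:
            raise ModelError(
                f"chain {chain!r} (protein {protein_id!r}) absent from "
                f"model {model.model_id!r}; chains present: {sorted(present)}"
            )
    return model


def load_model_config(path) -> list[StructureModel]:
    """Load models declared in a YAML run configuration.

    Expected layout::

        models:
          S1:
            path: s1.pdb
            role: primary
            chains: {MYH7: A, MYL3: B}
            offsets: {MYH7: 0}
          BH_lever:
            path: bent.pdb
            role: alternate
            chains: {MYH7: A}

    Paths are resolved relative to the configuration file.
    """
    cfg_path = Path(str(path))
    config = yaml.safe_load(cfg_path.read_text())
    if not config or "models" not in config:
        raise ModelError(f"configuration {path} declares no models")
    models = []
    for model_id, block in config["models"].items():
        model_path = Path(block["path"])
        if not model_path.is_absolute():
            model_path = cfg_path.parent / model_path
        models.append(
            read_structure(
                model_path,
                model_id=model_id,
                chain_map=block.get("chains", {}),
                offsets=block.get("offsets", {}),
                role=block.get("role", "primary"),
            )
        )
    return models


# ---------------------------------------------------------------------------
# distances


def ca_distance(model: StructureModel, site_a: ResidueRef, site_b: ResidueRef) -> float:
    """Euclidean Calpha-Calpha distance (Å) between two construct sites."""
    return float(np.linalg.norm(model.ca_position(site_a) - model.ca_position(site_b)))


@dataclass
class DistanceAnnotation:
    """Calpha-Calpha distance of one link in one model, with reach flag."""

    link_key: tuple
    model_id: str
    d_ca: Optional[float]
    within_reach: Optional[bool]  # defined only when mapped
    mapped: bool
    address_a: Optional[tuple[str, int]] = None
    address_b: Optional[tuple[str, int]] = None


def _candidate_sites(site: ResidueRef, alternates: tuple) -> list[ResidueRef]:
    return [site, *alternates]


def annotate_link_distances(
    links: Iterable[LinkSpecies],
    models: Sequence[StructureModel],
    reach: float = DEFAULT_REACH,
) -> list[DistanceAnnotation]:
    """Measure every cross-link in every model against the reach criterion.

    Monolinks are skipped (no residue pair to measure).  For links carrying
    an ambiguous residue set (e.g. K206/K207) the minimum distance over the
    candidate combinations is used: reachability only requires one candidate
    within range.  A link whose sites cannot both be resolved in a model is
    returned with ``mapped=False`` rather than raising.
    """
    annotations = []
    for link in links:
        if link.site_b is None:
            continue
        for model in models:
            best: Optional[float] = None
            addr_a = addr_b = None
            for cand_a, cand_b in itertools.product(
                _candidate_sites(link.site_a, link.site_a_alternates),
                _candidate_sites(link.site_b, link.site_b_alternates),
            ):
                try:
                    d = ca_distance(model, cand_a, cand_b)
                except KeyError:
                    continue
                if best is None or d < best:
                    best = d
                    addr_a = model.resolve_residue(cand_a)
                    addr_b = model.resolve_residue(cand_b)
            annotations.append(
                DistanceAnnotation(
                    link_key=link.key,
                    model_id=model.model_id,
                    d_ca=best,
                    within_reach=None if best is None else bool(best <= reach),
                    mapped=best is not None,
                    address_a=addr_a,
                    address_b=addr_b,
                )
            )
    return annotations


# ---------------------------------------------------------------------------
# dynamics classification


@dataclass
class DynamicsCall:
    """Dynamics category for one link given distances across models."""

    link_key: tuple
    category: str
    distances: dict[str, Optional[float]] = field(default_factory=dict)
    significant: bool = False
    direction: str = "none"


def classify_dynamics(
    diff,
    annotations: Sequence[DistanceAnnotation],
    roles: Optional[Mapping[str, str]] = None,
) -> DynamicsCall:
    """Classify one link's dynamics from its differential result and distances.

    ``roles`` maps model id -> "primary" | "alternate"; unlisted models
    default to primary.  The classification is total: every link receives
    exactly one category (see the module docstring for the rule table).
    """
    roles = dict(roles or {})
    distances = {a.model_id: a.d_ca for a in annotations}
    mapped = [a for a in annotations if a.mapped]

    if not diff.significant:
        category = "no_change"
    elif not mapped:
        category = "unannotated"
    else:
        primary = [a for a in mapped if roles.get(a.model_id, "primary") == "primary"]
        alternate = [a for a in mapped if roles.get(a.model_id, "primary") == "alternate"]
        reference = primary if primary else mapped
        in_reach_reference = any(a.within_reach for a in reference)
        if diff.direction == "increase":
            if in_reach_reference:
                category = "stabilized_state"
            elif any(a.within_reach for a in alternate):
                category = "alternate_state_sampling"
            else:
                category = "increased_dynamics"
        elif diff.direction == "decrease":
            category = "redistribution" if in_reach_reference else "lost_exploratory"
        else:
            category = "no_change"
    return DynamicsCall(
        link_key=diff.key,
        category=category,
        distances=distances,
        significant=diff.significant,
        direction=diff.direction,
    )


def classify_all(
    diffs: Sequence,
    annotations: Sequence[DistanceAnnotation],
    roles: Optional[Mapping[str, str]] = None,
) -> list[DynamicsCall]:
    """Classify every differential result, joining annotations by link key."""
    by_key: dict[tuple, list[DistanceAnnotation]] = {}
    for ann in annotations:
        by_key.setdefault(ann.link_key, []).append(ann)
    return [classify_dynamics(d, by_key.get(d.key, []), roles) for d in diffs]
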