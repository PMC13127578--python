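"""Synthetic quant tables and toy structures with known ground truth.

The quant generator emulates the design of a three-replicate, two-condition
label-free qXL-MS experiment: MS1 intensities with multiplicative log-normal
noise, replicate-specific loading factors, planted fold changes on chosen
links, unreacted "carrier" peptides that supply the normalization
denominator, a mixture of interpeptide / intrapeptide / monolink species,
multiple charge states per link, and a declared fraction of peptides with
ambiguous candidate sites (where the planted truth is always the residue the
resolution rule must pick, so recovery is checkable).

The structure generators build small polyalanine-with-lysine models: a
two-arm "hinge" pair in which one arm is rotated by a known angle about a
known axis (a stand-in for a lever swing between two motor conformations),
and a benchmark model trio in which every residue pair sits at a planted
Calpha-Calpha distance chosen to realize each dynamics category.

Everything is deterministic under a seed: the same seed reproduces tables
and coordinates bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from qxlms.struct_map import StructureModel
from qxlms.xlink_io import LinkSpecies, ResidueRef

#: Period-10 sequence motif: one lysine and, four residues later, one serine
#: per period — the serine serves as the ambiguity decoy next to each K.
_MOTIF = "GAVLKGAPSE"

TABLE_COLUMNS = (
    "protein_a",
    "site_a",
    "protein_b",
    "site_b",
    "link_kind",
    "peptide",
    "charge",
    "condition",
    "replicate",
    "intensity",
    "retention_time",
    "candidate_sites",
)


def _make_sequence(length: int) -> str:
    reps = -(-length // len(_MOTIF))
    return (_MOTIF * reps)[:length]


def _lysine_positions(length: int) -> list[int]:
    # 1-based positions of K in the repeated motif
    return [i + 1 for i, ch in enumerate(_make_sequence(length)) if ch == "K"]


def _noise_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0.0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


@dataclass
class QuantTruth:
    """Planted parameters of a simulated quant dataset."""

    log2_fold_change: dict[tuple, float]
    link_kinds: dict[tuple, str]
    loading_factors: dict[tuple[str, str], float]
    cv: float
    seed: int
    conditions: tuple[str, str]
    n_replicates: int


@dataclass
class SimulatedQuant:
    table: pd.DataFrame
    sequences: dict[str, str]
    truth: QuantTruth


def _resolve_loading(
    loading_factors, conditions: Sequence[str], replicates: Sequence[str]
) -> dict[tuple[str, str], float]:
    pairs = [(c, r) for c in conditions for r in replicates]
    if loading_factors is None:
        return {pair: 1.0 for pair in pairs}
    if isinstance(loading_factors, Mapping):
        return {pair: float(loading_factors.get(pair, 1.0)) for pair in pairs}
    values = list(loading_factors)
    if len(values) == len(replicates):
        values = values * len(conditions)
    if len(values) != len(pairs):
        raise ValueError(
            f"loading_factors must have {len(replicates)} or {len(pairs)} entries"
        )
    return {pair: float(v) for pair, v in zip(pairs, values)}


def simulate_quant_dataset(
    n_links: int = 100,
    n_replicates: int = 3,
    effects: Optional[Mapping[int, float]] = None,
    cv: float = 0.1,
    loading_factors=None,
    seed: int = 0,
    ambiguous_fraction: float = 0.0,
    kind_mix: tuple[float, float, float] = (0.4, 0.3, 0.3),
    conditions: tuple[str, str] = ("control", "treated"),
) -> SimulatedQuant:
    """Simulate a two-condition quant table with planted ground truth.

    Parameters
    ----------
    n_links : int
        Number of link species (interpeptide, intrapeptide and monolink mixed
        per ``kind_mix``).
    n_replicates : int
        Replicates per condition (three mirrors the usual design).
    effects : mapping, optional
        ``{link_index: log2 fold change}``; unlisted links are null.
    cv : float
        Coefficient of variation of the multiplicative log-normal intensity
        noise; 0 gives exact intensities.
    loading_factors : mapping or sequence, optional
        Per-replicate loading multipliers (keyed ``(condition, replicate)``,
        or one value per replicate reused across conditions).  These are what
        normalization must cancel.
    seed : int
        Seeds all randomness; identical seeds reproduce the table bit for bit.
    ambiguous_fraction : float
        Fraction of links whose peptides carry an ambiguous candidate list
        (the true lysine plus a decoy serine).
    """
    if n_links < 1:
        raise ValueError("n_links must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    effects = dict(effects or {})
    rng = np.random.default_rng(seed)

    heavy_id, light_id = "HEAVY_SYN", "LIGHT_SYN"
    sequences = {heavy_id: _make_sequence(840), light_id: _make_sequence(190)}
    heavy_k = _lysine_positions(840)
    light_k = _lysine_positions(190)

    replicates = tuple(str(i + 1) for i in range(n_replicates))
    loading = _resolve_loading(loading_factors, conditions, replicates)

    n_inter = max(1, round(kind_mix[0] * n_links))
    n_intra = round(kind_mix[1] * n_links)
    n_intra = min(n_intra, n_links - n_inter)
    n_mono = n_links - n_inter - n_intra

    links = []  # (index, kind, sites, candidate_sites_str)
    for i in range(n_inter):
        site_a = ResidueRef(heavy_id, heavy_k[i % len(heavy_k)], "K")
        site_b = ResidueRef(light_id, light_k[i % len(light_k)], "K")
        links.append((i, "interpeptide", (site_a, site_b)))
    for j in range(n_intra):
        i = n_inter + j
        pos = heavy_k[(2 * j) % (len(heavy_k) - 1)]
        nxt = heavy_k[(2 * j) % (len(heavy_k) - 1) + 1]
        links.append(
            (i, "intrapeptide", (ResidueRef(heavy_id, pos, "K"),
                                 ResidueRef(heavy_id, nxt, "K")))
        )
    for j in range(n_mono):
        i = n_inter + n_intra + j
        protein = heavy_id if j % 2 == 0 else light_id
        ks = heavy_k if j % 2 == 0 else light_k
        links.append((i, "monolink", (ResidueRef(protein, ks[j % len(ks)], "K"),)))

    n_ambiguous = round(ambiguous_fraction * n_links)

    rows = []
    truth_lfc: dict[tuple, float] = {}
    truth_kind: dict[tuple, str] = {}
    for index, kind, sites in links:
        lfc = float(effects.get(index, 0.0))
        species = LinkSpecies(
            kind, sites[0], sites[1] if len(sites) > 1 else None
        )
        truth_lfc[species.key] = lfc
        truth_kind[species.key] = kind

        base = float(10 ** rng.uniform(5.0, 7.0))
        # one or two charge states exercising cross-charge aggregation
        shares = [(2, 1.0)] if index % 3 else [(2, 0.7), (3, 0.3)]
        site_a = sites[0]
        seq = sequences[site_a.protein_id]
        start = max(1, site_a.residue_index - 5)
        peptide = seq[start - 1 : min(len(seq), site_a.residue_index + 4)]
        candidates = ""
        if index < n_ambiguous and kind != "intrapeptide":
            decoy = site_a.residue_index + 4  # the serine of the same motif
            if decoy <= len(seq) and seq[decoy - 1] == "S":
                candidates = f"K{site_a.residue_index};S{decoy}"

        for charge, share in shares:
            for condition_index, condition in enumerate(conditions):
                mean = base * share * (2.0**lfc if condition_index == 1 else 1.0)
                for replicate in replicates:
                    value = (
                        mean
                        * loading[(condition, replicate)]
                        * _noise_factor(rng, cv)
                    )
                    rows.append(
                        {
                            "protein_a": site_a.protein_id,
                            "site_a": site_a.site,
                            "protein_b": sites[1].protein_id if len(sites) > 1 else "",
                            "site_b": sites[1].site if len(sites) > 1 else "",
                            "link_kind": kind,
                            "peptide": peptide + ("" if charge == 2 else "G"),
                            "charge": charge,
                            "condition": condition,
                            "replicate": replicate,
                            "intensity": value,
                            "retention_time": "",
                            "candidate_sites": candidates,
                        }
                    )

    # unreacted carrier peptides: the normalization denominator
    for protein_id, bases in ((heavy_id, (4e6, 6e6, 8e6)), (light_id, (2e6, 3e6))):
        seq = sequences[protein_id]
        for k, base in enumerate(bases):
            peptide = seq[10 * k : 10 * k + 8].replace("K", "A")
            for condition in conditions:
                for replicate in replicates:
                    value = (
                        base
                        * loading[(condition, replicate)]
                        * _noise_factor(rng, cv)
                    )
                    rows.append(
                        {
                            "protein_a": protein_id,
                            "site_a": "",
                            "protein_b": "",
                            "site_b": "",
                            "link_kind": "unmodified",
                            "peptide": peptide,
                            "charge": 2,
                            "condition": condition,
                            "replicate": replicate,
                            "intensity": value,
                            "retention_time": "",
                            "candidate_sites": "",
                        }
                    )

    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    truth = QuantTruth(
        log2_fold_change=truth_lfc,
        link_kinds=truth_kind,
        loading_factors=loading,
        cv=cv,
        seed=seed,
        conditions=conditions,
        n_replicates=n_replicates,
    )
    return SimulatedQuant(table=table, sequences=sequences, truth=truth)


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for protein_id, seq in sequences.items():
            fh.write(f">{protein_id}\n")
            for start in range(0, len(seq), 60):
                fh.write(seq[start : start + 60] + "\n")


# ---------------------------------------------------------------------------
# toy structures


@dataclass
class ToyStructureTruth:
    """Ground truth emitted alongside toy structures."""

    hinge_angle_deg: float
    pair_distances: dict[tuple[int, int], float]
    reactive_sites: tuple[int, ...]
    motor_range: tuple[int, int]
    lever_range: tuple[int, int]


def _build_structure(name: str, residues) -> gemmi.Structure:
    """Assemble a single-chain gemmi structure from (num, resname, atoms)."""
    structure = gemmi.Structure()
    structure.name = name
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    for number, resname, atoms in residues:
        residue = gemmi.Residue()
        residue.name = resname
        residue.seqid = gemmi.SeqId(number, " ")
        for atom_name, pos in atoms:
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(atom_name[0])
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            residue.add_atom(atom)
        chain.add_residue(residue)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    return structure


def _rotation_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array(
        [[math.cos(a), -math.sin(a), 0.0], [math.sin(a), math.cos(a), 0.0],
         [0.0, 0.0, 1.0]]
    )


def _toy_model(model_id: str, coords: dict[int, np.ndarray],
               names: dict[int, str]) -> StructureModel:
    residues = [
        (num, names[num], [("CA", tuple(coords[num]))]) for num in sorted(coords)
    ]
    return StructureModel(
        model_id=model_id,
        structure=_build_structure(model_id, residues),
        chain_map={"TOY_SYN": "A"},
        offsets={"TOY_SYN": 0},
    )


def generate_toy_hinge(
    angle_deg: float,
    n_per_arm: int = 20,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> tuple[StructureModel, StructureModel, ToyStructureTruth]:
    """Two-arm hinge models differing by a planted lever rotation.

    Both models share a fixed "motor" arm (residues 1..n); the "lever" arm
    (residues n+1..2n) of the second model is rotated by ``angle_deg`` about
    the z axis through the hinge at the origin.  Arms follow a helical curve
    so no selection is collinear.  Six extra lysine probe residues are placed
    as three pairs at exactly 29.9, 30.0 and 31.0 Å to exercise the reach
    boundary.  ``noise_sigma`` adds isotropic Gaussian coordinate noise (Å)
    independently to both models.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError("angle_deg must be in [0, 180]")
    if n_per_arm < 4:
        raise ValueError("n_per_arm must be >= 4")
    rng = np.random.default_rng(seed)

    def helix(t: float) -> np.ndarray:
        return np.array([3.6 * t, 5.0 * math.sin(0.7 * t), 5.0 * math.cos(0.7 * t)])

    coords_a: dict[int, np.ndarray] = {}
    names: dict[int, str] = {}
    for i in range(1, n_per_arm + 1):  # motor arm, negative x
        coords_a[i] = helix(-(n_per_arm + 1 - i))
    for i in range(1, n_per_arm + 1):  # lever arm, positive x
        coords_a[n_per_arm + i] = helix(float(i))

    rot = _rotation_z(angle_deg)
    coords_b = {
        num: (rot @ pos if num > n_per_arm else pos.copy())
        for num, pos in coords_a.items()
    }

    probes = {
        2 * n_per_arm + 1: np.array([500.0, 0.0, 0.0]),
        2 * n_per_arm + 2: np.array([529.9, 0.0, 0.0]),
        2 * n_per_arm + 3: np.array([600.0, 0.0, 0.0]),
        2 * n_per_arm + 4: np.array([630.0, 0.0, 0.0]),
        2 * n_per_arm + 5: np.array([700.0, 0.0, 0.0]),
        2 * n_per_arm + 6: np.array([731.0, 0.0, 0.0]),
    }
    coords_a.update({k: v.copy() for k, v in probes.items()})
    coords_b.update({k: v.copy() for k, v in probes.items()})

    if noise_sigma > 0:
        for coords in (coords_a, coords_b):
            for num in coords:
                coords[num] = coords[num] + rng.normal(0.0, noise_sigma, 3)

    reactive = []
    for num in sorted(coords_a):
        if num > 2 * n_per_arm or num % 5 == 0:
            names[num] = "LYS"
            reactive.append(num)
        else:
            names[num] = "ALA"

    model_a = _toy_model("hinge_ref", coords_a, names)
    model_b = _toy_model("hinge_rot", coords_b, names)

    probe_pairs = [
        (2 * n_per_arm + 1, 2 * n_per_arm + 2),
        (2 * n_per_arm + 3, 2 * n_per_arm + 4),
        (2 * n_per_arm + 5, 2 * n_per_arm + 6),
    ]
    pair_distances = {
        pair: float(np.linalg.norm(coords_a[pair[0]] - coords_a[pair[1]]))
        for pair in probe_pairs
    }
    truth = ToyStructureTruth(
        hinge_angle_deg=float(angle_deg),
        pair_distances=pair_distances,
        reactive_sites=tuple(reactive),
        motor_range=(1, n_per_arm),
        lever_range=(n_per_arm + 1, 2 * n_per_arm),
    )
    return model_a, model_b, truth


def write_pdb(model: StructureModel, path) -> None:
    model.structure.write_pdb(str(path))


def rigid_transform_model(
    model: StructureModel,
    rotation: np.ndarray,
    translation: np.ndarray,
    model_id: Optional[str] = None,
) -> StructureModel:
    """A copy of ``model`` with every atom moved by ``R x + t``.

    Useful for asserting rigid-motion invariance of distances and
    superposition statistics.
    """
    structure = model.structure.clone()
    rotation = np.asarray(rotation, float)
    translation = np.asarray(translation, float)
    for st_model in structure:
        for chain in st_model:
            for residue in chain:
                for atom in residue:
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    moved = rotation @ pos + translation
                    atom.pos = gemmi.Position(*moved)
    return StructureModel(
        model_id=model_id or f"{model.model_id}_moved",
        structure=structure,
        chain_map=dict(model.chain_map),
        offsets=dict(model.offsets),
        role=model.role,
    )


# ---------------------------------------------------------------------------
# end-to-end dynamics benchmark


#: (category, planted log2 fold change, distance in primary models,
#:  distance in the alternate bent-lever model) — distances in Å, chosen on
#: either side of the 30 Å reach.
_BENCHMARK_PLAN = (
    ("stabilized_state", 2.0, 15.0, 15.0),
    ("alternate_state_sampling", 2.0, 45.0, 20.0),
    ("increased_dynamics", 2.0, 45.0, 45.0),
    ("lost_exploratory", -2.0, 45.0, 45.0),
    ("redistribution", -2.0, 15.0, 15.0),
    ("no_change", 0.0, 15.0, 15.0),
)


@dataclass
class DynamicsBenchmark:
    """A planted-truth benchmark spanning every dynamics category."""

    table: pd.DataFrame
    sequences: dict[str, str]
    models: list[StructureModel]
    roles: dict[str, str]
    truth_category: dict[tuple, str]
    truth: QuantTruth


def simulate_dynamics_benchmark(
    seed: int = 0, cv: float = 0.0, n_per_category: int = 3
) -> DynamicsBenchmark:
    """Quant table plus model trio planting every dynamics category.

    Each link's planted fold change (4x up, 4x down, or null) and its
    Calpha-Calpha distances in two primary models ("S1", "S1_mava") and one
    alternate bent-lever model ("BH_lever") are chosen so that the pipeline
    (normalize -> aggregate -> test -> annotate -> classify) must recover the
    category exactly at cv = 0.
    """
    protein_id = "BENCH_SYN"
    n_links = len(_BENCHMARK_PLAN) * n_per_category
    length = 20 * n_links + 20
    sequence = _make_sequence(length)
    rng = np.random.default_rng(seed)

    conditions = ("control", "treated")
    replicates = ("1", "2", "3")
    loading = {(c, r): 1.0 for c in conditions for r in replicates}

    coords: dict[str, dict[int, np.ndarray]] = {"S1": {}, "S1_mava": {}, "BH_lever": {}}
    names: dict[int, str] = {}
    rows = []
    truth_lfc: dict[tuple, float] = {}
    truth_kind: dict[tuple, str] = {}
    truth_category: dict[tuple, str] = {}

    link_index = 0
    for category, lfc, d_primary, d_alternate in _BENCHMARK_PLAN:
        for _ in range(n_per_category):
            r1 = 20 * link_index + 5
            r2 = 20 * link_index + 15
            assert sequence[r1 - 1] == "K" and sequence[r2 - 1] == "K"
            site_a = ResidueRef(protein_id, r1, "K")
            site_b = ResidueRef(protein_id, r2, "K")
            species = LinkSpecies("interpeptide", site_a, site_b)
            truth_lfc[species.key] = lfc
            truth_kind[species.key] = "interpeptide"
            truth_category[species.key] = category

            x0 = 100.0 * link_index
            for model_id in ("S1", "S1_mava"):
                coords[model_id][r1] = np.array([x0, 0.0, 0.0])
                coords[model_id][r2] = np.array([x0 + d_primary, 0.0, 0.0])
            coords["BH_lever"][r1] = np.array([x0, 0.0, 0.0])
            coords["BH_lever"][r2] = np.array([x0 + d_alternate, 0.0, 0.0])
            names[r1] = names[r2] = "LYS"

            base = float(10 ** rng.uniform(5.5, 6.5))
            peptide = sequence[r1 - 1 : r1 + 9]
            for condition_index, condition in enumerate(conditions):
                mean = base * (2.0**lfc if condition_index == 1 else 1.0)
                for replicate in replicates:
                    rows.append(
                        {
                            "protein_a": protein_id,
                            "site_a": site_a.site,
                            "protein_b": protein_id,
                            "site_b": site_b.site,
                            "link_kind": "interpeptide",
                            "peptide": peptide,
                            "charge": 2,
                            "condition": condition,
                            "replicate": replicate,
                            "intensity": mean * _noise_factor(rng, cv),
                            "retention_time": "",
                            "candidate_sites": "",
                        }
                    )
            link_index += 1

    for k, base in enumerate((4e6, 6e6, 8e6)):
        peptide = sequence[10 * k : 10 * k + 8].replace("K", "A")
        for condition in conditions:
            for replicate in replicates:
                rows.append(
                    {
                        "protein_a": protein_id,
                        "site_a": "",
                        "protein_b": "",
                        "site_b": "",
                        "link_kind": "unmodified",
                        "peptide": peptide,
                        "charge": 2,
                        "condition": condition,
                        "replicate": replicate,
                        "intensity": base * _noise_factor(rng, cv),
                        "retention_time": "",
                        "candidate_sites": "",
                    }
                )

    models = []
    roles = {"S1": "primary", "S1_mava": "primary", "BH_lever": "alternate"}
    for model_id in ("S1", "S1_mava", "BH_lever"):
        residues = [
            (num, names[num], [("CA", tuple(pos))])
            for num, pos in sorted(coords[model_id].items())
        ]
        models.append(
            StructureModel(
                model_id=model_id,
                structure=_build_structure(model_id, residues),
                chain_map={protein_id: "A"},
                offsets={protein_id: 0},
                role=roles[model_id],
            )
        )

    truth = QuantTruth(
        log2_fold_change=truth_lfc,
        link_kinds=truth_kind,
        loading_factors=loading,
        cv=cv,
        seed=seed,
        conditions=conditions,
        n_replicates=3,
    )
    return DynamicsBenchmark(
        table=pd.DataFrame(rows, columns=list(TABLE_COLUMNS)),
        sequences={protein_id: sequence},
        models=models,
        roles=roles,
        truth_category=truth_category,
        truth=truth,
    )
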