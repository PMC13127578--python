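"""Replicate normalization and peptide-to-residue aggregation.

Normalization follows the label-free qXL-MS convention: each replicate's raw
MS1 intensities are divided by a loading factor derived from the total signal
of peptides that carry *no* cross-linker modification in that replicate.
Anchoring the factors to the geometric mean of all replicates' totals makes
them symmetric and scale-stable; the anchor cancels in every between-condition
fold change, so only the relative totals matter.

Aggregation combines peptide species that report the same residue-to-residue
cross-link (or the same monolinked residue) regardless of charge state,
peptide length or modification status, by summing their normalized
intensities.  Summation conserves total signal per replicate.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import gmean

from qxlms.xlink_io import (
    REACTIVE_RESIDUES,
    LinkSpecies,
    PeptideQuant,
    ReplicateProfile,
    ResidueRef,
    canonical_sites,
)


class NormalizationError(ValueError):
    """Normalization denominator is undefined for some replicate."""


class AmbiguityError(ValueError):
    """A peptide still carries unresolved candidate sites."""


@dataclass
class AggregatedQuant:
    """Normalized, residue-level signal for one link species.

    ``normalized_intensity[(condition, replicate)]`` is the sum over member
    peptides of raw intensity divided by that replicate's norm factor; a cell
    is ``None`` only when it is missing in every member peptide.
    """

    link: LinkSpecies
    normalized_intensity: dict[tuple[str, str], Optional[float]]
    n_member_peptides: int


def compute_norm_factors(peptides: Iterable[PeptideQuant]) -> list[ReplicateProfile]:
    """Derive per-replicate normalization factors from unreacted peptides.

    ``total_unreacted_signal`` is the summed intensity of cross-linker-free
    peptides per (condition, replicate); ``norm_factor`` is that total divided
    by the geometric mean of all replicates' totals.  A replicate with zero
    (or no) unreacted signal makes normalization undefined and raises
    :class:`NormalizationError`.
    """
    peptides = list(peptides)
    declared: set[tuple[str, str]] = set()
    totals: dict[tuple[str, str], float] = defaultdict(float)
    for pep in peptides:
        declared.update(pep.intensities.keys())
        if pep.is_unmodified:
            for pair, value in pep.intensities.items():
                if value is not None:
                    totals[pair] += value

    missing = [pair for pair in declared if totals.get(pair, 0.0) <= 0.0]
    if missing:
        raise NormalizationError(
            "no unreacted (cross-linker-free) signal in replicate(s): "
            + ", ".join(f"{c}/{r}" for c, r in sorted(missing))
        )

    pairs = sorted(declared)
    anchor = float(gmean([totals[p] for p in pairs]))
    return [
        ReplicateProfile(
            condition=c,
            replicate=r,
            total_unreacted_signal=totals[(c, r)],
            norm_factor=totals[(c, r)] / anchor,
        )
        for c, r in pairs
    ]


def norm_factor_map(profiles: Sequence[ReplicateProfile]) -> dict[tuple[str, str], float]:
    return {(p.condition, p.replicate): p.norm_factor for p in profiles}


# ---------------------------------------------------------------------------
# ambiguous-site resolution


def build_evidence_counts(peptides: Iterable[PeptideQuant]) -> Counter:
    """Count, per residue, the distinct link species it participates in.

    Only unambiguous peptides contribute.  The counts feed the ambiguity
    rule: an ambiguous attachment goes to the candidate residue that produced
    the most *other* cross-links or monolinks.
    """
    seen: set[tuple] = set()
    for pep in peptides:
        if pep.is_ambiguous or pep.is_unmodified:
            continue
        species = (pep.link_kind, canonical_sites(pep.assigned_sites))
        for ref in pep.assigned_sites:
            seen.add((ref.protein_id, ref.residue_index, species))
    counts: Counter = Counter()
    for protein_id, index, _species in seen:
        counts[(protein_id, index)] += 1
    return counts


def resolve_ambiguous_site(
    peptide: PeptideQuant, link_evidence_counts: Optional[Mapping] = None
) -> ResidueRef:
    """Pick the attachment site for a peptide with ambiguous candidates.

    Rules, in order: prefer lysine over S/T/Y; among several lysines prefer
    the one with the greatest evidence count (other links/monolinks at that
    residue); remaining ties break to the lowest residue index, so the choice
    is deterministic.
    """
    counts = link_evidence_counts or {}
    candidates = [
        c
        for c in peptide.ambiguous_candidates
        if c.residue_code in REACTIVE_RESIDUES or c.residue_index == 1
    ]
    if not candidates:
        raise AmbiguityError(
            f"peptide {peptide.peptide_sequence!r} has no reactive candidate site"
        )
    lysines = [c for c in candidates if c.residue_code == "K"]
    pool = lysines if lysines else candidates
    return min(
        pool,
        key=lambda c: (-counts.get((c.protein_id, c.residue_index), 0), c.residue_index),
    )


def resolve_ambiguities(
    peptides: Sequence[PeptideQuant], link_evidence_counts: Optional[Mapping] = None
) -> list[PeptideQuant]:
    """Resolve every ambiguous peptide, replacing its first assigned site.

    Evidence counts default to :func:`build_evidence_counts` over the
    unambiguous peptides of the input.  Returns a new list; unambiguous
    peptides pass through unchanged.
    """
    counts = (
        link_evidence_counts
        if link_evidence_counts is not None
        else build_evidence_counts(peptides)
    )
    resolved = []
    for pep in peptides:
        if not pep.is_ambiguous:
            resolved.append(pep)
            continue
        choice = resolve_ambiguous_site(pep, counts)
        sites = (choice,) + tuple(pep.assigned_sites[1:])
        resolved.append(
            replace(
                pep,
                assigned_sites=canonical_sites(sites),
                ambiguous_candidates=(),
            )
        )
    return resolved


# ---------------------------------------------------------------------------
# aggregation


def aggregate_links(
    peptides: Iterable[PeptideQuant], profiles: Sequence[ReplicateProfile]
) -> list[AggregatedQuant]:
    """Combine peptides into residue-level link species (normalized sums).

    Grouping key: the canonical residue pair (single residue for monolinks)
    together with the link kind.  Intensities are normalized per replicate
    and summed across member peptides; a cell is missing only when missing in
    every member.  Unreacted carrier peptides are not aggregated.  Peptides
    with unresolved ambiguous sites raise :class:`AmbiguityError` — resolve
    them first via :func:`resolve_ambiguities`.
    """
    factors = norm_factor_map(profiles)
    groups: dict[tuple, list[PeptideQuant]] = defaultdict(list)
    for pep in peptides:
        if pep.is_unmodified:
            continue
        if pep.is_ambiguous:
            raise AmbiguityError(
                f"peptide {pep.peptide_sequence!r} has unresolved candidate "
                "sites; run resolve_ambiguities() first"
            )
        groups[(pep.link_kind, canonical_sites(pep.assigned_sites))].append(pep)

    aggregated = []
    for (kind, sites), members in sorted(
        groups.items(), key=lambda item: (item[0][0], tuple(map(str, item[0][1])))
    ):
        cells: dict[tuple[str, str], Optional[float]] = {}
        for pair in sorted({p for m in members for p in m.intensities}):
            values = [
                m.intensities[pair] / factors[pair]
                for m in members
                if m.intensities.get(pair) is not None
            ]
            cells[pair] = sum(values) if values else None
        link = LinkSpecies(
            link_kind=kind,
            site_a=sites[0],
            site_b=sites[1] if len(sites) > 1 else None,
            member_peptides=list(members),
        )
        aggregated.append(
            AggregatedQuant(
                link=link,
                normalized_intensity=cells,
                n_member_peptides=len(members),
            )
        )
    return aggregated
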