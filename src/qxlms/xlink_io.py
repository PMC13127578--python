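"""Data model and I/O for quantified cross-link / monolink tables.

The central objects are :class:`ResidueRef` (a residue-resolved cross-linker
attachment site), :class:`PeptideQuant` (one peptide species with per-replicate
MS1 intensities) and :class:`LinkSpecies` (a residue-to-residue cross-link,
intra-peptide link or monolink after peptide aggregation).

Input tables are delimited text (comma or tab, autodetected) with one row per
peptide species per replicate.  Mandatory columns::

    protein_a, site_a, protein_b, site_b, link_kind, peptide, charge,
    condition, replicate, intensity

``site_b`` is empty for monolinks; both site columns are empty for unreacted
("unmodified") carrier peptides, which exist only to supply the normalization
denominator.  Optional columns: ``retention_time``, ``candidate_sites``
(semicolon-separated list of alternative attachment sites for ambiguous
peptides).  Sites are written in the usual XL-MS shorthand, e.g. ``K206``.

Amine/hydroxyl-reactive cross-linkers such as DSBU attach to lysine, serine,
threonine and tyrosine side chains, or to the protein N-terminus; site
validation enforces exactly that against the supplied construct FASTA.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

#: Side chains an NHS-ester/hydroxyl-reactive cross-linker can attach to.
REACTIVE_RESIDUES = frozenset("KSTY")

LINK_KINDS = ("interpeptide", "intrapeptide", "monolink", "unmodified")

MANDATORY_COLUMNS = (
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
)

#: Pseudobond colors per dynamics category (solid/in-reach categories use
#: saturated colors, exploratory/beyond-reach ones use lighter shades, the
#: increase family is red-toned and the decrease family purple-toned).
CATEGORY_COLORS = {
    "stabilized_state": "red",
    "alternate_state_sampling": "orange",
    "increased_dynamics": "salmon",
    "redistribution": "purple",
    "lost_exploratory": "plum",
    "no_change": "gray",
    "unannotated": "dim gray",
}


class FormatError(ValueError):
    """A table does not conform to the declared schema."""


class ValidationError(ValueError):
    """One or more rows failed site validation against the FASTA.

    Attributes
    ----------
    rejected : list of RejectedRow
        Every offending row with its reason; counts conserve with the
        accepted rows.
    """

    def __init__(self, message: str, rejected: Sequence["RejectedRow"]):
        super().__init__(message)
        self.rejected = list(rejected)


@dataclass(frozen=True, order=True)
class ResidueRef:
    """A residue in a named construct sequence (1-based, incl. initiator Met)."""

    protein_id: str
    residue_index: int
    residue_code: str

    def __str__(self) -> str:  # e.g. "MYH7:K206"
        return f"{self.protein_id}:{self.residue_code}{self.residue_index}"

    @property
    def site(self) -> str:
        return f"{self.residue_code}{self.residue_index}"


_SITE_RE = re.compile(r"^([A-Za-z])(\d+)$")


def parse_site(protein_id: str, site: str) -> ResidueRef:
    """Parse a ``K206``-style site string into a :class:`ResidueRef`."""
    m = _SITE_RE.match(site.strip())
    if not m:
        raise FormatError(f"unparseable site {site!r} (expected e.g. 'K206')")
    return ResidueRef(protein_id, int(m.group(2)), m.group(1).upper())


@dataclass
class PeptideQuant:
    """One peptide species (sequence x charge x modification) with intensities.

    ``intensities`` maps ``(condition, replicate)`` to a non-negative MS1
    signal, or ``None`` where the measurement is absent.  Missingness is kept
    explicit and never imputed as zero: a zero would silently bias fold
    changes downstream.
    """

    peptide_sequence: str
    charge: int
    link_kind: str
    assigned_sites: tuple[ResidueRef, ...]
    intensities: dict[tuple[str, str], Optional[float]]
    modifications: tuple[tuple[int, str], ...] = ()
    retention_time: Optional[float] = None
    ambiguous_candidates: tuple[ResidueRef, ...] = ()

    @property
    def is_unmodified(self) -> bool:
        """True for carrier peptides bearing no cross-linker modification."""
        return self.link_kind == "unmodified"

    @property
    def is_ambiguous(self) -> bool:
        return len(self.ambiguous_candidates) > 0

    def species_key(self):
        return (
            self.link_kind,
            canonical_sites(self.assigned_sites),
            self.peptide_sequence,
            self.charge,
            self.ambiguous_candidates,
        )


def canonical_sites(sites: Sequence[ResidueRef]) -> tuple[ResidueRef, ...]:
    """Canonicalize a site tuple: unordered pairs sorted by (protein, index)."""
    return tuple(sorted(sites))


@dataclass
class LinkSpecies:
    """A residue-resolved cross-link, intra-peptide link or monolink.

    The unordered, canonically sorted residue pair (single residue for
    monolinks) is the unique key joining quantification, statistics and
    structure-mapping results.
    """

    link_kind: str
    site_a: ResidueRef
    site_b: Optional[ResidueRef] = None
    member_peptides: list = field(default_factory=list)
    site_a_alternates: tuple[ResidueRef, ...] = ()
    site_b_alternates: tuple[ResidueRef, ...] = ()

    def __post_init__(self) -> None:
        if self.link_kind == "monolink" and self.site_b is not None:
            raise ValueError("monolink must have exactly one site")
        if self.link_kind == "intrapeptide" and self.site_b is not None:
            if self.site_a.protein_id != self.site_b.protein_id:
                raise ValueError("intrapeptide link must stay on one protein")
        if self.site_b is not None and self.site_b < self.site_a:
            self.site_a, self.site_b = self.site_b, self.site_a
            self.site_a_alternates, self.site_b_alternates = (
                self.site_b_alternates,
                self.site_a_alternates,
            )

    @property
    def key(self):
        if self.site_b is None:
            return (self.link_kind, str(self.site_a))
        return (self.link_kind, str(self.site_a), str(self.site_b))

    @property
    def label(self) -> str:
        if self.site_b is None:
            return str(self.site_a)
        return f"{self.site_a}--{self.site_b}"


@dataclass
class ReplicateProfile:
    """Per-replicate normalization state.

    ``total_unreacted_signal`` is the summed intensity of peptides bearing no
    cross-linker modification in that replicate; ``norm_factor`` is that total
    divided by the geometric mean of all replicates' totals, so dividing each
    raw intensity by the factor corrects replicate-to-replicate loading.
    """

    condition: str
    replicate: str
    total_unreacted_signal: float
    norm_factor: float


@dataclass
class RejectedRow:
    row_number: int  # 1-based data row index in the input file
    reason: str


# ---------------------------------------------------------------------------
# readers


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA into ``{protein_id: sequence}``.

    Identifiers are the first whitespace-delimited token of each header.
    Duplicate identifiers and empty files raise :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    return sequences


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


@dataclass
class QuantTable:
    """Parsed quant table: accepted peptides plus the rejection report."""

    peptides: list[PeptideQuant]
    rejected: list[RejectedRow]
    conditions: tuple[str, ...]
    replicates: tuple[str, ...]


def _validate_site(
    ref: ResidueRef, sequences: Optional[Mapping[str, str]]
) -> Optional[str]:
    """Return a rejection reason, or None if the site is valid."""
    if sequences is not None:
        seq = sequences.get(ref.protein_id)
        if seq is None:
            return f"unknown protein {ref.protein_id!r}"
        if not (1 <= ref.residue_index <= len(seq)):
            return (
                f"site {ref} out of range for {ref.protein_id} "
                f"(length {len(seq)})"
            )
        if seq[ref.residue_index - 1] != ref.residue_code:
            return (
                f"site {ref} disagrees with FASTA residue "
                f"{seq[ref.residue_index - 1]!r} at that position"
            )
    if ref.residue_code not in REACTIVE_RESIDUES and ref.residue_index != 1:
        return (
            f"site {ref} is not cross-linker reactive "
            f"(need K/S/T/Y or the protein N-terminus)"
        )
    return None


def read_quant_table(
    path,
    sequences: Optional[Mapping[str, str]] = None,
    dialect: str = "auto",
    strict: bool = True,
) -> QuantTable:
    """Read a delimited quant table into :class:`PeptideQuant` objects.

    Parameters
    ----------
    path : path-like
        Comma- or tab-delimited text, one row per peptide species per
        replicate (columns as in the module docstring).
    sequences : mapping, optional
        Construct sequences from :func:`read_fasta`; enables full site
        validation (range, residue identity, reactivity).  Without it only
        reactivity of the residue code is checked.
    dialect : {"auto", "comma", "tab"}
        Field delimiter; ``auto`` sniffs the header line.
    strict : bool
        If True (default) raise :class:`ValidationError` when any row fails
        validation; if False, failed rows are returned in ``rejected`` and
        the remaining rows are parsed normally.  Either way every input row
        is accounted for: accepted + rejected row counts conserve.
    """
    if dialect == "auto":
        sep = _sniff_delimiter(path)
    elif dialect in ("comma", "csv"):
        sep = ","
    elif dialect in ("tab", "tsv"):
        sep = "\t"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for column in MANDATORY_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"missing mandatory column {column!r}")

    declared_pairs: set[tuple[str, str]] = set()
    groups: dict[tuple, dict] = {}
    rejected: list[RejectedRow] = []

    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        kind = row.link_kind.strip()
        if kind not in LINK_KINDS:
            rejected.append(RejectedRow(row_number, f"unknown link_kind {kind!r}"))
            continue
        try:
            sites: tuple[ResidueRef, ...] = ()
            candidates: tuple[ResidueRef, ...] = ()
            if kind != "unmodified":
                site_a = parse_site(row.protein_a, row.site_a)
                sites = (site_a,)
                if kind == "monolink":
                    if row.site_b.strip():
                        raise FormatError("monolink row carries a second site")
                else:
                    if not row.site_b.strip():
                        raise FormatError(f"{kind} row lacks site_b")
                    site_b = parse_site(row.protein_b or row.protein_a, row.site_b)
                    sites = (site_a, site_b)
                if hasattr(row, "candidate_sites") and row.candidate_sites.strip():
                    candidates = tuple(
                        parse_site(row.protein_a, tok)
                        for tok in row.candidate_sites.split(";")
                        if tok.strip()
                    )
        except FormatError as exc:
            rejected.append(RejectedRow(row_number, str(exc)))
            continue

        reason = None
        if kind == "intrapeptide" and len(sites) == 2:
            if sites[0].protein_id != sites[1].protein_id:
                reason = "intrapeptide link spans two proteins"
        for ref in sites + candidates:
            if reason is None:
                reason = _validate_site(ref, sequences)
        if kind == "unmodified" and sequences is not None:
            if row.protein_a and row.protein_a not in sequences:
                reason = f"unknown protein {row.protein_a!r}"
        if reason is not None:
            rejected.append(RejectedRow(row_number, reason))
            continue

        try:
            intensity = float(row.intensity) if row.intensity.strip() else None
        except ValueError:
            rejected.append(
                RejectedRow(row_number, f"unparseable intensity {row.intensity!r}")
            )
            continue
        if intensity is not None and intensity < 0:
            rejected.append(RejectedRow(row_number, "negative intensity"))
            continue

        condition = row.condition.strip()
        replicate = row.replicate.strip()
        declared_pairs.add((condition, replicate))
        rt = None
        if hasattr(row, "retention_time") and row.retention_time.strip():
            rt = float(row.retention_time)

        key = (kind, canonical_sites(sites), row.peptide, int(row.charge), candidates)
        entry = groups.setdefault(
            key,
            {
                "peptide": row.peptide,
                "charge": int(row.charge),
                "kind": kind,
                "sites": canonical_sites(sites),
                "candidates": candidates,
                "protein": row.protein_a,
                "intensities": {},
                "retention_time": rt,
            },
        )
        entry["intensities"][(condition, replicate)] = intensity

    if strict and rejected:
        lines = "; ".join(f"row {r.row_number}: {r.reason}" for r in rejected[:20])
        raise ValidationError(
            f"{len(rejected)} row(s) failed validation: {lines}", rejected
        )

    peptides = []
    for entry in groups.values():
        intensities = {
            pair: entry["intensities"].get(pair) for pair in sorted(declared_pairs)
        }
        peptides.append(
            PeptideQuant(
                peptide_sequence=entry["peptide"],
                charge=entry["charge"],
                link_kind=entry["kind"],
                assigned_sites=entry["sites"],
                intensities=intensities,
                retention_time=entry["retention_time"],
                ambiguous_candidates=entry["candidates"],
            )
        )

    conditions = tuple(sorted({c for c, _ in declared_pairs}))
    replicates = tuple(sorted({r for _, r in declared_pairs}))
    return QuantTable(peptides, rejected, conditions, replicates)


# ---------------------------------------------------------------------------
# writers


def _result_row(diff, annotations_by_model, call, model_ids):
    row = {
        "link": diff.label,
        "link_kind": diff.link_kind,
        "fold_change": diff.fold_change,
        "p_value": diff.p_value,
        "direction": diff.direction,
        "significant": diff.significant,
    }
    for model_id in model_ids:
        ann = annotations_by_model.get(model_id)
        if ann is not None and ann.mapped:
            row[f"d_ca_{model_id}"] = ann.d_ca
            row[f"within_reach_{model_id}"] = ann.within_reach
        else:
            row[f"d_ca_{model_id}"] = math.nan
            row[f"within_reach_{model_id}"] = None
    row["category"] = call.category if call is not None else ""
    return row


def write_results(diff_results, annotations, calls, path) -> pd.DataFrame:
    """Join differential results, distance annotations and dynamics calls on
    the link key and write a tab-delimited report (one row per link).

    Raises ``KeyError`` naming the offending key when an annotation or call
    does not join to a differential result.  Returns the frame written, so
    callers can keep working with it in memory.
    """
    diff_by_key = {r.key: r for r in diff_results}
    ann_by_key: dict[tuple, dict] = {}
    model_ids: list[str] = []
    for ann in annotations:
        if ann.link_key not in diff_by_key:
            raise KeyError(f"annotation for unknown link key {ann.link_key!r}")
        ann_by_key.setdefault(ann.link_key, {})[ann.model_id] = ann
        if ann.model_id not in model_ids:
            model_ids.append(ann.model_id)
    call_by_key = {}
    for call in calls:
        if call.link_key not in diff_by_key:
            raise KeyError(f"dynamics call for unknown link key {call.link_key!r}")
        call_by_key[call.link_key] = call

    rows = [
        _result_row(diff, ann_by_key.get(key, {}), call_by_key.get(key), model_ids)
        for key, diff in sorted(diff_by_key.items())
    ]
    frame = pd.DataFrame(
        rows,
        columns=["link", "link_kind", "fold_change", "p_value", "direction",
                 "significant"]
        + [c for m in model_ids for c in (f"d_ca_{m}", f"within_reach_{m}")]
        + ["category"],
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame


def read_results(path) -> pd.DataFrame:
    """Read back a results report written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def write_pseudobonds(annotations, model_id: str, path, categories=None) -> int:
    """Write a ChimeraX-style pseudobond file for one model.

    One line per mapped cross-link annotation of ``model_id``::

        /A:707@CA /A:715@CA red

    ``categories`` maps link key -> dynamics category; colors follow
    :data:`CATEGORY_COLORS` so the rendering distinguishes within-reach from
    exploratory links and increases from decreases.  Returns the number of
    lines written; unmapped annotations raise ``ValueError``.
    """
    categories = categories or {}
    lines = []
    for ann in annotations:
        if ann.model_id != model_id:
            continue
        if not ann.mapped or ann.address_a is None or ann.address_b is None:
            raise ValueError(
                f"link {ann.link_key!r} is not resolvable in model {model_id!r}"
            )
        color = CATEGORY_COLORS.get(categories.get(ann.link_key, ""), "gold")
        (chain_a, num_a), (chain_b, num_b) = ann.address_a, ann.address_b
        lines.append(f"/{chain_a}:{num_a}@CA /{chain_b}:{num_b}@CA {color}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return len(lines)
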