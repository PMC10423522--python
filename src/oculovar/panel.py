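"""Gene-panel data model for G2P-format disease gene panels.

A panel entry ties a gene to a disease through a *disease mechanism*: an
allelic requirement (the genotype configuration needed for disease, e.g.
biallelic) and a mutation consequence (the mechanism class of pathogenic
alleles, e.g. loss-of-function), with a curation confidence level.  The
filtering engine consumes these entries to decide which variants qualify
and whether a gene's requirement is satisfied in a given individual.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class AllelicRequirement(str, Enum):
    """Genotype configuration required for disease."""

    MONOALLELIC = "monoallelic"
    BIALLELIC = "biallelic"
    HEMIZYGOUS = "hemizygous"
    MONOALLELIC_AND_BIALLELIC = "monoallelic_and_biallelic"
    MITOCHONDRIAL = "mitochondrial"


class MutationConsequence(str, Enum):
    """Mechanism class of the disease alleles for a gene-disease pair."""

    LOSS_OF_FUNCTION = "loss_of_function"
    DOMINANT_NEGATIVE = "dominant_negative"
    ALL_MISSENSE_OR_INFRAME = "all_missense_or_inframe"
    ACTIVATING = "activating"
    UNCERTAIN = "uncertain"


class Confidence(str, Enum):
    """Curation confidence that the gene is implicated in the disease."""

    POSSIBLE = "possible"
    PROBABLE = "probable"
    CONFIRMED = "confirmed"


# ordering used by select_entries: possible < probable < confirmed
_CONFIDENCE_RANK = {
    Confidence.POSSIBLE: 0,
    Confidence.PROBABLE: 1,
    Confidence.CONFIRMED: 2,
}


class Compartment(str, Enum):
    RETINA = "retina"
    LENS = "lens"
    CORNEA = "cornea"
    VITREOUS = "vitreous"
    OPTIC_NERVE = "optic_nerve"
    OTHER = "other"


_HPO_RE = re.compile(r"^HP:\d{7}$")


class PanelError(ValueError):
    """Schema or validation failure while reading a panel file."""


@dataclass(frozen=True)
class PanelEntry:
    """One gene-disease thread of a curated panel."""

    gene_symbol: str
    disease_name: str
    allelic_requirement: AllelicRequirement
    mutation_consequence: MutationConsequence
    confidence: Confidence
    gene_id: str | None = None
    phenotype_terms: tuple[str, ...] = ()
    publications: tuple[str, ...] = ()
    compartment: Compartment | None = None

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise PanelError("gene_symbol must be non-empty")
        for term in self.phenotype_terms:
            if not _HPO_RE.match(term):
                raise PanelError(
                    f"phenotype term {term!r} does not match HP:NNNNNNN"
                )

    @property
    def key(self) -> tuple[str, str, AllelicRequirement]:
        return (self.gene_symbol, self.disease_name, self.allelic_requirement)


@dataclass
class Panel:
    """A named collection of panel entries."""

    entries: list[PanelEntry] = field(default_factory=list)
    name: str = "panel"
    version: str = "0"

    def gene_set(self) -> set[str]:
        return {e.gene_symbol for e in self.entries}

    def entries_for_gene(self, gene_symbol: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.gene_symbol == gene_symbol]

    def expand_requirements(self) -> "Panel":
        """Split monoallelic_and_biallelic entries into one entry per
        requirement so downstream logic handles a single requirement at a
        time."""
        out: list[PanelEntry] = []
        for e in self.entries:
            if e.allelic_requirement is AllelicRequirement.MONOALLELIC_AND_BIALLELIC:
                out.append(replace(e, allelic_requirement=AllelicRequirement.MONOALLELIC))
                out.append(replace(e, allelic_requirement=AllelicRequirement.BIALLELIC))
            else:
                out.append(e)
        return Panel(entries=out, name=self.name, version=self.version)

    def __len__(self) -> int:
        return len(self.entries)


#: canonical column names -> aliases accepted in panel CSV headers
DEFAULT_HEADER_MAP: dict[str, tuple[str, ...]] = {
    "gene_symbol": ("gene_symbol", "gene symbol", "gene"),
    "disease_name": ("disease_name", "disease name", "disease"),
    "allelic_requirement": ("allelic_requirement", "allelic requirement"),
    "mutation_consequence": ("mutation_consequence", "mutation consequence"),
    "confidence": ("confidence", "confidence category"),
    "gene_id": ("gene_id", "gene id", "gene mim"),
    "phenotype_terms": ("phenotype_terms", "hpo ids", "phenotypes"),
    "publications": ("publications", "pmids"),
    "compartment": ("compartment", "organ"),
}

_REQUIRED = (
    "gene_symbol",
    "disease_name",
    "allelic_requirement",
    "mutation_consequence",
    "confidence",
)


def _normalise_token(value: str) -> str:
    return value.strip().lower().replace(" ", "_").replace("-", "_")


def _parse_enum(enum_cls, token: str, row_num: int, column: str):
    norm = _normalise_token(token)
    try:
        return enum_cls(norm)
    except ValueError:
        raise PanelError(
            f"row {row_num}: unknown {column} value {token!r}"
        ) from None


def _resolve_header(
    fieldnames: Sequence[str], header_map: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    lowered = {name.strip().lower(): name for name in fieldnames}
    resolved: dict[str, str] = {}
    for canonical, aliases in header_map.items():
        for alias in aliases:
            if alias in lowered:
                resolved[canonical] = lowered[alias]
                break
    missing = [c for c in _REQUIRED if c not in resolved]
    if missing:
        raise PanelError(f"missing required column(s): {', '.join(missing)}")
    return resolved


def _split_multi(value: str | None) -> tuple[str, ...]:
    if not value:
        return ()
    return tuple(t.strip() for t in value.split(";") if t.strip())


def parse_panel_file(
    path: str | Path,
    *,
    name: str | None = None,
    version: str = "0",
    header_map: Mapping[str, tuple[str, ...]] | None = None,
) -> Panel:
    """Parse a comma-separated panel file into a :class:`Panel`.

    The header is matched case-insensitively against ``header_map``
    aliases.  Enum fields are normalised case-insensitively; a row with an
    unknown enum token raises :class:`PanelError` naming the row.
    Multi-valued fields (HPO terms, PMIDs) are semicolon-separated.
    """
    path = Path(path)
    header_map = dict(header_map or DEFAULT_HEADER_MAP)
    entries: list[PanelEntry] = []
    seen: set[tuple[str, str, AllelicRequirement]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PanelError(f"{path}: empty file, header row required")
        cols = _resolve_header(reader.fieldnames, header_map)
        for row_num, row in enumerate(reader, start=2):
            gene = (row.get(cols["gene_symbol"]) or "").strip()
            if not gene:
                raise PanelError(f"row {row_num}: empty gene symbol")
            compartment = None
            if "compartment" in cols and (row.get(cols["compartment"]) or "").strip():
                token = _normalise_token(row[cols["compartment"]])
                try:
                    compartment = Compartment(token)
                except ValueError:
                    compartment = Compartment.OTHER  # descriptive only
            entry = PanelEntry(
                gene_symbol=gene,
                disease_name=(row.get(cols["disease_name"]) or "").strip(),
                allelic_requirement=_parse_enum(
                    AllelicRequirement,
                    row.get(cols["allelic_requirement"]) or "",
                    row_num,
                    "allelic requirement",
                ),
                mutation_consequence=_parse_enum(
                    MutationConsequence,
                    row.get(cols["mutation_consequence"]) or "",
                    row_num,
                    "mutation consequence",
                ),
                confidence=_parse_enum(
                    Confidence, row.get(cols["confidence"]) or "", row_num, "confidence"
                ),
                gene_id=(row.get(cols.get("gene_id", ""), "") or "").strip() or None,
                phenotype_terms=_split_multi(row.get(cols.get("phenotype_terms", ""))),
                publications=_split_multi(row.get(cols.get("publications", ""))),
                compartment=compartment,
            )
            if entry.key in seen:
                raise PanelError(
                    f"row {row_num}: duplicate entry for {entry.key}"
                )
            seen.add(entry.key)
            entries.append(entry)
    return Panel(entries=entries, name=name or path.stem, version=version)


def write_panel_file(panel: Panel, path: str | Path) -> None:
    """Write a panel back to CSV in the canonical column layout.

    ``parse_panel_file(write_panel_file(p))`` round-trips field-for-field.
    """
    columns = [
        "gene_symbol",
        "gene_id",
        "disease_name",
        "allelic_requirement",
        "mutation_consequence",
        "confidence",
        "phenotype_terms",
        "publications",
        "compartment",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for e in panel.entries:
            writer.writerow(
                [
                    e.gene_symbol,
                    e.gene_id or "",
                    e.disease_name,
                    e.allelic_requirement.value,
                    e.mutation_consequence.value,
                    e.confidence.value,
                    ";".join(e.phenotype_terms),
                    ";".join(e.publications),
                    e.compartment.value if e.compartment else "",
                ]
            )


def select_entries(
    panel: Panel,
    min_confidence: Confidence | str = Confidence.POSSIBLE,
    genes: Iterable[str] | None = None,
) -> Panel:
    """Return a new panel restricted to entries at or above a confidence
    level, optionally intersected with a gene set.  The input panel is not
    modified; raising ``min_confidence`` never adds entries."""
    min_confidence = Confidence(min_confidence)
    threshold = _CONFIDENCE_RANK[min_confidence]
    gene_filter = set(genes) if genes is not None else None
    kept = [
        e
        for e in panel.entries
        if _CONFIDENCE_RANK[e.confidence] >= threshold
        and (gene_filter is None or e.gene_symbol in gene_filter)
    ]
    return Panel(entries=kept, name=panel.name, version=panel.version)


def panel_summary(panel: Panel) -> dict[str, dict[str, int]]:
    """Counts of entries along each descriptive axis.

    Within each axis the counts sum to ``len(panel)`` (compartment uses
    'unspecified' for entries without one).
    """
    axes: dict[str, dict[str, int]] = {
        "confidence": {m.value: 0 for m in Confidence},
        "allelic_requirement": {m.value: 0 for m in AllelicRequirement},
        "mutation_consequence": {m.value: 0 for m in MutationConsequence},
        "compartment": {m.value: 0 for m in Compartment} | {"unspecified": 0},
    }
    for e in panel.entries:
        axes["confidence"][e.confidence.value] += 1
        axes["allelic_requirement"][e.allelic_requirement.value] += 1
        axes["mutation_consequence"][e.mutation_consequence.value] += 1
        axes["compartment"][
            e.compartment.value if e.compartment else "unspecified"
        ] += 1
    return axes
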