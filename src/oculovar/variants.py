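"""Variant callset I/O: reading per-individual VCFs, normalisation,
merging SNV/indel and CNV callsets, VEP-style annotation parsing,
inclusion lists and region masks.

Coordinate conventions: variant calls are VCF 1-based; region masks are
BED 0-based half-open.  The conversion between the two happens only in
:func:`apply_region_mask`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from intervaltree import IntervalTree

VariantKey = tuple[str, int, str, str]


class VarClass(str, Enum):
    SNV = "snv"
    INDEL = "indel"
    CNV_DEL = "cnv_del"
    CNV_DUP = "cnv_dup"
    SV_OTHER = "sv_other"


class Zygosity(str, Enum):
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMIZYGOUS = "hemizygous"
    UNKNOWN = "unknown"


class VariantIOError(ValueError):
    """Malformed input or missing sample while reading variant files."""


_SYMBOLIC_CLASS = {
    "<DEL>": VarClass.CNV_DEL,
    "<DUP>": VarClass.CNV_DUP,
}


@dataclass(frozen=True)
class VariantCall:
    """One normalised variant (SNV/indel/CNV) for one individual."""

    chrom: str
    pos: int  # 1-based start, VCF convention
    ref: str
    alt: str  # single allele; symbolic <DEL>/<DUP> allowed for CNVs
    var_class: VarClass
    zygosity: Zygosity
    sample: str = ""
    end: int | None = None  # 1-based inclusive, CNV/SV only
    genotype: tuple[int | None, ...] = ()
    phased: bool = False
    filters: tuple[str, ...] = ()
    quality_ok: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantIOError(f"pos must be >= 1, got {self.pos}")
        if self.is_cnv and self.end is not None and self.end < self.pos:
            raise VariantIOError(f"CNV end {self.end} < pos {self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_cnv(self) -> bool:
        return self.var_class in (VarClass.CNV_DEL, VarClass.CNV_DUP, VarClass.SV_OTHER)

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open interval covered by this call."""
        if self.is_cnv and self.end is not None:
            return (self.pos - 1, self.end)
        return (self.pos - 1, self.pos - 1 + max(len(self.ref), 1))


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One variant x transcript consequence record."""

    variant_key: VariantKey
    gene_symbol: str
    transcript_id: str
    so_terms: tuple[str, ...]
    canonical: bool = False
    impact: str = "modifier"  # high / moderate / low / modifier
    max_pop_af: float | None = None
    cohort_presence: int | None = None

    def __post_init__(self) -> None:
        if not self.so_terms:
            raise VariantIOError("so_terms must be non-empty")
        if self.max_pop_af is not None and not (0.0 <= self.max_pop_af <= 1.0):
            raise VariantIOError(f"max_pop_af {self.max_pop_af} outside [0,1]")


@dataclass
class InclusionLists:
    """Allele inclusion lists that bypass the standard filters.

    * ``known_pathogenic`` — e.g. ClinVar pathogenic / likely pathogenic.
    * ``splice_flagged`` — alleles with a splice-impact delta score.
    * ``hypomorphic`` — pathogenic alleles too common for frequency filters.
    """

    known_pathogenic: set[VariantKey] = field(default_factory=set)
    splice_flagged: dict[VariantKey, float] = field(default_factory=dict)
    hypomorphic: set[VariantKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        for key, delta in self.splice_flagged.items():
            if not (0.0 <= delta <= 1.0):
                raise VariantIOError(f"splice delta {delta} for {key} outside [0,1]")


def normalize_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimonious representation of an allele pair.

    Trims shared trailing bases, then shared leading bases (keeping at
    least one base on each side), advancing ``pos`` past trimmed leading
    bases.  Idempotent.  Symbolic alleles pass through unchanged.
    """
    if alt.startswith("<"):
        return pos, ref, alt
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _classify(ref: str, alt: str) -> VarClass:
    if alt in _SYMBOLIC_CLASS:
        return _SYMBOLIC_CLASS[alt]
    if alt.startswith("<"):
        return VarClass.SV_OTHER
    if len(ref) == 1 and len(alt) == 1:
        return VarClass.SNV
    return VarClass.INDEL


def _zygosity_for_allele(
    alleles: Sequence[int | None], allele_index: int
) -> Zygosity:
    called = [a for a in alleles if a is not None]
    carried = sum(1 for a in called if a == allele_index)
    if len(called) == 1:
        # single-allele genotype: hemizygous by the ploidy rule
        return Zygosity.HEMIZYGOUS if carried == 1 else Zygosity.UNKNOWN
    if carried == 0:
        return Zygosity.UNKNOWN
    if carried == len(called):
        return Zygosity.HOM_ALT
    return Zygosity.HET


def read_callset(
    path: str | Path,
    sample: str,
    *,
    keep_noncarrier: bool = False,
) -> list[VariantCall]:
    """Read one sample's calls from a VCF, split multi-allelic records and
    normalise indels.

    Records with a fully missing genotype for the sample are dropped, as
    are (by default) split alleles the sample does not carry.
    ``quality_ok`` is True when FILTER is PASS or empty.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VariantIOError(f"cannot open VCF {path}: {exc}") from exc
    if sample not in vcf.header.samples:
        raise VariantIOError(
            f"sample {sample!r} not in {path}; available: "
            f"{', '.join(vcf.header.samples)}"
        )
    calls: list[VariantCall] = []
    for rec in vcf:
        sdata = rec.samples[sample]
        alleles = tuple(sdata.allele_indices) if sdata.allele_indices else ()
        if not alleles or all(a is None for a in alleles):
            continue
        phased = bool(sdata.phased)
        filters = tuple(rec.filter.keys())
        quality_ok = len(filters) == 0 or filters == ("PASS",)
        end = rec.stop  # pysam .stop is 0-based exclusive == 1-based inclusive END
        for alt_index, alt in enumerate(rec.alts or (), start=1):
            if alt is None:
                continue
            zyg = _zygosity_for_allele(alleles, alt_index)
            if zyg is Zygosity.UNKNOWN and not keep_noncarrier:
                continue
            var_class = _classify(rec.ref, alt)
            pos, ref, alt_n = rec.pos, rec.ref, alt
            cnv_end = None
            if var_class in (VarClass.CNV_DEL, VarClass.CNV_DUP, VarClass.SV_OTHER):
                cnv_end = end
            else:
                pos, ref, alt_n = normalize_allele(rec.pos, rec.ref, alt)
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt_n,
                    var_class=var_class,
                    zygosity=zyg,
                    sample=sample,
                    end=cnv_end,
                    genotype=alleles,
                    phased=phased,
                    filters=filters,
                    quality_ok=quality_ok,
                )
            )
    vcf.close()
    return calls


def _sort_key(call: VariantCall):
    return (call.chrom, call.pos, call.ref, call.alt)


def merge_callsets(
    small_variants: Iterable[VariantCall], cnvs: Iterable[VariantCall]
) -> list[VariantCall]:
    """Merge SNV/indel and CNV callsets into one coordinate-sorted list.

    Duplicate keys are deduplicated keeping the small-variant record.
    CNVs are keyed on (chrom, pos, end, alt) since symbolic alleles carry
    no sequence.
    """

    def dedup_key(c: VariantCall):
        if c.is_cnv:
            return (c.chrom, c.pos, c.end, c.alt)
        return c.key

    merged: dict = {}
    for call in cnvs:
        merged.setdefault(dedup_key(call), call)
    for call in small_variants:
        merged[dedup_key(call)] = call  # small-variant record wins
    return sorted(merged.values(), key=_sort_key)


#: field-name fragments treated as population frequencies in CSQ blocks
DEFAULT_AF_FIELD_MARKER = "AF"

_NON_AF_FIELDS = {"ALLELE", "FEATURE", "AFFECTED"}  # names that merely contain AF


def parse_annotation_block(
    csq_value: str,
    descriptor: Sequence[str],
    variant_key: VariantKey,
    *,
    af_field_marker: str = DEFAULT_AF_FIELD_MARKER,
) -> list[TranscriptAnnotation]:
    """Parse a VEP-style CSQ INFO value into transcript annotations.

    ``descriptor`` is the pipe-separated field-name list from the VCF
    header.  Transcript sub-records are comma-separated; SO terms within a
    record are '&'-separated.  ``max_pop_af`` is the maximum over every
    numeric field whose upper-cased name contains ``af_field_marker``
    (missing fields leave it None).
    """
    descriptor = list(descriptor)
    annotations: list[TranscriptAnnotation] = []
    for sub in csq_value.split(","):
        fields = sub.split("|")
        if len(fields) != len(descriptor):
            raise VariantIOError(
                f"CSQ record for {variant_key} has {len(fields)} fields, "
                f"descriptor declares {len(descriptor)}"
            )
        rec = dict(zip(descriptor, fields))
        afs: list[float] = []
        cohort_presence: int | None = None
        for name, value in rec.items():
            upper = name.upper()
            if value == "":
                continue
            if upper == "COHORT_PRESENCE":
                cohort_presence = int(value)
            elif af_field_marker in upper and upper not in _NON_AF_FIELDS:
                try:
                    afs.append(float(value))
                except ValueError:
                    continue
        so_terms = tuple(
            t for t in (rec.get("Consequence", "") or "").split("&") if t
        )
        annotations.append(
            TranscriptAnnotation(
                variant_key=variant_key,
                gene_symbol=rec.get("SYMBOL") or rec.get("Gene", ""),
                transcript_id=rec.get("Feature") or rec.get("Transcript", ""),
                so_terms=so_terms or ("intergenic_variant",),
                canonical=(rec.get("CANONICAL", "") or "").upper() == "YES",
                impact=(rec.get("IMPACT", "") or "modifier").lower(),
                max_pop_af=max(afs) if afs else None,
                cohort_presence=cohort_presence,
            )
        )
    return annotations


def read_annotations(path: str | Path) -> dict[VariantKey, list[TranscriptAnnotation]]:
    """Read every CSQ annotation in a VCF, keyed by normalised allele.

    The CSQ descriptor is taken from the header ``##INFO=<ID=CSQ,...
    Format: ...>`` line.  Annotation allele keys are normalised with the
    same rule as :func:`read_callset` so they join exactly.
    """
    vcf = pysam.VariantFile(str(path))
    info = vcf.header.info.get("CSQ")
    if info is None or "Format: " not in (info.description or ""):
        raise VariantIOError(f"{path}: no CSQ INFO with a Format descriptor")
    descriptor = info.description.split("Format: ", 1)[1].split("|")
    out: dict[VariantKey, list[TranscriptAnnotation]] = {}
    for rec in vcf:
        csq = rec.info.get("CSQ")
        if csq is None:
            continue
        if isinstance(csq, tuple):
            csq = ",".join(csq)
        for alt in rec.alts or ():
            if alt is None:
                continue
            if alt.startswith("<"):
                key = (rec.chrom, rec.pos, rec.ref, alt)
                allele_forms = (alt, alt.strip("<>"))
            else:
                pos, ref, alt_n = normalize_allele(rec.pos, rec.ref, alt)
                key = (rec.chrom, pos, ref, alt_n)
                allele_forms = (alt, alt_n)
            anns = parse_annotation_block(csq, descriptor, key)
            if len(rec.alts) > 1:
                # multi-allelic: keep sub-records whose Allele matches
                anns = [
                    a
                    for a, sub in zip(anns, csq.split(","))
                    if sub.split("|", 1)[0] in allele_forms
                ] or anns
            out.setdefault(key, []).extend(anns)
    vcf.close()
    return out


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into per-chromosome interval
    trees.  The 4th column, when present, is stored as interval data."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line_num, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise VariantIOError(f"{path}:{line_num}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise VariantIOError(f"{path}:{line_num}: non-integer coordinates") from exc
            if end <= start:
                raise VariantIOError(f"{path}:{line_num}: end <= start")
            name = parts[3] if len(parts) > 3 else None
            trees.setdefault(parts[0], IntervalTree()).addi(start, end, name)
    return trees


def apply_region_mask(
    calls: Sequence[VariantCall], mask: Mapping[str, IntervalTree]
) -> tuple[list[VariantCall], int]:
    """Drop calls intersecting masked regions (e.g. highly polymorphic or
    hard-to-survey loci excluded from analysis).

    Returns the retained calls and the number removed.  Intersection uses
    the call's 0-based half-open span against the BED intervals.
    """
    kept: list[VariantCall] = []
    removed = 0
    for call in calls:
        tree = mask.get(call.chrom)
        start, end = call.span
        if tree is not None and tree.overlap(start, end):
            removed += 1
        else:
            kept.append(call)
    return kept, removed


def _read_allele_rows(path: str | Path) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        sample = fh.read()
    delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
    for row in csv.reader(sample.splitlines(), delimiter=delimiter):
        if not row or row[0].startswith("#") or row[0].lower() in ("chrom", "chr"):
            continue
        rows.append(row)
    return rows


def _row_key(row: Sequence[str], path, idx: int) -> VariantKey:
    if len(row) < 4:
        raise VariantIOError(f"{path}: row {idx}: need chrom,pos,ref,alt")
    pos, ref, alt = normalize_allele(int(row[1]), row[2], row[3])
    return (row[0], pos, ref, alt)


def read_inclusion_lists(
    known_pathogenic: str | Path | None = None,
    splice_flagged: str | Path | None = None,
    hypomorphic: str | Path | None = None,
) -> InclusionLists:
    """Load inclusion-list files (tab- or comma-separated allele rows).

    Alleles are normalised with the same rule as the callset reader.  The
    splice file carries a delta score in its 5th column; scores outside
    [0,1] raise :class:`VariantIOError`.
    """
    lists = InclusionLists()
    if known_pathogenic:
        for i, row in enumerate(_read_allele_rows(known_pathogenic), start=1):
            lists.known_pathogenic.add(_row_key(row, known_pathogenic, i))
    if hypomorphic:
        for i, row in enumerate(_read_allele_rows(hypomorphic), start=1):
            lists.hypomorphic.add(_row_key(row, hypomorphic, i))
    if splice_flagged:
        for i, row in enumerate(_read_allele_rows(splice_flagged), start=1):
            if len(row) < 5:
                raise VariantIOError(
                    f"{splice_flagged}: row {i}: splice rows need a score column"
                )
            delta = float(row[4])
            if not (0.0 <= delta <= 1.0):
                raise VariantIOError(
                    f"{splice_flagged}: row {i}: delta {delta} outside [0,1]"
                )
            lists.splice_flagged[_row_key(row, splice_flagged, i)] = delta
    return lists
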