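"""Variant input parsing, allele resolution and the association p-value prefilter.

Four input dialects are accepted and unified into :class:`Variant` records:

``plink_like``
    Whitespace-delimited columns ``ID CHROM POS P`` with an optional header.
    Alleles are filled in later from a :class:`VariantCatalog`.
``vcf_like``
    The first five VCF columns ``CHROM POS ID REF ALT`` (header lines
    starting with ``#`` are skipped).  Ref/alt are taken verbatim and such
    records survive even when absent from every catalogue.
``rsid``
    One variant identifier per line; position and alleles come from the
    catalogue.
``chrom_pos``
    One ``chrom:pos`` locus per line; alleles come from the catalogue.

Coordinates are 1-based inclusive (VCF convention) in :class:`Variant`;
conversion to 0-based half-open for interval work happens in exactly one
place, :func:`point_0based`.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import CatalogConsistencyError, InputFormatError, ValidationError

log = logging.getLogger(__name__)

_VALID_FORMATS = ("plink_like", "vcf_like", "rsid", "chrom_pos")
_ALLELE_RE = re.compile(r"^[ACGTN]+$")
_PLAIN_CHROM_RE = re.compile(r"^(\d+|X|Y)$", re.IGNORECASE)
_CHROM_POS_RE = re.compile(r"^(\S+):(\d+)$")


def normalize_chrom(name: str) -> str:
    """Normalize plain autosome/X/Y names to ``chrN``; pass others verbatim."""
    name = name.strip()
    if _PLAIN_CHROM_RE.match(name):
        return "chr" + name.upper()
    return name


def point_0based(pos: int) -> int:
    """The single 1-based -> 0-based conversion used for interval queries."""
    return pos - 1


@dataclass
class Variant:
    """One genomic variant with a reference and alternative allele set.

    ``pos`` is 1-based (VCF convention).  ``ref_allele``/``alt_alleles`` may
    be empty for ``rsid``/``chrom_pos``/``plink_like`` inputs until
    :func:`resolve_alleles` fills them from a catalogue.
    """

    chrom: str = ""
    pos: int = 0
    id: str = ""
    ref_allele: str = ""
    alt_alleles: tuple[str, ...] = ()
    gwas_p: float | None = None
    source_format: str = "vcf_like"

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom) if self.chrom else ""
        self.ref_allele = self.ref_allele.upper()
        self.alt_alleles = tuple(a.upper() for a in self.alt_alleles)
        if self.pos and self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        for a in (self.ref_allele, *self.alt_alleles):
            if a and not _ALLELE_RE.match(a):
                raise ValidationError(f"invalid allele {a!r}")
        if self.ref_allele and self.ref_allele in self.alt_alleles:
            raise ValidationError(
                f"alt allele equals ref allele for {self.key}: {self.ref_allele}"
            )
        if self.gwas_p is not None and not (0.0 < self.gwas_p <= 1.0):
            raise ValidationError(f"gwas_p must lie in (0,1], got {self.gwas_p}")
        if self.source_format not in _VALID_FORMATS:
            raise ValidationError(f"unknown source format {self.source_format!r}")

    @property
    def key(self) -> str:
        """Stable key: the rs identifier when known, else ``chrom:pos``."""
        return self.id if self.id else f"{self.chrom}:{self.pos}"

    @property
    def has_alleles(self) -> bool:
        return bool(self.ref_allele) and bool(self.alt_alleles)


@dataclass
class ParseReport:
    parsed: int = 0
    skipped: int = 0
    rejected_lines: list[str] = field(default_factory=list)

    def reject(self, line: str) -> None:
        self.skipped += 1
        if len(self.rejected_lines) < 10:
            self.rejected_lines.append(line)


class VariantCatalog:
    """Allele catalogue keyed both by identifier and by coordinate.

    Mimics a dbSNP/1000G allele table: TSV columns
    ``ID CHROM POS REF ALTS`` with alts comma-separated.  Lookup by id and by
    (chrom, pos) return the same record; conflicting duplicates are fatal.
    """

    def __init__(self, name: str = "catalog") -> None:
        self.name = name
        self._by_id: dict[str, Variant] = {}
        self._by_coord: dict[tuple[str, int], Variant] = {}

    def __len__(self) -> int:
        return len(self.variants())

    def variants(self) -> list[Variant]:
        """All unique records, position-sorted."""
        seen: dict[tuple, Variant] = {}
        for v in (*self._by_id.values(), *self._by_coord.values()):
            seen.setdefault((v.chrom, v.pos, v.ref_allele, v.alt_alleles), v)
        return sorted(seen.values(), key=lambda v: (v.chrom, v.pos, v.id))

    def add(self, record: Variant) -> None:
        if not record.has_alleles or not record.chrom or not record.pos:
            raise ValidationError("catalogue records need coordinates and alleles")
        sig = (record.chrom, record.pos, record.ref_allele, record.alt_alleles)
        if record.id:
            prev = self._by_id.get(record.id)
            if prev is not None:
                if (prev.chrom, prev.pos, prev.ref_allele, prev.alt_alleles) != sig:
                    raise CatalogConsistencyError(
                        f"conflicting catalogue records for id {record.id}"
                    )
                return
            self._by_id[record.id] = record
        coord = (record.chrom, record.pos)
        prev = self._by_coord.get(coord)
        if prev is not None and (
            prev.ref_allele != record.ref_allele
            or prev.alt_alleles != record.alt_alleles
        ):
            raise CatalogConsistencyError(
                f"conflicting catalogue records at {coord[0]}:{coord[1]}"
            )
        self._by_coord[coord] = record

    def lookup(self, variant: Variant) -> Variant | None:
        if variant.id and variant.id in self._by_id:
            return self._by_id[variant.id]
        if variant.chrom and variant.pos:
            return self._by_coord.get((variant.chrom, variant.pos))
        return None

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "VariantCatalog":
        path = Path(path)
        cat = cls(name or path.stem)
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 5:
                    continue
                vid, chrom, pos, ref, alts = parts[:5]
                if not pos.isdigit():
                    continue  # header
                cat.add(
                    Variant(
                        chrom=chrom,
                        pos=int(pos),
                        id=vid if vid != "." else "",
                        ref_allele=ref,
                        alt_alleles=tuple(alts.split(",")),
                    )
                )
        return cat

    def to_tsv(self, path: str | Path) -> None:
        records = self.variants()
        with open(path, "w") as fh:
            fh.write("#ID\tCHROM\tPOS\tREF\tALTS\n")
            for v in records:
                fh.write(
                    f"{v.id or '.'}\t{v.chrom}\t{v.pos}\t{v.ref_allele}\t"
                    f"{','.join(v.alt_alleles)}\n"
                )


def _parse_p(token: str) -> float | None:
    try:
        p = float(token)
    except ValueError:
        return None
    if not (0.0 < p <= 1.0) or math.isnan(p):
        return None
    return p


def _parse_plink_line(parts: list[str]) -> Variant | None:
    if len(parts) < 3 or not parts[2].isdigit():
        return None
    gwas_p = _parse_p(parts[3]) if len(parts) >= 4 else None
    if len(parts) >= 4 and gwas_p is None and parts[3].upper() not in ("NA", "."):
        return None
    return Variant(
        chrom=parts[1], pos=int(parts[2]), id=parts[0],
        gwas_p=gwas_p, source_format="plink_like",
    )


def _parse_vcf_line(parts: list[str]) -> Variant | None:
    if len(parts) < 5 or not parts[1].isdigit():
        return None
    chrom, pos, vid, ref, alt = parts[:5]
    alts = tuple(a for a in alt.split(",") if a and a != ".")
    if not alts or not _ALLELE_RE.match(ref.upper()):
        return None
    if any(not _ALLELE_RE.match(a.upper()) for a in alts):
        return None
    if ref.upper() in (a.upper() for a in alts):
        return None
    return Variant(
        chrom=chrom, pos=int(pos), id=vid if vid != "." else "",
        ref_allele=ref, alt_alleles=alts, source_format="vcf_like",
    )


def _parse_rsid_line(parts: list[str]) -> Variant | None:
    if len(parts) != 1 or ":" in parts[0]:
        return None
    return Variant(id=parts[0], source_format="rsid")


def _parse_chrom_pos_line(parts: list[str]) -> Variant | None:
    if len(parts) != 1:
        return None
    m = _CHROM_POS_RE.match(parts[0])
    if not m:
        return None
    return Variant(chrom=m.group(1), pos=int(m.group(2)), source_format="chrom_pos")


_LINE_PARSERS = {
    "plink_like": _parse_plink_line,
    "vcf_like": _parse_vcf_line,
    "rsid": _parse_rsid_line,
    "chrom_pos": _parse_chrom_pos_line,
}


def sniff_format(path: str | Path) -> str:
    """Guess the input dialect from the first data line."""
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            # most-specific first: vcf (5 cols with alleles), plink, then lists
            for fmt in ("vcf_like", "plink_like", "chrom_pos", "rsid"):
                if _LINE_PARSERS[fmt](parts) is not None:
                    return fmt
    raise InputFormatError(f"could not sniff variant format of {path}")


def parse_variants(
    path: str | Path, format: str = "auto"
) -> tuple[list[Variant], ParseReport]:
    """Parse a variant file into :class:`Variant` records.

    Malformed lines are skipped and counted in the returned
    :class:`ParseReport`; a file with zero parsable lines is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"variant file not found: {path}")
    if format == "auto":
        format = sniff_format(path)
    if format not in _VALID_FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_VALID_FORMATS}")
    parser = _LINE_PARSERS[format]
    variants: list[Variant] = []
    report = ParseReport()
    header_skipped = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = parser(line.split())
            except ValidationError:
                v = None
            if v is None:
                # tolerate one leading header row in column formats
                if not header_skipped and not variants and format in (
                    "plink_like", "vcf_like",
                ):
                    header_skipped = True
                    continue
                report.reject(line)
                continue
            variants.append(v)
            report.parsed += 1
    if not variants:
        first = report.rejected_lines[0] if report.rejected_lines else "<empty file>"
        raise InputFormatError(
            f"no parsable {format} lines in {path}; first rejected line: {first!r}"
        )
    if report.skipped:
        log.warning("%s: skipped %d malformed lines", path, report.skipped)
    return variants, report


def resolve_alleles(
    variants: list[Variant], catalogs: VariantCatalog | list[VariantCatalog]
) -> tuple[list[Variant], list[Variant]]:
    """Fill coordinates/alleles from the first catalogue containing each variant.

    VCF-like records pass through untouched.  Records found in no catalogue
    are returned in ``dropped`` (they cannot be affinity-scored).  The
    operation is idempotent.
    """
    if isinstance(catalogs, VariantCatalog):
        catalogs = [catalogs]
    resolved: list[Variant] = []
    dropped: list[Variant] = []
    for v in variants:
        if v.source_format == "vcf_like":
            resolved.append(v)
            continue
        hit = next((c.lookup(v) for c in catalogs if c.lookup(v) is not None), None)
        if hit is None:
            dropped.append(v)
            continue
        resolved.append(
            replace(
                v,
                chrom=hit.chrom,
                pos=hit.pos,
                id=v.id or hit.id,
                ref_allele=hit.ref_allele,
                alt_alleles=hit.alt_alleles,
            )
        )
    if dropped:
        log.info("dropped %d variants absent from all catalogues", len(dropped))
    return resolved, dropped


def filter_by_pvalue(
    variants: list[Variant], cutoff: float, no_gwas_mode: bool = False
) -> list[Variant]:
    """Keep variants with ``gwas_p <= cutoff``.

    Variants without a p-value survive only in no-GWAS mode (bare variant
    lists, where the association dimension is excluded downstream).
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"p-value cutoff must lie in (0,1], got {cutoff}")
    kept = [
        v
        for v in variants
        if (v.gwas_p is not None and v.gwas_p <= cutoff)
        or (v.gwas_p is None and no_gwas_mode)
    ]
    if variants and not kept:
        log.warning("p-value cutoff %g removed all %d variants", cutoff, len(variants))
    return kept


def write_variants_tsv(variants: list[Variant], path: str | Path) -> None:
    """Write the canonical internal variant TSV (round-trips losslessly)."""
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tID\tREF\tALTS\tP\tSOURCE\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.chrom or ".",
                        str(v.pos),
                        v.id or ".",
                        v.ref_allele or ".",
                        ",".join(v.alt_alleles) or ".",
                        repr(v.gwas_p) if v.gwas_p is not None else "NA",
                        v.source_format,
                    ]
                )
                + "\n"
            )


def read_variants_tsv(path: str | Path) -> list[Variant]:
    variants = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, vid, ref, alts, p, source = line.split("\t")
            variants.append(
                Variant(
                    chrom="" if chrom == "." else chrom,
                    pos=int(pos),
                    id="" if vid == "." else vid,
                    ref_allele="" if ref == "." else ref,
                    alt_alleles=() if alts == "." else tuple(alts.split(",")),
                    gwas_p=None if p == "NA" else float(p),
                    source_format=source,
                )
            )
    return variants
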