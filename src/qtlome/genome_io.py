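"""Readers and writers for the external formats of a QTL-catalog analysis.

All coordinates are held internally as 0-based half-open intervals
(``length == end - start``), the BED convention.  GFF input/output converts
from/to the format's 1-based inclusive convention at this boundary and
nowhere else.

Supported inputs:

* chromosome-size tables (two-column TSV: name, length in bp);
* QTL annotations in the AnimalQTLdb GFF dialect — one 9-column feature
  per QTL with trait/study metadata in the attributes column;
* gene annotations in GFF3 or BED;
* SNP position tables (two-column TSV or BED);
* gene-of-interest lists (one symbol per line, or BED intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger("qtlome")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome names and lengths defining the coordinate space."""

    species_label: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise FormatError("duplicate chromosome name in assembly")
        for name, length in self.chromosomes:
            if length <= 0:
                raise FormatError(f"non-positive length for chromosome {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return any(name == chrom for name, _ in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)


@dataclass(frozen=True)
class QTLRecord:
    """One QTL annotation: an interval plus trait and study provenance.

    ``start``/``end`` are ``None`` when the source line carried no
    coordinates; such records are kept and flagged so the QC stage can
    account for them rather than dropping them silently.
    """

    chrom: str
    start: Optional[int]
    end: Optional[int]
    qtl_id: str
    trait_name: str
    trait_type: str = ""
    trait_class: str = ""
    study_id: str = ""
    gene_symbol: str = ""
    source_line: int = -1
    extra: tuple[tuple[str, str], ...] = ()

    @property
    def has_coordinates(self) -> bool:
        return self.start is not None and self.end is not None

    @property
    def length(self) -> int:
        if not self.has_coordinates:
            raise ValueError(f"QTL {self.qtl_id!r} has no coordinates")
        return self.end - self.start  # type: ignore[operator]

    @property
    def midpoint(self) -> int:
        if not self.has_coordinates:
            raise ValueError(f"QTL {self.qtl_id!r} has no coordinates")
        return (self.start + self.end) // 2  # type: ignore[operator]

    def resolvable(self, assembly: GenomeAssembly) -> bool:
        return self.chrom in assembly

    def with_interval(self, start: int, end: int) -> "QTLRecord":
        return replace(self, start=start, end=end)


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int
    end: int
    gene_id: str
    symbol: str = ""
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene_id!r}: end <= start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneSet:
    """A labelled list of genes of interest (e.g. major or candidate genes)."""

    label: str
    members: tuple[GeneRecord, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.label!r} is empty")

    def intervals(self) -> list[tuple[str, int, int]]:
        return [(g.chrom, g.start, g.end) for g in self.members]


@dataclass
class GffParseReport:
    """Bookkeeping for one GFF parse: line counts, not record content."""

    n_lines: int = 0
    n_records: int = 0
    n_malformed: int = 0
    malformed_lines: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Attribute-key mapping for the AnimalQTLdb GFF dialect
# ---------------------------------------------------------------------------

#: Which GFF attribute keys feed each QTLRecord field.  Several candidate
#: keys per field; the first one present on a line wins.  The source dialect
#: is not formally documented, so this map is configurable (CLI: --attr-map).
DEFAULT_ATTR_MAP: dict[str, tuple[str, ...]] = {
    "qtl_id": ("QTL_ID", "ID"),
    "trait_name": ("trait", "Name"),
    "trait_type": ("trait_type", "Trait_type"),
    "trait_class": ("trait_class", "Class", "VTO_name"),
    "study_id": ("PUBMED_ID", "pubmed_id", "study"),
    "gene_symbol": ("gene_ID", "gene_id", "Gene"),
}


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, value = chunk.split("=", 1)
        else:
            key, value = chunk, ""
        out[key.strip()] = value.strip().strip('"')
    return out


def _format_attributes(pairs: Iterable[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_assembly(path: str | Path, species_label: str = "") -> GenomeAssembly:
    """Read a two-column TSV of chromosome name and length (bp)."""
    path = Path(path)
    chroms: list[tuple[str, int]] = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{i}: expected 'name<TAB>length'")
        try:
            length = int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: length is not an integer") from exc
        chroms.append((parts[0], length))
    if not chroms:
        raise FormatError(f"{path}: no chromosomes found")
    return GenomeAssembly(species_label or path.stem, tuple(chroms))


def _coord(value: str) -> Optional[int]:
    value = value.strip()
    if value in ("", "."):
        return None
    return int(float(value))  # some dumps carry '1.2e+07'-style coordinates


def parse_qtl_gff(
    path: str | Path,
    attr_map: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[QTLRecord], GffParseReport]:
    """Parse an AnimalQTLdb-dialect GFF file into QTL records.

    Lines with fewer than 9 columns are counted as malformed, not fatal.
    Missing coordinates ('.') are kept as ``None`` for QC to account for.
    1-based inclusive file coordinates become 0-based half-open.
    """
    path = Path(path)
    amap = {**DEFAULT_ATTR_MAP, **(dict(attr_map) if attr_map else {})}
    mapped_keys = {k for keys in amap.values() for k in keys}
    records: list[QTLRecord] = []
    report = GffParseReport()
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            report.n_lines += 1
            cols = line.split("\t")
            if len(cols) < 9:
                report.n_malformed += 1
                report.malformed_lines.append(lineno)
                continue
            chrom = cols[0].strip()
            start1 = _coord(cols[3])
            end1 = _coord(cols[4])
            attrs = _parse_attributes(cols[8])

            def pick(field_name: str) -> str:
                for key in amap[field_name]:
                    if key in attrs:
                        return attrs[key]
                return ""

            extra = tuple(
                (k, v) for k, v in sorted(attrs.items()) if k not in mapped_keys
            )
            records.append(
                QTLRecord(
                    chrom=chrom,
                    start=None if start1 is None else start1 - 1,
                    end=end1,
                    qtl_id=pick("qtl_id") or f"QTL_{lineno}",
                    trait_name=pick("trait_name"),
                    trait_type=pick("trait_type"),
                    trait_class=pick("trait_class"),
                    study_id=pick("study_id"),
                    gene_symbol=pick("gene_symbol"),
                    source_line=lineno,
                    extra=extra,
                )
            )
            report.n_records += 1
    if report.n_malformed:
        logger.warning(
            "%s: %d malformed line(s) skipped", path, report.n_malformed
        )
    return records, report


def read_qtl_gff(
    path: str | Path,
    assembly: GenomeAssembly | None = None,
    attr_map: Mapping[str, Sequence[str]] | None = None,
) -> list[QTLRecord]:
    records, _ = parse_qtl_gff(path, attr_map)
    if assembly is not None:
        n_bad = sum(1 for r in records if not r.resolvable(assembly))
        if n_bad:
            logger.warning(
                "%s: %d record(s) on chromosomes absent from the assembly "
                "(flagged for QC)", path, n_bad,
            )
    return records


def _sniff_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return "bed"
    if suffix in (".gff", ".gff3", ".gtf"):
        return "gff3"
    raise FormatError(f"{path}: unrecognized extension; pass fmt='bed' or 'gff3'")


def read_genes(
    path: str | Path,
    assembly: GenomeAssembly | None = None,
    fmt: Optional[str] = None,
    feature_type: str = "gene",
) -> list[GeneRecord]:
    """Read gene annotations from GFF3 (filtered to ``feature_type``) or BED."""
    path = Path(path)
    kind = _sniff_format(path, fmt)
    genes: list[GeneRecord] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if kind == "bed":
                if len(cols) < 3:
                    raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
                name = cols[3] if len(cols) > 3 else f"gene_{lineno}"
                genes.append(
                    GeneRecord(cols[0], int(cols[1]), int(cols[2]), name, name)
                )
            else:
                if len(cols) < 9:
                    raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
                if cols[2] != feature_type:
                    continue
                attrs = _parse_attributes(cols[8])
                gene_id = attrs.get("ID", f"gene_{lineno}")
                if gene_id.startswith("gene:"):
                    gene_id = gene_id[5:]
                genes.append(
                    GeneRecord(
                        chrom=cols[0],
                        start=int(cols[3]) - 1,
                        end=int(cols[4]),
                        gene_id=gene_id,
                        symbol=attrs.get("Name", ""),
                        biotype=attrs.get("biotype", ""),
                    )
                )
    if not genes:
        logger.warning("%s: no %r features found", path, feature_type)
    if assembly is not None:
        unknown = {g.chrom for g in genes} - set(assembly.names)
        if unknown:
            logger.warning("%s: genes on unknown chromosomes %s", path, unknown)
    return genes


def read_snps(path: str | Path, fmt: Optional[str] = None) -> list[tuple[str, int]]:
    """Read SNP positions from a two-column TSV (chrom, 0-based pos) or BED."""
    path = Path(path)
    kind = "bed" if (fmt == "bed" or path.suffix.lower() == ".bed") else "tsv"
    out: list[tuple[str, int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 2:
            raise FormatError(f"{path}:{lineno}: expected chrom and position")
        out.append((cols[0], int(cols[1])))
    return out


def read_gene_set(
    path: str | Path,
    genes: Sequence[GeneRecord] | None = None,
    label: str | None = None,
    fmt: Optional[str] = None,
) -> GeneSet:
    """Read a gene-of-interest set from a symbol list (TSV) or BED intervals.

    Symbol lists are resolved against ``genes``; unresolved symbols are
    logged and dropped.
    """
    path = Path(path)
    label = label or path.stem
    kind = "bed" if (fmt == "bed" or path.suffix.lower() == ".bed") else "symbols"
    if kind == "bed":
        members = tuple(read_genes(path, fmt="bed"))
        return GeneSet(label, members)
    if genes is None:
        raise FormatError("a gene annotation is required to resolve symbols")
    by_symbol: dict[str, GeneRecord] = {}
    for g in genes:
        by_symbol.setdefault(g.symbol, g)
        by_symbol.setdefault(g.gene_id, g)
    members: list[GeneRecord] = []
    missing: list[str] = []
    for line in path.read_text().splitlines():
        symbol = line.split("\t")[0].strip()
        if not symbol or symbol.startswith("#"):
            continue
        if symbol in by_symbol:
            members.append(by_symbol[symbol])
        else:
            missing.append(symbol)
    if missing:
        logger.warning("%s: %d symbol(s) not in the gene annotation", path, len(missing))
    return GeneSet(label, tuple(members))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_TSV_HEADER = (
    "chrom\tstart\tend\tqtl_id\ttrait_name\ttrait_type\ttrait_class"
    "\tstudy_id\tgene_symbol\tsource_line\textra"
)


def write_qtl_tsv(records: Iterable[QTLRecord], path: str | Path) -> None:
    """Write records to the internal TSV; round-trips field-for-field."""
    lines = [_TSV_HEADER]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    "." if r.start is None else str(r.start),
                    "." if r.end is None else str(r.end),
                    r.qtl_id,
                    r.trait_name,
                    r.trait_type,
                    r.trait_class,
                    r.study_id,
                    r.gene_symbol,
                    str(r.source_line),
                    _format_attributes(r.extra),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_qtl_tsv(path: str | Path) -> list[QTLRecord]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _TSV_HEADER:
        raise FormatError(f"{path}: not an internal QTL TSV")
    records = []
    for line in lines[1:]:
        if not line:
            continue
        c = line.split("\t")
        extra = tuple(sorted(_parse_attributes(c[10]).items())) if len(c) > 10 and c[10] else ()
        records.append(
            QTLRecord(
                chrom=c[0],
                start=None if c[1] == "." else int(c[1]),
                end=None if c[2] == "." else int(c[2]),
                qtl_id=c[3],
                trait_name=c[4],
                trait_type=c[5],
                trait_class=c[6],
                study_id=c[7],
                gene_symbol=c[8],
                source_line=int(c[9]),
                extra=extra,
            )
        )
    return records


def write_qtl_gff(records: Iterable[QTLRecord], path: str | Path) -> None:
    """Export records as AnimalQTLdb-dialect GFF (1-based inclusive)."""
    lines = ["##gff-version 2"]
    for r in records:
        attrs: list[tuple[str, str]] = [("QTL_ID", r.qtl_id), ("trait", r.trait_name)]
        if r.trait_type:
            attrs.append(("trait_type", r.trait_type))
        if r.trait_class:
            attrs.append(("trait_class", r.trait_class))
        if r.study_id:
            attrs.append(("PUBMED_ID", r.study_id))
        if r.gene_symbol:
            attrs.append(("gene_ID", r.gene_symbol))
        attrs.extend(r.extra)
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    "AnimalQTLdb",
                    "QTL",
                    "." if r.start is None else str(r.start + 1),
                    "." if r.end is None else str(r.end),
                    ".",
                    ".",
                    ".",
                    _format_attributes(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_assembly(assembly: GenomeAssembly, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{name}\t{length}\n" for name, length in assembly.chromosomes)
    )


def write_genes_gff3(genes: Iterable[GeneRecord], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID=gene:{g.gene_id};Name={g.symbol};biotype={g.biotype}"
        lines.append(
            f"{g.chrom}\tqtlome\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
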