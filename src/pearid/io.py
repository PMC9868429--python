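"""Readers and writers for genotype tables, clustering-run summaries and histograms.

All formats are plain delimited text:

* genotype tables — one row per accession, columns ``accession_id, name,
  province`` followed by one column per locus holding slash-separated allele
  sizes (``"134/138"``, ``"134/138/142"``, empty cell = missing);
* clustering-run tables — columns ``K, replicate, lnP``;
* histograms — columns ``channel, count``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import (
    AlleleSet,
    Accession,
    GermplasmTable,
    Histogram,
    ModelError,
    StructureRun,
    StructureRunTable,
    allele_set,
)

logger = logging.getLogger(__name__)

META_COLUMNS = ("accession_id", "name", "province")


class ParseError(ValueError):
    """Malformed input with row/column coordinates."""


@dataclass
class ReadReport:
    """Record of accessions dropped and cells coerced during parsing."""

    dropped: list[tuple[str, str]] = field(default_factory=list)
    coerced_cells: list[tuple[str, str, str]] = field(default_factory=list)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def parse_allele_token(
    token: str, locus_id: str, *, max_alleles: int = 3, bin_width: int = 0
) -> AlleleSet:
    """Parse a slash-separated allele-size cell into an :class:`AlleleSet`.

    Fractional sizes are rounded half-up; with ``bin_width > 0`` sizes are
    snapped to the nearest multiple of the bin width.  More than
    ``max_alleles`` distinct sizes is a parse error.
    """
    token = token.strip()
    if not token:
        return AlleleSet(locus_id)
    sizes: list[int] = []
    for part in token.split("/"):
        part = part.strip()
        if not part:
            raise ParseError(f"empty allele in token {token!r}")
        try:
            val = float(part)
        except ValueError as exc:
            raise ParseError(f"unparseable allele {part!r} in token {token!r}") from exc
        size = _round_half_up(val)
        if bin_width > 0:
            size = _round_half_up(size / bin_width) * bin_width
        if size <= 0:
            raise ParseError(f"non-positive allele size {part!r}")
        sizes.append(size)
    distinct = sorted(set(sizes))
    if len(distinct) > max_alleles:
        raise ParseError(
            f"{len(distinct)} distinct alleles in token {token!r} exceeds max {max_alleles}"
        )
    return AlleleSet(locus_id, tuple(distinct))


def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_genotype_table(
    path: str | Path,
    *,
    delimiter: str | None = None,
    max_alleles: int = 3,
    bin_width: int = 0,
    max_missing_frac: float = 0.5,
    strict: bool = True,
    report: ReadReport | None = None,
) -> GermplasmTable:
    """Read a wide-format genotype table.

    Accessions whose fraction of missing loci exceeds ``max_missing_frac``
    after parsing are dropped with a logged reason.  With ``strict=True`` a
    malformed allele token raises :class:`ParseError` carrying row/column
    coordinates; otherwise the cell is coerced to missing and recorded.
    Duplicate accession ids are always fatal.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    if not text:
        raise ParseError(f"{path}: empty file")
    delim = delimiter or _detect_delimiter(text[0])
    rows = list(csv.reader(text, delimiter=delim))
    header = [h.strip() for h in rows[0]]
    if len(header) < 4:
        raise ParseError(f"{path}: expected id,name,province plus >=1 locus column")
    loci = header[3:]
    if report is None:
        report = ReadReport()

    accessions: list[Accession] = []
    for i, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) != len(header):
            raise ParseError(f"{path}:{i}: expected {len(header)} fields, got {len(row)}")
        acc_id, name, province = (c.strip() for c in row[:3])
        genotype: dict[str, AlleleSet] = {}
        for locus, cell in zip(loci, row[3:]):
            try:
                genotype[locus] = parse_allele_token(
                    cell, locus, max_alleles=max_alleles, bin_width=bin_width
                )
            except ParseError as exc:
                if strict:
                    raise ParseError(f"{path}:{i}: column {locus!r}: {exc}") from exc
                logger.warning("%s:%d: column %s coerced to missing (%s)", path, i, locus, exc)
                report.coerced_cells.append((acc_id, locus, str(exc)))
                genotype[locus] = AlleleSet(locus)
        acc = Accession(acc_id, name, province, genotype)
        frac_missing = acc.n_missing(loci) / len(loci)
        if frac_missing > max_missing_frac:
            logger.info(
                "dropping accession %s: %.0f%% of loci missing", acc_id, 100 * frac_missing
            )
            report.dropped.append((acc_id, f"{frac_missing:.2f} missing"))
            continue
        accessions.append(acc)
    return GermplasmTable(loci=loci, accessions=accessions)


def write_genotype_table(
    table: GermplasmTable, path: str | Path, *, delimiter: str = ","
) -> None:
    """Write a table in the canonical wide format (UTF-8, ``/``-separated alleles)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(list(META_COLUMNS) + list(table.loci))
        for acc in table.accessions:
            writer.writerow(
                [acc.accession_id, acc.raw_name, acc.province]
                + [str(acc.allele_set(l)) for l in table.loci]
            )


def write_genalex(table: GermplasmTable, path: str | Path) -> None:
    """Export in a GenAlEx-style codominant layout (three columns per locus).

    Missing alleles are padded with 0; homozygous diploids repeat the single
    allele in the first two columns.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow([len(table.loci), table.n, 1, table.n])
        header = ["Sample", "Pop"]
        for l in table.loci:
            header += [l, "", ""]
        writer.writerow(header)
        for acc in table.accessions:
            row: list[str | int] = [acc.accession_id, acc.province]
            for l in table.loci:
                a = list(acc.allele_set(l).alleles)
                if len(a) == 1:
                    a = [a[0], a[0]]
                a = (a + [0, 0, 0])[:3]
                row += a
            writer.writerow(row)


def read_structure_runs(path: str | Path, *, delimiter: str | None = None) -> StructureRunTable:
    """Read a clustering-run table with columns K, replicate, lnP (any case)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    if not text:
        raise ParseError(f"{path}: empty file")
    delim = delimiter or _detect_delimiter(text[0])
    rows = list(csv.reader(text, delimiter=delim))
    header = [h.strip().lower() for h in rows[0]]
    try:
        ki = header.index("k")
        ri = next(i for i, h in enumerate(header) if h in ("replicate", "rep", "run"))
        li = next(i for i, h in enumerate(header) if h in ("lnp", "ln_p", "lnprob", "ln(p)"))
    except (ValueError, StopIteration) as exc:
        raise ParseError(f"{path}: need K, replicate and lnP columns, got {header}") from exc
    records: list[StructureRun] = []
    for i, row in enumerate(rows[1:], start=2):
        if not any(c.strip() for c in row):
            continue
        try:
            records.append(
                StructureRun(int(row[ki]), int(row[ri]), float(row[li]))
            )
        except (ValueError, IndexError, ModelError):
            logger.warning("%s:%d: record rejected (malformed K/replicate/lnP)", path, i)
    return StructureRunTable(records)


def write_structure_runs(runs: StructureRunTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["K", "replicate", "lnP"])
        for r in sorted(runs.records, key=lambda r: (r.k, r.replicate)):
            writer.writerow([r.k, r.replicate, repr(r.ln_p)])


def read_histogram(path: str | Path, *, delimiter: str | None = None) -> Histogram:
    """Read a two-column channel/count histogram; channels must be ascending."""
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    if not text:
        raise ParseError(f"{path}: empty file")
    delim = delimiter or _detect_delimiter(text[0])
    rows = list(csv.reader(text, delimiter=delim))
    start = 0
    try:
        float(rows[0][0])
    except (ValueError, IndexError):
        start = 1  # header row
    channels: list[float] = []
    counts: list[float] = []
    for i, row in enumerate(rows[start:], start=start + 1):
        if not any(c.strip() for c in row):
            continue
        try:
            channels.append(float(row[0]))
            counts.append(float(row[1]))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{i}: malformed channel/count row") from exc
    try:
        return Histogram(np.asarray(channels), np.asarray(counts))
    except ModelError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_histogram(hist: Histogram, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["channel", "count"])
        for c, n in zip(hist.channels, hist.counts):
            writer.writerow([repr(float(c)), repr(float(n))])
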