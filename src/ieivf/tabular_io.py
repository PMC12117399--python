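"""Read and write annotated-variant tables and gene lists.

The table layout (shared by the ``.xlsx`` and tab-separated dialects) is:

    Gene Symbol | Gene Id | Chr | Position | Ref | Var |
    <sample id> | Depth | Var/Depth | ... one triplet per sample ... |
    Variant Effect | Existing Variation

The sample-triplet header cell carries the sample identifier; the data cells
in that column may carry the caller's genotype label (``P_Homo_var`` style) or
be empty.  ``Existing Variation`` holds a dbSNP id; an empty cell and the
literal ``Null`` both mean "none" and are always written back as empty.
Chromosome labels are kept verbatim ("chr6" and "6" are different strings and
never reconciled — mismatches are logged, not fixed).

Written filtered tables repeat the input layout and append three columns,
``WHITELIST_HIT``, ``COMPOUND_HET`` and ``REMOVAL_REASONS``; the reader
recognizes and restores them, so the TSV dialect round-trips exactly.  The
spreadsheet dialect additionally fills white-list rows green and
compound-heterozygote rows pink.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import AssemblyMismatchError, RowParseError, SchemaError
from .genotype_model import (
    Assembly,
    Role,
    SampleObservation,
    VariantKey,
    VariantRecord,
)

log = logging.getLogger(__name__)

FIXED_LEFT = ("Gene Symbol", "Gene Id", "Chr", "Position", "Ref", "Var")
FIXED_RIGHT = ("Variant Effect", "Existing Variation")
FLAG_COLUMNS = ("WHITELIST_HIT", "COMPOUND_HET", "REMOVAL_REASONS")

GREEN_FILL = "C6EFCE"  # white-list hit
PINK_FILL = "FFC7CE"  # compound heterozygote


class Dialect(str, Enum):
    TSV = "tsv"
    SPREADSHEET = "xlsx"


class Polarity(str, Enum):
    WHITE = "white"
    BLACK = "black"


@dataclass
class SampleRoster:
    """Ordered sample -> role assignment plus the shared assembly tag."""

    samples: list[tuple[str, Role]]
    assembly: Assembly

    def __post_init__(self):
        ids = [s for s, _ in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise SchemaError(f"duplicate sample ids in roster: {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    def role_of(self, sample_id: str) -> Optional[Role]:
        for s, r in self.samples:
            if s == sample_id:
                return r
        return None

    def ids_with_role(self, role: Role) -> list[str]:
        return [s for s, r in self.samples if r == role]

    @property
    def n_patients(self) -> int:
        return len(self.ids_with_role(Role.PATIENT))

    @property
    def n_controls(self) -> int:
        return len(self.ids_with_role(Role.CONTROL))

    @property
    def n_parents(self) -> int:
        return len(self.ids_with_role(Role.PARENT))


@dataclass(frozen=True)
class GeneList:
    """Named gene set with polarity (white = keep/flag, black = remove).

    A gene matches the list when its symbol matches case-insensitively OR,
    when HGNC ids are present, its numeric id matches.  Symbols are stored
    uppercase.
    """

    name: str
    polarity: Polarity
    symbols: frozenset[str]
    hgnc_ids: Optional[frozenset[int]] = None

    def __post_init__(self):
        if not self.symbols:
            raise SchemaError(f"gene list {self.name!r} is empty")

    def contains(self, symbol: str, gene_id: Optional[int] = None) -> bool:
        if symbol.strip().upper() in self.symbols:
            return True
        return bool(self.hgnc_ids) and gene_id is not None and gene_id in self.hgnc_ids

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# table reading


def _raw_rows(path: Path) -> list[list]:
    if path.suffix.lower() == ".xlsx":
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
        try:
            ws = wb.active
            return [list(row) for row in ws.iter_rows(values_only=True)]
        finally:
            wb.close()
    with open(path, newline="", encoding="utf-8") as fh:
        return [list(r) for r in csv.reader(fh, delimiter="\t")]


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value).strip()


@dataclass
class _Schema:
    sample_ids: list[str]
    has_flags: bool


def _parse_header(header: Sequence, path: Path) -> _Schema:
    cells = [_cell(c) for c in header]
    for i, expected in enumerate(FIXED_LEFT):
        if i >= len(cells) or cells[i] != expected:
            raise SchemaError(
                f"{path.name}: missing or misplaced mandatory column "
                f"{expected!r} (header position {i + 1})"
            )
    try:
        effect_idx = cells.index("Variant Effect")
    except ValueError:
        raise SchemaError(f"{path.name}: missing mandatory column 'Variant Effect'")
    sample_cols = cells[len(FIXED_LEFT): effect_idx]
    if not sample_cols or len(sample_cols) % 3 != 0:
        raise SchemaError(
            f"{path.name}: expected sample triplets (<id>, Depth, Var/Depth) "
            f"between 'Var' and 'Variant Effect'; found {len(sample_cols)} columns"
        )
    sample_ids = []
    for j in range(0, len(sample_cols), 3):
        sid, d, vd = sample_cols[j: j + 3]
        if d != "Depth" or vd != "Var/Depth":
            raise SchemaError(
                f"{path.name}: sample triplet for {sid!r} must be followed by "
                f"'Depth' and 'Var/Depth' columns, found ({d!r}, {vd!r})"
            )
        if not sid:
            raise SchemaError(f"{path.name}: empty sample id in header triplet {j // 3 + 1}")
        sample_ids.append(sid)
    if effect_idx + 1 >= len(cells) or cells[effect_idx + 1] != "Existing Variation":
        raise SchemaError(f"{path.name}: missing mandatory column 'Existing Variation'")
    trailing = [c for c in cells[effect_idx + 2:] if c]
    if trailing == list(FLAG_COLUMNS):
        has_flags = True
    elif not trailing:
        has_flags = False
    else:
        raise SchemaError(
            f"{path.name}: unexpected trailing columns {trailing}; only "
            f"{list(FLAG_COLUMNS)} are recognized"
        )
    return _Schema(sample_ids=sample_ids, has_flags=has_flags)


def _parse_bool(text: str, row_index: int, column: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    raise RowParseError(row_index, f"cannot parse {column} value {text!r} as a boolean")


def _parse_row(
    cells: list[str],
    schema: _Schema,
    assembly: Assembly,
    roster: SampleRoster,
    row_index: int,
) -> VariantRecord:
    gene_symbol = cells[0]
    if not gene_symbol:
        raise RowParseError(row_index, "empty Gene Symbol")
    gene_id: Optional[int] = None
    if cells[1]:
        try:
            gene_id = int(cells[1])
        except ValueError:
            raise RowParseError(row_index, f"non-integer Gene Id {cells[1]!r}")
    try:
        position = int(cells[3])
    except ValueError:
        raise RowParseError(row_index, f"non-integer Position {cells[3]!r}")
    try:
        key = VariantKey(
            chromosome=cells[2],
            position=position,
            ref=cells[4].upper(),
            alt=cells[5].upper(),
            assembly=assembly,
        )
    except SchemaError as exc:
        raise RowParseError(row_index, str(exc))

    observations: dict[str, SampleObservation] = {}
    base = len(FIXED_LEFT)
    for j, sid in enumerate(schema.sample_ids):
        label, depth_s, ab_s = cells[base + 3 * j: base + 3 * j + 3]
        try:
            depth = int(depth_s) if depth_s else 0
        except ValueError:
            raise RowParseError(row_index, f"sample {sid}: non-integer Depth {depth_s!r}")
        ab: Optional[float] = None
        if ab_s:
            try:
                ab = float(ab_s)
            except ValueError:
                raise RowParseError(row_index, f"sample {sid}: non-numeric Var/Depth {ab_s!r}")
        if depth > 0 and ab is None:
            raise RowParseError(row_index, f"sample {sid}: Var/Depth missing at depth {depth}")
        role = roster.role_of(sid) or Role.CONTROL
        try:
            observations[sid] = SampleObservation(
                sample_id=sid, role=role, depth=depth, allele_balance=ab,
                genotype_label=label,
            )
        except SchemaError as exc:
            raise RowParseError(row_index, str(exc))

    effect_idx = base + 3 * len(schema.sample_ids)
    variant_effect = cells[effect_idx]
    existing = cells[effect_idx + 1]
    if existing.strip().lower() == "null":
        existing = ""

    rec = VariantRecord(
        key=key,
        gene_symbol=gene_symbol,
        gene_id=gene_id,
        variant_effect=variant_effect,
        existing_variation=existing,
        observations=observations,
    )
    if schema.has_flags:
        rec.whitelist_hit = _parse_bool(cells[effect_idx + 2], row_index, "WHITELIST_HIT")
        rec.compound_het = _parse_bool(cells[effect_idx + 3], row_index, "COMPOUND_HET")
        reasons = cells[effect_idx + 4].strip()
        rec.removal_reasons = reasons.split(";") if reasons else []
    return rec


def read_variant_table(
    path: str | Path,
    assembly: Assembly | str,
    roster_hint: Optional[SampleRoster] = None,
    collect_errors: Optional[list[RowParseError]] = None,
) -> tuple[list[VariantRecord], SampleRoster]:
    """Read one annotated-variant table (``.xlsx`` or tab-separated).

    Sample triplets are detected from the header; roles come from
    *roster_hint* (samples absent from the hint default to ``control``, with a
    log message).  Duplicate (chromosome, position, ref, alt) rows are
    collapsed keeping the first occurrence.

    Malformed data rows raise :class:`RowParseError` naming the 1-based file
    row, unless *collect_errors* is a list, in which case bad rows are
    appended there and skipped so that no row is ever silently dropped:
    ``input rows == len(records before dedup) + len(collect_errors)``.
    """
    path = Path(path)
    assembly = assembly if isinstance(assembly, Assembly) else Assembly.parse(assembly)
    if roster_hint is not None and roster_hint.assembly != assembly:
        raise AssemblyMismatchError(
            f"{path.name} declared as {assembly.value} but the analysis roster is "
            f"{roster_hint.assembly.value}; only tables from the same human genome "
            "assembly can be filtered together"
        )
    rows = _raw_rows(path)
    if not rows:
        raise SchemaError(f"{path.name}: file is empty (no header row)")
    schema = _parse_header(rows[0], path)

    hinted = {s: r for s, r in roster_hint.samples} if roster_hint else {}
    roster_samples: list[tuple[str, Role]] = []
    for sid in schema.sample_ids:
        role = hinted.get(sid)
        if role is None:
            log.info("sample %r has no assigned role; defaulting to control", sid)
            role = Role.CONTROL
        roster_samples.append((sid, role))
    roster = SampleRoster(samples=roster_samples, assembly=assembly)

    n_cols = len(FIXED_LEFT) + 3 * len(schema.sample_ids) + len(FIXED_RIGHT)
    if schema.has_flags:
        n_cols += len(FLAG_COLUMNS)

    records: list[VariantRecord] = []
    seen: set[VariantKey] = set()
    for i, raw in enumerate(rows[1:], start=2):
        cells = [_cell(c) for c in raw]
        if not any(cells):
            continue  # trailing blank line
        cells += [""] * (n_cols - len(cells))
        try:
            rec = _parse_row(cells, schema, assembly, roster, i)
        except RowParseError as exc:
            if collect_errors is None:
                raise
            collect_errors.append(exc)
            continue
        if rec.key in seen:
            log.warning(
                "%s: duplicate variant %s %s>%s collapsed (keeping first)",
                path.name, rec.key.locus, rec.key.ref, rec.key.alt,
            )
            continue
        seen.add(rec.key)
        records.append(rec)
    log.info("%s: read %d records, %d samples", path.name, len(records), len(roster.samples))
    return records, roster


def merge_tables(
    loaded: Sequence[tuple[list[VariantRecord], SampleRoster]],
) -> tuple[list[VariantRecord], SampleRoster]:
    """Concatenate tables loaded for one analysis, enforcing one assembly.

    Tables must agree on assembly (hard error otherwise) and carry identical
    sample rosters; records are concatenated with cross-table duplicate keys
    collapsed keeping the first.
    """
    if not loaded:
        raise SchemaError("no tables to merge")
    _, roster0 = loaded[0]
    records: list[VariantRecord] = []
    seen: set[VariantKey] = set()
    for recs, roster in loaded:
        if roster.assembly != roster0.assembly:
            raise AssemblyMismatchError(
                f"cannot merge {roster.assembly.value} with {roster0.assembly.value} "
                "tables; only tables from the same human genome assembly can be "
                "filtered together"
            )
        if roster.sample_ids != roster0.sample_ids:
            raise SchemaError(
                f"sample rosters differ across tables: {roster.sample_ids} vs "
                f"{roster0.sample_ids}"
            )
        for rec in recs:
            if rec.key in seen:
                log.warning("duplicate variant %s across tables collapsed", rec.key.locus)
                continue
            seen.add(rec.key)
            records.append(rec)
    return records, roster0


# ---------------------------------------------------------------------------
# table writing


def _format_ab(ab: Optional[float]) -> str:
    return "" if ab is None else repr(ab)


def _record_cells(rec: VariantRecord, sample_ids: list[str]) -> list[str]:
    cells = [
        rec.gene_symbol,
        "" if rec.gene_id is None else str(rec.gene_id),
        rec.key.chromosome,
        str(rec.key.position),
        rec.key.ref,
        rec.key.alt,
    ]
    for sid in sample_ids:
        obs = rec.observations[sid]
        cells += [obs.genotype_label, str(obs.depth), _format_ab(obs.allele_balance)]
    cells += [
        rec.variant_effect,
        rec.existing_variation,
        "true" if rec.whitelist_hit else "false",
        "true" if rec.compound_het else "false",
        ";".join(rec.removal_reasons),
    ]
    return cells


def _header_cells(sample_ids: list[str]) -> list[str]:
    cells = list(FIXED_LEFT)
    for sid in sample_ids:
        cells += [sid, "Depth", "Var/Depth"]
    cells += list(FIXED_RIGHT) + list(FLAG_COLUMNS)
    return cells


def write_filtered_table(
    records: Sequence[VariantRecord],
    path: str | Path,
    dialect: Optional[Dialect | str] = None,
    include_removed: bool = False,
    roster: Optional[SampleRoster] = None,
) -> Path:
    """Write records back out in the input layout plus the three flag columns.

    The TSV dialect is UTF-8, tab-separated, LF line endings, allele balances
    in shortest-exact float notation — byte-for-byte reproducible.  The
    spreadsheet dialect fills surviving white-list rows green and surviving
    compound-het rows pink (pink wins when both flags are set, being the rarer
    signal).  Removed records are written only with *include_removed*, their
    reasons semicolon-joined in ``REMOVAL_REASONS``.
    """
    path = Path(path)
    if dialect is None:
        dialect = Dialect.SPREADSHEET if path.suffix.lower() == ".xlsx" else Dialect.TSV
    dialect = Dialect(dialect)

    if roster is not None:
        sample_ids = roster.sample_ids
    elif records:
        sample_ids = list(records[0].observations)
    else:
        sample_ids = []
    out = [r for r in records if include_removed or r.surviving]
    header = _header_cells(sample_ids)

    if dialect is Dialect.TSV:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write("\t".join(header) + "\n")
            for rec in out:
                fh.write("\t".join(_record_cells(rec, sample_ids)) + "\n")
        return path

    from openpyxl import Workbook
    from openpyxl.styles import PatternFill

    green = PatternFill(start_color=GREEN_FILL, end_color=GREEN_FILL, fill_type="solid")
    pink = PatternFill(start_color=PINK_FILL, end_color=PINK_FILL, fill_type="solid")
    wb = Workbook()
    ws = wb.active
    ws.title = "filtered"
    ws.append(header)
    for rec in out:
        ws.append(_record_cells(rec, sample_ids))
        if rec.surviving and (rec.compound_het or rec.whitelist_hit):
            fill = pink if rec.compound_het else green
            for cell in ws[ws.max_row]:
                cell.fill = fill
    wb.save(path)
    return path


# ---------------------------------------------------------------------------
# gene lists


def read_gene_list(
    path: str | Path,
    polarity: Polarity | str,
    name: Optional[str] = None,
) -> GeneList:
    """Read a gene list: one symbol per line, or two columns (symbol, HGNC id).

    Accepts plain text / TSV or an ``.xlsx`` sheet.  Symbols are uppercased
    and deduplicated; an empty list is an error (a polarity list with zero
    genes is always a user mistake).
    """
    path = Path(path)
    polarity = Polarity(polarity)
    if path.suffix.lower() == ".xlsx":
        rows = _raw_rows(path)
        fields = [[_cell(c) for c in row] for row in rows]
    else:
        with open(path, encoding="utf-8") as fh:
            fields = [line.rstrip("\n").split("\t") for line in fh]

    symbols: set[str] = set()
    ids: set[int] = set()
    for row in fields:
        row = [c.strip() for c in row if c and c.strip()]
        if not row:
            continue
        symbols.add(row[0].upper())
        if len(row) > 1:
            try:
                ids.add(int(row[1]))
            except ValueError:
                log.warning("%s: ignoring non-integer HGNC id %r", path.name, row[1])
    if not symbols:
        raise SchemaError(f"gene list {path.name} contains no gene symbols")
    gl = GeneList(
        name=name or path.stem,
        polarity=polarity,
        symbols=frozenset(symbols),
        hgnc_ids=frozenset(ids) if ids else None,
    )
    log.info("%s: %d gene symbols (%s list)", path.name, len(gl), polarity.value)
    return gl
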