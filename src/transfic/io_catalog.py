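"""Readers and writers for every external representation.

All files are UTF-8 TSV with "." decimals. Floats are serialized with
``repr`` so every writer/reader pair round-trips exactly.

Formats
-------
* variant score table: TSV with a header row; column names are mapped to
  logical fields by a :class:`~transfic.models.ColumnSpec`;
* gene sets: GMT — one term per line, ``term_id<TAB>description<TAB>gene...``;
* baseline table: TSV opened by a ``#transfic-baseline v1`` line, one row per
  gene x tool plus ``*`` rows for the catalog-wide global entry;
* transformed output: TSV with per-tool raw, oriented, transfic, category and
  fallback columns.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, TextIO, Tuple

from .errors import ConfigurationError, ParseError
from .models import (
    BaselineTable,
    Category,
    ColumnSpec,
    GeneBaseline,
    GeneSetCollection,
    ScoredVariant,
    ToolResult,
    ToolStats,
    TransficRecord,
)

__all__ = [
    "VariantReadReport",
    "read_variant_scores",
    "write_variant_scores",
    "read_gmt",
    "write_gmt",
    "BASELINE_FORMAT_HEADER",
    "write_baseline_table",
    "read_baseline_table",
    "write_transfic_records",
    "read_transfic_records",
]

logger = logging.getLogger(__name__)

BASELINE_FORMAT_HEADER = "#transfic-baseline v1"
_GLOBAL_GENE = "*"
_EMPTY = "-"


def _fmt(x: float) -> str:
    return repr(float(x))


@dataclass
class VariantReadReport:
    """Bookkeeping from one variant-table read."""

    n_rows: int = 0
    n_dropped_scoreless: int = 0
    n_duplicates_collapsed: int = 0
    n_unparseable_cells: int = 0
    warnings: List[str] = field(default_factory=list)


def read_variant_scores(
    stream: TextIO,
    column_spec: ColumnSpec | None = None,
    report: VariantReadReport | None = None,
) -> List[ScoredVariant]:
    """Read a TSV variant score table.

    Rows with no parseable score in any configured column are dropped and
    counted. Duplicate variant ids are collapsed to the first occurrence; a
    conflicting duplicate is logged. Unparseable numeric cells are warnings
    and leave the score absent.

    Parameters
    ----------
    stream
        Text stream positioned at the header row.
    column_spec
        Logical-field to column-name mapping; defaults to
        ``id / gene / sift,pph2,ma``.
    report
        Optional mutable report collecting drop/duplicate counters.
    """
    spec = column_spec or ColumnSpec()
    rep = report if report is not None else VariantReadReport()

    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty variant table: no header row")
    col = {name: i for i, name in enumerate(header)}

    for mandatory in (spec.variant_id, spec.gene):
        if mandatory not in col:
            raise ConfigurationError(f"variant table is missing mandatory column {mandatory!r}")
    score_cols = {tool: c for tool, c in spec.scores.items() if c in col}
    if not score_cols:
        raise ConfigurationError(
            f"variant table has none of the configured score columns {sorted(spec.scores.values())}"
        )
    if spec.sample_count is not None and spec.sample_count not in col:
        raise ConfigurationError(
            f"variant table is missing sample-count column {spec.sample_count!r}"
        )

    out: Dict[str, ScoredVariant] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        rep.n_rows += 1
        vid = row[col[spec.variant_id]].strip()
        gene = row[col[spec.gene]].strip()
        if not vid or not gene:
            raise ParseError("empty variant or gene id", line=lineno)
        scores: Dict[str, float] = {}
        for tool, cname in score_cols.items():
            idx = col[cname]
            cell = row[idx].strip() if idx < len(row) else ""
            if not cell or cell.upper() in ("NA", "NAN", _EMPTY, "."):
                continue
            try:
                scores[tool] = float(cell)
            except ValueError:
                rep.n_unparseable_cells += 1
                msg = f"line {lineno}: unparseable {tool} score {cell!r}; treated as absent"
                rep.warnings.append(msg)
                logger.warning(msg)
        if not scores:
            rep.n_dropped_scoreless += 1
            continue
        sample_count = 1
        if spec.sample_count is not None:
            cell = row[col[spec.sample_count]].strip()
            if cell:
                try:
                    sample_count = int(cell)
                except ValueError:
                    raise ParseError(f"unparseable sample count {cell!r}", line=lineno)
        if vid in out:
            rep.n_duplicates_collapsed += 1
            prev = out[vid]
            if prev.gene_id != gene or prev.scores != scores:
                msg = f"line {lineno}: duplicate variant id {vid!r} with conflicting fields; keeping first"
                rep.warnings.append(msg)
                logger.warning(msg)
            if spec.sample_count is None:
                # without an explicit count column, each input row is one
                # observation, so collapsing accumulates recurrence
                prev.sample_count += 1
            continue
        out[vid] = ScoredVariant(
            variant_id=vid, gene_id=gene, scores=scores, sample_count=sample_count
        )
    return list(out.values())


def write_variant_scores(
    variants: Sequence[ScoredVariant],
    stream: TextIO,
    column_spec: ColumnSpec | None = None,
) -> None:
    """Write a variant score table readable by :func:`read_variant_scores`."""
    spec = column_spec or ColumnSpec()
    tools = list(spec.scores)
    header = [spec.variant_id, spec.gene] + [spec.scores[t] for t in tools]
    if spec.sample_count is not None:
        header.append(spec.sample_count)
    stream.write("\t".join(header) + "\n")
    for v in variants:
        row = [v.variant_id, v.gene_id]
        row += [_fmt(v.scores[t]) if t in v.scores else "" for t in tools]
        if spec.sample_count is not None:
            row.append(str(v.sample_count))
        stream.write("\t".join(row) + "\n")


def read_gmt(stream: TextIO, name: str = "geneset") -> GeneSetCollection:
    """Read a GMT gene-set file.

    Each line is ``term_id<TAB>description<TAB>gene1<TAB>gene2...``; member
    genes are deduplicated within a term, and a line with fewer than three
    fields is a parse error reported with its line number.
    """
    terms: Dict[str, Tuple[str, frozenset]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"GMT line needs term, description and at least one gene; got {len(fields)} fields",
                line=lineno,
            )
        term_id, description = fields[0], fields[1]
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise ParseError(f"term {term_id!r} has no non-empty member genes", line=lineno)
        if term_id in terms:
            raise ParseError(f"duplicate term id {term_id!r}", line=lineno)
        terms[term_id] = (description, genes)
    return GeneSetCollection(name, terms)


def write_gmt(collection: GeneSetCollection, stream: TextIO) -> None:
    for term_id, (description, genes) in collection.items():
        stream.write("\t".join([term_id, description, *sorted(genes)]) + "\n")


def write_baseline_table(table: BaselineTable, stream: TextIO) -> None:
    """Serialize a baseline table; read/write round-trips field-for-field."""
    stream.write(BASELINE_FORMAT_HEADER + "\n")
    stream.write(
        "\t".join(["collection", "gene", "tool", "dm", "dstd", "n_pooled", "fallback", "terms_used"])
        + "\n"
    )

    def emit(gene: str, tool: str, st: ToolStats, n: int, fallback: bool, terms: Tuple[str, ...]):
        stream.write(
            "\t".join(
                [
                    table.collection_name,
                    gene,
                    tool,
                    _fmt(st.dm),
                    _fmt(st.dstd),
                    str(n),
                    "1" if fallback else "0",
                    ",".join(terms) if terms else _EMPTY,
                ]
            )
            + "\n"
        )

    for tool, st in table.global_stats.items():
        emit(_GLOBAL_GENE, tool, st, table.global_n, False, ())
    for gene in sorted(table.per_gene):
        entry = table.per_gene[gene]
        for tool, st in entry.stats.items():
            emit(gene, tool, st, entry.n_pooled, entry.fallback, entry.terms_used)


def read_baseline_table(stream: TextIO) -> BaselineTable:
    first = stream.readline().rstrip("\n")
    if first != BASELINE_FORMAT_HEADER:
        raise ParseError(
            f"not a baseline table: expected {BASELINE_FORMAT_HEADER!r} header, got {first!r}"
        )
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("baseline table has no column header")
    expected = ["collection", "gene", "tool", "dm", "dstd", "n_pooled", "fallback", "terms_used"]
    if header != expected:
        raise ParseError(f"unexpected baseline columns {header}")

    collection_name: str | None = None
    global_stats: Dict[str, ToolStats] = {}
    global_n = 0
    acc: Dict[str, dict] = {}
    for lineno, row in enumerate(reader, start=3):
        if not row:
            continue
        coll, gene, tool, dm, dstd, n_pooled, fallback, terms_used = row
        if collection_name is None:
            collection_name = coll
        elif coll != collection_name:
            raise ParseError(f"mixed collections {collection_name!r}/{coll!r}", line=lineno)
        st = ToolStats(dm=float(dm), dstd=float(dstd))
        if gene == _GLOBAL_GENE:
            global_stats[tool] = st
            global_n = int(n_pooled)
            continue
        slot = acc.setdefault(
            gene,
            {
                "stats": {},
                "n_pooled": int(n_pooled),
                "fallback": fallback == "1",
                "terms_used": tuple(terms_used.split(",")) if terms_used != _EMPTY else (),
            },
        )
        slot["stats"][tool] = st
    if collection_name is None or not global_stats:
        raise ParseError("baseline table has no global entry rows")
    per_gene = {
        gene: GeneBaseline(
            stats=slot["stats"],
            n_pooled=slot["n_pooled"],
            terms_used=slot["terms_used"],
            fallback=slot["fallback"],
        )
        for gene, slot in acc.items()
    }
    return BaselineTable(
        collection_name=collection_name,
        per_gene=per_gene,
        global_stats=global_stats,
        global_n=global_n,
    )


def _tools_in(records: Iterable[TransficRecord]) -> List[str]:
    seen: Dict[str, None] = {}
    for r in records:
        for t in r.results:
            seen.setdefault(t)
    return list(seen)


def write_transfic_records(records: Sequence[TransficRecord], stream: TextIO) -> None:
    """Write transformed output: id, gene, then per-tool result columns."""
    tools = _tools_in(records)
    header = ["id", "gene"]
    for t in tools:
        header += [t, f"oriented_{t}", f"transfic_{t}", f"category_{t}", f"fallback_{t}"]
    stream.write("\t".join(header) + "\n")
    for r in records:
        row = [r.variant_id, r.gene_id]
        for t in tools:
            res = r.results.get(t)
            if res is None:
                row += ["", "", "", "", ""]
            else:
                row += [
                    _fmt(res.raw),
                    _fmt(res.oriented),
                    _fmt(res.transfic),
                    str(res.category) if res.category is not None else _EMPTY,
                    "1" if res.fallback_used else "0",
                ]
        stream.write("\t".join(row) + "\n")


def read_transfic_records(stream: TextIO) -> List[TransficRecord]:
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty transfic output: no header row")
    if header[:2] != ["id", "gene"]:
        raise ParseError(f"unexpected transfic output header {header[:2]}")
    tools = [h[len("transfic_"):] for h in header if h.startswith("transfic_")]
    col = {name: i for i, name in enumerate(header)}
    out: List[TransficRecord] = []
    for row in reader:
        if not row:
            continue
        results: Dict[str, ToolResult] = {}
        for t in tools:
            raw = row[col[t]]
            if raw == "":
                continue
            cat = row[col[f"category_{t}"]]
            results[t] = ToolResult(
                raw=float(raw),
                oriented=float(row[col[f"oriented_{t}"]]),
                transfic=float(row[col[f"transfic_{t}"]]),
                category=None if cat == _EMPTY else Category(cat),
                fallback_used=row[col[f"fallback_{t}"]] == "1",
            )
        out.append(TransficRecord(variant_id=row[0], gene_id=row[1], results=results))
    return out
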