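"""Readers for the annotation formats consumed by the toolkit.

Supported inputs
----------------
* JGI MycoCosm-style tab-separated KOG, GO and KEGG annotation exports
  (``#``-prefixed header line; default column roles below, overridable per
  file through a ``column_map``),
* two-column KEGG orthology link files (``gene<TAB>ko`` with optional
  database prefixes, as served by the KEGG REST ``link`` endpoint),
* eggNOG-mapper v2 ``.emapper.annotations`` tables,
* Gene Ontology OBO flat files (via :mod:`obonet`).

All readers accept plain or gzip-compressed files (detected from the ``.gz``
suffix), trim whitespace, collapse duplicate (protein, category) pairs, and
never invent identifiers absent from the input. Malformed lines are skipped
with a logged warning rather than aborting the parse.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationRecord",
    "EggnogRecord",
    "ColumnConfigError",
    "FormatError",
    "parse_kog_annotation",
    "parse_go_annotation",
    "parse_kegg_annotation",
    "parse_ko_link",
    "parse_eggnog_annotation",
    "parse_obo",
    "normalize_go_accession",
    "normalize_namespace",
]

GO_ACCESSION_RE = re.compile(r"^GO:\d{7}$")
_KO_RE = re.compile(r"^K\d{5}$")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: KEGG aggregation axes, in the order records are emitted per row.
KEGG_AXES = ("pathway_type", "pathway_class", "pathway_name", "enzyme")


class ColumnConfigError(ValueError):
    """A required column is missing from an annotation table."""


class FormatError(ValueError):
    """A file does not follow the expected format."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein-to-category assignment from any annotation source.

    ``category_id`` is a KOG letter, a ``GO:NNNNNNN`` accession, a KEGG
    pathway type/class/name string, or an EC number, depending on ``source``
    and (for KEGG) ``category_group``, which records the aggregation axis.
    """

    protein_id: str
    category_id: str
    category_label: str = ""
    category_group: str | None = None
    source: str = "kog"  # one of {"kog", "go", "kegg", "eggnog"}

    def __post_init__(self) -> None:
        if not self.protein_id.strip():
            raise ValueError("protein_id must be non-empty")
        if self.source == "go" and not GO_ACCESSION_RE.match(self.category_id):
            raise ValueError(f"malformed GO accession: {self.category_id!r}")


@dataclass(frozen=True)
class EggnogRecord:
    """One query row of an eggNOG-mapper ``.emapper.annotations`` table.

    The ``-`` sentinel used by eggNOG-mapper for missing annotations always
    becomes an empty collection, never a literal ``"-"`` member.
    """

    query: str
    cog_letters: tuple[str, ...] = ()
    go_ids: frozenset[str] = field(default_factory=frozenset)
    kegg_kos: frozenset[str] = field(default_factory=frozenset)
    kegg_pathways: frozenset[str] = field(default_factory=frozenset)
    ec_numbers: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def normalize_go_accession(value: str) -> str | None:
    """Normalize a GO id to the zero-padded ``GO:NNNNNNN`` form.

    Accepts ``GO:0008150``, ``0008150`` and plain ``8150``; returns ``None``
    for anything that cannot be a GO accession.
    """
    value = value.strip()
    if value.upper().startswith("GO:"):
        digits = value[3:]
    else:
        digits = value
    if not digits.isdigit() or len(digits) > 7 or not digits:
        return None
    return f"GO:{int(digits):07d}"


def normalize_namespace(value: str) -> str | None:
    """Map a free-form GO term-type string onto the three OBO namespaces."""
    key = value.strip().lower().replace(" ", "_").replace("-", "_")
    aliases = {"bp": "biological_process", "mf": "molecular_function", "cc": "cellular_component"}
    key = aliases.get(key, key)
    return key if key in NAMESPACES else None


def _read_header_and_rows(path: str | Path) -> tuple[list[str], Iterator[tuple[int, list[str]]]]:
    """Yield the (possibly ``#``-prefixed) header and subsequent data rows.

    Comment lines (``#`` after the header) and blank lines are skipped; rows
    are split on tabs with cell-level whitespace trimmed.
    """
    handle = _open_text(path)
    header: list[str] | None = None
    for line in handle:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        header = [c.strip() for c in line.lstrip("#").split("\t")]
        break
    if header is None:
        handle.close()
        return [], iter(())

    def rows() -> Iterator[tuple[int, list[str]]]:
        with handle:
            for lineno, line in enumerate(handle, start=2):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                yield lineno, [c.strip() for c in line.split("\t")]

    return header, rows()


def _resolve_columns(
    header: Sequence[str],
    defaults: Mapping[str, str],
    column_map: Mapping[str, str] | None,
    required: Iterable[str],
) -> dict[str, int]:
    """Resolve role → column index from a header.

    ``defaults`` maps column name → role for the expected dialect;
    ``column_map`` (same shape) overrides or extends it per file.
    """
    name_to_role = dict(defaults)
    if column_map:
        name_to_role.update(column_map)
    role_to_index: dict[str, int] = {}
    for idx, name in enumerate(header):
        role = name_to_role.get(name)
        if role is not None and role not in role_to_index:
            role_to_index[role] = idx
    for role in required:
        if role not in role_to_index:
            raise ColumnConfigError(
                f"required column for role {role!r} not found in header {list(header)!r}"
            )
    return role_to_index


def _cell(row: Sequence[str], idx: int | None) -> str:
    if idx is None or idx >= len(row):
        return ""
    return row[idx].strip()


# ---------------------------------------------------------------------------
# KOG
# ---------------------------------------------------------------------------

KOG_DEFAULT_COLUMNS = {
    "proteinId": "protein_id",
    "kogid": "kog_id",
    "kogdefline": "defline",
    "kogClass": "kog_class",
    "kogLetter": "kog_letter",
}


def parse_kog_annotation(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Parse a JGI-style KOG annotation table.

    One record per distinct (protein, KOG letter) pair; ``category_group``
    carries the KOG class string read from the file and ``category_label``
    the canonical letter name.
    """
    from . import _kog

    header, rows = _read_header_and_rows(path)
    if not header:
        log.warning("KOG annotation file %s is empty", path)
        return []
    cols = _resolve_columns(
        header, KOG_DEFAULT_COLUMNS, column_map, required=("protein_id", "kog_letter")
    )
    out: dict[tuple[str, str], AnnotationRecord] = {}
    for _lineno, row in rows:
        protein = _cell(row, cols["protein_id"])
        letter = _cell(row, cols["kog_letter"])
        if not protein or not letter:
            continue
        key = (protein, letter)
        if key in out:
            continue
        out[key] = AnnotationRecord(
            protein_id=protein,
            category_id=letter,
            category_label=_kog.letter_name(letter),
            category_group=_cell(row, cols.get("kog_class")) or _kog.letter_class(letter),
            source="kog",
        )
    if not out:
        log.warning("KOG annotation file %s yielded no records", path)
    return list(out.values())


# ---------------------------------------------------------------------------
# GO
# ---------------------------------------------------------------------------

GO_DEFAULT_COLUMNS = {
    "proteinId": "protein_id",
    "gotermId": "term",
    "goName": "name",
    "gotermType": "namespace",
    "goAcc": "term",  # some exports carry the accession in a separate column
}


def parse_go_annotation(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[AnnotationRecord], int]:
    """Parse a JGI-style GO annotation table.

    Returns ``(records, n_skipped)``. Numeric GO ids are normalized to
    zero-padded accessions; the term type is normalized to the three OBO
    namespace strings and stored in ``category_group``. Rows whose GO id is
    unparseable (or whose namespace is unrecognizable) are skipped and
    counted.
    """
    header, rows = _read_header_and_rows(path)
    if not header:
        log.warning("GO annotation file %s is empty", path)
        return [], 0
    cols = _resolve_columns(
        header, GO_DEFAULT_COLUMNS, column_map, required=("protein_id", "term", "namespace")
    )
    out: dict[tuple[str, str], AnnotationRecord] = {}
    skipped = 0
    for lineno, row in rows:
        protein = _cell(row, cols["protein_id"])
        accession = normalize_go_accession(_cell(row, cols["term"]))
        namespace = normalize_namespace(_cell(row, cols["namespace"]))
        if not protein or accession is None or namespace is None:
            skipped += 1
            log.warning("%s:%d skipped: unparseable GO row %r", path, lineno, row)
            continue
        key = (protein, accession)
        if key in out:
            continue
        out[key] = AnnotationRecord(
            protein_id=protein,
            category_id=accession,
            category_label=_cell(row, cols.get("name")) or accession,
            category_group=namespace,
            source="go",
        )
    return list(out.values()), skipped


# ---------------------------------------------------------------------------
# KEGG
# ---------------------------------------------------------------------------

KEGG_DEFAULT_COLUMNS = {
    "proteinId": "protein_id",
    "ecNum": "ec",
    "definition": "definition",
    "pathway": "pathway",
    "pathway_class": "pathway_class",
    "pathway_type": "pathway_type",
}


def parse_kegg_annotation(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Parse a JGI-style KEGG annotation table.

    Each row yields up to four records for the same protein — one per
    aggregation axis (pathway type, pathway class, pathway name, enzyme
    definition), with ``category_group`` naming the axis. Rows carrying an
    EC number but no pathway still yield the enzyme record, so enzyme-level
    models can cover proteins the pathway models cannot (the EC fallback).
    """
    header, rows = _read_header_and_rows(path)
    if not header:
        log.warning("KEGG annotation file %s is empty", path)
        return []
    cols = _resolve_columns(header, KEGG_DEFAULT_COLUMNS, column_map, required=("protein_id",))
    out: dict[tuple[str, str, str], AnnotationRecord] = {}
    for _lineno, row in rows:
        protein = _cell(row, cols["protein_id"])
        if not protein:
            continue
        pathway = _cell(row, cols.get("pathway"))
        pclass = _cell(row, cols.get("pathway_class"))
        ptype = _cell(row, cols.get("pathway_type"))
        ec = _cell(row, cols.get("ec"))
        definition = _cell(row, cols.get("definition"))
        axes: list[tuple[str, str, str]] = []  # (axis, category_id, label)
        if ptype:
            axes.append(("pathway_type", ptype, ptype))
        if pclass:
            axes.append(("pathway_class", pclass, pclass))
        if pathway:
            axes.append(("pathway_name", pathway, pathway))
        if ec:
            axes.append(("enzyme", ec, definition or ec))
        for axis, category, label in axes:
            key = (protein, axis, category)
            if key in out:
                continue
            out[key] = AnnotationRecord(
                protein_id=protein,
                category_id=category,
                category_label=label,
                category_group=axis,
                source="kegg",
            )
    return list(out.values())


# ---------------------------------------------------------------------------
# KEGG orthology link files
# ---------------------------------------------------------------------------

def parse_ko_link(path: str | Path) -> list[tuple[str, str]]:
    """Parse a two-column KEGG ``link``-style gene→KO file.

    Database prefixes up to and including the first ``:`` are stripped from
    both columns (``tre:TRIREDRAFT_1`` → ``TRIREDRAFT_1``, ``ko:K00001`` →
    ``K00001``); duplicate pairs collapse; lines without a tab are skipped
    with a warning.
    """
    pairs: dict[tuple[str, str], None] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" not in line:
                log.warning("%s:%d skipped: no tab separator", path, lineno)
                continue
            gene, ko = (line.split("\t", 2) + [""])[:2]
            gene = gene.strip().split(":", 1)[-1]
            ko = ko.strip().split(":", 1)[-1]
            if gene and ko:
                pairs[(gene, ko)] = None
    return list(pairs)


# ---------------------------------------------------------------------------
# eggNOG-mapper
# ---------------------------------------------------------------------------

_EGGNOG_REQUIRED = ("query", "COG_category", "GOs", "KEGG_ko", "KEGG_Pathway", "EC")


def _split_cell(cell: str) -> list[str]:
    if cell in ("", "-"):
        return []
    return [tok.strip() for tok in cell.split(",") if tok.strip() and tok.strip() != "-"]


def parse_eggnog_annotation(path: str | Path) -> list[EggnogRecord]:
    """Parse an eggNOG-mapper v2 ``.emapper.annotations`` table.

    ``##`` lines are comments; the header line begins with ``#query``.
    ``-`` cells yield empty collections; multi-letter ``COG_category`` cells
    explode into single letters; KO tokens keep only the ``KNNNNN`` part.
    """
    header: list[str] | None = None
    records: list[EggnogRecord] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("##"):
                continue
            if header is None:
                if not line.startswith("#query"):
                    raise FormatError(
                        f"{path}: expected an eggNOG-mapper header line starting with '#query'"
                    )
                header = line.lstrip("#").split("\t")
                missing = [c for c in _EGGNOG_REQUIRED if c not in header]
                if missing:
                    raise ColumnConfigError(f"{path}: missing eggNOG columns {missing}")
                continue
            row = line.split("\t")
            cells = {name: _cell(row, idx) for idx, name in enumerate(header)}
            query = cells.get("query", "")
            if not query:
                continue
            letters: list[str] = []
            for ch in cells.get("COG_category", ""):
                if ch.isalpha() and ch.isupper() and ch not in letters:
                    letters.append(ch)
            gos = frozenset(
                acc
                for tok in _split_cell(cells.get("GOs", ""))
                if (acc := normalize_go_accession(tok)) is not None
            )
            kos = frozenset(
                tok.split(":", 1)[-1]
                for tok in _split_cell(cells.get("KEGG_ko", ""))
                if _KO_RE.match(tok.split(":", 1)[-1])
            )
            pathways = frozenset(_split_cell(cells.get("KEGG_Pathway", "")))
            ecs = frozenset(_split_cell(cells.get("EC", "")))
            records.append(
                EggnogRecord(
                    query=query,
                    cog_letters=tuple(letters),
                    go_ids=gos,
                    kegg_kos=kos,
                    kegg_pathways=pathways,
                    ec_numbers=ecs,
                )
            )
    if header is None:
        raise FormatError(f"{path}: no '#query' header line found")
    return records


# ---------------------------------------------------------------------------
# OBO ontologies
# ---------------------------------------------------------------------------

def parse_obo(path: str | Path):
    """Read an OBO 1.2/1.4 ontology file into a :class:`~mycoenrich.ontology.GoDag`.

    Only non-obsolete terms and ``is_a``/``part_of`` edges are retained;
    ``alt_id`` accessions become aliases resolving to their primary term.
    Raises if the parent relation is cyclic (GO must be a DAG).
    """
    import obonet

    from .ontology import GoDag

    with _open_text(path) as handle:
        graph = obonet.read_obo(handle, ignore_obsolete=True)

    terms: set[str] = set(graph.nodes)
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    parent_edges: dict[str, set[tuple[str, str]]] = {t: set() for t in terms}
    aliases: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        names[term] = data.get("name", term)
        ns = normalize_namespace(data.get("namespace", "")) or "biological_process"
        namespaces[term] = ns
        for alt in data.get("alt_id", []):
            aliases[alt] = term
    # obonet edges run child -> parent with the relation as the edge key
    for child, parent, relation in graph.edges(keys=True):
        if relation in ("is_a", "part_of") and parent in terms:
            parent_edges[child].add((parent, relation))
    return GoDag(
        terms=terms,
        names=names,
        namespaces=namespaces,
        parent_edges=parent_edges,
        aliases=aliases,
    )
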