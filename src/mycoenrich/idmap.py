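"""Gene-name / transcript-ID / protein-ID conversion from GTF or GFF3 models.

Annotation files and upstream analyses rarely agree on an identifier
namespace: JGI annotation exports key on protein ids while differential
expression output keys on transcript ids or gene names. This module builds
a per-transcript conversion table from the gene models (via :mod:`gffutils`)
and converts identifier lists between the three namespaces, reporting what
could not be mapped instead of guessing — identifiers are compared as exact
strings after trimming.
"""

from __future__ import annotations

import gzip
import logging
import re
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

log = logging.getLogger(__name__)

__all__ = ["ConversionRow", "IdConversionTable", "build_conversion_table", "convert_ids",
           "rewrite_ids", "write_table_tsv", "read_table_tsv"]

ROLES = ("gene_name", "transcript_id", "protein_id")

#: Default attribute keys per dialect and role. GFF3 protein ids default to
#: the JGI "proteinId" attribute; override via ``attribute_map`` elsewhere.
DEFAULT_ATTRIBUTES = {
    "gtf": {"gene_name": "gene_name", "gene_id": "gene_id",
            "transcript_id": "transcript_id", "protein_id": "protein_id"},
    "gff3": {"gene_name": "Name", "gene_id": "ID",
             "transcript_id": "ID", "protein_id": "proteinId"},
}

_TRANSCRIPT_TYPES = ("transcript", "mRNA")


@dataclass(frozen=True)
class ConversionRow:
    gene_name: str = ""
    transcript_id: str = ""
    protein_id: str = ""

    def get(self, role: str) -> str:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
        return getattr(self, role)


@dataclass
class IdConversionTable:
    """One row per transcript; (transcript_id, protein_id) pairs are unique."""

    rows: list[ConversionRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique: list[ConversionRow] = []
        for row in self.rows:
            if not (row.gene_name or row.transcript_id or row.protein_id):
                continue  # entirely empty rows carry no information
            key = (row.transcript_id, row.protein_id)
            if key in seen and any(key):
                continue
            seen.add(key)
            unique.append(row)
        self.rows = unique

    def index(self, role: str) -> dict[str, list[ConversionRow]]:
        out: dict[str, list[ConversionRow]] = {}
        for row in self.rows:
            value = row.get(role)
            if value:
                out.setdefault(value, []).append(row)
        return out

    def __len__(self) -> int:
        return len(self.rows)


def detect_dialect(path: str | Path) -> str:
    """Guess gtf vs gff3 from the first feature line (``=`` vs space attrs)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt", encoding="utf-8") as handle:  # type: ignore[operator]
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            attrs = cols[8]
            first = attrs.split(";", 1)[0].strip()
            return "gff3" if "=" in first else "gtf"
    raise ValueError(f"{path}: no feature lines found")


def _attr_first(feature: gffutils.Feature, key: str) -> str:
    values = feature.attributes.get(key, [])
    return values[0].strip() if values else ""


def build_conversion_table(
    path: str | Path,
    dialect: str = "auto",
    attribute_map: Mapping[str, str] | None = None,
) -> IdConversionTable:
    """Extract one conversion row per transcript from a GTF/GFF3 file.

    ``gene_name`` falls back to the gene id when absent; a transcript
    lacking a protein id keeps an empty ``protein_id`` cell. For GFF3,
    gene/transcript links follow ``Parent`` chains and the protein id is
    read from the transcript's attributes (default key ``proteinId``, the
    JGI convention) or, failing that, from its CDS children.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = detect_dialect(path)
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    attrs = dict(DEFAULT_ATTRIBUTES[dialect])
    if attribute_map:
        attrs.update(attribute_map)

    tmp = None
    source = str(path)
    if path.suffix == ".gz":
        tmp = tempfile.NamedTemporaryFile("wb", suffix=".gff", delete=False)
        with gzip.open(path, "rb") as fin:
            shutil.copyfileobj(fin, tmp)
        tmp.close()
        source = tmp.name
    try:
        try:
            db = gffutils.create_db(
                source,
                dbfn=":memory:",
                force=True,
                keep_order=True,
                merge_strategy="create_unique",
                disable_infer_genes=True,
                disable_infer_transcripts=True,
            )
        except Exception as exc:  # gffutils raises assorted errors on garbage
            raise ValueError(f"{path}: could not parse gene models ({exc})") from exc
        rows = _rows_from_db(db, dialect, attrs)
    finally:
        if tmp is not None:
            Path(tmp.name).unlink(missing_ok=True)
    if not rows:
        raise ValueError(f"{path}: no transcript features with recognizable attributes")
    return IdConversionTable(rows=rows)


def _rows_from_db(db: "gffutils.FeatureDB", dialect: str, attrs: Mapping[str, str]) -> list[ConversionRow]:
    rows: list[ConversionRow] = []
    for ftype in _TRANSCRIPT_TYPES:
        for tr in db.features_of_type(ftype, order_by=("seqid", "start", "file_order")):
            if dialect == "gtf":
                transcript_id = _attr_first(tr, attrs["transcript_id"])
                gene_name = _attr_first(tr, attrs["gene_name"]) or _attr_first(tr, attrs["gene_id"])
                protein_id = _attr_first(tr, attrs["protein_id"])
            else:
                transcript_id = _attr_first(tr, attrs["transcript_id"]) or tr.id
                gene_name = ""
                for parent in db.parents(tr, featuretype="gene"):
                    gene_name = _attr_first(parent, attrs["gene_name"]) or parent.id
                    break
                protein_id = _attr_first(tr, attrs["protein_id"])
            if not protein_id:
                for child in db.children(tr, featuretype="CDS"):
                    protein_id = _attr_first(child, attrs["protein_id"])
                    if protein_id:
                        break
            if transcript_id or gene_name or protein_id:
                rows.append(ConversionRow(gene_name=gene_name,
                                          transcript_id=transcript_id,
                                          protein_id=protein_id))
    return rows


def convert_ids(
    ids: Sequence[str],
    table: IdConversionTable,
    from_role: str,
    to_role: str,
) -> tuple[list[str], list[str]]:
    """Convert identifiers between namespaces via the conversion table.

    Order-preserving: one-to-many mappings expand in place (targets sorted
    for determinism), many-to-one mappings keep duplicates. Ids with no
    mapping (or whose rows have an empty target) are returned in
    ``unmapped``.
    """
    if from_role == to_role:
        raise ValueError("from_role and to_role must differ")
    for role in (from_role, to_role):
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    index = table.index(from_role)
    converted: list[str] = []
    unmapped: list[str] = []
    for raw in ids:
        ident = raw.strip()
        targets = sorted({row.get(to_role) for row in index.get(ident, [])} - {""})
        if targets:
            converted.extend(targets)
        else:
            unmapped.append(ident)
    return converted, unmapped


def rewrite_ids(ids: Iterable[str], pattern: str, replacement: str) -> list[str]:
    """Regex-rewrite identifiers (e.g. trimming FASTA-header decorations
    from eggNOG-mapper query ids so they match the gene-model protein ids)."""
    compiled = re.compile(pattern)
    return [compiled.sub(replacement, ident) for ident in ids]


def write_table_tsv(table: IdConversionTable, path: str | Path) -> None:
    lines = ["gene_name\ttranscript_id\tprotein_id"]
    for row in table.rows:
        lines.append(f"{row.gene_name}\t{row.transcript_id}\t{row.protein_id}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_table_tsv(path: str | Path) -> IdConversionTable:
    rows = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
        if i == 0 or not line.strip():
            continue
        cells = (line.split("\t") + ["", "", ""])[:3]
        rows.append(ConversionRow(*[c.strip() for c in cells]))
    return IdConversionTable(rows=rows)
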