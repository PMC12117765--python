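"""Background frequency models for overrepresentation analysis.

A model holds, per functional category, the set of background proteins
assigned to it. The background size is the number of *distinct* proteins
annotated to at least one category of the model — never the sum of
per-category counts — so proteins mapped to multiple categories are counted
once, which keeps category frequencies on a common denominator.

Models are built from KOG, GO (propagated up the ontology) and KEGG
annotation records, from either JGI-style exports or eggNOG-mapper output,
and serialize to a plain tab-separated form so precomputed models can be
shipped and reloaded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from . import _kog
from .annotation_io import AnnotationRecord, EggnogRecord, FormatError, NAMESPACES
from .ontology import GoDag, propagate_annotations

log = logging.getLogger(__name__)

__all__ = [
    "CategoryEntry",
    "EnrichmentModel",
    "GoModels",
    "KeggModels",
    "EggnogModelBundle",
    "ModelError",
    "create_kog_model",
    "create_go_model",
    "create_kegg_models",
    "create_models_from_eggnog",
    "write_model_tsv",
    "read_model_tsv",
]

MODEL_KINDS = (
    "kog_letter",
    "kog_class",
    "go_bp",
    "go_mf",
    "go_cc",
    "kegg_type",
    "kegg_class",
    "kegg_name",
    "kegg_enzyme",
)

_NS_TO_KIND = {
    "biological_process": "go_bp",
    "molecular_function": "go_mf",
    "cellular_component": "go_cc",
}

_KEGG_AXIS_TO_KIND = {
    "pathway_type": "kegg_type",
    "pathway_class": "kegg_class",
    "pathway_name": "kegg_name",
    "enzyme": "kegg_enzyme",
}


class ModelError(ValueError):
    """Raised when a model cannot be built from the given records."""


@dataclass
class CategoryEntry:
    """One functional category: id, label, optional group, member proteins."""

    category_id: str
    label: str
    group: str | None
    proteins: set[str]

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"category {self.category_id!r} has an empty protein set")
        if not self.label:
            self.label = self.category_id

    @property
    def count(self) -> int:
        return len(self.proteins)


@dataclass
class EnrichmentModel:
    """Background frequency model: categories and their protein sets."""

    model_kind: str
    categories: dict[str, CategoryEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")

    @property
    def background(self) -> frozenset[str]:
        """Union of all categories' protein sets (the annotated universe)."""
        out: set[str] = set()
        for entry in self.categories.values():
            out |= entry.proteins
        return frozenset(out)

    @property
    def background_size(self) -> int:
        return len(self.background)

    def __len__(self) -> int:
        return len(self.categories)


class GoModels(NamedTuple):
    bp: EnrichmentModel
    mf: EnrichmentModel
    cc: EnrichmentModel


class KeggModels(NamedTuple):
    type: EnrichmentModel
    pathway_class: EnrichmentModel
    name: EnrichmentModel
    enzyme: EnrichmentModel


@dataclass
class EggnogModelBundle:
    """All models derivable from one eggNOG-mapper annotation run."""

    kog_letter: EnrichmentModel
    kog_class: EnrichmentModel
    go: GoModels
    kegg_name: EnrichmentModel


def _build(model_kind: str, records: Iterable[AnnotationRecord]) -> EnrichmentModel:
    cats: dict[str, CategoryEntry] = {}
    for r in records:
        entry = cats.get(r.category_id)
        if entry is None:
            cats[r.category_id] = CategoryEntry(
                category_id=r.category_id,
                label=r.category_label or r.category_id,
                group=r.category_group,
                proteins={r.protein_id},
            )
        else:
            entry.proteins.add(r.protein_id)
    return EnrichmentModel(model_kind=model_kind, categories=cats)


# ---------------------------------------------------------------------------
# KOG
# ---------------------------------------------------------------------------

def create_kog_model(
    records: Sequence[AnnotationRecord],
) -> tuple[EnrichmentModel, EnrichmentModel]:
    """Build the KOG letter- and class-level models from KOG records.

    The class model's protein sets are unions over the letters belonging to
    each class, so a protein carrying two letters of one class counts once
    at the class level. Both models share one background universe (every
    KOG-annotated protein).
    """
    records = [r for r in records if r.source == "kog"]
    if not records:
        raise ModelError("no KOG records to build a model from")
    letter_model = _build("kog_letter", records)
    class_records = [
        AnnotationRecord(
            protein_id=r.protein_id,
            category_id=r.category_group or _kog.letter_class(r.category_id) or "Unclassified",
            category_label=r.category_group or "Unclassified",
            category_group=None,
            source="kog",
        )
        for r in records
    ]
    class_model = _build("kog_class", class_records)
    return letter_model, class_model


# ---------------------------------------------------------------------------
# GO
# ---------------------------------------------------------------------------

def create_go_model(records: Sequence[AnnotationRecord], dag: GoDag) -> GoModels:
    """Build one model per GO namespace, after ancestry propagation.

    Records are first closed under the true-path rule, then split by
    namespace; each namespace's background counts the distinct proteins
    annotated there. An empty namespace yields an empty model.
    """
    propagated, dropped = propagate_annotations(dag, records)
    if dropped:
        log.warning("%d GO record(s) referenced terms absent from the ontology", dropped)
    by_ns: dict[str, list[AnnotationRecord]] = {ns: [] for ns in NAMESPACES}
    for r in propagated:
        by_ns[r.category_group].append(r)  # propagation sets group = namespace
    return GoModels(
        bp=_build("go_bp", by_ns["biological_process"]),
        mf=_build("go_mf", by_ns["molecular_function"]),
        cc=_build("go_cc", by_ns["cellular_component"]),
    )


# ---------------------------------------------------------------------------
# KEGG
# ---------------------------------------------------------------------------

def create_kegg_models(records: Sequence[AnnotationRecord]) -> KeggModels:
    """Build the four KEGG aggregation-axis models.

    Each axis has its own background universe — the proteins with a
    non-empty value on that axis — so enzyme-level coverage (the EC
    fallback) can exceed pathway coverage without deflating either.
    """
    records = [r for r in records if r.source == "kegg"]
    by_axis: dict[str, list[AnnotationRecord]] = {a: [] for a in _KEGG_AXIS_TO_KIND}
    for r in records:
        if r.category_group in by_axis:
            by_axis[r.category_group].append(r)
    return KeggModels(
        type=_build("kegg_type", by_axis["pathway_type"]),
        pathway_class=_build("kegg_class", by_axis["pathway_class"]),
        name=_build("kegg_name", by_axis["pathway_name"]),
        enzyme=_build("kegg_enzyme", by_axis["enzyme"]),
    )


# ---------------------------------------------------------------------------
# eggNOG-mapper
# ---------------------------------------------------------------------------

_PATHWAY_ID_RE = re.compile(r"^(?:ko|map|path:?(?:ko|map)?)?(\d{5})$")


def normalize_pathway_id(pathway: str) -> str:
    """Unify ``ko00010`` / ``map00010`` spellings onto ``map00010``."""
    m = _PATHWAY_ID_RE.match(pathway.strip())
    if m:
        return f"map{m.group(1)}"
    return pathway.strip()


def create_models_from_eggnog(
    records: Sequence[EggnogRecord],
    dag: GoDag,
    ko_pathway_map: Mapping[str, Iterable[str]] | None = None,
    pathway_labels: Mapping[str, str] | None = None,
    letter_class_map: Mapping[str, str] | None = None,
) -> EggnogModelBundle:
    """Build KOG, GO and KEGG models directly from eggNOG-mapper output.

    COG letters feed the KOG letter model (classes via the built-in
    canonical letter→class table, overridable through ``letter_class_map``);
    GO ids feed :func:`create_go_model`; KEGG pathway ids (from the
    KEGG_Pathway column, optionally expanded from KOs through
    ``ko_pathway_map``) feed the KEGG pathway-name model. The eggNOG query
    id is used as the protein id throughout.
    """
    kog_records: list[AnnotationRecord] = []
    go_records: list[AnnotationRecord] = []
    kegg_records: list[AnnotationRecord] = []
    for rec in records:
        for letter in rec.cog_letters:
            cls = (letter_class_map or {}).get(letter) or _kog.letter_class(letter) or "Unclassified"
            kog_records.append(
                AnnotationRecord(
                    protein_id=rec.query,
                    category_id=letter,
                    category_label=_kog.letter_name(letter),
                    category_group=cls,
                    source="kog",
                )
            )
        for go_id in rec.go_ids:
            if go_id in dag:
                go_records.append(
                    AnnotationRecord(
                        protein_id=rec.query,
                        category_id=go_id,
                        category_label=dag.name(go_id),
                        category_group=dag.namespace(go_id),
                        source="go",
                    )
                )
        pathways = {normalize_pathway_id(p) for p in rec.kegg_pathways}
        if ko_pathway_map:
            for ko in rec.kegg_kos:
                pathways |= {normalize_pathway_id(p) for p in ko_pathway_map.get(ko, ())}
        for pathway in pathways:
            label = (pathway_labels or {}).get(pathway, pathway)
            kegg_records.append(
                AnnotationRecord(
                    protein_id=rec.query,
                    category_id=pathway,
                    category_label=label,
                    category_group="pathway_name",
                    source="kegg",
                )
            )
    empty = [
        name
        for name, recs in (("kog", kog_records), ("go", go_records), ("kegg", kegg_records))
        if not recs
    ]
    if len(empty) == 3:
        raise ModelError(f"eggNOG records carried no usable annotations (empty models: {empty})")
    if empty:
        log.warning("eggNOG source yields empty model(s): %s", empty)

    if kog_records:
        kog_letter, kog_class = create_kog_model(kog_records)
    else:
        kog_letter = EnrichmentModel(model_kind="kog_letter")
        kog_class = EnrichmentModel(model_kind="kog_class")
    go_models = create_go_model(go_records, dag)
    kegg_name = _build("kegg_name", kegg_records)
    return EggnogModelBundle(
        kog_letter=kog_letter, kog_class=kog_class, go=go_models, kegg_name=kegg_name
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_model_tsv(model: EnrichmentModel, path: str | Path) -> None:
    """Serialize a model to tab-separated text.

    Two ``#`` header lines record the model kind and background size; one
    row per category with comma-joined sorted protein ids. Round-trips
    exactly through :func:`read_model_tsv`.
    """
    path = Path(path)
    lines = [
        f"# model_kind: {model.model_kind}",
        f"# background_size: {model.background_size}",
        "category_id\tlabel\tgroup\tcount\tproteins",
    ]
    for cat_id in sorted(model.categories):
        entry = model.categories[cat_id]
        lines.append(
            "\t".join(
                [
                    entry.category_id,
                    entry.label,
                    entry.group or "",
                    str(entry.count),
                    ",".join(sorted(entry.proteins)),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_model_tsv(path: str | Path) -> EnrichmentModel:
    """Load a model written by :func:`write_model_tsv`, verifying its counts."""
    path = Path(path)
    model_kind: str | None = None
    declared_background: int | None = None
    cats: dict[str, CategoryEntry] = {}
    header_seen = False
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("model_kind:"):
                model_kind = body.split(":", 1)[1].strip()
            elif body.startswith("background_size:"):
                declared_background = int(body.split(":", 1)[1].strip())
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        cells = line.split("\t")
        if len(cells) != 5:
            raise FormatError(f"{path}: malformed model row {line!r}")
        cat_id, label, group, count, proteins = cells
        protein_set = set(p for p in proteins.split(",") if p)
        if int(count) != len(protein_set):
            raise FormatError(f"{path}: count mismatch for category {cat_id!r}")
        cats[cat_id] = CategoryEntry(
            category_id=cat_id, label=label, group=group or None, proteins=protein_set
        )
    if model_kind is None:
        raise FormatError(f"{path}: missing '# model_kind:' header")
    model = EnrichmentModel(model_kind=model_kind, categories=cats)
    if declared_background is not None and model.background_size != declared_background:
        raise FormatError(
            f"{path}: declared background_size {declared_background} != computed "
            f"{model.background_size}"
        )
    return model
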