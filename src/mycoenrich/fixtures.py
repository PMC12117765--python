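"""Synthetic annotation fixtures with planted, known-truth enrichment.

The generator emits a mutually consistent mini-genome annotation bundle in
every dialect the toolkit reads — a KOG table, a GO table with a matching
toy OBO ontology, a KEGG table (including EC-only fallback rows), a KEGG
orthology link file, an eggNOG-mapper table, a GTF gene-model file and a
query protein list — all over one protein universe, plus a machine-readable
ground truth recording which categories were planted as enriched and at
what realized counts.

Enrichment is planted by composing the query from a fixed number of members
of each planted category (``round(fold * K/N * query_size)`` by default) and
uniform draws for the remainder, so a planted fold of 1.0 is the null. All
randomness flows from the mandatory seed: identical configurations produce
byte-identical files. Category sizes are roughly uniform by design; the
generator makes no attempt to mimic real fungal genome annotation-size
distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kog
from .annotation_io import AnnotationRecord, EggnogRecord
from .ontology import GoDag

__all__ = ["PlantedCategory", "FixtureConfig", "FixtureTruth", "SyntheticAnnotations",
           "synthesize", "generate_fixture", "FixtureConfigError"]

NAMESPACE_BASES = {
    "biological_process": 1000000,
    "molecular_function": 2000000,
    "cellular_component": 3000000,
}

_KEGG_CLASSES = [
    ("Carbohydrate metabolism", "Metabolism"),
    ("Amino acid metabolism", "Metabolism"),
    ("Energy metabolism", "Metabolism"),
    ("Lipid metabolism", "Metabolism"),
    ("Translation", "Genetic Information Processing"),
    ("Transport and catabolism", "Cellular Processes"),
]


class FixtureConfigError(ValueError):
    """Raised when a fixture configuration is inconsistent."""


@dataclass(frozen=True)
class PlantedCategory:
    """A category to overrepresent in the query.

    ``fold`` is the target enrichment ratio (1.0 = null, no planting);
    ``query_fraction`` overrides the computed fraction of the query drawn
    from the category.
    """

    category_id: str
    fold: float = 4.0
    query_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.fold < 1.0:
            raise FixtureConfigError("planted fold must be >= 1")
        if self.query_fraction is not None and not (0.0 <= self.query_fraction <= 1.0):
            raise FixtureConfigError("query_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic annotation generator (seed is mandatory)."""

    seed: int
    n_proteins: int = 1000
    n_kog_letters: int = 18
    n_go_terms: int = 40  # biological_process; MF/CC get half each
    go_second_parent_prob: float = 0.3
    go_part_of_prob: float = 0.15
    n_kegg_pathways: int = 12
    n_enzymes: int = 15
    annotation_density: float = 0.8
    multi_category_prob: float = 0.15
    planted: tuple[PlantedCategory, ...] = ()
    query_size: int = 50

    def __post_init__(self) -> None:
        for p, name in ((self.annotation_density, "annotation_density"),
                        (self.multi_category_prob, "multi_category_prob"),
                        (self.go_second_parent_prob, "go_second_parent_prob"),
                        (self.go_part_of_prob, "go_part_of_prob")):
            if not (0.0 <= p <= 1.0):
                raise FixtureConfigError(f"{name} must lie in [0, 1]")
        if self.n_proteins < 1 or self.query_size < 1:
            raise FixtureConfigError("n_proteins and query_size must be >= 1")


@dataclass
class FixtureTruth:
    """Ground truth for a generated fixture."""

    planted: list[dict]  # category_id, model_kind, fold, k, K, n, N, enriched
    query: list[str]
    files: dict[str, str] = field(default_factory=dict)

    @property
    def enriched_ids(self) -> list[str]:
        return [p["category_id"] for p in self.planted if p["enriched"]]

    def to_json(self) -> str:
        return json.dumps(
            {"planted": self.planted, "query": self.query, "files": self.files},
            indent=2, sort_keys=True,
        ) + "\n"


@dataclass
class SyntheticAnnotations:
    """In-memory form of a fixture: records, ontology, texts and truth."""

    proteins: list[str]
    kog_records: list[AnnotationRecord]
    go_records: list[AnnotationRecord]
    kegg_records: list[AnnotationRecord]
    ko_links: list[tuple[str, str]]
    eggnog_records: list[EggnogRecord]
    dag: GoDag
    obo_text: str
    gtf_text: str
    conversion_rows: list[tuple[str, str, str]]
    query: list[str]
    truth: FixtureTruth
    #: model kind -> {category_id -> protein set}; GO sets are propagated.
    model_sets: dict[str, dict[str, set[str]]]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _make_go_namespace(rng: np.random.Generator, namespace: str, n_terms: int,
                       second_parent_prob: float, part_of_prob: float):
    """Random single-rooted DAG for one namespace: term 0 is the root and
    every later term picks 1-2 earlier terms as parents."""
    base = NAMESPACE_BASES[namespace]
    ids = [f"GO:{base + i:07d}" for i in range(n_terms)]
    parents: dict[str, set[tuple[str, str]]] = {t: set() for t in ids}
    for i in range(1, n_terms):
        first = int(rng.integers(0, i))
        relation = "part_of" if rng.random() < part_of_prob else "is_a"
        parents[ids[i]].add((ids[first], relation))
        if i >= 2 and rng.random() < second_parent_prob:
            second = int(rng.integers(0, i))
            if second != first:
                parents[ids[i]].add((ids[second], "is_a"))
    names = {ids[0]: f"{namespace} root"}
    names.update({ids[i]: f"{namespace} term {i}" for i in range(1, n_terms)})
    return ids, parents, names


def _ancestor_closure(parents: dict[str, set[tuple[str, str]]]) -> dict[str, set[str]]:
    """Reflexive-transitive closure, memoized bottom-up (independent of the
    ontology module's BFS so round-trip checks cross two code paths)."""
    closure: dict[str, set[str]] = {}

    def close(term: str) -> set[str]:
        if term not in closure:
            acc = {term}
            for parent, _rel in parents[term]:
                acc |= close(parent)
            closure[term] = acc
        return closure[term]

    for t in parents:
        close(t)
    return closure


def synthesize(config: FixtureConfig) -> SyntheticAnnotations:
    """Generate the full annotation bundle in memory."""
    rng = np.random.default_rng(config.seed)
    proteins = [f"FGP_{i:05d}" for i in range(1, config.n_proteins + 1)]

    # --- KOG ---------------------------------------------------------------
    all_letters = sorted(_kog.KOG_LETTERS)
    n_letters = min(config.n_kog_letters, len(all_letters))
    # planted single-letter ids must exist, so force them into the draw
    forced = [p.category_id for p in config.planted if p.category_id in _kog.KOG_LETTERS]
    pool = [l for l in all_letters if l not in forced]
    drawn = rng.choice(pool, size=max(0, n_letters - len(forced)), replace=False).tolist()
    letters = sorted(set(forced) | set(drawn))
    n_letters = len(letters)
    kog_assign: dict[str, list[str]] = {}
    for protein in proteins:
        if rng.random() >= config.annotation_density:
            continue
        chosen = [letters[int(rng.integers(0, n_letters))]]
        if rng.random() < config.multi_category_prob:
            extra = letters[int(rng.integers(0, n_letters))]
            if extra != chosen[0]:
                chosen.append(extra)
        kog_assign[protein] = chosen
    kog_records = [
        AnnotationRecord(protein_id=p, category_id=letter,
                         category_label=_kog.letter_name(letter),
                         category_group=_kog.letter_class(letter), source="kog")
        for p in sorted(kog_assign) for letter in kog_assign[p]
    ]

    # --- GO ----------------------------------------------------------------
    ns_sizes = {
        "biological_process": max(3, config.n_go_terms),
        "molecular_function": max(3, config.n_go_terms // 2),
        "cellular_component": max(3, config.n_go_terms // 2),
    }
    terms: set[str] = set()
    go_parents: dict[str, set[tuple[str, str]]] = {}
    go_names: dict[str, str] = {}
    go_namespaces: dict[str, str] = {}
    ns_term_ids: dict[str, list[str]] = {}
    for ns, size in ns_sizes.items():
        ids, parents, names = _make_go_namespace(
            rng, ns, size, config.go_second_parent_prob, config.go_part_of_prob
        )
        ns_term_ids[ns] = ids
        terms.update(ids)
        go_parents.update(parents)
        go_names.update(names)
        go_namespaces.update({t: ns for t in ids})
    dag = GoDag(terms=terms, names=go_names, namespaces=go_namespaces,
                parent_edges=go_parents)

    go_assign: dict[str, set[str]] = {}
    ns_list = list(ns_sizes)
    ns_weights = [0.5, 0.3, 0.2]
    for protein in proteins:
        if rng.random() >= config.annotation_density * 0.75:
            continue
        assigned: set[str] = set()
        n_spaces = 2 if rng.random() < 0.3 else 1
        for ns in rng.choice(ns_list, size=n_spaces, replace=False, p=ns_weights):
            ids = ns_term_ids[ns]
            n_terms_here = 2 if rng.random() < 0.4 else 1
            for _ in range(n_terms_here):
                assigned.add(ids[int(rng.integers(1, len(ids)))])  # never the root
        go_assign[protein] = assigned
    go_records = [
        AnnotationRecord(protein_id=p, category_id=t, category_label=go_names[t],
                         category_group=go_namespaces[t], source="go")
        for p in sorted(go_assign) for t in sorted(go_assign[p])
    ]

    # --- KEGG --------------------------------------------------------------
    pathways = []
    for i in range(config.n_kegg_pathways):
        pclass, ptype = _KEGG_CLASSES[i % len(_KEGG_CLASSES)]
        pathways.append(
            {"name": f"Pathway {i + 1:02d}", "class": pclass, "type": ptype,
             "map_id": f"map{10 + i:05d}", "ko_id": f"K{100 + i:05d}"}
        )
    enzymes = [
        {"ec": f"1.1.{1 + i // 10}.{1 + i % 10}", "definition": f"synthetic enzyme {i + 1}"}
        for i in range(config.n_enzymes)
    ]
    # rows: (protein, ec, definition, pathway, class, type); EC-only rows keep
    # empty pathway cells to exercise the enzyme-definition fallback.
    kegg_rows: list[tuple[str, str, str, str, str, str]] = []
    kegg_pathway_assign: dict[str, dict] = {}
    kegg_ec_assign: dict[str, dict] = {}
    for protein in proteins:
        r = rng.random()
        if r < config.annotation_density * 0.5:
            pw = pathways[int(rng.integers(0, len(pathways)))]
            kegg_pathway_assign[protein] = pw
            if rng.random() < 0.8:
                enzyme = enzymes[int(rng.integers(0, len(enzymes)))]
                kegg_ec_assign[protein] = enzyme
                kegg_rows.append((protein, enzyme["ec"], enzyme["definition"],
                                  pw["name"], pw["class"], pw["type"]))
            else:
                kegg_rows.append((protein, "", "", pw["name"], pw["class"], pw["type"]))
        elif r < config.annotation_density * 0.5 + 0.15:
            enzyme = enzymes[int(rng.integers(0, len(enzymes)))]
            kegg_ec_assign[protein] = enzyme
            kegg_rows.append((protein, enzyme["ec"], enzyme["definition"], "", "", ""))
    kegg_records = []
    for protein, ec, definition, pname, pclass, ptype in kegg_rows:
        if ptype:
            kegg_records.append(AnnotationRecord(protein, ptype, ptype, "pathway_type", "kegg"))
        if pclass:
            kegg_records.append(AnnotationRecord(protein, pclass, pclass, "pathway_class", "kegg"))
        if pname:
            kegg_records.append(AnnotationRecord(protein, pname, pname, "pathway_name", "kegg"))
        if ec:
            kegg_records.append(AnnotationRecord(protein, ec, definition, "enzyme", "kegg"))

    ko_links = sorted(
        {(p, kegg_pathway_assign[p]["ko_id"]) for p in kegg_pathway_assign}
    )

    # --- eggNOG ------------------------------------------------------------
    eggnog_records = []
    for protein in proteins:
        letters_here = kog_assign.get(protein, [])
        gos_here = sorted(go_assign.get(protein, ()))
        pw = kegg_pathway_assign.get(protein)
        enzyme = kegg_ec_assign.get(protein)
        if not (letters_here or gos_here or pw or enzyme):
            continue
        eggnog_records.append(
            EggnogRecord(
                query=protein,
                cog_letters=tuple(letters_here),
                go_ids=frozenset(gos_here),
                kegg_kos=frozenset([pw["ko_id"]] if pw else []),
                kegg_pathways=frozenset(
                    [pw["map_id"], "ko" + pw["map_id"][3:]] if pw else []
                ),
                ec_numbers=frozenset([enzyme["ec"]] if enzyme else []),
            )
        )

    # --- gene models (GTF) -------------------------------------------------
    conversion_rows: list[tuple[str, str, str]] = []
    gtf_lines: list[str] = []
    pos = 1
    for i, protein in enumerate(proteins, start=1):
        gene, gene_name = f"gene_{i:05d}", f"g{i:05d}"
        n_isoforms = 2 if i % 20 == 0 else 1
        start, end = pos, pos + 999
        gtf_lines.append(
            f"chr1\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\t"
            f'gene_id "{gene}"; gene_name "{gene_name}";'
        )
        for iso in range(1, n_isoforms + 1):
            transcript = f"{gene}.t{iso}"
            gtf_lines.append(
                f"chr1\tsynthetic\ttranscript\t{start}\t{end}\t.\t+\t.\t"
                f'gene_id "{gene}"; gene_name "{gene_name}"; '
                f'transcript_id "{transcript}"; protein_id "{protein}";'
            )
            conversion_rows.append((gene_name, transcript, protein))
        pos += 1500
    gtf_text = "\n".join(gtf_lines) + "\n"

    # --- model-level ground-truth sets --------------------------------------
    closure = _ancestor_closure(go_parents)
    model_sets: dict[str, dict[str, set[str]]] = {
        "kog_letter": {}, "kog_class": {}, "go_bp": {}, "go_mf": {}, "go_cc": {},
        "kegg_type": {}, "kegg_class": {}, "kegg_name": {}, "kegg_enzyme": {},
        "eggnog_kegg_name": {},
    }
    for p, ls in kog_assign.items():
        for letter in ls:
            model_sets["kog_letter"].setdefault(letter, set()).add(p)
            cls = _kog.letter_class(letter) or "Unclassified"
            model_sets["kog_class"].setdefault(cls, set()).add(p)
    ns_kind = {"biological_process": "go_bp", "molecular_function": "go_mf",
               "cellular_component": "go_cc"}
    for p, ts in go_assign.items():
        for t in ts:
            for anc in closure[t]:
                model_sets[ns_kind[go_namespaces[anc]]].setdefault(anc, set()).add(p)
    for protein, ec, definition, pname, pclass, ptype in kegg_rows:
        if ptype:
            model_sets["kegg_type"].setdefault(ptype, set()).add(protein)
        if pclass:
            model_sets["kegg_class"].setdefault(pclass, set()).add(protein)
        if pname:
            model_sets["kegg_name"].setdefault(pname, set()).add(protein)
        if ec:
            model_sets["kegg_enzyme"].setdefault(ec, set()).add(protein)
    for p, pw in kegg_pathway_assign.items():
        model_sets["eggnog_kegg_name"].setdefault(pw["map_id"], set()).add(p)

    # --- query with planted enrichment --------------------------------------
    query, planted_info = _sample_query(rng, config, proteins, model_sets)

    truth = FixtureTruth(planted=planted_info, query=query)
    return SyntheticAnnotations(
        proteins=proteins,
        kog_records=kog_records,
        go_records=go_records,
        kegg_records=kegg_records,
        ko_links=ko_links,
        eggnog_records=eggnog_records,
        dag=dag,
        obo_text=_render_obo(terms, go_names, go_namespaces, go_parents),
        gtf_text=gtf_text,
        conversion_rows=conversion_rows,
        query=query,
        truth=truth,
        model_sets=model_sets,
    )


_PLANT_SEARCH_ORDER = ("kog_letter", "kog_class", "go_bp", "go_mf", "go_cc",
                       "kegg_name", "kegg_class", "kegg_type", "kegg_enzyme",
                       "eggnog_kegg_name")


def _sample_query(rng: np.random.Generator, config: FixtureConfig,
                  proteins: Sequence[str],
                  model_sets: dict[str, dict[str, set[str]]]):
    chosen: list[str] = []
    chosen_set: set[str] = set()
    planted_info: list[dict] = []
    locations: list[tuple[PlantedCategory, str, set[str], set[str]]] = []
    for planted in config.planted:
        kind = next(
            (k for k in _PLANT_SEARCH_ORDER if planted.category_id in model_sets[k]), None
        )
        if kind is None:
            raise FixtureConfigError(
                f"planted category {planted.category_id!r} was not generated by this config"
            )
        members = model_sets[kind][planted.category_id]
        background = set().union(*model_sets[kind].values())
        locations.append((planted, kind, members, background))

    for planted, kind, members, background in locations:
        K, N = len(members), len(background)
        if planted.fold > 1.0:
            frac = planted.query_fraction
            if frac is None:
                frac = min(1.0, planted.fold * K / N)
            available = sorted(members - chosen_set)
            m = min(int(round(frac * config.query_size)), len(available),
                    config.query_size - len(chosen))
            picks = rng.choice(available, size=m, replace=False) if m > 0 else []
            for p in picks:
                chosen.append(str(p))
                chosen_set.add(str(p))

    remaining = [p for p in proteins if p not in chosen_set]
    n_fill = config.query_size - len(chosen)
    if n_fill > len(remaining):
        raise FixtureConfigError("query_size exceeds the protein universe")
    if n_fill:
        for p in rng.choice(remaining, size=n_fill, replace=False):
            chosen.append(str(p))
            chosen_set.add(str(p))

    for planted, kind, members, background in locations:
        K, N = len(members), len(background)
        n = len(chosen_set & background)
        k = len(chosen_set & members)
        planted_info.append(
            {"category_id": planted.category_id, "model_kind": kind,
             "fold": planted.fold, "k": k, "K": K, "n": n, "N": N,
             "enriched": planted.fold > 1.0}
        )
    return chosen, planted_info


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _render_obo(terms, names, namespaces, parents) -> str:
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for term in sorted(terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {names[term]}")
        lines.append(f"namespace: {namespaces[term]}")
        for parent, relation in sorted(parents.get(term, ())):
            if relation == "is_a":
                lines.append(f"is_a: {parent} ! {names[parent]}")
            else:
                lines.append(f"relationship: part_of {parent} ! {names[parent]}")
        lines.append("")
    return "\n".join(lines)


def generate_fixture(config: FixtureConfig, out_dir: str | Path) -> FixtureTruth:
    """Write the full fixture bundle to ``out_dir`` and return its truth.

    Emits ``kog.tsv``, ``go.tsv``, ``ontology.obo``, ``kegg.tsv``,
    ``ko_link.tsv``, ``proteome.emapper.annotations``, ``genes.gtf``,
    ``query.txt`` and ``truth.json``; identical configurations produce
    byte-identical trees.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    syn = synthesize(config)

    kog_lines = ["#proteinId\tkogid\tkogdefline\tkogClass\tkogLetter"]
    for r in syn.kog_records:
        kog_lines.append(
            f"{r.protein_id}\tKOG{ord(r.category_id[0]):04d}\t{r.category_label}\t"
            f"{r.category_group}\t{r.category_id}"
        )
    go_lines = ["#proteinId\tgotermId\tgoName\tgotermType"]
    for r in syn.go_records:
        go_lines.append(f"{r.protein_id}\t{r.category_id}\t{r.category_label}\t{r.category_group}")

    # reconstruct one table row per protein from its axis records
    kegg_lines = ["#proteinId\tecNum\tdefinition\tpathway\tpathway_class\tpathway_type"]
    seen_rows: set[str] = set()
    per_protein: dict[str, dict[str, str]] = {}
    for r in syn.kegg_records:
        cells = per_protein.setdefault(
            r.protein_id, {"ec": "", "definition": "", "pathway": "", "class": "", "type": ""}
        )
        if r.category_group == "enzyme":
            cells["ec"], cells["definition"] = r.category_id, r.category_label
        elif r.category_group == "pathway_name":
            cells["pathway"] = r.category_id
        elif r.category_group == "pathway_class":
            cells["class"] = r.category_id
        elif r.category_group == "pathway_type":
            cells["type"] = r.category_id
    for protein in sorted(per_protein):
        c = per_protein[protein]
        line = f"{protein}\t{c['ec']}\t{c['definition']}\t{c['pathway']}\t{c['class']}\t{c['type']}"
        if line not in seen_rows:
            seen_rows.add(line)
            kegg_lines.append(line)

    ko_lines = [f"tre:{gene}\tko:{ko}" for gene, ko in syn.ko_links]

    egg_lines = [
        "## synthetic eggNOG-mapper style annotation",
        "#query\tseed_ortholog\tevalue\tscore\tCOG_category\tGOs\tEC\tKEGG_ko\tKEGG_Pathway",
    ]
    for rec in syn.eggnog_records:
        egg_lines.append("\t".join([
            rec.query,
            "synthetic.ortholog",
            "1e-50",
            "500.0",
            "".join(rec.cog_letters) or "-",
            ",".join(sorted(rec.go_ids)) or "-",
            ",".join(sorted(rec.ec_numbers)) or "-",
            ",".join(f"ko:{ko}" for ko in sorted(rec.kegg_kos)) or "-",
            ",".join(sorted(rec.kegg_pathways)) or "-",
        ]))

    files = {
        "kog": "kog.tsv",
        "go": "go.tsv",
        "obo": "ontology.obo",
        "kegg": "kegg.tsv",
        "ko_link": "ko_link.tsv",
        "eggnog": "proteome.emapper.annotations",
        "gtf": "genes.gtf",
        "query": "query.txt",
        "truth": "truth.json",
    }
    (out_dir / files["kog"]).write_text("\n".join(kog_lines) + "\n", encoding="utf-8")
    (out_dir / files["go"]).write_text("\n".join(go_lines) + "\n", encoding="utf-8")
    (out_dir / files["obo"]).write_text(syn.obo_text, encoding="utf-8")
    (out_dir / files["kegg"]).write_text("\n".join(kegg_lines) + "\n", encoding="utf-8")
    (out_dir / files["ko_link"]).write_text("\n".join(ko_lines) + "\n", encoding="utf-8")
    (out_dir / files["eggnog"]).write_text("\n".join(egg_lines) + "\n", encoding="utf-8")
    (out_dir / files["gtf"]).write_text(syn.gtf_text, encoding="utf-8")
    (out_dir / files["query"]).write_text("\n".join(syn.query) + "\n", encoding="utf-8")

    truth = syn.truth
    truth.files = {name: str(out_dir / rel) for name, rel in files.items()}
    (out_dir / files["truth"]).write_text(truth.to_json(), encoding="utf-8")
    return truth
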