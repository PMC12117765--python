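"""Enrichment models for a novel genome from eggNOG-mapper output.

When a genome has no curated functional annotation, eggNOG-mapper output
(COG letters, GO terms, KEGG KOs/pathways, EC numbers per query protein)
can stand in. One parse feeds all three model families; the KOG class
level comes from the canonical COG/KOG letter→class table.
"""

import tempfile

from mycoenrich import create_models_from_eggnog, enrich, parse_eggnog_annotation, parse_obo
from mycoenrich.fixtures import FixtureConfig, PlantedCategory, generate_fixture

with tempfile.TemporaryDirectory() as tmp:
    config = FixtureConfig(seed=5, n_proteins=800, query_size=50,
                           planted=(PlantedCategory("E", fold=4.0),))
    truth = generate_fixture(config, tmp)
    records = parse_eggnog_annotation(truth.files["eggnog"])
    dag = parse_obo(truth.files["obo"])
    bundle = create_models_from_eggnog(records, dag)
    query = open(truth.files["query"]).read().split()

    print(f"{len(records)} eggNOG query proteins ->")
    print(f"  KOG letter model: {len(bundle.kog_letter)} categories, "
          f"background {bundle.kog_letter.background_size}")
    print(f"  GO BP model:      {len(bundle.go.bp)} categories, "
          f"background {bundle.go.bp.background_size}")
    print(f"  KEGG pathways:    {len(bundle.kegg_name)} categories, "
          f"background {bundle.kegg_name.background_size}\n")
    top = enrich(bundle.kog_letter, query).results[0]
    print(f"top KOG category: {top.category_id} ({top.label}), "
          f"ratio {top.ratio:.2f}, adjusted p {top.p_adjusted:.3g}")
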