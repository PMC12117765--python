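"""Converting between gene names, transcript ids and protein ids.

Differential-expression output rarely uses the same identifier namespace
as the annotation model. A conversion table built from the gene models
(GTF here; GFF3 works the same) maps between the three namespaces;
unmapped ids are reported, never silently dropped.
"""

import tempfile

from mycoenrich import build_conversion_table, convert_ids
from mycoenrich.fixtures import FixtureConfig, generate_fixture

with tempfile.TemporaryDirectory() as tmp:
    truth = generate_fixture(FixtureConfig(seed=2, n_proteins=50, query_size=10), tmp)
    table = build_conversion_table(truth.files["gtf"], dialect="auto")
    print(f"conversion table: {len(table)} transcripts")

    transcripts = ["gene_00001.t1", "gene_00020.t1", "gene_00020.t2", "ghost.t1"]
    proteins, unmapped = convert_ids(transcripts, table, "transcript_id", "protein_id")
    print(f"{transcripts} -> {proteins}; unmapped: {unmapped}")

    # gene 20 has two isoforms sharing one protein: gene-level conversion
    # expands to every protein of the gene
    expanded, _ = convert_ids(["g00020"], table, "gene_name", "protein_id")
    print(f"gene g00020 -> proteins {expanded}")
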