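"""Bar and lollipop enrichment plots with significance stars.

Writes one bar plot grouped by KOG class and one lollipop plot to the
current directory. Labels carry the star convention: * for adjusted
p < 0.05, ** for < 0.01, *** for < 0.001; non-significant categories are
drawn in grey. SVG output is byte-deterministic.
"""

import tempfile

from mycoenrich import PlotSpec, create_kog_model, enrich, parse_kog_annotation, render_enrichment_plot
from mycoenrich.fixtures import FixtureConfig, PlantedCategory, generate_fixture

with tempfile.TemporaryDirectory() as tmp:
    config = FixtureConfig(seed=4, n_proteins=1000, query_size=60,
                           planted=(PlantedCategory("E", 4.0), PlantedCategory("C", 3.0)))
    truth = generate_fixture(config, tmp)
    model, _ = create_kog_model(parse_kog_annotation(truth.files["kog"]))
    report = enrich(model, open(truth.files["query"]).read().split())

    bar = render_enrichment_plot(
        report, PlotSpec(style="bar", group_rows=True, title="KOG enrichment"),
        "kog_enrichment_bar.svg")
    lolli = render_enrichment_plot(
        report, PlotSpec(style="lollipop", value_axis="neg_log10_padj", top_n=10),
        "kog_enrichment_lollipop.png")
    print(f"wrote {bar} and {lolli}")
    for r in report.results[:3]:
        from mycoenrich import significance_stars
        print(f"{r.label}: ratio {r.ratio:.2f}, p_adj {r.p_adjusted:.3g} "
              f"{significance_stars(r.p_adjusted)!r}")
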