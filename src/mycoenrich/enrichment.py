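"""Overrepresentation tests, multiple-testing adjustment, redundancy reduction.

Given a background model (N annotated proteins, K of them in a category) and
a query list (n mapped proteins, k of them in the category), enrichment is
quantified by the ratio (k/n)/(K/N) and tested with a one-sided
hypergeometric tail P(X >= k) — the probability of drawing at least k
category members in n draws without replacement — or, alternatively, a
chi-squared test of independence on the 2x2 table. Raw p-values are
adjusted for multiple testing (Benjamini-Hochberg by default) across the
*whole* category family of the model: categories absent from the query
still count toward the number of tests, since the background model defines
the hypothesis family.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import EnrichmentModel
from .ontology import GoDag, grouped_by_shared_ancestor

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "EnrichmentReport",
    "hypergeometric_pvalue",
    "chisquared_pvalue",
    "adjust_pvalues",
    "enrich",
    "reduce_go_redundancy",
    "write_report_tsv",
    "read_report_tsv",
]

CORRECTION_METHODS = {
    "BH": "fdr_bh",
    "bonferroni": "bonferroni",
    "holm": "holm",
    "BY": "fdr_by",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
    "none": None,
}

REPORT_COLUMNS = [
    "category_id",
    "label",
    "group",
    "k",
    "K",
    "n",
    "N",
    "ratio",
    "p_value",
    "p_adjusted",
    "query_hits",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Test outcome for one functional category."""

    category_id: str
    label: str
    group: str | None
    k: int  # query proteins in the category
    K: int  # background proteins in the category
    n: int  # mapped query size
    N: int  # background size
    ratio: float  # (k/n) / (K/N)
    p_value: float
    p_adjusted: float
    query_hits: frozenset[str] = field(default_factory=frozenset)


@dataclass
class EnrichmentReport:
    """Ordered results plus query-mapping bookkeeping.

    ``n_input = n_mapped + len(dropped_ids)`` always holds; ``dropped_ids``
    are query ids absent from the model's background universe.
    """

    results: list[EnrichmentResult]
    n_input: int
    n_mapped: int
    dropped_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category_id": r.category_id,
                "label": r.label,
                "group": r.group or "",
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "ratio": r.ratio,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "query_hits": ",".join(sorted(r.query_hits)),
            }
            for r in self.results
        ]
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _validate_counts(k: int, K: int, n: int, N: int) -> None:
    if min(k, K, n, N) < 0:
        raise ValueError(f"counts must be non-negative: k={k} K={K} n={n} N={N}")
    if not (k <= K <= N and k <= n <= N):
        raise ValueError(f"counts must satisfy k<=K<=N and k<=n<=N: k={k} K={K} n={n} N={N}")


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts category members among n proteins drawn without replacement
    from a background of N containing K category members. Computed via the
    survival function of ``scipy.stats.hypergeom`` and clamped to [0, 1];
    P(X >= 0) is exactly 1.
    """
    _validate_counts(k, K, n, N)
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(0.0, p))


def chisquared_pvalue(k: int, K: int, n: int, N: int, correction: bool = True) -> float:
    """Chi-squared test of independence on the 2x2 enrichment table.

    The table is [[k, n-k], [K-k, (N-K)-(n-k)]] (query vs rest, in-category
    vs out). Yates continuity correction is applied by default. The test is
    inherently two-sided; direction should be read off the enrichment
    ratio. Degenerate tables (any expected cell 0) return p = 1 with a
    warning.
    """
    _validate_counts(k, K, n, N)
    table = np.array([[k, n - k], [K - k, (N - K) - (n - k)]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.warning("degenerate 2x2 table for (k=%d, K=%d, n=%d, N=%d); p set to 1", k, K, n, N)
        return 1.0
    result = stats.chi2_contingency(table, correction=correction)
    return float(result.pvalue)


def adjust_pvalues(ps: Sequence[float], method: str = "BH") -> list[float]:
    """Multiple-testing adjustment, aligned to the input order.

    ``method`` is one of BH, bonferroni, holm, BY, hochberg, hommel, none —
    matching the classical definitions (and R's ``p.adjust`` semantics).
    """
    ps = list(ps)
    if method not in CORRECTION_METHODS:
        raise ValueError(f"unknown correction method {method!r}")
    for p in ps:
        if not (0.0 <= p <= 1.0) or math.isnan(p):
            raise ValueError(f"p-value out of [0, 1]: {p!r}")
    if method == "none" or not ps:
        return ps
    adjusted = multipletests(ps, method=CORRECTION_METHODS[method])[1]
    return [float(q) for q in adjusted]


def enrich(
    model: EnrichmentModel,
    query: Iterable[str],
    test: str = "hypergeometric",
    correction: str = "BH",
    chi_continuity_correction: bool = True,
) -> EnrichmentReport:
    """Test every model category for overrepresentation in a query set.

    The query is deduplicated and intersected with the model's background;
    unmapped ids are recorded, not fatal. Categories with no query hits are
    omitted from the report but still count toward the number of tests used
    by the correction. Results are sorted by adjusted p, then category id.
    An empty mapped query yields an empty report with a warning.
    """
    if test not in ("hypergeometric", "chisquared"):
        raise ValueError(f"unknown test {test!r}")
    if len(model) == 0:
        raise ValueError("cannot run enrichment against an empty model")
    query_set = {q.strip() for q in query if q and q.strip()}
    background = model.background
    mapped = query_set & background
    dropped = sorted(query_set - background)
    n, N = len(mapped), len(background)
    if n == 0:
        log.warning("no query ids mapped to the %s background (%d supplied)",
                    model.model_kind, len(query_set))
        return EnrichmentReport(results=[], n_input=len(query_set), n_mapped=0,
                                dropped_ids=dropped)

    cat_ids = sorted(model.categories)
    ks, ps = [], []
    for cat_id in cat_ids:
        entry = model.categories[cat_id]
        k = len(entry.proteins & mapped)
        K = entry.count
        if test == "hypergeometric":
            p = hypergeometric_pvalue(k, K, n, N)
        else:
            p = chisquared_pvalue(k, K, n, N, correction=chi_continuity_correction)
        ks.append(k)
        ps.append(p)
    adjusted = adjust_pvalues(ps, method=correction)

    results = []
    for cat_id, k, p, q in zip(cat_ids, ks, ps, adjusted):
        if k == 0:
            continue  # skipped from the report; already counted toward m
        entry = model.categories[cat_id]
        ratio = (k / n) / (entry.count / N)
        results.append(
            EnrichmentResult(
                category_id=cat_id,
                label=entry.label,
                group=entry.group,
                k=k,
                K=entry.count,
                n=n,
                N=N,
                ratio=ratio,
                p_value=p,
                p_adjusted=q,
                query_hits=frozenset(entry.proteins & mapped),
            )
        )
    results.sort(key=lambda r: (r.p_adjusted, r.category_id))
    return EnrichmentReport(results=results, n_input=len(query_set), n_mapped=n,
                            dropped_ids=dropped)


def reduce_go_redundancy(
    report: EnrichmentReport,
    dag: GoDag,
    depth_limit: int,
    alpha: float = 0.05,
) -> EnrichmentReport:
    """Collapse redundant significant GO terms to one representative each.

    Rows with adjusted p <= ``alpha`` are partitioned into groups of terms
    sharing a common ancestor within ``depth_limit`` upward hops of each
    member; only the most significant row per group survives (ties: smaller
    raw p, then lexicographic id). Rows above ``alpha`` are dropped.
    Adjusted p-values are *not* recomputed after reduction. All rows must
    belong to one GO namespace.
    """
    significant = [r for r in report.results if r.p_adjusted <= alpha]
    if not significant:
        return EnrichmentReport(results=[], n_input=report.n_input,
                                n_mapped=report.n_mapped, dropped_ids=list(report.dropped_ids))
    namespaces = {dag.namespace(r.category_id) for r in significant}
    if len(namespaces) > 1:
        raise ValueError(f"report mixes GO namespaces: {sorted(namespaces)}")
    by_id = {dag.resolve(r.category_id): r for r in significant}
    blocks = grouped_by_shared_ancestor(dag, by_id.keys(), depth_limit)
    survivors = [
        min((by_id[t] for t in block),
            key=lambda r: (r.p_adjusted, r.p_value, r.category_id))
        for block in blocks
    ]
    survivors.sort(key=lambda r: (r.p_adjusted, r.category_id))
    return EnrichmentReport(results=survivors, n_input=report.n_input,
                            n_mapped=report.n_mapped, dropped_ids=list(report.dropped_ids))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_report_tsv(report: EnrichmentReport, path: str | Path) -> None:
    """Write a report as TSV plus a ``<path>.meta.json`` mapping sidecar."""
    path = Path(path)
    frame = report.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "n_input": report.n_input,
        "n_mapped": report.n_mapped,
        "n_dropped": len(report.dropped_ids),
        "dropped_ids": sorted(report.dropped_ids),
    }
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_report_tsv(path: str | Path) -> EnrichmentReport:
    """Load a report written by :func:`write_report_tsv`."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"category_id": str}, keep_default_na=False)
    results = [
        EnrichmentResult(
            category_id=str(row["category_id"]),
            label=str(row["label"]),
            group=str(row["group"]) or None,
            k=int(row["k"]),
            K=int(row["K"]),
            n=int(row["n"]),
            N=int(row["N"]),
            ratio=float(row["ratio"]),
            p_value=float(row["p_value"]),
            p_adjusted=float(row["p_adjusted"]),
            query_hits=frozenset(str(row["query_hits"]).split(",")) if row["query_hits"] else frozenset(),
        )
        for _, row in frame.iterrows()
    ]
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        n_input = meta["n_input"]
        n_mapped = meta["n_mapped"]
        dropped = list(meta["dropped_ids"])
    else:
        n_mapped = results[0].n if results else 0
        n_input, dropped = n_mapped, []
    return EnrichmentReport(results=results, n_input=n_input, n_mapped=n_mapped,
                            dropped_ids=dropped)
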