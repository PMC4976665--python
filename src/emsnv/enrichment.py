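"""Term enrichment for a study gene set against a population.

A generic upper-tail hypergeometric test over a user-supplied gene->term
map (e.g. GO annotations exported from any source), with Benjamini-
Hochberg false-discovery-rate correction across the tested terms. No
ontology structure is assumed: terms are opaque identifiers.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int  # study genes carrying the term
    n: int  # study size
    K: int  # population genes carrying the term
    N: int  # population size
    p: float
    q: float


def read_gene2term(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read a gene->term TSV with columns gene_id, term_id, term_name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: gene2term file needs columns {sorted(required)}")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    out: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for row in df.itertuples(index=False):
        out[row.gene_id].append((row.term_id, str(row.term_name)))
    return dict(out)


def hypergeom_enrichment(
    study: set[str] | list[str],
    gene2term: dict[str, list[tuple[str, str]]],
    population: set[str] | list[str] | None = None,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of each term in the study set.

    p = P(X >= k) for X ~ Hypergeom(N, K, n). The population defaults to
    all genes in the annotation map; study genes must be drawn from it.
    Terms annotated to no population gene are skipped; rows come back
    sorted by p then term id, with BH-adjusted q values.
    """
    if population is None:
        population = set(gene2term)
    population = set(population)
    study = set(study)
    if not study <= population:
        missing = sorted(study - population)[:5]
        raise ValueError(f"study genes absent from population: {missing} ...")

    term_pop: dict[str, set[str]] = defaultdict(set)
    term_study: dict[str, set[str]] = defaultdict(set)
    term_names: dict[str, str] = {}
    for gene, terms in gene2term.items():
        if gene not in population:
            continue
        for term_id, term_name in terms:
            term_pop[term_id].add(gene)
            term_names.setdefault(term_id, term_name)
            if gene in study:
                term_study[term_id].add(gene)

    N, n = len(population), len(study)
    raw = []
    for term_id, pop_genes in sorted(term_pop.items()):
        K = len(pop_genes)
        if K == 0:
            continue
        k = len(term_study.get(term_id, ()))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        raw.append((term_id, k, K, min(p, 1.0)))
    if not raw:
        return []
    qvals = multipletests([p for _, _, _, p in raw], method="fdr_bh")[1]
    rows = [
        EnrichmentRow(
            term_id=term_id,
            term_name=term_names[term_id],
            k=k, n=n, K=K, N=N, p=p, q=float(q),
        )
        for (term_id, k, K, p), q in zip(raw, qvals)
    ]
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "q": r.q,
            }
            for r in rows
        ],
        columns=["term_id", "term_name", "k", "n", "K", "N", "p", "q"],
    )
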