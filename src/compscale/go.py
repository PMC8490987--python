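"""GO term enrichment with true-path (ancestor) propagation.

Annotations are closed over the is_a DAG (every gene annotated to a term is
implicitly annotated to all its ancestors), then each term is tested with a
classic one-sided hypergeometric test of gene membership in a set of
interest against a compartment-specific background.  Terms annotating more
than a namespace-specific number of background genes are excluded *before*
testing, and the top-k records sorted by fold enrichment are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .rnaseq import bh_adjust


@dataclass
class GoDag:
    """An is_a DAG over GO-like terms with namespaces."""

    graph: nx.DiGraph            # edges child -> parent
    namespaces: pd.Series        # term -> namespace

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GoDag":
        """Build from a (term, parent, namespace) table; empty parent = root."""
        g = nx.DiGraph()
        ns = {}
        for _, row in table.iterrows():
            term = row["term"]
            g.add_node(term)
            ns[term] = row["namespace"]
            parent = row.get("parent", "")
            if isinstance(parent, str) and parent:
                g.add_edge(term, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("GO relation graph contains a cycle")
        return cls(graph=g, namespaces=pd.Series(ns))

    def ancestors(self, term: str) -> set[str]:
        return set(nx.descendants(self.graph, term))  # edges point rootward


def propagate(dag: GoDag, annotations: pd.DataFrame) -> dict[str, set[str]]:
    """Ancestor-closed term sets per gene (idempotent).

    ``annotations`` has columns gene, term; every annotated term must exist
    in the DAG.
    """
    closure_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.groupby("gene")["term"]:
        closed: set[str] = set()
        for term in terms:
            if term not in dag.graph:
                raise ValueError(f"annotated term {term!r} missing from DAG")
            if term not in closure_cache:
                closure_cache[term] = {term} | dag.ancestors(term)
            closed |= closure_cache[term]
        out[gene] = closed
    return out


def term_enrichment(
    gene_set: set[str],
    background: set[str],
    dag: GoDag,
    annotations: pd.DataFrame,
    namespace: str | None = None,
    max_annotated: int | None = None,
) -> pd.DataFrame:
    """Classic hypergeometric enrichment per term.

    For each term: x = set genes annotated (after propagation), n = |set|,
    K = background genes annotated, N = |background|.  Terms with
    K > ``max_annotated`` are excluded before testing.  Records are sorted
    by fold enrichment (observed / expected).
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise ValueError("gene set must be contained in the background")
    closure = propagate(dag, annotations[annotations["gene"].isin(background)])
    term_genes: dict[str, set[str]] = {}
    for gene, terms in closure.items():
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    n = len(gene_set)
    N = len(background)
    rows = []
    for term, genes in sorted(term_genes.items()):
        if namespace is not None and dag.namespaces.get(term) != namespace:
            continue
        K = len(genes)
        if max_annotated is not None and K > max_annotated:
            continue
        x = len(genes & gene_set)
        expected = n * K / N
        fe = (x / expected) if expected > 0 else np.nan
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        rows.append({"term": term, "namespace": dag.namespaces.get(term),
                     "x": x, "n": n, "K": K, "N": N,
                     "FE": fe, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["FE", "term"], ascending=[False, True]).reset_index(
        drop=True)


def top_terms(records: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k records per namespace, sorted by fold enrichment."""
    if records.empty:
        return records
    return (records.sort_values(["namespace", "FE"], ascending=[True, False])
            .groupby("namespace", sort=True).head(k).reset_index(drop=True))
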