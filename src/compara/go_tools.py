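"""GO ontology utilities: level-3 rollup profiles and hypergeometric enrichment.

The ontology is read from OBO (is_a edges only, part_of ignored) into a DAG.
A term's level is 1 + the length of the SHORTEST is_a path to its namespace
root (root = level 1), the convention of level-based functional profiling.
Annotation rollup propagates each annotated term to all of its level-k
ancestors; because the ontology is a DAG a gene can legitimately contribute
to more than one level-k term, so per-namespace fractions may sum above 1.

Enrichment of a study set against a population uses the upper-tail
hypergeometric probability P(X >= k) for each term with k >= 1 study genes,
after propagating annotations to all ancestors.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import networkx as nx
import obonet
import pandas as pd
from scipy import stats


@dataclass
class GOGraph:
    """is_a DAG over GO terms; edges point child -> parent."""

    graph: nx.DiGraph
    roots: dict[str, str]  # namespace -> root term id

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term]["namespace"]

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of a term (term itself excluded)."""
        return nx.descendants(self.graph, term)


def load_obo(source) -> GOGraph:
    """Parse a minimal OBO document (path, handle, or text) into a GOGraph.

    Cycles are a hard error; terms lacking a namespace are a parse error
    naming the stanza; orphan terms (no path to their namespace root) get a
    warning attribute but load fine.
    """
    if isinstance(source, str) and "\n" in source:
        source = _io.StringIO(source)
    multi = obonet.read_obo(source)
    g = nx.DiGraph()
    for term, data in multi.nodes(data=True):
        if "namespace" not in data:
            raise ValueError(f"OBO stanza for term {term} is missing a namespace")
        g.add_node(term, name=data.get("name", term), namespace=data["namespace"])
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"is_a cycle detected in ontology: {cycle}")
    roots: dict[str, str] = {}
    for term, data in g.nodes(data=True):
        if g.out_degree(term) == 0:
            ns = data["namespace"]
            if ns in roots:
                raise ValueError(f"namespace {ns} has multiple roots "
                                 f"({roots[ns]}, {term})")
            roots[ns] = term
    return GOGraph(graph=g, roots=roots)


def term_level(go: GOGraph, term: str) -> int:
    """1 + shortest is_a path length to the namespace root (root = level 1)."""
    if term not in go.graph:
        raise KeyError(f"term {term} not in ontology")
    root = go.roots.get(go.namespace(term))
    if root is None:
        raise ValueError(f"no root for namespace {go.namespace(term)}")
    try:
        return 1 + nx.shortest_path_length(go.graph, term, root)
    except nx.NetworkXNoPath:
        raise ValueError(f"term {term} cannot reach namespace root {root}") from None


def terms_at_level(go: GOGraph, level: int) -> set[str]:
    return {t for t in go.graph.nodes if term_level(go, t) == level}


def propagate_annotations(annotations: dict[str, set], go: GOGraph):
    """Extend each gene's term set with all is_a ancestors.

    Terms absent from the ontology are skipped; returns
    ``(propagated dict, n_skipped_terms)``.
    """
    out: dict[str, set] = {}
    skipped = 0
    for gene, terms in annotations.items():
        full: set[str] = set()
        for t in terms:
            if t not in go.graph:
                skipped += 1
                continue
            full.add(t)
            full |= go.ancestors(t)
        out[gene] = full
    return out, skipped


def rollup_to_level(annotations: dict[str, set], go: GOGraph,
                    level: int = 3) -> pd.DataFrame:
    """Per-namespace level-k profile of an annotation set.

    Each gene counts once toward every level-k ancestor (or the term itself
    if at level k) of any of its annotations; fractions are over the number
    of genes with at least one in-ontology annotation in that namespace.
    """
    if level < 2:
        raise ValueError("rollup level must be >= 2")
    level_terms = terms_at_level(go, level)
    propagated, _ = propagate_annotations(annotations, go)
    genes_per_term: dict[str, set] = {}
    ns_genes: dict[str, set] = {}
    for gene, terms in propagated.items():
        for t in terms:
            ns_genes.setdefault(go.namespace(t), set()).add(gene)
            if t in level_terms:
                genes_per_term.setdefault(t, set()).add(gene)
    rows = []
    for t in sorted(genes_per_term):
        ns = go.namespace(t)
        n = len(genes_per_term[t])
        rows.append({"namespace": ns, "term_id": t, "term_name": go.name(t),
                     "level": level, "n_genes": n,
                     "fraction": n / len(ns_genes[ns])})
    return pd.DataFrame(rows, columns=["namespace", "term_id", "term_name",
                                       "level", "n_genes", "fraction"])


def hypergeometric_enrichment(study: set, population: set,
                              annotations: dict[str, set], go: GOGraph,
                              alpha: float = 0.05,
                              bh_correct: bool = False) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a study set within a population.

    For each term carried (after ancestor propagation) by k >= 1 study genes,
    p = P(X >= k) with X ~ Hypergeom(N population genes, K carriers, n study
    genes). No multiple-testing correction by default; ``bh_correct`` adds a
    Benjamini-Hochberg q-value column.
    """
    study, population = set(study), set(population)
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    propagated, _ = propagate_annotations(
        {g: annotations.get(g, set()) for g in population}, go)
    N, n = len(population), len(study)
    carriers: dict[str, set] = {}
    for gene, terms in propagated.items():
        for t in terms:
            carriers.setdefault(t, set()).add(gene)
    rows = []
    for t, genes in carriers.items():
        k = len(genes & study)
        if k == 0:
            continue
        K = len(genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": t, "term_name": go.name(t),
                     "namespace": go.namespace(t), "k": k, "n": n, "K": K,
                     "N": N, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "namespace",
                                     "k", "n", "K", "N", "p_value"])
    if df.empty:
        df["significant"] = pd.Series(dtype=bool)
        return df
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    if bh_correct:
        m = len(df)
        ranked = df["p_value"].to_numpy() * m / (pd.RangeIndex(1, m + 1).to_numpy())
        q = pd.Series(ranked[::-1]).cummin()[::-1].to_numpy()
        df["q_value"] = q.clip(max=1.0)
        df["significant"] = df["q_value"] < alpha
    else:
        df["significant"] = df["p_value"] < alpha
    return df
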