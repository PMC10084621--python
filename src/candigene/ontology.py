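"""GO annotation transfer, true-path propagation, hypergeometric enrichment
and level-based functional categorization.

Annotation transfer follows a conservative cross-species consensus rule: a
target gene inherits a GO-term set S only if genes with the same normalized
name carry EXACTLY the set S in at least ``min_species`` distinct reference
insect species. Enrichment uses the hypergeometric upper tail against the
annotated background within each namespace, with Benjamini-Hochberg FDR per
namespace.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import OntologyGraph, ValidationError

logger = logging.getLogger("candigene")

_PUNCT = re.compile(r"[^a-z0-9 ]+")


@dataclass
class TransferRule:
    min_species: int = 3
    require_identical_sets: bool = True

    def __post_init__(self) -> None:
        if self.min_species < 1:
            raise ValueError("min_species must be >= 1")


def normalize_gene_name(name: str) -> str:
    """Lowercase, strip punctuation and a trailing '-like' suffix."""
    s = str(name).strip().lower()
    s = re.sub(r"[-\s]+like$", "", s)
    s = _PUNCT.sub(" ", s)
    return " ".join(s.split())


def transfer_annotations(target_genes: pd.DataFrame, reference: pd.DataFrame,
                         rule: TransferRule | None = None) -> dict[str, set[str]]:
    """Assign GO sets to target genes by the >= min_species consensus rule.

    ``target_genes`` needs columns ``gene`` and ``name``; ``reference`` is the
    table from :func:`candigene.io.read_reference`. A target receives set S
    iff at least ``min_species`` distinct species have a same-named gene
    annotated with exactly S. If several sets qualify, the one supported by
    the most species wins (ties broken by sorted set representation, for
    determinism). Unmatched genes are left unannotated.
    """
    rule = rule or TransferRule()
    if reference.empty:
        raise ValidationError("reference annotation table is empty")
    # normalized name -> frozenset(GO) -> set of species
    support: dict[str, dict[frozenset, set[str]]] = {}
    for row in reference.itertuples(index=False):
        key = normalize_gene_name(row.gene_name)
        support.setdefault(key, {}).setdefault(frozenset(row.go_terms), set()).add(row.species)

    out: dict[str, set[str]] = {}
    for row in target_genes.itertuples(index=False):
        key = normalize_gene_name(row.name)
        candidates = []
        for go_set, species in support.get(key, {}).items():
            if len(species) >= rule.min_species:
                candidates.append((len(species), tuple(sorted(go_set)), go_set))
        if candidates:
            candidates.sort(key=lambda c: (-c[0], c[1]))
            out[row.gene] = set(candidates[0][2])
    return out


def propagate(ann: dict[str, set[str]], onto: OntologyGraph) -> dict[str, set[str]]:
    """Close every gene's annotation under is_a ancestry (true-path rule).

    Idempotent; terms absent from the ontology are dropped with a warning.
    """
    cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in ann.items():
        closed: set[str] = set()
        for t in terms:
            if t not in onto.terms:
                logger.warning("propagate: term %s (gene %s) absent from ontology", t, gene)
                continue
            if t not in cache:
                cache[t] = {t} | onto.ancestors(t)
            closed |= cache[t]
        if closed:
            out[gene] = closed
    return out


def enrich(candidates: set[str], background: set[str], ann: dict[str, set[str]],
           onto: OntologyGraph, fdr: float = 0.05,
           min_term_size: int = 3) -> pd.DataFrame:
    """Hypergeometric GO-term enrichment of candidates against background.

    Per namespace: the universe is the ANNOTATED background genes of that
    namespace; every term with K >= min_term_size background genes and k >= 1
    candidate genes is tested with p = P(X >= k) under Hypergeom(N, K, n);
    BH correction is applied within the namespace. Returns the full table
    sorted by p-value, with an ``enriched`` flag for fdr < threshold.
    """
    if not candidates <= background:
        raise ValidationError("candidate set must be a subset of the background")
    rows = []
    for namespace in sorted({ns for _, ns in onto.terms.values()}):
        ns_terms = {t for t, (_, ns) in onto.terms.items() if ns == namespace}
        bg = {g for g in background if g in ann and (ann[g] & ns_terms)}
        cand = candidates & bg
        if not bg:
            continue
        term_to_bg: dict[str, int] = {}
        term_to_cand: dict[str, int] = {}
        for g in bg:
            for t in ann[g] & ns_terms:
                term_to_bg[t] = term_to_bg.get(t, 0) + 1
                if g in cand:
                    term_to_cand[t] = term_to_cand.get(t, 0) + 1
        n_bg, n_cand = len(bg), len(cand)
        for term, K in sorted(term_to_bg.items()):
            k = term_to_cand.get(term, 0)
            if K < min_term_size or k < 1:
                continue
            p = float(hypergeom.sf(k - 1, n_bg, K, n_cand))
            rows.append({
                "term": term, "name": onto.terms[term][0], "namespace": namespace,
                "k": k, "K": K, "n": n_cand, "N_bg": n_bg, "p_value": min(p, 1.0),
            })
    if not rows:
        logger.warning("enrich: nothing to test (empty candidate set or no annotations)")
        return pd.DataFrame(columns=["term", "name", "namespace", "k", "K", "n",
                                     "N_bg", "p_value", "fdr", "enriched"])
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    for namespace in table["namespace"].unique():
        mask = table["namespace"] == namespace
        table.loc[mask, "fdr"] = multipletests(table.loc[mask, "p_value"],
                                               method="fdr_bh")[1]
    table["enriched"] = table["fdr"] < fdr
    return table.sort_values(["p_value", "term"]).reset_index(drop=True)


def term_depths(onto: OntologyGraph, namespace: str) -> dict[str, int]:
    """Shortest is_a path length from the namespace root(s) per term."""
    import networkx as nx

    roots = onto.roots(namespace)
    depths: dict[str, int] = {}
    rev = onto.graph.reverse(copy=False)  # parent -> child
    for root in roots:
        for term, d in nx.single_source_shortest_path_length(rev, root).items():
            if term not in depths or d < depths[term]:
                depths[term] = d
    return depths


def categorize(genes: set[str], ann: dict[str, set[str]], onto: OntologyGraph,
               level: int = 2) -> pd.DataFrame:
    """WEGO-style functional categorization: per namespace, count genes whose
    propagated annotation reaches each term at the given depth from the root.
    A gene with several level-``level`` ancestors counts in each of them.
    """
    rows = []
    for namespace in sorted({ns for _, ns in onto.terms.values()}):
        depths = term_depths(onto, namespace)
        level_terms = sorted(t for t, d in depths.items() if d == level)
        for term in level_terms:
            count = sum(1 for g in genes if term in ann.get(g, ()))
            rows.append({"namespace": namespace, "term": term,
                         "name": onto.terms[term][0], "n_genes": count})
    return pd.DataFrame(rows, columns=["namespace", "term", "name", "n_genes"])
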