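"""Hypergeometric over-representation analysis (ORA) with BH-FDR control.

A local stand-in for web-service GO enrichment: given a query gene list
and a GMT collection of annotated sets, each set is scored by the
upper-tail hypergeometric probability of the observed overlap, with
Benjamini-Hochberg correction across all sets tested. The background
universe defaults to the genes that survived the expression pipeline
(the selection-consistent background), not the whole genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with categories, intersected with a universe."""

    sets: dict[str, set[str]]
    universe: set[str]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        trimmed = {}
        for name, genes in self.sets.items():
            inter = set(genes) & self.universe
            if inter:
                trimmed[name] = inter
            else:
                logger.info("gene set %r has no genes in the universe; dropped", name)
        self.sets = trimmed

    @classmethod
    def from_gmt(cls, path, universe: set[str]) -> "GeneSetCollection":
        """Read a GMT file (set name <tab> description <tab> genes...)."""
        sets, categories = {}, {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                name, desc, genes = parts[0], parts[1], parts[2:]
                sets[name] = set(g for g in genes if g)
                categories[name] = desc
        return cls(sets=sets, universe=universe, categories=categories)


def ora(query_genes, collection: GeneSetCollection) -> pd.DataFrame:
    """Over-representation of the query in each gene set.

    p = P(X >= k) for X ~ Hypergeometric(N, K, n) with N the universe size,
    K the set size, n the query size and k the overlap; q is BH-FDR across
    all sets. Query genes outside the universe are dropped (counted in the
    log). Rows are sorted by ascending p.
    """
    query = set(query_genes)
    dropped = query - collection.universe
    if dropped:
        logger.info("%d query genes outside the universe dropped", len(dropped))
    query &= collection.universe
    if not query:
        raise ValueError("query is empty after intersection with the universe")

    n_universe = len(collection.universe)
    n_query = len(query)
    rows = []
    for name, genes in collection.sets.items():
        k = len(query & genes)
        K = len(genes)
        p = float(hypergeom.sf(k - 1, n_universe, K, n_query))
        rows.append(
            {
                "set": name,
                "category": collection.categories.get(name, ""),
                "overlap": k,
                "set_size": K,
                "query_size": n_query,
                "universe_size": n_universe,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    return table
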