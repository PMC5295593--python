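"""Functional-category over-representation analysis.

A FunCat-style test: for each category, a one-sided Fisher exact test
(hypergeometric upper tail) asks whether the query gene list contains
more members of the category than expected from the genome background,
followed by Benjamini-Hochberg adjustment across the categories tested.
Query genes without any category annotation are dropped (and counted),
mirroring how only genes with a known function or domain enter such an
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from scipy import stats
from statsmodels.stats.multitest import multipletests

from aimchip.models import EnrichmentResult

logger = logging.getLogger(__name__)


@dataclass
class CategoryMap:
    """gene -> categories mapping over a defined background."""

    gene_categories: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def background(self) -> frozenset[str]:
        return frozenset(g for g, cats in self.gene_categories.items() if cats)

    @property
    def categories(self) -> frozenset[str]:
        out: set[str] = set()
        for cats in self.gene_categories.values():
            out.update(cats)
        return frozenset(out)

    def genes_in(self, category: str) -> frozenset[str]:
        return frozenset(
            g for g, cats in self.gene_categories.items() if category in cats
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CategoryMap":
        """Read a two-column TSV: gene <tab> category (one row per pair)."""
        mapping: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                gene, category = line.split("\t")[:2]
                mapping.setdefault(gene, set()).add(category)
        return cls({g: frozenset(c) for g, c in mapping.items()})


def enrich(
    query_genes: set[str] | list[str],
    category_map: CategoryMap,
    min_category_size: int = 2,
) -> tuple[list[EnrichmentResult], int]:
    """Over-representation of each category in the query gene list.

    Returns (results sorted by p, number of query genes dropped for
    lacking any category annotation).  A gene belonging to several
    categories counts once in each.  p is the hypergeometric upper tail
    P(X >= k); q is Benjamini-Hochberg across the tested categories.
    """
    background = category_map.background
    query = set(query_genes)
    dropped = len(query - background)
    query &= background
    if dropped:
        logger.info("enrich: dropped %d query genes without categories", dropped)
    if not query:
        raise ValueError("no query genes remain after dropping unannotated genes")

    N = len(background)
    n = len(query)
    tested = []
    for category in sorted(category_map.categories):
        members = category_map.genes_in(category)
        K = len(members)
        if K < min_category_size:
            continue
        k = len(members & query)
        # upper tail P(X >= k) of Hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        tested.append((category, k, n, K, N, min(p, 1.0)))
    if not tested:
        return [], dropped
    pvals = [t[5] for t in tested]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(cat, k, n, K, N, p, float(q))
        for (cat, k, n, K, N, p), q in zip(tested, qvals)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.category)), dropped
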