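"""Gene-set over-representation analysis (hypergeometric test).

A generic replacement for web-service enrichment tools: given a query gene
list, a measurement universe and a GMT collection of gene sets, each set is
scored with the upper-tail hypergeometric probability of observing at
least the seen overlap, followed by Benjamini-Hochberg adjustment across
sets.  Gene sets are intersected with the universe before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    table: pd.DataFrame             # per set: overlap, set_size, p, p_adjusted
    universe_size: int
    query_size: int

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> pd.DataFrame:
        col = "p_adjusted" if adjusted else "p"
        return self.table[self.table[col] < alpha]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, tab-separated
    ``name <tab> description <tab> member...``."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, members): {line[:80]}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def ora_enrichment(
    query: set[str] | list[str],
    universe: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``query`` in each gene set.

    ``query`` must be a subset of ``universe``; gene sets are clipped to
    the universe.  For a universe of M genes, a clipped set of K and a
    query of n genes with overlap k, p = P(X >= k), X ~ Hypergeom(M, K, n).
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError(f"{len(query - universe)} query genes are not in the universe")
    m = len(universe)
    n = len(query)
    rows = []
    for name, members in gene_sets.items():
        clipped = members & universe
        k = len(clipped & query)
        p = float(hypergeom.sf(k - 1, m, len(clipped), n)) if clipped else 1.0
        rows.append((name, k, len(clipped), min(max(p, 0.0), 1.0)))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"]).set_index("set")
    if len(table):
        table["p_adjusted"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values("p")
    else:
        table["p_adjusted"] = []
    return EnrichmentResult(table=table, universe_size=m, query_size=n)
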