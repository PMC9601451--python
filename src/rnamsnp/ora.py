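"""Gene-set over-representation analysis (hypergeometric / one-sided Fisher).

For a query of n genes drawn from a universe of N, a set containing K
universe genes and an overlap of k, the enrichment p-value is the
hypergeometric upper tail ``P(X >= k)`` — identical to the one-sided Fisher
exact test on the 2x2 overlap table.  Benjamini-Hochberg correction is
applied across the sets tested.  The default universe is the union of all
genes in the collection; an explicit universe overrides it.  An EASE-style
conservative mode (tail computed at k-1) is available behind a flag.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = ["ora_test"]


def ora_test(
    query,
    gene_sets: GeneSetCollection,
    universe=None,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Returns one row per set with overlap count ``k``, query size ``n``,
    set size ``K``, universe size ``N``, ``p`` (hypergeometric upper tail),
    BH-adjusted ``q`` and the overlapping genes, sorted by p ascending.
    Query genes outside the universe are dropped with a warning; an empty
    query is an error.
    """
    query = {str(g).upper() for g in query}
    if not query:
        raise ValueError("empty query gene list")
    if universe is not None:
        universe = frozenset(str(g).upper() for g in universe)
    elif gene_sets.universe is not None:
        universe = gene_sets.universe
    else:
        universe = gene_sets.all_genes()
    dropped = query - universe
    if dropped:
        warnings.warn(f"{len(dropped)} query gene(s) outside the universe dropped: "
                      f"{sorted(dropped)[:5]}{'...' if len(dropped) > 5 else ''}")
    query &= universe
    if not query:
        raise ValueError("no query gene lies in the universe")

    N = len(universe)
    n = len(query)
    rows = []
    for name, genes in gene_sets.sets.items():
        members = genes & universe
        K = len(members)
        overlap = sorted(query & members)
        k = len(overlap)
        k_eff = max(k - 1, 0) if ease else k
        p = float(stats.hypergeom.sf(k_eff - 1, N, K, n)) if k_eff > 0 else 1.0
        rows.append(
            {
                "set": name,
                "k_overlap": k,
                "n_query": n,
                "K_set": K,
                "N_universe": N,
                "p": min(p, 1.0),
                "genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows, columns=["set", "k_overlap", "n_query", "K_set", "N_universe", "p", "genes"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
        out = out[["set", "k_overlap", "n_query", "K_set", "N_universe", "p", "q", "genes"]]
    return out
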