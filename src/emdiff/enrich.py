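"""Gene-set overlap statistics.

Three tools: an upper-tail hypergeometric overlap (concordance) test between
two gene lists within a stated universe; local overrepresentation analysis of a
query list against a GMT collection with BH adjustment across terms; and
UpSet-style exclusive intersection counts for families of gene sets.

The universe matters: by convention it is the set of genes actually tested in
the differential-expression run that produced the query list, and genes outside
it are dropped (with a count) before testing.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .de import bh_adjust

logger = logging.getLogger(__name__)


def hypergeom_overlap_test(query, reference, universe) -> dict:
    """Upper-tail hypergeometric test of |query ∩ reference| within universe.

    p = P(X >= k) for X ~ Hypergeometric(N=|universe|, K=|reference ∩ U|,
    n=|query ∩ U|). Genes outside the universe are dropped with a logged count.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query)
    reference = set(reference)
    dropped = len(query - universe) + len(reference - universe)
    if dropped:
        logger.info("hypergeom_overlap_test: dropped %d genes outside universe",
                    dropped)
    q = query & universe
    r = reference & universe
    k = len(q & r)
    N, K, n = len(universe), len(r), len(q)
    p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
    return {"k": k, "K": K, "n": n, "N": N, "p_raw": min(p, 1.0),
            "n_dropped_outside_universe": dropped}


def ora_gmt(query, universe, collection: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Overrepresentation analysis of ``query`` against every term of a GMT
    collection, BH-adjusted across terms; significant <=> p_adj < alpha.

    Terms with no genes in the universe are skipped (logged). Output is sorted
    by p_adj, then term name.
    """
    universe = set(universe)
    query = set(query) & universe
    rows = []
    skipped = 0
    for term, (desc, genes) in collection.items():
        in_univ = set(genes) & universe
        if not in_univ:
            skipped += 1
            continue
        res = hypergeom_overlap_test(query, in_univ, universe)
        rows.append({
            "term": term,
            "description": desc,
            "k": res["k"], "K": res["K"], "n": res["n"], "N": res["N"],
            "p_raw": res["p_raw"],
        })
    if skipped:
        logger.info("ora_gmt: skipped %d terms with no genes in universe", skipped)
    out = pd.DataFrame(rows, columns=["term", "description", "k", "K", "n",
                                      "N", "p_raw"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
        out = out.sort_values(["p_adj", "term"], kind="stable").reset_index(
            drop=True)
    else:
        out["p_adj"] = np.array([], dtype=float)
        out["significant"] = np.array([], dtype=bool)
    return out


def upset_membership(named_sets: dict) -> pd.DataFrame:
    """Exclusive-intersection counts for a family of named sets.

    For every non-empty combination of set labels, counts the elements
    belonging to exactly that combination; the counts partition the union.
    Output columns: one boolean column per set label, ``degree`` and ``count``;
    zero-count combinations are included so callers see the full lattice.
    """
    if len(named_sets) < 2:
        raise ValueError("upset_membership needs at least 2 sets")
    labels = sorted(named_sets)
    sets = {lab: set(named_sets[lab]) for lab in labels}
    union = set().union(*sets.values())
    tally = {}
    for el in union:
        key = tuple(el in sets[lab] for lab in labels)
        tally[key] = tally.get(key, 0) + 1
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(range(len(labels)), r):
            key = tuple(i in combo for i in range(len(labels)))
            rows.append(
                {**{lab: key[i] for i, lab in enumerate(labels)},
                 "degree": r, "count": tally.get(key, 0)}
            )
    return pd.DataFrame(rows, columns=labels + ["degree", "count"])
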