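"""Hypergeometric gene-set enrichment and Fisher meta-analysis across models.

Each query gene set (the concordant "feature genes" of one model) is
tested against every term of a GMT collection with the exact
hypergeometric upper tail; Benjamini-Hochberg q-values are appended per
query. The meta-analysis combines each term's per-query p-values with
Fisher's method (chi-square with 2K degrees of freedom for K queries) and
ranks terms by the combined p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .deg_io import GeneSetCollection


def enrich_one(query, collection: GeneSetCollection, universe_n: int) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of one query gene set.

    Returns a DataFrame with columns term_id, term_name, set_size,
    query_size, overlap, pvalue, qvalue (BH), sorted by ascending p then
    term_id for determinism.
    """
    query = set(query)
    if not query:
        raise ValueError("query gene set is empty")
    if universe_n < len(query):
        raise ValueError("universe smaller than the query set")
    rows = []
    for term_id, (term_name, genes) in collection.sets.items():
        if len(genes) > universe_n:
            raise ValueError(f"term {term_id!r} larger than the universe")
        overlap = len(query & genes)
        p = float(stats.hypergeom.sf(overlap - 1, universe_n, len(genes), len(query)))
        rows.append((term_id, term_name, len(genes), len(query), overlap, p))
    df = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "set_size", "query_size", "overlap", "pvalue"],
    )
    df["qvalue"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(drop=True)


def meta_enrich(queries, collection: GeneSetCollection, universe_n: int) -> pd.DataFrame:
    """Meta-enrichment across several query gene sets.

    queries: mapping set_id -> gene set (order does not affect the
    ranking). Returns one row per term with meta_p (Fisher's method over
    the per-query p-values), n_significant_sets (per-query BH q < 0.05),
    a unique 1-based rank by ascending meta_p (ties broken by term_id),
    and one ``p_<set_id>`` column per query.
    """
    queries = dict(queries)
    if not queries:
        raise ValueError("meta-analysis needs at least one query set")
    per_set = {
        set_id: enrich_one(q, collection, universe_n).set_index("term_id")
        for set_id, q in queries.items()
    }
    terms = sorted(collection.sets)
    k = len(queries)
    pmat = np.column_stack(
        [per_set[s].loc[terms, "pvalue"].to_numpy() for s in sorted(queries)]
    )
    qmat = np.column_stack(
        [per_set[s].loc[terms, "qvalue"].to_numpy() for s in sorted(queries)]
    )
    chi = -2.0 * np.log(np.clip(pmat, 1e-300, 1.0)).sum(axis=1)
    meta_p = stats.chi2.sf(chi, 2 * k)
    df = pd.DataFrame(
        {
            "term_id": terms,
            "term_name": [collection.sets[t][0] for t in terms],
            "meta_p": meta_p,
            "n_significant_sets": (qmat < 0.05).sum(axis=1),
        }
    )
    for j, s in enumerate(sorted(queries)):
        df[f"p_{s}"] = pmat[:, j]
    df = df.sort_values(["meta_p", "term_id"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
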