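"""Hypergeometric term enrichment and slim-category tabulations.

Over-representation of annotation terms (GO, KEGG pathways, TF families) in
a study set against a population background: the p-value for a term with K
annotated features in a population of N, of which a study of size n hits k,
is the hypergeometric upper tail P(X >= k).  BH adjustment runs across the
tested terms (terms with at least one study hit).  No GO-DAG reasoning is
done: a supplied term -> level-2 slim mapping is taken as given.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, PipelineError
from .destats import bh_adjust, fisher_two_library_batch


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError("need 0 <= K <= N and 0 <= n <= N")
    if k < 0 or k > min(n, K):
        raise DomainError("need 0 <= k <= min(n, K)")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    study: set,
    population: set,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term over-representation of ``study`` against ``population``.

    ``annotation`` carries (feature_id, term_id[, term_name[, namespace]])
    rows; annotations outside the population are ignored.  Returns one row
    per term with at least one study hit, sorted by p then term id, with
    columns k, n, K, N, p, q and ``significant`` (q <= alpha).
    """
    study = set(study)
    population = set(population)
    stray = study - population
    if stray:
        raise PipelineError(
            f"study features outside the population: {sorted(stray)[:10]}"
        )
    ann = annotation[annotation["feature_id"].isin(population)]
    N = len(population)
    n = len(study)
    rows = []
    for term, sub in ann.groupby("term_id", sort=True):
        feats = set(sub["feature_id"])
        K = len(feats)
        k = len(feats & study)
        if k == 0:
            continue
        name = sub["term_name"].iloc[0] if "term_name" in sub else ""
        rows.append((term, name, k, n, K, N))
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "n", "K", "N"])
    if out.empty:
        out["p"] = out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["p"] = stats.hypergeom.sf(out["k"] - 1, out["N"], out["K"], out["n"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] <= alpha
    return out.sort_values(["p", "term_id"], kind="mergesort", ignore_index=True)


def compare_sets_by_term(
    set_a: set,
    set_b: set,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term 2x2 exact comparison of two feature sets.

    For every term annotating at least one member of either set, tests
    whether the term's frequency differs between set_a and set_b (two-sided
    exact test on hits_a/size_a vs hits_b/size_b) with BH across terms.
    ``b_overrepresented`` flags terms where set_b's hit rate exceeds set_a's
    (e.g. non-additive over additive genes).
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a or not set_b:
        raise PipelineError("both feature sets must be non-empty")
    ann = annotation[annotation["feature_id"].isin(set_a | set_b)]
    rows = []
    for term, sub in ann.groupby("term_id", sort=True):
        feats = set(sub["feature_id"])
        ka, kb = len(feats & set_a), len(feats & set_b)
        if ka == 0 and kb == 0:
            continue
        name = sub["term_name"].iloc[0] if "term_name" in sub else ""
        rows.append((term, name, ka, len(set_a), kb, len(set_b)))
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "hits_a", "size_a", "hits_b", "size_b"]
    )
    if out.empty:
        out["p"] = out["q"] = pd.Series(dtype=float)
        out["significant"] = out["b_overrepresented"] = pd.Series(dtype=bool)
        return out
    ps = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        ps[i] = fisher_two_library_batch(
            np.asarray([row.hits_a]), row.size_a, np.asarray([row.hits_b]), row.size_b
        )[0]
    out["p"] = ps
    out["q"] = bh_adjust(ps)
    out["significant"] = out["q"] <= alpha
    out["b_overrepresented"] = (out["hits_b"] / out["size_b"]) > (
        out["hits_a"] / out["size_a"]
    )
    return out.sort_values(["p", "term_id"], kind="mergesort", ignore_index=True)


def slim_tabulate(
    features: set,
    slim_map: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Distinct-feature counts per (namespace, level-2 slim term).

    ``slim_map`` maps term_id -> (namespace, slim_term); annotation terms
    absent from the map are tallied under namespace ``unmapped``.  A feature
    annotated to several terms of one slim category counts once there, but a
    feature may count in multiple categories.
    """
    features = set(features)
    ann = annotation.loc[annotation["feature_id"].isin(features), ["feature_id", "term_id"]]
    lookup = slim_map.set_index("term_id")[["namespace", "slim_term"]]
    joined = ann.join(lookup, on="term_id")
    unmapped = joined["slim_term"].isna()
    joined.loc[unmapped, "namespace"] = "unmapped"
    joined.loc[unmapped, "slim_term"] = joined.loc[unmapped, "term_id"]
    counts = (
        joined.groupby(["namespace", "slim_term"])["feature_id"]
        .nunique()
        .reset_index(name="feature_count")
        .sort_values(["namespace", "slim_term"], ignore_index=True)
    )
    return counts
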