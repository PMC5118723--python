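"""miRNA-mRNA anti-correlation ("related target") network.

A predicted miRNA target gene is a *related target* when, in the same
polyploid-vs-parent comparison, the gene's differential-expression direction
is opposite to its miRNA's (miRNA up & target down, or miRNA down & target
up).  Pairs where either side is not significant are excluded; pairs where
both move in the same direction are kept out of the network but available as
an optional positively-correlated side table.  Edges from the two
comparisons are merged by multiset union; distinct-gene totals are computed
on the union, so a gene related in both comparisons counts once.
"""

from __future__ import annotations

import logging

import pandas as pd

from ._util import pct_half_up
from .errors import ConsistencyError

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["mirna_id", "gene_id", "comparison", "mirna_call", "gene_call"]


def related_targets(
    mirna_de: pd.DataFrame,
    gene_de: pd.DataFrame,
    pairs: pd.DataFrame,
    comparison: str,
    keep_positive: bool = False,
) -> pd.DataFrame:
    """Anti-correlated edges for one comparison.

    ``mirna_de`` / ``gene_de`` are DE result frames (indexed by feature id,
    with a ``call`` column) for the *same* comparison.  Pairs referencing a
    feature absent from its DE table are skipped with a logged warning and
    counted in the returned frame's ``attrs["skipped_pairs"]``.

    With ``keep_positive`` the same-direction pairs are returned too, marked
    by ``anticorrelated=False``; they never enter summaries.
    """
    known = pairs["mirna_id"].isin(mirna_de.index) & pairs["gene_id"].isin(gene_de.index)
    skipped = int((~known).sum())
    if skipped:
        logger.warning(
            "%d target pair(s) reference features absent from the DE tables "
            "(comparison %s); skipped", skipped, comparison,
        )
    use = pairs.loc[known]
    mcall = mirna_de["call"].reindex(use["mirna_id"]).to_numpy()
    gcall = gene_de["call"].reindex(use["gene_id"]).to_numpy()
    both_de = (mcall != "ns") & (gcall != "ns")
    anti = both_de & (mcall != gcall)
    sel = anti | (keep_positive & both_de)
    edges = pd.DataFrame(
        {
            "mirna_id": use["mirna_id"].to_numpy()[sel],
            "gene_id": use["gene_id"].to_numpy()[sel],
            "comparison": comparison,
            "mirna_call": mcall[sel],
            "gene_call": gcall[sel],
            "anticorrelated": anti[sel],
        }
    )
    if not keep_positive:
        edges = edges.drop(columns=["anticorrelated"])
    edges.attrs["skipped_pairs"] = skipped
    return edges


def merge_networks(edges_ca: pd.DataFrame, edges_cb: pd.DataFrame) -> pd.DataFrame:
    """Multiset union of the two comparisons' edge lists."""
    merged = pd.concat([edges_ca, edges_cb], ignore_index=True)
    merged.attrs["skipped_pairs"] = edges_ca.attrs.get(
        "skipped_pairs", 0
    ) + edges_cb.attrs.get("skipped_pairs", 0)
    return merged


def network_summary(network: pd.DataFrame, nonadditive_flags: pd.Series) -> dict:
    """Totals, per-comparison up/down gene counts and per-miRNA tallies.

    ``nonadditive_flags`` must cover every gene in the network (boolean,
    indexed by gene id).
    """
    genes = pd.Index(network["gene_id"].unique()) if len(network) else pd.Index([])
    missing = genes.difference(nonadditive_flags.index)
    if len(missing):
        raise ConsistencyError(
            f"non-additivity flag missing for network gene(s): {sorted(missing)[:10]}"
        )
    n_edges = len(network)
    per_comparison: dict = {}
    if n_edges:
        for comp, sub in network.groupby("comparison"):
            per_comparison[comp] = {
                "edges": len(sub),
                "related_genes": int(sub["gene_id"].nunique()),
                "genes_up": int(sub.loc[sub["gene_call"] == "up", "gene_id"].nunique()),
                "genes_down": int(sub.loc[sub["gene_call"] == "down", "gene_id"].nunique()),
            }
    gene_nonadd = nonadditive_flags.reindex(genes).astype(bool) if len(genes) else pd.Series(dtype=bool)
    nonadd_total = int(gene_nonadd.sum())

    per_mirna: list[dict] = []
    if n_edges:
        for mid, sub in network.groupby("mirna_id"):
            targets = pd.Index(sub["gene_id"].unique())
            n_na = int(nonadditive_flags.reindex(targets).astype(bool).sum())
            per_mirna.append(
                {
                    "mirna_id": mid,
                    "edges": len(sub),
                    "related_targets": len(targets),
                    "nonadditive_targets": n_na,
                    "nonadditive_pct": pct_half_up(n_na, len(targets)),
                    "edge_share_pct": pct_half_up(len(sub), n_edges),
                }
            )
        per_mirna.sort(key=lambda r: (-r["related_targets"], r["mirna_id"]))
    return {
        "edge_total": n_edges,
        "related_gene_total": int(len(genes)),
        "related_mirna_total": int(network["mirna_id"].nunique()) if n_edges else 0,
        "per_comparison": per_comparison,
        "nonadditive_related_total": nonadd_total,
        "nonadditive_related_pct": pct_half_up(nonadd_total, len(genes)) if len(genes) else 0.0,
        "nonadditive_related_mirnas": int(
            network.loc[network["gene_id"].isin(gene_nonadd.index[gene_nonadd]), "mirna_id"].nunique()
        ) if n_edges else 0,
        "per_mirna": per_mirna,
    }


def export_edgelist(network: pd.DataFrame, path, nonadditive_flags: pd.Series | None = None) -> None:
    """Deterministically sorted TSV edge list.

    Columns: mirna_id, gene_id, comparison, mirna_call, gene_call and, when
    flags are supplied, gene_nonadditive.
    """
    out = network[EDGE_COLUMNS].copy()
    if nonadditive_flags is not None:
        out["gene_nonadditive"] = (
            nonadditive_flags.reindex(out["gene_id"]).astype(bool).to_numpy().astype(int)
        )
    out = out.sort_values(["mirna_id", "gene_id", "comparison"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def read_edgelist(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def to_networkx(network: pd.DataFrame):
    """Bipartite graph view (miRNA and gene nodes, one edge per pair)."""
    import networkx as nx

    g = nx.Graph()
    for row in network.itertuples(index=False):
        g.add_node(row.mirna_id, kind="mirna")
        g.add_node(row.gene_id, kind="gene")
        if g.has_edge(row.mirna_id, row.gene_id):
            g.edges[row.mirna_id, row.gene_id]["comparisons"].append(row.comparison)
        else:
            g.add_edge(row.mirna_id, row.gene_id, comparisons=[row.comparison])
    return g
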