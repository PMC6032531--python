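"""Gene signal-transduction network construction and candidate selection.

The two-stage candidate rule: (1) "major genes" are network nodes whose
degree, closeness and betweenness all lie strictly above the respective
medians over the DEG subnetwork; (2) candidates are the major genes that
additionally show strong dysregulation (fold change > 1.5 or < 1/1.5, and
p < 0.05).

Closeness is computed per connected component as (nc-1)/sum(distances)
with nc the component size; selection compares ranks against a median, so
any monotone rescaling of closeness would select the same genes.
Betweenness is unnormalized shortest-path betweenness. Degree defaults to
the incident-edge count; a weighted variant (sum of combined scores) is
available behind a flag.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._exceptions import DataError, EmptyInputError, MissingRecordError

EDGE_COLUMNS = ["gene_a", "gene_b", "combined_score"]


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read a scored edge table (TSV or STRING protein-links dialect).

    Accepts tab- or whitespace-separated files with or without a header;
    the first two columns are gene identifiers, and the score column is
    ``combined_score`` when named, else the third column.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else r"\s+"
    tokens = first.split("\t" if sep == "\t" else None)
    has_header = any(not _is_number(t) for t in tokens[2:3]) and "score" in first.lower()
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None, engine="python")
    if has_header and "combined_score" in df.columns:
        score = df["combined_score"]
        a, b = df.iloc[:, 0], df.iloc[:, 1]
    else:
        a, b, score = df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]
    out = pd.DataFrame(
        {"gene_a": a.astype(str), "gene_b": b.astype(str), "combined_score": score.astype(float)}
    )
    return _validate_edges(out)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _validate_edges(edges: pd.DataFrame) -> pd.DataFrame:
    if (edges["gene_a"] == edges["gene_b"]).any():
        raise DataError("self-loop edges are not allowed")
    if (edges["combined_score"] <= 0).any():
        raise DataError("combined scores must be positive")
    return edges


def filter_edges_by_median(edges: pd.DataFrame) -> pd.DataFrame:
    """Retain edges whose score lies strictly above the median of all scores.

    With all scores equal the result is empty (nothing exceeds the
    median) — a documented degenerate case.
    """
    if len(edges) == 0:
        raise EmptyInputError("edge table is empty")
    edges = _validate_edges(edges[EDGE_COLUMNS].copy())
    median = float(np.median(edges["combined_score"]))
    return edges.loc[edges["combined_score"] > median].reset_index(drop=True)


def build_network(deg_genes: list[str], edges: pd.DataFrame) -> nx.Graph:
    """Undirected DEG subnetwork: both endpoints must be DEGs.

    Edges are deduplicated after canonical endpoint ordering; isolated
    DEG genes do not enter the node set. Expects a median-filtered table.
    """
    deg_set = set(deg_genes)
    graph = nx.Graph()
    for a, b, score in edges[EDGE_COLUMNS].itertuples(index=False):
        if a in deg_set and b in deg_set and a != b:
            graph.add_edge(a, b, combined_score=float(score))
    return graph


def compute_topology(net: nx.Graph, weighted_degree: bool = False) -> pd.DataFrame:
    """Per-node degree, closeness and betweenness.

    degree: incident-edge count, or the sum of incident combined scores
    when ``weighted_degree``; closeness: (nc-1)/sum(shortest-path
    distances) within the node's component; betweenness: unnormalized,
    over all node pairs (cross-component pairs contribute nothing).
    Shortest paths are unweighted throughout.
    """
    if net.number_of_nodes() == 0:
        raise EmptyInputError("network has no nodes")
    if weighted_degree:
        degree = dict(net.degree(weight="combined_score"))
    else:
        degree = dict(net.degree())
    closeness = nx.closeness_centrality(net, wf_improved=False)
    betweenness = nx.betweenness_centrality(net, normalized=False)
    nodes = sorted(net.nodes)
    return pd.DataFrame(
        {
            "gene_id": nodes,
            "degree": [float(degree[n]) for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
        }
    ).set_index("gene_id", drop=False)


def select_major_genes(records: pd.DataFrame) -> list[str]:
    """Genes whose degree, closeness AND betweenness all exceed the medians.

    Strict inequality on each feature: nodes sitting exactly at a median
    are excluded, so a network of identical nodes selects nothing.
    """
    if len(records) < 2:
        raise DataError("need at least 2 topology records")
    keep = np.ones(len(records), dtype=bool)
    for feature in ("degree", "closeness", "betweenness"):
        keep &= records[feature].to_numpy() > float(np.median(records[feature]))
    return sorted(records.loc[keep, "gene_id"])


def select_candidates(
    major_genes: list[str],
    deg_records: pd.DataFrame,
    fold_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> list[str]:
    """Major genes with strong dysregulation; the candidate biomarkers.

    Keeps major genes with ``p_value < p_threshold`` and fold change
    strictly above ``fold_threshold`` (up) or below ``1/fold_threshold``
    (down). Output sorted alphabetically.
    """
    if fold_threshold <= 1:
        raise DataError("fold_threshold must be > 1")
    missing = [g for g in major_genes if g not in deg_records.index]
    if missing:
        raise MissingRecordError(
            f"major genes without a differential-expression record: {missing}"
        )
    selected = []
    for gene in major_genes:
        rec = deg_records.loc[gene]
        fc, p = float(rec["fc"]), float(rec["p_value"])
        if p < p_threshold and (fc > fold_threshold or fc < 1.0 / fold_threshold):
            selected.append(gene)
    return sorted(selected)
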