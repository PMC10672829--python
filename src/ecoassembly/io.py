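"""Reading and writing the external formats: TSV tables, CSV metadata,
newick trees, and network node/edge exports (CSV + GraphML)."""

from __future__ import annotations

import pathlib

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import ConsistencyError, OtuTable, SampleFrame, ValidationError


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

def read_otu_table(path, transpose: bool = False) -> OtuTable:
    """Read a tab-separated OTU table.

    On disk, rows are samples and columns are OTUs (first column holds the
    sample identifiers). Set ``transpose=True`` for taxa-by-samples files,
    as emitted by many upstream tools.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise ValidationError(f"failed to parse OTU table {path}: {exc}") from exc
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split("\t")[1:]
    idx = pd.Index(header)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique())
        raise ValidationError(f"duplicate column header(s) in {path}: {dups}")
    if transpose:
        df = df.T
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValidationError(
                f"non-integer cell in {path} at row {bad!r}, column {col!r}"
            )
    return OtuTable(df)


def write_otu_table(table: OtuTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> SampleFrame:
    """Read the sample metadata CSV (sample_id, habitat, treatment, season,
    tank, then covariates)."""
    return SampleFrame(pd.read_csv(path))


def write_metadata(frame: SampleFrame, path) -> None:
    frame.data.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path, default_branch_length: float | None = None) -> TreeNode:
    """Read a rooted newick tree with branch lengths.

    Nodes lacking a branch length (other than the root) are an error unless
    ``default_branch_length`` supplies a fill-in value. Negative branch
    lengths are always rejected.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValidationError(f"failed to parse newick file {path}: {exc}") from exc
    return _check_branch_lengths(tree, default_branch_length)


def tree_from_newick(newick: str, default_branch_length: float | None = None) -> TreeNode:
    import io as _io

    try:
        tree = TreeNode.read(_io.StringIO(newick), format="newick")
    except Exception as exc:
        raise ValidationError(f"failed to parse newick string: {exc}") from exc
    return _check_branch_lengths(tree, default_branch_length)


def _check_branch_lengths(tree: TreeNode, default: float | None) -> TreeNode:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if default is None:
                raise ValidationError(
                    f"node {node.name!r} lacks a branch length and no default was given"
                )
            node.length = default
        elif node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def patristic_distances(tree: TreeNode, otu_ids) -> np.ndarray:
    """Tip-to-tip path-length (patristic) distance matrix over ``otu_ids``.

    Returns a symmetric matrix with zero diagonal, rows/columns ordered as
    ``otu_ids``. Any id that is not a tip of the tree is a hard error.
    """
    otu_ids = list(otu_ids)
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(otu_ids) - tips)
    if missing:
        raise ConsistencyError(f"OTU id(s) not found among tree tips: {missing}")
    dm = tree.tip_tip_distances(endpoints=otu_ids)
    order = [list(dm.ids).index(o) for o in otu_ids]
    return np.asarray(dm.data)[np.ix_(order, order)]


# ---------------------------------------------------------------------------
# Cross-file consistency
# ---------------------------------------------------------------------------

def validate_consistency(
    table: OtuTable,
    frame: SampleFrame | None = None,
    tree: TreeNode | None = None,
    require_tree_cover: bool = False,
) -> None:
    """Check identifier agreement across table, metadata and tree.

    Every table sample must have exactly one metadata row. Tree tips may be
    a superset of the OTU set; missing tips are an error only when
    ``require_tree_cover`` is set (i.e. for phylogenetic operations). All
    offenders are listed exhaustively.
    """
    problems = []
    if frame is not None:
        missing_meta = sorted(set(table.sample_ids) - set(frame.sample_ids))
        if missing_meta:
            problems.append(f"samples without metadata: {missing_meta}")
    if tree is not None and require_tree_cover:
        tips = {t.name for t in tree.tips()}
        missing_tips = sorted(set(table.otu_ids) - tips)
        if missing_tips:
            problems.append(f"OTUs absent from the tree: {missing_tips}")
    if problems:
        raise ConsistencyError("; ".join(problems))


# ---------------------------------------------------------------------------
# Network exports
# ---------------------------------------------------------------------------

def write_edge_list(graph: nx.Graph, nodes_path, edges_path) -> None:
    """Write node and edge CSV tables loadable by external graph tools.

    The node table carries id, phylum (``"unknown"`` when not annotated),
    and degree; the edge table carries source, target, weight (Spearman r)
    and sign.
    """
    nodes = pd.DataFrame(
        {
            "id": list(graph.nodes),
            "phylum": [graph.nodes[n].get("phylum", "unknown") for n in graph.nodes],
            "degree": [graph.degree(n) for n in graph.nodes],
        }
    )
    edges = pd.DataFrame(
        [
            {
                "source": u,
                "target": v,
                "weight": d.get("weight", np.nan),
                "sign": d.get("sign", "positive" if d.get("weight", 0) >= 0 else "negative"),
            }
            for u, v, d in graph.edges(data=True)
        ],
        columns=["source", "target", "weight", "sign"],
    )
    nodes.to_csv(nodes_path, index=False)
    edges.to_csv(edges_path, index=False)


def read_edge_list(nodes_path, edges_path) -> nx.Graph:
    graph = nx.Graph()
    nodes = pd.read_csv(nodes_path)
    for _, row in nodes.iterrows():
        graph.add_node(str(row["id"]), phylum=row.get("phylum", "unknown"))
    edges = pd.read_csv(edges_path)
    for _, row in edges.iterrows():
        graph.add_edge(
            str(row["source"]), str(row["target"]),
            weight=float(row["weight"]), sign=str(row["sign"]),
        )
    return graph


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))


def write_report_table(table: pd.DataFrame, path, index: bool = False) -> None:
    """Write a report table as TSV."""
    pathlib.Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index)


def write_distance_matrix(labels, values: np.ndarray, path) -> None:
    """Square distance/score matrix as TSV with header row and column."""
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t")


def read_distance_matrix(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.index.astype(str).tolist(), df.to_numpy(dtype=float)
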