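"""Node-level segregation metrics: participation coefficient and connection
counts.

The participation coefficient of node *i* against a partition into modules
``M`` is

    PC_i = 1 - sum_{m in M} (k_i(m) / k_i)^2

where ``k_i`` is the node's degree and ``k_i(m)`` its number of connections
into module *m*.  PC is 0 when all edges stay in one module and approaches
``1 - 1/M`` when they spread evenly over all modules.  All metrics are
computed per proportional threshold and then averaged with equal weights;
connection counts averaged over thresholds are therefore fractional.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from connseg.graph_build import BinaryGraphSet
from connseg.partition import ModularPartition


def _as_adjacency(graph, n_nodes: int) -> np.ndarray:
    if isinstance(graph, nx.Graph):
        return nx.to_numpy_array(graph, nodelist=range(n_nodes), dtype=float)
    adj = np.asarray(graph)
    return adj.astype(float)


def participation_coefficient(graph, partition: ModularPartition) -> np.ndarray:
    """Per-node participation coefficient of one binary graph.

    ``graph`` may be a boolean/0-1 adjacency matrix or a networkx Graph with
    integer nodes 0..n-1.  Isolated nodes (degree 0) are assigned PC = 0 —
    a node with no connections has no connectivity diversity.
    """
    n = partition.n_nodes
    if isinstance(graph, nx.Graph):
        extra = set(graph.nodes) - set(range(n))
        if extra:
            raise ValueError(f"graph node(s) absent from partition: {sorted(extra)}")
    adj = _as_adjacency(graph, n)
    if adj.shape != (n, n):
        raise ValueError(
            f"adjacency shape {adj.shape} does not match partition size {n}"
        )
    # k_i(m) for all nodes/modules at once: adjacency times membership
    k_m = adj @ partition.indicator().astype(float)
    k = k_m.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 1.0 - np.sum((k_m / k[:, None]) ** 2, axis=1)
    pc[k == 0] = 0.0
    return pc


def threshold_averaged_pc(
    graphset: BinaryGraphSet, partition: ModularPartition
) -> tuple[np.ndarray, np.ndarray]:
    """Mean PC per node across thresholds, plus the per-threshold values.

    Returns ``(mean_pc, per_threshold)`` with ``per_threshold`` shaped
    (n_thresholds, n_nodes); per-threshold values are retained because
    effects are expected to be visible at each threshold, not only in the
    average.
    """
    per = np.stack(
        [participation_coefficient(a, partition) for a in graphset.adjacency]
    )
    return per.mean(axis=0), per


def module_connection_counts(
    graphset: BinaryGraphSet, partition: ModularPartition, node: int
) -> pd.DataFrame:
    """Threshold-averaged connection counts of one node into every module.

    Returns a DataFrame with one row per module: ``module_id``,
    ``module_name``, ``mean_count``, and an ``is_own`` flag for the node's
    own module.  Within-module connectivity is the own-module row;
    between-module connectivity is the sum of the rest.
    """
    n = partition.n_nodes
    if not (0 <= node < n):
        raise ValueError(f"node {node} out of range 0..{n - 1}")
    ind = partition.indicator().astype(float)
    counts = np.stack([a[node].astype(float) @ ind for a in graphset.adjacency])
    mean_counts = counts.mean(axis=0)
    own = partition.module_of(node)
    return pd.DataFrame(
        {
            "module_id": np.arange(partition.n_modules),
            "module_name": [partition.name_of(m) for m in range(partition.n_modules)],
            "mean_count": mean_counts,
            "is_own": np.arange(partition.n_modules) == own,
        }
    )


def within_between_counts(
    graphset: BinaryGraphSet, partition: ModularPartition, node: int
) -> tuple[float, float]:
    """(within, between) threshold-averaged connection counts of one node."""
    table = module_connection_counts(graphset, partition, node)
    within = float(table.loc[table["is_own"], "mean_count"].sum())
    between = float(table.loc[~table["is_own"], "mean_count"].sum())
    return within, between


def hemisphere_connection_counts(
    graphset: BinaryGraphSet,
    partition: ModularPartition,
    node: int,
    node_table: pd.DataFrame,
) -> pd.DataFrame:
    """Within/between counts with the neighbor set restricted per hemisphere.

    One row per hemisphere with ``within`` and ``between`` threshold-averaged
    counts; the two rows sum to the whole-brain counts because the
    hemispheres partition the neighbor set.
    """
    if node_table["hemisphere"].isna().any():
        missing = node_table.loc[node_table["hemisphere"].isna(), "label"].tolist()
        raise ValueError(f"node(s) missing hemisphere annotation: {missing}")
    own = partition.module_of(node)
    same_module = partition.assignment == own
    rows = []
    hemi = node_table.sort_values("node_id")["hemisphere"].to_numpy()
    for h in ("L", "R"):
        sel = hemi == h
        within = np.mean(
            [a[node, sel & same_module].sum() for a in graphset.adjacency]
        )
        between = np.mean(
            [a[node, sel & ~same_module].sum() for a in graphset.adjacency]
        )
        rows.append(
            {"hemisphere": h, "within": float(within), "between": float(between)}
        )
    return pd.DataFrame(rows)


def node_metric_record(
    graphset: BinaryGraphSet,
    partition: ModularPartition,
    node: int,
    node_table: pd.DataFrame,
    subject_id: str = "",
    timepoint: str = "",
) -> dict:
    """All metrics of one node for one scan, as a flat record."""
    mean_pc, per = threshold_averaged_pc(graphset, partition)
    within, between = within_between_counts(graphset, partition, node)
    per_module = module_connection_counts(graphset, partition, node)
    per_hemi = hemisphere_connection_counts(graphset, partition, node, node_table)
    return dict(
        subject_id=subject_id,
        timepoint=timepoint,
        node_id=node,
        pc=float(mean_pc[node]),
        per_threshold_pc=per[:, node].tolist(),
        within_count=within,
        between_count=between,
        per_module_counts=per_module["mean_count"].tolist(),
        per_hemisphere={
            row["hemisphere"]: (row["within"], row["between"])
            for _, row in per_hemi.iterrows()
        },
    )


def metrics_table(
    graphsets: dict,
    partition: ModularPartition,
    node_table: pd.DataFrame,
    nodes: list[int],
) -> pd.DataFrame:
    """Long-format metric table over scans and analysis nodes.

    ``graphsets`` maps ``(subject_id, timepoint)`` to a BinaryGraphSet.
    Columns: subject_id, timepoint, node_id, node_label, metric, threshold
    (a proportion or "mean"), value.
    """
    label_of = dict(
        zip(node_table["node_id"].astype(int), node_table["label"])
    )
    rows = []
    for (sid, tp), gs in graphsets.items():
        mean_pc, per = threshold_averaged_pc(gs, partition)
        for node in nodes:
            lab = label_of[node]
            rows.append((sid, tp, node, lab, "pc", "mean", float(mean_pc[node])))
            for t, val in zip(gs.thresholds, per[:, node]):
                rows.append((sid, tp, node, lab, "pc", f"{t:g}", float(val)))
            within, between = within_between_counts(gs, partition, node)
            rows.append((sid, tp, node, lab, "within_count", "mean", within))
            rows.append((sid, tp, node, lab, "between_count", "mean", between))
            per_module = module_connection_counts(gs, partition, node)
            for _, mrow in per_module.iterrows():
                rows.append(
                    (sid, tp, node, lab, f"count_{mrow['module_name']}", "mean",
                     float(mrow["mean_count"]))
                )
            per_hemi = hemisphere_connection_counts(gs, partition, node, node_table)
            for _, hrow in per_hemi.iterrows():
                rows.append(
                    (sid, tp, node, lab, f"within_count_{hrow['hemisphere']}",
                     "mean", float(hrow["within"]))
                )
                rows.append(
                    (sid, tp, node, lab, f"between_count_{hrow['hemisphere']}",
                     "mean", float(hrow["between"]))
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "timepoint", "node_id", "node_label",
            "metric", "threshold", "value",
        ],
    )
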