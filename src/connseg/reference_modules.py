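"""Deriving the reference modular organization from healthy-control data.

The healthy-control group-mean Fisher-z matrix is clustered with Ward's
criterion — each node's feature vector is its row of the mean matrix
(diagonal zeroed), with Euclidean inter-row distance — and the dendrogram
is cut at a configured number of modules (default 7).  The resulting
partition is computed once and then frozen: every subject's participation
coefficient is measured against the same reference organization.

A packaged synthetic reference partition (76 labels in 7 named bilateral
modules, the stimulation target in the perisylvian module) can be loaded
instead of re-deriving one.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import ClusterWarning, fcluster, linkage
from sklearn.metrics import silhouette_score

from connseg.nodes import validate_node_table
from connseg.partition import ModularPartition

#: Canonical module names of the seven-module reference organization.
MODULE_NAMES = (
    "perisylvian",
    "temporal",
    "FP",
    "dFP",
    "vmPFC",
    "occipital_temporal",
    "subcortical",
)


def group_mean_matrix(matrices) -> np.ndarray:
    """Entrywise arithmetic mean of connectivity matrices (same node set)."""
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if not mats:
        raise ValueError("need at least one matrix")
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError(f"matrix shapes differ: {m.shape} vs {shape}")
    mean = np.mean(mats, axis=0)
    return (mean + mean.T) / 2


def ward_partition(mean_matrix: np.ndarray, k: int) -> ModularPartition:
    """Cut a Ward dendrogram of the mean matrix's rows into exactly k modules.

    Deterministic given the input; module ids are renumbered by first node
    occurrence.
    """
    mean_matrix = np.asarray(mean_matrix, dtype=float)
    n = mean_matrix.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    features = mean_matrix.copy()
    np.fill_diagonal(features, 0.0)
    if k == n:
        return ModularPartition(np.arange(n))
    with warnings.catch_warnings():
        # rows of the mean matrix are used as feature vectors by design;
        # scipy warns that the square symmetric input looks like a distance
        # matrix, which is exactly the ambiguity we are resolving here
        warnings.simplefilter("ignore", ClusterWarning)
        z = linkage(features, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ModularPartition(labels - 1).relabel_canonical()


def silhouette_report(mean_matrix: np.ndarray, k_range=range(2, 13)) -> pd.DataFrame:
    """Mean silhouette score of the Ward cut over a range of k — guidance
    only; the module count is a configuration choice, not auto-selected."""
    rows = []
    features = np.asarray(mean_matrix, dtype=float).copy()
    np.fill_diagonal(features, 0.0)
    n = features.shape[0]
    for k in k_range:
        part = ward_partition(mean_matrix, k)
        # tied merges can leave fewer clusters than requested; the
        # silhouette is undefined outside 2..n-1 distinct labels
        if not (1 < part.n_modules < n):
            rows.append({"k": k, "silhouette": float("nan")})
            continue
        score = silhouette_score(features, part.assignment)
        rows.append({"k": k, "silhouette": float(score)})
    return pd.DataFrame(rows)


def write_partition(
    partition: ModularPartition, node_table: pd.DataFrame, path
) -> None:
    """Write a two-column (node_label, module_name) tab-separated file."""
    labels = node_table.sort_values("node_id")["label"].tolist()
    df = pd.DataFrame(
        {
            "node_label": labels,
            "module_name": [
                partition.name_of(partition.module_of(i)) for i in range(len(labels))
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_reference_partition(path, node_table: pd.DataFrame) -> ModularPartition:
    """Load and validate a two-column partition file against a node table.

    Raises distinct errors for unknown labels, missing nodes, and duplicate
    nodes.
    """
    validate_node_table(node_table)
    df = pd.read_csv(path, sep="\t")
    if not {"node_label", "module_name"} <= set(df.columns):
        raise ValueError(
            f"partition file must have columns node_label, module_name; "
            f"got {df.columns.tolist()}"
        )
    known = set(node_table["label"])
    unknown = sorted(set(df["node_label"]) - known)
    if unknown:
        raise ValueError(f"unknown node label(s) in partition file: {unknown}")
    dupes = df.loc[df["node_label"].duplicated(), "node_label"].tolist()
    if dupes:
        raise ValueError(f"duplicate node(s) in partition file: {sorted(set(dupes))}")
    missing = sorted(known - set(df["node_label"]))
    if missing:
        raise ValueError(f"partition file missing node(s): {missing}")

    module_ids: dict[str, int] = {}
    by_label = dict(zip(df["node_label"], df["module_name"]))
    assignment = np.empty(len(node_table), dtype=int)
    for _, row in node_table.sort_values("node_id").iterrows():
        name = by_label[row["label"]]
        if name not in module_ids:
            module_ids[name] = len(module_ids)
        assignment[int(row["node_id"])] = module_ids[name]
    names = {mid: name for name, mid in module_ids.items()}
    return ModularPartition(assignment, module_names=names)


def packaged_reference_path() -> Path:
    """Path of the packaged synthetic seven-module reference partition."""
    return Path(
        resources.files("connseg").joinpath("data/reference_partition_synthetic.tsv")
    )


def load_packaged_reference(node_table: pd.DataFrame) -> ModularPartition:
    """Load the packaged synthetic reference partition (7 named bilateral
    modules over the default 76-node table; a stand-in for a study-derived
    organization, not estimated from any real data)."""
    return load_reference_partition(packaged_reference_path(), node_table)
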