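"""Node tables: the ROI set underlying every connectome in the pipeline.

A node table is a pandas DataFrame with columns ``node_id`` (0-based,
contiguous), ``label`` (unique anatomical name) and ``hemisphere``
(``"L"`` or ``"R"``).  The default table mirrors a whole-brain gray-matter
parcellation of 76 structures, 38 per hemisphere, with each left-hemisphere
structure paired with its right homolog (``L_X`` at index ``i`` pairs with
``R_X`` at index ``i + 38``).
"""

from __future__ import annotations

import pandas as pd

#: 38 bilateral gray-matter structure names (one hemisphere's worth).
#: Synthetic stand-in for a standard anatomical parcellation; the IFG
#: subdivisions and precuneus carry their conventional names because they
#: serve as the analysis target and control ROIs.
BASE_STRUCTURES = (
    "IFG_tri",
    "IFG_oper",
    "IFG_orb",
    "SFG",
    "MFG",
    "PrCG",
    "PoCG",
    "SMA",
    "Paracentral",
    "SPL",
    "SMG",
    "AngularGyrus",
    "Precuneus",
    "Cuneus",
    "SOG",
    "MOG",
    "IOG",
    "LingualGyrus",
    "Fusiform",
    "STG",
    "MTG",
    "ITG",
    "TemporalPole",
    "Hippocampus",
    "PHG",
    "Amygdala",
    "Entorhinal",
    "Insula",
    "ACC",
    "MCC",
    "PCC",
    "RectusGyrus",
    "MedialOFC",
    "LateralOFC",
    "Caudate",
    "Putamen",
    "GlobusPallidus",
    "Thalamus",
)

TARGET_LABEL = "L_IFG_tri"
CONTROL_LABELS = ("R_IFG_tri", "R_Precuneus", "L_IFG_orb", "L_IFG_oper")


def default_node_table() -> pd.DataFrame:
    """Return the default 76-node table (38 structures x 2 hemispheres).

    Left-hemisphere nodes occupy ids 0..37, right-hemisphere nodes 38..75,
    in the same structure order, so homolog pairs differ by 38.
    """
    rows = []
    for hemi, offset in (("L", 0), ("R", len(BASE_STRUCTURES))):
        for i, base in enumerate(BASE_STRUCTURES):
            rows.append(
                {"node_id": offset + i, "label": f"{hemi}_{base}", "hemisphere": hemi}
            )
    return pd.DataFrame(rows, columns=["node_id", "label", "hemisphere"])


def validate_node_table(table: pd.DataFrame) -> None:
    """Check node-table invariants; raise ValueError on violation."""
    required = {"node_id", "label", "hemisphere"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"node table missing columns: {sorted(missing)}")
    n = len(table)
    ids = table["node_id"].to_numpy()
    if sorted(ids.tolist()) != list(range(n)):
        raise ValueError("node_ids must be 0..n-1 with no gaps")
    if table["label"].duplicated().any():
        dupes = table.loc[table["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate node labels: {dupes}")
    bad = set(table["hemisphere"].unique()) - {"L", "R"}
    if bad:
        raise ValueError(f"hemisphere must be 'L' or 'R', got {sorted(bad)}")


def node_id_of(table: pd.DataFrame, label: str) -> int:
    """Resolve a node label to its id; KeyError if absent."""
    hit = table.loc[table["label"] == label, "node_id"]
    if hit.empty:
        raise KeyError(f"node label {label!r} not in node table")
    return int(hit.iloc[0])
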