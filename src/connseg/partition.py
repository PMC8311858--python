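"""Modular partitions: the node -> module assignment PC is computed against.

A :class:`ModularPartition` assigns every node to exactly one of ``M``
modules with contiguous module ids ``0..M-1``.  The reference partition is
derived once from healthy-control data (or loaded from file) and then held
fixed for every subject and timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ModularPartition:
    """Assignment of every node to exactly one module.

    Parameters
    ----------
    assignment
        Integer module id per node, indexed by node_id; ids must be
        contiguous ``0..M-1``.
    module_names
        Optional map from module id to a human-readable name
        (e.g. ``{0: "perisylvian"}``).
    """

    assignment: np.ndarray
    module_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("assignment must be a nonempty 1-D array")
        present = np.unique(arr)
        if present[0] != 0 or present[-1] != present.size - 1:
            raise ValueError(
                f"module ids must be contiguous 0..M-1, got {present.tolist()}"
            )
        for mid in self.module_names:
            if mid not in present:
                raise ValueError(f"module_names refers to unknown module {mid}")

    @property
    def n_nodes(self) -> int:
        return self.assignment.size

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1

    def module_of(self, node: int) -> int:
        return int(self.assignment[node])

    def name_of(self, module_id: int) -> str:
        return self.module_names.get(module_id, f"module_{module_id}")

    def indicator(self) -> np.ndarray:
        """Boolean n x M membership matrix."""
        n, m = self.n_nodes, self.n_modules
        ind = np.zeros((n, m), dtype=bool)
        ind[np.arange(n), self.assignment] = True
        return ind

    def members(self, module_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == module_id)

    def relabel_canonical(self) -> "ModularPartition":
        """Renumber modules by order of first node occurrence (names dropped)."""
        mapping: dict[int, int] = {}
        new = np.empty_like(self.assignment)
        for i, m in enumerate(self.assignment):
            if m not in mapping:
                mapping[int(m)] = len(mapping)
            new[i] = mapping[int(m)]
        return ModularPartition(new)
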