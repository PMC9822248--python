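"""Nested (batch -> cell -> sweep) measurement datasets for four-group designs.

The experimental design compares two knockout lines against their own
genetically matched controls.  Each group is a tree: culture batches contain
cells, cells contain repeated sweep measurements (one scalar per sweep, e.g.
a PSC amplitude in pA or a sucrose charge in pC).  The four canonical group
roles are ``control_a`` / ``ko_a`` (line A) and ``control_b`` / ``ko_b``
(line B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

#: Canonical group roles, in fixed order (line A control/KO, line B control/KO).
GROUP_LABELS: tuple[str, str, str, str] = ("control_a", "ko_a", "control_b", "ko_b")

# tree type: {batch_label: {cell_label: np.ndarray of sweep values}}
GroupTree = dict[str, dict[str, np.ndarray]]


@dataclass
class NestedDataset:
    """Four labelled groups, each a batch -> cell -> sweep tree of scalars.

    Parameters
    ----------
    groups
        Mapping from each of the four labels in :data:`GROUP_LABELS` to a
        nested ``{batch: {cell: values}}`` dictionary.  Sweep values are
        stored as 1-D float arrays.
    single_sweep
        If True the sweep level is degenerate by design (one measurement per
        cell, e.g. sucrose-evoked charge) and resampling skips it.
    """

    groups: dict[str, GroupTree]
    single_sweep: bool = field(default=False)

    def __post_init__(self) -> None:
        if set(self.groups) != set(GROUP_LABELS):
            raise InputError(
                f"dataset must have exactly the groups {GROUP_LABELS}, "
                f"got {sorted(self.groups)}"
            )
        for g, tree in self.groups.items():
            if len(tree) == 0:
                raise InputError(f"group {g!r} has no batches")
            for b, cells in tree.items():
                if len(cells) == 0:
                    raise InputError(f"batch {g}/{b} has no cells")
                for c, vals in cells.items():
                    arr = np.asarray(vals, dtype=float)
                    if arr.ndim != 1 or arr.size == 0:
                        raise InputError(f"cell {g}/{b}/{c} needs >= 1 sweep value")
                    if not np.all(np.isfinite(arr)):
                        raise InputError(f"non-finite value in cell {g}/{b}/{c}")
                    cells[c] = arr

    # ------------------------------------------------------------------ views
    def group_values(self, label: str) -> np.ndarray:
        """All sweep values of one group pooled into a flat array."""
        tree = self.groups[label]
        return np.concatenate(
            [vals for cells in tree.values() for vals in cells.values()]
        )

    def group_cell_means(self, label: str) -> np.ndarray:
        """Per-cell mean values of one group (one entry per cell)."""
        tree = self.groups[label]
        return np.array(
            [vals.mean() for cells in tree.values() for vals in cells.values()]
        )

    def group_mean(self, label: str, level: str = "sweeps") -> float:
        """Grand mean of a group.

        ``level='sweeps'`` pools all sweep values (default); ``level='cells'``
        averages per-cell means instead.
        """
        if level == "sweeps":
            return float(self.group_values(label).mean())
        if level == "cells":
            return float(self.group_cell_means(label).mean())
        raise InputError(f"unknown level {level!r}")

    def counts(self, label: str) -> tuple[int, list[int], list[list[int]]]:
        """(n_batches, cells per batch, sweeps per cell per batch)."""
        tree = self.groups[label]
        n_cells = [len(cells) for cells in tree.values()]
        n_sweeps = [[v.size for v in cells.values()] for cells in tree.values()]
        return len(tree), n_cells, n_sweeps

    # ------------------------------------------------------------- table I/O
    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns group, batch, cell, sweep, value."""
        rows = []
        for g in GROUP_LABELS:
            for b, cells in self.groups[g].items():
                for c, vals in cells.items():
                    for i, v in enumerate(vals):
                        rows.append((g, b, c, i, v))
        return pd.DataFrame(rows, columns=["group", "batch", "cell", "sweep", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, single_sweep: bool = False) -> "NestedDataset":
        """Build a dataset from a long-format (group, batch, cell, sweep, value) table."""
        required = {"group", "batch", "cell", "value"}
        if not required.issubset(df.columns):
            raise InputError(f"table needs columns {sorted(required)}")
        groups: dict[str, GroupTree] = {}
        for (g, b, c), sub in df.groupby(["group", "batch", "cell"], sort=True):
            groups.setdefault(str(g), {}).setdefault(str(b), {})[str(c)] = (
                sub["value"].to_numpy(dtype=float)
            )
        return cls(groups=groups, single_sweep=single_sweep)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, single_sweep: bool = False) -> "NestedDataset":
        return cls.from_frame(pd.read_csv(path), single_sweep=single_sweep)
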