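"""Nested four-group electrophysiology datasets with known ground truth.

The generator reproduces the statistical structure of a nested culture
experiment: two knockout lines, each with its own control, measured over
independent culture batches, cells within batches, and repeated sweeps
within cells.  Values are log-normal (positive, right-skewed, as typical of
PSC amplitudes) with multiplicative random effects at the batch and cell
levels and multiplicative sweep noise:

    value = baseline * group_effect * exp(b) * exp(c) * eps

with b ~ N(0, batch_sd^2), c ~ N(0, cell_sd^2) and eps log-normal with mean
1 and coefficient of variation ``sweep_cv``.  The defaults emulate an ~85%
single-knockout reduction and a further ~50% reduction in the double
manipulation, i.e. a true ratio-of-ratios T of 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError
from ..nested import GROUP_LABELS, NestedDataset

__all__ = ["EphysSimParams", "EphysGroundTruth", "simulate_ephys_dataset"]


def _default_effects() -> dict[str, float]:
    return {"control_a": 1.0, "ko_a": 0.15, "control_b": 1.0, "ko_b": 0.075}


@dataclass(frozen=True)
class EphysSimParams:
    """Shape, effect sizes and variance components of a simulated dataset.

    ``n_cells_per_batch`` and ``n_sweeps_per_cell`` may be a single count or
    an inclusive ``(low, high)`` range sampled per batch / per cell.
    ``batch_sd`` and ``cell_sd`` are standard deviations of the log-scale
    random effects; ``sweep_cv`` is the coefficient of variation of the
    multiplicative within-cell sweep noise.
    """

    n_batches_per_group: int = 3
    n_cells_per_batch: int | tuple[int, int] = 6
    n_sweeps_per_cell: int | tuple[int, int] = (3, 4)
    baseline_mean: float = 100.0                     # pA
    group_effects: dict[str, float] = field(default_factory=_default_effects)
    batch_sd: float = 0.3                            # log units
    cell_sd: float = 0.3                             # log units
    sweep_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches_per_group < 1:
            raise ParameterError("n_batches_per_group must be >= 1")
        for name in ("n_cells_per_batch", "n_sweeps_per_cell"):
            v = getattr(self, name)
            lo = v[0] if isinstance(v, tuple) else v
            hi = v[1] if isinstance(v, tuple) else v
            if lo < 1 or hi < lo:
                raise ParameterError(f"invalid count range for {name}: {v}")
        if min(self.batch_sd, self.cell_sd, self.sweep_cv) < 0:
            raise ParameterError("scale parameters must be >= 0")
        if self.baseline_mean <= 0:
            raise ParameterError("baseline_mean must be > 0")
        if set(self.group_effects) != set(GROUP_LABELS):
            raise ParameterError(f"group_effects must have exactly the labels {GROUP_LABELS}")
        if any(e <= 0 for e in self.group_effects.values()):
            raise ParameterError("group_effects must be > 0")

    @property
    def t_true(self) -> float:
        """True ratio-of-ratios implied by the group effects."""
        e = self.group_effects
        return (e["ko_a"] / e["control_a"]) / (e["ko_b"] / e["control_b"])


@dataclass(frozen=True)
class EphysGroundTruth:
    """True effects and realized per-level random effects of one dataset."""

    t_true: float
    group_effects: dict[str, float]
    batch_effects: dict[str, dict[str, float]]           # exp(b) factors
    cell_effects: dict[str, dict[str, dict[str, float]]]  # exp(c) factors


def _draw_count(count: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(count, tuple):
        return int(rng.integers(count[0], count[1] + 1))
    return int(count)


def simulate_ephys_dataset(
    params: EphysSimParams,
) -> tuple[NestedDataset, EphysGroundTruth]:
    """Generate one nested dataset plus its ground-truth record.

    Batches are drawn independently for every group (controls and knockouts
    of the same line do not share cultures), mirroring independent
    per-group resampling in the bootstrap.  Bit-for-bit reproducible for a
    given seed.
    """
    rng = np.random.default_rng(params.seed)
    # lognormal sweep noise with mean 1 and CV sweep_cv
    s2 = np.log1p(params.sweep_cv**2)
    sweep_sigma = np.sqrt(s2)

    groups: dict[str, dict] = {}
    batch_fx: dict[str, dict[str, float]] = {}
    cell_fx: dict[str, dict[str, dict[str, float]]] = {}
    for g in GROUP_LABELS:
        effect = params.group_effects[g]
        groups[g] = {}
        batch_fx[g] = {}
        cell_fx[g] = {}
        for b in range(params.n_batches_per_group):
            b_label = f"b{b}"
            bf = float(np.exp(rng.normal(0.0, params.batch_sd)))
            batch_fx[g][b_label] = bf
            cells = {}
            cell_fx[g][b_label] = {}
            for c in range(_draw_count(params.n_cells_per_batch, rng)):
                c_label = f"c{c}"
                cf = float(np.exp(rng.normal(0.0, params.cell_sd)))
                cell_fx[g][b_label][c_label] = cf
                n_sweeps = _draw_count(params.n_sweeps_per_cell, rng)
                noise = np.exp(rng.normal(-s2 / 2, sweep_sigma, size=n_sweeps))
                cells[c_label] = params.baseline_mean * effect * bf * cf * noise
            groups[g][b_label] = cells
    single = (params.n_sweeps_per_cell == 1)
    dataset = NestedDataset(groups=groups, single_sweep=single)
    truth = EphysGroundTruth(
        t_true=params.t_true,
        group_effects=dict(params.group_effects),
        batch_effects=batch_fx,
        cell_effects=cell_fx,
    )
    return dataset, truth
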