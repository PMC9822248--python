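"""Three-level hierarchical bootstrap of a ratio-of-ratios statistic.

The test statistic compares two knockout lines after normalizing each to its
own control:

    T = [mean(ko_a) / mean(control_a)] / [mean(ko_b) / mean(control_b)]

with null value T = 1.  Its sampling distribution is estimated by resampling
with replacement at three nested levels — culture batch, cell, sweep —
independently within each of the four groups, so that batch-level,
cell-level and sweep-level variability all propagate into the replicate
distribution T*.  The 95% confidence interval uses the percentile method and
the directional null probability is the fraction of replicates on the null
side of 1:

    P_H0 = #{T* <= 1} / n_iter   (alternative T > 1, e.g. PSC amplitudes)
    P_H0 = #{T* >= 1} / n_iter   (alternative T < 1, e.g. paired-pulse ratios)

Unlike a classical p-value this is a direct estimate of the probability of
the null hypothesis given the data.  The procedure makes no distributional
assumptions and tolerates unequal variances between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, InputError, UndefinedMetricError
from .nested import GROUP_LABELS, GroupTree, NestedDataset

__all__ = [
    "BootstrapResult",
    "statistic_T",
    "resample_nested",
    "run_bootstrap",
    "percentile_interval",
    "p_null",
]

# Fixed iteration chunk so the stream of RNG draws — hence the result under a
# given seed — does not depend on n_iter batching internals.
_CHUNK = 4096
_MAX_REDRAW_ROUNDS = 100


@dataclass(frozen=True)
class BootstrapResult:
    """Observed statistic, its bootstrap replicates and derived summaries."""

    t_obs: float
    t_star: np.ndarray
    ci_95: tuple[float, float]
    p_h0: float
    direction: str
    n_iter: int
    seed: int
    n_redraws: int = 0
    level: str = "sweeps"
    ci_level: float = 0.95
    quantile_rule: str = "linear"

    def summary(self) -> dict:
        """JSON-ready summary (without the full replicate sample)."""
        return {
            "t_obs": self.t_obs,
            "ci_95": list(self.ci_95),
            "p_h0": self.p_h0,
            "direction": self.direction,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "n_redraws": self.n_redraws,
            "level": self.level,
            "quantile_rule": self.quantile_rule,
        }


# --------------------------------------------------------------------------
# statistic
# --------------------------------------------------------------------------
def statistic_T(dataset: NestedDataset, level: str = "sweeps") -> float:
    """Ratio-of-ratios statistic T on the observed dataset.

    T = (mean(ko_a)/mean(control_a)) / (mean(ko_b)/mean(control_b)), each
    mean taken over all sweep values pooled within the group (``level
    ='sweeps'``, default) or over per-cell means (``level='cells'``).
    """
    m = {g: dataset.group_mean(g, level=level) for g in GROUP_LABELS}
    if m["control_a"] == 0.0 or m["control_b"] == 0.0:
        raise UndefinedMetricError("control group mean is zero; T is undefined")
    return (m["ko_a"] / m["control_a"]) / (m["ko_b"] / m["control_b"])


# --------------------------------------------------------------------------
# explicit tree resampling (one draw)
# --------------------------------------------------------------------------
def _resample_group(tree: GroupTree, rng: np.random.Generator,
                    single_sweep: bool) -> GroupTree:
    batch_labels = list(tree)
    drawn_batches = rng.integers(0, len(batch_labels), size=len(batch_labels))
    out: GroupTree = {}
    for i, bi in enumerate(drawn_batches):
        cells = tree[batch_labels[bi]]
        cell_labels = list(cells)
        drawn_cells = rng.integers(0, len(cell_labels), size=len(cell_labels))
        new_cells: dict[str, np.ndarray] = {}
        for j, ci in enumerate(drawn_cells):
            vals = cells[cell_labels[ci]]
            if single_sweep:
                new_cells[f"c{j}"] = vals.copy()
            else:
                new_cells[f"c{j}"] = vals[rng.integers(0, vals.size, size=vals.size)]
        out[f"b{i}"] = new_cells
    return out


def resample_nested(dataset: NestedDataset,
                    rng: np.random.Generator) -> NestedDataset:
    """One hierarchical resample of the dataset.

    Within each group independently: batches are drawn with replacement
    (same count as the original), then each drawn batch's cells are drawn
    with replacement (that batch's own cell count), then each drawn cell's
    sweeps (that cell's own sweep count).  Group identity is preserved.  For
    single-sweep designs (e.g. sucrose charge) the sweep level is skipped.
    """
    groups = {
        g: _resample_group(dataset.groups[g], rng, dataset.single_sweep)
        for g in GROUP_LABELS
    }
    return NestedDataset(groups=groups, single_sweep=dataset.single_sweep)


# --------------------------------------------------------------------------
# vectorized resampled group means
# --------------------------------------------------------------------------
def _as_balanced_array(tree: GroupTree) -> np.ndarray | None:
    """(B, C, S) value array if the tree is balanced, else None."""
    cell_lists = [list(cells.values()) for cells in tree.values()]
    n_cells = {len(cl) for cl in cell_lists}
    n_sweeps = {v.size for cl in cell_lists for v in cl}
    if len(n_cells) != 1 or len(n_sweeps) != 1:
        return None
    return np.array([[v for v in cl] for cl in cell_lists], dtype=float)


def _balanced_means(vals: np.ndarray, n: int, rng: np.random.Generator,
                    single_sweep: bool, level: str) -> np.ndarray:
    """Means of `n` hierarchical resamples of a balanced (B, C, S) tree."""
    B, C, S = vals.shape
    bi = rng.integers(0, B, size=(n, B))
    ci = rng.integers(0, C, size=(n, B, C))
    x = vals[bi[:, :, None], ci]                      # (n, B, C, S)
    if not single_sweep and S > 1:
        si = rng.integers(0, S, size=(n, B, C, S))
        x = np.take_along_axis(x, si, axis=3)
    if level == "cells":
        return x.mean(axis=3).mean(axis=(1, 2))
    return x.mean(axis=(1, 2, 3))


def _unbalanced_means(tree: GroupTree, n: int, rng: np.random.Generator,
                      single_sweep: bool, level: str) -> np.ndarray:
    batches = [list(cells.values()) for cells in tree.values()]
    B = len(batches)
    out = np.empty(n)
    for it in range(n):
        total = 0.0
        count = 0
        cell_means_sum = 0.0
        n_cells_tot = 0
        for bi in rng.integers(0, B, size=B):
            cells = batches[bi]
            C = len(cells)
            for ci in rng.integers(0, C, size=C):
                v = cells[ci]
                if single_sweep or v.size == 1:
                    s = v.sum()
                else:
                    s = v[rng.integers(0, v.size, size=v.size)].sum()
                total += s
                count += v.size
                cell_means_sum += s / v.size
                n_cells_tot += 1
        out[it] = cell_means_sum / n_cells_tot if level == "cells" else total / count
    return out


def _group_means(tree: GroupTree, n: int, rng: np.random.Generator,
                 single_sweep: bool, level: str) -> np.ndarray:
    balanced = _as_balanced_array(tree)
    if balanced is not None:
        return _balanced_means(balanced, n, rng, single_sweep, level)
    return _unbalanced_means(tree, n, rng, single_sweep, level)


# --------------------------------------------------------------------------
# replicate summaries
# --------------------------------------------------------------------------
def percentile_interval(samples: np.ndarray,
                        level: float = 0.95) -> tuple[float, float]:
    """Percentile-method confidence interval (linear-interpolated quantiles)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1:
        raise InputError("need at least one sample for a percentile interval")
    lo, hi = np.quantile(samples, [(1 - level) / 2, 1 - (1 - level) / 2],
                         method="linear")
    return float(lo), float(hi)


def p_null(samples: np.ndarray, direction: str) -> float:
    """Directional probability of the null T = 1 from the replicate sample.

    ``direction='greater'`` (alternative T > 1) counts replicates <= 1;
    ``direction='less'`` counts replicates >= 1.  Ties at exactly 1 are
    always on the null side.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise InputError("empty replicate sample")
    if direction == "greater":
        return float(np.mean(samples <= 1.0))
    if direction == "less":
        return float(np.mean(samples >= 1.0))
    raise InputError(f"direction must be 'greater' or 'less', got {direction!r}")


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------
def run_bootstrap(dataset: NestedDataset, n_iter: int = 100_000,
                  direction: str = "greater", seed: int = 0,
                  level: str = "sweeps") -> BootstrapResult:
    """Full hierarchical bootstrap of T.

    Draws ``n_iter`` replicates T*, each computed on an independent
    three-level resample of the four groups, and summarizes them with the
    percentile 95% CI and the directional null probability.  Replicates in
    which a resampled control mean is exactly zero are re-drawn (the count
    is reported in the result).  Fully reproducible for a given seed.
    """
    if direction not in ("greater", "less"):
        raise InputError(f"direction must be 'greater' or 'less', got {direction!r}")
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    t_obs = statistic_T(dataset, level=level)
    rng = np.random.default_rng(seed)

    t_star = np.empty(n_iter)
    n_redraws = 0
    pos = 0
    while pos < n_iter:
        n = min(_CHUNK, n_iter - pos)
        means = {
            g: _group_means(dataset.groups[g], n, rng, dataset.single_sweep, level)
            for g in GROUP_LABELS
        }
        bad = (means["control_a"] == 0.0) | (means["control_b"] == 0.0)
        rounds = 0
        while bad.any():
            rounds += 1
            if rounds > _MAX_REDRAW_ROUNDS:
                raise DegenerateDataError(
                    "could not obtain nonzero resampled control means"
                )
            n_redraws += int(bad.sum())
            k = int(bad.sum())
            for g in GROUP_LABELS:
                means[g][bad] = _group_means(
                    dataset.groups[g], k, rng, dataset.single_sweep, level
                )
            bad = (means["control_a"] == 0.0) | (means["control_b"] == 0.0)
        t_star[pos:pos + n] = (
            (means["ko_a"] / means["control_a"])
            / (means["ko_b"] / means["control_b"])
        )
        pos += n

    ci = percentile_interval(t_star, 0.95)
    return BootstrapResult(
        t_obs=t_obs, t_star=t_star, ci_95=ci,
        p_h0=p_null(t_star, direction), direction=direction,
        n_iter=n_iter, seed=seed, n_redraws=n_redraws, level=level,
    )
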