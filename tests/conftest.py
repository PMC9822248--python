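import numpy as np
import pytest

from synapkit import NestedDataset


def constant_dataset(value: float = 5.0, n_batches: int = 2, n_cells: int = 2,
                     n_sweeps: int = 2) -> NestedDataset:
    """All four groups identical with no within-group variation."""
    groups = {
        g: {
            f"b{b}": {f"c{c}": np.full(n_sweeps, value) for c in range(n_cells)}
            for b in range(n_batches)
        }
        for g in ("control_a", "ko_a", "control_b", "ko_b")
    }
    return NestedDataset(groups=groups)


def two_batch_dataset(values: dict[str, tuple[float, float]]) -> NestedDataset:
    """2 batches x 1 cell x 1 sweep per group, one scalar per batch."""
    groups = {
        g: {f"b{i}": {"c0": np.array([v])} for i, v in enumerate(vals)}
        for g, vals in values.items()
    }
    return NestedDataset(groups=groups)


@pytest.fixture
def tiny_values() -> dict[str, tuple[float, float]]:
    return {
        "control_a": (10.0, 14.0),
        "ko_a": (2.0, 5.0),
        "control_b": (9.0, 13.0),
        "ko_b": (1.0, 2.0),
    }


@pytest.fixture
def tiny_dataset(tiny_values) -> NestedDataset:
    return two_batch_dataset(tiny_values)


def enumerate_tiny_bootstrap(values: dict[str, tuple[float, float]]):
    """Exhaustive oracle for the 2-batch x 1-cell x 1-sweep design.

    Each group's resampled mean is the average of two batch draws with
    replacement: {a, (a+b)/2, b} with probabilities {1/4, 1/2, 1/4}.  The
    joint distribution of T* over the four independent groups has 3^4
    support points (256 equiprobable draws).  Returns (t_values, weights).
    """
    means, probs = {}, {}
    for g, (a, b) in values.items():
        means[g] = np.array([a, (a + b) / 2.0, b])
        probs[g] = np.array([0.25, 0.5, 0.25])
    t_vals, weights = [], []
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    t = (means["ko_a"][j] / means["control_a"][i]) / (
                        means["ko_b"][l] / means["control_b"][k]
                    )
                    t_vals.append(t)
                    weights.append(probs["control_a"][i] * probs["ko_a"][j]
                                   * probs["control_b"][k] * probs["ko_b"][l])
    return np.array(t_vals), np.array(weights)


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Population quantile (inverse CDF) of a discrete distribution."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w)
    return float(v[np.searchsorted(cdf, q, side="left")])
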