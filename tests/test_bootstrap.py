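"""Unit and property tests for the three-level hierarchical bootstrap."""

import numpy as np
import pytest

from synapkit import (
    NestedDataset,
    p_null,
    percentile_interval,
    resample_nested,
    run_bootstrap,
    statistic_T,
)
from synapkit.errors import InputError, UndefinedMetricError

from conftest import (
    constant_dataset,
    enumerate_tiny_bootstrap,
    two_batch_dataset,
    weighted_quantile,
)


# --------------------------------------------------------------------- T
def test_statistic_null_value_is_one():
    assert statistic_T(constant_dataset(5.0)) == pytest.approx(1.0)


def test_statistic_ratio_of_ratios():
    ds = two_batch_dataset({
        "control_a": (10.0, 10.0), "ko_a": (2.0, 2.0),
        "control_b": (10.0, 10.0), "ko_b": (1.0, 1.0),
    })
    assert statistic_T(ds) == pytest.approx(2.0)


def test_statistic_zero_control_mean_errors():
    ds = two_batch_dataset({
        "control_a": (1.0, -1.0), "ko_a": (2.0, 2.0),
        "control_b": (10.0, 10.0), "ko_b": (1.0, 1.0),
    })
    with pytest.raises(UndefinedMetricError):
        statistic_T(ds)


# ------------------------------------------------------------- resampling
def test_resample_single_leaf_is_identity():
    groups = {g: {"b0": {"c0": np.array([float(i)])}}
              for i, g in enumerate(("control_a", "ko_a", "control_b", "ko_b"), 1)}
    ds = NestedDataset(groups=groups)
    out = resample_nested(ds, np.random.default_rng(0))
    for g in ds.groups:
        np.testing.assert_array_equal(out.group_values(g), ds.group_values(g))


def test_resample_preserves_level_counts():
    rng = np.random.default_rng(1)
    groups = {g: {
        "b0": {"c0": np.array([1.0, 2.0]), "c1": np.array([3.0])},
        "b1": {"c0": np.array([4.0, 5.0, 6.0])},
    } for g in ("control_a", "ko_a", "control_b", "ko_b")}
    ds = NestedDataset(groups=groups)
    for _ in range(20):
        out = resample_nested(ds, rng)
        n_b, n_cells, n_sweeps = out.counts("ko_a")
        assert n_b == 2
        # each drawn batch keeps its own cell count; each drawn cell its sweep count
        assert sorted(n_cells) in ([1, 1], [1, 2], [2, 2])
        for cells, sweeps in zip(n_cells, n_sweeps):
            assert len(sweeps) == cells


def test_two_batch_group_mean_enumeration():
    """Resampled group mean of a 2-batch/1-cell/1-sweep group takes the values
    {a, (a+b)/2, b} with probabilities {1/4, 1/2, 1/4}."""
    ds = two_batch_dataset({
        "control_a": (1.0, 3.0), "ko_a": (1.0, 3.0),
        "control_b": (1.0, 3.0), "ko_b": (1.0, 3.0),
    })
    rng = np.random.default_rng(7)
    n = 40_000
    means = np.array([resample_nested(ds, rng).group_mean("ko_a") for _ in range(n)])
    freq = {v: np.mean(means == v) for v in (1.0, 2.0, 3.0)}
    for v, p in ((1.0, 0.25), (2.0, 0.5), (3.0, 0.25)):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq[v] - p) < 3 * se


# ------------------------------------------------------------- summaries
def test_percentile_interval_constant_and_degenerate_level():
    assert percentile_interval(np.full(10, 3.0)) == (3.0, 3.0)
    x = np.arange(1.0, 12.0)
    lo, hi = percentile_interval(x, level=0.0)
    assert lo == hi == np.median(x)


def test_percentile_interval_matches_independent_quantile():
    """Cross-check against a hand-coded linear-interpolation quantile."""
    x = np.arange(1.0, 1001.0)
    rng = np.random.default_rng(3)
    rng.shuffle(x)

    def manual_quantile(sorted_x, q):
        h = (len(sorted_x) - 1) * q
        lo = int(np.floor(h))
        return sorted_x[lo] + (h - lo) * (sorted_x[min(lo + 1, len(sorted_x) - 1)] - sorted_x[lo])

    xs = np.sort(x)
    lo, hi = percentile_interval(x, 0.95)
    assert lo == pytest.approx(manual_quantile(xs, 0.025))
    assert hi == pytest.approx(manual_quantile(xs, 0.975))


def test_p_null_directional_counts():
    t = np.array([0.5, 0.9, 1.0, 1.2])
    assert p_null(t, "greater") == pytest.approx(0.75)
    assert p_null(t, "less") == pytest.approx(0.5)
    assert p_null(np.array([1.1, 2.0]), "greater") == 0.0
    with pytest.raises(InputError):
        p_null(np.array([]), "greater")


def test_p_null_complements_strict_fraction():
    rng = np.random.default_rng(5)
    t = np.concatenate([rng.lognormal(size=500), np.ones(17)])
    assert p_null(t, "greater") + np.mean(t > 1.0) == pytest.approx(1.0, abs=0)


# ----------------------------------------------------------------- driver
def test_degenerate_dataset_gives_exact_null():
    ds = constant_dataset(5.0)
    res = run_bootstrap(ds, n_iter=2000, direction="greater", seed=0)
    assert np.all(res.t_star == 1.0)
    assert res.ci_95 == (1.0, 1.0)
    assert res.p_h0 == 1.0


def test_bootstrap_matches_exhaustive_enumeration(tiny_dataset, tiny_values):
    t_exact, w = enumerate_tiny_bootstrap(tiny_values)
    p_exact = float(w[t_exact <= 1.0].sum())
    res = run_bootstrap(tiny_dataset, n_iter=100_000, direction="greater", seed=11)
    se = np.sqrt(p_exact * (1 - p_exact) / res.n_iter)
    assert abs(res.p_h0 - p_exact) < 3 * se
    assert res.ci_95[0] == pytest.approx(weighted_quantile(t_exact, w, 0.025))
    assert res.ci_95[1] == pytest.approx(weighted_quantile(t_exact, w, 0.975))


def test_bootstrap_determinism(tiny_dataset):
    a = run_bootstrap(tiny_dataset, n_iter=5000, seed=42)
    b = run_bootstrap(tiny_dataset, n_iter=5000, seed=42)
    np.testing.assert_array_equal(a.t_star, b.t_star)
    c = run_bootstrap(tiny_dataset, n_iter=5000, seed=43)
    assert not np.array_equal(a.t_star, c.t_star)


def test_scale_invariance_of_line(tiny_values):
    """Multiplying ko_a and control_a by the same constant leaves T and,
    under the same seed, every T* unchanged."""
    base = two_batch_dataset(tiny_values)
    scaled_values = dict(tiny_values)
    scaled_values["ko_a"] = tuple(3.0 * v for v in tiny_values["ko_a"])
    scaled_values["control_a"] = tuple(3.0 * v for v in tiny_values["control_a"])
    scaled = two_batch_dataset(scaled_values)
    r1 = run_bootstrap(base, n_iter=2000, seed=9)
    r2 = run_bootstrap(scaled, n_iter=2000, seed=9)
    assert r1.t_obs == pytest.approx(r2.t_obs)
    np.testing.assert_allclose(r1.t_star, r2.t_star, rtol=1e-12)


def test_single_group_scaling_scales_t_star(tiny_values):
    """Scaling only ko_a by c multiplies T_obs and every T* by c (same seed)."""
    base = two_batch_dataset(tiny_values)
    scaled_values = dict(tiny_values)
    scaled_values["ko_a"] = tuple(2.5 * v for v in tiny_values["ko_a"])
    scaled = two_batch_dataset(scaled_values)
    r1 = run_bootstrap(base, n_iter=2000, seed=13)
    r2 = run_bootstrap(scaled, n_iter=2000, seed=13)
    np.testing.assert_allclose(r2.t_star, 2.5 * r1.t_star, rtol=1e-12)


def test_single_sweep_flag_skips_sweep_level():
    """With the sweep level collapsed, a 1-batch/1-cell group is resampled
    to itself, so all T* equal T_obs."""
    groups = {g: {"b0": {"c0": np.array([2.0, 4.0])}}
              for g in ("control_a", "ko_a", "control_b", "ko_b")}
    ds = NestedDataset(groups=groups, single_sweep=True)
    res = run_bootstrap(ds, n_iter=500, seed=1)
    assert np.all(res.t_star == res.t_obs)
    ds2 = NestedDataset(groups={g: {k: {c: v.copy() for c, v in cc.items()}
                                    for k, cc in groups[g].items()}
                               for g in groups}, single_sweep=False)
    res2 = run_bootstrap(ds2, n_iter=500, seed=1)
    assert not np.all(res2.t_star == res2.t_obs)


def test_moderate_variance_effect_detected():
    """A generated dataset with a true 2-fold ratio and moderate variance
    yields p_h0(greater) < 0.05 at a fixed seed."""
    from synapkit.synthetic import EphysSimParams, simulate_ephys_dataset

    params = EphysSimParams(batch_sd=0.15, cell_sd=0.15, sweep_cv=0.2,
                            n_sweeps_per_cell=3, seed=0)
    ds, truth = simulate_ephys_dataset(params)
    assert truth.t_true == pytest.approx(2.0)
    res = run_bootstrap(ds, n_iter=10_000, direction="greater", seed=0)
    assert res.p_h0 < 0.05


def test_ci_coverage_envelope():
    """Across 500 generated datasets with known T_true the 95% percentile CI
    contains the truth in >= 85% of runs (the hierarchical bootstrap is
    approximately, not exactly, calibrated)."""
    from synapkit.synthetic import EphysSimParams, simulate_ephys_dataset

    covered = 0
    n = 500
    for i in range(n):
        params = EphysSimParams(n_batches_per_group=3, n_cells_per_batch=6,
                                n_sweeps_per_cell=3, batch_sd=0.3, cell_sd=0.3,
                                sweep_cv=0.3, seed=31_000 + i)
        ds, truth = simulate_ephys_dataset(params)
        res = run_bootstrap(ds, n_iter=2000, seed=62_000 + i)
        lo, hi = res.ci_95
        covered += lo <= truth.t_true <= hi
    assert covered / n >= 0.85
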