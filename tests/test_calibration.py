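import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import rbe2f as rb
from rbe2f.calibration import (
    ROUND_FREE_PARAMETERS,
    FitProblem,
    WeightScheme,
    build_weights,
    gls_objective,
    multistart_fit,
    round_presets,
    sample_starts,
)
from rbe2f.model import ObservableMap, observe, simulate
from rbe2f.synth import Design, NoiseModel, TimeCourseDataset, generate


def _problem(dataset, theta, free=("kCDS", "kkCE"), **kw):
    return FitProblem(dataset=dataset, free_names=list(free),
                      theta_nominal=theta, **kw)


def test_objective_is_zero_at_perfect_fit(zero_noise_dataset, original):
    prob = _problem(zero_noise_dataset, original)
    assert gls_objective(original, prob) == 0.0


def test_objective_scales_quadratically_with_residuals(zero_noise_dataset,
                                                       original):
    base = zero_noise_dataset.df
    shifted = base.copy()
    shifted["value"] = shifted["value"] + 0.01
    shifted2 = base.copy()
    shifted2["value"] = shifted2["value"] + 0.03
    meta = zero_noise_dataset.meta
    J1 = gls_objective(original, _problem(TimeCourseDataset(shifted, meta),
                                          original))
    J3 = gls_objective(original, _problem(TimeCourseDataset(shifted2, meta),
                                          original))
    assert J1 > 0
    assert np.isclose(J3 / J1, 9.0, rtol=1e-10)


def test_objective_matches_hand_computed_weighted_sum(original,
                                                      quiescent_original):
    """Three-point toy block checked against an explicit r'Qr sum."""
    times = np.array([2.0, 5.0, 9.0])
    values = np.array([0.2, 0.4, 0.3])
    weights = np.array([1.0, 2.0, 0.5])
    df = pd.DataFrame({"experiment": 1, "observable": "CycD", "time": times,
                       "value": values, "weight": weights})
    ds = TimeCourseDataset(df, meta={"S": 1.5,
                                     "init": list(quiescent_original)})
    prob = _problem(ds, original)

    traj = simulate(original, quiescent_original, 1.5,
                    np.concatenate([[0.0], times]))
    y = observe(traj, ObservableMap.default(), names=["CycD"])
    y = y[np.isin(y["time"], times)]["CycD"].to_numpy()
    expected = float(np.sum(weights * (y - values) ** 2))
    assert np.isclose(gls_objective(original, prob), expected, rtol=1e-12)


def test_objective_invariant_to_row_order(zero_noise_dataset, original):
    shuffled = zero_noise_dataset.df.sample(frac=1.0, random_state=0)
    shuffled = shuffled.sort_values(["observable", "time"])  # keep times valid
    ds = TimeCourseDataset(shuffled, meta=zero_noise_dataset.meta)
    theta = original.replace(kCDS=0.6)
    assert np.isclose(gls_objective(theta, _problem(ds, original)),
                      gls_objective(theta, _problem(zero_noise_dataset,
                                                    original)),
                      rtol=1e-12)


def test_equal_weights_are_identity(zero_noise_dataset):
    w = build_weights(zero_noise_dataset, WeightScheme("equal"))
    for block in w.values():
        assert np.array_equal(block, np.ones_like(block))


def test_excluded_observable_has_no_influence(zero_noise_dataset, original):
    """Zero weights remove an observable's residuals from J exactly."""
    times = zero_noise_dataset.block(1, "CycE")["time"].to_numpy()
    scheme = WeightScheme("exclude",
                          excluded=tuple((1, "CycE", t) for t in times))
    corrupted = zero_noise_dataset.df.copy()
    mask = corrupted["observable"] == "CycE"
    corrupted.loc[mask, "value"] = 99.0
    ds_bad = TimeCourseDataset(corrupted, meta=zero_noise_dataset.meta)

    theta = original.replace(kCDS=0.5)
    J_clean = gls_objective(theta, _problem(zero_noise_dataset, original,
                                            weight_scheme=scheme))
    J_bad = gls_objective(theta, _problem(ds_bad, original,
                                          weight_scheme=scheme))
    assert J_clean == J_bad


def test_perturbing_excluded_datum_leaves_fit_identical(zero_noise_dataset,
                                                        original):
    t0 = float(zero_noise_dataset.block(1, "CycD")["time"].iloc[0])
    scheme = WeightScheme("exclude", excluded=((1, "CycD", t0),))
    corrupted = zero_noise_dataset.df.copy()
    hit = (corrupted["observable"] == "CycD") & (corrupted["time"] == t0)
    corrupted.loc[hit, "value"] = 123.0
    ds_bad = TimeCourseDataset(corrupted, meta=zero_noise_dataset.meta)

    starts = np.array([[0.3, 0.2]])
    fit_a = multistart_fit(_problem(zero_noise_dataset, original,
                                    weight_scheme=scheme), starts=starts)
    fit_b = multistart_fit(_problem(ds_bad, original, weight_scheme=scheme),
                           starts=starts)
    assert fit_a.J == fit_b.J
    assert fit_a.theta.values == fit_b.theta.values


def test_scale_reduce_balances_observable_magnitudes(original,
                                                     quiescent_original):
    """At a common relative error, a 10x larger observable contributes
    within 2x of the smaller one under scale_reduce weighting."""
    times = np.array([1.0, 2.0, 3.0])
    small = np.array([0.10, 0.11, 0.12])
    big = 10 * small
    rel = 0.05
    df = pd.DataFrame({
        "experiment": 1,
        "observable": ["CycD"] * 3 + ["RbTotal"] * 3,
        "time": np.concatenate([times, times]),
        "value": np.concatenate([small * (1 + rel), big * (1 + rel)]),
        "weight": 1.0,
    })
    ds = TimeCourseDataset(df)
    w = build_weights(ds, WeightScheme("scale_reduce"))
    contrib_small = float(np.sum(w[(1, "CycD")] * (small * rel) ** 2))
    contrib_big = float(np.sum(w[(1, "RbTotal")] * (big * rel) ** 2))
    assert 0.5 < contrib_big / contrib_small < 2.0
    # the literal printed form amplifies the large observable instead
    w_lit = build_weights(ds, WeightScheme("scale_reduce", literal=True))
    lit_big = float(np.sum(w_lit[(1, "RbTotal")] * (big * rel) ** 2))
    lit_small = float(np.sum(w_lit[(1, "CycD")] * (small * rel) ** 2))
    assert lit_big / lit_small > 100


def test_sample_starts_support_and_degenerate_bounds(zero_noise_dataset,
                                                     original):
    prob = _problem(zero_noise_dataset, original, free=("kCDS", "kkCE"))
    starts = sample_starts(prob, 1000, seed=1)
    lo, hi = prob.bounds_arrays()
    assert np.all(starts >= lo) and np.all(starts <= hi)

    degen = _problem(zero_noise_dataset, original, free=("kCDS",),
                     bounds={"kCDS": (0.45, 0.45)})
    assert np.allclose(sample_starts(degen, 1, seed=0), [[0.45]])


def test_starts_are_log_uniform(zero_noise_dataset, original):
    """KS test of the log-coordinates against uniformity, per parameter."""
    prob = _problem(zero_noise_dataset, original, free=("kCDS", "kkCE"))
    starts = sample_starts(prob, 5000, seed=7)
    lo, hi = prob.bounds_arrays()
    z = (np.log10(starts) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
    for dim in range(z.shape[1]):
        assert kstest(z[:, dim], "uniform").pvalue > 0.01


def test_start_at_truth_recovers_truth(zero_noise_dataset, original):
    free = ("kCDS", "kkCE")
    prob = _problem(zero_noise_dataset, original, free=free)
    truth = np.array([original[n] for n in free])
    fit = multistart_fit(prob, starts=truth[None, :])
    assert fit.J < 1e-10
    for n in free:
        assert np.isclose(fit.theta[n], original[n], rtol=1e-6)


def test_best_objective_not_worse_than_any_start(zero_noise_dataset,
                                                 original):
    prob = _problem(zero_noise_dataset, original, free=("kCDS", "kkCE"))
    starts = sample_starts(prob, 5, seed=2)
    fit = multistart_fit(prob, starts=starts)
    for s in starts:
        assert fit.J <= gls_objective(prob.theta_from_free(s), prob) + 1e-12
    assert fit.J == min(r["J"] for r in fit.starts)
    assert len(fit.starts) == 5


def test_quick_two_parameter_recovery(zero_noise_dataset, original):
    prob = _problem(zero_noise_dataset, original, free=("kCDS", "kR"))
    fit = multistart_fit(prob, n_starts=4, seed=5)
    assert abs(fit.theta["kCDS"] - original["kCDS"]) / original["kCDS"] < 1e-3
    assert abs(fit.theta["kR"] - original["kR"]) / original["kR"] < 1e-3


def test_round_presets_free_the_documented_parameters():
    r1 = round_presets("round1")
    assert len(r1.free_names) == 12
    assert set(r1.free_names) == {"kRE", "kkE", "kkM", "kCDS", "kR", "KS",
                                  "kkCE", "KE", "KCE", "dRP", "kkCD", "kb"}
    r2 = round_presets("round2")
    assert len(r2.free_names) == 10
    assert set(r2.free_names) == (set(r1.free_names)
                                  - {"KCE", "kkCD", "kRE", "KS"}
                                  | {"kP1", "kP2"})
    r3 = round_presets("round3")
    assert len(r3.free_names) == 14
    assert set(r3.free_names) == {"dMC", "KM", "kkM", "dE", "kRE", "kR",
                                  "dR", "dRP", "dCE", "KCE", "kkCE", "kkCD",
                                  "kCDS", "KS"}
    with pytest.raises(KeyError):
        round_presets("round9")


def test_round_preset_builds_problem(zero_noise_dataset, original):
    prob = round_presets("round2").problem(zero_noise_dataset,
                                           theta_nominal=original)
    assert prob.label == "round2"
    assert set(prob.free_names) | set(prob.fixed_names) == set(
        rb.CANONICAL_NAMES)
    assert set(prob.free_names) & set(prob.fixed_names) == set()
    for lo, hi in prob.bounds.values():
        assert 0 < lo <= hi


def test_fit_problem_validation(zero_noise_dataset, original):
    with pytest.raises(ValueError):
        FitProblem(dataset=zero_noise_dataset, free_names=["kCDS", "kCDS"],
                   theta_nominal=original)
    with pytest.raises(ValueError):
        FitProblem(dataset=zero_noise_dataset, free_names=["kCDS"],
                   theta_nominal=original, bounds={"kCDS": (1.0, 0.5)})
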