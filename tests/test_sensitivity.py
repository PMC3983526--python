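import numpy as np
import pytest
from scipy.stats import kstest, spearmanr

import rbe2f as rb
from rbe2f.model import ObservableMap
from rbe2f.sensitivity import (
    RankTable,
    SensitivityDesign,
    SensitivityTensor,
    compare_ranks,
    forward_sensitivities,
    global_rank,
    lhs_sample,
    local_rank,
    relative_sensitivities,
)

MYC_MAP = ObservableMap({"Myc": {"MC": 1.0}})


def test_relative_sensitivity_matches_closed_form(original):
    """Myc decouples from the rest of the network, so its sensitivities
    to its own synthesis and decay constants have closed forms.

    From a zero start, MC(t) = (kkM fS / d)(1 - exp(-d t)) with d = dMC:
    the relative sensitivity to kkM is exactly 1, and to dMC it is
    -1 + d t exp(-d t) / (1 - exp(-d t)).
    """
    times = (1.0, 3.0, 8.0)
    design = SensitivityDesign(times=times, observables=("Myc",), S=1.5)
    tensor = relative_sensitivities(original, design,
                                    parameters=("kkM", "dMC"),
                                    obs_map=MYC_MAP, init=np.zeros(7))
    d = original["dMC"]
    t = np.asarray(times)
    expected_dMC = -1 + d * t * np.exp(-d * t) / (1 - np.exp(-d * t))
    got_kkM = tensor.values[0, 0, :, 0]
    got_dMC = tensor.values[0, 0, :, 1]
    assert np.allclose(got_kkM, 1.0, atol=1e-6)
    assert np.allclose(got_dMC, expected_dMC, atol=1e-5)


def test_finite_difference_agrees_with_forward_sensitivity_odes(original,
                                                                quiescent_original):
    """Two independent derivative routes agree on the full model."""
    design = SensitivityDesign(times=(3.0, 10.0, 20.0, 30.0), S=1.5)
    params = ("kCDS", "dCD", "kR", "kP1")
    fd = relative_sensitivities(original, design, parameters=params,
                                init=quiescent_original)
    fwd = forward_sensitivities(original, design, parameters=params,
                                init=quiescent_original)
    a, b = fd.values, fwd.values
    mask = np.abs(b) > 1e-3
    assert np.all(np.abs(a[mask] - b[mask]) / np.abs(b[mask]) < 1e-3)
    assert np.allclose(a[~mask], b[~mask], atol=1e-4)


def test_msqr_hand_computed_on_toy_tensor():
    vals = np.array([[[[1.0, 0.0], [3.0, 0.0]]]])  # (1, 1, 2, 2)
    tensor = SensitivityTensor(values=vals, observables=("A",),
                               times=np.array([1.0, 2.0]),
                               parameters=("p", "q"))
    scores = tensor.msqr()
    assert np.isclose(scores[0], np.sqrt((1 + 9) / 2))
    assert scores[1] == 0.0
    # homogeneity: doubling every sensitivity doubles every score
    doubled = SensitivityTensor(values=2 * vals, observables=("A",),
                                times=np.array([1.0, 2.0]),
                                parameters=("p", "q"))
    assert np.allclose(doubled.msqr(), 2 * scores)
    # rootless variant is the square
    assert np.allclose(tensor.msqr(sqrt=False), scores ** 2)


def test_msqr_invariant_to_axis_reordering():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(2, 3, 4, 5))
    t = SensitivityTensor(values=vals, observables=tuple("abc"),
                          times=np.arange(4.0), parameters=tuple("pqrst"),
                          thetas=[None, None])
    permuted = SensitivityTensor(values=vals[:, ::-1, ::-1, :],
                                 observables=tuple("cba"),
                                 times=np.arange(4.0),
                                 parameters=tuple("pqrst"),
                                 thetas=[None, None])
    assert np.allclose(t.msqr(), permuted.msqr())


def test_local_rank_covers_all_24_parameters(original):
    table = local_rank(original)
    assert len(table.scores) == 24
    assert set(table.scores) == set(rb.CANONICAL_NAMES)
    assert all(v >= 0 for v in table.scores.values())
    scores = list(table.scores.values())
    assert scores == sorted(scores, reverse=True)


def test_zero_trajectory_sensitivities_are_finite_and_zero(original):
    """At S=0 from the empty state, Myc stays identically zero; the
    epsilon guard must return zero sensitivities, not NaNs."""
    design = SensitivityDesign(times=(1.0, 5.0), observables=("Myc",), S=0.0)
    tensor = relative_sensitivities(original, design, parameters=("kkM",),
                                    obs_map=MYC_MAP, init=np.zeros(7))
    assert np.all(np.isfinite(tensor.values))
    assert np.allclose(tensor.values, 0.0, atol=1e-6)


def test_lhs_single_sample_inside_bounds(original):
    bounds = {n: (0.1 * original[n], 10 * original[n])
              for n in rb.CANONICAL_NAMES}
    (sample,) = lhs_sample(bounds, 1, seed=0)
    for n, v in sample.items():
        assert bounds[n][0] <= v <= bounds[n][1]


def test_lhs_stratification_property():
    """Each parameter's 64 log-values occupy 64 distinct equal strata."""
    bounds = {"kCDS": (0.045, 4.5), "kR": (0.018, 1.8)}
    samples = lhs_sample(bounds, 64, seed=3)
    for name in bounds:
        lo, hi = np.log10(bounds[name][0]), np.log10(bounds[name][1])
        z = (np.log10([s[name] for s in samples]) - lo) / (hi - lo)
        strata = np.floor(z * 64).astype(int)
        assert sorted(strata) == list(range(64))


def test_lhs_marginals_log_uniform():
    bounds = {"kCDS": (0.045, 4.5)}
    samples = lhs_sample(bounds, 2000, seed=9)
    z = (np.log10([s["kCDS"] for s in samples]) - np.log10(0.045)) / 2.0
    assert kstest(z, "uniform").pvalue > 0.01


def test_global_rank_with_single_sample_equals_local_rank(original):
    design = SensitivityDesign(times=(3.0, 12.0, 30.0), S=1.5)
    local = local_rank(original, design)
    glob = global_rank(original, n_lhs=1, design=design, seed=4)
    assert glob.ranking() == local.ranking()
    for n in local.scores:
        assert glob.scores[n] == local.scores[n]


def test_global_rank_stable_across_seeds(original):
    """Rankings from independent LHS draws correlate strongly.

    Run at a reduced sample count to stay fast; the correlation
    threshold is set accordingly.
    """
    design = SensitivityDesign(times=(3.0, 9.0, 15.0, 21.0, 30.0), S=1.5)
    r1 = global_rank(original, n_lhs=16, design=design, seed=11)
    r2 = global_rank(original, n_lhs=16, design=design, seed=22)
    names = sorted(r1.scores)
    rho = spearmanr([r1.scores[n] for n in names],
                    [r2.scores[n] for n in names]).statistic
    assert rho > 0.75


def test_rank_table_tie_break_is_canonical_order():
    table = RankTable({"kb": 1.0, "dMC": 1.0, "KS": 2.0})
    assert table.ranking() == ["KS", "dMC", "kb"]
    with pytest.raises(ValueError):
        RankTable({"kb": -0.1})


def test_compare_ranks_identity():
    t = RankTable({"kb": 1.0, "dMC": 3.0, "KS": 2.0})
    cmp = compare_ranks(t, t)
    assert np.allclose(cmp["ratio"], 1.0)
    assert (cmp["displacement"] == 0).all()


def test_compare_ranks_detects_swap_and_guards_zero():
    a = RankTable({"kb": 4.0, "dMC": 2.0, "KS": 0.0})
    b = RankTable({"kb": 2.0, "dMC": 4.0, "KS": 0.0})
    cmp = compare_ranks(a, b).set_index("name")
    assert cmp.loc["kb", "displacement"] == -1
    assert cmp.loc["dMC", "displacement"] == 1
    assert cmp.loc["KS", "ratio"] == 1.0  # 0/0 guarded
    with pytest.raises(ValueError):
        compare_ranks(a, RankTable({"kb": 1.0}))


def test_scale_equivariance_of_relative_sensitivities(original,
                                                      quiescent_original):
    """Rescaling an observable's units leaves relative sensitivities
    unchanged (they are dimensionless)."""
    design = SensitivityDesign(times=(5.0, 15.0), observables=("X",), S=1.5)
    m1 = ObservableMap({"X": {"CD": 1.0}})
    m2 = ObservableMap({"X": {"CD": 7.3}})
    t1 = relative_sensitivities(original, design, parameters=("kCDS",),
                                obs_map=m1, init=quiescent_original)
    t2 = relative_sensitivities(original, design, parameters=("kCDS",),
                                obs_map=m2, init=quiescent_original)
    assert np.allclose(t1.values, t2.values, rtol=1e-9)


def test_recalibration_spares_myc_e2f_metabolism(original, opt1):
    """After the first re-calibration the model becomes less locally
    sensitive overall, except for the constants governing Myc and E2F
    metabolism, which dominate the re-fitted ranking."""
    ta = local_rank(original)
    tb = local_rank(opt1)
    cmp = compare_ranks(ta, tb).set_index("name")
    group = ["dMC", "kkM", "KM", "dE", "kkE"]
    for name in group:
        assert cmp.loc[name, "ratio"] > 1.0
    assert cmp.drop(index=group)["ratio"].median() < 1.0
    # the Myc/E2F metabolism constants fill the top of the opt1 ranking
    assert {"kkE", "kkM", "KM", "dMC", "dE"} <= set(tb.ranking()[:6])


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=25, deadline=None)
@given(n=st.integers(min_value=1, max_value=40),
       seed=st.integers(min_value=0, max_value=2**16))
def test_lhs_stratification_holds_for_any_sample_count(n, seed):
    bounds = {"kCDS": (0.045, 4.5), "kR": (0.018, 1.8)}
    samples = lhs_sample(bounds, n, seed=seed)
    for name, (lo, hi) in bounds.items():
        z = (np.log10([s[name] for s in samples]) - np.log10(lo)) \
            / (np.log10(hi) - np.log10(lo))
        strata = np.floor(np.clip(z, 0, 1 - 1e-12) * n).astype(int)
        assert sorted(strata) == list(range(n))
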