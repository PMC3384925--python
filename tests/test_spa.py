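"""Subwindow permutation analysis: Mann-Whitney machinery, COSS, selection,
and the Monte-Carlo submodel loop."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from koplspa import (
    MetaboliteScore,
    SPAConfig,
    compute_coss,
    mann_whitney_u,
    pooled_t_from_summary,
    run_spa,
    select_informative,
    ttest_crosscheck,
)
from koplspa.spa import prediction_errors_for_run, scores_to_frame

from conftest import PLANTED_INDICES, make_cohort


# ---------------------------------------------------- Mann-Whitney U test

def enumeration_p(a, b):
    """Independent oracle: exact one-sided P (B stochastically larger) by
    enumerating all assignments of the pooled values to the two samples.

    The statistic is U_A, the number of (a, b) pairs with a > b (ties count
    one half); small U_A is evidence that B is larger.
    """
    def u_stat(aa, bb):
        return sum(1 for x in aa for y in bb if x > y) + 0.5 * sum(
            1 for x in aa for y in bb if x == y
        )

    pooled = list(a) + list(b)
    na = len(a)
    u_obs = u_stat(a, b)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        aa = [pooled[i] for i in comb]
        bb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        count += u_stat(aa, bb) <= u_obs + 1e-12
        total += 1
    return count / total


def test_textbook_case_exact_p():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.05)  # 1 of C(6,3)=20 assignments as extreme


def test_identical_samples_not_significant():
    _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p >= 0.5


def test_exact_branch_agrees_with_enumeration_oracle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        a = rng.permutation(20)[: rng.integers(2, 5)].astype(float)
        b = rng.permutation(40)[: rng.integers(2, 5)].astype(float) + 0.5
        _, p = mann_whitney_u(a, b, method="exact")
        assert p == pytest.approx(enumeration_p(a, b), abs=1e-12)


def test_asymptotic_branch_close_to_enumeration():
    rng = np.random.default_rng(1)
    for _ in range(5):
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        _, p_asym = mann_whitney_u(a, b, method="asymptotic")
        assert abs(p_asym - enumeration_p(a, b)) < 0.02


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ------------------------------------------------------------------ COSS

def test_coss_boundary_and_trivial_values():
    assert compute_coss(0.01, dmean=0.1) == pytest.approx(2.0)
    assert compute_coss(1.0, dmean=0.1) == pytest.approx(0.0)
    assert compute_coss(0.1, dmean=-0.1) == pytest.approx(-math.log10(1.1))


def test_coss_clamps_nonpositive_p_with_warning():
    with pytest.warns(RuntimeWarning):
        val = compute_coss(0.0, dmean=0.1)
    assert np.isfinite(val) and val > 300


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    p1=st.floats(min_value=1e-12, max_value=1.0),
    p2=st.floats(min_value=1e-12, max_value=1.0),
)
def test_coss_monotone_decreasing_in_p_for_positive_dmean(p1, p2):
    lo, hi = sorted([p1, p2])
    assert compute_coss(lo, 0.5) >= compute_coss(hi, 0.5)


# -------------------------------------------------------------- selection

def score(name, dmean, p):
    return MetaboliteScore(name, 100, 0.1, 0.1 + dmean, dmean, 0.0, p,
                           compute_coss(p, dmean))


def test_selection_flags_only_below_threshold():
    out = select_informative([score("a", 0.05, 0.001), score("b", 0.04, 0.5)], 0.01)
    assert [s.name for s in out] == ["a", "b"]
    assert [s.informative for s in out] == [True, False]


def test_negative_dmean_removed_before_testing():
    out = select_informative([score("bad", -0.02, 1e-4), score("ok", 0.01, 0.02)], 0.05)
    flagged = {s.name: s.informative for s in out}
    assert flagged == {"ok": True, "bad": False}
    assert out[-1].name == "bad"  # removed metabolites ordered last


# ------------------------------------------------------------- run loop

def test_run_spa_deterministic_under_seed():
    conc = make_cohort(seed=1, n_group1=30, n_group2=30)
    cfg = SPAConfig(N=30, sigma=1.0, ao=1, seed=9)
    s1 = scores_to_frame(run_spa(conc.values, conc.labels, conc.metabolite_names, cfg))
    s2 = scores_to_frame(run_spa(conc.values, conc.labels, conc.metabolite_names, cfg))
    assert s1.equals(s2)


def test_run_spa_rejects_oversized_subwindow():
    conc = make_cohort(seed=1, n_group1=20, n_group2=20)
    with pytest.raises(ValueError):
        run_spa(conc.values, conc.labels, conc.metabolite_names,
                SPAConfig(N=5, Q=11, sigma=1.0, ao=1))


def test_config_validation():
    for bad in (dict(R=0.0), dict(R=1.0), dict(N=0), dict(Q=0)):
        with pytest.raises(ValueError):
            SPAConfig(**bad)


def test_constant_validation_column_permutes_to_identical_error():
    """If a subwindow variable takes a single value across the validation
    rows, permuting it cannot change the predictions."""
    rng = np.random.default_rng(4)
    X = rng.uniform(1, 2, size=(24, 5))
    cal = np.arange(16)
    val = np.arange(16, 24)
    X[val, 2] = 1.5  # constant across validation rows only
    y = np.r_[np.zeros(8, int), np.ones(8, int), np.zeros(4, int), np.ones(4, int)]
    err, permuted = prediction_errors_for_run(
        X, y, cal, val, np.array([0, 2, 4]), sigma=1.0, ao=1, rng=rng
    )
    assert permuted[2] == err


def test_every_metabolite_appears_in_the_expected_share_of_models():
    """n_models is Binomial(N, Q/p): at N=1000, Q=8, p=10 each metabolite
    should sit in about 800 submodels."""
    conc = make_cohort(seed=2, n_group1=15, n_group2=15)
    scores = run_spa(conc.values, conc.labels, conc.metabolite_names,
                     SPAConfig(N=1000, sigma=1.0, ao=1, seed=0))
    sd = math.sqrt(1000 * 0.8 * 0.2)
    for s in scores:
        assert abs(s.n_models - 800) <= 5 * sd


# ------------------------------------------------ planted-effect behavior

def test_planted_markers_score_high_across_replicates(planted_spa_replicates):
    """Each strongly planted marker should show DMEAN > 0 and COSS > 2 in at
    least 95% of replicate cohorts."""
    from koplspa.simulate import DEFAULT_METABOLITES

    planted_names = {DEFAULT_METABOLITES[i - 1] for i in PLANTED_INDICES}
    n_rep = len(planted_spa_replicates)
    hits = {name: 0 for name in planted_names}
    for scores in planted_spa_replicates:
        by_name = {s.name: s for s in scores}
        for name in planted_names:
            s = by_name[name]
            hits[name] += (s.dmean > 0) and (s.coss > 2)
    for name, h in hits.items():
        assert h >= 0.95 * n_rep, f"{name}: {h}/{n_rep}"


def test_noise_metabolites_rarely_reach_coss_two(planted_spa_replicates):
    from koplspa.simulate import DEFAULT_METABOLITES

    noise_names = {DEFAULT_METABOLITES[i - 1] for i in range(1, 11)
                   if i not in PLANTED_INDICES}
    n_rep = len(planted_spa_replicates)
    ok = 0
    for scores in planted_spa_replicates:
        by_name = {s.name: s for s in scores}
        ok += all(by_name[n].coss < 2 for n in noise_names)
    assert ok >= 0.9 * n_rep


# ---------------------------------------------------------- t-test twin

def test_ttest_crosscheck_detects_planted_marker():
    conc = make_cohort(seed=5, informative_indices=(1,), effect_size=2.0)
    p = ttest_crosscheck(conc.values, conc.labels)
    assert p[0] < 1e-3


def test_ttest_crosscheck_matches_summary_based_pooled_t():
    conc = make_cohort(seed=6, n_group1=30, n_group2=20)
    p = ttest_crosscheck(conc.values, conc.labels)
    x = conc.values[:, 3]
    classes = np.unique(conc.labels)
    g1, g2 = x[conc.labels == classes[0]], x[conc.labels == classes[1]]
    _, _, p_sum = pooled_t_from_summary(
        g1.mean(), g1.std(ddof=1), g1.size, g2.mean(), g2.std(ddof=1), g2.size
    )
    assert abs(p[3] - p_sum) < 1e-12
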