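"""Circular descriptive measures and the four inferential tests.

Small-sample oracles: a dense-grid half-plane sweep for the Hodges-Ajne m,
linear one-way ANOVA in the small-dispersion limit for Watson-Williams,
scipy's exact Wilcoxon (tie-free data) and full sign-assignment reasoning
for the signed-rank test.
"""

import math
import warnings

import numpy as np
import pytest
from scipy import stats as sp_stats

from anemotrack import circstats as cs

TWO_PI = 2 * math.pi


# --- descriptive -----------------------------------------------------------

def test_circ_mean_var_concentrated():
    mean, var, rbar = cs.circ_mean_var([math.pi / 2] * 3)
    assert (mean, var, rbar) == pytest.approx((math.pi / 2, 0.0, 1.0))


def test_circ_mean_var_antipodal_pair_undefined_mean():
    mean, var, rbar = cs.circ_mean_var([0.0, math.pi])
    assert math.isnan(mean)
    assert var == 1.0
    assert rbar == 0.0


def test_circ_mean_var_right_angle_pair():
    mean, var, rbar = cs.circ_mean_var([0.0, math.pi / 2])
    assert mean == pytest.approx(math.pi / 4)
    assert rbar == pytest.approx(math.sqrt(2) / 2)
    assert var == pytest.approx(1 - math.sqrt(2) / 2)


def test_kappa_ml_inverts_a1():
    """The piecewise inverse agrees with numerical inversion of A1."""
    from scipy import special, optimize

    for rbar in (0.2, 0.5, 0.6, 0.8, 0.9, 0.95):
        kappa = cs.kappa_ml(rbar)
        exact = optimize.brentq(
            lambda k: special.i1e(k) / special.i0e(k) - rbar, 1e-6, 1e4
        )
        assert kappa == pytest.approx(exact, rel=0.02)


# --- Hodges-Ajne -----------------------------------------------------------

def hodges_ajne_m_oracle(angles):
    """O(n^2)-style oracle: evaluate the closed half-plane count over a dense
    grid of diameters plus boundaries just past each data angle."""
    th = np.mod(np.asarray(angles, float), TWO_PI)
    n = th.size
    cands = np.concatenate([
        np.linspace(0, TWO_PI, 720, endpoint=False),
        th + 1e-9, th - 1e-9, th + math.pi + 1e-9,
    ])
    best = n
    for phi in cands:
        c = int(np.sum(np.mod(th - phi, TWO_PI) < math.pi))
        best = min(best, c, n - c)
    return best


def test_hodges_ajne_m_matches_sweep_oracle():
    rng = np.random.default_rng(11)
    for _ in range(60):
        n = int(rng.integers(4, 51))
        th = rng.uniform(0, TWO_PI, n)
        assert cs.hodges_ajne_m(th) == hodges_ajne_m_oracle(th)


def test_hodges_ajne_half_circle_exact_p():
    """All 10 angles in one half circle: m=0, p = 10/512 exactly."""
    th = np.linspace(0.1, math.pi - 0.1, 10)
    res = cs.hodges_ajne_test(th)
    assert res.statistic == 0
    assert res.p_value == pytest.approx(10 / 512)


def test_hodges_ajne_evenly_spaced_is_maximally_dispersed():
    th = np.arange(10) * TWO_PI / 10
    res = cs.hodges_ajne_test(th)
    assert res.statistic == 5
    assert res.p_value == 1.0


def test_hodges_ajne_four_points():
    """n=4: evenly spread is uninformative; the smallest attainable p (m=0)
    is 0.5, so n=4 can never reject at 0.05."""
    res = cs.hodges_ajne_test(np.arange(4) * math.pi / 2)
    assert res.p_value == 1.0
    res = cs.hodges_ajne_test([0.1, 0.2, 0.3, 0.4])
    assert res.p_value == pytest.approx(0.5)
    with pytest.raises(ValueError):
        cs.hodges_ajne_test([0.0, 1.0, 2.0])


def test_hodges_ajne_rotation_invariant():
    rng = np.random.default_rng(3)
    th = rng.vonmises(1.0, 1.5, 25) % TWO_PI
    base = cs.hodges_ajne_test(th)
    for delta in (0.7, 2.9, 4.4):
        rot = cs.hodges_ajne_test((th + delta) % TWO_PI)
        assert rot.statistic == base.statistic
        assert rot.p_value == base.p_value


# --- Watson-Williams -------------------------------------------------------

def test_ww_identical_groups_f_zero():
    g = [0.4, 0.5, 0.6, 0.45, 0.55]
    res = cs.watson_williams_test([g, g])
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0)


def test_ww_strong_separation_power():
    rng = np.random.default_rng(21)
    g1 = rng.vonmises(0.0, 10.0, 50)
    g2 = rng.vonmises(math.pi / 2, 10.0, 50)
    res = cs.watson_williams_test([g1, g2])
    assert res.p_value < 1e-6
    assert res.df == (1, 98)


def test_ww_small_dispersion_limit_matches_anova():
    """Angles that are really tiny linear perturbations: the circular F must
    agree with the linear one-way ANOVA F to within 1%."""
    rng = np.random.default_rng(5)
    base = 1.0
    g1 = base + rng.normal(0, 1e-3, 30)
    g2 = base + 5e-4 + rng.normal(0, 1e-3, 30)
    res = cs.watson_williams_test([g1, g2])
    f_lin = sp_stats.f_oneway(g1, g2).statistic
    assert res.statistic == pytest.approx(f_lin, rel=0.01)


def test_ww_symmetric_in_group_order():
    rng = np.random.default_rng(8)
    g1 = rng.vonmises(0.5, 3.0, 20)
    g2 = rng.vonmises(0.9, 3.0, 20)
    a = cs.watson_williams_test([g1, g2])
    b = cs.watson_williams_test([g2, g1])
    assert a.statistic == pytest.approx(b.statistic)
    assert a.p_value == pytest.approx(b.p_value)


def test_ww_rotation_invariant():
    rng = np.random.default_rng(9)
    g1 = rng.vonmises(0.5, 3.0, 20)
    g2 = rng.vonmises(1.2, 3.0, 20)
    a = cs.watson_williams_test([g1, g2])
    b = cs.watson_williams_test([(g1 + 2.5) % TWO_PI, (g2 + 2.5) % TWO_PI])
    assert a.statistic == pytest.approx(b.statistic)


def test_ww_warns_at_low_concentration():
    rng = np.random.default_rng(10)
    g1 = rng.uniform(0, TWO_PI, 30)
    g2 = rng.uniform(0, TWO_PI, 30)
    with pytest.warns(UserWarning, match="kappa"):
        cs.watson_williams_test([g1, g2])


def test_ww_rejects_degenerate_groups():
    with pytest.raises(ValueError):
        cs.watson_williams_test([[0.0, math.pi], [0.1, 0.2]])
    with pytest.raises(ValueError):
        cs.watson_williams_test([[0.1, 0.2]])


# --- Harrison-Kanji --------------------------------------------------------

def _hk_design(rng, mu_cells, kappa=4.0, per_cell=18):
    angles, fa, fb = [], [], []
    for (a, b), mu in mu_cells.items():
        angles.extend(rng.vonmises(mu, kappa, per_cell) % TWO_PI)
        fa.extend([a] * per_cell)
        fb.extend([b] * per_cell)
    return np.array(angles), np.array(fa), np.array(fb)


def test_hk_label_coding_invariance():
    """Jointly permuting rows leaves every statistic unchanged."""
    rng = np.random.default_rng(14)
    th, a, b = _hk_design(rng, {
        ("N", "d"): 0.3, ("N", "w"): 0.3, ("S", "d"): 0.3, ("S", "w"): 0.3,
    })
    base = cs.harrison_kanji_test(th, a, b)
    perm = rng.permutation(len(th))
    mixed = cs.harrison_kanji_test(th[perm], a[perm], b[perm])
    for r1, r2 in zip(base, mixed):
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


def test_hk_detects_strong_main_effect():
    """Cell means pi apart on factor A at kappa=4: essentially sure rejection
    of factor A, and the test names its approximation branch."""
    rng = np.random.default_rng(15)
    th, a, b = _hk_design(rng, {
        ("N", "d"): 0.0, ("N", "w"): 0.0,
        ("S", "d"): math.pi, ("S", "w"): math.pi,
    })
    res_a, res_b, res_i = cs.harrison_kanji_test(th, a, b)
    assert res_a.p_value < 0.01
    assert res_b.p_value > 0.01
    assert "branch" in res_a.method_note


def test_hk_rotation_invariant():
    rng = np.random.default_rng(16)
    th, a, b = _hk_design(rng, {
        ("N", "d"): 0.3, ("N", "w"): 1.0, ("S", "d"): 0.6, ("S", "w"): 0.2,
    })
    base = cs.harrison_kanji_test(th, a, b)
    rot = cs.harrison_kanji_test((th + 1.9) % TWO_PI, a, b)
    for r1, r2 in zip(base, rot):
        assert r1.statistic == pytest.approx(r2.statistic)


def test_hk_requires_complete_two_level_design():
    th = np.array([0.1, 0.2, 0.3, 0.4])
    with pytest.raises(ValueError, match="empty cell"):
        cs.harrison_kanji_test(th, ["N", "N", "S", "S"], ["d", "d", "d", "w"])
    with pytest.raises(ValueError, match="levels"):
        cs.harrison_kanji_test(th, ["N"] * 4, ["d", "w", "d", "w"])


# --- Wilcoxon signed rank --------------------------------------------------

def test_wilcoxon_all_equal_pairs():
    with pytest.warns(UserWarning):
        res = cs.wilcoxon_signed_rank([(3, 3), (5, 5)])
    assert res.p_value == 1.0


def test_wilcoxon_ten_onesided_pairs_exact():
    """Ten (5,0) pairs: the only sign assignments at least as extreme are
    all-positive and all-negative, so p = 2/1024 exactly."""
    res = cs.wilcoxon_signed_rank([(5, 0)] * 10)
    assert res.p_value == pytest.approx(2 / 1024)
    assert "exact" in res.method_note


def test_wilcoxon_exact_matches_scipy_on_tie_free_data():
    """Dual route: with distinct |differences| scipy's exact method applies
    and must agree with the convolution."""
    rng = np.random.default_rng(30)
    for _ in range(10):
        d = rng.permutation(np.arange(1, 13)) * rng.choice([-1, 1], 12)
        pairs = [(float(x), 0.0) for x in d]
        ours = cs.wilcoxon_signed_rank(pairs)
        ref = sp_stats.wilcoxon(d.astype(float), method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)


def test_wilcoxon_large_sample_branch():
    rng = np.random.default_rng(31)
    pairs = [(float(m), float(f)) for m, f in
             zip(rng.poisson(10, 40), rng.poisson(10, 40))]
    res = cs.wilcoxon_signed_rank(pairs)
    assert 0.0 <= res.p_value <= 1.0
    assert "approximation" in res.method_note
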