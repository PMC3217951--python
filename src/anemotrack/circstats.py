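"""Circular descriptive and inferential statistics.

Self-contained implementations, from the primary statistical literature, of
the descriptive measures and the four tests the directional analysis needs:

* circular mean / variance / mean resultant length;
* the Hodges-Ajne "omnibus" test of circular uniformity (Hodges 1955);
* the Watson-Williams F test for equality of mean directions;
* the Harrison-Kanji two-factor ANOVA analogue for angular responses
  (Harrison & Kanji 1988), with its high- and low-concentration branches;
* the Wilcoxon signed-rank test (used on per-trap male vs female counts —
  linear, not circular, but reported through the same result type).

Conventions: angles are radians reduced mod 2*pi.  A sample whose resultant
vanishes has an undefined mean direction; such degeneracies raise or return
NaN sentinels rather than silently substituting 0.  Each result carries a
method_note naming the approximation branch used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "CircularTestResult",
    "circ_mean_var",
    "kappa_ml",
    "hodges_ajne_m",
    "hodges_ajne_test",
    "watson_williams_test",
    "harrison_kanji_test",
    "wilcoxon_signed_rank",
]

TWO_PI = 2.0 * math.pi

# Fixed, documented switchover constants.
WILCOXON_EXACT_MAX_PAIRS = 25   # exact convolution up to this many non-zero pairs
HK_KAPPA_BRANCH = 2.0           # Harrison & Kanji's recommended branch point


@dataclass
class CircularTestResult:
    """Outcome of one inferential test."""

    test_name: str
    statistic: float
    df: int | tuple[int, int] | None
    p_value: float
    method_note: str = ""


def _resultant(angles: np.ndarray) -> complex:
    return complex(np.exp(1j * angles).sum())


def circ_mean_var(angles: Sequence[float]) -> tuple[float, float, float]:
    """Circular mean direction, circular variance and mean resultant length.

    Returns (mean_theta, circ_variance, rbar) with rbar = |sum e^{i theta}|/n
    and variance = 1 - rbar.  With a vanishing resultant the mean is NaN and
    the variance is exactly 1.
    """
    th = np.mod(np.asarray(angles, dtype=float), TWO_PI)
    if th.size == 0:
        raise ValueError("circ_mean_var requires at least one angle")
    z = _resultant(th)
    rbar = abs(z) / th.size
    if rbar < 1e-12:
        return math.nan, 1.0, 0.0
    return float(np.angle(z) % TWO_PI), 1.0 - rbar, rbar


def _a1(kappa: float) -> float:
    """A1(kappa) = I1(kappa)/I0(kappa), computed with scaled Bessels."""
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_ml(rbar: float, n: int | None = None) -> float:
    """von Mises concentration from a mean resultant length.

    Piecewise inverse of A1 (Fisher 1993, after Best & Fisher 1981):

        rbar < 0.53        : 2 r + r^3 + 5 r^5 / 6
        0.53 <= rbar < 0.85: -0.4 + 1.39 r + 0.43 / (1 - r)
        rbar >= 0.85       : 1 / (r^3 - 4 r^2 + 3 r)

    If n is given and n < 15 the usual small-sample bias correction is
    applied (Fisher 1993, sec. 4.5.5).
    """
    r = float(rbar)
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"rbar must be in [0, 1], got {r}")
    if r >= 1.0:
        return math.inf
    if r < 0.53:
        kappa = 2.0 * r + r ** 3 + 5.0 * r ** 5 / 6.0
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        kappa = 1.0 / (r ** 3 - 4.0 * r ** 2 + 3.0 * r)
    if n is not None and 1 < n < 15:
        if kappa < 2.0:
            kappa = max(kappa - 2.0 / (n * kappa), 0.0) if kappa > 0 else 0.0
        else:
            kappa = kappa * (n - 1) ** 3 / (n ** 3 + n)
    return kappa


def hodges_ajne_m(angles: Sequence[float]) -> int:
    """Minimum half-plane count m.

    m is the minimum, over all half circles bounded by a diameter, of the
    number of sample angles falling in the half circle.  As the diameter
    rotates the count only changes when its boundary crosses a data angle,
    so it suffices to evaluate, for every data angle theta_i, the count in
    the half-open arc [theta_i, theta_i + pi) and in its complement.
    """
    th = np.sort(np.mod(np.asarray(angles, dtype=float), TWO_PI))
    n = th.size
    if n == 0:
        raise ValueError("hodges_ajne_m requires at least one angle")
    ext = np.concatenate([th, th + TWO_PI])
    hi = np.searchsorted(ext, th + math.pi, side="left")
    c = hi - np.arange(n)
    return int(np.minimum(c, n - c).min())


def hodges_ajne_test(angles: Sequence[float]) -> CircularTestResult:
    """Hodges-Ajne omnibus test of circular uniformity.

    p = min(1, 2^(1-n) (n - 2m) C(n, m)) — the exact null probability of
    Hodges (1955).  When n = 2m (data maximally spread, every half circle
    holding exactly half the sample) the exact formula degenerates to 0 and
    p is reported as 1: such data carry no evidence against uniformity.
    """
    th = np.asarray(angles, dtype=float)
    n = th.size
    if n < 4:
        raise ValueError("hodges_ajne_test requires n >= 4")
    m = hodges_ajne_m(th)
    if n - 2 * m == 0:
        p = 1.0
        note = f"n=2m={n}; exact formula degenerate, maximally dispersed, p=1"
    else:
        p = min(1.0, float((n - 2 * m) * math.comb(n, m)) * 2.0 ** (1 - n))
        note = f"exact Hodges (1955) formula, n={n}, m={m}"
    return CircularTestResult(
        test_name="hodges_ajne", statistic=float(m), df=None, p_value=p,
        method_note=note,
    )


def watson_williams_test(
    groups: Sequence[Sequence[float]],
) -> CircularTestResult:
    """Watson-Williams F test for a common mean direction across k groups.

    Assumes a shared von Mises concentration; the concentration is estimated
    from the within-group weighted mean resultant length by the inverse-A
    approximation and the F statistic carries the standard 1 + 3/(8 kappa)
    correction.  A warning is raised when the estimated kappa < 1 (the
    F approximation is unreliable at low concentration).
    """
    gs = [np.mod(np.asarray(g, dtype=float), TWO_PI) for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("watson_williams_test requires at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group must contain at least 2 angles")
    Rs = [abs(_resultant(g)) for g in gs]
    if any(R < 1e-12 for R in Rs):
        raise ValueError("a group has zero resultant: mean direction undefined")
    N = sum(g.size for g in gs)
    R_all = abs(_resultant(np.concatenate(gs)))
    sum_R = float(sum(Rs))
    rw = sum_R / N
    kappa = kappa_ml(rw)
    notes = [f"kappa_hat={kappa:.4g}"]
    if kappa < 1.0:
        msg = (
            f"Watson-Williams assumes concentrated data; estimated kappa="
            f"{kappa:.3g} < 1, F approximation unreliable"
        )
        warnings.warn(msg)
        notes.append("low-concentration warning")
    df = (k - 1, N - k)
    denom = N - sum_R
    if denom < 1e-12:
        # every angle identical within groups; compare the group means exactly
        if sum_R - R_all < 1e-9:
            F, p = 0.0, 1.0
            notes.append("degenerate: zero dispersion, identical means")
        else:
            F, p = math.inf, 0.0
            notes.append("degenerate: zero dispersion, distinct means")
    else:
        F = ((N - k) * (sum_R - R_all)) / ((k - 1) * denom)
        F *= 1.0 + 3.0 / (8.0 * kappa)
        p = float(stats.f.sf(F, *df))
    return CircularTestResult(
        test_name="watson_williams", statistic=float(F), df=df, p_value=p,
        method_note="; ".join(notes),
    )


def harrison_kanji_test(
    angles: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    factor_names: tuple[str, str] = ("A", "B"),
) -> list[CircularTestResult]:
    """Harrison-Kanji two-factor ANOVA for angular data.

    Decomposes squared resultant lengths by cell, row and column (Harrison &
    Kanji 1988).  The pooled concentration is estimated from the total
    resultant; above the published branch point (kappa >= 2) the effects are
    tested with F ratios against the residual mean square (main effects
    carry the 1/(1 - 1/(5k) - 1/(10k^2)) correction), below it with the
    chi-square approximation on components.  Returns three results: factor
    A, factor B, interaction; the branch and residual df are recorded in
    each method_note.
    """
    th = np.mod(np.asarray(angles, dtype=float), TWO_PI)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (th.size == a.size == b.size):
        raise ValueError("angles and factor labels must have equal length")
    a_lev = np.unique(a)
    b_lev = np.unique(b)
    p, q = a_lev.size, b_lev.size
    if p < 2 or q < 2:
        raise ValueError("each factor needs at least 2 levels")
    n = th.size

    def rlen(mask: np.ndarray) -> tuple[float, int]:
        sub = th[mask]
        return abs(_resultant(sub)), sub.size

    cell_R = np.empty((p, q))
    cell_n = np.empty((p, q), dtype=int)
    for i, al in enumerate(a_lev):
        for j, bl in enumerate(b_lev):
            R, cn = rlen((a == al) & (b == bl))
            if cn == 0:
                raise ValueError(
                    f"empty cell ({al!r}, {bl!r}): complete design required"
                )
            cell_R[i, j], cell_n[i, j] = R, cn
    row_R = np.array([rlen(a == al)[0] for al in a_lev])
    row_n = cell_n.sum(axis=1)
    col_R = np.array([rlen(b == bl)[0] for bl in b_lev])
    col_n = cell_n.sum(axis=0)
    tR = abs(_resultant(th))

    sum_row = float(np.sum(row_R ** 2 / row_n))
    sum_col = float(np.sum(col_R ** 2 / col_n))
    sum_cell = float(np.sum(cell_R ** 2 / cell_n))
    tterm = tR ** 2 / n

    df_a, df_b, df_i, df_r = p - 1, q - 1, (p - 1) * (q - 1), n - p * q
    kappa = kappa_ml(tR / n)

    eff_a = max(sum_row - tterm, 0.0)
    eff_b = max(sum_col - tterm, 0.0)
    eff_i = max(sum_cell - sum_row - sum_col + tterm, 0.0)

    if kappa >= HK_KAPPA_BRANCH:
        if df_r < 1:
            raise ValueError("no residual degrees of freedom for the F branch")
        beta = 1.0 / (1.0 - 1.0 / (5.0 * kappa) - 1.0 / (10.0 * kappa ** 2))
        ms_r = (n - sum_cell) / df_r
        note = (
            f"high-concentration F branch, kappa_hat={kappa:.4g}, "
            f"residual df={df_r}"
        )
        if ms_r < 1e-12:
            # zero within-cell dispersion: an effect is either absent (F=0)
            # or infinitely sharp
            note += "; degenerate zero residual dispersion"
            def _ratio(eff):
                return 0.0 if eff < 1e-9 else math.inf
            F_a, F_b, F_i = _ratio(eff_a), _ratio(eff_b), _ratio(eff_i)
        else:
            F_a = beta * (eff_a / df_a) / ms_r
            F_b = beta * (eff_b / df_b) / ms_r
            F_i = (eff_i / df_i) / ms_r
        results = [
            CircularTestResult(
                f"harrison_kanji[{factor_names[0]}]", float(F_a), (df_a, df_r),
                float(stats.f.sf(F_a, df_a, df_r)), note),
            CircularTestResult(
                f"harrison_kanji[{factor_names[1]}]", float(F_b), (df_b, df_r),
                float(stats.f.sf(F_b, df_b, df_r)), note),
            CircularTestResult(
                "harrison_kanji[interaction]", float(F_i), (df_i, df_r),
                float(stats.f.sf(F_i, df_i, df_r)), note),
        ]
    else:
        # Low concentration: the between-group resultant decomposition has a
        # cosine and a sine component, each asymptotically chi-square with
        # (levels - 1) df once scaled by 2/(1 - A1(kappa)^2), so each effect
        # is referred to chi-square with twice its ANOVA df (exact as
        # kappa -> 0, where both component variances equal 1/2).
        rr = _a1(kappa)
        f_c = 2.0 / (1.0 - rr ** 2)
        cdf_a, cdf_b, cdf_i = 2 * df_a, 2 * df_b, 2 * df_i
        note = (
            f"low-concentration chi-square branch, kappa_hat={kappa:.4g}, "
            f"component df doubled, residual df={df_r}"
        )
        chi_a = f_c * eff_a
        chi_b = f_c * eff_b
        chi_i = f_c * eff_i
        results = [
            CircularTestResult(
                f"harrison_kanji[{factor_names[0]}]", float(chi_a), cdf_a,
                float(stats.chi2.sf(chi_a, cdf_a)), note),
            CircularTestResult(
                f"harrison_kanji[{factor_names[1]}]", float(chi_b), cdf_b,
                float(stats.chi2.sf(chi_b, cdf_b)), note),
            CircularTestResult(
                "harrison_kanji[interaction]", float(chi_i), cdf_i,
                float(stats.chi2.sf(chi_i, cdf_i)), note),
        ]
    return results


def _wilcoxon_exact_two_sided(ranks: np.ndarray, wplus: float) -> float:
    """Exact two-sided p for the signed-rank sum with midranks.

    Doubling the (possibly half-integer) midranks makes them integers; the
    null distribution of the doubled positive-rank sum is then built by
    convolution over the 2^n equiprobable sign assignments.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    probs = np.zeros(total + 1)
    probs[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(probs)
        shifted[r:] = probs[: total + 1 - r]
        probs = 0.5 * (probs + shifted)
    w2 = int(round(2.0 * wplus))
    cdf = float(probs[: w2 + 1].sum())
    sf = float(probs[w2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]],
) -> CircularTestResult:
    """Two-sided Wilcoxon signed-rank test on paired counts.

    Differences are first - second per pair; zero differences are dropped.
    Up to 25 non-zero pairs the null is enumerated exactly (valid with tied
    absolute differences); beyond that the normal approximation with tie and
    continuity corrections (scipy) is used.  The reported statistic is
    min(W+, W-).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (first, second) tuples")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    n_nz = d.size
    if n_nz == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return CircularTestResult(
            "wilcoxon_signed_rank", 0.0, None, 1.0,
            "all differences zero; no information",
        )
    ranks = stats.rankdata(np.abs(d))
    wplus = float(ranks[d > 0].sum())
    wminus = float(ranks.sum()) - wplus
    statistic = min(wplus, wminus)
    if n_nz <= WILCOXON_EXACT_MAX_PAIRS:
        pval = _wilcoxon_exact_two_sided(ranks, wplus)
        note = f"exact enumeration, {n_nz} non-zero pairs"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(
                d, zero_method="wilcox", correction=True, method="approx"
            )
        pval = float(res.pvalue)
        note = (
            f"normal approximation with tie/continuity correction, "
            f"{n_nz} non-zero pairs"
        )
    return CircularTestResult(
        "wilcoxon_signed_rank", statistic, None, pval, note
    )
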