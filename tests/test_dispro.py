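"""Disproportionality statistics against independent oracles.

Every estimator is checked along a second, independent route: exact
rational arithmetic for ROR/PRR, the algebraic chi-square identity and
scipy's contingency test for chi2, the exact gamma posterior quantile
for the IC credibility bound, and quadrature + bisection for EBGM.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from faersig.dispro import (
    CANONICAL_PRIOR,
    BcpnnVariant,
    ContingencyTable,
    DegenerateBackgroundError,
    GPSHyperparams,
    SignalResult,
    TermLevel,
    bcpnn_ic,
    build_contingency,
    ebgm,
    ebgm_from_counts,
    evaluate_terms,
    fit_gps_prior,
    flag_signals,
    gps_log_marginal_likelihood,
    prr_chi2,
    ror,
)


def random_tables(n, seed, max_cell=400):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        a, b, c, d = rng.integers(0, max_cell, size=4)
        if a + b > 0 and c + d > 0 and a + b + c + d > 0:
            out.append(ContingencyTable(int(a), int(b), int(c), int(d)))
    return out


class TestBuildContingency:
    def test_enumeration_example(self):
        cohort = {("r1", "X"), ("r1", "Y"), ("r2", "X")}
        background = {("r3", "X"), ("r3", "Z")}
        ct = build_contingency(cohort, background, "X")
        assert (ct.a, ct.b, ct.c, ct.d) == (2, 1, 1, 1)

    def test_absent_term(self):
        ct = build_contingency({("r1", "Y")}, {("r3", "Z")}, "X")
        assert ct.a == 0 and ct.c == 0

    def test_degenerate_background_raises(self):
        with pytest.raises(DegenerateBackgroundError):
            build_contingency({("r1", "X")}, set(), "X")

    def test_conservation_over_terms(self, small_corpus):
        """Sum of a+b over every term equals total cohort event count."""
        from faersig.cohort import deduplicate, select_cohort
        from faersig.synthetic import FOCAL_DRUG, background_events

        _cfg, demo, drug, reac, ther, _truth = small_corpus
        reports = deduplicate(demo)
        cs = select_cohort(reports, drug, reac, ther, [FOCAL_DRUG])
        bg = background_events(reports, reac, cs.primaryids)
        for term in {t for _, t in cs.events}:
            ct = build_contingency(cs.events, bg, term)
            assert ct.a + ct.b == len(cs.events)
            assert ct.c + ct.d == len(bg)


class TestRor:
    def test_closed_form_example(self):
        ct = ContingencyTable(10, 90, 100, 9900)
        est, lo, hi = ror(ct)
        assert est == pytest.approx(11.0)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert lo == pytest.approx(math.exp(math.log(11.0) - 1.959963984540054 * se))
        assert hi == pytest.approx(math.exp(math.log(11.0) + 1.959963984540054 * se))

    def test_balanced_table_is_unity_and_symmetric(self):
        est, lo, hi = ror(ContingencyTable(5, 5, 5, 5))
        assert est == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale

    def test_monotone_in_a(self):
        r1, _, _ = ror(ContingencyTable(10, 90, 100, 9900))
        r2, _, _ = ror(ContingencyTable(20, 90, 100, 9900))
        assert r2 > r1

    def test_zero_cell_marker_and_haldane(self):
        ct = ContingencyTable(0, 10, 5, 100)
        assert all(math.isnan(v) for v in ror(ct))
        est, lo, hi = ror(ct, haldane=True)
        assert est == pytest.approx((0.5 * 100.5) / (10.5 * 5.5))
        assert lo < est < hi

    def test_exact_rational_arithmetic(self):
        for ct in random_tables(300, seed=1):
            est, _, _ = ror(ct)
            if min(ct.a, ct.b, ct.c, ct.d) == 0:
                assert math.isnan(est)
            else:
                truth = Fraction(ct.a * ct.d, ct.b * ct.c)
                assert est == pytest.approx(float(truth), rel=1e-12)


class TestPrrChi2:
    def test_closed_form_example(self):
        prr, _ = prr_chi2(ContingencyTable(10, 90, 100, 9900))
        assert prr == pytest.approx(10.0)

    def test_homogeneous_table(self):
        # a/(a+b) == c/(c+d) -> PRR 1, uncorrected chi2 0
        prr, chi2 = prr_chi2(ContingencyTable(10, 90, 100, 900), yates=False)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_chi2_identity_uncorrected(self):
        """chi2 equals N(ad-bc)^2 / product of margins on any table."""
        for ct in random_tables(300, seed=2):
            a, b, c, d = ct.a, ct.b, ct.c, ct.d
            if (a + c) == 0 or (b + d) == 0:
                continue
            _, chi2 = prr_chi2(ct, yates=False)
            n = ct.n
            ident = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(ident, abs=1e-9, rel=1e-9)

    def test_yates_matches_scipy(self):
        for ct in random_tables(100, seed=3):
            if min(ct.a + ct.c, ct.b + ct.d) == 0:
                continue
            _, chi2 = prr_chi2(ct, yates=True)
            ref = stats.chi2_contingency(
                [[ct.a, ct.b], [ct.c, ct.d]], correction=True
            ).statistic
            assert chi2 == pytest.approx(ref, abs=1e-9, rel=1e-9)

    def test_zero_c_marker(self):
        prr, _ = prr_chi2(ContingencyTable(5, 10, 0, 100))
        assert math.isnan(prr)

    def test_ror_farther_from_one_than_prr(self):
        """|log ROR| >= |log PRR| whenever both are defined."""
        for ct in random_tables(200, seed=4):
            if min(ct.a, ct.b, ct.c, ct.d) == 0:
                continue
            r, _, _ = ror(ct)
            p, _ = prr_chi2(ct)
            assert abs(math.log(r)) >= abs(math.log(p)) - 1e-12


class TestBcpnn:
    def test_observed_equals_expected_gives_zero_ic(self):
        # a == E exactly: E = (100)(100)/1000 = 10 = a, shrinkage cancels
        ct = ContingencyTable(10, 90, 90, 810)
        assert ct.expected == pytest.approx(float(ct.a))
        ic, _ = bcpnn_ic(ct)
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_ic025_below_ic_everywhere(self):
        for ct in random_tables(200, seed=5):
            ic, ic025 = bcpnn_ic(ct)
            assert ic025 < ic

    @pytest.mark.parametrize("a,b,c,d", [(12, 100, 120, 100000), (12, 100, 400, 30000), (3, 40, 50, 9000), (30, 200, 1000, 80000)])
    def test_credibility_bound_close_to_exact_posterior(self, a, b, c, d):
        """The Noren closed form tracks the exact gamma posterior quantile."""
        ct = ContingencyTable(a, b, c, d)
        _, ic025 = bcpnn_ic(ct)
        e = ct.expected
        exact = math.log2(stats.gamma.ppf(0.025, a + 0.5, scale=1 / (e + 0.5)))
        assert abs(ic025 - exact) < 0.15

    def test_original_variant_runs_and_orders(self):
        ct = ContingencyTable(12, 100, 120, 100000)
        ic, ic025 = bcpnn_ic(ct, variant=BcpnnVariant.ORIGINAL)
        assert ic025 < ic


def _ebgm_quadrature_oracle(a, e, hp):
    """Independent EBGM/EBGM05: numerical integration + root bracketing."""
    lp1 = stats.nbinom.logpmf(a, hp.alpha1, hp.beta1 / (hp.beta1 + e))
    lp2 = stats.nbinom.logpmf(a, hp.alpha2, hp.beta2 / (hp.beta2 + e))
    l1, l2 = math.log(hp.w) + lp1, math.log(1 - hp.w) + lp2
    q1 = 1.0 / (1.0 + math.exp(l2 - l1))
    s1, r1 = hp.alpha1 + a, hp.beta1 + e
    s2, r2 = hp.alpha2 + a, hp.beta2 + e

    def pdf(lam):
        return q1 * stats.gamma.pdf(lam, s1, scale=1 / r1) + (1 - q1) * stats.gamma.pdf(
            lam, s2, scale=1 / r2
        )

    upper = max(stats.gamma.ppf(1 - 1e-12, s1, scale=1 / r1),
                stats.gamma.ppf(1 - 1e-12, s2, scale=1 / r2))
    mean_log, _ = integrate.quad(lambda l: math.log(l) * pdf(l), 0, upper, limit=200)

    def cdf(x):
        return q1 * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - q1) * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    p05 = optimize.brentq(lambda x: cdf(x) - 0.05, 1e-12, upper)
    return math.exp(mean_log), p05


class TestEbgm:
    def test_quadrature_oracle_canonical_prior(self):
        got = ebgm_from_counts(12, 1.2, CANONICAL_PRIOR)
        want = _ebgm_quadrature_oracle(12, 1.2, CANONICAL_PRIOR)
        assert got[0] == pytest.approx(want[0], abs=1e-3)
        assert got[1] == pytest.approx(want[1], abs=1e-3)

    def test_quadrature_oracle_random_tables(self):
        for ct in random_tables(25, seed=6):
            if ct.expected <= 0:
                continue
            got = ebgm(ct, CANONICAL_PRIOR)
            want = _ebgm_quadrature_oracle(ct.a, ct.expected, CANONICAL_PRIOR)
            assert got[0] == pytest.approx(want[0], abs=1e-3, rel=1e-3)
            assert got[1] == pytest.approx(want[1], abs=1e-3, rel=1e-3)

    def test_full_shrinkage_limit(self):
        # near-degenerate prior at lambda ~ mean 1 with huge precision
        hp = GPSHyperparams(5e4, 5e4, 5e4, 5e4, 0.5)
        for a in (0, 5, 50):
            val, _ = ebgm_from_counts(a, 2.0, hp)
            assert val == pytest.approx(1.0, abs=0.01)

    def test_shrinkage_bounds(self):
        """EBGM shrinks the raw ratio toward the prior.

        The upper bound a/E holds for any table with a/E > 1.  The lower
        bound of 1 only holds once the data dominate the prior: EBGM is a
        posterior *geometric* mean and the canonical prior's geometric
        mean is far below its arithmetic mean of 1, so weakly-informed
        tables can land below 1.  Checked here for a >= 10.
        """
        rng = np.random.default_rng(7)
        for _ in range(100):
            e = float(rng.uniform(0.5, 20))
            a = int(np.ceil(e * rng.uniform(1.2, 6)))
            val, _ = ebgm_from_counts(a, e, CANONICAL_PRIOR)
            assert val < max(1.0, a / e) + 1e-9
            if a >= 10:
                assert val > min(1.0, a / e) - 1e-9

    def test_monotone_in_a(self):
        vals = [ebgm_from_counts(a, 3.0, CANONICAL_PRIOR)[0] for a in range(0, 40, 4)]
        assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))


@pytest.fixture(scope="module")
def simulated():
    rng = np.random.default_rng(7)
    n = 5000
    comp = rng.random(n) < CANONICAL_PRIOR.w
    lam = np.where(
        comp,
        rng.gamma(CANONICAL_PRIOR.alpha1, 1 / CANONICAL_PRIOR.beta1, n),
        rng.gamma(CANONICAL_PRIOR.alpha2, 1 / CANONICAL_PRIOR.beta2, n),
    )
    e = rng.uniform(0.5, 20, n)
    a = rng.poisson(lam * e)
    return a, e


class TestFitGpsPrior:
    def test_parameter_recovery(self, simulated):
        a, e = simulated
        hp = fit_gps_prior(a, e, init=GPSHyperparams(0.5, 0.5, 1.0, 1.0, 0.5))
        # allow label swap between the two components
        comps = sorted(
            [(hp.alpha1, hp.beta1, hp.w), (hp.alpha2, hp.beta2, 1 - hp.w)],
            key=lambda t: t[0],
        )
        lo, hi = comps
        assert abs(lo[2] - CANONICAL_PRIOR.w) < 0.1
        assert abs(lo[0] - 0.2) / 0.2 < 0.3 and abs(lo[1] - 0.1) / 0.1 < 0.3
        assert abs(hi[0] - 2.0) / 2.0 < 0.3 and abs(hi[1] - 4.0) / 4.0 < 0.3

    def test_optimum_at_least_canonical(self, simulated):
        a, e = simulated
        hp = fit_gps_prior(a, e, init=GPSHyperparams(0.5, 0.5, 1.0, 1.0, 0.5))
        assert gps_log_marginal_likelihood(a, e, hp) >= gps_log_marginal_likelihood(
            a, e, CANONICAL_PRIOR
        ) - 1e-6

    def test_null_corpus_concentrates_near_unity(self):
        e = np.full(2000, 50.0)
        a = np.full(2000, 50)
        hp = fit_gps_prior(a, e)
        val, _ = ebgm_from_counts(50, 50.0, hp)
        assert val == pytest.approx(1.0, abs=0.05)


def _result(term, a, ror_lo, prr=1.0, chi2=0.0, ic025=-1.0, ebgm05=1.0, ror_val=2.0):
    return SignalResult(
        term=term,
        level=TermLevel.PT,
        a=a,
        ror=ror_val,
        ror_lo=ror_lo,
        ror_hi=ror_val * 2,
        prr=prr,
        chi2=chi2,
        ebgm=ebgm05 * 2,
        ebgm05=ebgm05,
        ic=ic025 + 1.6,
        ic025=ic025,
    )


class TestFlagSignals:
    def test_bcpnn_flag_on_positive_ic025(self):
        # SOC-style row: IC025 = 0.59 > 0 flags BCPNN
        (r,) = flag_signals([_result("congenital", 3, ror_lo=1.61, ic025=0.59)])
        assert r.flag_bcpnn and r.flag_any

    def test_any_via_ror_despite_negative_ic025(self):
        # ROR CI (1.23, 1.95) with IC025 = -1.07: flagged via ROR only
        (r,) = flag_signals([_result("gastrointestinal", 78, ror_lo=1.23, ic025=-1.07)])
        assert r.flag_ror and not r.flag_bcpnn and r.flag_any

    def test_minimum_count_gate(self):
        (r,) = flag_signals([_result("rare", 2, ror_lo=50.0, ror_val=100.0)])
        assert not r.flag_ror

    def test_flag_any_is_or_of_methods(self):
        for kwargs in (
            dict(prr=2.5, chi2=5.0),
            dict(ebgm05=2.5),
            dict(ic025=0.2),
            dict(),
        ):
            (r,) = flag_signals([_result("t", 10, ror_lo=0.8, **kwargs)])
            assert r.flag_any == (r.flag_ror or r.flag_prr or r.flag_bcpnn or r.flag_mgps)


def test_null_calibration_ror_flag_rate():
    """Under the null, the ROR flag fires in well under 7.5% of terms."""
    rng = np.random.default_rng(11)
    n_terms = 1000
    flagged = 0
    eligible = 0
    for _ in range(n_terms):
        e = rng.uniform(3, 30)
        a = int(rng.poisson(e))
        c = int(rng.poisson(e * 50))
        b = 3000 - a
        d = 150000 - c
        if min(a, b, c, d) <= 0:
            continue
        ct = ContingencyTable(a, b, c, d)
        est, lo, _ = ror(ct)
        if a >= 3:
            eligible += 1
            if lo > 1:
                flagged += 1
    assert eligible > 500
    assert flagged / eligible <= 0.075
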