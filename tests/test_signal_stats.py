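"""Disproportionality estimators against closed-form, brute-force and
Monte-Carlo oracles, plus the signal-criteria logic."""

import numpy as np
import pytest
from scipy import stats

from basalvig.cohort import ContingencyTable
from basalvig.reference import load_signals
from basalvig.signal_stats import (
    GPS_START,
    GPSHyperparams,
    SignalResult,
    bcpnn_ic,
    compute_signal,
    ebgm,
    fit_gps,
    prr_chi2,
    ror,
    signal_flags,
)


def random_tables(n, seed, min_cell=1):
    rng = np.random.default_rng(seed)
    cells = rng.integers(min_cell, 2000, size=(n, 4))
    return [ContingencyTable(*map(int, row)) for row in cells]


def simulate_gps_universe(seed: int, n: int = 10_000):
    """Pair universe drawn from the classical two-gamma mixture prior."""
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < GPS_START.p_mix
    lam = np.where(
        comp,
        rng.gamma(GPS_START.alpha1, 1 / GPS_START.beta1, n),
        rng.gamma(GPS_START.alpha2, 1 / GPS_START.beta2, n),
    )
    e = rng.lognormal(1.0, 1.0, n)
    return rng.poisson(lam * e), e


def chi2_bruteforce(t: ContingencyTable, yates: bool) -> float:
    """Independent oracle: expected-counts cell sum instead of the
    determinant shortcut."""
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    rows, cols = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True)
    exp = rows @ cols / obs.sum()
    d = np.abs(obs - exp)
    if yates:
        d = np.maximum(d - 0.5, 0.0)
    return float((d**2 / exp).sum())


class TestROR:
    def test_independence(self):
        est, _ = ror(ContingencyTable(10, 90, 100, 900))
        assert est == pytest.approx(1.0)

    def test_worked_example(self):
        est, (lo, hi) = ror(ContingencyTable(5, 95, 10, 890))
        assert est == pytest.approx(4.684210526315789, abs=1e-12)
        assert lo == pytest.approx(1.5683678200306523, abs=1e-9)
        assert hi == pytest.approx(13.99023110179525, abs=1e-9)

    def test_transpose_symmetry(self):
        for t in random_tables(50, seed=1):
            swapped = ContingencyTable(t.a, t.c, t.b, t.d)
            assert ror(t)[0] == pytest.approx(ror(swapped)[0], rel=1e-12)

    def test_zero_cell_non_estimable_unless_haldane(self):
        t = ContingencyTable(5, 0, 10, 890)
        assert np.isnan(ror(t)[0])
        est, _ = ror(t, haldane=True)
        assert np.isfinite(est)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.contingency_tables import Table2x2

        for t in random_tables(100, seed=2):
            sm_tab = Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
            est, (lo, hi) = ror(t)
            assert est == pytest.approx(sm_tab.oddsratio, rel=1e-10)
            sm_lo, sm_hi = sm_tab.oddsratio_confint(0.05)
            assert lo == pytest.approx(sm_lo, rel=1e-6)
            assert hi == pytest.approx(sm_hi, rel=1e-6)


class TestPRRChi2:
    def test_independence_floors_chi2(self):
        est, _, chi2 = prr_chi2(ContingencyTable(10, 90, 100, 900))
        assert est == pytest.approx(1.0)
        assert chi2 == 0.0

    def test_worked_example(self):
        est, _, chi2 = prr_chi2(ContingencyTable(5, 95, 10, 890))
        assert est == pytest.approx(4.5, abs=1e-12)
        assert chi2 == pytest.approx(6.768189509306261, abs=1e-9)

    def test_scaling_property(self):
        t = ContingencyTable(5, 95, 10, 890)
        t10 = ContingencyTable(50, 950, 100, 8900)
        assert prr_chi2(t10)[0] == pytest.approx(prr_chi2(t)[0], rel=1e-12)
        # uncorrected Pearson scales exactly with n; Yates only approximately
        assert prr_chi2(t10, yates=False)[2] == pytest.approx(10 * prr_chi2(t, yates=False)[2], rel=1e-12)
        # the Yates statistic approaches the uncorrected one as counts grow
        assert prr_chi2(t10)[2] == pytest.approx(10 * prr_chi2(t, yates=False)[2], rel=0.1)

    @pytest.mark.parametrize("yates", [True, False])
    def test_chi2_bruteforce_oracle(self, yates):
        for t in random_tables(1000, seed=3):
            got = prr_chi2(t, yates=yates)[2]
            assert got == pytest.approx(chi2_bruteforce(t, yates), abs=1e-9 * max(1, got))

    def test_chi2_matches_scipy(self):
        for t in random_tables(200, seed=4):
            obs = np.array([[t.a, t.b], [t.c, t.d]])
            if abs(t.a * t.d - t.b * t.c) <= t.n / 2:
                continue  # scipy does not floor the Yates statistic
            expected = stats.chi2_contingency(obs, correction=True)[0]
            assert prr_chi2(t)[2] == pytest.approx(expected, rel=1e-10)


class TestBCPNN:
    def test_ic_zero_when_observed_equals_expected(self):
        # a = 10 with margins giving E = 10
        t = ContingencyTable(10, 90, 90, 810)
        ic, ic025 = bcpnn_ic(t)
        assert ic == pytest.approx(0.0, abs=1e-12)
        assert ic025 < 0

    def test_worked_example(self):
        ic, _ = bcpnn_ic(ContingencyTable(5, 95, 10, 890))
        assert ic == pytest.approx(np.log2(5.5 / 2.0), abs=1e-12)

    def test_ic025_below_ic(self):
        for t in random_tables(200, seed=5, min_cell=0):
            if t.expected <= 0:
                continue
            ic, ic025 = bcpnn_ic(t)
            assert ic025 < ic

    def test_ic025_monte_carlo(self):
        """Gamma-quantile IC025 against a 10^6-draw posterior sample."""
        rng = np.random.default_rng(6)
        for t in [ContingencyTable(5, 95, 10, 890),
                  ContingencyTable(50, 950, 100, 8900),
                  ContingencyTable(1, 9, 10, 980)]:
            e = t.expected
            lam = rng.gamma(t.a + 0.5, 1.0 / (e + 0.5), size=1_000_000)
            mc = np.log2(np.quantile(lam, 0.025))
            assert bcpnn_ic(t)[1] == pytest.approx(mc, abs=0.01)

    def test_shrinkage_toward_null(self):
        for t in random_tables(200, seed=7):
            e = t.expected
            if t.a == 0 or abs(t.a / e - 1) < 1e-9:
                continue
            ic, _ = bcpnn_ic(t)
            assert abs(ic) <= abs(np.log2(t.a / e)) + 1e-12


class TestEBGM:
    def test_single_component_closed_form(self):
        """Gamma(1,1) prior, a=5, E=1.5: posterior Gamma(6, 2.5)."""
        hyper = GPSHyperparams(1, 1, 1, 1, 1.0)
        t = ContingencyTable(5, 95, 10, 890)
        assert t.expected == pytest.approx(1.5)
        est, _ = ebgm(t, hyper)
        from scipy.special import digamma

        assert est == pytest.approx(np.exp(digamma(6) - np.log(2.5)), abs=1e-10)
        assert est == pytest.approx(2.203, abs=1e-3)

    def test_spike_prior_shrinks_to_one(self):
        spike = GPSHyperparams(1e6, 1e6, 1e6, 1e6, 0.5)
        est, lo = ebgm(ContingencyTable(8, 2, 10, 980), spike)
        assert est == pytest.approx(1.0, abs=0.01)
        assert lo <= est

    def test_eb05_monte_carlo(self):
        rng = np.random.default_rng(8)
        hyper = GPSHyperparams(0.2, 0.1, 2.0, 4.0, 1 / 3)
        for t in [ContingencyTable(5, 95, 10, 890), ContingencyTable(40, 60, 100, 9800)]:
            est, eb05 = ebgm(t, hyper)
            from basalvig.signal_stats import _posterior_weight

            e = t.expected
            q = _posterior_weight(t.a, e, hyper)
            comp = rng.random(1_000_000) < q
            draws = np.where(
                comp,
                rng.gamma(hyper.alpha1 + t.a, 1 / (hyper.beta1 + e), 1_000_000),
                rng.gamma(hyper.alpha2 + t.a, 1 / (hyper.beta2 + e), 1_000_000),
            )
            assert eb05 == pytest.approx(np.quantile(draws, 0.05), abs=0.01)
            assert est == pytest.approx(np.exp(np.mean(np.log(draws))), abs=0.01)

    def test_shrinkage_direction(self):
        hyper = GPSHyperparams(0.5, 0.5, 2.0, 2.0, 0.4)
        prior_mean = hyper.prior_mean
        for t in random_tables(100, seed=9):
            raw = t.a / t.expected
            if raw <= prior_mean:
                continue
            est, _ = ebgm(t, hyper)
            assert prior_mean - 1e-9 <= est <= raw + 1e-9


class TestMonotonicity:
    def test_increasing_a_increases_all_estimators(self):
        hyper = GPSHyperparams(0.2, 0.1, 2.0, 4.0, 1 / 3)
        prev = None
        for a in (5, 10, 20, 40):
            t = ContingencyTable(a, 95, 10, 890)
            res = compute_signal(t, hyper)
            if prev is not None:
                assert res.ror > prev.ror
                assert res.prr > prev.prr
                assert res.ic > prev.ic
                assert res.ebgm > prev.ebgm
            prev = res


class TestFitGPS:
    def test_null_universe_prior_mean_near_one(self):
        rng = np.random.default_rng(10)
        e = rng.lognormal(1.0, 1.0, 5000)
        a = rng.poisson(e)
        hyper = fit_gps(a, e, seed=0)
        assert hyper.prior_mean == pytest.approx(1.0, abs=0.1)

    def test_recovers_planted_mixture(self):
        """Hyperparameter recovery from the classical mixture at 10^4 pairs."""
        from tests.test_signal_stats import simulate_gps_universe

        a, e = simulate_gps_universe(seed=0)
        hyper = fit_gps(a, e, seed=0)
        # canonical order: component 1 is the smaller prior mean, here (2, 4)
        truth = (2.0, 4.0, 0.2, 0.1, 1 - GPS_START.p_mix)
        est = (hyper.alpha1, hyper.beta1, hyper.alpha2, hyper.beta2, hyper.p_mix)
        for got, want in zip(est, truth):
            assert abs(got - want) / want < 0.25

    def test_warns_on_small_universe(self):
        rng = np.random.default_rng(11)
        e = rng.lognormal(0, 1, 20)
        with pytest.warns(UserWarning, match="20 pairs"):
            fit_gps(rng.poisson(e), e, seed=0, n_starts=2)


class TestSignalFlags:
    def _result(self, row) -> SignalResult:
        return SignalResult(
            a=int(row["n"]), expected=np.nan,
            ror=row["ror"], ror_ci=(row["ror_lo"], row["ror_hi"]),
            prr=row["prr"], prr_ci=(np.nan, np.nan), chi2=row["chi2"],
            ic=row["ic"], ic025=row["ic025"], ebgm=row["ebgm"], eb05=row["eb05"],
        )

    def test_reference_degludec_fails_only_prr(self):
        """The full-corpus degludec ocular row: PRR 1.49 < 2 fails its
        criterion while ROR/BCPNN/MGPS all flag."""
        ref = load_signals().set_index(["scope", "drug"])
        flags = signal_flags(self._result(ref.loc[("overall_ocular", "insulin_degludec")]))
        assert flags == {"ror_sig": True, "prr_sig": False, "bcpnn_sig": True, "mgps_sig": True}

    def test_reference_glargine_meets_all_four(self):
        ref = load_signals().set_index(["scope", "drug"])
        flags = signal_flags(self._result(ref.loc[("overall_ocular", "insulin_glargine")]))
        assert all(flags.values())

    def test_null_table_all_false(self):
        hyper = GPSHyperparams(1e6, 1e6, 1e6, 1e6, 0.5)
        res = compute_signal(ContingencyTable(10, 90, 100, 900), hyper)
        assert not any(signal_flags(res).values())
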