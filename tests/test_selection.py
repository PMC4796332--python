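"""Stationary density, association tests and cheap MCMC sanity checks.

The expensive posterior-accuracy checks (grid-posterior agreement, replicate
recovery ordering) live in the acceptance suite; here the sampler is
exercised on small instances for exchangeability and interface contracts.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from hapalt.datamodel import MISSING
from hapalt.selection import (
    FitnessModel,
    McmcSettings,
    SelectionFit,
    P_VALUE_FLOOR,
    allele_counts_by_population,
    altitude_association,
    altitude_association_by_population,
    fit_selection,
    region_summary,
    stationary_log_density,
)

from conftest import make_panel


class TestFitnessModel:
    @pytest.mark.parametrize(
        "mode,expected",
        [
            ("additive", (1.10, 1.05, 1.0)),
            ("dominant", (1.10, 1.10, 1.0)),
            ("recessive", (1.10, 1.0, 1.0)),
        ],
    )
    def test_genotype_fitness(self, mode, expected):
        fm = FitnessModel(mode=mode, w=0.10)
        assert fm.genotype_fitness() == pytest.approx(expected)

    def test_negative_advantage_rejected(self):
        with pytest.raises(ValueError):
            FitnessModel(mode="additive", w=-0.1)


class TestStationaryDensity:
    def test_sigma_zero_is_beta(self):
        """With no selection the stationary law is exactly
        Beta(M*pi, M*(1-pi))."""
        p = np.linspace(0.01, 0.99, 23)
        for M, pi in [(10.0, 0.3), (2.0, 0.5), (50.0, 0.05)]:
            got = stationary_log_density(p, M, pi, 0.0)
            want = stats.beta.logpdf(p, M * pi, M * (1 - pi))
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_quadrature_normalization(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            M = float(rng.uniform(0.5, 80))
            pi = float(rng.uniform(0.05, 0.95))
            sigma = float(rng.uniform(0, 200))
            val, _ = integrate.quad(
                lambda x: math.exp(
                    stationary_log_density(x, M, pi, sigma)
                ),
                0, 1,
            )
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_strong_selection_concentrates_near_one(self):
        """sigma = 118 pushes nearly all stationary mass toward fixation."""
        mean, _ = integrate.quad(
            lambda x: x * math.exp(stationary_log_density(x, 10.0, 0.1, 118.0)),
            0, 1,
        )
        assert mean > 0.9

    def test_boundary_and_domain_errors(self):
        with pytest.raises(ValueError):
            stationary_log_density(0.0, 10, 0.5, 0)
        with pytest.raises(ValueError):
            stationary_log_density(0.5, -1, 0.5, 0)
        with pytest.raises(ValueError):
            stationary_log_density(0.5, 10, 0.5, -2)

    def test_large_sigma_asymptotic_branch_is_finite_and_normalized(self):
        val, _ = integrate.quad(
            lambda x: math.exp(stationary_log_density(x, 5.0, 0.2, 900.0)),
            0, 1, points=[0.99],
        )
        assert val == pytest.approx(1.0, rel=1e-3)


class TestFitSelectionInterface:
    SMALL = McmcSettings(pilot_runs=2, pilot_len=50, burn_in=300, thin=2,
                         n_samples=150, seed=4)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_selection(np.array([[1.0]]), np.array([[10.0]]))  # 1 deme
        with pytest.raises(ValueError):
            fit_selection(np.array([[5.0], [20.0]]),
                          np.array([[10.0], [10.0]]))  # count > total

    def test_identical_demes_exchangeable(self):
        """Two demes with identical counts get statistically equivalent
        sigma posteriors."""
        derived = np.array([[30.0, 90.0], [30.0, 90.0]])
        totals = np.full((2, 2), 120.0)
        fit = fit_selection(derived, totals, mcmc=self.SMALL)
        m = fit.sigma_samples.mean(axis=0)
        sd = fit.sigma_samples.std(axis=0)
        for j in range(2):
            pooled = math.hypot(sd[0, j], sd[1, j]) / math.sqrt(
                len(fit.sigma_samples)
            )
            # generous Monte-Carlo envelope: means differ by < 6 pooled SE
            # or by a small absolute amount for near-zero posteriors
            assert abs(m[0, j] - m[1, j]) < max(6 * 10 * pooled, 0.5)

    def test_summary_invariants(self):
        derived = np.array([[10.0, 60.0], [50.0, 55.0]])
        totals = np.full((2, 2), 100.0)
        fit = fit_selection(derived, totals, demes=["lo", "hi"],
                            locus_ids=["a", "b"], mcmc=self.SMALL)
        s = fit.summary
        assert (s["ci_low"] <= s["post_median"]).all()
        assert (s["post_median"] <= s["ci_high"]).all()
        assert set(s["deme"]) == {"lo", "hi"}
        assert (fit.sigma_samples >= 0).all()
        assert set(fit.diagnostics["accept_rate"]) == {"p", "sigma", "pi", "M"}


class TestRegionSummary:
    def _fake_fit(self, means, demes, locus_ids):
        samples = np.broadcast_to(
            np.asarray(means)[None, :, :], (10, len(demes), len(locus_ids))
        ).copy()
        return SelectionFit(
            summary=pd.DataFrame(), sigma_samples=samples, demes=demes,
            locus_ids=locus_ids, diagnostics={}, settings=McmcSettings(),
        )

    def test_uniform_sigma_every_region_equal(self):
        fit = self._fake_fit([[5.0, 5.0, 5.0]], ["d"], ["a", "b", "c"])
        out = region_summary(fit, {"r1": ["a", "b"], "r2": ["c"]})
        assert (out["mean_sigma"] == 5.0).all()

    def test_region_ordering_preserved(self):
        fit = self._fake_fit([[110.0, 108.0, 1.0, 2.0]], ["d"],
                             ["a", "b", "c", "e"])
        out = region_summary(
            fit, {"r1": ["a", "b"], "r2": ["c", "e"]}
        ).set_index("region")
        assert out.loc["r1", "mean_sigma"] > out.loc["r2", "mean_sigma"]

    def test_single_locus_regions(self):
        fit = self._fake_fit([[3.0, 7.0]], ["d"], ["a", "b"])
        out = region_summary(fit, {"ra": ["a"], "rb": ["b"]})
        assert out["mean_sigma"].tolist() == [3.0, 7.0]

    def test_empty_or_unknown_region_rejected(self):
        fit = self._fake_fit([[1.0]], ["d"], ["a"])
        with pytest.raises(ValueError):
            region_summary(fit, {"r": []})
        with pytest.raises(ValueError):
            region_summary(fit, {"r": ["nope"]})


class TestAssociation:
    def _panel(self, dosages, altitudes_by_sample):
        pops = [f"P{i:02d}"[:3] for i in range(len(dosages))]
        # one synthetic population per distinct altitude
        codes = []
        alts = {}
        for i, a in enumerate(altitudes_by_sample):
            code = f"A{int(a):04d}"[:3] + str(i % 10)
            codes.append(code)
            alts[code] = float(a)
        return make_panel(dosages, pop_codes=codes, altitudes=alts)

    def test_additive_matches_direct_regression(self):
        dosages = [[0], [1], [2], [1], [0], [2]]
        alts = [100, 900, 2100, 1500, 300, 2500]
        panel = self._panel(dosages, alts)
        table = altitude_association(panel, mode="additive")
        ref = stats.linregress([d[0] for d in dosages], alts)
        assert table.loc[0, "beta"] == pytest.approx(ref.slope)
        assert table.loc[0, "p"] == pytest.approx(ref.pvalue)

    def test_dominant_and_recessive_coding(self):
        dosages = [[0], [1], [2], [2], [0], [1]]
        alts = [100, 900, 2100, 1500, 300, 2500]
        panel = self._panel(dosages, alts)
        dom = altitude_association(panel, mode="dominant")
        rec = altitude_association(panel, mode="recessive")
        x = np.array([d[0] for d in dosages])
        ref_dom = stats.linregress((x >= 1).astype(float), alts)
        ref_rec = stats.linregress((x == 2).astype(float), alts)
        assert dom.loc[0, "beta"] == pytest.approx(ref_dom.slope)
        assert rec.loc[0, "beta"] == pytest.approx(ref_rec.slope)

    def test_monomorphic_locus_undefined(self):
        panel = self._panel([[0, 1], [0, 2], [0, 0]], [100, 900, 2100])
        table = altitude_association(panel)
        assert math.isnan(table.loc[0, "p"])
        assert not math.isnan(table.loc[1, "p"])

    def test_perfect_collinearity_hits_floor(self):
        # altitude is an exact linear function of dosage
        panel = self._panel([[0], [1], [2], [0], [1], [2]],
                            [0, 1000, 2000, 0, 1000, 2000])
        table = altitude_association(panel)
        assert table.loc[0, "p"] == P_VALUE_FLOOR

    def test_missing_dosages_dropped_per_locus(self):
        panel = self._panel(
            [[0, MISSING], [1, 0], [2, 1], [1, 2]], [100, 900, 2100, 3000]
        )
        table = altitude_association(panel)
        assert table.loc[0, "n"] == 4
        assert table.loc[1, "n"] == 3

    def test_hardy_weinberg_identity_with_population_frequencies(self):
        """On population-structured data the additive individual-level slope
        equals 2 * weighted cov(altitude, pop frequency) / var(dosage) —
        an exact algebraic identity because altitude is constant within
        populations."""
        rng = np.random.default_rng(11)
        pops = {"AAA": (500.0, 0.1), "BBB": (2000.0, 0.4),
                "CCC": (4000.0, 0.8)}
        dosages, codes = [], []
        for code, (alt, f) in pops.items():
            g = rng.binomial(2, f, size=60)
            dosages += [[int(v)] for v in g]
            codes += [code] * 60
        panel = make_panel(
            dosages, pop_codes=codes,
            altitudes={c: a for c, (a, _) in pops.items()},
        )
        table = altitude_association(panel, mode="additive")
        alt = np.array([pops[c][0] for c in codes])
        x = np.array([d[0] for d in dosages], dtype=float)
        phat = {c: x[np.array(codes) == c].mean() / 2 for c in pops}
        w = np.array([60, 60, 60], dtype=float)
        pv = np.array([phat[c] for c in pops])
        av = np.array([pops[c][0] for c in pops])
        cov_w = np.sum(w * (av - alt.mean()) * (pv - x.mean() / 2)) / w.sum()
        beta_identity = 2 * cov_w / x.var()
        assert table.loc[0, "beta"] == pytest.approx(beta_identity, rel=1e-10)

    def test_by_population_agrees_in_sign_and_scale(self):
        rng = np.random.default_rng(13)
        pops = {"AAA": (500.0, 0.1), "BBB": (2000.0, 0.45),
                "CCC": (3500.0, 0.7), "DDD": (4500.0, 0.9)}
        dosages, codes = [], []
        for code, (alt, f) in pops.items():
            g = rng.binomial(2, f, size=80)
            dosages += [[int(v)] for v in g]
            codes += [code] * 80
        panel = make_panel(
            dosages, pop_codes=codes,
            altitudes={c: a for c, (a, _) in pops.items()},
        )
        ind = altitude_association(panel)
        pop = altitude_association_by_population(panel)
        assert np.sign(ind.loc[0, "beta"]) == np.sign(pop.loc[0, "beta"])
        assert pop.loc[0, "p"] < 0.05

    def test_too_few_altitude_levels_rejected(self):
        panel = self._panel([[0], [1]], [100, 900])
        with pytest.raises(ValueError):
            altitude_association(panel)


def test_allele_counts_by_population():
    panel = make_panel(
        [[0, 1], [2, MISSING], [1, 1], [2, 2]],
        pop_codes=["AAA", "AAA", "BBB", "BBB"],
        altitudes={"AAA": 100.0, "BBB": 4000.0},
    )
    derived, totals, codes = allele_counts_by_population(panel)
    assert codes == ["AAA", "BBB"]
    np.testing.assert_array_equal(derived, [[2, 1], [3, 3]])
    np.testing.assert_array_equal(totals, [[4, 2], [4, 4]])
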