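"""Core-motif calling, frequencies, altitude correlation, variant filter."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hapalt.datamodel import MISSING, PanelValidationError
from hapalt.haplotypes import (
    CoreMotif,
    altitude_correlation,
    carries_core,
    derived_freq_profile,
    pop_core_frequencies,
    profile_by_group,
    shared_variant_filter,
)
from hapalt.phasing import em_phase
from hapalt.synthetic import SimPanelSpec, simulate_panel

from conftest import make_loci, make_panel


MOTIF5 = CoreMotif(locus_ids=("L00", "L01", "L02", "L03", "L04"))
LOCI10 = [f"L{j:02d}" for j in range(10)]


class TestCarriesCore:
    def test_all_derived(self):
        assert carries_core("1" * 10, MOTIF5, LOCI10)

    def test_four_of_five_is_not_core(self):
        assert not carries_core("1110111111", MOTIF5, LOCI10)

    def test_motif_locus_absent_raises(self):
        with pytest.raises(PanelValidationError):
            carries_core("111", MOTIF5, ["L00", "L01", "L02"])

    def test_two_cluster_fixture_with_recombinant(self):
        """Exactly the core-cluster haplotypes plus the one recombinant
        (motif on a background backbone) are called carriers."""
        cluster_core = ["1111111100", "1111101100", "1111111110"]
        recombinant = "1111100011"  # core motif, distant backbone
        cluster_bg = ["0000000011", "0000010011", "0000000000"]
        carriers = [
            h for h in cluster_core + [recombinant] + cluster_bg
            if carries_core(h, MOTIF5, LOCI10)
        ]
        assert carriers == cluster_core + [recombinant]


class TestPopCoreFrequencies:
    def _phase(self, genotypes, pop_codes, altitudes):
        panel = make_panel(genotypes, pop_codes=pop_codes,
                           altitudes=altitudes, core=2)
        hs = em_phase(panel)
        motif = CoreMotif.from_panel(panel.loci)
        return pop_core_frequencies(hs, panel, motif), panel

    def test_all_core_population(self):
        freqs, _ = self._phase(
            [[2, 2, 0]] * 4, ["AAA"] * 4, {"AAA": 4000.0}
        )
        assert freqs.loc[0, "core_frequency"] == 1.0
        assert freqs.loc[0, "n_chromosomes"] == 8

    def test_identical_populations_identical_frequencies(self):
        genotypes = [[2, 2, 0], [0, 0, 0], [2, 2, 2], [0, 0, 0]]
        freqs, _ = self._phase(
            genotypes + genotypes,
            ["AAA"] * 4 + ["BBB"] * 4,
            {"AAA": 1000.0, "BBB": 4000.0},
        )
        assert freqs["core_frequency"].nunique() == 1

    def test_counts_sum_to_total_core_chromosomes(self):
        spec = SimPanelSpec(
            n_populations=5, samples_per_pop=60, missing_rate=0.0,
            failed_sample_rate=0.0, genotype_error_rate=0.0,
            duplicate_pairs=0, sex_discordant=0, seed=3,
        )
        panel, _ = simulate_panel(spec)
        hs = em_phase(panel)
        motif = CoreMotif.from_panel(panel.loci)
        freqs = pop_core_frequencies(hs, panel, motif)
        idx = motif.indices(panel.locus_ids)
        total = sum(
            all(h[i] == "1" for i in idx)
            for col in ("hap1", "hap2")
            for h in hs.assignments[col]
        )
        assert freqs["core_count"].sum() == total

    def test_estimates_track_generator_truth(self):
        spec = SimPanelSpec(
            n_populations=6, samples_per_pop=250, missing_rate=0.0,
            failed_sample_rate=0.0, genotype_error_rate=0.0,
            duplicate_pairs=0, sex_discordant=0, seed=29,
        )
        panel, _ = simulate_panel(spec)
        hs = em_phase(panel)
        motif = CoreMotif.from_panel(panel.loci)
        freqs = pop_core_frequencies(hs, panel, motif)
        for _, row in freqs.iterrows():
            p = spec.core_freq_fn(row["altitude_m"])
            se = math.sqrt(max(p * (1 - p), 1e-4) / row["n_chromosomes"])
            assert abs(row["core_frequency"] - p) < 3.5 * se


def spearman_perm_oracle(x, y):
    """Independent exhaustive-permutation Spearman p-value."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(stats.pearsonr(rx, ry).statistic)
    count = total = 0
    for perm in itertools.permutations(ry):
        r = abs(stats.pearsonr(rx, np.array(perm)).statistic)
        if r >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestAltitudeCorrelation:
    def _table(self, altitudes, freqs):
        return pd.DataFrame(
            {
                "population_code": [f"P{i}" for i in range(len(altitudes))],
                "altitude_m": altitudes,
                "core_frequency": freqs,
            }
        )

    def test_monotone_increasing_is_one(self):
        t = self._table([100, 500, 2500, 4000, 4500], [0, 0.1, 0.4, 0.6, 0.9])
        rho, p = altitude_correlation(t)
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_reversed_ranks_is_minus_one(self):
        t = self._table([100, 500, 2500, 4000, 4500], [0.9, 0.6, 0.4, 0.1, 0])
        rho, _ = altitude_correlation(t)
        assert rho == pytest.approx(-1.0)

    def test_small_n_p_matches_permutation_oracle(self):
        alt = [86, 900, 2000, 3100, 4115, 4550]
        freq = [0.05, 0.02, 0.30, 0.25, 0.78, 0.63]
        t = self._table(alt, freq)
        rho, p = altitude_correlation(t)
        assert p == pytest.approx(spearman_perm_oracle(alt, freq), abs=1e-12)

    def test_monotone_transform_invariance(self):
        alt = [86, 900, 2000, 3100, 4115]
        freq = [0.05, 0.02, 0.30, 0.25, 0.78]
        t1 = self._table(alt, freq)
        t2 = self._table(np.exp(np.asarray(alt) / 1000.0), freq)
        assert altitude_correlation(t1) == altitude_correlation(t2)

    def test_constant_input_undefined(self):
        t = self._table([100, 100, 100], [0.1, 0.2, 0.3])
        with pytest.warns(UserWarning):
            rho, p = altitude_correlation(t)
        assert math.isnan(rho) and math.isnan(p)

    def test_fewer_than_three_populations_rejected(self):
        with pytest.raises(ValueError):
            altitude_correlation(self._table([1, 2], [0.1, 0.2]))


class TestDerivedFreqProfile:
    def test_all_derived_group(self):
        panel = make_panel([[2, 2], [2, 2]])
        np.testing.assert_allclose(derived_freq_profile(panel), [1.0, 1.0])

    def test_missing_locus_is_nan_only_there(self):
        panel = make_panel([[MISSING, 1], [MISSING, 2]])
        prof = derived_freq_profile(panel)
        assert math.isnan(prof[0])
        assert prof[1] == pytest.approx(0.75)

    def test_mixture_weights_closed_form(self):
        """Cluster-mixture panel frequencies match the weighted average of
        cluster allele profiles."""
        hap_a, hap_b = "1100", "0011"
        genotypes, w = [], 0.25
        # deterministic composition: 25% AA, 50% AB, 25% BB on 200 samples
        genotypes += [[2, 2, 0, 0]] * 50 + [[1, 1, 1, 1]] * 100 + \
            [[0, 0, 2, 2]] * 50
        panel = make_panel(genotypes)
        prof = derived_freq_profile(panel)
        expected = 0.5 * np.array([1, 1, 0, 0]) + 0.5 * np.array([0, 0, 1, 1])
        np.testing.assert_allclose(prof, expected)

    def test_group_restriction_and_empty_group(self):
        panel = make_panel([[2, 0], [0, 2]])
        prof = derived_freq_profile(panel, ["S000"])
        np.testing.assert_allclose(prof, [1.0, 0.0])
        with pytest.raises(ValueError):
            derived_freq_profile(panel, ["nope"])

    def test_profile_by_altitude_class(self):
        panel = make_panel(
            [[2, 0], [0, 2]],
            pop_codes=["AAA", "BBB"],
            altitudes={"AAA": 4000.0, "BBB": 100.0},
        )
        prof = profile_by_group(panel, by="altitude_class")
        assert prof["group"].tolist() == ["high", "low"]
        assert prof.loc[0, "L00"] == 1.0
        assert prof.loc[1, "L01"] == 1.0


class TestSharedVariantFilter:
    LIDS = [f"V{j:02d}" for j in range(13)]

    def test_archaic_identical_to_carriers(self):
        carriers = ["1111000000000"] * 3
        non_carriers = ["0000000000000"] * 2
        out = shared_variant_filter(carriers, non_carriers,
                                    "1111000000000", self.LIDS)
        assert out == ["V00", "V01", "V02", "V03"]

    def test_thirteen_locus_fixture_selects_exactly_two(self):
        """Constructed 13-variant screen in which exactly two variants are
        derived, archaic-shared and carrier-specific."""
        # V00, V01 pass all four conditions; every other variant fails at
        # least one: V02/V09/V10/V12 ancestral in the archaic, V04 ancestral
        # in a carrier, V06 ancestral in another carrier, V03/V05/V07/V08/V11
        # present in a non-carrier
        archaic = "1101111110000"
        carriers = [
            "1111011110000",
            "1101011111000",
            "1101010110100",
        ]
        non_carriers = [
            "0011010110000",
            "0000000110010",
        ]
        out = shared_variant_filter(carriers, non_carriers, archaic, self.LIDS)
        assert out == ["V00", "V01"]

    def test_locus_derived_in_carriers_but_ancestral_in_archaic(self):
        out = shared_variant_filter(["11"], ["00"], "10", ["a", "b"])
        assert out == ["a"]

    def test_output_shrinks_as_non_carriers_grow(self):
        rng = np.random.default_rng(5)
        carriers = ["".join(rng.choice(["0", "1"], 8)) for _ in range(3)]
        archaic = "11111111"
        pool = ["".join(rng.choice(["0", "1"], 8)) for _ in range(6)]
        prev = None
        for k in range(len(pool) + 1):
            out = set(shared_variant_filter(carriers, pool[:k], archaic,
                                            [str(j) for j in range(8)]))
            if prev is not None:
                assert out <= prev
            prev = out

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shared_variant_filter(["111"], ["00"], "111", ["a", "b", "c"])
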