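import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoperf.errors import ValidationError
from thermoperf.metabolic_stats import (
    ModelSpec,
    candidate_set,
    aicc_from_loglik,
    fit_candidates,
    fit_mixed,
    log10_prepare,
    rank_group_tests,
    species_adjusted_comparison,
)
from thermoperf.respirometry import RMRRecord
from thermoperf.synthetic import make_default_profiles, simulate_rmr

T_M = ModelSpec("T+M", ("treatment", "log_mass"))


def perfect_records(n=12, treatments=(15, 25, 30, 36), seed=0,
                    intercept=-0.9, offsets=None, slope=0.6):
    offsets = offsets or {15: 0.0, 25: 0.4, 30: 0.55, 36: 0.7}
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        mass = 10.0 ** rng.normal(1.2, 0.3)
        for t in treatments:
            log = intercept + offsets[t] + slope * np.log10(mass)
            recs.append(RMRRecord(f"id{i}", "sp", t, mass, 10.0 ** log, "M"))
    return recs


class TestLog10Prepare:
    def test_unit_vco2(self):
        recs = [RMRRecord("a", "sp", 15.0, 10.0, 1.0)]
        assert log10_prepare(recs)["log_rmr"].iloc[0] == pytest.approx(0.0)

    def test_forced_arithmetic(self):
        recs = [RMRRecord("a", "sp", 15.0, 100.0, 0.1)]
        row = log10_prepare(recs).iloc[0]
        assert (row.log_rmr, row.log_mass) == (pytest.approx(-1.0),
                                               pytest.approx(2.0))

    def test_nonpositive_rows_dropped_with_count(self):
        recs = [
            RMRRecord("a", "sp", 15.0, 10.0, 0.5),
            RMRRecord("b", "sp", 15.0, 10.0, 0.0),
        ]
        table = log10_prepare(recs)
        assert len(table) == 1
        assert table.attrs["n_dropped"] == 1

    def test_all_dropped_errors(self):
        with pytest.raises(ValidationError):
            log10_prepare([RMRRecord("a", "sp", 15.0, 10.0, 0.0)])


class TestCandidateSet:
    def test_exactly_seven(self):
        assert len(candidate_set()) == 7

    def test_unique_names(self):
        names = [s.name for s in candidate_set()]
        assert len(set(names)) == 7

    def test_exactly_one_interaction(self):
        n_int = sum(
            "treatment:log_mass" in s.fixed_terms for s in candidate_set()
        )
        assert n_int == 1

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValidationError):
            ModelSpec("bad", ("treatment", "treatment:log_mass"))


class TestAICcLoglik:
    def test_matches_formula(self):
        assert aicc_from_loglik(-10.0, 30, 5) == pytest.approx(
            20 + 10 + 2 * 5 * 6 / 24
        )

    def test_small_n_errors(self):
        with pytest.raises(Exception):
            aicc_from_loglik(-10.0, 6, 5)


class TestFitMixed:
    def test_perfect_fit_limit(self):
        """Zero-noise, zero-random-effect data from T+M is recovered exactly."""
        table = log10_prepare(perfect_records())
        fit = fit_mixed(table, T_M)
        assert fit.conditional_r2 == pytest.approx(1.0, abs=1e-6)
        est = fit.coefficients.set_index("term")["estimate"]
        assert est["Intercept"] == pytest.approx(-0.9, abs=1e-6)
        assert est["log_mass"] == pytest.approx(0.6, abs=1e-6)
        for t, off in [(25, 0.4), (30, 0.55), (36, 0.7)]:
            term = f"C(treatment, Treatment(reference=15))[T.{t}]"
            assert est[term] == pytest.approx(off, abs=1e-6)

    def test_variance_components_recovered(self, fossorial):
        recs = simulate_rmr(fossorial, seed=5, n=120)
        fit = fit_mixed(log10_prepare(recs), T_M)
        assert fit.re_var == pytest.approx(
            fossorial.random_intercept_sd**2, rel=0.5
        )
        assert fit.resid_var == pytest.approx(fossorial.residual_sd**2, rel=0.3)

    def test_conditional_r2_rises_with_less_noise(self, fossorial):
        import dataclasses

        noisy = dataclasses.replace(fossorial, residual_sd=0.3)
        quiet = dataclasses.replace(fossorial, residual_sd=0.02)
        r2 = {}
        for tag, prof in [("noisy", noisy), ("quiet", quiet)]:
            fit = fit_mixed(log10_prepare(simulate_rmr(prof, seed=2, n=40)), T_M)
            r2[tag] = fit.conditional_r2
        assert 0.0 <= r2["noisy"] < r2["quiet"] <= 1.0


class TestFitCandidates:
    def test_best_is_generating_spec_on_strong_data(self, fossorial):
        wins = 0
        for rep in range(10):
            recs = simulate_rmr(fossorial, treatments=(15.0, 25.0, 30.0, 36.0),
                                seed=100 + rep, n=26)
            _, best = fit_candidates(log10_prepare(recs))
            wins += best.spec.name == "T+M"
        assert wins >= 8

    def test_requires_two_treatments(self, fossorial):
        recs = simulate_rmr(fossorial, treatments=(25.0,), seed=0, n=10)
        with pytest.raises(ValidationError):
            fit_candidates(log10_prepare(recs))

    def test_simpler_model_preferred_on_pure_noise(self):
        # long-run AICc ordering of nested structures under the null
        rng = np.random.default_rng(33)
        simpler = 0
        for rep in range(20):
            recs = []
            for i in range(20):
                mass = 10.0 ** rng.normal(1.2, 0.3)
                for t in (15, 25, 30, 36):
                    v = 10.0 ** rng.normal(-0.3, 0.15)
                    recs.append(RMRRecord(f"id{i}", "sp", t, mass, v, "M"))
            table = log10_prepare(recs)
            t_fit = fit_mixed(table, ModelSpec("T", ("treatment",)))
            tm_fit = fit_mixed(table, T_M)
            simpler += t_fit.aicc < tm_fit.aicc
        assert simpler >= 11


def species_table(delta_intercept=0.0, slope=0.6, n=40, seed=0,
                  slope_b=None):
    rng = np.random.default_rng(seed)
    rows = []
    for sp, d, b in [("A", 0.0, slope), ("B", delta_intercept,
                                         slope_b or slope)]:
        for i in range(n):
            lm = rng.normal(1.2, 0.3)
            lr = -0.5 + d + b * lm + rng.normal(0.0, 0.1)
            rows.append(
                {"individual_id": f"{sp}{i}", "species": sp, "treatment": 25,
                 "sex": "M", "body_mass": 10**lm, "vco2": 10**lr,
                 "log_rmr": lr, "log_mass": lm}
            )
    return pd.DataFrame(rows)


class TestSpeciesComparison:
    def test_null_case_small_contrast(self):
        comp = species_adjusted_comparison(species_table(0.0, seed=1))
        assert abs(comp.contrasts["estimate"].iloc[0]) < 0.05
        assert abs(comp.contrasts["t"].iloc[0]) < 2.0

    def test_intercept_shift_recovered(self):
        diffs = []
        for seed in range(20):
            comp = species_adjusted_comparison(
                species_table(0.2, seed=seed), interaction="never"
            )
            means = comp.adjusted_means
            diffs.append(means["B"] - means["A"])
        assert np.mean(diffs) == pytest.approx(0.2, abs=0.03)

    def test_adjusted_means_invariant_to_recentering(self):
        table = species_table(0.15, seed=3)
        shifted = table.copy()
        shifted["log_mass"] = shifted["log_mass"] - 5.0
        a = species_adjusted_comparison(table, interaction="never")
        b = species_adjusted_comparison(shifted, interaction="never")
        assert np.allclose(a.adjusted_means.values, b.adjusted_means.values)

    def test_interaction_detected_when_slopes_differ(self):
        comp = species_adjusted_comparison(
            species_table(0.0, slope=0.4, slope_b=1.0, n=80, seed=2)
        )
        assert comp.interaction_retained

    def test_single_species_errors(self):
        table = species_table(0.0)
        with pytest.raises(ValidationError):
            species_adjusted_comparison(table[table.species == "A"])

    def test_contrasts_cover_all_pairs(self):
        comp = species_adjusted_comparison(species_table(0.1))
        assert len(comp.contrasts) == 1
        assert set(comp.groups) == {"A", "B"}


class TestRankGroupTests:
    def test_hand_computed_h_on_toy(self):
        # oracle: H = 12/(N(N+1)) * sum n_i (rbar_i - (N+1)/2)^2, no ties
        groups = {"a": [1, 2, 3], "b": [101, 102, 103], "c": [201, 202, 203]}
        res = rank_group_tests(groups)
        assert res.h == pytest.approx(7.2)
        assert res.h == pytest.approx(
            12 / (9 * 10) * (3 * (2 - 5) ** 2 + 3 * (5 - 5) ** 2 + 3 * (8 - 5) ** 2)
        )

    def test_matches_scipy_with_ties(self, rng):
        samples = [rng.integers(0, 5, 12).astype(float) for _ in range(3)]
        res = rank_group_tests({f"g{i}": s for i, s in enumerate(samples)})
        h, p = sps.kruskal(*samples)
        assert res.h == pytest.approx(h)
        assert res.p == pytest.approx(p)

    def test_degenerate_all_tied(self):
        res = rank_group_tests({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res.h == 0.0
        assert res.p == 1.0
        assert (res.posthoc["p_adj"] == 1.0).all()

    def test_monotone_transform_invariance(self, rng):
        groups = {g: rng.normal(i, 1.0, 10) for i, g in enumerate("abc")}
        res1 = rank_group_tests(groups)
        res2 = rank_group_tests({g: np.exp(v) for g, v in groups.items()})
        assert res1.h == pytest.approx(res2.h)
        assert np.allclose(
            res1.posthoc["z"].to_numpy(), res2.posthoc["z"].to_numpy()
        )

    def test_dunn_flags_separated_groups(self, rng):
        groups = {
            "lo": rng.normal(0, 1, 15),
            "hi": rng.normal(8, 1, 15),
            "mid": rng.normal(4, 1, 15),
        }
        res = rank_group_tests(groups)
        assert (res.posthoc["p_adj"] < 0.05).any()

    def test_needs_two_groups(self):
        with pytest.raises(ValidationError):
            rank_group_tests({"a": [1.0, 2.0]})
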