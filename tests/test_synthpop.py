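"""Generator tests: censuses, event simulation, the coder, the registry."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cohortbridge.causes import CAUSES
from cohortbridge.synthpop import (
    ConfigurationError,
    HazardConfig,
    PopulationConfig,
    UnlinkConfig,
    analytic_step_factor,
    assign_official_cause,
    calibrate_mention_prob,
    degrade_to_registry,
    generate_census,
    official_cause_probabilities,
    simulate_followup,
    zero_unlink_config,
)


def _flat_hazards(rates: dict, bands=(0,), **kw) -> HazardConfig:
    z = (0.0,) * len(bands)
    base = {c: {"female": z, "male": z} for c in CAUSES}
    for (cause, sex), r in rates.items():
        base[cause][sex] = (r,) * len(bands)
    return HazardConfig(age_breaks=bands, baseline_hazard=base,
                        log_linear_trend={}, mention_prob={},
                        emigration_hazard=z, covariate_log_hr={},
                        marital_transition_rate=0.0, residence_move_prob=0.0,
                        **kw)


class TestGenerateCensus:
    def test_row_count_and_unique_ids(self):
        c = generate_census(PopulationConfig(n_persons=1000, seed=7))
        assert len(c) == 1000
        assert c["person_id"].nunique() == 1000

    def test_empty_population_rejected(self):
        with pytest.raises(ConfigurationError):
            PopulationConfig(n_persons=0)

    def test_invalid_marginals_rejected(self):
        cfg = PopulationConfig(n_persons=10)
        bad = dict(cfg.marginals)
        bad["sex"] = {"female": 0.6, "male": 0.6}
        with pytest.raises(ConfigurationError):
            PopulationConfig(n_persons=10, marginals=bad)

    def test_sex_marginal_within_binomial_error(self):
        # 0.51/0.49 at n=50,000: 3 SE = 3*sqrt(.51*.49/50000) ~ 0.0067
        cfg = PopulationConfig(n_persons=50_000, seed=1)
        c = generate_census(cfg)
        p = (c["sex"] == "female").mean()
        assert abs(p - 0.51) < 3 * np.sqrt(0.51 * 0.49 / 50_000)

    def test_determinism(self):
        a = generate_census(PopulationConfig(n_persons=500, seed=3))
        b = generate_census(PopulationConfig(n_persons=500, seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_region_follows_canton(self):
        from cohortbridge.geography import CANTON_TO_REGION
        c = generate_census(PopulationConfig(n_persons=2000, seed=5))
        assert (c["region"] == c["canton"].map(CANTON_TO_REGION)).all()

    def test_birth_dates_within_range_and_before_census(self):
        cfg = PopulationConfig(n_persons=2000, seed=9)
        c = generate_census(cfg)
        assert (c["birth_date"] <= pd.Timestamp(cfg.census_date)).all()


class TestSimulateFollowup:
    def test_null_hazard_produces_no_events(self):
        census = generate_census(PopulationConfig(n_persons=300, seed=2))
        hz = _flat_hazards({}, bands=(0,))
        d, e = simulate_followup(census, hz, date(1990, 12, 5), date(1995, 12, 31))
        assert len(d) == 0 and len(e) == 0

    def test_invalid_window_rejected(self):
        census = generate_census(PopulationConfig(n_persons=10, seed=2))
        hz = _flat_hazards({}, bands=(0,))
        with pytest.raises(ConfigurationError):
            simulate_followup(census, hz, date(1995, 1, 1), date(1994, 1, 1))

    def test_exponential_death_count(self):
        # single cause, lambda = 0.1/yr, 1-year window:
        # E[deaths] = n(1-e^-0.1), binomial 3-SE band
        n = 10_000
        census = generate_census(PopulationConfig(n_persons=n, seed=4))
        hz = _flat_hazards({("other", "female"): 0.1, ("other", "male"): 0.1},
                           bands=(0,))
        d, _ = simulate_followup(census, hz, date(1991, 1, 1), date(1992, 1, 1),
                                 seed=8)
        p = 1 - np.exp(-0.1)
        assert abs(len(d) - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_symmetric_competing_causes(self):
        n = 10_000
        census = generate_census(PopulationConfig(n_persons=n, seed=4))
        hz = _flat_hazards({("other", "female"): 0.15, ("other", "male"): 0.15,
                            ("cardiovascular", "female"): 0.15,
                            ("cardiovascular", "male"): 0.15}, bands=(0,))
        d, _ = simulate_followup(census, hz, date(1991, 1, 1), date(1993, 1, 1),
                                 seed=9)
        share = (d["underlying_cause"] == "other").mean()
        assert abs(share - 0.5) < 3 * np.sqrt(0.25 / len(d))

    def test_event_dates_inside_window_and_one_event_per_person(self):
        census = generate_census(PopulationConfig(n_persons=3000, seed=6))
        hz = HazardConfig()
        d, e = simulate_followup(census, hz, date(1990, 12, 5), date(2000, 12, 4))
        assert (d["death_date"] > pd.Timestamp(1990, 12, 5)).all()
        assert (d["death_date"] <= pd.Timestamp(2000, 12, 4)).all()
        assert not set(d["person_id"]) & set(e["person_id"])
        assert d["person_id"].is_unique and e["person_id"].is_unique

    def test_determinism(self):
        census = generate_census(PopulationConfig(n_persons=1000, seed=6))
        hz = HazardConfig()
        d1, e1 = simulate_followup(census, hz, date(1990, 12, 5), date(1995, 1, 1),
                                   seed=3)
        d2, e2 = simulate_followup(census, hz, date(1990, 12, 5), date(1995, 1, 1),
                                   seed=3)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(e1, e2)


class TestOfficialCauseCoder:
    def test_pre_switch_cancer_mention_overrides(self):
        got = assign_official_cause("cardiovascular",
                                    {"cardiovascular", "breast"},
                                    date(1993, 6, 1))
        assert got == "breast"

    def test_post_switch_strict_underlying(self):
        got = assign_official_cause("cardiovascular",
                                    {"cardiovascular", "breast"},
                                    date(1996, 6, 1))
        assert got == "cardiovascular"

    def test_singleton_mentions(self):
        for when in (date(1993, 1, 1), date(1999, 1, 1)):
            assert assign_official_cause("other", {"other"}, when) == "other"

    def test_external_priority_beats_cancer(self):
        got = assign_official_cause("suicide", {"suicide", "breast"},
                                    date(1993, 1, 1))
        assert got == "suicide"

    def test_icd_codes_accepted(self):
        got = assign_official_cause("cardiovascular", {"cardiovascular", "C50"},
                                    date(1993, 1, 1))
        assert got == "breast"

    def test_empty_mentions_rejected(self):
        with pytest.raises(ValueError):
            assign_official_cause("other", set(), date(1993, 1, 1))
        with pytest.raises(ValueError):
            assign_official_cause("other", {"breast"}, date(1993, 1, 1))

    @given(st.sampled_from(CAUSES),
           st.sets(st.sampled_from(CAUSES), min_size=0, max_size=3),
           st.dates(min_value=date(1991, 1, 1), max_value=date(2007, 12, 31)))
    def test_official_always_among_mentions(self, underlying, extra, when):
        mentions = extra | {underlying}
        got = assign_official_cause(underlying, mentions, when)
        assert got in mentions
        if when >= date(1995, 1, 1):
            assert got == underlying


class TestCodingStepAnalytics:
    def test_probabilities_match_enumeration(self):
        # independent check of the closed form: enumerate all mention
        # subsets with their Bernoulli probabilities and run the coder
        hz = _flat_hazards({("other_cancer", "female"): 0.04,
                            ("cardiovascular", "female"): 0.08,
                            ("suicide", "female"): 0.001,
                            ("other", "female"): 0.05}, bands=(0,))
        hz.mention_prob = {"other_cancer": 0.06, "suicide": 0.02}
        probs = official_cause_probabilities(hz, "female", 0)
        import itertools
        for d in ("cardiovascular", "other_cancer", "suicide", "other"):
            acc = {c: 0.0 for c in hz.causes}
            optional = [c for c in hz.causes
                        if c != d and hz.mention_prob.get(c, 0.0) > 0]
            for r in range(len(optional) + 1):
                for sub in itertools.combinations(optional, r):
                    p = 1.0
                    for c in optional:
                        pc = hz.mention_prob.get(c, 0.0)
                        p *= pc if c in sub else 1 - pc
                    official = assign_official_cause(
                        d, set(sub) | {d}, date(1993, 1, 1),
                        priority_causes=hz.priority_causes)
                    acc[official] += p
            for c in hz.causes:
                assert probs[d][c] == pytest.approx(acc[c], abs=1e-12)

    def test_calibration_hits_target_factor(self):
        hz = _flat_hazards({("other_cancer", "female"): 0.04,
                            ("cardiovascular", "female"): 0.08,
                            ("other", "female"): 0.05}, bands=(0,))
        m = calibrate_mention_prob(hz, "other_cancer", "female", 0, 0.85)
        hz.mention_prob = {"other_cancer": m}
        assert analytic_step_factor(hz, "other_cancer", "female", 0) \
            == pytest.approx(0.85, abs=1e-12)

    def test_step_emerges_in_simulated_rates(self):
        # with a cancer mention probability, pre-1995 official rates must
        # exceed underlying rates; post-1995 they coincide
        n = 20_000
        census = generate_census(PopulationConfig(
            n_persons=n, seed=13,
            birth_date_range=(date(1910, 1, 1), date(1920, 1, 1))))
        hz = _flat_hazards({("other_cancer", "female"): 0.03,
                            ("other_cancer", "male"): 0.03,
                            ("cardiovascular", "female"): 0.08,
                            ("cardiovascular", "male"): 0.08}, bands=(0,))
        hz.mention_prob = {"other_cancer": 0.2}
        d, _ = simulate_followup(census, hz, date(1990, 12, 5),
                                 date(2000, 12, 31), seed=14)
        pre = d[d["death_date"] < pd.Timestamp(1995, 1, 1)]
        post = d[d["death_date"] >= pd.Timestamp(1995, 1, 1)]
        assert (pre["official_cause"] == "other_cancer").sum() \
            > (pre["underlying_cause"] == "other_cancer").sum()
        assert (post["official_cause"] == post["underlying_cause"]).all()


@pytest.fixture(scope="module")
def deaths():
    census = generate_census(PopulationConfig(n_persons=20_000, seed=21))
    return simulate_followup(census, HazardConfig(), date(1990, 12, 5),
                             date(2000, 12, 4), seed=22)[0]


class TestDegradeToRegistry:

    def test_no_degradation(self, deaths):
        reg, truth = degrade_to_registry(deaths, zero_unlink_config(), seed=1)
        assert reg["linked"].all()
        assert (reg["person_id"].to_numpy() == truth["truth_person_id"].to_numpy()).all()
        d = deaths.sort_values(["death_date", "person_id"])
        assert (reg["birth_date"].to_numpy() == d["cert_birth_date"].to_numpy()).all()
        assert (reg["canton"].to_numpy() == d["cert_canton"].to_numpy()).all()

    def test_full_degradation(self, deaths):
        uc = UnlinkConfig(base_prob_by_band={b: 1.0 for b in range(10)},
                          nationality_multiplier={}, marital_multiplier={},
                          sex_multiplier={})
        reg, _ = degrade_to_registry(deaths, uc, seed=1)
        assert not reg["linked"].any()
        assert reg["person_id"].isna().all()

    def test_conservation_and_stratified_fractions(self, deaths):
        # Swiss 0.047 vs non-Swiss 0.122-ish within 3 binomial SEs
        uc = UnlinkConfig(base_prob_by_band={b: 0.047 for b in range(10)},
                          nationality_multiplier={"Swiss": 1.0,
                                                  "non-Swiss": 0.122 / 0.047},
                          marital_multiplier={}, sex_multiplier={})
        reg, truth = degrade_to_registry(deaths, uc, seed=5)
        assert len(reg) == len(deaths) == len(truth)
        for nat, target in (("Swiss", 0.047), ("non-Swiss", 0.122)):
            sub = reg[reg["nationality"] == nat]
            frac = (~sub["linked"]).mean()
            assert abs(frac - target) < 3 * np.sqrt(target * (1 - target) / len(sub))

    def test_determinism(self, deaths):
        r1, t1 = degrade_to_registry(deaths, UnlinkConfig(), seed=7)
        r2, t2 = degrade_to_registry(deaths, UnlinkConfig(), seed=7)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1, t2)
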