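"""Generator correctness: calibration, dependence, determinism."""

import numpy as np
import pandas as pd
import pytest

import recapture as rc
from recapture.config import SOURCES
from recapture.synthetic_data import (
    derive_overcoverage_count,
    marginal_capture_probabilities,
)


def _independent_config(p=0.1, n=10_000, **kw):
    lam = float(np.log(p / (1 - p)))
    return rc.SimulationConfig(
        true_population_size=n,
        years=[2012],
        capture_main_effects={s: lam for s in SOURCES},
        capture_pair_effects={},
        covariate_capture_effects={},
        member_fraction_pb=1.0,
        overcoverage_count=0,
        **kw,
    )


class TestSimulatePopulation:
    def test_observed_count_matches_closed_form(self):
        # independent sources, each p = 0.1: P(seen at least once) = 1 - 0.9^4
        cfg = _independent_config(seed=11)
        res = rc.simulate_population(cfg)
        members = res.truth[res.truth["member"]]
        observed = int((members[list(SOURCES)].sum(axis=1) > 0).sum())
        p_obs = 1 - 0.9**4
        expect = 10_000 * p_obs
        sd = np.sqrt(10_000 * p_obs * (1 - p_obs))
        assert abs(observed - expect) < 3 * sd

    def test_member_fraction_among_pb_captures(self):
        cfg = rc.SimulationConfig(true_population_size=2000, years=[2012], seed=3)
        res = rc.simulate_population(cfg)
        pb = res.truth[res.truth["PB"] == 1]
        frac = pb["member"].mean()
        assert frac == pytest.approx(0.13, abs=0.025)

    def test_zero_capture_probabilities_give_empty_extracts(self):
        cfg = rc.SimulationConfig(
            true_population_size=500,
            years=[2012],
            capture_main_effects={s: -40.0 for s in SOURCES},
            capture_pair_effects={},
            covariate_capture_effects={},
            overcoverage_count=0,
            seed=1,
        )
        res = rc.simulate_population(cfg)
        for src in SOURCES:
            assert len(res.extracts[src]) == 0

    def test_conservation_of_individuals(self, default_sim):
        cfg = default_sim.config
        cap = cfg.population_by_year()[2012] + derive_overcoverage_count(cfg)
        seen = default_sim.truth[
            default_sim.truth[list(SOURCES)].sum(axis=1) > 0
        ]["person_id"].nunique()
        assert seen <= cap

    def test_seed_determinism(self):
        cfg = rc.SimulationConfig(true_population_size=300, years=[2012, 2013], seed=9)
        a = rc.simulate_population(cfg)
        b = rc.simulate_population(
            rc.SimulationConfig(true_population_size=300, years=[2012, 2013], seed=9)
        )
        for src in SOURCES:
            assert a.extracts[src].to_csv() == b.extracts[src].to_csv()
        assert a.truth.to_csv() == b.truth.to_csv()

    def test_death_terminates_capture(self):
        cfg = rc.SimulationConfig(true_population_size=800, years=[2012, 2013, 2014], seed=5)
        res = rc.simulate_population(cfg)
        died = res.truth[(res.truth["year"] == 2012) & (res.truth["DR"] == 1)]["person_id"]
        later = res.truth[res.truth["year"] > 2012]
        assert not later["person_id"].isin(set(died)).any()

    def test_contaminants_only_in_pb(self, default_sim):
        contam = default_sim.truth[~default_sim.truth["member"]]
        assert (contam["PB"] == 1).all()
        assert (contam[["DR", "HIF-T", "HIF-F"]].sum(axis=1) == 0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            rc.SimulationConfig(true_population_size=0)
        with pytest.raises(ValueError):
            rc.SimulationConfig(member_fraction_pb=0.0)
        with pytest.raises(ValueError):
            rc.SimulationConfig(
                covariate_distribution={
                    "sex": {"M": 0.6, "F": 0.6},
                    "age_group": {"15-44": 0.9, "45+": 0.1},
                    "county": {"Harju": 0.5, "Ida-Viru": 0.35, "other": 0.15},
                }
            )

    def test_yaml_round_trip(self, tmp_path):
        cfg = rc.SimulationConfig(true_population_size=123, seed=4)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = rc.SimulationConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()

    def test_marginal_calibration_across_seeds(self):
        # per-source member capture counts stay within 3 SD of the analytic
        # expectation for (almost) every seed
        cfg0 = rc.SimulationConfig(
            true_population_size=1000, years=[2012], member_fraction_pb=1.0,
            overcoverage_count=0,
        )
        probs = marginal_capture_probabilities(cfg0)
        n = 1000
        checks = ok = 0
        for seed in range(25):
            cfg = rc.SimulationConfig(
                true_population_size=n, years=[2012], member_fraction_pb=1.0,
                overcoverage_count=0, seed=seed,
            )
            truth = rc.simulate_population(cfg).truth
            members = truth[truth["member"]]
            for src in SOURCES:
                p = probs[src]
                sd = np.sqrt(n * p * (1 - p))
                checks += 1
                ok += abs(members[src].sum() - n * p) <= 3 * sd
        assert ok / checks >= 0.95


class TestEmpiricalCaptureORs:
    def test_independence_gives_unit_ors(self):
        res = rc.simulate_population(_independent_config(n=20_000, seed=2))
        ors = rc.empirical_capture_ors(res.truth)
        se = np.sqrt((1 / ors[["n11", "n10", "n01", "n00"]]).sum(axis=1))
        assert (np.abs(np.log(ors["odds_ratio"])) < 3 * se).all()

    def test_pairwise_interaction_equals_log_or(self):
        cfg = _independent_config(n=40_000, seed=8)
        cfg.capture_pair_effects = {("DR", "PB"): float(np.log(2.0))}
        res = rc.simulate_population(cfg)
        ors = rc.empirical_capture_ors(res.truth)
        row = ors[(ors["source_a"] == "DR") & (ors["source_b"] == "PB")].iloc[0]
        se = np.sqrt(sum(1 / row[k] for k in ("n11", "n10", "n01", "n00")))
        assert abs(np.log(row["odds_ratio"]) - np.log(2.0)) < 3 * se

    def test_cross_product_by_hand(self):
        # 2x2 member counts a=20 b=30 c=10 d=40 -> OR = 8/3
        rows = []
        for count, (x, y) in zip((20, 30, 10, 40), ((1, 1), (1, 0), (0, 1), (0, 0))):
            for i in range(count):
                rows.append(
                    {
                        "person_id": len(rows),
                        "year": 2012,
                        "member": True,
                        "DR": x,
                        "PB": y,
                        "HIF-T": 0,
                        "HIF-F": 0,
                    }
                )
        truth = pd.DataFrame(rows)
        ors = rc.empirical_capture_ors(truth)
        row = ors[(ors["source_a"] == "DR") & (ors["source_b"] == "PB")].iloc[0]
        assert row["odds_ratio"] == pytest.approx(8 / 3)
        assert not row["continuity_corrected"]

    def test_zero_margin_flagged(self):
        truth = pd.DataFrame(
            {
                "person_id": range(4),
                "year": 2012,
                "member": True,
                "DR": [1, 1, 0, 0],
                "PB": [1, 0, 1, 0],
                "HIF-T": [0, 0, 0, 0],
                "HIF-F": [1, 1, 1, 1],
            }
        )
        ors = rc.empirical_capture_ors(truth)
        row = ors[(ors["source_a"] == "DR") & (ors["source_b"] == "HIF-T")].iloc[0]
        assert row["continuity_corrected"]
        assert np.isfinite(row["odds_ratio"]) and row["odds_ratio"] > 0

    def test_requires_two_active_sources(self):
        truth = pd.DataFrame(
            {
                "person_id": [0],
                "year": 2012,
                "member": True,
                "DR": [1],
                "PB": [0],
                "HIF-T": [0],
                "HIF-F": [0],
            }
        )
        with pytest.raises(ValueError):
            rc.empirical_capture_ors(truth)
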