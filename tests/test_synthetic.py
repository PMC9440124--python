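import math
from dataclasses import replace

import numpy as np
import pytest

from teamdx.calibration import accuracy_by_confidence, switch_rate_by_confidence
from teamdx.data_model import validate_cohort
from teamdx.endpoints import ENDPOINT_NAMES, estimate_endpoint
from teamdx.synthetic import (
    GeneratorConfig,
    ai_determinate_accuracy_closed_form,
    ai_indeterminate_fraction_closed_form,
    generate_cohort,
    integrate_beliefs,
    simulate_ai,
    simulate_power,
    simulate_s1,
)

CONF_ORDER = ["VeryLow", "Low", "High", "VeryHigh"]


class TestConfig:
    def test_defaults_valid(self):
        GeneratorConfig().validate()

    @pytest.mark.parametrize(
        "bad",
        [
            {"adenoma_prevalence": 1.5},
            {"confidence_cutpoints_human": (1.0, 0.5, 2.0)},
            {"n_expert": 30},
            {"s2_mode": "telepathy"},
            {"uncertain_band_human": 0.9},
            {"weight_ai": {"VeryLow": -1, "Low": 0.5, "High": 1, "VeryHigh": 2}},
        ],
    )
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            replace(GeneratorConfig(), **bad).validate()

    def test_dict_roundtrip(self):
        cfg = GeneratorConfig(seed=42, misread_prob=0.1)
        assert GeneratorConfig.from_dict(cfg.to_dict()) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            GeneratorConfig.from_dict({"n_rater": 5})


class TestSimulateAi:
    def test_infinite_threshold_all_undetermined(self):
        cfg = replace(GeneratorConfig(), ai_indeterminate_threshold=math.inf)
        labels, _, _ = simulate_ai(np.ones(200), cfg, np.random.default_rng(0))
        assert (labels == "Undetermined").all()

    def test_zero_skill_symmetric(self):
        cfg = replace(GeneratorConfig(), ai_skill=0.0, ai_indeterminate_threshold=0.0)
        sign = np.where(np.random.default_rng(1).random(200_000) < 0.5, 1.0, -1.0)
        labels, _, _ = simulate_ai(sign, cfg, np.random.default_rng(2))
        correct = (labels == np.where(sign > 0, "Adenoma", "NonAdenoma")).mean()
        assert correct == pytest.approx(0.5, abs=0.005)

    def test_matches_closed_form_within_3_se(self):
        cfg = GeneratorConfig()
        n = 200_000
        sign = np.where(np.random.default_rng(3).random(n) < 0.6, 1.0, -1.0)
        labels, _, _ = simulate_ai(sign, cfg, np.random.default_rng(4))
        det = labels != "Undetermined"
        acc_hat = (labels[det] == np.where(sign[det] > 0, "Adenoma", "NonAdenoma")).mean()
        ind_hat = (~det).mean()
        acc = ai_determinate_accuracy_closed_form(cfg.ai_skill, cfg.ai_indeterminate_threshold)
        ind = ai_indeterminate_fraction_closed_form(cfg.ai_skill, cfg.ai_indeterminate_threshold)
        assert abs(acc_hat - acc) < 3 * math.sqrt(acc * (1 - acc) / det.sum())
        assert abs(ind_hat - ind) < 3 * math.sqrt(ind * (1 - ind) / n)

    def test_default_calibration_targets(self):
        cfg = GeneratorConfig()
        acc = ai_determinate_accuracy_closed_form(cfg.ai_skill, cfg.ai_indeterminate_threshold)
        ind = ai_indeterminate_fraction_closed_form(cfg.ai_skill, cfg.ai_indeterminate_threshold)
        assert abs(acc - 0.85) < 0.02
        assert abs(ind - 0.14) < 0.03


class TestSimulateS1:
    def test_zero_discriminability_is_chance(self):
        from scipy.special import ndtr

        cfg = GeneratorConfig()
        sign = np.where(np.random.default_rng(0).random(100_000) < 0.5, 1.0, -1.0)
        dx, conf, _ = simulate_s1(0.0, 0.0, sign, cfg, np.random.default_rng(1))
        correct = (dx == np.where(sign > 0, "Adenoma", "NonAdenoma")).mean()
        # chance level minus the sliver lost to the uncertain band
        expected = 1.0 - ndtr(cfg.uncertain_band_human)
        assert correct == pytest.approx(expected, abs=0.01)
        determinate = dx != "Uncertain"
        assert (dx[determinate] == "Adenoma").mean() == pytest.approx(0.5, abs=0.01)

    def test_huge_skill_all_very_high_and_correct(self):
        cfg = GeneratorConfig()
        sign = np.ones(1000)
        dx, conf, _ = simulate_s1(50.0, 0.0, sign, cfg, np.random.default_rng(2))
        assert (dx == "Adenoma").all()
        assert (conf == "VeryHigh").all()

    def test_confidence_gradient_monotone(self):
        # calibration-by-construction: accuracy strictly increases in the bin
        cfg = GeneratorConfig()
        n = 200_000
        rng = np.random.default_rng(5)
        sign = np.where(rng.random(n) < 0.6, 1.0, -1.0)
        d = cfg.lesion_difficulty_sd * rng.standard_normal(n)
        dx, conf, _ = simulate_s1(cfg.nonexpert_skill, d, sign, cfg, rng)
        correct = dx == np.where(sign > 0, "Adenoma", "NonAdenoma")
        accs = [correct[conf == lev].mean() for lev in CONF_ORDER]
        assert all(a < b for a, b in zip(accs, accs[1:]))


class TestIntegrateBeliefs:
    def _inputs(self, n=5000, seed=0):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(seed)
        sign = np.where(rng.random(n) < 0.6, 1.0, -1.0)
        d = cfg.lesion_difficulty_sd * rng.standard_normal(n)
        dx, conf, x = simulate_s1(cfg.nonexpert_skill, d, sign, cfg, rng)
        ai_labels, ai_conf, _ = simulate_ai(sign, cfg, rng)
        pconf = np.where(ai_labels != "Undetermined", ai_conf, "")
        perceived = np.where(ai_labels == "Undetermined", "Uncertain", ai_labels)
        return cfg, dx, conf, x, perceived, pconf

    def test_zero_ai_weight_reproduces_s1(self):
        cfg, dx, conf, x, perceived, pconf = self._inputs()
        cfg = replace(
            cfg,
            weight_ai={k: 0.0 for k in CONF_ORDER},
            weight_human={k: 1.0 for k in CONF_ORDER + ["Uncertain"]},
        )
        _, dx2, conf2 = integrate_beliefs(x, conf, perceived, pconf, cfg)
        assert (dx2 == dx).all()
        assert (conf2 == conf).all()

    def test_zero_human_weight_follows_determinate_ai(self):
        cfg, dx, conf, x, perceived, pconf = self._inputs()
        cfg = replace(cfg, weight_human={k: 0.0 for k in CONF_ORDER + ["Uncertain"]})
        _, dx2, _ = integrate_beliefs(x, conf, perceived, pconf, cfg)
        det = (perceived == "Adenoma") | (perceived == "NonAdenoma")
        assert (dx2[det] == perceived[det]).all()

    def test_switch_probability_increasing_in_ai_confidence(self):
        cfg, dx, conf, x, perceived, pconf = self._inputs(n=200_000, seed=9)
        _, dx2, _ = integrate_beliefs(x, conf, perceived, pconf, cfg)
        det = (perceived == "Adenoma") | (perceived == "NonAdenoma")
        cand = det & (dx != perceived)
        rates = []
        for lev in CONF_ORDER:
            m = cand & (pconf == lev)
            rates.append((dx2[m] == perceived[m]).mean())
        assert all(a < b for a, b in zip(rates, rates[1:]))


class TestGenerateCohort:
    def test_small_cohort_valid(self):
        cfg = GeneratorConfig(n_raters=2, n_expert=1, n_lesions=3, seed=7)
        cohort = generate_cohort(cfg)
        assert len(cohort.df) == 12
        assert cohort.n_raters == 2 and cohort.n_lesions == 3

    def test_same_seed_byte_identical_csv(self, tmp_path):
        from teamdx.io import write_cohort_csv

        cfg = GeneratorConfig(n_raters=3, n_expert=1, n_lesions=20, seed=123)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort_csv(generate_cohort(cfg), p1)
        write_cohort_csv(generate_cohort(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        c1 = generate_cohort(GeneratorConfig(n_raters=3, n_expert=1, n_lesions=20, seed=1))
        c2 = generate_cohort(GeneratorConfig(n_raters=3, n_expert=1, n_lesions=20, seed=2))
        assert not c1.df.equals(c2.df)

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="invalid generator config"):
            generate_cohort(replace(GeneratorConfig(), adenoma_prevalence=2.0))

    def test_expertise_split(self, default_cohort):
        vals = list(default_cohort.raters.values())
        assert vals.count("Expert") == 10 and vals.count("NonExpert") == 11

    def test_calibration_monotone_both_sessions(self, default_cohort):
        for target in ("S1", "S2"):
            tab = accuracy_by_confidence(default_cohort, target)
            accs = [tab.cells[lev][0] for lev in CONF_ORDER]
            assert all(a < b for a, b in zip(accs, accs[1:])), (target, accs)

    def test_switch_rate_monotone_in_ai_conf(self, default_cohort):
        tab = switch_rate_by_confidence(default_cohort, "ai_conf")
        rates = [tab.cells[lev][0] for lev in CONF_ORDER]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_default_influence_in_calibrated_bracket(self):
        # scaled-down version of the 20-seed calibration run
        ors = []
        for seed in (11, 12, 13):
            cohort = generate_cohort(GeneratorConfig(seed=seed))
            ors.append(estimate_endpoint(cohort, "influence").or_value)
        assert all(2.0 <= v <= 4.5 for v in ors), ors


class TestUnderReliance:
    def test_all_ors_one_when_ai_ignored(self):
        cfg = GeneratorConfig(
            seed=31,
            weight_ai={k: 0.0 for k in CONF_ORDER},
            weight_human={k: 1.0 for k in CONF_ORDER + ["Uncertain"]},
        )
        cohort = generate_cohort(cfg)
        for name in ENDPOINT_NAMES:
            est = estimate_endpoint(cohort, name)
            assert abs(est.log_or) < 1e-6, (name, est.or_value)


class TestOverReliance:
    def test_over_reliance_pattern(self):
        # exactly zero human weight makes the influence fit separate (S2
        # agreement becomes constant), so use a token residual weight
        cfg = GeneratorConfig(
            seed=37,
            weight_human={k: 0.15 for k in CONF_ORDER + ["Uncertain"]},
        )
        cohort = generate_cohort(cfg)
        est = {n: estimate_endpoint(cohort, n) for n in ENDPOINT_NAMES}
        assert est["influence"].or_value > 5
        assert est["effectiveness"].or_value > 5
        assert est["safety"].or_value < 0.3
        assert est["effectiveness"].or_value > est["accuracy"].or_value


class TestPower:
    def test_huge_effect_full_power(self):
        # strong reliance on a near-perfect AI, few reps needed
        cfg = GeneratorConfig(
            n_raters=6, n_expert=3, n_lesions=80,
            ai_skill=3.0, misread_prob=0.0, seed=5,
        )
        res = simulate_power(cfg, n_reps=5, endpoints=("accuracy",))
        assert res.rejection_rate["accuracy"] == 1.0
        assert res.n_failed["accuracy"] == 0

    def test_power_nondecreasing_in_raters(self):
        # moderate effect so power is off the ceiling at the small size
        weak = dict(weight_ai={"VeryLow": 0.05, "Low": 0.1, "High": 0.3, "VeryHigh": 0.5})
        lo = simulate_power(
            GeneratorConfig(n_raters=3, n_expert=1, n_lesions=40, seed=9, **weak),
            n_reps=40, endpoints=("accuracy",),
        )
        hi = simulate_power(
            GeneratorConfig(n_raters=12, n_expert=6, n_lesions=40, seed=9, **weak),
            n_reps=40, endpoints=("accuracy",),
        )
        assert hi.rejection_rate["accuracy"] >= lo.rejection_rate["accuracy"]

    def test_result_structure(self):
        cfg = GeneratorConfig(n_raters=3, n_expert=1, n_lesions=30, seed=3)
        res = simulate_power(cfg, n_reps=3, endpoints=("influence", "safety"))
        d = res.to_dict()
        assert set(d["rejection_rate"]) == {"influence", "safety"}
        assert all(0 <= v <= 1 for v in d["rejection_rate"].values())
        assert res.n_reps == 3
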