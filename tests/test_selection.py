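"""SIC scoring, tie-breaks, the resampling filter, and the advance rule."""

import numpy as np
import pandas as pd
import pytest

from ouregimes.oumodels import ModelFit, ModelParams, ModelSpec
from ouregimes.selection import (ModelSet, ScoreTable, SensitivityResult,
                                 _rank_models, advance_rule,
                                 pooled_specimen_sd, sampling_sensitivity,
                                 score_models)
from ouregimes.synthetic_data import TraitConfig
from ouregimes.traitsim import simulate_traits


def _fake_fit(name, lnl, p, n=125):
    spec = ModelSpec(name, "BM") if name == "BM1" else ModelSpec(
        name, "OU", optima=tuple(f"o{i}" for i in range(p - 2)),
        regime_map={f"o{i}": f"o{i}" for i in range(p - 2)})
    params = ModelParams(spec=spec, sigma2=1.0,
                         alpha=None if name == "BM1" else 1.0,
                         theta={o: 0.0 for o in spec.optima}, x0=0.0)
    return ModelFit(spec=spec, params=params, lnl=lnl,
                    sic=-2 * lnl + p * np.log(n), n=n)


def _fake_table(sics: dict[str, float]) -> ScoreTable:
    # build fits whose SIC ordering matches the requested values
    fits = {}
    for name, s in sics.items():
        p = {"BM1": 2, "OU1": 3, "OU2_foss": 4, "OU2_arb&Ma": 4,
             "OU2_arb&Xe": 4, "OU3": 5}[name]
        lnl = -(s - p * np.log(125)) / 2
        fits[name] = _fake_fit(name, lnl, p)
    return ScoreTable(trait="t", fits=fits, order=_rank_models(fits))


class TestRanking:
    def test_equal_sic_and_p_break_by_model_order(self):
        fits = {"OU2_arb&Xe": _fake_fit("OU2_arb&Xe", -10.0, 4),
                "OU2_foss": _fake_fit("OU2_foss", -10.0, 4),
                "OU2_arb&Ma": _fake_fit("OU2_arb&Ma", -10.0, 4)}
        order = _rank_models(fits)
        assert order == ["OU2_foss", "OU2_arb&Ma", "OU2_arb&Xe"]

    def test_equal_lnl_prefers_fewer_parameters(self):
        fits = {"OU3": _fake_fit("OU3", -10.0, 5),
                "OU1": _fake_fit("OU1", -10.0, 3)}
        assert _rank_models(fits)[0] == "OU1"

    def test_score_models_on_strong_homoplasy_signal(self, small_frame):
        tree, painting, specs = small_frame
        truth = TraitConfig("t").params(specs)
        x = simulate_traits(tree, painting, truth, 1, seed=30).values[0]
        table = score_models(tree, painting, x, trait="t", specs=specs)
        assert set(table.fits) == set(specs)
        assert table.rank(table.best) == 1
        assert sorted(table.order) == sorted(specs)
        row = table.to_row()
        assert row["best"] == table.best

    def test_score_batch_matches_scalar_scoring(self, small_frame):
        tree, painting, specs = small_frame
        truth = TraitConfig("t").params(specs)
        X = simulate_traits(tree, painting, truth, 10, seed=31).values
        ms = ModelSet(tree, painting, specs=specs)
        best_batch, sics = ms.score_batch(X)
        for d in range(10):
            assert ms.score(X[d]).best == best_batch[d]


class TestSensitivity:
    def test_zero_sd_is_degenerate_and_passes(self, small_frame):
        tree, painting, specs = small_frame
        truth = TraitConfig("t").params(specs)
        x = simulate_traits(tree, painting, truth, 1, seed=40).values[0]
        sens = sampling_sensitivity(tree, painting, x, 0.0, n_replicates=50,
                                    seed=0, specs=specs)
        assert sens.frequencies[sens.modal] == pytest.approx(100.0)
        assert sens.passed

    def test_frequencies_sum_to_100(self, small_frame):
        tree, painting, specs = small_frame
        truth = TraitConfig("t").params(specs)
        x = simulate_traits(tree, painting, truth, 1, seed=41).values[0]
        sens = sampling_sensitivity(tree, painting, x, 0.2, n_replicates=60,
                                    seed=2, specs=specs)
        assert sum(sens.frequencies.values()) == pytest.approx(100.0, abs=0.1)

    def test_small_noise_keeps_strong_signal(self, small_frame):
        tree, painting, specs = small_frame
        cfg = TraitConfig("t")
        truth = cfg.params(specs)
        sep = abs(truth.theta["arb"] - truth.theta["foss"])
        x = simulate_traits(tree, painting, truth, 1, seed=42).values[0]
        sens = sampling_sensitivity(tree, painting, x, 0.25 * sep,
                                    n_replicates=100, seed=3, specs=specs)
        assert sens.frequencies[sens.empirical_best] > 50.0

    def test_negative_sd_rejected(self, small_frame):
        tree, painting, specs = small_frame
        with pytest.raises(ValueError, match=">= 0"):
            sampling_sensitivity(tree, painting, np.zeros(tree.n_tips), -0.1,
                                 n_replicates=5, specs=specs)


class TestPooledSD:
    def test_known_pooled_value(self):
        df = pd.DataFrame([
            {"species": "a", "specimen": "sp1", "trait": "t", "value": 0.0},
            {"species": "a", "specimen": "sp2", "trait": "t", "value": 2.0},
            {"species": "b", "specimen": "sp1", "trait": "t", "value": 5.0},
            {"species": "b", "specimen": "sp2", "trait": "t", "value": 5.0},
            {"species": "c", "specimen": "sp1", "trait": "t", "value": 9.0},
        ])
        # within-species SS = 2 + 0 over 2 dof -> sd = 1
        assert pooled_specimen_sd(df, "t") == pytest.approx(1.0)

    def test_no_multispecimen_species_is_error(self):
        df = pd.DataFrame([{"species": "a", "specimen": "sp1", "trait": "t",
                            "value": 1.0}])
        with pytest.raises(ValueError, match="2 specimens"):
            pooled_specimen_sd(df, "t")


class TestAdvanceRule:
    def _sens(self, empirical_best, modal):
        return SensitivityResult(trait="t", n_replicates=10,
                                 frequencies={modal: 60.0}, modal=modal,
                                 empirical_best=empirical_best, seed=0,
                                 noise_sd=0.1)

    def test_homoplasy_first_advances(self):
        table = _fake_table({"OU2_foss": -40.0, "BM1": 0.0, "OU1": -28.0,
                             "OU2_arb&Ma": -31.0, "OU2_arb&Xe": -26.0,
                             "OU3": -37.0})
        ok, reason = advance_rule(table, self._sens("OU2_foss", "OU2_foss"))
        assert ok and "first" in reason

    def test_second_behind_ou3_advances(self):
        table = _fake_table({"OU3": -45.0, "OU2_foss": -43.0, "OU1": -40.0,
                             "BM1": 0.0, "OU2_arb&Ma": -30.0,
                             "OU2_arb&Xe": -29.0})
        ok, reason = advance_rule(table, self._sens("OU3", "OU3"))
        assert ok and "OU3" in reason

    def test_second_behind_other_model_stops(self):
        table = _fake_table({"OU2_arb&Xe": -45.0, "OU2_foss": -43.0,
                             "OU1": -40.0, "BM1": 0.0, "OU2_arb&Ma": -30.0,
                             "OU3": -29.0})
        ok, reason = advance_rule(table, self._sens("OU2_arb&Xe", "OU2_arb&Xe"))
        assert not ok

    def test_sensitivity_failure_dismisses(self):
        table = _fake_table({"OU2_foss": -40.0, "BM1": 0.0, "OU1": -28.0,
                             "OU2_arb&Ma": -31.0, "OU2_arb&Xe": -26.0,
                             "OU3": -37.0})
        ok, reason = advance_rule(table, self._sens("OU2_foss", "OU2_arb&Xe"))
        assert not ok and "sensitivity" in reason

    def test_pure_function_of_inputs(self):
        table = _fake_table({"OU2_foss": -40.0, "BM1": 0.0, "OU1": -28.0,
                             "OU2_arb&Ma": -31.0, "OU2_arb&Xe": -26.0,
                             "OU3": -37.0})
        sens = self._sens("OU2_foss", "OU2_foss")
        assert advance_rule(table, sens) == advance_rule(table, sens)
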