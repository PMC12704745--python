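"""Synthetic-observer properties: determinism, chance behaviour, monotonicity
and the questionnaire inclusion rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from bodymeta import (ConfigurationError, DDMObserverParams, DesignSpec,
                      QuestionnaireScores, SDTObserverParams,
                      design_for_template, inclusion_filter,
                      simulate_ddm_trials, simulate_sdt_dataset)
from bodymeta.design import ValidationError


class TestDesignSpec:
    def test_templates_match_study_sizes(self):
        assert design_for_template("exp1").n_trials_total == 300
        assert design_for_template("exp2").n_trials_total == 300
        assert design_for_template("exp3").n_trials_total == 480
        assert design_for_template("exp3").speeded

    @pytest.mark.parametrize("asyncs", [(31, 18), (18, 18, 52), (0, 31)])
    def test_asynchronies_must_increase(self, asyncs):
        with pytest.raises(ConfigurationError):
            DesignSpec(asynchrony_levels_ms=asyncs)

    def test_missing_condition_dprime_rejected(self):
        design = DesignSpec(asynchrony_levels_ms=(18, 31), trials_per_condition=10,
                            n_subjects=1)
        params = SDTObserverParams(dprime_by_condition={(18, 6): 0.5})
        with pytest.raises(ConfigurationError):
            simulate_sdt_dataset(design, params, seed=1)


class TestSDTObserver:
    def test_seed_reproducibility_byte_for_byte(self):
        design = DesignSpec(asynchrony_levels_ms=(31, 88), trials_per_condition=50,
                            n_subjects=2, seed=9)
        params = SDTObserverParams(
            dprime_by_condition={(31, 6): 0.5, (88, 6): 1.3})
        a = simulate_sdt_dataset(design, params, seed=123).to_csv(index=False)
        b = simulate_sdt_dataset(design, params, seed=123).to_csv(index=False)
        assert a == b

    def test_chance_observer_near_half_correct(self):
        design = DesignSpec(asynchrony_levels_ms=(52,), trials_per_condition=10_000,
                            n_subjects=1, seed=2)
        params = SDTObserverParams(dprime_by_condition={(52, 6): 0.0})
        tr = simulate_sdt_dataset(design, params, seed=5)
        pc = (tr.sync_side == tr.response_side).mean()
        assert abs(pc - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_accuracy_monotone_in_dprime(self):
        pcs = []
        for d in (0.0, 0.5, 1.0, 1.8):
            design = DesignSpec(asynchrony_levels_ms=(52,),
                                trials_per_condition=10_000, n_subjects=1, seed=3)
            params = SDTObserverParams(dprime_by_condition={(52, 6): d})
            tr = simulate_sdt_dataset(design, params, seed=31)
            pcs.append((tr.sync_side == tr.response_side).mean())
        tol = 3 * np.sqrt(0.25 / 10_000)
        assert all(b > a - tol for a, b in zip(pcs, pcs[1:]))

    def test_full_lapse_destroys_accuracy_and_type2_link(self):
        design = DesignSpec(asynchrony_levels_ms=(88,), trials_per_condition=10_000,
                            n_subjects=1, seed=4)
        params = SDTObserverParams(dprime_by_condition={(88, 6): 1.5},
                                   lapse_rate=1.0)
        tr = simulate_sdt_dataset(design, params, seed=6)
        pc = (tr.sync_side == tr.response_side).mean()
        assert abs(pc - 0.5) < 3 * np.sqrt(0.25 / 10_000)
        correct = (tr.sync_side == tr.response_side)
        table = pd.crosstab(correct, tr.pas)
        _, p, _, _ = chi2_contingency(table)
        assert p > 1e-3  # PAS carries no information about correctness


class TestDDMObserver:
    def test_symmetric_diffusion_choice_half(self):
        params = DDMObserverParams(drift_by_condition={(52, 15): 0.0},
                                   boundary=1.5, start_point=0.5)
        tr = simulate_ddm_trials(params, 10_000, seed=8)
        frac = (tr.response_side == "right").mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_mean_rt_decreases_with_drift_increases_with_boundary(self):
        def mean_rt(v, a):
            params = DDMObserverParams(drift_by_condition={(52, 15): v},
                                       boundary=a, start_point=0.5,
                                       nondecision_t0=0.0)
            tr = simulate_ddm_trials(params, 4_000, seed=12)
            return tr[~tr.censored].rt_decision_s.mean()

        assert mean_rt(2.0, 1.5) < mean_rt(0.8, 1.5) < mean_rt(0.3, 1.5)
        assert mean_rt(1.0, 1.0) < mean_rt(1.0, 2.0) < mean_rt(1.0, 3.0)

    def test_censoring_flags_slow_trials(self):
        params = DDMObserverParams(drift_by_condition={(18, 15): 0.05},
                                   boundary=4.0, start_point=0.5)
        design = DesignSpec(asynchrony_levels_ms=(18,), touches_levels=(15,),
                            trials_per_condition=200, n_subjects=1,
                            speeded=True, max_stim_duration_s=1.0)
        tr = simulate_ddm_trials(params, 200, seed=3, design=design)
        assert tr.censored.any()
        assert (tr.loc[tr.censored, "rt_decision_s"]
                >= 1.0).all()  # censored at the stimulation ceiling

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            DDMObserverParams(drift_by_condition={(52, 15): 1.0}, boundary=-1.0)
        with pytest.raises(ConfigurationError):
            DDMObserverParams(drift_by_condition={(52, 15): 1.0}, start_point=1.2)
        params = DDMObserverParams(drift_by_condition={(52, 15): 1.0})
        with pytest.raises(ConfigurationError):
            simulate_ddm_trials(params, 0, seed=1)


class TestInclusionFilter:
    def test_clear_responder_included(self):
        q = QuestionnaireScores(ownership_items=(2, 2, 2),
                                control_items=(0,) * 6)
        assert inclusion_filter(q)

    def test_boundary_cases_excluded(self):
        q1 = QuestionnaireScores(ownership_items=(1, 1, 1),
                                 control_items=(0,) * 6)
        assert not inclusion_filter(q1)  # ownership mean not > 1
        q2 = QuestionnaireScores(ownership_items=(3, 3, 3),
                                 control_items=(2.5,) * 6)
        assert not inclusion_filter(q2)  # difference only 0.5

    def test_missing_item_rejected(self):
        with pytest.raises(ValidationError):
            QuestionnaireScores(ownership_items=(2, 2), control_items=(0,) * 6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(own=st.lists(st.floats(-3, 3), min_size=3, max_size=3),
           ctrl=st.lists(st.floats(-3, 3), min_size=6, max_size=6))
    def test_rule_matches_direct_computation(self, own, ctrl):
        q = QuestionnaireScores(ownership_items=tuple(own),
                                control_items=tuple(ctrl))
        expected = (np.mean(own) > 1) and (np.mean(own) - np.mean(ctrl) > 1)
        assert inclusion_filter(q) == expected
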