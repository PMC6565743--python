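"""Bootstrap condition means, category assignment, session-resampled stats."""

import numpy as np
import pandas as pd
import pytest

from tvrpipe.classification import (
    CATEGORIES,
    CONDITION_ORDER,
    ConditionMeans,
    ConditionNotRealized,
    bootstrap_condition_means,
    category_distribution_stats,
    classify,
)


def frames_with_conditions(n_trials=8, frames_per_trial=50):
    """Trial-structured running/touch labels realizing all four conditions."""
    n = n_trials * frames_per_trial
    trial_index = np.repeat(np.arange(n_trials), frames_per_trial)
    running = np.tile(np.r_[np.zeros(25), np.ones(25)], n_trials).astype(bool)
    touch = np.tile(np.r_[np.zeros(13), np.ones(12), np.zeros(12), np.ones(13)], n_trials).astype(bool)
    return running, touch, trial_index, n


class TestBootstrapConditionMeans:
    def test_identical_trials_zero_sd(self):
        running, touch, trial_index, n = frames_with_conditions()
        dff = np.tile(np.linspace(0, 1, 50), 8)  # identical trials
        cm = bootstrap_condition_means(dff, running, touch, trial_index, seed=0,
                                       smooth_window_s=0.0)
        assert all(sd == pytest.approx(0.0, abs=1e-12) for sd in cm.sds.values())

    def test_single_condition_drive(self):
        running, touch, trial_index, n = frames_with_conditions()
        dff = (running & touch).astype(float)
        cm = bootstrap_condition_means(dff, running, touch, trial_index, seed=1,
                                       smooth_window_s=0.0)
        assert cm.means["run_touch"] == pytest.approx(1.0)
        for c in ("norun_notouch", "run_notouch", "norun_touch"):
            assert cm.means[c] == pytest.approx(0.0, abs=1e-12)

    def test_missing_condition_excludes_session(self):
        n = 400
        trial_index = np.repeat(np.arange(8), 50)
        running = np.zeros(n, dtype=bool)  # never runs -> run conditions absent
        touch = np.tile(np.r_[np.zeros(25), np.ones(25)], 8).astype(bool)
        with pytest.raises(ConditionNotRealized):
            bootstrap_condition_means(np.ones(n), running, touch, trial_index)

    def test_generator_means_match_gains(self, open_loop_session):
        """Condition means of a generator neuron track its gain structure."""
        from tvrpipe.pipeline import preprocess_stage
        from tvrpipe.segmentation import segment_session

        b = open_loop_session
        dff, _ = preprocess_stage(b)
        tl = segment_session(b)
        trial_index = b.trial_index_of_frames()
        # neuron 3 is integrative: run_touch mean should dominate
        cm = bootstrap_condition_means(dff[3], tl.running, tl.touch, trial_index, seed=2)
        assert cm.means["run_touch"] == max(cm.means.values())


def make_cm(means, sds=None):
    sds = sds or {c: 0.0 for c in CONDITION_ORDER}
    return ConditionMeans(means=dict(zip(CONDITION_ORDER, means)), sds=sds, n_bootstrap=100)


class TestClassify:
    def test_clear_integrative(self):
        cm = make_cm([0.0, 0.1, 0.1, 0.9], {c: 0.05 for c in CONDITION_ORDER})
        res = classify(cm)
        assert res.category == "integrative" and not res.demoted
        assert res.margin == pytest.approx(0.8)

    def test_demotion_to_second_largest(self):
        cm = make_cm([0.0, 0.5, 0.1, 0.52], {**{c: 0.0 for c in CONDITION_ORDER},
                                             "run_touch": 0.1})
        res = classify(cm)
        assert res.category == "run" and res.demoted
        assert res.margin == pytest.approx(0.02)

    def test_zero_sd_reduces_to_argmax(self):
        cm = make_cm([0.1, 0.3, 0.2, 0.31])
        assert classify(cm).category == "integrative"

    def test_scale_invariance(self):
        means = [0.05, 0.4, 0.1, 0.45]
        sds = {c: 0.02 for c in CONDITION_ORDER}
        r1 = classify(make_cm(means, sds))
        r2 = classify(make_cm([3 * m for m in means], {c: 3 * s for c, s in sds.items()}))
        assert r1.category == r2.category and r1.demoted == r2.demoted

    def test_tie_breaks_to_less_specific(self):
        cm = make_cm([0.1, 0.5, 0.5, 0.1])
        assert classify(cm).category == "run"  # run precedes touch


class TestCategoryDistributionStats:
    def _table(self, rng, p_int_a=0.5, p_int_b=0.5, n_sessions=24, n_per=20):
        rows = []
        for s in range(n_sessions):
            layer = "L2/3" if s % 2 == 0 else "L5"
            p_int = p_int_a if layer == "L2/3" else p_int_b
            for i in range(n_per):
                cat = "integrative" if rng.uniform() < p_int else rng.choice(
                    ["rest", "run", "touch"]
                )
                rows.append({"session": f"s{s}", "layer": layer, "category": cat})
        return pd.DataFrame(rows)

    def test_identical_layers_no_systematic_difference(self):
        """With identical category distributions in both layers the t-tests
        show no systematic effect (mean p over meta-seeds well above 0.05)."""
        rng = np.random.default_rng(0)
        pvals = {c: [] for c in CATEGORIES}
        for meta in range(50):
            table = self._table(rng)
            stats = category_distribution_stats(table, seed=meta)
            for c in CATEGORIES:
                pvals[c].append(stats["t_tests"][c]["p"])
        for c in CATEGORIES:
            assert np.mean(pvals[c]) > 0.05

    def test_distinct_integrative_fractions_recovered(self):
        """77% vs 51% integrative fractions come back within 5 points."""
        rng = np.random.default_rng(1)
        table = self._table(rng, p_int_a=0.77, p_int_b=0.51, n_per=50)
        stats = category_distribution_stats(table, seed=0)
        assert stats["per_layer"]["L2/3"]["integrative"]["mean"] == pytest.approx(77.0, abs=5)
        assert stats["per_layer"]["L5"]["integrative"]["mean"] == pytest.approx(51.0, abs=5)
        assert stats["t_tests"]["integrative"]["p"] < 0.01

    def test_single_category_is_hundred_percent(self):
        rows = [
            {"session": f"s{s}", "layer": "L2/3", "category": "touch"}
            for s in range(12)
        ]
        stats = category_distribution_stats(pd.DataFrame(rows), seed=0)
        assert stats["per_layer"]["L2/3"]["touch"]["mean"] == pytest.approx(100.0)
        assert stats["per_layer"]["L2/3"]["rest"]["mean"] == pytest.approx(0.0)

    def test_too_few_sessions_rejected(self):
        rows = [{"session": "s0", "layer": "L2/3", "category": "run"}]
        with pytest.raises(ValueError):
            category_distribution_stats(pd.DataFrame(rows))


class TestCategoryRecovery:
    def test_strong_gain_neurons_recovered(self):
        """>= 90% of synthetic neurons with strong single-condition or
        interaction gains are assigned their generative category."""
        from tvrpipe.pipeline import preprocess_stage
        from tvrpipe.segmentation import segment_session
        from tvrpipe.synth import BehaviorConfig, NeuronSpec, generate_behavior, generate_fluorescence

        behavior = generate_behavior(
            BehaviorConfig(n_trials=20, condition="open_loop", rng_seed=51)
        )
        rng = np.random.default_rng(52)
        cats = ["rest", "run", "touch", "integrative"]
        specs = [NeuronSpec.make(cats[i % 4], rng) for i in range(60)]
        session = generate_fluorescence(behavior, specs, rng_seed=53)
        dff, _ = preprocess_stage(session)
        tl = segment_session(session)
        trial_index = session.trial_index_of_frames()
        correct = 0
        for i, spec in enumerate(specs):
            cm = bootstrap_condition_means(dff[i], tl.running, tl.touch, trial_index,
                                           seed=100 + i)
            correct += classify(cm).category == spec.category
        assert correct >= int(0.9 * len(specs))
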