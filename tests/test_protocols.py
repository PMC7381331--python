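"""Experiment plans, trial scoring, error taxonomy, and the grid runner."""

import numpy as np
import pandas as pd
import pytest

from lexinaming.lexicon import LexiconSpec, build_wwt_battery, generate_lexicon
from lexinaming.model import ModelConfig, NamingModel
from lexinaming.network import AblationSpec, SimilarityTrace
from lexinaming.protocols import (
    ExperimentPlan,
    RunTable,
    TrialResult,
    cell_seed,
    classify_error,
    enumerate_plan,
    evaluate_trial,
    plan_size,
    run_experiment,
    run_trial,
)


@pytest.fixture(scope="module")
def tiny_world():
    spec = LexiconSpec.reduced(
        n_nouns=2, n_verbs=1, n_superordinates=1, n_antonyms=1,
        dimension=32, seed=4,
    )
    lex = generate_lexicon(spec)
    model = NamingModel(lex, ModelConfig(dimension=32, seed=1, backend="direct"))
    battery = build_wwt_battery(lex)
    return lex, model, battery


class TestPlan:
    def test_full_scale_simulation_count(self):
        plan = ExperimentPlan()
        assert plan_size(plan, 95) == 15675

    def test_small_plan_counts(self):
        plan = ExperimentPlan(locations=("a",), levels=(0,), families=("control",))
        assert plan_size(plan, 10) == 10
        plan2 = ExperimentPlan(locations=("a", "b"))
        assert plan_size(plan2, 95) == 2 * 11 * 95 * 3

    def test_deterministic_ordering(self, tiny_world):
        _, _, battery = tiny_world
        plan = ExperimentPlan(locations=("a", "b"), levels=(0, 50))
        cells = enumerate_plan(plan, battery)
        assert len(cells) == plan_size(plan, len(battery))
        assert cells == enumerate_plan(plan, battery)
        locs = [c.location for c in cells]
        assert locs == sorted(locs, key=lambda x: ("a", "b").index(x))

    def test_empty_battery_rejected(self):
        with pytest.raises(ValueError):
            enumerate_plan(ExperimentPlan(), [])

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            ExperimentPlan(locations=("z",))
        with pytest.raises(ValueError):
            ExperimentPlan(levels=(120,))

    def test_cell_seed_stable_and_bounded(self):
        s = cell_seed(3, "d", 40, "semantic", 7)
        assert s == cell_seed(3, "d", 40, "semantic", 7)
        assert 0 <= s < 2**31
        assert s != cell_seed(3, "d", 40, "semantic", 8)
        assert s != cell_seed(4, "d", 40, "semantic", 7)


def synthetic_trace(labels, series, dt=0.01, t1=1.0):
    time = np.arange(dt, t1 + dt / 2, dt)
    values = np.stack([np.full_like(time, s) for s in series], axis=1)
    return SimilarityTrace("phono_prod", time, labels, values)


class TestEvaluate:
    def test_strong_target_is_correct(self):
        tr = synthetic_trace(["tgt", "other"], [0.6, 0.1])
        correct, winner, mean, _ = evaluate_trial(tr, "tgt", (0.2, 0.9))
        assert correct and winner == "tgt"
        assert mean == pytest.approx(0.6)

    def test_all_below_threshold_is_no_reaction(self):
        tr = synthetic_trace(["tgt", "other"], [0.15, 0.1])
        correct, winner, _, _ = evaluate_trial(tr, "tgt", (0.2, 0.9))
        assert not correct and winner is None

    def test_competitor_with_higher_mean_wins(self):
        tr = synthetic_trace(["tgt", "comp"], [0.4, 0.5])
        correct, winner, _, _ = evaluate_trial(tr, "tgt", (0.2, 0.9))
        # argmax oracle: competitor at 0.5 beats target at 0.4
        assert not correct and winner == "comp"

    def test_empty_window_rejected(self):
        tr = synthetic_trace(["tgt"], [0.4])
        with pytest.raises(ValueError):
            evaluate_trial(tr, "tgt", (2.0, 3.0))


class TestClassifyError:
    def test_no_output_is_no_reaction(self, tiny_world):
        lex, _, battery = tiny_world
        assert classify_error(None, battery[0].target, lex) == "no_reaction"

    def test_sibling_is_semantic(self, tiny_world):
        lex, _, battery = tiny_world
        target = battery[0].target
        sibling = lex[target].cues.semantic[0]
        assert classify_error(sibling, target, lex) == "semantic"

    def test_unrelated_entry(self, tiny_world):
        lex, _, battery = tiny_world
        target = battery[0].target
        unrelated = [
            c
            for c in lex.entries
            if not lex.shares_deep_concept(c, target)
            and not lex.shares_deep_phono(c, target)
        ]
        assert classify_error(unrelated[0], target, lex) == "unrelated"

    def test_shared_onset_without_concept_is_phonological(self, tiny_world):
        lex, _, battery = tiny_world
        target = battery[0].target
        mates = [
            c
            for c in lex.entries
            if c != target
            and lex.shares_deep_phono(c, target)
            and not lex.shares_deep_concept(c, target)
        ]
        if not mates:
            pytest.skip("no onset mate in this tiny lexicon")
        assert classify_error(mates[0], target, lex) == "phonological"

    def test_subword_output_is_syllable(self, tiny_world):
        lex, _, battery = tiny_world
        target = battery[0].target
        cls = classify_error(None, target, lex, winner_label="on:s")
        assert cls == "syllable"

    def test_unknown_winner_rejected(self, tiny_world):
        lex, _, battery = tiny_world
        with pytest.raises(KeyError):
            classify_error("ghost", battery[0].target, lex)

    def test_correct_result_carries_no_error_class(self):
        with pytest.raises(ValueError):
            TrialResult(
                item="x", category="noun", condition="RwO", location="-",
                level=0, phase="RwO", correct=True, winner="f",
                winner_concept="x", peak_similarity=1.0, mean_similarity=0.9,
                error_class="semantic", seed=0,
            )


class TestRunTrial:
    def test_intact_noun_trial_correct(self, tiny_world):
        _, model, battery = tiny_world
        noun = next(i for i in battery if i.category == "noun")
        (res,) = run_trial(model, noun, "RwO", seed=2)
        assert res.correct
        assert res.error_class == "none"

    def test_full_lesion_silences_output(self, tiny_world):
        _, model, battery = tiny_world
        noun = next(i for i in battery if i.category == "noun")
        spec = AblationSpec("am_word_phono", 1.0, seed=3)
        (res,) = run_trial(model, noun, "RwO", ablation=spec, seed=2)
        assert not res.correct
        assert res.winner is None
        assert res.error_class == "no_reaction"

    def test_same_cell_same_seed_identical(self, tiny_world):
        _, model, battery = tiny_world
        noun = next(i for i in battery if i.category == "noun")
        spec = AblationSpec("concept_prod", 0.4, seed=9)
        a = run_trial(model, noun, "RwS", ablation=spec, seed=5)
        b = run_trial(model, noun, "RwS", ablation=spec, seed=5)
        assert [r.__dict__ for r in a] == [r.__dict__ for r in b]

    def test_cue_condition_returns_paired_phases(self, tiny_world):
        _, model, battery = tiny_world
        noun = next(i for i in battery if i.category == "noun")
        res = run_trial(model, noun, "RwP", seed=2)
        assert [r.phase for r in res] == ["RwO", "RwP"]


class TestRunExperiment:
    def test_tiny_plan_yields_count_table(self, tiny_world, tmp_path):
        _, model, battery = tiny_world
        plan = ExperimentPlan(
            locations=("d",), levels=(0, 50, 100), families=("control",),
            n_items=3,
        )
        out = tmp_path / "results.csv"
        table = run_experiment(plan, model, battery, base_seed=1, out_path=out)
        counts = table.counts()
        rwo = counts[counts.condition == "RwO"]
        assert len(rwo) == 3  # one row per level
        assert set(rwo.level) == {0, 50, 100}
        # full lesion forces zero correct
        assert rwo[rwo.level == 100].correct.iloc[0] == 0

    def test_resume_skips_completed_cells(self, tiny_world, tmp_path):
        _, model, battery = tiny_world
        plan = ExperimentPlan(
            locations=("d",), levels=(0,), families=("control",), n_items=2
        )
        out = tmp_path / "partial.csv"
        t1 = run_experiment(plan, model, battery, base_seed=1, out_path=out)
        n_rows = len(pd.read_csv(out))
        t2 = run_experiment(plan, model, battery, base_seed=1, out_path=out)
        assert len(pd.read_csv(out)) == n_rows  # nothing re-run
        assert len(t2.results) == len(t1.results)

    def test_unwritable_path_rejected_before_simulation(self, tiny_world):
        _, model, battery = tiny_world
        plan = ExperimentPlan(locations=("d",), levels=(0,), n_items=1)
        with pytest.raises(ValueError, match="does not exist"):
            run_experiment(
                plan, model, battery, out_path="/nonexistent/dir/out.csv"
            )

    def test_pairing_integrity(self, tiny_world):
        _, model, battery = tiny_world
        plan = ExperimentPlan(
            locations=("d",), levels=(0, 60), families=("phonological",),
            n_items=3,
        )
        table = run_experiment(plan, model, battery, base_seed=2)
        paired = table.paired()
        # every cue-phase row has a same-cell baseline from the same run
        cue_rows = table.results[table.results.phase != "RwO"]
        assert len(paired) == len(cue_rows)
        # the merge keys include the seed: pairs come from the same run
        assert "seed" in paired.columns
        assert paired.seed.notna().all()
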