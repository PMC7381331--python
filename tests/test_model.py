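"""Architecture assembly, census, task control, and trial schedules."""

import numpy as np
import pytest

from lexinaming.lexicon import LexiconSpec, build_wwt_battery, generate_lexicon
from lexinaming.model import (
    BUFFER_NAMES,
    DYSFUNCTION_SITES,
    ModelConfig,
    NamingModel,
    build_action_rules,
    model_census,
)


@pytest.fixture(scope="module")
def reduced_model():
    spec = LexiconSpec.reduced(
        n_nouns=2, n_verbs=1, n_superordinates=1, n_antonyms=1,
        dimension=16, seed=4,
    )
    lex = generate_lexicon(spec)
    return NamingModel(lex, ModelConfig(dimension=16, seed=1))


class TestCensus:
    def test_full_scale_neuron_totals(self):
        census = model_census()
        assert census["neurons_per_buffer"] == 3250
        assert census["n_buffers"] == 22
        assert census["buffer_neurons_total"] == 71500
        assert census["n_assoc_memories"] == 26
        assert census["assoc_memory_neurons_total"] == 169000
        assert census["n_cleanup_memories"] == 4
        assert census["basal_ganglia_neurons"] == 2100
        assert census["thalamus_neurons"] == 400

    def test_assembled_model_component_inventory(self, reduced_model):
        built = reduced_model.network.summary()["components"]
        buffers = [n for n, c in built.items() if c["kind"] == "buffer"]
        memories = [n for n, c in built.items() if c["kind"] != "buffer"]
        assert sorted(buffers) == sorted(BUFFER_NAMES)
        assert len(memories) == 26

    def test_dysfunction_resolver(self, reduced_model):
        assert reduced_model.dysfunction_site("d") == "am_word_phono"
        assert reduced_model.dysfunction_site("a") == "concept_prod"
        assert set(DYSFUNCTION_SITES) == set("abcde")
        for site in DYSFUNCTION_SITES.values():
            assert site in reduced_model.network.components
        with pytest.raises(KeyError):
            reduced_model.dysfunction_site("z")

    def test_no_dangling_connections(self, reduced_model):
        net = reduced_model.network
        for conn in net.connections:
            assert conn.source in net.components
            assert conn.target in net.components
        # every gate referenced by the controller exists on some connection
        gates = set(net.gates)
        for rule in reduced_model.controller.rules:
            assert set(rule.gates) <= gates

    def test_production_chain_present_and_acyclic(self, reduced_model):
        net = reduced_model.network
        chain = [
            ("concept_out", "am_out_prod", "concept_prod"),
            ("concept_prod", "am_prod_word", "word_prod"),
            ("word_prod", "am_word_phono", "phono_prod"),
        ]
        pairs = {(c.source, c.target) for c in net.connections}
        for src, mem, tgt in chain:
            assert (src, mem) in pairs and (mem, tgt) in pairs
            assert (tgt, mem) not in pairs  # no backward edge


class TestActionRules:
    @pytest.mark.parametrize("task", ["noun", "verb", "opposite", "superordinate"])
    def test_control_grammar_per_task(self, task):
        rules = build_action_rules(task)
        names = [r.name for r in rules]
        assert names[0].startswith("PROCESS_")
        assert "SPEAK" in names and "PROCESS_CUE" in names

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            build_action_rules("poetry")

    def test_opposite_task_routes_through_oppo_gate(self):
        rules = {r.name: r for r in build_action_rules("opposite")}
        assert rules["PROCESS_OPPOSITE"].gates.get("oppo") == 1.0
        assert "through" not in rules["PROCESS_OPPOSITE"].gates

    def test_single_candidate_rule_always_wins(self, reduced_model):
        ctrl = reduced_model.controller
        vocab = ctrl.vocab
        state = vocab["Q_NOUN"].vector
        rule, utility = ctrl.winner(state)
        assert rule.name == "PROCESS_NOUN"
        assert utility == pytest.approx(1.0, abs=0.05)

    def test_below_threshold_no_rule_wins(self, reduced_model):
        rule, _ = reduced_model.controller.winner(
            np.zeros(reduced_model.config.dimension)
        )
        assert rule is None

    def test_gate_exclusivity_of_routes(self, reduced_model):
        """At most one of the through/oppo/super routes is open per action."""
        for rule in reduced_model.controller.rules:
            routes_open = sum(
                rule.gates.get(g, 0.0) > 0 for g in ("through", "oppo", "super")
            )
            assert routes_open <= 1


class TestSchedules:
    @pytest.fixture(scope="class")
    def battery(self, reduced_model):
        return build_wwt_battery(reduced_model.lexicon)

    def test_rws_control_sequence(self, reduced_model, battery):
        noun = next(i for i in battery if i.category == "noun")
        sched = reduced_model.schedule_trial(noun, "RwS")
        assert sched.control_sequence == [
            "Q_NOUN",
            "PRODUCE_NOUN",
            "CUE",
            "PRODUCE_NOUN_CUE",
        ]
        assert len(sched.speak_windows) == 2

    def test_rwp_presents_single_onset_token(self, reduced_model, battery):
        verb = next(i for i in battery if i.category == "verb")
        sched = reduced_model.schedule_trial(verb, "RwP")
        cue = reduced_model.lexicon[verb.target].cues.phonological
        onset_events = [
            e for e in sched.events
            if e.target == "audio_in"
            and np.allclose(
                e.vector,
                reduced_model.config.cue_stim_gain
                * reduced_model.lexicon.phonos[f"on:{cue}"].vector,
            )
        ]
        assert len(onset_events) == 1

    def test_rwt_extends_answer_span_without_input(self, reduced_model, battery):
        noun = next(i for i in battery if i.category == "noun")
        rwo = reduced_model.schedule_trial(noun, "RwO")
        rwt = reduced_model.schedule_trial(noun, "RwT")
        assert rwt.duration == pytest.approx(
            rwo.duration + reduced_model.config.rwt_gap
            + reduced_model.config.t_produce
        )
        # no auditory input anywhere in the control condition
        assert not any(e.target == "audio_in" for e in rwt.events)

    def test_phase_durations_sum_to_trial_duration(self, reduced_model, battery):
        cfg = reduced_model.config
        noun = next(i for i in battery if i.category == "noun")
        sched = reduced_model.schedule_trial(noun, "RwS")
        expected = cfg.t_question + cfg.t_produce + 3 * cfg.t_cue + cfg.t_produce
        assert sched.duration == pytest.approx(expected)

    def test_superordinate_exemplars_sequential(self, reduced_model, battery):
        sup = next(i for i in battery if i.category == "superordinate")
        cfg = reduced_model.config
        sched = reduced_model.schedule_trial(sup, "RwO")
        vis = sorted(
            (
                e
                for e in sched.events
                if e.target == "visual_in" and e.t_start < 4 * cfg.t_exemplar
            ),
            key=lambda e: e.t_start,
        )
        # four focus presentations back to back, then the joint display
        assert len(vis) == 4
        for first, second in zip(vis[:-1], vis[1:]):
            assert second.t_start == pytest.approx(first.t_end)
        joint = [
            e
            for e in sched.events
            if e.target == "visual_in" and e.t_start >= 4 * cfg.t_exemplar
        ]
        assert len(joint) == 1 and joint[0].t_end == pytest.approx(sched.duration)

    def test_antonym_item_uses_partner_as_audio(self, reduced_model, battery):
        adj = next(i for i in battery if i.category == "adjective")
        sched = reduced_model.schedule_trial(adj, "RwO")
        lex = reduced_model.lexicon
        form = lex[adj.audio].phono_form
        audio = [e for e in sched.events if e.target == "audio_in"]
        assert len(audio) == 1
        assert np.allclose(
            audio[0].vector, reduced_model.config.stim_gain * lex.phonos[form].vector
        )

    def test_unknown_condition_rejected(self, reduced_model, battery):
        with pytest.raises(ValueError):
            reduced_model.schedule_trial(battery[0], "RwX")
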