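"""The picture-naming model: architecture assembly, task control, and
per-trial input schedules.

The model wires 22 named state buffers and 26 associative memories (4 of
them winner-take-all cleanups) into a visual and an auditory perception
pathway, a cognitive processing module with task-dependent routing
(straight-through, antonym, superordinate, and cue paths), and a production
pathway ``concept_out -> concept_prod -> word_prod -> phono_prod`` whose
final buffer is read out to score naming trials.  A task-control module
(cortical control buffers plus a basal-ganglia/thalamus-style
winner-take-all over action utilities) opens and closes the routing gates
according to the control pointers scheduled in the ``input_control`` buffer.

Neural dysfunctions are introduced by ablating a fraction of neurons at one
of five production-pathway locations:

====  =======================================
a     ``concept_prod`` buffer (concept level)
b     concept-to-lemma memory (cleanup)
c     ``word_prod`` buffer (lemma level)
d     lemma-to-phonological memory
e     ``phono_prod`` buffer (phonological level)
====  =======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lexicon import SyntheticLexicon, WWTItem, derive_phonological_cue
from .nef import LIFParams
from .network import InputEvent, Network
from .pointers import SPVocabulary

__all__ = [
    "ModelConfig",
    "ActionRule",
    "TaskController",
    "TrialSchedule",
    "NamingModel",
    "build_action_rules",
    "model_census",
    "DYSFUNCTION_SITES",
    "BUFFER_NAMES",
]

#: the five lesion sites of the production pathway
DYSFUNCTION_SITES = {
    "a": "concept_prod",
    "b": "am_prod_word",
    "c": "word_prod",
    "d": "am_word_phono",
    "e": "phono_prod",
}

BUFFER_NAMES = [
    "visual_in",
    "concept_visual",
    "audio_in",
    "phono_audio",
    "word_audio",
    "concept_audio",
    "concept_perc",
    "concept_in",
    "concept_through",
    "oppo_in",
    "oppo_out",
    "super_in",
    "super_out",
    "s_cue_in",
    "p_cue_in",
    "cue_out",
    "concept_out",
    "concept_prod",
    "word_prod",
    "phono_prod",
    "input_control",
    "action_control",
]

_INPUT_BUFFERS = {"visual_in", "audio_in", "input_control", "action_control"}
_MEMORY_BUFFERS = {
    "concept_through",
    "oppo_out",
    "super_out",
    "cue_out",
}
# production working memories settle within one SPEAK window (faster leak)
_PRODUCTION_BUFFERS = {"concept_prod", "word_prod", "phono_prod"}

_TASK_BY_CATEGORY = {
    "noun": "NOUN",
    "verb": "VERB",
    "adjective": "OPPOSITE",
    "superordinate": "SUPER",
}

CONDITIONS = ("RwO", "RwS", "RwP", "RwT")


@dataclass(frozen=True)
class ModelConfig:
    """All tunable constants of the assembled model.

    Only ``dimension`` and ``n_neurons`` are printed facts of the modelled
    architecture (64 and 50 at full scale); the synapse, gain and timing
    constants follow common conventions for this model family and are
    surfaced here so that every simulation records the values it used.
    """

    dimension: int = 64
    n_neurons: int = 50
    dt: float = 0.001
    backend: str = "spiking"
    seed: int = 0
    # synapses and buffer dynamics
    tau_ff: float = 0.01
    tau_relay: float = 0.03
    tau_mem: float = 0.1
    fb_relay: float = 0.3
    fb_memory: float = 0.95
    fb_production: float = 0.9
    gain_relay: float = 0.7
    gain_memory: float = 0.35
    gain_production: float = 0.35
    output_gain: float = 0.3
    radius_scale: float = 2.5
    # associative memory constants
    am_threshold: float = 0.6
    am_ramp: float = 0.35
    am_inhibit: float = 0.1
    map_threshold: float = 0.3
    map_ramp: float = 0.7
    cleanup_threshold: float = 0.3
    cleanup_ramp: float = 0.3
    cleanup_inhibit: float = 1.2
    cleanup_gain: float = 1.3
    cleanup_tau: float = 0.01
    cue_cleanup_threshold: float = 0.25
    cue_cleanup_inhibit: float = 0.6
    s_cue_scale: float = 1.0
    cue_out_scale: float = 0.4
    spread_gain: float = 0.02
    spread_threshold: float = 0.8
    # evaluation
    eval_threshold: float = 0.2
    eval_settle: float = 0.15
    # trial phase durations (s)
    t_question: float = 0.3
    t_produce: float = 0.5
    t_cue: float = 0.3
    t_exemplar: float = 0.2
    rwt_gap: float = 0.9
    t_settle: float = 0.2
    # stimulus amplitudes
    stim_gain: float = 1.0
    distractor_gain: float = 0.6
    cue_stim_gain: float = 1.0
    # action selection
    utility_threshold: float = 0.3
    act_gain: float = 0.8
    bg_ensembles: int = 42
    thalamus_ensembles: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.eval_threshold < 1.0:
            raise ValueError("evaluation threshold must lie in (0, 1)")
        for nm in ("t_question", "t_produce", "t_cue", "t_exemplar"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"phase duration {nm} must be positive")

    @property
    def radius(self) -> float:
        return self.radius_scale / np.sqrt(self.dimension)


def model_census(config: "ModelConfig | None" = None) -> dict:
    """Structural neuron accounting at the configured scale.

    Each buffer holds one scalar ensemble per pointer dimension plus one
    gating/routing ensemble; associative memories hold twice as many
    neurons as a buffer; the action-selection module is sized by its
    ensemble inventory.  At full scale (D=64, 50 neurons per ensemble) this
    yields 3250 neurons per buffer, 71500 over the 22 buffers, 169000 over
    the 26 associative memories, and 2100/400 neurons in the
    basal-ganglia/thalamus networks.
    """
    cfg = config or ModelConfig()
    # census convention: every buffer carries one gating/routing ensemble in
    # addition to its per-dimension state ensembles
    per_buffer = (cfg.dimension + 1) * cfg.n_neurons
    per_am = 2 * per_buffer
    n_buffers = len(BUFFER_NAMES)
    n_ams = len(_AM_WIRING)
    n_cleanups = sum(
        1 for _, _, _, kind in _AM_WIRING if kind.startswith("cleanup")
    )
    return {
        "dimension": cfg.dimension,
        "neurons_per_ensemble": cfg.n_neurons,
        "n_buffers": n_buffers,
        "n_assoc_memories": n_ams,
        "n_cleanup_memories": n_cleanups,
        "neurons_per_buffer": per_buffer,
        "neurons_per_assoc_memory": per_am,
        "buffer_neurons_total": n_buffers * per_buffer,
        "assoc_memory_neurons_total": n_ams * per_am,
        "basal_ganglia_neurons": cfg.bg_ensembles * cfg.n_neurons,
        "thalamus_neurons": cfg.thalamus_ensembles * cfg.n_neurons,
    }


# (name, source buffer, target buffer, kind); kind selects prototype maps
_AM_WIRING = [
    ("am_visual", "visual_in", "concept_visual", "concept_id"),
    ("am_vis_perc", "concept_visual", "concept_perc", "concept_id"),
    ("am_audio", "audio_in", "phono_audio", "phono_id"),
    ("am_phono_word", "phono_audio", "word_audio", "form_to_lemma"),
    ("am_word_concept", "word_audio", "concept_audio", "cleanup_lemma_concept"),
    ("am_audio_perc", "concept_audio", "concept_perc", "concept_id:percaudio"),
    ("am_perc_in", "concept_perc", "concept_in", "cleanup_concept"),
    ("am_in_through", "concept_in", "concept_through", "concept_id:through"),
    ("am_through_out", "concept_through", "concept_out", "concept_id"),
    ("am_in_oppo", "concept_in", "oppo_in", "concept_id:oppo"),
    ("am_oppo", "oppo_in", "oppo_out", "antonym"),
    ("am_oppo_out", "oppo_out", "concept_out", "concept_id"),
    ("am_in_super", "concept_in", "super_in", "concept_id:super"),
    ("am_super", "super_in", "super_out", "superordinate"),
    ("am_super_out", "super_out", "concept_out", "concept_id"),
    ("am_audio_scue", "concept_audio", "s_cue_in", "cue_id:cue"),
    ("am_audio_pcue", "phono_audio", "p_cue_in", "onset_id:cue"),
    ("am_scue_out", "s_cue_in", "cue_out", "cue_id"),
    ("am_pcue_out", "p_cue_in", "cue_out", "onset_to_concepts"),
    ("am_cue_concept_out", "cue_out", "concept_out", "cleanup_cue"),
    ("am_out_prod", "concept_out", "concept_prod", "concept_id:speak"),
    ("am_prod_word", "concept_prod", "word_prod", "cleanup_concept_lemma"),
    ("am_word_phono", "word_prod", "phono_prod", "lemma_to_form"),
    ("am_concept_net", "concept_perc", "concept_perc", "spread_concept"),
    ("am_concept_net_prod", "concept_prod", "concept_prod", "spread_concept"),
    ("am_phono_net", "phono_prod", "phono_prod", "spread_phono"),
]


@dataclass(frozen=True)
class ActionRule:
    """One task-control rule: if the control state is most similar to one of
    the trigger pointers, open exactly this gate configuration."""

    name: str
    triggers: tuple[str, ...]
    gates: "dict[str, float]" = field(default_factory=dict)


_ALL_GATES = ("through", "oppo", "super", "cue", "speak", "percaudio")

def _task_rules(task: str, route: str) -> list[ActionRule]:
    """The control grammar of one subtask.

    While the model speaks, the task route stays open (the stimulus remains
    in view); the cue path opens during cue processing and cue production.
    """
    return [
        ActionRule(
            f"PROCESS_{task}", (f"Q_{task}",), {route: 1.0, "percaudio": 1.0}
        ),
        ActionRule(
            "SPEAK",
            (f"PRODUCE_{task}",),
            {"speak": 1.0, route: 1.0, "percaudio": 1.0},
        ),
        # while cues are processed, auditory input is routed to the cue
        # path only, away from the straight perception route
        ActionRule("PROCESS_CUE", ("CUE",), {"cue": 1.0}),
        ActionRule(
            "SPEAK",
            (f"PRODUCE_{task}_CUE",),
            {"speak": 1.0, route: 1.0, "cue": 1.0},
        ),
    ]


_RULES_BY_TASK = {
    "NOUN": _task_rules("NOUN", "through"),
    "VERB": _task_rules("VERB", "through"),
    "OPPOSITE": _task_rules("OPPOSITE", "oppo"),
    "SUPER": _task_rules("SUPER", "super"),
}

CONTROL_POINTERS = sorted(
    {t for rules in _RULES_BY_TASK.values() for r in rules for t in r.triggers}
)
ACTION_POINTERS = sorted(
    {r.name for rules in _RULES_BY_TASK.values() for r in rules}
)


def build_action_rules(task: str) -> list[ActionRule]:
    """Control grammar for one subtask (``noun``/``verb``/``opposite``/
    ``superordinate`` or the internal uppercase task keys)."""
    key = task.upper()
    key = {"OPPOSITE": "OPPOSITE", "SUPERORDINATE": "SUPER"}.get(key, key)
    if key not in _RULES_BY_TASK:
        raise ValueError(
            f"unknown task {task!r}; expected noun, verb, opposite or superordinate"
        )
    return list(_RULES_BY_TASK[key])


class TaskController:
    """Winner-take-all action selection over rule utilities.

    Utilities are the dot products between the decoded ``input_control``
    state and each rule's trigger pointers; the winning rule's gate
    configuration is applied and its action pointer is driven into the
    ``action_control`` buffer.  Below the utility threshold no rule wins and
    all gates stay shut.
    """

    watch = ["input_control"]

    def __init__(
        self,
        rules: list[ActionRule],
        control_vocab: SPVocabulary,
        utility_threshold: float = 0.3,
        act_gain: float = 0.8,
    ):
        self.rules = rules
        self.vocab = control_vocab
        self.utility_threshold = utility_threshold
        self.act_gain = act_gain
        triggers = [t for r in rules for t in r.triggers]
        self._trigger_matrix = control_vocab.matrix(triggers)
        self._offsets = np.cumsum([0] + [len(r.triggers) for r in rules])[:-1]
        self._action_vectors = [
            control_vocab[r.name].vector if r.name in control_vocab else None
            for r in rules
        ]

    def winner(self, state: np.ndarray) -> "tuple[ActionRule | None, float]":
        u = self._trigger_matrix @ state
        utilities = np.maximum.reduceat(u, self._offsets)
        best = int(np.argmax(utilities))
        if utilities[best] < self.utility_threshold:
            return None, float(utilities[best])
        return self.rules[best], float(utilities[best])

    def __call__(self, t: float, state: dict) -> tuple[dict, dict]:
        rule, _ = self.winner(state["input_control"])
        gates = {g: 0.0 for g in _ALL_GATES}
        inputs = {}
        if rule is not None:
            gates.update(rule.gates)
            idx = self.rules.index(rule)
            vec = self._action_vectors[idx]
            if vec is not None:
                inputs["action_control"] = self.act_gain * vec
        return gates, inputs


@dataclass
class TrialSchedule:
    """Timed inputs for one trial plus the windows scored as speech output."""

    item: WWTItem
    condition: str
    events: list[InputEvent]
    speak_windows: list[tuple[float, float]]
    duration: float
    control_sequence: list[str]


class NamingModel:
    """The assembled architecture over a given synthetic lexicon."""

    def __init__(self, lexicon: SyntheticLexicon, config: "ModelConfig | None" = None):
        self.lexicon = lexicon
        cfg = config or ModelConfig(dimension=lexicon.spec.dimension)
        if cfg.dimension != lexicon.spec.dimension:
            cfg = replace(cfg, dimension=lexicon.spec.dimension)
        self.config = cfg
        self.control_vocab = SPVocabulary(cfg.dimension, seed=cfg.seed + 901)
        for lb in CONTROL_POINTERS + [a for a in ACTION_POINTERS]:
            if lb not in self.control_vocab:
                self.control_vocab.create(lb)
        rules = []
        seen = set()
        for task in _RULES_BY_TASK:
            for r in _RULES_BY_TASK[task]:
                key = (r.name, r.triggers)
                if key not in seen:
                    seen.add(key)
                    rules.append(r)
        self.controller = TaskController(
            rules, self.control_vocab, cfg.utility_threshold, cfg.act_gain
        )
        self.network = self._assemble()
        # output candidates scored at phono_prod: word forms plus sub-word units
        self.output_labels = list(lexicon.surface_forms) + list(lexicon.deep_phonos)

    # -- architecture ----------------------------------------------------

    def _prototype_maps(self, kind: str):
        """(input prototypes, output prototypes, threshold, wta, inhibit)"""
        lex, cfg = self.lexicon, self.config
        C = lex.concepts
        concepts = list(lex.entries)
        cmat = C.matrix(concepts)
        if kind in ("concept_id", "spread_concept"):
            return cmat, cmat, False
        if kind == "phono_id" or kind == "spread_phono":
            labels = lex.surface_forms + lex.deep_phonos
            m = lex.phonos.matrix(labels)
            return m, m, False
        if kind == "form_to_lemma":
            forms, lemmas = [], []
            seen = set()
            for c, e in lex.entries.items():
                if e.phono_form not in seen:
                    seen.add(e.phono_form)
                    forms.append(e.phono_form)
                    lemmas.append(c)
            return lex.phonos.matrix(forms), lex.lemmas.matrix(lemmas), False
        if kind == "cleanup_lemma_concept":
            return lex.lemmas.matrix(concepts), cmat, True
        if kind == "cleanup_concept":
            return cmat, cmat, True
        if kind == "cleanup_concept_lemma":
            return cmat, lex.lemmas.matrix(concepts), True
        if kind == "lemma_to_form":
            out = lex.phonos.matrix([lex.entries[c].phono_form for c in concepts])
            return lex.lemmas.matrix(concepts), out, False
        if kind == "antonym":
            ins = [c for c, e in lex.entries.items() if e.antonym]
            outs = [lex.entries[c].antonym for c in ins]
            if not ins:
                return cmat[:1], cmat[:1], False
            return C.matrix(ins), C.matrix(outs), True
        if kind == "superordinate":
            # several exemplar channels are co-active (sequential residues
            # plus mutual similarity); scale the summed output down so the
            # superordinate arrives near unit amplitude
            ins, outs = [], []
            for c, e in lex.entries.items():
                for ex in e.exemplars:
                    ins.append(ex)
                    outs.append(c)
            if not ins:
                return cmat[:1], cmat[:1], False
            return C.matrix(ins), 0.5 * C.matrix(outs), False
        if kind == "cue_id":
            # a heard cue word activates its deep category: the boost aligns
            # with the whole semantic neighbourhood of the target instead of
            # competing as a word of its own
            cues = self.cue_words
            if not cues:
                return cmat[:1], cmat[:1], False
            outs = []
            for cue in cues:
                parents = lex.entries[cue].deep_parents
                v = C.matrix(list(parents)).mean(axis=0)
                outs.append(v / np.linalg.norm(v))
            return C.matrix(cues), np.array(outs), False
        if kind == "onset_id":
            onsets = [lb for lb in lex.deep_phonos if lb.startswith("on:")]
            m = lex.phonos.matrix(onsets)
            return m, m, False
        if kind == "onset_to_concepts":
            onsets = [lb for lb in lex.deep_phonos if lb.startswith("on:")]
            outs = []
            for lb in onsets:
                prefix = lb[3:]
                members = lex.concepts_with_prefix(prefix)
                if members:
                    v = C.matrix(members).sum(axis=0)
                    v = v / np.linalg.norm(v)
                else:
                    v = np.zeros(cfg.dimension)
                outs.append(v)
            return lex.phonos.matrix(onsets), np.array(outs), False
        if kind == "cleanup_cue":
            # the cue path may carry deep-category pointers as well
            labels = concepts + lex.deep_concepts
            m = C.matrix(labels)
            return m, m, True
        raise ValueError(f"unknown associative memory kind: {kind!r}")

    def _assemble(self) -> Network:
        lex, cfg = self.lexicon, self.config
        self.cue_words = sorted(
            {c for e in lex.entries.values() if e.cues for c in e.cues.semantic}
        )
        params = LIFParams(dt=cfg.dt)
        net = Network(params=params, seed=cfg.seed)
        D = cfg.dimension
        for name in BUFFER_NAMES:
            if name in _INPUT_BUFFERS:
                net.add_buffer(name, D, cfg.n_neurons, radius=cfg.radius)
            elif name in _MEMORY_BUFFERS:
                net.add_buffer(
                    name,
                    D,
                    cfg.n_neurons,
                    recurrent=True,
                    radius=cfg.radius,
                    feedback=cfg.fb_memory,
                    tau_feedback=cfg.tau_mem,
                )
            elif name in _PRODUCTION_BUFFERS:
                # production working memories only hold while the model
                # speaks: their feedback loop is gated by the SPEAK action
                net.add_buffer(name, D, cfg.n_neurons, radius=cfg.radius)
                net.connect(
                    name,
                    name,
                    transform=cfg.fb_production,
                    synapse=cfg.tau_mem,
                    gate="speak",
                )
            else:
                net.add_buffer(
                    name,
                    D,
                    cfg.n_neurons,
                    recurrent=True,
                    radius=cfg.radius,
                    feedback=cfg.fb_relay,
                    tau_feedback=cfg.tau_relay,
                )
        budget = 2 * D * cfg.n_neurons
        for name, src, tgt, kind in _AM_WIRING:
            kind, _, gate = kind.partition(":")
            spread = kind.startswith("spread")
            cleanup = kind.startswith("cleanup")
            ins, outs, wta = self._prototype_maps(kind)
            mapping = kind in (
                "form_to_lemma",
                "lemma_to_form",
                "antonym",
                "superordinate",
                "onset_to_concepts",
            )
            radius, fmax = 2.0, 2.0
            if kind == "cleanup_cue":
                theta = cfg.cue_cleanup_threshold
                inhibit = cfg.cue_cleanup_inhibit
                ramp = cfg.cleanup_ramp
                radius, fmax = 1.3, cfg.cleanup_gain
            elif name == "am_prod_word":
                # the word-selection cleanup passes amplitude grading so
                # that concept-level boosts (cues) reach the lower levels
                theta = cfg.cleanup_threshold
                inhibit = cfg.cleanup_inhibit
                ramp = 0.8
                radius, fmax = 2.0, 2.0
            elif cleanup or wta:
                theta = cfg.cleanup_threshold
                inhibit = cfg.cleanup_inhibit
                ramp = cfg.cleanup_ramp
                radius, fmax = 1.3, cfg.cleanup_gain
            elif spread:
                theta, inhibit, ramp = cfg.spread_threshold, 0.0, None
                fmax = 0.5
            elif kind == "onset_id":
                # responds to onset tokens only, not to whole word forms
                # (which sit near 0.7 similarity to their onset unit)
                theta, inhibit, ramp = 0.85, 0.0, 0.15
            elif mapping:
                theta, inhibit, ramp = cfg.map_threshold, 0.0, cfg.map_ramp
                fmax = 3.0
            else:
                theta, inhibit, ramp = cfg.am_threshold, cfg.am_inhibit, cfg.am_ramp
                fmax = 4.0
            n_per = max(4, int(round(budget / len(ins))))
            net.add_assoc_memory(
                name, ins, outs, threshold=theta, winner_take_all=wta,
                n_per=n_per, inhibit=inhibit, ramp=ramp, radius=radius, fmax=fmax,
                lateral_synapse=cfg.cleanup_tau,
            )
            net.connect(src, name, 1.0, synapse=cfg.tau_ff, gate=gate or None)
            if tgt in ("word_prod", "phono_prod"):
                gain = cfg.output_gain
            elif name == "am_scue_out":
                gain = cfg.gain_memory * cfg.s_cue_scale
            elif name == "am_cue_concept_out":
                # the cue path is an additional, subordinate input to the
                # concept output: it boosts rather than replaces the main path
                gain = cfg.gain_relay * cfg.cue_out_scale
            elif spread:
                gain = cfg.spread_gain
            elif tgt in _PRODUCTION_BUFFERS:
                gain = cfg.gain_production
            elif tgt in _MEMORY_BUFFERS:
                gain = cfg.gain_memory
            elif tgt in _INPUT_BUFFERS:
                gain = 1.0
            else:
                gain = cfg.gain_relay
            net.connect(name, tgt, gain, synapse=cfg.tau_ff)
        return net

    def simulator(self, backend: "str | None" = None, seed: "int | None" = None):
        from .network import Simulator

        return Simulator(
            self.network,
            dt=self.config.dt,
            backend=backend or self.config.backend,
            seed=self.config.seed if seed is None else seed,
        )

    def dysfunction_site(self, location: str) -> str:
        """Resolve a lesion location letter (a-e) to its component name."""
        if location not in DYSFUNCTION_SITES:
            raise KeyError(
                f"unknown dysfunction location {location!r}; valid: a, b, c, d, e"
            )
        return DYSFUNCTION_SITES[location]

    def census(self) -> dict:
        """Census of the assembled components at the configured scale."""
        out = model_census(self.config)
        built = self.network.summary()
        out["built_components"] = built["components"]
        return out

    # -- trial scheduling -------------------------------------------------

    def schedule_trial(self, item: WWTItem, condition: str) -> TrialSchedule:
        """Timed step inputs for one battery item under one cue condition.

        Every cue condition embeds the corresponding no-cue phase first: the
        trial runs question -> production (scored), and for RwS/RwP/RwT a
        cue (or silent control) phase -> second production (scored).
        """
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; valid: {CONDITIONS}")
        lex, cfg = self.lexicon, self.config
        entry = lex.entries[item.target]
        cvoc, pvoc = lex.concepts, lex.phonos
        task = _TASK_BY_CATEGORY[item.category]
        events: list[InputEvent] = []
        control: list[str] = []

        def ctrl(label: str, t0: float, t1: float):
            events.append(
                InputEvent("input_control", self.control_vocab[label].vector, t0, t1)
            )
            control.append(label)

        # phase layout depends on the condition; the pictured stimulus stays
        # in view until the end of the trial (as in the test booklet)
        if item.mode == "visual_four":
            t_q = 4 * cfg.t_exemplar + cfg.t_settle
        else:
            t_q = cfg.t_question
        t_end_q = t_q + cfg.t_produce
        if condition == "RwO":
            total = t_end_q
        elif condition == "RwS":
            total = t_end_q + 3 * cfg.t_cue + cfg.t_produce
        elif condition == "RwP":
            total = t_end_q + cfg.t_cue + cfg.t_produce
        else:
            total = t_end_q + cfg.rwt_gap + cfg.t_produce

        # --- question phase ---
        if item.mode in ("visual", "visual_action"):
            distractors = entry.distractors
            if distractors:
                slot = 0.5 * t_q / len(distractors)
                for i, d in enumerate(distractors):
                    events.append(
                        InputEvent(
                            "visual_in",
                            cfg.distractor_gain * cvoc[d].vector,
                            i * slot,
                            (i + 1) * slot,
                        )
                    )
            # the picture (the target) stays visible for the whole trial
            events.append(
                InputEvent(
                    "visual_in",
                    cfg.stim_gain * cvoc[item.target].vector,
                    t_q / 3.0,
                    total,
                )
            )
        elif item.mode == "visual_four":
            # sequential focus pass over the four pictures, a short settle
            # pause, then all four remain in view (weaker, concurrent) for
            # the rest of the trial as on the test sheet
            for i, ex in enumerate(item.visual):
                events.append(
                    InputEvent(
                        "visual_in",
                        cfg.stim_gain * cvoc[ex].vector,
                        i * cfg.t_exemplar,
                        (i + 1) * cfg.t_exemplar,
                    )
                )
            joint = cvoc.matrix(list(item.visual)).sum(axis=0)
            joint = joint / np.linalg.norm(joint)
            events.append(
                InputEvent(
                    "visual_in",
                    1.4 * cfg.stim_gain * joint,
                    4 * cfg.t_exemplar,
                    total,
                )
            )
        elif item.mode == "audio_antonym":
            form = lex.entries[item.audio].phono_form
            events.append(
                InputEvent(
                    "audio_in",
                    cfg.stim_gain * pvoc[form].vector,
                    0.0,
                    t_q + cfg.t_produce,
                )
            )
        else:
            raise ValueError(f"unknown stimulus mode {item.mode!r}")
        ctrl(f"Q_{task}", 0.0, t_q)

        # --- first production (scored for every condition) ---
        t0 = t_q
        ctrl(f"PRODUCE_{task}", t0, t0 + cfg.t_produce)
        windows = [(t0 + cfg.eval_settle, t0 + cfg.t_produce)]
        t1 = t0 + cfg.t_produce

        # --- cue or control phase plus second production ---
        if condition != "RwO":
            if entry.cues is None:
                raise ValueError(
                    f"item {item.target!r} carries no cues and cannot be run "
                    f"under condition {condition}"
                )
            if condition == "RwS":
                for i, cue in enumerate(entry.cues.semantic):
                    form = lex.entries[cue].phono_form
                    events.append(
                        InputEvent(
                            "audio_in",
                            cfg.cue_stim_gain * pvoc[form].vector,
                            t1 + i * cfg.t_cue,
                            t1 + (i + 1) * cfg.t_cue,
                        )
                    )
                t_cue_end = t1 + 3 * cfg.t_cue
                ctrl("CUE", t1, t_cue_end)
            elif condition == "RwP":
                onset = f"on:{entry.cues.phonological}"
                events.append(
                    InputEvent(
                        "audio_in",
                        cfg.cue_stim_gain * pvoc[onset].vector,
                        t1,
                        t1 + cfg.t_cue,
                    )
                )
                t_cue_end = t1 + cfg.t_cue
                ctrl("CUE", t1, t_cue_end)
            else:  # RwT: the answer span is extended with no further input
                t_cue_end = t1 + cfg.rwt_gap
            ctrl(f"PRODUCE_{task}_CUE", t_cue_end, t_cue_end + cfg.t_produce)
            windows.append((t_cue_end + cfg.eval_settle, t_cue_end + cfg.t_produce))
            t1 = t_cue_end + cfg.t_produce

        return TrialSchedule(
            item=item,
            condition=condition,
            events=events,
            speak_windows=windows,
            duration=t1,
            control_sequence=control,
        )
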