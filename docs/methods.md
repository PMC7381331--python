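# Methods

This note documents the model implemented in `lexinaming`: its scientific
assumptions, the numerical choices behind the implementation, the synthetic
lexicon that stands in for a naming-test vocabulary, and the limits of what
desk-scale simulations can show.

## The model in brief

The package implements a three-level mental lexicon (concepts, lemmas,
phonological word forms) and the working-memory circuitry needed to run a
picture-naming test on it. Every lexical item is a *semantic pointer*: a
random unit vector in D dimensions (D = 64 at full scale, 16–32 in tests).
Similarity between items is the dot product of their pointers. Relatedness
is built in geometrically: a derived pointer is a normalized mixture
`sqrt(1 − w²)·u + w·p̄` of fresh noise `u` and the mean `p̄` of its parent
pointers, so that a child resembles a single parent with expected similarity
`w` (default 0.7) and two children of the same parent resemble each other at
`w²` (0.49). Within-level "assoc_with" relations connect a surface network
(nameable items) to a deep network (category units at the concept level;
onsets and shared syllables at the phonological level).

Vectors are represented by populations of leaky integrate-and-fire (LIF)
neurons following the standard encoding/decoding account: each buffer is an
array of scalar ensembles (one per vector dimension, 50 neurons each, ±1
encoders, random maximum rates and intercepts), and the value carried by an
ensemble is read out with ridge-regularized least-squares decoders over the
neuron tuning curves. Buffers are connected through *associative memories*:
banks of thresholded channels, one per prototype pair, that compute the dot
product of the incoming vector with an input prototype, rectify it above a
threshold, and emit the paired output prototype. Winner-take-all variants
(cleanup memories) add mutual inhibition between channels so that only the
best-matching prototype survives; they are used where a noisy mixture must
be resolved into a single clean item.

## Architecture

The naming model wires 22 named buffers and 26 associative memories (4 of
them cleanups):

* **Perception**: `visual_in → concept_visual → concept_perc` and
  `audio_in → phono_audio → word_audio → concept_audio → concept_perc`,
  ending in a cleanup into `concept_in`.
* **Cognitive routing**: from `concept_in`, gates select the
  straight-through route (nouns/verbs), the antonym route
  (`oppo_in → oppo_out`), or the superordinate route
  (`super_in → super_out`); all re-converge on `concept_out`.
* **Cue path**: while cues are processed, auditory input is routed (by a
  gate) away from the straight perception route and into
  `s_cue_in`/`p_cue_in → cue_out`, which adds a *subordinate* extra input
  into `concept_out`. A heard semantic cue word is translated to its deep
  category pointer, so the boost aligns with the target's whole semantic
  neighbourhood instead of competing as a word of its own; a phonological
  cue is the deep onset unit of the target's word form, mapped to the
  normalized sum of all concepts whose forms share that onset. The onset
  gate responds only to onset tokens themselves (threshold 0.85), not to
  whole word forms, which sit near 0.7 similarity to their onset unit.
* **Production**: `concept_out → concept_prod → (cleanup) → word_prod →
  (lemma-to-form memory) → phono_prod`. The model's answer is read from
  `phono_prod`.
* **Task control**: control pointers in `input_control` drive a
  winner-take-all over action utilities (dot products with the trigger
  pointers of each rule); the winning action opens exactly one gate
  configuration and is echoed into `action_control`. At full scale the
  action-selection module is sized at 42 basal-ganglia and 8 thalamus
  ensembles of 50 neurons (2100/400 neurons).

The census convention counts one gating ensemble per buffer in addition to
the per-dimension state ensembles, giving (D + 1) × 50 = 3250 neurons per
buffer at D = 64, 71 500 over 22 buffers, and — with associative memories at
twice a buffer — 169 000 over the 26 memories. The built (reduced-scale)
network allocates the same memory budget across each memory's prototype
channels, so `network.summary()` reports the actual allocation while
`model_census()` reports the configuration contract.

## Dynamics and numerical choices

* LIF constants: membrane time constant 20 ms, refractory period 2 ms,
  maximum rates uniform 200–400 Hz, intercepts uniform (−1, 1), dt = 1 ms.
  The spiking backend integrates the membrane equation exactly over each
  step with sub-step refractory handling; the direct backend evaluates the
  same graph as deterministic functions (per-dimension saturation for
  buffers, the channel rectifier for memories) and falls back to masked
  rate-curve decoding for ablated components, so silencing a neuron removes
  its decoder contribution identically in both backends.
* Synapses: 10 ms feedforward, 30 ms for fast relay recurrence, 100 ms for
  working-memory feedback.
* Buffers: relays carry feedback 0.3 (fast, DC gain one); route memories
  (`concept_through`, `oppo_out`, `super_out`, `cue_out`) carry feedback
  0.95 and retain their content across the cue phase; production buffers
  carry feedback 0.9 but their feedback loop is *gated by the SPEAK
  action*, so they integrate evidence only while the model speaks and drain
  between answer windows. This makes the time-extension control (RwT)
  approximately neutral: a second answer window restarts from the same
  retained inputs instead of double-charging the output buffers.
* Associative memories: identity/relay memories use threshold 0.6 with a
  linear rise of width 0.35 and an output ceiling of 4 (linear well past
  unit amplitude, so relative evidence is preserved rather than clipped);
  mapping memories (lemma→form, antonym, superordinate, onset→concepts) use
  threshold 0.3, rise 0.7, ceiling 3; cleanups use threshold 0.3, rise 0.3,
  ceiling 1.3 with lateral inhibition 1.2, which restores the winner to a
  fixed amplitude and suppresses the rest. The word-selection cleanup
  (`concept_prod → word_prod`) is the exception: it keeps the lateral
  competition but passes amplitude grading (rise 0.8, ceiling 2), so that
  concept-level boosts — cues in particular — can still raise the drive
  reaching the lower production levels. Identity memories additionally
  carry weak lateral inhibition (0.1) that subtracts a common baseline and
  sharpens ratios at any amplitude. The many-to-one superordinate map
  scales its output by 0.5 because several exemplar channels are co-active.
* Representation radius: per-dimension range 2.5/√D, wide enough for the
  components of mixtures of a few pointers, narrow enough that runaway
  growth saturates.
* Within-level spreading (the dashed lexicon-access links) is implemented
  as weak self-memories over the concept and phonological vocabularies
  (gain 0.02, threshold 0.8, ceiling 0.5); stronger settings destabilize
  the phonological level into "onset family" attractors.

## Trial protocol and scoring

A trial presents the stimulus during a question phase (0.3 s; four
superordinate exemplars sequentially for 0.2 s each plus a 0.2 s settle
pause, after which all four remain jointly in view as on the test sheet;
pictured targets stay in view until the end of the trial, preceded by
brief scene-object distractors at 0.6 amplitude), then a production phase
(0.5 s)
controlled by `Q_<TASK>` then `PRODUCE_<TASK>` pointers. Cue conditions
append a cue phase (three 0.3 s semantic cue words for RwS, one 0.3 s onset
token for RwP, a 0.9 s silent gap for RwT) and a second production phase
(`CUE`, then `PRODUCE_<TASK>_CUE`). Both production phases are scored: the
candidate (word form or sub-word unit) with the highest time-averaged
similarity in `phono_prod` over the SPEAK window (skipping the first 150 ms
of rise) wins, and the answer is correct when the winner is the target's
form with mean similarity above 0.2. Cue conditions are booked the way the
naming test counts them: the cue round retests what the no-cue round
missed, so an item is correct under a cue condition if either production
phase produced it (`correct_cum` in the run tables); the cue round can add
items but never remove them. Incorrect answers are classified, in
precedence order, as no reaction (nothing above threshold), semantic (the
produced word shares a deep concept with the target), phonological (shares
a deep phonological unit but no deep concept), syllable (a sub-word unit
was produced), or unrelated.

Lesions silence `floor(fraction × n)` seeded-random neurons of one
component for the whole run, at five production-pathway sites: the concept,
lemma, and phonological buffers (a, c, e) and the concept-to-lemma and
lemma-to-form memories (b, d). Ablating a between-level memory samples
uniformly over the memory's full neuron pool.

## The synthetic lexicon

No naming-test vocabulary is publicly available, so the generator builds
one with the same statistical structure: battery targets (pictured nouns
and verbs, superordinates with four exemplars, antonym adjective pairs, in
proportions 26/23/23/23 at full scale) each own a deep-concept parent;
three dedicated semantic cue words share that parent; pictured items carry
3–4 scene-object distractors related to each other through a separate scene
parent (visually co-present but not semantic neighbours of the target);
filler words with 1–2 random parents complete the inventory (1202 surface
concepts, 663 deep concepts, 1202 lemmas, 1110 forms, 1119 deep
phonological units at full scale). Word forms are 1–3 CV syllables over a
SAMPA-like alphabet; forms derive from their onset unit (first sound, or
first two sounds after a plosive or /h/ — the phonological-cue rule) plus a
shared first-syllable unit. Lemmas are independent pointers, mapped
one-to-one between levels.

What the generator does **not** emulate: real orthography/phonology, word
frequency, age-graded acquisition, graded association strengths from
experience, polysemy, and the idiosyncratic picture materials of the real
test. Passing tests therefore show that the *mechanisms* (ablation
dose-response, cue facilitation, error classes) behave as described, not
that the model reproduces any particular child's scores.

## Desk-scale study conditions

All simulation-based tests run a reduced configuration chosen once: pointer
dimension 32 (16 for structure-only checks), 50 neurons per ensemble, a
10-item battery (4/2/2/2) over a ~75-entry lexicon, the direct backend for
experiment grids, and the spiking backend for the headline checks (intact
naming, the forced full lesion, backend agreement). At 16 dimensions a
75-entry vocabulary is too crowded for reliable naming (random pointer
pairs reach similarities near the relatedness level), which is why the
functional tests use 32 dimensions.

Full-scale behavioural numbers (e.g. the published average of 48/95 intact
items) are not reproducible at this scale and are not targeted; the
reduced-scale analogues are the fraction of correctly named items, the
monotone per-location dose-response, and the ordering of cue effects
(phonological and semantic facilitation above the time control).

## Known limitations

* Action selection is computed algorithmically (argmax over rule
  utilities) rather than by a spiking basal-ganglia circuit; the census
  accounts for the full-scale circuit, but gating is exact rather than
  neural.
* The direct backend's function evaluation is an idealisation of the rate
  dynamics; agreement with the spiking backend is itself a tested property
  rather than a guarantee.
* Cue effects at this scale are carried by few items and are sensitive to
  the crowding of the reduced vocabulary. Both cue types add correctly
  named items at moderate ablation and phonological cues outperform the
  pure time-extension control, but semantic-cue facilitation is the most
  fragile of the replicated effects: its advantage over the time control
  is not reliably resolved on a 10-item battery, and naming a semantic
  neighbour of the target (scored as a semantic error) is its typical
  failure mode.
* Homophones (fewer forms than lemmas at full scale) are mapped
  many-to-one; scoring treats any concept with the produced form as that
  form's owner.
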