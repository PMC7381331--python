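# lexinaming

A spiking neural model of the **mental lexicon** and of lexical access in a
picture-naming test, with neuron-ablation lesions and semantic/phonological
cueing.

## The problem

Word-finding difficulties — in children with specific language impairment
as in acquired aphasia — are diagnosed with picture-naming batteries in
which an examiner shows pictures, asks for the word, and offers *semantic*
cues (related words) or *phonological* cues (the first sound of the word)
when naming fails. Which level of the lexical system is damaged, and why
each cue type helps, cannot be decided from behaviour alone. This package
implements a neurocomputational model in which those questions become
experiments: a three-level mental lexicon (concepts → lemmas →
phonological word forms) is encoded in populations of leaky
integrate-and-fire neurons, a naming battery is simulated end to end, and
precisely located lesions (silencing a chosen fraction of neurons in one
buffer or one inter-level memory) are mapped to behavioural deficits and
cue effects.

## The model

Every lexical item is a *semantic pointer* — a D-dimensional unit vector;
similarity is the dot product, and relatedness is built in geometrically:
a pointer derived from parents `P` with weight `w` is
`normalize(sqrt(1 − w²)·u + w·mean(P))`, so related items have expected
similarity `w` (default 0.7) and co-hyponyms `w²`. Vectors are represented
by arrays of scalar LIF ensembles (NEF-style encoders, tuning curves, and
regularized least-squares decoders), connected through thresholded
associative memories (winner-take-all *cleanup* memories where a noisy
mixture must resolve to one item). A task-control module selects actions
(`PROCESS_NOUN`, `SPEAK`, `PROCESS_CUE`, …) by a winner-take-all over the
dot products between control pointers and the current control state, and
opens the matching routing gates.

The naming battery mirrors a standardized word-finding test: 95 items at
full scale (26 pictured nouns, 23 pictured verbs, 23 superordinates probed
with four exemplar pictures, 23 antonym adjectives probed auditorily),
each with three semantic cues and one phonological cue (the first sound of
the word; the first two sounds after a plosive or /h/). A lesion
experiment crosses five dysfunction locations (concept, lemma, and
phonological buffers; concept→lemma and lemma→form memories) with ablation
levels 0–100%, under paired no-cue / cue conditions (RwO, RwS, RwP, and a
time-extension control RwT). Scores are compared against the test's norm
table (mean 39/95, normal range 27–52; below 27 is pathological).

Because no naming-test vocabulary is published, the package generates a
**synthetic lexicon** with the same statistical structure (surface/deep
concept and phonological networks, one-to-one between-level maps, cue
tables); see `docs/methods.md` for what it does and does not emulate.

## Worked example

```python
from lexinaming.lexicon import LexiconSpec, generate_lexicon, build_wwt_battery
from lexinaming.model import ModelConfig, NamingModel
from lexinaming.protocols import run_trial
from lexinaming.network import AblationSpec

spec = LexiconSpec.reduced(n_nouns=4, n_verbs=2, n_superordinates=2,
                           n_antonyms=2, dimension=32, seed=7)
lexicon = generate_lexicon(spec)
battery = build_wwt_battery(lexicon)
model = NamingModel(lexicon, ModelConfig(dimension=32, seed=3, backend="direct"))
sim = model.simulator(seed=3)

item = battery[0]
(intact,) = run_trial(model, item, "RwO", simulator=sim, seed=1)
print(item.target, lexicon.form_of(item.target), intact.correct,
      round(intact.mean_similarity, 2))

lesion = AblationSpec("am_word_phono", 0.8, seed=1)   # location d, 80%
(lesioned,) = run_trial(model, item, "RwO", ablation=lesion,
                        simulator=sim, seed=1)
print(lesioned.correct, lesioned.winner, lesioned.error_class)
```

prints

```
noun000 nu True 0.62
False None no_reaction
```

The intact model names the pictured item `noun000` (word form `nu`) with a
mean output similarity of 0.62 — comfortably above the 0.2 correctness
threshold. After silencing 80% of the lemma-to-phonological memory the
output stays below threshold for every candidate, so the trial scores as a
word-finding failure of the "no reaction" class, exactly the behaviour the
lesion location predicts.

A command-line interface wraps the same machinery
(`lexinaming gen-lexicon`, `lexinaming plan`, `lexinaming census`,
`lexinaming run`, `lexinaming analyze`).

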