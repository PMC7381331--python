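"""Synthetic mental lexicon and naming-test battery generator.

The generator emulates the statistical structure of a three-level mental
lexicon for a picture-naming test:

* a **concept level** with a surface network (nameable concepts) and a deep
  network (category-like units that are not necessarily words), linked by
  ``assoc_with`` relations so that semantically related surface concepts
  share deep parents and therefore have similar pointers;
* a **lemma level** with one independent pointer per concept;
* a **phonological level** with a surface network of syllabified word forms
  and a deep network of sub-word units (onsets and shared syllables), linked
  so that forms sharing an onset have similar pointers;
* one-to-one concept -> lemma -> phonological-form maps between levels.

The battery mirrors the structure of a standardised word-finding test for
children: pictured nouns, pictured verbs, superordinates probed with four
exemplar pictures, and antonym adjectives probed auditorily, in the
proportions 26/23/23/23 at full scale.  Every battery target carries three
single-word semantic cues (assoc_with neighbours of the target) and one
phonological cue (the beginning of its word form).

Word forms are synthetic CV-syllable strings over a SAMPA-like alphabet;
real orthography, word frequency, and age-graded vocabulary growth are out
of scope.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .pointers import SPVocabulary

__all__ = [
    "LexiconSpec",
    "LexEntry",
    "CueSet",
    "WWTItem",
    "SyntheticLexicon",
    "generate_lexicon",
    "derive_phonological_cue",
    "derive_semantic_cues",
    "build_wwt_battery",
    "PLOSIVES",
    "CONSONANTS",
    "VOWELS",
]

PLOSIVES = frozenset("pbtdkg")
CONSONANTS = "pbtdkgfsShmnlr"
VOWELS = "aeiou"


@dataclass(frozen=True)
class LexiconSpec:
    """Size and structure parameters of a generated lexicon.

    The full-scale preset stores 1202 surface concepts, 663 deep concepts,
    1202 lemmata, 1110 surface phonological forms and 1119 deep phonological
    units, with battery category counts 26/23/23/23.
    """

    n_surface_concepts: int = 1202
    n_deep_concepts: int = 663
    n_lemmata: int = 1202
    n_surface_phonos: int = 1110
    n_deep_phonos: int = 1119
    n_nouns: int = 26
    n_verbs: int = 23
    n_superordinates: int = 23
    n_antonyms: int = 23
    distractors_min: int = 3
    distractors_max: int = 4
    parents_min: int = 1
    parents_max: int = 2
    w: float = 0.7
    dimension: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_surface_concepts,
            self.n_deep_concepts,
            self.n_lemmata,
            self.n_surface_phonos,
            self.n_deep_phonos,
            self.n_nouns,
            self.n_verbs,
            self.n_superordinates,
            self.n_antonyms,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all lexicon counts must be positive")
        if self.n_deep_concepts > self.n_surface_concepts:
            raise ValueError("deep concept count must not exceed surface count")
        if self.n_lemmata != self.n_surface_concepts:
            raise ValueError("the lemma level maps one-to-one onto concepts")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "LexiconSpec":
        """The full-scale configuration (no simulation intended)."""
        return cls(seed=seed)

    @classmethod
    def reduced(
        cls,
        n_nouns: int = 4,
        n_verbs: int = 2,
        n_superordinates: int = 2,
        n_antonyms: int = 2,
        dimension: int = 16,
        seed: int = 0,
        w: float = 0.7,
        margin: int = 4,
    ) -> "LexiconSpec":
        """A desk-scale lexicon just large enough for the given battery."""
        need = _entries_needed(n_nouns, n_verbs, n_superordinates, n_antonyms)
        n_surface = need + margin
        n_deep = n_nouns + n_verbs + n_superordinates + n_antonyms + margin
        return cls(
            n_surface_concepts=n_surface,
            n_deep_concepts=n_deep,
            n_lemmata=n_surface,
            n_surface_phonos=n_surface,
            # enough units for every possible onset prefix plus shared syllables
            n_deep_phonos=max(45, n_surface // 2),
            n_nouns=n_nouns,
            n_verbs=n_verbs,
            n_superordinates=n_superordinates,
            n_antonyms=n_antonyms,
            dimension=dimension,
            seed=seed,
            w=w,
        )


def _n_distractors(spec: LexiconSpec, item_index: int) -> int:
    """Distractor count per picture alternates between the min and max."""
    if spec.distractors_min == spec.distractors_max:
        return spec.distractors_min
    return spec.distractors_min + (item_index % 2)


def _entries_needed(n_nouns, n_verbs, n_super, n_ant) -> int:
    targets = n_nouns + n_verbs + n_super + n_ant
    distractors = sum(3 + (i % 2) for i in range(n_nouns + n_verbs))
    return targets + 3 * targets + distractors + 4 * n_super + n_ant


@dataclass(frozen=True)
class CueSet:
    """Three single-word semantic cues plus one phonological cue (a prefix
    of the target's word form)."""

    semantic: tuple[str, str, str]
    phonological: str


@dataclass
class LexEntry:
    """One lexicon entry spanning all three levels."""

    concept: str
    lemma: str
    phono_form: str
    category: str  # noun | verb | adjective | superordinate | other
    deep_parents: tuple[str, ...] = ()
    antonym: "str | None" = None
    exemplars: tuple[str, ...] = ()
    distractors: tuple[str, ...] = ()
    cues: "CueSet | None" = None


@dataclass(frozen=True)
class WWTItem:
    """One battery item: the target plus the stimuli used to elicit it."""

    index: int
    target: str
    category: str
    mode: str  # visual | visual_action | audio_antonym | visual_four
    visual: tuple[str, ...] = ()
    audio: "str | None" = None


_MODE_BY_CATEGORY = {
    "noun": "visual",
    "verb": "visual_action",
    "adjective": "audio_antonym",
    "superordinate": "visual_four",
}


def derive_phonological_cue(phono_form: str) -> str:
    """First sound of a word form; first two sounds if the form starts with
    a plosive (p, b, t, d, k, g) or with /h/.

    Examples: ``fEAze -> "f"``, ``beru:fe -> "be"``, ``hENkel -> "hE"``.
    """
    if not phono_form:
        raise ValueError("empty phonological form")
    first = phono_form[0]
    if first in PLOSIVES or first == "h":
        return phono_form[:2]
    return first


class SyntheticLexicon:
    """A generated lexicon: three pointer vocabularies, the entry table, the
    between-level maps and the battery inventories."""

    def __init__(self, spec: LexiconSpec):
        self.spec = spec
        seeds = np.random.default_rng(spec.seed).integers(2**31, size=4)
        self.concepts = SPVocabulary(spec.dimension, seed=int(seeds[0]))
        self.lemmas = SPVocabulary(spec.dimension, seed=int(seeds[1]))
        self.phonos = SPVocabulary(spec.dimension, seed=int(seeds[2]))
        self._rng = np.random.default_rng(int(seeds[3]))
        self.entries: dict[str, LexEntry] = {}
        self.deep_concepts: list[str] = []
        self.deep_phonos: list[str] = []
        self.surface_forms: list[str] = []
        self.by_category: dict[str, list[str]] = {
            "noun": [],
            "verb": [],
            "superordinate": [],
            "adjective": [],
        }
        self.targets: list[str] = []

    # -- access ----------------------------------------------------------

    def __getitem__(self, concept: str) -> LexEntry:
        return self.entries[concept]

    def __len__(self) -> int:
        return len(self.entries)

    def lemma_of(self, concept: str) -> str:
        return self.entries[concept].lemma

    def form_of(self, concept: str) -> str:
        return self.entries[concept].phono_form

    def concepts_with_prefix(self, prefix: str) -> list[str]:
        """Surface concepts whose word form carries the given cue prefix."""
        return [
            c
            for c, e in self.entries.items()
            if derive_phonological_cue(e.phono_form) == prefix
        ]

    def shares_deep_concept(self, a: str, b: str) -> bool:
        pa = set(self.entries[a].deep_parents)
        return bool(pa & set(self.entries[b].deep_parents))

    def shares_deep_phono(self, a: str, b: str) -> bool:
        fa, fb = self.entries[a].phono_form, self.entries[b].phono_form
        return derive_phonological_cue(fa) == derive_phonological_cue(fb)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "spec": asdict(self.spec),
            "entries": {
                c: {
                    "lemma": e.lemma,
                    "phono_form": e.phono_form,
                    "category": e.category,
                    "deep_parents": list(e.deep_parents),
                    "antonym": e.antonym,
                    "exemplars": list(e.exemplars),
                    "distractors": list(e.distractors),
                    "cues": (
                        None
                        if e.cues is None
                        else {
                            "semantic": list(e.cues.semantic),
                            "phonological": e.cues.phonological,
                        }
                    ),
                }
                for c, e in self.entries.items()
            },
            "deep_concepts": self.deep_concepts,
            "deep_phonos": self.deep_phonos,
            "targets": self.targets,
        }
        return json.dumps(doc)


def _make_forms(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct 1-3 syllable CV forms; onset distribution favours reuse so
    that phonological neighbourhoods (shared onsets) arise."""
    syllables = ["".join(p) for p in itertools.product(CONSONANTS, VOWELS)]
    forms: list[str] = []
    seen = set()
    while len(forms) < n:
        k = int(rng.integers(1, 4))
        f = "".join(syllables[int(rng.integers(len(syllables)))] for _ in range(k))
        if f not in seen:
            seen.add(f)
            forms.append(f)
    return forms


def generate_lexicon(spec: LexiconSpec) -> SyntheticLexicon:
    """Generate a seeded synthetic lexicon per the given spec.

    Deep pointers are created first; every surface concept derives from one
    or two deep parents; phonological forms derive from their onset unit
    (plus a shared first-syllable unit where one exists); lemma pointers are
    independent; between-level maps are one-to-one by construction.
    """
    lex = SyntheticLexicon(spec)
    w = spec.w
    n_targets = spec.n_nouns + spec.n_verbs + spec.n_superordinates + spec.n_antonyms
    needed = _entries_needed(
        spec.n_nouns, spec.n_verbs, spec.n_superordinates, spec.n_antonyms
    )
    if needed > spec.n_surface_concepts:
        raise ValueError(
            f"infeasible spec: the battery requires {needed} surface concepts "
            f"but only {spec.n_surface_concepts} were requested"
        )
    if n_targets > spec.n_deep_concepts:
        raise ValueError(
            f"infeasible spec: {n_targets} battery targets need at least as "
            f"many deep concepts, got {spec.n_deep_concepts}"
        )

    # --- deep concept network -------------------------------------------
    for i in range(spec.n_deep_concepts):
        lb = f"deep{i:04d}"
        lex.concepts.create(lb)
        lex.deep_concepts.append(lb)

    # --- phonological level ----------------------------------------------
    forms = _make_forms(lex._rng, spec.n_surface_phonos)
    lex.surface_forms = forms
    prefixes = sorted({derive_phonological_cue(f) for f in forms})
    # extra sub-clustering by first syllable where the cue prefix is shorter
    first_syls = sorted({f[:2] for f in forms if derive_phonological_cue(f) != f[:2]})
    if spec.n_deep_phonos < len(prefixes):
        raise ValueError(
            f"infeasible spec: {len(prefixes)} onset units required but only "
            f"{spec.n_deep_phonos} deep phonological units requested"
        )
    for p in prefixes:
        lex.phonos.create(f"on:{p}")
        lex.deep_phonos.append(f"on:{p}")
    for s in first_syls:
        if len(lex.deep_phonos) >= spec.n_deep_phonos:
            break
        lex.phonos.create(f"syl:{s}")
        lex.deep_phonos.append(f"syl:{s}")
    i = 0
    while len(lex.deep_phonos) < spec.n_deep_phonos:
        lb = f"sub{i:04d}"
        lex.phonos.create(lb)
        lex.deep_phonos.append(lb)
        i += 1
    for f in forms:
        prefix = derive_phonological_cue(f)
        parents = [f"on:{prefix}"]
        syl = f"syl:{f[:2]}"
        if prefix != f[:2] and syl in lex.phonos:
            parents.append(syl)
        lex.phonos.derive(f, parents, w)

    # --- surface concepts, lemmas, maps ----------------------------------
    parent_cycle = itertools.cycle(range(spec.n_deep_concepts))

    def add_entry(label: str, category: str, parents: "list[str]", weight=w):
        idx = len(lex.entries)
        if idx >= spec.n_surface_concepts:
            raise ValueError("surface concept budget exhausted")
        lex.concepts.derive(label, parents, weight)
        lex.lemmas.create(label)
        form = forms[idx % spec.n_surface_phonos]
        entry = LexEntry(
            concept=label,
            lemma=label,
            phono_form=form,
            category=category,
            deep_parents=tuple(parents),
        )
        lex.entries[label] = entry
        if category in lex.by_category:
            lex.by_category[category].append(label)
        return entry

    def fresh_parent() -> str:
        return lex.deep_concepts[next(parent_cycle)]

    # battery targets with their cue words, distractors, exemplars, antonyms
    cats = (
        [("noun", i) for i in range(spec.n_nouns)]
        + [("verb", i) for i in range(spec.n_verbs)]
        + [("superordinate", i) for i in range(spec.n_superordinates)]
        + [("adjective", i) for i in range(spec.n_antonyms)]
    )
    pictured = 0
    for cat, i in cats:
        home = fresh_parent()
        label = f"{cat[:5]}{i:03d}"
        entry = add_entry(label, cat, [home])
        lex.targets.append(label)
        # three semantic cue words: assoc_with neighbours via the home parent
        for k in range(1, 4):
            add_entry(f"{label}_cue{k}", "other", [home])
        if cat in ("noun", "verb"):
            # visually co-present scene objects: related to each other
            # through a scene context, not to the target's semantic cluster
            scene = fresh_parent()
            nd = _n_distractors(spec, pictured)
            pictured += 1
            dlabels = []
            for k in range(1, nd + 1):
                add_entry(f"{label}_vis{k}", "other", [scene])
                dlabels.append(f"{label}_vis{k}")
            entry.distractors = tuple(dlabels)
        elif cat == "superordinate":
            ex = []
            for k in range(1, 5):
                add_entry(f"{label}_ex{k}", "other", [home])
                ex.append(f"{label}_ex{k}")
            entry.exemplars = tuple(ex)
        elif cat == "adjective":
            opp = add_entry(f"{label}_opp", "other", [home])
            entry.antonym = opp.concept
            opp.antonym = label

    # filler vocabulary up to the requested size
    n_fill = spec.n_surface_concepts - len(lex.entries)
    for j in range(n_fill):
        k = spec.parents_min + int(
            lex._rng.integers(spec.parents_max - spec.parents_min + 1)
        )
        parents = list(
            lex._rng.choice(lex.deep_concepts, size=min(k, len(lex.deep_concepts)),
                            replace=False)
        )
        add_entry(f"word{j:04d}", "other", parents)

    # attach cue sets to battery targets
    for label in lex.targets:
        lex.entries[label].cues = derive_semantic_cues(lex.entries[label], lex)

    assert len(lex.entries) == spec.n_surface_concepts
    return lex


def derive_semantic_cues(entry: LexEntry, lexicon: SyntheticLexicon) -> CueSet:
    """The target's three semantic cue words plus its phonological cue.

    Semantic cues are the three lowest-index surface ``assoc_with``
    neighbours of the target (the generator registers the dedicated cue
    words first, so they are picked deterministically).
    """
    neighbors = [
        lb
        for lb in lexicon.concepts.neighbors(entry.concept)
        if lb in lexicon.entries and lb != entry.concept
    ]
    # neighbours through shared deep parents, in registration order
    shared = [
        lb
        for lb in lexicon.entries
        if lb != entry.concept
        and set(lexicon.entries[lb].deep_parents) & set(entry.deep_parents)
    ]
    ordered = neighbors + [lb for lb in shared if lb not in neighbors]
    if len(ordered) < 3:
        raise ValueError(
            f"entry {entry.concept!r} has fewer than 3 assoc_with neighbours"
        )
    return CueSet(
        semantic=tuple(ordered[:3]),
        phonological=derive_phonological_cue(entry.phono_form),
    )


def build_wwt_battery(
    lexicon: SyntheticLexicon, spec: "LexiconSpec | None" = None
) -> list[WWTItem]:
    """The ordered naming battery: nouns, verbs, superordinates, antonyms.

    At full scale this yields 95 items with category counts 26/23/23/23;
    reduced lexicons preserve whatever counts their spec requests.
    """
    spec = lexicon.spec if spec is None else spec
    wanted = [
        ("noun", spec.n_nouns),
        ("verb", spec.n_verbs),
        ("superordinate", spec.n_superordinates),
        ("adjective", spec.n_antonyms),
    ]
    items: list[WWTItem] = []
    for cat, n in wanted:
        have = lexicon.by_category[cat]
        if len(have) < n:
            raise ValueError(
                f"insufficient {cat} inventory: need {n}, lexicon has {len(have)}"
            )
        for label in have[:n]:
            entry = lexicon.entries[label]
            mode = _MODE_BY_CATEGORY[cat]
            if cat in ("noun", "verb"):
                visual = entry.distractors + (label,)
                audio = None
            elif cat == "superordinate":
                visual = entry.exemplars
                audio = None
            else:
                visual = ()
                audio = entry.antonym
            items.append(
                WWTItem(
                    index=len(items),
                    target=label,
                    category=cat,
                    mode=mode,
                    visual=visual,
                    audio=audio,
                )
            )
    return items


def battery_to_frame(items: list[WWTItem], lexicon: SyntheticLexicon):
    """Battery as a tidy table (item id, category, target, stimuli, cues)."""
    import pandas as pd

    rows = []
    for it in items:
        cues = lexicon.entries[it.target].cues
        rows.append(
            {
                "item": it.index,
                "category": it.category,
                "target": it.target,
                "mode": it.mode,
                "visual": "|".join(it.visual),
                "audio": it.audio or "",
                "semantic_cues": "|".join(cues.semantic) if cues else "",
                "phonological_cue": cues.phonological if cues else "",
            }
        )
    return pd.DataFrame(rows)
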