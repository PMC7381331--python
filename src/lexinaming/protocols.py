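"""Naming-experiment protocols: trial execution, scoring, error
classification, and the lesion-grid experiment runner.

An experiment enumerates cells over dysfunction locations (a-e), ablation
levels (0-100% in steps of 10 by default), battery items, and condition
families.  Each family pairs a no-cue baseline with its manipulation in
one simulation, mirroring the test procedure in which a cue round for an
item directly follows the no-cue round:

* ``semantic``      - RwO baseline phase + RwS (three auditory word cues)
* ``phonological``  - RwO baseline phase + RwP (one auditory onset cue)
* ``control``       - RwO baseline phase + RwT (time extension, no cue)

A trial is scored from the similarity trace of the ``phono_prod`` buffer:
within each SPEAK window the candidate with the highest time-averaged
similarity wins, and the answer is correct when the winner is the target's
word form with mean similarity above the evaluation threshold (0.2).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lexicon import WWTItem
from .model import DYSFUNCTION_SITES, NamingModel
from .network import AblationSpec, SimilarityTrace

__all__ = [
    "ExperimentPlan",
    "TrialResult",
    "RunTable",
    "enumerate_plan",
    "evaluate_trial",
    "classify_error",
    "run_trial",
    "run_experiment",
    "FAMILIES",
    "cell_seed",
]

FAMILIES = {
    "baseline": "RwO",
    "semantic": "RwS",
    "phonological": "RwP",
    "control": "RwT",
}

ERROR_CLASSES = (
    "no_reaction",
    "semantic",
    "phonological",
    "syllable",
    "unrelated",
    "none",
)


@dataclass(frozen=True)
class ExperimentPlan:
    """The full factorial grid of one lesion experiment."""

    locations: tuple[str, ...] = ("a", "b", "c", "d", "e")
    levels: tuple[int, ...] = tuple(range(0, 101, 10))  # ablation percentages
    n_items: "int | None" = None  # None = whole battery
    families: tuple[str, ...] = ("semantic", "phonological", "control")
    seeds_per_cell: int = 1

    def __post_init__(self) -> None:
        for loc in self.locations:
            if loc not in DYSFUNCTION_SITES:
                raise ValueError(f"unknown dysfunction location {loc!r}")
        for lv in self.levels:
            if not 0 <= lv <= 100:
                raise ValueError(f"ablation level {lv} outside [0, 100]")
        for fam in self.families:
            if fam not in FAMILIES:
                raise ValueError(f"unknown condition family {fam!r}")


@dataclass(frozen=True)
class Cell:
    location: str
    level: int
    family: str
    item_index: int


@dataclass
class TrialResult:
    item: str
    category: str
    condition: str
    location: str
    level: int
    phase: str  # "RwO" or the cue condition of the family
    correct: bool
    winner: "str | None"
    winner_concept: "str | None"
    peak_similarity: float
    mean_similarity: float
    error_class: str
    seed: int

    def __post_init__(self) -> None:
        if self.correct and self.error_class != "none":
            raise ValueError("a correct trial carries no error class")
        if self.winner is None and not self.correct:
            assert self.error_class == "no_reaction"


def enumerate_plan(plan: ExperimentPlan, battery: list[WWTItem]) -> list[Cell]:
    """Deterministic cell order: location, level, family, item."""
    if not battery:
        raise ValueError("empty battery")
    n = len(battery) if plan.n_items is None else min(plan.n_items, len(battery))
    return [
        Cell(loc, lv, fam, i)
        for loc in plan.locations
        for lv in plan.levels
        for fam in plan.families
        for i in range(n)
    ]


def plan_size(plan: ExperimentPlan, battery_size: int) -> int:
    n = battery_size if plan.n_items is None else min(plan.n_items, battery_size)
    return len(plan.locations) * len(plan.levels) * len(plan.families) * n


def cell_seed(base_seed: int, location: str, level: int, family: str, item: int) -> int:
    """Stable per-cell seed below 2^31, independent of enumeration order."""
    key = f"{base_seed}|{location}|{level}|{family}|{item}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def evaluate_trial(
    trace: SimilarityTrace,
    target_label: str,
    window: tuple[float, float],
    threshold: float = 0.2,
) -> tuple[bool, "str | None", float, float]:
    """Score one SPEAK window of a similarity trace.

    The winner is the label with the highest time-averaged similarity over
    the window; the answer is correct when the winner is the target and its
    mean similarity exceeds the threshold.  Returns
    ``(correct, winner, mean, peak)``.
    """
    t0, t1 = window
    mask = (trace.time >= t0) & (trace.time < t1)
    if not mask.any():
        raise ValueError(f"empty evaluation window {window}")
    means = trace.values[mask].mean(axis=0)
    best = int(np.argmax(means))
    peak = float(trace.values[mask].max()) if mask.any() else 0.0
    if means[best] <= threshold:
        return False, None, float(means[best]), peak
    winner = trace.labels[best]
    return winner == target_label, winner, float(means[best]), peak


def classify_error(winner_concept, target, lexicon, winner_label=None) -> str:
    """Error taxonomy for an incorrect answer.

    Precedence: no reaction (no output above threshold), semantic (the
    produced word shares a deep concept with the target), phonological
    (shares a deep phonological unit but no deep concept), syllable (the
    output is a sub-word unit rather than a word form), unrelated.
    """
    if winner_concept is None and winner_label is None:
        return "no_reaction"
    if winner_concept is not None:
        if winner_concept not in lexicon.entries:
            raise KeyError(f"winner {winner_concept!r} not in lexicon")
        if lexicon.shares_deep_concept(winner_concept, target):
            return "semantic"
        if lexicon.shares_deep_phono(winner_concept, target):
            return "phonological"
        return "unrelated"
    # an output label with no owning concept is a sub-word unit
    return "syllable"


def _result_from_window(
    model: NamingModel, trace, window, item, condition, phase, location, level, seed
) -> TrialResult:
    lex = model.lexicon
    target_form = lex.form_of(item.target)
    correct, winner, mean_sim, peak = evaluate_trial(
        trace, target_form, window, model.config.eval_threshold
    )
    winner_concept = None
    if winner is not None:
        owners = [c for c in lex.entries if lex.form_of(c) == winner]
        winner_concept = owners[0] if owners else None
    if correct:
        err = "none"
    else:
        err = classify_error(
            winner_concept if winner is not None else None,
            item.target,
            lex,
            winner_label=winner,
        )
    return TrialResult(
        item=item.target,
        category=item.category,
        condition=condition,
        location=location,
        level=level,
        phase=phase,
        correct=bool(correct),
        winner=winner,
        winner_concept=winner_concept,
        peak_similarity=peak,
        mean_similarity=mean_sim,
        error_class=err,
        seed=seed,
    )


def run_trial(
    model: NamingModel,
    item: WWTItem,
    condition: str,
    ablation: "AblationSpec | None" = None,
    seed: int = 0,
    backend: "str | None" = None,
    simulator=None,
) -> list[TrialResult]:
    """Run one item under one condition, optionally lesioned.

    For cue conditions the paired no-cue phase runs first in the same
    simulation and both phases are scored; the returned list holds one
    result per SPEAK window.  Passing a prebuilt ``simulator`` (matching
    the model and backend) avoids recompiling the network per trial.
    """
    sched = model.schedule_trial(item, condition)
    sim = simulator or model.simulator(backend=backend, seed=seed)
    sim.reset()
    sim.time = 0.0
    sim.clear_ablations()
    location, level = "-", 0
    if ablation is not None:
        sim.ablate(ablation)
        location = {v: k for k, v in DYSFUNCTION_SITES.items()}.get(
            ablation.target, ablation.target
        )
        level = int(round(ablation.fraction * 100))
    out = sim.run(
        sched.duration,
        events=sched.events,
        controller=model.controller,
        probes=["phono_prod"],
    )
    times, values = out["phono_prod"]
    if not np.isfinite(values).all():
        raise FloatingPointError(
            f"simulation diverged (item {item.target}, condition {condition})"
        )
    trace = sim.similarity_trace(
        "phono_prod", times, values, model.lexicon.phonos, model.output_labels
    )
    phases = ["RwO"] if condition == "RwO" else ["RwO", condition]
    return [
        _result_from_window(
            model, trace, win, item, condition, phase, location, level, seed
        )
        for phase, win in zip(phases, sched.speak_windows)
    ]


@dataclass
class RunTable:
    """Aggregated correct counts per (location, level, phase)."""

    results: pd.DataFrame

    @classmethod
    def from_results(cls, results: "list[TrialResult] | pd.DataFrame") -> "RunTable":
        if isinstance(results, pd.DataFrame):
            df = results.copy()
        else:
            df = pd.DataFrame([r.__dict__ for r in results])
        return cls(df)

    def counts(self, cumulative: bool = True) -> pd.DataFrame:
        """Tidy count table: one row per (location, level, condition).

        With ``cumulative`` (the default, matching the test procedure) a cue
        condition counts an item as correct if it was named in the no-cue
        round or in the cue round; otherwise each scored phase is counted
        on its own.
        """
        base = (
            self.results[self.results.phase == "RwO"]
            .groupby(["location", "level"])["correct"]
            .sum()
            .reset_index()
            .assign(condition="RwO")
        )
        cue = self.results[self.results.phase != "RwO"]
        if cumulative and len(cue):
            p = self.paired()
            cue_counts = (
                p.groupby(["location", "level", "condition"])["correct_cum"]
                .sum()
                .reset_index()
                .rename(columns={"correct_cum": "correct"})
            )
        else:
            cue_counts = (
                cue.groupby(["location", "level", "phase"])["correct"]
                .sum()
                .reset_index()
                .rename(columns={"phase": "condition"})
            )
        g = pd.concat([base, cue_counts], ignore_index=True)
        g["correct"] = g["correct"].astype(float)
        return g[["location", "level", "condition", "correct"]]

    def paired(self) -> pd.DataFrame:
        """Per-item paired outcomes: RwO phase vs cue phase of one family.

        The column ``correct_cum`` scores the cue condition the way the
        naming test books it: an item already named correctly in the no-cue
        round stays correct; the cue round can only add items.
        """
        cue = self.results[self.results.phase != "RwO"]
        base = self.results[self.results.phase == "RwO"]
        merged = cue.merge(
            base,
            on=["item", "condition", "location", "level", "seed"],
            suffixes=("_cue", "_rwo"),
        )
        merged["correct_cum"] = merged.correct_cue | merged.correct_rwo
        return merged

    def cue_effects(self) -> pd.DataFrame:
        """Cumulative cue-effect differences per (location, level,
        condition): mean over items of (cue-round score - no-cue score)."""
        p = self.paired()
        if not len(p):
            return pd.DataFrame(
                columns=["location", "level", "condition", "difference"]
            )
        p = p.assign(
            difference=p.correct_cum.astype(float) - p.correct_rwo.astype(float)
        )
        return (
            p.groupby(["location", "level", "condition"])["difference"]
            .mean()
            .reset_index()
        )

    def error_counts(self) -> pd.DataFrame:
        wrong = self.results[~self.results.correct]
        return (
            wrong.groupby("error_class")
            .size()
            .reindex(ERROR_CLASSES, fill_value=0)
            .rename("count")
            .reset_index()
        )


def run_experiment(
    plan: ExperimentPlan,
    model: NamingModel,
    battery: list[WWTItem],
    base_seed: int = 0,
    backend: "str | None" = None,
    out_path: "str | Path | None" = None,
    progress: bool = False,
) -> RunTable:
    """Execute every cell of the plan, streaming results to CSV if asked.

    Each cell gets an independent, reproducible seed derived from the base
    seed and the cell coordinates.  With ``out_path`` set, partial results
    on disk are reused (resumable runs): completed cells are skipped.
    """
    cells = enumerate_plan(plan, battery)
    out_file = Path(out_path) if out_path else None
    done: set = set()
    prior: "pd.DataFrame | None" = None
    if out_file is not None:
        if out_file.parent and not out_file.parent.exists():
            raise ValueError(f"output directory {out_file.parent} does not exist")
        if out_file.exists():
            prior = pd.read_csv(out_file)
            done = {
                (r.location, r.level, r.condition, r.item)
                for r in prior.itertuples()
            }

    sim = model.simulator(backend=backend, seed=model.config.seed)
    rows: list[TrialResult] = []
    inverse_sites = DYSFUNCTION_SITES
    for k, cell in enumerate(cells):
        item = battery[cell.item_index]
        condition = FAMILIES[cell.family]
        key = (cell.location, cell.level, condition, item.target)
        if key in done:
            continue
        seed = cell_seed(base_seed, cell.location, cell.level, cell.family,
                         cell.item_index)
        spec = AblationSpec(
            target=inverse_sites[cell.location],
            fraction=cell.level / 100.0,
            seed=seed,
        )
        res = run_trial(
            model, item, condition, ablation=spec, seed=seed, simulator=sim
        )
        rows.extend(res)
        if progress and (k % 10 == 0):
            print(f"[{k + 1}/{len(cells)}] {cell}", flush=True)
        if out_file is not None:
            chunk = pd.DataFrame([r.__dict__ for r in res])
            chunk.to_csv(
                out_file,
                mode="a",
                header=not out_file.exists(),
                index=False,
            )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if prior is not None and len(prior):
        df = pd.concat([prior, df], ignore_index=True)
    return RunTable.from_results(df)
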