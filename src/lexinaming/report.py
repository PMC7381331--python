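"""Report generation: tabular summaries of an experiment run.

Writes plain CSV/JSON artifacts: the correct-vs-ablation curves per
location and condition, the cue-effect difference curves, a per-location
summary (mean +/- SD of the differences over ablation levels), a JSON
stats summary, and a short plain-text narrative including the norm
classification of the unlesioned model.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import NormTable, StatsResult, build_diff_table, classify_against_norms

__all__ = ["write_report"]


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def write_report(
    run_table,
    out_dir: "str | Path",
    stats: "list[StatsResult] | None" = None,
    norms: "NormTable | None" = None,
    battery_size: "int | None" = None,
) -> dict:
    """Emit the report files into ``out_dir``; returns the file map."""
    out = Path(out_dir)
    if not out.parent.exists():
        raise ValueError(f"unwritable output path: parent {out.parent} missing")
    out.mkdir(parents=True, exist_ok=True)
    norms = norms or NormTable()
    stats = stats or []

    counts = run_table.counts()
    counts_path = out / "correct_counts.csv"
    counts.to_csv(counts_path, index=False, float_format="%.3f")

    files = {"correct_counts": str(counts_path)}

    has_pairs = (counts.condition != "RwO").any()
    if has_pairs:
        diff = build_diff_table(counts)
        diff_path = out / "cue_differences.csv"
        diff.to_csv(diff_path, index=False, float_format="%.3f")
        summary_path = out / "cue_summary.csv"
        diff.attrs["summary"].to_csv(summary_path, index=False, float_format="%.3f")
        files["cue_differences"] = str(diff_path)
        files["cue_summary"] = str(summary_path)

    stats_doc = [
        {
            "test": s.test,
            "statistic": s.statistic,
            "p_value": s.p_value,
            "alpha": s.alpha,
            "significant": s.significant,
            "degenerate": s.degenerate,
            "detail": s.detail,
        }
        for s in stats
    ]
    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(stats_doc, indent=2, sort_keys=True))
    files["stats"] = str(stats_path)

    # narrative with the norm classification of the intact model
    lines = ["Naming experiment summary", "=" * 25, ""]
    base = counts[(counts.condition == "RwO") & (counts.level == 0)]
    if len(base):
        intact = float(base["correct"].mean())
        n_items = battery_size or int(run_table.results.groupby("item").ngroups)
        scaled = intact * norms.battery_size / max(n_items, 1)
        verdict = classify_against_norms(
            int(round(min(scaled, norms.battery_size))), norms
        )
        lines.append(
            f"Intact model (0% ablation): {_fmt(intact)} of {n_items} items "
            f"correct per run; scaled to the {norms.battery_size}-item battery "
            f"this corresponds to {scaled:.1f} items, assessed as "
            f"'{verdict}' against the {norms.age_band} norms "
            f"(cutoff {norms.cutoff})."
        )
    for s in stats_doc:
        flag = "significant" if s["significant"] else "not significant"
        lines.append(
            f"{s['test']}: statistic={_fmt(s['statistic'])}, "
            f"p={_fmt(s['p_value'])} ({flag} at alpha={s['alpha']})"
        )
    narrative = out / "summary.txt"
    narrative.write_text("\n".join(lines) + "\n")
    files["summary"] = str(narrative)
    return files
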