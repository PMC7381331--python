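"""Nonparametric tests, norm-based classification, and summary tables for
naming-experiment run tables.

The statistical toolkit mirrors what is conventional for naming-test
analyses: Mann-Whitney U for independent comparisons between dysfunction
conditions, the Wilcoxon signed-rank test for paired no-cue/cue score
differences, and a two-factor ANOVA (cue type x dysfunction location) on
the difference values.  The nonparametric tests switch to exact
enumeration of the null distribution at small sample sizes, where the
normal approximation is unreliable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "NormTable",
    "StatsResult",
    "classify_against_norms",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "two_way_anova",
    "build_diff_table",
]


@dataclass(frozen=True)
class NormTable:
    """Reference statistics of the naming test for one age band.

    Defaults are the norms for the youngest band (5;6-6;5): mean 39 of 95
    items, normal range 27-52 (mean +/- 1 SD), observed maximum 76; scores
    below the cutoff of 27 are assessed as pathological.
    """

    age_band: str = "5;6-6;5"
    mean_correct: int = 39
    normal_low: int = 27
    normal_high: int = 52
    maximum: int = 76
    battery_size: int = 95

    def __post_init__(self) -> None:
        ok = (
            self.normal_low
            <= self.mean_correct
            <= self.normal_high
            <= self.maximum
            <= self.battery_size
        )
        if not ok:
            raise ValueError("norm table must satisfy low <= mean <= high <= max <= N")

    @property
    def cutoff(self) -> int:
        return self.normal_low


@dataclass
class StatsResult:
    test: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    degenerate: bool = False
    detail: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < self.alpha


def classify_against_norms(
    correct_count: int, norms: "NormTable | None" = None
) -> str:
    """``pathological`` below the cutoff, ``normal`` within one SD of the
    mean, ``above_average`` beyond the upper bound."""
    norms = norms or NormTable()
    if not 0 <= correct_count <= norms.battery_size:
        raise ValueError(
            f"correct count {correct_count} outside [0, {norms.battery_size}]"
        )
    if correct_count < norms.cutoff:
        return "pathological"
    if correct_count <= norms.normal_high:
        return "normal"
    return "above_average"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: number of (a, b) pairs with a > b, ties counting 1/2."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(
    group_a, group_b, exact_max_n: int = 8
) -> StatsResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration of all group assignments when both groups have
    at most ``exact_max_n`` observations (valid with ties), and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = a.size, b.size
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return StatsResult("mann-whitney-u", u, 1.0, degenerate=True)

    mid = n * m / 2.0
    if n <= exact_max_n and m <= exact_max_n:
        # enumerate all C(n+m, n) assignments of the pooled values
        idx = np.arange(n + m)
        count = 0
        total = 0
        obs_dev = abs(u - mid) - 1e-12
        for comb in itertools.combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mid) >= obs_dev:
                count += 1
        p = count / total
        method = "exact"
    else:
        ranks = rankdata(pooled)
        _, tie_counts = np.unique(pooled, return_counts=True)
        nm = n + m
        tie_term = np.sum(tie_counts**3 - tie_counts) / (nm * (nm - 1))
        sigma = np.sqrt(n * m / 12.0 * (nm + 1 - tie_term))
        z = (u - mid) / sigma
        from scipy.stats import norm as _norm

        p = float(2.0 * _norm.sf(abs(z)))
        method = "normal"
    return StatsResult(
        "mann-whitney-u", u, min(1.0, p), detail={"n": n, "m": m, "method": method}
    )


def wilcoxon_signed_rank(paired_diffs, exact_max_n: int = 12) -> StatsResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; the null distribution is enumerated over
    all 2^n sign patterns when n <= ``exact_max_n``, otherwise the normal
    approximation with tie correction is used.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return StatsResult("wilcoxon-signed-rank", 0.0, 1.0, degenerate=True)
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= exact_max_n:
        obs_dev = abs(w_plus - mu) - 1e-12
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            if abs(w - mu) >= obs_dev:
                count += 1
        p = count / 2.0**n
        method = "exact"
    else:
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        sigma = np.sqrt(
            n * (n + 1) * (2 * n + 1) / 24.0
            - np.sum(tie_counts**3 - tie_counts) / 48.0
        )
        from scipy.stats import norm as _norm

        z = (w_plus - mu) / sigma
        p = float(2.0 * _norm.sf(abs(z)))
        method = "normal"
    return StatsResult(
        "wilcoxon-signed-rank",
        w_plus,
        min(1.0, p),
        detail={"n": n, "method": method},
    )


def two_way_anova(
    differences, factor_cue, factor_location
) -> list[StatsResult]:
    """Two-factor ANOVA on cue-effect differences.

    Factors are the cue type (semantic vs phonological) and the dysfunction
    location (a-e); type-II sums of squares on the (near-)balanced design.
    Returns results for both main effects and the interaction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "diff": np.asarray(differences, dtype=float),
            "cue": pd.Categorical(factor_cue),
            "location": pd.Categorical(factor_location),
        }
    )
    counts = df.groupby(["cue", "location"], observed=True).size()
    expected = len(df.cue.cat.categories) * len(df.location.cat.categories)
    if len(counts) < expected or (counts == 0).any():
        missing = [
            (c, l)
            for c in df.cue.cat.categories
            for l in df.location.cat.categories
            if (c, l) not in counts.index
        ]
        raise ValueError(f"empty design cells: {missing}")
    model = smf.ols("diff ~ C(cue) * C(location)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = []
    names = {
        "C(cue)": "cue",
        "C(location)": "location",
        "C(cue):C(location)": "cue:location",
    }
    for row, label in names.items():
        f = float(table.loc[row, "F"])
        p = float(table.loc[row, "PR(>F)"])
        out.append(
            StatsResult(
                f"anova[{label}]",
                f,
                p,
                detail={
                    "df_effect": float(table.loc[row, "df"]),
                    "df_resid": float(table.loc["Residual", "df"]),
                    "sum_sq": float(table.loc[row, "sum_sq"]),
                },
            )
        )
    return out


def build_diff_table(run_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(location, level) cue-effect differences with per-location
    summary statistics.

    Expects a tidy run table with columns ``location``, ``level``,
    ``condition`` and ``correct`` (counts of correctly named items); the
    paired difference is ``cue condition - RwO`` at the same cell.  The SD
    column is the population standard deviation over ablation levels.
    """
    required = {"location", "level", "condition", "correct"}
    if not required.issubset(run_table.columns):
        raise ValueError(f"run table must have columns {sorted(required)}")
    wide = run_table.pivot_table(
        index=["location", "level"],
        columns="condition",
        values="correct",
        aggfunc="mean",
    )
    if "RwO" not in wide.columns:
        raise ValueError("run table carries no RwO baseline")
    rows = []
    for cue_cond in [c for c in ("RwS", "RwP", "RwT") if c in wide.columns]:
        missing = wide[wide[cue_cond].isna() | wide["RwO"].isna()]
        if len(missing):
            raise ValueError(
                f"missing paired cells for {cue_cond}: {list(missing.index)}"
            )
        diff = wide[cue_cond] - wide["RwO"]
        for (loc, level), value in diff.items():
            rows.append(
                {
                    "location": loc,
                    "level": level,
                    "condition": cue_cond,
                    "rwo": wide.loc[(loc, level), "RwO"],
                    "cue": wide.loc[(loc, level), cue_cond],
                    "difference": value,
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["location", "condition"])["difference"]
        .agg(["mean", lambda s: float(np.std(s, ddof=0))])
        .rename(columns={"<lambda_0>": "sd"})
        .reset_index()
    )
    table.attrs["summary"] = summary
    return table
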