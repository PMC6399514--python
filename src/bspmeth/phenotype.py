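"""Eggshell-color statistics, laying-stage segmentation and qPCR expression.

Color: each egg is measured at three positions along the longitudinal axis
(obtuse, medium, acute end) and the per-egg value is their mean; smaller
values mean a darker (greener/bluer) shell.  Weekly summaries report mean,
sample SD (n-1), CV = SD/mean, min, max and n.

Expression: relative quantification by the 2^-ddCt method against a
reference gene and a calibrator group, with replicate Ct values averaged
before differencing.  Week effects are assessed by one-way ANOVA with a
Tukey-HSD-backed compact letter display; consecutive weeks sharing a
letter are merged into laying stages.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EggColorMeasurement",
    "WeekColorSummary",
    "RelativeExpression",
    "egg_color_value",
    "summarize_week",
    "summarize_color",
    "one_way_anova",
    "tukey_pairwise_p",
    "compact_letters",
    "assign_stages",
    "ddct",
]


@dataclass(frozen=True)
class EggColorMeasurement:
    week: int
    egg_id: str
    readings: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.readings) != 3:
            raise ValueError(
                f"egg {self.egg_id!r}: expected 3 position readings, "
                f"got {len(self.readings)}"
            )
        if any(r <= 0 for r in self.readings):
            raise ValueError(f"egg {self.egg_id!r}: readings must be positive")


@dataclass(frozen=True)
class WeekColorSummary:
    week: int
    n: int
    mean: float
    sd: float
    cv: float
    min: float
    max: float


@dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    week: int
    delta_ct: float
    delta_delta_ct: float
    rq: float


def egg_color_value(measurement: EggColorMeasurement) -> float:
    """Per-egg color value: arithmetic mean of the three position readings."""
    return float(np.mean(measurement.readings))


def summarize_week(week: int, values) -> WeekColorSummary:
    """Weekly summary with sample SD (ddof=1) and CV = sd/mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError(f"week {week}: need >= 2 eggs for a summary")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return WeekColorSummary(
        week=week,
        n=len(values),
        mean=mean,
        sd=sd,
        cv=sd / mean,
        min=float(values.min()),
        max=float(values.max()),
    )


def summarize_color(color: pd.DataFrame) -> pd.DataFrame:
    """Summarise a per-egg color table into a per-week table.

    Expects columns week, egg_id, r1, r2, r3 and optionally exclude (truthy
    rows are dropped before averaging, mirroring the exclusion of
    rough-shelled and abnormal eggs at measurement time).
    """
    df = color.copy()
    if "exclude" in df.columns:
        df = df[~df["exclude"].astype(bool)]
    df["value"] = df[["r1", "r2", "r3"]].mean(axis=1)
    rows = []
    for week, grp in df.groupby("week"):
        s = summarize_week(int(week), grp["value"].to_numpy())
        rows.append(
            {"week": s.week, "n": s.n, "mean": s.mean, "sd": s.sd,
             "cv": s.cv, "min": s.min, "max": s.max}
        )
    return pd.DataFrame(rows).set_index("week").sort_index()


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across >= 2 groups of n >= 2."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 2 values")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        warnings.warn("zero total variance; F reported as 0, p as 1", stacklevel=2)
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # groups internally constant but identical means
        return 0.0, 1.0
    return float(f), float(p)


def tukey_pairwise_p(groups: list[np.ndarray]) -> np.ndarray:
    """Symmetric matrix of Tukey-HSD pairwise p-values (familywise control).

    Unequal group sizes use the Tukey-Kramer standard error.  p-values come
    from the studentized range distribution with N-k error degrees of
    freedom, evaluated in one vectorised call over all pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    df = ns.sum() - k
    mse = sum(((g - m) ** 2).sum() for g, m in zip(groups, means)) / df
    i, j = np.triu_indices(k, 1)
    if mse == 0:
        mat = np.ones((k, k))
        differ = means[i] != means[j]
        mat[i[differ], j[differ]] = mat[j[differ], i[differ]] = 0.0
        return mat
    se = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
    q = np.abs(means[i] - means[j]) / se
    p = np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0)
    mat = np.ones((k, k))
    mat[i, j] = mat[j, i] = p
    return mat


def compact_letters(pairwise_p: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pairwise comparison is
    non-significant at ``alpha``.  Letters are assigned a, b, c, ... in
    group order; redundant letters are absorbed.
    """
    p = np.asarray(pairwise_p, dtype=float)
    k = p.shape[0]
    if p.shape != (k, k):
        raise ValueError("pairwise p matrix must be square")
    # columns = letters, each a set of group indices with no significant pair
    columns: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if p[i, j] >= alpha:
            continue
        for col in list(columns):
            if i in col and j in col:
                columns.remove(col)
                a, b = col - {j}, col - {i}
                for new in (a, b):
                    if not any(new <= other for other in columns):
                        columns.append(new)
    # absorb: drop columns contained in another
    columns = [c for c in columns if not any(c < o for o in columns)]
    columns.sort(key=lambda c: min(c))
    letters = ["" for _ in range(k)]
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in sorted(col):
            letters[g] += letter
    return letters


@dataclass(frozen=True)
class Stage:
    label: int  # rank of the stage mean (1 = smallest mean)
    weeks: tuple[int, ...]
    mean: float


def assign_stages(weeks: list[int], letters: list[str], means: list[float]) -> list[Stage]:
    """Merge consecutive weeks sharing a letter into laying stages.

    A stage is a maximal run of consecutive weeks whose letter sets have a
    common letter (the running intersection stays non-empty).  Stage labels
    are the rank of each stage's mean color value, 1 = darkest (smallest).
    """
    if not (len(weeks) == len(letters) == len(means)):
        raise ValueError("weeks, letters and means must align")
    runs: list[list[int]] = []
    current = [0]
    shared = set(letters[0])
    for i in range(1, len(weeks)):
        nxt = shared & set(letters[i])
        if nxt:
            current.append(i)
            shared = nxt
        else:
            runs.append(current)
            current = [i]
            shared = set(letters[i])
    runs.append(current)
    stage_means = [float(np.mean([means[i] for i in run])) for run in runs]
    ranks = np.argsort(np.argsort(stage_means)) + 1
    return [
        Stage(label=int(rank), weeks=tuple(weeks[i] for i in run), mean=m)
        for run, m, rank in zip(runs, stage_means, ranks)
    ]


def ddct(ct: pd.DataFrame, calibrator_week: int) -> pd.DataFrame:
    """Relative expression by 2^-ddCt.

    ``ct`` has one row per (sample, gene_role, replicate) with columns
    sample_id, week, gene_role in {target, reference}, ct.  Per sample,
    replicate Cts are averaged; dCt = mean target Ct - mean reference Ct;
    ddCt subtracts the calibrator group's mean dCt; rq = 2^-ddCt.
    Samples missing either gene are dropped with a warning.
    """
    rows = []
    for (sample, week), grp in ct.groupby(["sample_id", "week"]):
        t = grp.loc[grp["gene_role"] == "target", "ct"]
        r = grp.loc[grp["gene_role"] == "reference", "ct"]
        if t.empty or r.empty:
            warnings.warn(
                f"sample {sample!r}: missing target or reference Ct; dropped",
                stacklevel=2,
            )
            continue
        rows.append(
            {"sample_id": sample, "week": int(week),
             "delta_ct": float(t.mean() - r.mean())}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no usable samples in Ct table")
    calib = df.loc[df["week"] == calibrator_week, "delta_ct"]
    if calib.empty:
        raise ValueError(f"calibrator week {calibrator_week} has no samples")
    df["delta_delta_ct"] = df["delta_ct"] - calib.mean()
    df["rq"] = 2.0 ** (-df["delta_delta_ct"])
    return df
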