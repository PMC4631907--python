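"""Group-comparison statistics: one-way ANOVA with LSD letter display,
elevation relative-effect summaries, and simple OLS regression.

The comparison design is a one-way layout over species × elevation groups
(classical equal-variance ANOVA, no Welch correction).  Pairwise structure is
summarised by Fisher's least significant difference,

    LSD_ij = t(1 − α/2, df_within) · sqrt(MS_within·(1/n_i + 1/n_j)),

rendered as a compact letter display: groups sharing a letter do not differ
at level α.  The LSD step is protected by default — letters collapse to a
single group unless the omnibus F test is significant.

Elevation effects are expressed as percent change of the high-elevation group
mean relative to the low-elevation mean, with a first-order (delta-method)
standard error propagated from the two group SEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "AnovaResult",
    "RelativeEffect",
    "LinearFit",
    "one_way_anova",
    "lsd_letters",
    "percent_change",
    "propagate_percent_se",
    "relative_effect",
    "linear_fit",
]


@dataclass(frozen=True)
class GroupSample:
    """One comparison group (e.g. a species at one elevation)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size < 2:
            raise ValueError(f"group {self.label!r} needs n >= 2, got {v.size}")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float
    group_means: dict[str, float]
    group_ns: dict[str, int]
    group_letters: dict[str, str] = field(default_factory=dict)
    lsd_value: float | None = None


@dataclass(frozen=True)
class RelativeEffect:
    """Percent change of a parameter between a baseline and a contrast group."""

    parameter: str
    species: str
    low_mean: float
    high_mean: float
    percent_change: float
    se_percent: float


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float


def one_way_anova(
    groups: Sequence[GroupSample],
    alpha: float = 0.05,
    letters: bool = True,
    protected: bool = True,
) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA with optional LSD letters.

    The sum-of-squares decomposition is computed directly (SS_total =
    SS_between + SS_within); F = MS_between/MS_within on (k−1, N−k) degrees
    of freedom.  Raises if fewer than two groups or all groups are internally
    constant (MS_within = 0 leaves F undefined).
    """
    if len(groups) < 2:
        raise ValueError(f"ANOVA needs >= 2 groups, got {len(groups)}")
    all_values = np.concatenate([g.values for g in groups])
    grand_mean = float(np.mean(all_values))
    k = len(groups)
    n_total = int(all_values.size)

    ss_between = float(sum(g.n * (g.mean - grand_mean) ** 2 for g in groups))
    ss_within = float(sum(np.sum((g.values - g.mean) ** 2) for g in groups))
    df_between = k - 1
    df_within = n_total - k
    if ss_within <= 0:
        raise ValueError("zero within-group variance in every group; F undefined")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f_stat = ms_between / ms_within
    p_value = float(sps.f.sf(f_stat, df_between, df_within))

    result = AnovaResult(
        f_stat=f_stat,
        df_between=df_between,
        df_within=df_within,
        p_value=p_value,
        ms_within=ms_within,
        group_means={g.label: g.mean for g in groups},
        group_ns={g.label: g.n for g in groups},
    )
    if letters:
        if protected and p_value > alpha:
            letter_map = {g.label: "a" for g in groups}
            lsd = None
        else:
            letter_map, lsd = lsd_letters(
                groups, ms_within=ms_within, df_within=df_within, alpha=alpha
            )
        result = AnovaResult(
            **{**result.__dict__, "group_letters": letter_map, "lsd_value": lsd}
        )
    return result


def _lsd_threshold(
    ms_within: float, df_within: int, n_i: int, n_j: int, alpha: float
) -> float:
    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, df_within))
    return t_crit * np.sqrt(ms_within * (1.0 / n_i + 1.0 / n_j))


def lsd_letters(
    groups: Sequence[GroupSample],
    ms_within: float,
    df_within: int,
    alpha: float = 0.05,
) -> tuple[dict[str, str], float]:
    """Compact letter display from pairwise LSD comparisons.

    Uses the insert-and-absorb algorithm: start with one letter covering all
    groups; every significant pair splits the letters containing both, and
    redundant (subset) letters are absorbed.  Groups are ordered by descending
    mean before lettering, so the display is deterministic.  The returned LSD
    value uses the harmonic-mean group size; pairwise thresholds use the exact
    per-pair sizes.
    """
    order = sorted(range(len(groups)), key=lambda i: -groups[i].mean)
    ordered = [groups[i] for i in order]
    k = len(ordered)

    significant = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            thr = _lsd_threshold(
                ms_within, df_within, ordered[i].n, ordered[j].n, alpha
            )
            if abs(ordered[i].mean - ordered[j].mean) >= thr:
                significant[i, j] = significant[j, i] = True

    # insert-and-absorb over letter columns (sets of group indices)
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                columns.append(col - {i})
                columns.append(col - {j})
            # absorb: drop empty columns, duplicates and strict subsets
            unique: list[set[int]] = []
            for c in columns:
                if c and c not in unique:
                    unique.append(c)
            columns = [c for c in unique if not any(c < other for other in unique)]

    columns.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letter_map = {g.label: "" for g in ordered}
    for letter, col in zip(alphabet, columns):
        for idx in sorted(col):
            letter_map[ordered[idx].label] += letter

    n_harm = k / sum(1.0 / g.n for g in ordered)
    lsd = _lsd_threshold(ms_within, df_within, n_harm, n_harm, alpha)
    return letter_map, float(lsd)


def percent_change(low_mean: float, high_mean: float) -> float:
    """Signed percent change of ``high_mean`` relative to ``low_mean``.

    A published "reduction of X %" corresponds to a value of −X here; the
    reporting layer renders the sign as increase/reduction wording.
    """
    if low_mean == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (high_mean - low_mean) / low_mean


def propagate_percent_se(
    low_mean: float, low_se: float, high_mean: float, high_se: float
) -> float:
    """Delta-method SE of the percent change for two independent group means.

    First-order propagation of var(100·(h/l − 1)) = 100²·[(se_h/l)² +
    (h·se_l/l²)²]; invariant to a common rescaling of means and SEs.
    """
    if low_mean == 0:
        raise ValueError("percent change undefined for a zero baseline")
    var = (high_se / low_mean) ** 2 + (high_mean * low_se / low_mean**2) ** 2
    return 100.0 * float(np.sqrt(var))


def relative_effect(
    parameter: str,
    species: str,
    low_mean: float,
    low_se: float,
    high_mean: float,
    high_se: float,
) -> RelativeEffect:
    """Bundle the elevation percent change and its propagated SE."""
    return RelativeEffect(
        parameter=parameter,
        species=species,
        low_mean=low_mean,
        high_mean=high_mean,
        percent_change=percent_change(low_mean, high_mean),
        se_percent=propagate_percent_se(low_mean, low_se, high_mean, high_se),
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares y = a + b·x with R², F and p on (1, n−2) df.

    F is the regression F statistic (n−2)·R²/(1−R²), identical to the square
    of the slope t statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("linear_fit needs matched x/y with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    n = x.size
    r2 = float(res.rvalue**2)
    if r2 >= 1.0:
        f_stat = float("inf")
        p = 0.0
    else:
        f_stat = (n - 2) * r2 / (1.0 - r2)
        p = float(sps.f.sf(f_stat, 1, n - 2))
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        f_stat=f_stat,
        df1=1,
        df2=n - 2,
        p_value=p,
    )
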