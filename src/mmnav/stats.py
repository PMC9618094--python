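"""Repeated-measures and mixed ANOVAs, correlation families, outlier filters.

The ANOVAs are explicit balanced sum-of-squares decompositions in the
classical univariate style: each fully-within effect is tested against its
interaction with subjects, the between-group effect of a mixed design against
subjects-within-groups, and the within/interaction effects against the
within-subjects residual. Effect size is partial eta squared,
SS_effect / (SS_effect + SS_error). No sphericity correction is applied (the
designs used here have two-level within factors, where sphericity holds
trivially, except the three-level radius factor — the degrees of freedom are
reported so a correction could be layered on).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "IncompleteDesignError",
    "DegenerateVarianceError",
    "rm_anova",
    "rm_anova_2x2",
    "mixed_anova",
    "one_way_anova",
    "PairCorrelation",
    "CorrelationMatrixResult",
    "pearson_bonferroni",
    "OutlierFilterResult",
    "sd_outlier_filter",
]


class IncompleteDesignError(ValueError):
    """A subject is missing one or more design cells."""


class DegenerateVarianceError(ValueError):
    """An effect's error sum of squares is exactly zero while the effect sum
    of squares is not — the F ratio is undefined."""


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta2: float
    ss_effect: float
    ss_error: float

    def format(self) -> str:
        return (
            f"{self.name}: F({self.df_num}, {self.df_den}) = {self.F:.3f}, "
            f"P = {self.p:.3f}, partial eta^2 = {self.partial_eta2:.3f}"
        )


@dataclass
class AnovaResult:
    effects: dict[str, AnovaEffect]

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.name, "F": e.F, "df1": e.df_num, "df2": e.df_den,
                    "p": e.p, "partial_eta2": e.partial_eta2,
                }
                for e in self.effects.values()
            ]
        )

    def format(self) -> str:
        return "\n".join(e.format() for e in self.effects.values())


def _f_effect(name, ss_eff, df_eff, ss_err, df_err) -> AnovaEffect:
    if ss_eff <= 0.0:
        # no effect variance at all: F = 0 by convention, even when the
        # matching error term is also zero (pure subject-offset data)
        return AnovaEffect(name, 0.0, df_eff, df_err, 1.0, 0.0, 0.0, ss_err)
    if ss_err <= 0.0:
        raise DegenerateVarianceError(
            f"effect {name!r}: zero error sum of squares"
        )
    F = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_eff, df_err))
    return AnovaEffect(
        name, float(F), df_eff, df_err, p,
        float(ss_eff / (ss_eff + ss_err)), float(ss_eff), float(ss_err),
    )


# ---------------------------------------------------------------------------
# fully within-subject designs


def _balanced_cube(data: pd.DataFrame, dv: str, factors: Sequence[str]
                   ) -> tuple[np.ndarray, list[list]]:
    """Pivot a long table into an ndarray over the factor levels; raises
    IncompleteDesignError on missing or duplicated cells."""
    levels = [sorted(data[f].unique()) for f in factors]
    shape = tuple(len(lv) for lv in levels)
    expected = int(np.prod(shape))
    if len(data) != expected:
        raise IncompleteDesignError(
            f"expected {expected} rows (one per design cell), got {len(data)}"
        )
    cube = np.full(shape, np.nan)
    index = [{lv: i for i, lv in enumerate(lvs)} for lvs in levels]
    for _, row in data.iterrows():
        pos = tuple(index[k][row[f]] for k, f in enumerate(factors))
        if not np.isnan(cube[pos]):
            raise IncompleteDesignError(f"duplicate observation for cell {pos}")
        cube[pos] = row[dv]
    if np.isnan(cube).any():
        raise IncompleteDesignError("missing design cells")
    return cube, levels


def _subset_ss(cube: np.ndarray, subset: tuple[int, ...]) -> float:
    """Balanced-design sum of squares of the pure interaction effect over the
    factor axes in ``subset`` (inclusion-exclusion over marginal means)."""
    ndim = cube.ndim
    eff = None
    for t_size in range(len(subset) + 1):
        for t in itertools.combinations(subset, t_size):
            # marginal mean over every axis not in t, kept broadcastable
            drop = tuple(ax for ax in range(ndim) if ax not in t)
            m = cube.mean(axis=drop, keepdims=True) if drop else cube
            sign = (-1) ** (len(subset) - t_size)
            eff = sign * m if eff is None else eff + sign * m
    n_rep = cube.size / np.prod([cube.shape[ax] for ax in subset])
    return float(n_rep * (eff ** 2).sum())


def rm_anova(data: pd.DataFrame, dv: str, within: Sequence[str],
             subject: str) -> AnovaResult:
    """Fully within-subject ANOVA for any number of crossed within factors
    (complete balanced design, one observation per cell).

    Each effect (main effects and all interactions among the within factors)
    is tested against its own interaction with subjects.
    """
    within = list(within)
    factors = [subject] + within
    cube, levels = _balanced_cube(data[factors + [dv]], dv, factors)
    if cube.shape[0] < 3:
        raise IncompleteDesignError("need at least 3 subjects")
    effects: dict[str, AnovaEffect] = {}
    w_axes = list(range(1, len(factors)))
    for size in range(1, len(w_axes) + 1):
        for combo in itertools.combinations(w_axes, size):
            name = " x ".join(within[ax - 1] for ax in combo)
            ss_eff = _subset_ss(cube, combo)
            ss_err = _subset_ss(cube, (0,) + combo)
            df_eff = int(np.prod([cube.shape[ax] - 1 for ax in combo]))
            df_err = df_eff * (cube.shape[0] - 1)
            effects[name] = _f_effect(name, ss_eff, df_eff, ss_err, df_err)
    return AnovaResult(effects)


def rm_anova_2x2(data: pd.DataFrame, dv: str, within: Sequence[str],
                 subject: str) -> AnovaResult:
    """Two crossed two-level within factors (e.g. condition x test): the
    classical 2 x 2 repeated-measures ANOVA with partial eta squared."""
    within = list(within)
    if len(within) != 2:
        raise ValueError("rm_anova_2x2 takes exactly two within factors")
    for f in within:
        if data[f].nunique() != 2:
            raise IncompleteDesignError(f"factor {f!r} must have 2 levels")
    return rm_anova(data, dv, within, subject)


# ---------------------------------------------------------------------------
# mixed design (one within factor, one between factor)


def mixed_anova(data: pd.DataFrame, dv: str, within: str, between: str,
                subject: str) -> AnovaResult:
    """Mixed-design ANOVA: the between effect is tested over
    subjects-within-groups; the within effect and the interaction over the
    within-subjects residual. Unbalanced group sizes use observation-weighted
    means (each subject still needs every within level)."""
    sub_groups = data.groupby(subject)[between].nunique()
    if (sub_groups > 1).any():
        raise IncompleteDesignError("a subject appears in more than one group")
    counts = data.groupby(between)[subject].nunique()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise IncompleteDesignError(f"groups with < 2 subjects: {small}")
    w_levels = sorted(data[within].unique())
    w = len(w_levels)
    per_sub = data.groupby(subject)[within].nunique()
    if (per_sub != w).any():
        raise IncompleteDesignError("a subject is missing within levels")

    y = data[dv].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    sub_mean = data.groupby(subject)[dv].mean()
    sub_group = data.groupby(subject)[between].first()
    grp_mean = data.groupby(between)[dv].mean()
    lvl_mean = data.groupby(within)[dv].mean()
    cell_mean = data.groupby([between, within])[dv].mean()
    n_g = data.groupby(between)[subject].nunique()

    ss_between = float(
        (w * n_g * (grp_mean - grand) ** 2).sum()
    )
    ss_subj_within = float(
        (w * (sub_mean - grp_mean.loc[sub_group].set_axis(sub_mean.index)) ** 2)
        .sum()
    )
    n_subjects = int(data[subject].nunique())
    ss_within = float((n_subjects * (lvl_mean - grand) ** 2).sum())
    ss_cells = 0.0
    for (g, k), c in cell_mean.items():
        ss_cells += n_g[g] * (c - grand) ** 2
    ss_cells = float(ss_cells)
    ss_interaction = ss_cells - ss_between - ss_within
    ss_err_within = ss_total - ss_cells - ss_subj_within

    g = len(n_g)
    df_between, df_err_b = g - 1, n_subjects - g
    df_within = w - 1
    df_inter = (g - 1) * (w - 1)
    df_err_w = (n_subjects - g) * (w - 1)
    # numerical guard: residuals can come out at -1e-12 on clean data
    ss_interaction = max(ss_interaction, 0.0)
    ss_err_within = max(ss_err_within, 0.0)
    return AnovaResult({
        between: _f_effect(between, ss_between, df_between,
                           ss_subj_within, df_err_b),
        within: _f_effect(within, ss_within, df_within,
                          ss_err_within, df_err_w),
        f"{within} x {between}": _f_effect(
            f"{within} x {between}", ss_interaction, df_inter,
            ss_err_within, df_err_w,
        ),
    })


def one_way_anova(groups: Sequence[Sequence[float]],
                  names: Optional[Sequence[str]] = None) -> AnovaResult:
    """Standard between-groups one-way ANOVA with eta squared."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs at least 2 values")
    allv = np.concatenate(arrs)
    grand = allv.mean()
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrs))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_b = len(arrs) - 1
    df_w = len(allv) - len(arrs)
    name = "group" if names is None else " vs ".join(names)
    return AnovaResult({
        "group": _f_effect("group", ss_between, df_b, ss_within, df_w)
    })


# ---------------------------------------------------------------------------
# correlation families


@dataclass(frozen=True)
class PairCorrelation:
    a: str
    b: str
    r: float
    p: float
    n: int
    significant: bool
    note: str = ""


@dataclass
class CorrelationMatrixResult:
    pairs: list[PairCorrelation]
    alpha: float
    corrected_alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "a": c.a, "b": c.b, "r": c.r, "p": c.p, "n": c.n,
                    "significant": c.significant, "note": c.note,
                }
                for c in self.pairs
            ]
        )


def pearson_bonferroni(table: pd.DataFrame,
                       family: Optional[Sequence[tuple[str, str]]] = None,
                       alpha: float = 0.05) -> CorrelationMatrixResult:
    """Pearson correlations over a family of measure pairs with Bonferroni
    correction: significance is judged at alpha / |family|.

    ``table`` holds one column per measure, one row per observation; the
    family defaults to all unordered column pairs. Rows with a missing value
    in either member of a pair are dropped pairwise; pairs with fewer than 3
    complete observations or zero variance get an undefined-r marker.
    """
    if family is None:
        cols = list(table.columns)
        family = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    family = list(family)
    if not family:
        raise ValueError("empty correlation family")
    corrected = alpha / len(family)
    pairs = []
    for a, b in family:
        sub = table[[a, b]].dropna()
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if len(sub) < 3:
            pairs.append(PairCorrelation(a, b, np.nan, np.nan, len(sub),
                                         False, "fewer than 3 observations"))
            continue
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            pairs.append(PairCorrelation(a, b, np.nan, np.nan, len(sub),
                                         False, "zero variance"))
            continue
        r, p = sps.pearsonr(x, y)
        pairs.append(
            PairCorrelation(a, b, float(r), float(p), len(sub), p <= corrected)
        )
    return CorrelationMatrixResult(pairs=pairs, alpha=alpha,
                                   corrected_alpha=corrected)


# ---------------------------------------------------------------------------
# outlier filtering


@dataclass
class OutlierFilterResult:
    kept: np.ndarray       # boolean mask over the input
    removed: np.ndarray    # integer positions removed
    mean: float
    sd: float
    zero_sd: bool

    @property
    def n_removed(self) -> int:
        return int(len(self.removed))


def sd_outlier_filter(values, threshold_sd: float = 2.5,
                      mode: str = "two_sided") -> OutlierFilterResult:
    """Single-pass SD-based exclusion.

    The mean and SD (population SD, ddof=0) come from the *full* input — one
    exclusion step, no recursion. ``two_sided`` removes units beyond
    ``threshold_sd`` SDs either way (item-level exclusion); ``above_only``
    removes only high outliers (participant-level exclusion of poor
    performers when larger scores mean worse performance). Zero SD removes
    nothing and is flagged.
    """
    if mode not in ("two_sided", "above_only"):
        raise ValueError(f"bad mode {mode!r}")
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    mu = float(v.mean())
    sd = float(v.std(ddof=0))
    if sd == 0.0:
        return OutlierFilterResult(np.ones(v.size, bool),
                                   np.array([], dtype=int), mu, sd, True)
    z = (v - mu) / sd
    if mode == "two_sided":
        out = np.abs(z) > threshold_sd
    else:
        out = z > threshold_sd
    return OutlierFilterResult(~out, np.flatnonzero(out), mu, sd, False)
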