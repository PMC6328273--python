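"""Statistical battery for pooled rhythm-metric tables.

Per protocol direction, a univariate Type III repeated-measures ANOVA
tests the pH effect on each measure, followed (only when the ANOVA is
significant) by paired t-tests of every pH step against the pre-protocol
control with Bonferroni correction. The two ganglia are compared with a
two-way mixed-measures ANOVA (ganglion between subjects, pH within) and
Bonferroni-corrected independent-samples t-tests per condition. Violin
summaries report the KDE, mean, median, IQR and 95% CI of the mean.

For the balanced single-within-factor designs used here the Type I/II/III
sums-of-squares decompositions coincide, so the classical repeated-measures
decomposition matches the Type III procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sst

__all__ = [
    "DistributionSummary",
    "AnovaResult",
    "distribution_summary",
    "bonferroni",
    "rm_anova_posthoc",
    "mixed_anova_posthoc",
    "baseline_extreme_correlation",
    "plot_violins",
]


@dataclass
class DistributionSummary:
    """Summary of one pooled distribution, the quantities drawn in a violin."""

    n: int
    mean: float
    median: float
    iqr: tuple[float, float]
    ci95: tuple[float, float] | None
    kde_grid: np.ndarray | None = None
    kde_density: np.ndarray | None = None


@dataclass
class AnovaResult:
    """ANOVA table plus the gated, Bonferroni-corrected post-hoc table."""

    anova: pd.DataFrame
    posthoc: pd.DataFrame | None
    alpha: float
    effect_p: float
    family_size: int = 0
    notes: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.effect_p < self.alpha)


def distribution_summary(values, grid_size: int = 256,
                         bw_method="scott") -> DistributionSummary:
    """Mean, median, IQR, t-based 95% CI of the mean, and a Gaussian KDE.

    With fewer than two finite values the KDE and CI are omitted (logged as
    a warning) rather than raising.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values to summarize")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    if x.size < 2:
        warnings.warn("fewer than two values: KDE and CI omitted", stacklevel=2)
        return DistributionSummary(1, float(x[0]), float(med), (float(q25), float(q75)),
                                   None)
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size))
    tcrit = float(sst.t.ppf(0.975, x.size - 1))
    mean = float(np.mean(x))
    ci = (mean - tcrit * sem, mean + tcrit * sem)
    grid = kde = None
    if np.ptp(x) > 0:
        k = sst.gaussian_kde(x, bw_method=bw_method)
        span = 3.0 * k.factor * float(np.std(x, ddof=1))
        grid = np.linspace(x.min() - span, x.max() + span, grid_size)
        kde = k(grid)
    else:
        warnings.warn("degenerate (constant) sample: KDE omitted", stacklevel=2)
    return DistributionSummary(int(x.size), mean, float(med),
                               (float(q25), float(q75)), ci, grid, kde)


def bonferroni(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Bonferroni adjustment: ``min(1, p * m)``."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def _pcol(aov: pd.DataFrame) -> str:
    for col in ("p_unc", "p-unc"):
        if col in aov.columns:
            return col
    raise KeyError("no uncorrected p-value column in ANOVA table")


def _validate_complete(table: pd.DataFrame, subject: str, within: str,
                       dv: str) -> None:
    counts = table.groupby([subject, within], observed=True)[dv].count()
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise ValueError(
            "incomplete within-subject design; expected exactly one value per "
            f"(preparation, condition), offending cells: {bad.index.tolist()[:5]}")
    wide = counts.unstack(within)
    if wide.isna().any().any():
        missing = [(s, c) for s in wide.index for c in wide.columns
                   if pd.isna(wide.loc[s, c])]
        raise ValueError(f"missing cells in design: {missing[:5]}")


def rm_anova_posthoc(table: pd.DataFrame, control: str, dv: str = "value",
                     within: str = "condition", subject: str = "preparation",
                     alpha: float = 0.05,
                     family: list[str] | None = None) -> AnovaResult:
    """Repeated-measures ANOVA for the pH factor with gated paired post-hocs.

    ``table`` holds one bin-averaged scalar per preparation and condition
    for one protocol direction. When the ANOVA pH effect is significant at
    ``alpha``, each non-control condition (or the explicit ``family``) is
    compared against ``control`` by paired t-tests with Bonferroni
    correction over the family size; otherwise no t-tests are performed.
    The table also reports the Greenhouse-Geisser corrected p-value
    alongside the uncorrected one.
    """
    _validate_complete(table, subject, within, dv)
    if control not in set(table[within]):
        raise ValueError(f"control condition {control!r} not present")
    aov = pg.rm_anova(data=table, dv=dv, within=within, subject=subject,
                      detailed=True, correction=True)
    effect_p = float(aov.loc[aov["Source"] == within, _pcol(aov)].iloc[0])

    posthoc = None
    m = 0
    if effect_p < alpha:
        wide = table.pivot(index=subject, columns=within, values=dv)
        conditions = family if family is not None else \
            [c for c in wide.columns if c != control]
        m = len(conditions)
        rows = []
        for c in conditions:
            t, p = sst.ttest_rel(wide[c], wide[control])
            rows.append((c, float(t), float(p), float(bonferroni(p, m))))
        posthoc = pd.DataFrame(rows, columns=["condition", "t", "p_raw", "p_bonf"])
    return AnovaResult(aov, posthoc, alpha, effect_p, m,
                       notes="paired t-tests vs control, Bonferroni"
                             if posthoc is not None else
                             "ANOVA not significant: post-hocs not performed")


def mixed_anova_posthoc(table: pd.DataFrame, dv: str = "value",
                        within: str = "condition", between: str = "ganglion",
                        subject: str = "preparation",
                        alpha: float = 0.05) -> AnovaResult:
    """Two-way mixed-measures ANOVA (ganglion between, pH within) with
    per-condition independent-samples post-hocs.

    Post-hoc t-tests (one per pH condition, Bonferroni-corrected over the
    number of conditions) are gated on any of the three effects (pH,
    ganglion, interaction) being significant at ``alpha``.
    """
    _validate_complete(table, subject, within, dv)
    groups = table[between].unique()
    if len(groups) != 2:
        raise ValueError("mixed design needs exactly two between-subject groups")
    sizes = table.groupby(between, observed=True)[subject].nunique()
    if (sizes < 2).any():
        raise ValueError(f"a group has fewer than two preparations: {dict(sizes)}")
    aov = pg.mixed_anova(data=table, dv=dv, within=within, between=between,
                         subject=subject)
    effect_p = float(aov[_pcol(aov)].min())

    posthoc = None
    m = 0
    if effect_p < alpha:
        conditions = list(pd.unique(table[within]))
        m = len(conditions)
        g0, g1 = groups
        rows = []
        for c in conditions:
            sub = table[table[within] == c]
            a = sub.loc[sub[between] == g0, dv]
            b = sub.loc[sub[between] == g1, dv]
            t, p = sst.ttest_ind(a, b)
            rows.append((c, float(t), float(p), float(bonferroni(p, m))))
        posthoc = pd.DataFrame(rows, columns=["condition", "t", "p_raw", "p_bonf"])
    return AnovaResult(aov, posthoc, alpha, effect_p, m,
                       notes=f"independent t-tests {groups[0]} vs {groups[1]}, "
                             "Bonferroni" if posthoc is not None else
                             "ANOVA not significant: post-hocs not performed")


def baseline_extreme_correlation(table: pd.DataFrame, control: str,
                                 extremes: list[str], dv: str = "value",
                                 within: str = "condition",
                                 subject: str = "preparation") -> pd.DataFrame:
    """Pearson correlation of per-preparation means: control vs each extreme.

    Preparations missing either value are excluded pairwise; the retained
    pair count is reported. Fewer than three pairs flag the correlation as
    undefined (``nan``) rather than raising.
    """
    wide = table.pivot_table(index=subject, columns=within, values=dv,
                             aggfunc="mean", observed=True)
    if control not in wide.columns:
        raise ValueError(f"control condition {control!r} not present")
    rows = []
    for ext in extremes:
        if ext not in wide.columns:
            raise ValueError(f"extreme condition {ext!r} not present")
        pair = wide[[control, ext]].dropna()
        n = len(pair)
        if n < 3:
            warnings.warn(f"fewer than 3 pairs for {ext}: correlation undefined",
                          stacklevel=2)
            rows.append((ext, n, np.nan, np.nan))
            continue
        r, p = sst.pearsonr(pair[control], pair[ext])
        rows.append((ext, n, float(r), float(p)))
    return pd.DataFrame(rows, columns=["extreme", "n", "r", "p"])


def plot_violins(table: pd.DataFrame, dv: str = "value",
                 within: str = "condition", order: list[str] | None = None,
                 ax=None, ylabel: str = ""):
    """Violin summaries (KDE body, mean bar, median dot, IQR box) per
    condition, in the style used for pooled rhythm measures."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.8 * table[within].nunique(), 3.2))
    conditions = order if order is not None else list(pd.unique(table[within]))
    data = [table.loc[table[within] == c, dv].dropna().to_numpy()
            for c in conditions]
    parts = ax.violinplot(data, showextrema=False)
    for pc in parts["bodies"]:
        pc.set_alpha(0.6)
    for i, x in enumerate(data, start=1):
        s = distribution_summary(x)
        ax.hlines(s.mean, i - 0.25, i + 0.25, lw=1.5)
        ax.plot(i, s.median, "o", ms=3, color="k")
        ax.vlines(i, s.iqr[0], s.iqr[1], lw=4, alpha=0.5)
        if s.ci95:
            ax.vlines(i, s.ci95[0], s.ci95[1], lw=1)
    ax.set_xticks(range(1, len(conditions) + 1), conditions)
    ax.set_ylabel(ylabel or dv)
    return ax
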