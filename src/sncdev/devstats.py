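"""Developmental-stage statistics.

Stage comparisons follow the study's scheme: a normality gate
(Shapiro-Wilk per group at alpha = 0.05) selects one-way ANOVA with Tukey's
post hoc test, or Kruskal-Wallis with Dunn's post hoc test; paired
ABD-vs-nABD comparisons use a paired t test; morphology/AP-shape relations
use Pearson regression.  The multivariate layer stacks pairwise
significance bands over a parameter panel, clusters neurons by
agglomerative hierarchical clustering (Ward linkage on z-scored features,
automatic largest-gap threshold) and projects them by linear discriminant
analysis.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .synthetic import AHC_FEATURES, FEATURE_COLUMNS, LDA_FEATURES, STAGES

__all__ = [
    "ComparisonResult",
    "compare_stages",
    "paired_abd_nabd",
    "pearson_regression",
    "stacking_matrix",
    "ahc",
    "lda",
    "significance_band",
    "STAGE_AGE",
]

STAGE_AGE = {"P3": 3, "P7": 7, "P14": 14, "P21": 21}
BANDS = ("ns", "<0.05", "<0.01", "<0.001")


def significance_band(p: float) -> str:
    if not 0.0 <= p <= 1.0 or math.isnan(p):
        raise ValueError(f"p-value out of range: {p}")
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    return "ns"


@dataclass
class ComparisonResult:
    parameter: str
    test: str                      # 'anova_tukey' or 'kruskal_dunn'
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]

    @property
    def bands(self) -> dict[tuple[str, str], str]:
        return {k: significance_band(v) for k, v in self.pairwise_p.items()}


def _groups(table: pd.DataFrame, parameter: str,
            min_n: int = 3) -> dict[str, np.ndarray]:
    if parameter not in table.columns:
        raise KeyError(f"unknown parameter {parameter!r}")
    out = {}
    for stage in STAGES:
        vals = table.loc[table["stage"] == stage, parameter].dropna().to_numpy()
        if len(vals) >= min_n:
            out[stage] = vals
    return out


def _dunn(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's rank-based post hoc test with tie correction and Bonferroni
    adjustment over the stage pairs."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(all_vals)
    n = len(all_vals)
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n) if n > 1 else 1.0
    mean_rank, sizes = {}, {}
    i = 0
    for g in names:
        k = len(groups[g])
        mean_rank[g] = ranks[i:i + k].mean()
        sizes[g] = k
        i += k
    m = len(names) * (len(names) - 1) // 2
    out = {}
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt((n * (n + 1) / 12.0) * tie
                       * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = abs(mean_rank[a] - mean_rank[b]) / se
        p = min(1.0, 2.0 * stats.norm.sf(z) * m)
        out[(a, b)] = p
    return out


def compare_stages(table: pd.DataFrame, parameter: str) -> ComparisonResult:
    """All pairwise stage comparisons for one parameter.

    Shapiro-Wilk at alpha = 0.05 in every group gates the parametric branch
    (ANOVA + Tukey); otherwise Kruskal-Wallis + Dunn.
    """
    groups = _groups(table, parameter)
    if len(groups) < 2:
        raise ValueError(f"{parameter}: need >= 2 stages with >= 3 values")
    arrays = list(groups.values())
    normal = all(stats.shapiro(g).pvalue >= 0.05 for g in arrays
                 if len(np.unique(g)) > 1)
    if normal:
        omnibus = stats.f_oneway(*arrays).pvalue
        tk = stats.tukey_hsd(*arrays)
        names = list(groups)
        pair_p = {(a, b): float(tk.pvalue[i, j])
                  for (i, a), (j, b) in
                  itertools.combinations(enumerate(names), 2)}
        test = "anova_tukey"
    else:
        omnibus = stats.kruskal(*arrays).pvalue
        pair_p = _dunn(groups)
        test = "kruskal_dunn"
    return ComparisonResult(parameter, test, float(omnibus), pair_p)


def paired_abd_nabd(table: pd.DataFrame, kind: str = "length"
                    ) -> dict[str, dict]:
    """Per-stage paired t test of ABD vs averaged-nABD length or complexity.

    Somatic-axon neurons (NaN ABD values) are excluded pairwise.  Returns
    stage -> {p, t, n, mean_difference (ABD − nABD)}.
    """
    cols = {"length": ("len_abd", "len_nabd_avg"),
            "complexity": ("n_segments_abd", "avg_segments_per_nabd")}
    if kind not in cols:
        raise ValueError("kind must be 'length' or 'complexity'")
    ca, cb = cols[kind]
    out = {}
    for stage in STAGES:
        sub = table.loc[table["stage"] == stage, [ca, cb]].dropna()
        if len(sub) < 3:
            out[stage] = {"p": math.nan, "t": math.nan, "n": len(sub),
                          "mean_difference": math.nan}
            continue
        diffs = (sub[ca] - sub[cb]).to_numpy()
        if np.allclose(diffs, 0.0):
            out[stage] = {"p": 1.0, "t": 0.0, "n": int(len(sub)),
                          "mean_difference": 0.0}
            continue
        res = stats.ttest_rel(sub[ca], sub[cb])
        out[stage] = {"p": float(res.pvalue), "t": float(res.statistic),
                      "n": int(len(sub)),
                      "mean_difference": float((sub[ca] - sub[cb]).mean())}
    return out


def pearson_regression(x, y):
    """Pearson r with two-sided p and the least-squares line.

    Returns (r, p, n, slope, intercept); complete pairs only.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least three complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan, len(x), math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return float(r), float(p), int(len(x)), float(slope), float(intercept)


def stacking_matrix(table: pd.DataFrame,
                    parameters: list[str] | None = None) -> pd.DataFrame:
    """Stage-pair × parameter grid of significance bands.

    Rows are the six stage pairs (P3-P7, P3-P14, ...), columns the
    parameters; cells hold 'ns', '<0.05', '<0.01' or '<0.001'.
    """
    parameters = list(parameters) if parameters is not None else \
        [c for c in FEATURE_COLUMNS if c in table.columns]
    pairs = list(itertools.combinations(STAGES, 2))
    grid = pd.DataFrame("ns", index=[f"{a}-{b}" for a, b in pairs],
                        columns=parameters)
    for param in parameters:
        try:
            res = compare_stages(table, param)
        except ValueError:
            grid[param] = "n/a"
            continue
        for (a, b), band in res.bands.items():
            grid.loc[f"{a}-{b}", param] = band
    return grid


def _zscore_complete(table: pd.DataFrame, parameters: list[str]):
    sub = table[list(parameters)].dropna()
    z = (sub - sub.mean()) / sub.std(ddof=0).replace(0.0, 1.0)
    return sub.index, z.to_numpy()


@dataclass
class AHCResult:
    labels: pd.Series           # class id per neuron (complete cases)
    n_classes: int
    linkage: np.ndarray
    threshold: float
    class_mean_age: dict[int, float]


def ahc(table: pd.DataFrame, parameters=AHC_FEATURES) -> AHCResult:
    """Agglomerative hierarchical clustering of neurons.

    Ward linkage on Euclidean distance over z-scored features,
    complete-case rows; the flat cut sits at the largest gap between
    successive merge dissimilarities.
    """
    idx, z = _zscore_complete(table, list(parameters))
    if len(idx) < 4:
        raise ValueError("need at least four complete-case neurons")
    link = hierarchy.linkage(z, method="ward")
    heights = link[:, 2]
    gaps = np.diff(heights)
    cut_at = int(np.argmax(gaps)) + 1          # first merge above the gap
    threshold = 0.5 * (heights[cut_at - 1] + heights[cut_at])
    labels = hierarchy.fcluster(link, t=threshold, criterion="distance")
    ser = pd.Series(labels, index=idx, name="ahc_class")
    ages = {}
    if "stage" in table.columns:
        age = table.loc[idx, "stage"].map(STAGE_AGE)
        for c in np.unique(labels):
            ages[int(c)] = float(age[ser == c].mean())
    return AHCResult(ser, int(len(np.unique(labels))), link,
                     float(threshold), ages)


@dataclass
class LDAResult:
    projection: pd.DataFrame     # F1/F2 per neuron + stage
    centroids: pd.DataFrame      # per-stage F1/F2
    loadings: pd.DataFrame       # per-parameter contributions to F1/F2
    explained: np.ndarray


def lda(table: pd.DataFrame, parameters=LDA_FEATURES) -> LDAResult:
    """Two-axis linear discriminant projection of the staged population."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    params = list(parameters)
    sub = table[params + ["stage"]].dropna()
    classes = sub["stage"].unique()
    if len(classes) < 2:
        raise ValueError("need at least two stages with complete cases")
    z = (sub[params] - sub[params].mean()) / sub[params].std(ddof=0)
    try:
        model = LinearDiscriminantAnalysis(n_components=min(2, len(classes) - 1))
        proj = model.fit_transform(z.to_numpy(), sub["stage"].to_numpy())
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class scatter; using shrinkage solver")
        model = LinearDiscriminantAnalysis(
            solver="eigen", shrinkage="auto",
            n_components=min(2, len(classes) - 1))
        proj = model.fit_transform(z.to_numpy(), sub["stage"].to_numpy())
    axes = [f"F{i+1}" for i in range(proj.shape[1])]
    pr = pd.DataFrame(proj, index=sub.index, columns=axes)
    pr["stage"] = sub["stage"]
    cents = pr.groupby("stage", sort=False)[axes].mean()
    load = pd.DataFrame(model.scalings_[:, :len(axes)], index=params,
                        columns=axes)
    return LDAResult(pr, cents, load,
                     np.asarray(model.explained_variance_ratio_[:len(axes)]))
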