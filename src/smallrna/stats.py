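"""Detection filtering, RPM-log2 normalization, and differential expression.

Statistics follow the standard small RNA-seq playbook: per-group Shapiro-Wilk
normality, Welch t-test and Wilcoxon Mann-Whitney for two groups, one-way
ANOVA and Kruskal-Wallis for more, Benjamini-Hochberg FDR control per
comparison, and effect sizes as fold change (on RPM), ROC AUC, and Cohen's d
(on the log2 scale).  The candidate filter is the AND of mean expression of
at least 1 RPM in some level, an AUC effect of at least 0.7 (or at most 0.3),
and an adjusted p-value below 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix


@dataclass
class NormalizedMatrix:
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # log2(RPM + 1), features x samples
    depth_per_sample: np.ndarray
    rna_class: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @property
    def rpm(self) -> np.ndarray:
        return np.exp2(self.values) - 1.0


@dataclass
class GroupDesign:
    variable_name: str
    assignment: dict[str, str]
    levels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.levels:
            self.levels = sorted(set(self.assignment.values()))

    def samples_of(self, level: str) -> list[str]:
        return [s for s, l in self.assignment.items() if l == level]


def detection_filter(matrix: CountMatrix, design: GroupDesign | None = None,
                     min_reads: int = 3, frac: float = 0.5) -> CountMatrix:
    """Keep features detected (count >= min_reads) in >= ``frac`` of samples.

    Without a design the fraction is over all samples; with one, a feature
    survives if it reaches the fraction within at least one level.  Both
    comparisons are inclusive (>=).
    """
    counts = matrix.counts
    detected = counts >= min_reads
    if design is None:
        keep = detected.mean(axis=1) >= frac
    else:
        keep = np.zeros(len(matrix.feature_ids), dtype=bool)
        for level in design.levels:
            cols = [i for i, s in enumerate(matrix.sample_ids)
                    if design.assignment.get(s) == level]
            if not cols:
                warnings.warn(f"level {level!r} has no samples; ignored in detection filter")
                continue
            keep |= detected[:, cols].mean(axis=1) >= frac
    kept = [f for f, k in zip(matrix.feature_ids, keep) if k]
    return CountMatrix(kept, list(matrix.sample_ids), counts[keep], matrix.rna_class)


def normalize(matrix: CountMatrix, depths: np.ndarray | list[float] | None = None) -> NormalizedMatrix:
    """log2(RPM + 1) normalization.

    ``depths`` defaults to per-sample column sums; the recommended input is
    the per-sample total mapped-read depth so values are comparable across
    RNA classes.
    """
    depths = np.asarray(depths if depths is not None else matrix.counts.sum(axis=0), dtype=float)
    if np.any(depths <= 0):
        bad = [s for s, d in zip(matrix.sample_ids, depths) if d <= 0]
        raise ValueError(f"zero sequencing depth for samples: {bad}")
    rpm = matrix.counts / depths[None, :] * 1e6
    return NormalizedMatrix(list(matrix.feature_ids), list(matrix.sample_ids),
                            np.log2(rpm + 1.0), depths, matrix.rna_class)


def pairwise_comparisons(design: GroupDesign) -> list[tuple[str, str]]:
    """All unordered level pairs in level order: k levels -> k(k-1)/2 pairs."""
    if len(design.levels) < 2:
        raise ValueError("differential expression needs at least 2 levels")
    return list(combinations(design.levels, 2))


def _safe_p(p: float) -> float:
    return float(p) if np.isfinite(p) else np.nan


def test_feature(values_a: np.ndarray, values_b: np.ndarray,
                 rpm_a: np.ndarray | None = None, rpm_b: np.ndarray | None = None) -> dict:
    """Two-group statistics for one feature on log2(RPM+1) values.

    Returns Shapiro-Wilk p per group, Welch t and Wilcoxon Mann-Whitney
    p-values, the fold change on the RPM scale (with +1 pseudo-offset), its
    log2, the ROC AUC (ties counted half), and Cohen's d with pooled SD.
    Degenerate inputs follow p = 1 conventions for identical constant groups
    and report d as missing when the pooled SD is zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, nb = len(a), len(b)
    if rpm_a is None:
        rpm_a = np.exp2(a) - 1.0
    if rpm_b is None:
        rpm_b = np.exp2(b) - 1.0

    out: dict = {"n_a": na, "n_b": nb,
                 "mean_rpm_a": float(np.mean(rpm_a)), "mean_rpm_b": float(np.mean(rpm_b))}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["p_shapiro_a"] = _safe_p(sps.shapiro(a).pvalue) if na >= 3 and np.ptp(a) > 0 else np.nan
        out["p_shapiro_b"] = _safe_p(sps.shapiro(b).pvalue) if nb >= 3 and np.ptp(b) > 0 else np.nan

        constant = np.ptp(np.concatenate([a, b])) == 0
        if constant:
            out["p_t"] = 1.0
            out["p_wmw"] = 1.0
        else:
            out["p_t"] = _safe_p(sps.ttest_ind(a, b, equal_var=False).pvalue)
            try:
                method = "exact" if (min(na, nb) <= 8
                                     and len(np.unique(np.concatenate([a, b]))) == na + nb) else "asymptotic"
                out["p_wmw"] = _safe_p(sps.mannwhitneyu(a, b, alternative="two-sided",
                                                        method=method).pvalue)
            except ValueError:
                out["p_wmw"] = np.nan

    # AUC from the Mann-Whitney U statistic, ties counted one half
    u = 0.0
    for x in a:
        u += np.sum(x > b) + 0.5 * np.sum(x == b)
    out["auc"] = float(u / (na * nb)) if na and nb else np.nan

    fc = (out["mean_rpm_a"] + 1.0) / (out["mean_rpm_b"] + 1.0)
    out["fold_change"] = float(fc)
    out["log2fc"] = float(np.log2(fc))

    var_a = np.var(a, ddof=1) if na > 1 else 0.0
    var_b = np.var(b, ddof=1) if nb > 1 else 0.0
    pooled = math.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / max(na + nb - 2, 1))
    out["cohens_d"] = float((np.mean(a) - np.mean(b)) / pooled) if pooled > 0 else np.nan
    if pooled == 0 and np.mean(a) == np.mean(b):
        out["cohens_d"] = 0.0
    return out


def multigroup_tests(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA and Kruskal-Wallis p-values across >= 3 levels."""
    if any(len(g) == 0 for g in groups):
        return np.nan, np.nan
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 1.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_anova = _safe_p(sps.f_oneway(*groups).pvalue)
        try:
            p_kw = _safe_p(sps.kruskal(*groups).pvalue)
        except ValueError:
            p_kw = 1.0
    return p_anova, p_kw


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN entries are left out
    of the family and returned as NaN."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def differential_expression(norm: NormalizedMatrix, design: GroupDesign) -> dict[tuple[str, str], pd.DataFrame]:
    """All pairwise-comparison DE tables for one normalized matrix.

    Each table carries the per-feature two-group statistics, multigroup
    ANOVA/Kruskal-Wallis p-values when more than two levels exist, and
    BH-adjusted Wilcoxon Mann-Whitney q-values (the headline adjusted p);
    the BH family is the features of that comparison.
    """
    rpm = norm.rpm
    level_cols = {lvl: [i for i, s in enumerate(norm.sample_ids)
                        if design.assignment.get(s) == lvl]
                  for lvl in design.levels}
    multigroup = len(design.levels) > 2
    mg: dict[str, tuple[float, float]] = {}
    if multigroup:
        for fi, feat in enumerate(norm.feature_ids):
            groups = [norm.values[fi, cols] for cols in level_cols.values()]
            mg[feat] = multigroup_tests(groups)

    tables = {}
    for lvl_a, lvl_b in pairwise_comparisons(design):
        ca, cb = level_cols[lvl_a], level_cols[lvl_b]
        rows = []
        for fi, feat in enumerate(norm.feature_ids):
            res = test_feature(norm.values[fi, ca], norm.values[fi, cb],
                               rpm[fi, ca], rpm[fi, cb])
            res["feature_id"] = feat
            if multigroup:
                res["p_anova"], res["p_kw"] = mg[feat]
            rows.append(res)
        df = pd.DataFrame(rows).set_index("feature_id")
        df["q_wmw"] = benjamini_hochberg(df["p_wmw"].to_numpy())
        df["q_t"] = benjamini_hochberg(df["p_t"].to_numpy())
        tables[(lvl_a, lvl_b)] = df
    return tables


def candidate_filter(results: pd.DataFrame, min_rpm: float = 1.0,
                     min_effect: float = 0.7, max_p: float = 0.05,
                     effect: str = "auc") -> pd.DataFrame:
    """AND-filter DE results: expression, effect size, and significance.

    Keeps features with mean RPM >= ``min_rpm`` in at least one level, an
    effect of at least ``min_effect`` (for AUC, symmetrically <= 1 -
    min_effect), and adjusted p < ``max_p``.  ``effect`` selects AUC
    (default) or the absolute Cohen's d.
    """
    expr_ok = (results["mean_rpm_a"] >= min_rpm) | (results["mean_rpm_b"] >= min_rpm)
    if effect == "auc":
        eff_ok = (results["auc"] >= min_effect) | (results["auc"] <= 1.0 - min_effect)
    elif effect == "cohens_d":
        eff_ok = results["cohens_d"].abs() >= min_effect
    else:
        raise ValueError(f"unknown effect measure {effect!r}")
    sig_ok = results["q_wmw"] < max_p
    return results[expr_ok & eff_ok & sig_ok]


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """log2 fold change vs -log10 adjusted p, the data behind a volcano plot."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(results["q_wmw"].to_numpy(dtype=float))
    return pd.DataFrame({"log2fc": results["log2fc"], "neg_log10_q": neglog},
                        index=results.index)
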