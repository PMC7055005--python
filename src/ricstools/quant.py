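"""Scalar quantifications and the adaptive statistical harness.

Covers region-median intensity quantification from z-projections, the
Stokes-Einstein fold prediction for diffusion of globular complexes,
transcription/translation time arithmetic, and the normality-driven
test-selection decision tree (Shapiro-Wilk -> F/Levene -> t/ANOVA+Tukey
versus Wilcoxon/Kruskal-Wallis+Dunn).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "RegionQuant",
    "TestReport",
    "region_median_intensity",
    "stokes_einstein_fold",
    "synthesis_time",
    "select_and_run_test",
]


@dataclass
class RegionQuant:
    """Median intensities of small square regions on a z-projection."""

    region_medians: np.ndarray
    summary_median: float
    regions_px: list[tuple[int, int, int]]     # (y0, x0, size_px)


def region_median_intensity(stack: np.ndarray,
                            regions: Sequence[tuple[float, float]],
                            pixel_size: float,
                            region_size: float = 1.0) -> RegionQuant:
    """Median of small square regions on an average-intensity z-projection.

    ``regions`` are (y, x) corners in µm of squares with side ``region_size``
    µm (default 1 µm); the stack is first averaged along z, each region's
    median is taken, and the summary is the median of region medians.
    """
    stack = np.asarray(stack, dtype=float)
    proj = stack.mean(axis=0) if stack.ndim == 3 else stack
    size_px = max(int(round(region_size / pixel_size)), 1)
    if not regions:
        raise ValueError("at least one region required")
    medians, specs = [], []
    for y_um, x_um in regions:
        y0, x0 = int(round(y_um / pixel_size)), int(round(x_um / pixel_size))
        if (y0 < 0 or x0 < 0 or y0 + size_px > proj.shape[0]
                or x0 + size_px > proj.shape[1]):
            raise ValueError(f"region at ({y_um}, {x_um}) µm outside image")
        medians.append(float(np.median(proj[y0:y0 + size_px, x0:x0 + size_px])))
        specs.append((y0, x0, size_px))
    medians = np.asarray(medians)
    return RegionQuant(region_medians=medians,
                       summary_median=float(np.median(medians)),
                       regions_px=specs)


def stokes_einstein_fold(mass_ratio: float) -> float:
    """Predicted diffusion-rate fold difference between two globular species.

    Stokes-Einstein gives D proportional to 1/R_h and, for roughly spherical
    complexes, R_h proportional to mass^(1/3); a mass ratio m therefore
    predicts a diffusion fold of m^(1/3), reported to two significant
    figures (e.g. mass ratio 3 -> 1.4-fold).
    """
    if mass_ratio <= 0:
        raise ValueError("mass ratio must be positive")
    fold = mass_ratio ** (1.0 / 3.0)
    return float(np.format_float_positional(
        fold, precision=2, unique=False, fractional=False))


def synthesis_time(gene_length_kb: float, txn_rate_kb_per_min: float,
                   protein_length_aa: float, translation_rate_aa_per_s: float,
                   ) -> tuple[float, float, float]:
    """Transcription, translation, and total synthesis time in minutes.

    ``transcription = gene_length / txn_rate``;
    ``translation = protein_length / (rate * 60)``.
    """
    if txn_rate_kb_per_min <= 0 or translation_rate_aa_per_s <= 0:
        raise ValueError("rates must be positive")
    if gene_length_kb < 0 or protein_length_aa < 0:
        raise ValueError("lengths must be non-negative")
    txn = gene_length_kb / txn_rate_kb_per_min
    tln = protein_length_aa / (translation_rate_aa_per_s * 60.0)
    return (txn, tln, txn + tln)


@dataclass
class TestReport:
    """Outcome of the adaptive test-selection procedure."""

    test_name: str
    statistic: float
    p_value: float
    normality_p: tuple[float, ...]
    variance_test: Optional[str]
    variance_p: Optional[float]
    group_summaries: pd.DataFrame = field(repr=False, default=None)
    posthoc: Optional[pd.DataFrame] = field(repr=False, default=None)


def _dunn_test(groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based multiple-comparison test with tie correction and
    Bonferroni adjustment."""
    k = len(groups)
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    start, mean_ranks, sizes = 0, [], []
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    n_comp = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group1": i, "group2": j, "z": z,
                         "p_raw": p, "p_adj": min(p * n_comp, 1.0)})
    return pd.DataFrame(rows)


def select_and_run_test(groups: Sequence[Sequence[float]],
                        paired: bool = False,
                        alpha_normality: float = 0.05) -> TestReport:
    """Run the normality-driven test-selection decision tree.

    Shapiro-Wilk is applied per group at ``alpha_normality``.  If every group
    is consistent with normality, variance homogeneity is checked with an F
    test (two groups) or Levene's test (more); normal samples with equal
    variances are compared with Student's t test or one-way ANOVA with a
    Tukey HSD post-hoc, any departure from normality switches to the
    Wilcoxon rank-sum test or the Kruskal-Wallis test with a Dunn post-hoc.
    Unequal variances under normality fall back to Welch's t test (two
    groups) or the rank-based branch (more than two).
    """
    if paired:
        raise NotImplementedError("paired designs are not implemented")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("at least two groups required")
    if any(g.size < 3 for g in gs):
        raise ValueError("every group needs at least 3 observations")

    summaries = pd.DataFrame({
        "n": [g.size for g in gs],
        "mean": [g.mean() for g in gs],
        "median": [float(np.median(g)) for g in gs],
        "sd": [g.std(ddof=1) for g in gs],
    })
    norm_p = tuple(float(stats.shapiro(g).pvalue) for g in gs)
    all_normal = all(p > alpha_normality for p in norm_p)

    var_name = var_p = None
    equal_var = True
    if all_normal:
        if len(gs) == 2:
            f = gs[0].var(ddof=1) / gs[1].var(ddof=1)
            d1, d2 = gs[0].size - 1, gs[1].size - 1
            var_p = float(2.0 * min(stats.f.cdf(f, d1, d2),
                                    stats.f.sf(f, d1, d2)))
            var_name = "F"
        else:
            stat, var_p = stats.levene(*gs)
            var_p = float(var_p)
            var_name = "levene"
        equal_var = var_p > alpha_normality

    posthoc = None
    if all_normal and equal_var:
        if len(gs) == 2:
            res = stats.ttest_ind(gs[0], gs[1], equal_var=True)
            name = "student_t"
        else:
            res = stats.f_oneway(*gs)
            name = "anova"
            labels = np.concatenate([[i] * g.size for i, g in enumerate(gs)])
            tk = pairwise_tukeyhsd(np.concatenate(gs), labels)
            posthoc = pd.DataFrame(tk.summary().data[1:],
                                   columns=tk.summary().data[0])
        stat, p = float(res.statistic), float(res.pvalue)
    elif all_normal and len(gs) == 2:
        res = stats.ttest_ind(gs[0], gs[1], equal_var=False)
        name = "welch_t"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if len(gs) == 2:
            res = stats.ranksums(gs[0], gs[1])
            name = "wilcoxon_ranksum"
        else:
            res = stats.kruskal(*gs)
            name = "kruskal_wallis"
            posthoc = _dunn_test(gs)
        stat, p = float(res.statistic), float(res.pvalue)

    return TestReport(test_name=name, statistic=stat, p_value=p,
                      normality_p=norm_p, variance_test=var_name,
                      variance_p=var_p, group_summaries=summaries,
                      posthoc=posthoc)
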