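"""Univariate FC feature screening.

Two screens run on the training split only: a Spearman rank-correlation
screen of every FC feature against each clinical metric (ten alcohol-use
severities plus eight ASR psychiatric scores), and a Wilcoxon rank-sum
screen of case vs. control group differences.  A feature passes the
Spearman screen when it correlates with *one or more* metrics at the
chosen alpha (minimum p across metrics, no cross-metric correction —
union semantics).  The two screens are combined by elementwise OR.

The alpha sweep {0.05, 0.005, 0.0005} produces nested masks feeding the
downstream 9-cell (alpha x UMAP-dimension) biotyping grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

ALCOHOL_METRICS = (
    "12DrinksPerDay",
    "12Frq",
    "12Frq5plus",
    "12FrqDrk",
    "12MaxDrinks",
    "HvyDrinksPerDay",
    "HvyFrq",
    "HvyFrq5plus",
    "HvyFrqDrk",
    "HvyMaxDrinks",
)
ASR_SCORES = (
    "Depression",
    "Anxiety",
    "Somatic",
    "Avoidant",
    "ADHD",
    "Inattention",
    "Hyperactivity",
    "Antisocial",
)
METRIC_COLUMNS = ALCOHOL_METRICS + ASR_SCORES

DEFAULT_ALPHAS = (0.05, 0.005, 0.0005)


@dataclass(frozen=True)
class FeatureMask:
    """Boolean selection over FC features with its provenance."""

    selected: np.ndarray
    alpha: float
    provenance: str  # "spearman" | "wilcoxon" | "union"

    def __post_init__(self) -> None:
        object.__setattr__(self, "selected", np.asarray(self.selected, dtype=bool))

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def __len__(self) -> int:
        return len(self.selected)


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Average-tie ranks of every column."""
    return np.apply_along_axis(stats.rankdata, 0, x)


def spearman_pvalues(fc: np.ndarray, metrics: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p for every feature-metric pair.

    Vectorized: Pearson correlation of average ranks, p from the exact-df
    t approximation (the standard large-sample Spearman p-value).
    Returns (rho, p), each features x metrics.  Constant columns yield
    rho = nan, p = nan.
    """
    fc = np.asarray(fc, dtype=float)
    metrics = np.asarray(metrics, dtype=float)
    n = fc.shape[0]
    if metrics.shape[0] != n:
        raise ValueError("FC panel and metric table must have equal subject counts")
    rf = _rank_columns(fc)
    rm = _rank_columns(metrics)
    rf_c = rf - rf.mean(axis=0)
    rm_c = rm - rm.mean(axis=0)
    denom = np.sqrt(np.outer((rf_c**2).sum(axis=0), (rm_c**2).sum(axis=0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rf_c.T @ rm_c) / denom
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    return rho, p


def spearman_screen(fc: np.ndarray, metrics: np.ndarray, alpha: float) -> FeatureMask:
    """Select features rank-correlated with at least one clinical metric.

    A feature is kept iff its minimum two-sided Spearman p across the
    metric columns is below ``alpha``.  Constant features have undefined
    correlations and are never selected (a warning is emitted).
    """
    _, p = spearman_pvalues(fc, metrics)
    all_nan = np.isnan(p).all(axis=1)
    if all_nan.any():
        warnings.warn(
            f"{int(all_nan.sum())} constant feature(s) have undefined Spearman p; not selected",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        min_p = np.nanmin(np.where(np.isnan(p), np.inf, p), axis=1)
    return FeatureMask(selected=min_p < alpha, alpha=alpha, provenance="spearman")


def wilcoxon_pvalues(
    fc: np.ndarray, group_labels: np.ndarray, exact_max_n: int = 20
) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per feature for case vs control.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` subjects, else the tie-corrected normal
    approximation with continuity correction.
    """
    fc = np.asarray(fc, dtype=float)
    labels = np.asarray(group_labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be non-empty for the rank-sum screen")
    method = "exact" if max(n1, n0) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(
        fc[labels], fc[~labels], axis=0, alternative="two-sided", method=method
    )
    return np.asarray(res.pvalue)


def wilcoxon_screen(fc: np.ndarray, group_labels: np.ndarray, alpha: float) -> FeatureMask:
    """Select features whose distributions differ between cases and controls."""
    p = wilcoxon_pvalues(fc, group_labels)
    return FeatureMask(selected=p < alpha, alpha=alpha, provenance="wilcoxon")


def union_mask(a: FeatureMask, b: FeatureMask) -> FeatureMask:
    """Elementwise OR of two screens over the same panel."""
    if len(a) != len(b):
        raise ValueError("feature masks cover panels of different widths")
    alpha = a.alpha if a.alpha == b.alpha else max(a.alpha, b.alpha)
    return FeatureMask(selected=a.selected | b.selected, alpha=alpha, provenance="union")


def screen_features(
    fc: np.ndarray,
    metrics: np.ndarray,
    group_labels: np.ndarray,
    alpha: float,
    spearman_population: str = "all",
) -> FeatureMask:
    """Run both screens at one alpha and return their union.

    ``spearman_population`` selects whether the rank-correlation screen
    uses all training subjects (controls carry alcohol metrics too) or
    cases only.
    """
    if spearman_population not in ("all", "am"):
        raise ValueError("spearman_population must be 'all' or 'am'")
    if spearman_population == "am":
        sub = np.asarray(group_labels).astype(bool)
        sp = spearman_screen(fc[sub], np.asarray(metrics)[sub], alpha)
    else:
        sp = spearman_screen(fc, metrics, alpha)
    wx = wilcoxon_screen(fc, group_labels, alpha)
    return union_mask(sp, wx)
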