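"""Group-comparison statistics and reporting utilities.

Implements the declared toolkit: Pearson chi-squared homogeneity tests on
raw count tables (percentages are refused), Wilcoxon rank-sum with exact
small-sample enumeration, the unpaired two-tailed t-test, Bonferroni-Holm
step-down adjustment, significance stars, the regulon specificity score
(1 - sqrt of the base-2 Jensen-Shannon divergence), and the caliper
tumor-volume formula V = d^2 * D / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import jensenshannon

from .errors import ConfigError, InvariantError

__all__ = [
    "TestResult",
    "chi_squared_composition",
    "wilcoxon_rank_sum",
    "t_test_unpaired",
    "holm_adjust",
    "stars",
    "regulon_specificity_score",
    "tumor_volume",
]

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    """Significance label: p<1e-4 '****', <1e-3 '***', <0.01 '**', <0.05 '*',
    else 'ns' (strict inequalities)."""
    if not 0.0 <= p <= 1.0:
        raise InvariantError(f"p-value {p} outside [0,1]")
    for thr, label in _STAR_THRESHOLDS:
        if p < thr:
            return label
    return "ns"


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    df: Optional[float] = None
    p_adj: Optional[float] = None
    warnings: Sequence[str] = ()

    @property
    def stars(self) -> str:
        return stars(self.p_adj if self.p_adj is not None else self.p)


def chi_squared_composition(
    table, continuity_correction: bool = False
) -> TestResult:
    """Pearson chi-squared homogeneity test on an r x c table of raw counts.

    Expected counts come from the row/column margins; df = (r-1)(c-1).
    Raises on fractional input (the test is invalid on percentages) and on
    zero expected counts; attaches a warning when any expected count is < 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ConfigError("chi-squared requires an r x c table with r,c >= 2")
    if np.any(obs < 0):
        raise ConfigError("counts must be non-negative")
    if not np.allclose(obs, np.round(obs)):
        raise ConfigError(
            "table does not look like raw counts (fractional entries); "
            "chi-squared on percentages is invalid"
        )
    total = obs.sum()
    if total <= 0:
        raise ConfigError("grand total must be positive")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ConfigError("a zero expected count makes the test undefined")
    warns: List[str] = []
    if np.any(expected < 5):
        warns.append("some expected counts are < 5; the chi-squared "
                     "approximation may be poor")
    diff = np.abs(obs - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult("chi_squared", stat, p, df=df, warnings=tuple(warns))


def wilcoxon_rank_sum(x, y, exact_max_n: int = 8) -> TestResult:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    When both samples have at most ``exact_max_n`` observations and there are
    no ties, the two-sided p-value is computed by full enumeration of rank
    assignments (P(|W - mu| >= |w - mu|)); otherwise the normal approximation
    with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = float(ranks[:nx].sum())
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if np.all(combined == combined[0]):
        warnings.warn("all values identical across both samples", UserWarning,
                      stacklevel=2)
        return TestResult("wilcoxon_rank_sum", w, 1.0)

    if nx <= exact_max_n and ny <= exact_max_n and not has_ties:
        obs_dev = abs(w - mu)
        hits = 0
        for subset in combinations(range(1, n + 1), nx):
            if abs(sum(subset) - mu) >= obs_dev - 1e-12:
                hits += 1
        p = hits / comb(n, nx)
        return TestResult("wilcoxon_rank_sum_exact", w, float(min(p, 1.0)))

    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        warnings.warn("zero rank variance; p set to 1", UserWarning, stacklevel=2)
        return TestResult("wilcoxon_rank_sum", w, 1.0)
    z = (w - mu) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult("wilcoxon_rank_sum", w, p)


def t_test_unpaired(x, y, welch: bool = False) -> TestResult:
    """Unpaired two-tailed t-test (classic pooled variance by default,
    Welch by flag)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ConfigError("each arm needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult("t_test_unpaired", 0.0, 1.0,
                              df=float(x.size + y.size - 2))
        raise ConfigError("zero variance in both arms with unequal means")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(x.size + y.size - 2)
    return TestResult("t_test_welch" if welch else "t_test_unpaired",
                      float(res.statistic), float(res.pvalue), df=df)


def holm_adjust(pvals: Sequence[float]) -> List[float]:
    """Bonferroni-Holm step-down adjustment, returned in input order.

    Sorted ascending, p_(i) is multiplied by (m - i + 1); a running maximum
    enforces monotonicity and values are capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj.tolist()


def regulon_specificity_score(
    activity: pd.DataFrame, labels: Sequence[str]
) -> pd.DataFrame:
    """Regulon x label specificity: RSS = 1 - sqrt(JSD(p_activity, p_label)).

    ``activity`` is a regulon x cell matrix of non-negative activities;
    ``labels`` gives one group label per cell (column).  Each regulon's
    activity vector is normalised to a distribution over cells and compared
    to the indicator distribution of each label using the Jensen-Shannon
    divergence with base-2 logs (so the divergence, and hence RSS, lies in
    [0,1]).  Regulons whose activity is all zero get NaN.
    """
    act = activity.to_numpy(dtype=float)
    if np.any(act < 0):
        raise InvariantError("activities must be non-negative")
    labels = np.asarray(labels)
    if labels.size != act.shape[1]:
        raise ConfigError("one label per cell column is required")
    unique_labels = sorted(set(labels.tolist()))
    out = np.full((act.shape[0], len(unique_labels)), np.nan)
    totals = act.sum(axis=1)
    for i in range(act.shape[0]):
        if totals[i] == 0:
            continue
        p = act[i] / totals[i]
        for j, lab in enumerate(unique_labels):
            q = (labels == lab).astype(float)
            q /= q.sum()
            # scipy returns the JS *distance*, i.e. sqrt of the divergence
            out[i, j] = 1.0 - float(jensenshannon(p, q, base=2))
    return pd.DataFrame(out, index=activity.index, columns=unique_labels)


def tumor_volume(d: float, D: float) -> float:
    """Caliper volume V = d^2 * D / 2 (d = shortest, D = longest diameter)."""
    if d <= 0 or D <= 0:
        raise ConfigError("diameters must be positive")
    if d > D:
        raise ConfigError("shortest diameter exceeds longest (swapped inputs?)")
    return d * d * D / 2.0
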