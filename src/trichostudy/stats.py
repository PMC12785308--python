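"""Diagnostic-accuracy estimation and group comparison.

Accuracy is the proportion of correct evaluations (pooled over raters and
cases) with a Wilson score 95% confidence interval.  Groups are compared
with Pearson's chi-square on the correct/incorrect x group table, replaced
by Fisher's exact test (exact for 2x2, seeded Monte-Carlo otherwise) when
any expected cell falls below 5 (Cochran's rule).  Significant omnibus
tests are followed by all pairwise 2x2 comparisons with Holm-Bonferroni
step-down adjustment.

Evaluations are treated as independent — no clustering by rater or case —
which matches how reader studies of this design are conventionally
summarised; see the methods note for the implied caveats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .scoring import CorrectnessMatrix


@dataclass(frozen=True)
class AccuracyResult:
    """Correct count k of n evaluations with a Wilson score interval."""

    label: str
    mode: str
    k: int
    n: int
    proportion: float
    ci_lower: float
    ci_upper: float
    ci_level: float = 0.95


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    table: tuple[tuple[int, int], tuple[int, int]]
    test: str
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class ComparisonResult:
    """Omnibus test over >= 2 groups plus optional Holm-adjusted post hocs."""

    groups: tuple[str, ...]
    table: tuple[tuple[int, int], ...]  # (correct, incorrect) per group
    test: str                           # chi_square | fisher | fisher_mc
    statistic: float | None
    df: int | None
    p_value: float
    pairwise: tuple[PairwiseComparison, ...] = ()


# ---------------------------------------------------------------------------
# proportion CIs
# ---------------------------------------------------------------------------

def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Centre (p + z^2/2n) / (1 + z^2/n), half-width
    z sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n); the interval obtained by
    inverting the score test, well behaved at small n and extreme p.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = sps.norm.ppf(1 - (1 - level) / 2)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    # the score interval hits the boundary exactly at k = 0 / k = n
    lower = 0.0 if k == 0 else max(float(centre - half), 0.0)
    upper = 1.0 if k == n else min(float(centre + half), 1.0)
    return (lower, upper)


def accuracy(matrix: CorrectnessMatrix, groups: str | Sequence[str] | None = None,
             rater: str | None = None, label: str | None = None,
             mode: str = "", level: float = 0.95) -> AccuracyResult:
    """Pooled proportion correct over a selection of the matrix.

    ``groups`` selects one group or a list of groups to pool; ``rater``
    selects a single rater; neither selects everything.  Missing cells are
    excluded from the denominator.
    """
    if groups is not None and rater is not None:
        raise ValueError("select by groups or by rater, not both")
    if rater is not None:
        if rater not in matrix.rater_ids:
            raise KeyError(f"unknown rater {rater!r}")
        raters = [rater]
        default_label = rater
    elif groups is not None:
        raters = matrix.raters_in(groups)
        default_label = groups if isinstance(groups, str) else "+".join(groups)
    else:
        raters = None
        default_label = "all"
    k, n = matrix.counts(raters)
    if n == 0:
        raise ValueError(f"selection {default_label!r} contains no evaluations")
    lo, hi = wilson_ci(k, n, level)
    return AccuracyResult(label=label or default_label, mode=mode, k=k, n=n,
                          proportion=k / n, ci_lower=lo, ci_upper=hi,
                          ci_level=level)


# ---------------------------------------------------------------------------
# contingency tests
# ---------------------------------------------------------------------------

def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ValueError("table must be at least 2 x 2")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    res = sps.chi2_contingency(tab, correction=False)
    expected = res.expected_freq
    if (expected <= 0).any():
        raise ValueError("all expected counts must be positive")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def expected_counts(table) -> np.ndarray:
    tab = np.asarray(table, dtype=float)
    return np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric enumeration)."""
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("table must be 2 x 2 with nonnegative integer counts")
    return float(sps.fisher_exact(tab, alternative="two-sided")[1])


def _log_table_prob(tab: np.ndarray) -> float:
    # probability of an r x c table under fixed margins (multiv. hypergeometric)
    tab = np.asarray(tab, dtype=float)
    return float(gammaln(tab.sum(axis=1) + 1).sum()
                 + gammaln(tab.sum(axis=0) + 1).sum()
                 - gammaln(tab.sum() + 1)
                 - gammaln(tab + 1).sum())


def fisher_monte_carlo(table, n_samples: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo Fisher exact test for an r x c table with fixed margins.

    Samples tables from the fixed-margin null and counts those no more
    probable than the observed one; p = (1 + #extreme) / (1 + n_samples).
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2 or (tab < 0).any():
        raise ValueError("table must be a nonnegative integer matrix")
    rng = np.random.default_rng(seed)
    dist = sps.random_table(tab.sum(axis=1), tab.sum(axis=0))
    samples = dist.rvs(n_samples, random_state=rng)
    logp_obs = _log_table_prob(tab)
    logp = (gammaln(tab.sum(axis=1) + 1).sum()
            + gammaln(tab.sum(axis=0) + 1).sum()
            - gammaln(tab.sum() + 1)
            - gammaln(samples + 1).sum(axis=(1, 2)))
    extreme = int((logp <= logp_obs + 1e-9).sum())
    return (1 + extreme) / (1 + n_samples)


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjustment, returned in input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce a running
    maximum so the adjusted values are monotone, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min((m - rank) * p[idx], 1.0))
        adjusted[idx] = running
    return adjusted.tolist()


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def _correct_incorrect_table(matrix: CorrectnessMatrix,
                             groups: Sequence[str],
                             grouping: Mapping[str, str] | None):
    labels: list[str] = []
    rows: list[tuple[int, int]] = []
    if grouping:
        pooled: dict[str, list[str]] = {}
        for g in groups:
            pooled.setdefault(grouping.get(g, g), []).append(g)
        for label, members in pooled.items():
            k, n = matrix.counts(matrix.raters_in(members))
            labels.append(label)
            rows.append((k, n - k))
    else:
        for g in groups:
            k, n = matrix.counts(matrix.raters_in(g))
            labels.append(g)
            rows.append((k, n - k))
    return labels, rows


def compare_groups(matrix: CorrectnessMatrix,
                   groups: Sequence[str] | None = None,
                   grouping: Mapping[str, str] | None = None,
                   alpha: float = 0.05,
                   mc_samples: int = 100_000,
                   seed: int = 0) -> ComparisonResult:
    """Omnibus comparison of per-group accuracy, with Holm post hocs.

    ``groups`` restricts/orders the groups compared (default: all groups in
    the matrix); ``grouping`` optionally pools them under coarser labels
    (e.g. the three dermatologist groups into one).  The omnibus test is
    Pearson chi-square unless any expected cell is below 5, in which case
    Fisher's exact test is used (Monte-Carlo with ``mc_samples`` seeded
    tables beyond 2x2).  If the omnibus p is below ``alpha``, every pair is
    tested the same way and the p-values are Holm-adjusted.
    """
    if groups is None:
        groups = list(dict.fromkeys(matrix.groups))
    labels, rows = _correct_incorrect_table(matrix, groups, grouping)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups to compare")
    for label, (k, wrong) in zip(labels, rows):
        if k + wrong == 0:
            raise ValueError(f"group {label!r} has no evaluations")
    tab = np.asarray(rows, dtype=int)

    def one_test(t, tag):
        if (expected_counts(t) >= 5).all():
            stat, df, p = pearson_chi2(t)
            return "chi_square", stat, df, p
        if t.shape == (2, 2):
            return "fisher", None, None, fisher_exact_2x2(t)
        p = fisher_monte_carlo(t, mc_samples, seed=seed if tag is None else seed + tag)
        return "fisher_mc", None, None, p

    test, stat, df, p = one_test(tab, None)

    pairwise: list[PairwiseComparison] = []
    if p < alpha and len(labels) > 2:
        pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
        raw = []
        meta = []
        for i, j in pairs:
            sub = tab[[i, j]]
            t_name, _, _, p_pair = one_test(sub, None)
            raw.append(p_pair)
            meta.append((labels[i], labels[j], sub, t_name))
        adj = holm_adjust(raw)
        for (a, b, sub, t_name), pr, pa in zip(meta, raw, adj):
            pairwise.append(PairwiseComparison(
                group_a=a, group_b=b,
                table=tuple(map(tuple, sub.tolist())),
                test=t_name, p_raw=float(pr), p_adjusted=float(pa)))
    return ComparisonResult(
        groups=tuple(labels), table=tuple(map(tuple, tab.tolist())),
        test=test, statistic=stat, df=df, p_value=float(p),
        pairwise=tuple(pairwise))
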