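"""Gwet's AC1 inter-rater agreement for binary correctness ratings.

AC1 corrects observed agreement for chance with p_e = 2 pi (1 - pi), where
pi is the mean prevalence of the "correct" rating across items.  Unlike
Cohen's or Fleiss' kappa it stays stable when prevalence is skewed — the
usual situation when most raters get most cases right (or wrong).

The multi-rater form with missing ratings: for item i rated by r_i >= 2
raters of whom r_i1 rated "correct",

    item agreement a_i = sum_k r_ik (r_ik - 1) / (r_i (r_i - 1)),
    p_a = mean a_i,   pi = mean (r_i1 / r_i),   over items with r_i >= 2,
    AC1 = (p_a - p_e) / (1 - p_e),   p_e = 2 pi (1 - pi).

Standard errors come from a leave-one-item-out jackknife, which needs no
distributional assumptions and handles unequal r_i naturally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import CorrectnessMatrix

#: interpretation bands, upper bound inclusive
_BANDS = ((0.20, "slight"), (0.40, "fair"), (0.60, "moderate"),
          (0.80, "good"), (1.0, "very good"))


@dataclass(frozen=True)
class AgreementResult:
    """AC1 with its ingredients, jackknife SE, CI and interpretation band."""

    label: str
    n_raters: int
    n_items: int
    observed_agreement: float
    prevalence: float
    chance_agreement: float
    ac1: float
    se: float
    ci_lower: float
    ci_upper: float
    category: str
    ci_level: float = 0.95


def categorize_ac1(value: float) -> str:
    """Map an AC1 value to its interpretation band.

    Bands: < 0 poor, 0-0.20 slight, 0.21-0.40 fair, 0.41-0.60 moderate,
    0.61-0.80 good, 0.81-1 very good (each upper bound inclusive).
    """
    if value > 1:
        raise ValueError("AC1 cannot exceed 1")
    if value < 0:
        return "poor"
    for upper, name in _BANDS:
        if value <= upper:
            return name
    return "very good"


def _item_stats(values: np.ndarray):
    """Per-item agreement a_i and correct-fraction q_i for items with >= 2 ratings."""
    present = np.isfinite(values)
    r = present.sum(axis=0)
    keep = r >= 2
    r = r[keep].astype(float)
    ones = np.nansum(values[:, keep], axis=0)
    zeros = r - ones
    a = (ones * (ones - 1) + zeros * (zeros - 1)) / (r * (r - 1))
    q = ones / r
    return a, q


def _ac1_from_items(a: np.ndarray, q: np.ndarray) -> tuple[float, float, float, float]:
    p_a = float(a.mean())
    pi = float(q.mean())
    p_e = 2 * pi * (1 - pi)
    if p_e >= 1.0:  # unreachable for pi in [0,1]: max p_e = 0.5
        raise ZeroDivisionError
    ac1 = (p_a - p_e) / (1 - p_e)
    return p_a, pi, p_e, ac1


def gwet_ac1(matrix: CorrectnessMatrix | pd.DataFrame,
             raters: Sequence[str] | None = None,
             label: str = "all", level: float = 0.95) -> AgreementResult:
    """Multi-rater AC1 on a correctness matrix, missing ratings allowed.

    Items (cases) rated by fewer than 2 of the selected raters are
    excluded; at least 2 items must remain.  The CI is AC1 +/- z * SE
    (jackknife over items), truncated to [-1, 1].
    """
    values = matrix.values if isinstance(matrix, CorrectnessMatrix) else matrix
    if raters is not None:
        values = values.loc[list(raters)]
    arr = values.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("AC1 needs at least 2 raters")
    a, q = _item_stats(arr)
    m = len(a)
    if m < 2:
        raise ValueError("fewer than 2 items have ratings from >= 2 raters")
    p_a, pi, p_e, ac1 = _ac1_from_items(a, q)

    # leave-one-item-out jackknife
    loo = np.empty(m)
    sum_a, sum_q = a.sum(), q.sum()
    for i in range(m):
        p_a_i = (sum_a - a[i]) / (m - 1)
        pi_i = (sum_q - q[i]) / (m - 1)
        p_e_i = 2 * pi_i * (1 - pi_i)
        loo[i] = (p_a_i - p_e_i) / (1 - p_e_i)
    se = float(np.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum()))
    z = sps.norm.ppf(1 - (1 - level) / 2)
    lo = max(ac1 - z * se, -1.0)
    hi = min(ac1 + z * se, 1.0)
    return AgreementResult(
        label=label, n_raters=arr.shape[0], n_items=m,
        observed_agreement=p_a, prevalence=pi, chance_agreement=p_e,
        ac1=float(ac1), se=se, ci_lower=float(lo), ci_upper=float(hi),
        category=categorize_ac1(float(ac1)), ci_level=level)


def majority_vote(matrix: CorrectnessMatrix, raters: Sequence[str]) -> pd.Series:
    """Per-case majority correctness over a rater subset; ties count incorrect.

    Cases with no ratings from the subset are missing.
    """
    sub = matrix.values.loc[list(raters)]
    n = sub.notna().sum(axis=0)
    ones = sub.sum(axis=0, skipna=True)
    out = (ones > n / 2).astype(float)
    out[n == 0] = np.nan
    return out


def between_group_agreement(matrix: CorrectnessMatrix,
                            grouping: Mapping[str, Sequence[str]] | None = None,
                            label: str = "between_groups",
                            level: float = 0.95) -> AgreementResult:
    """AC1 between groups, each collapsed to a majority-vote pseudo-rater.

    ``grouping`` maps pseudo-rater labels to lists of group labels (default:
    every group in the matrix becomes one pseudo-rater).  Ties within a
    group count as incorrect.
    """
    if grouping is None:
        grouping = {g: [g] for g in dict.fromkeys(matrix.groups)}
    if len(grouping) < 2:
        raise ValueError("need at least 2 groups")
    rows = {}
    for name, members in grouping.items():
        rows[name] = majority_vote(matrix, matrix.raters_in(list(members)))
    pseudo = pd.DataFrame(rows).T
    pseudo_matrix = CorrectnessMatrix(pseudo, pd.Series({n: n for n in rows}))
    return gwet_ac1(pseudo_matrix, label=label, level=level)
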