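"""Post-prediction utilities: per-drug ranking of unmeasured cell lines and
mutated-vs-wild-type group comparison by the Wilcoxon rank-sum test.

After fitting on all known responses, the predicted grid R̂ = ABᵀ covers
drug/cell-line pairs that were never measured.  ``rank_unmeasured`` orders
those pairs most-sensitive-first for a drug; ``ranksum_compare`` tests
whether two groups of responses (e.g. cell lines carrying a mutation versus
wild type) differ in location, using exact enumeration of the rank-sum
distribution for small samples and a tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .similarity import ValidationError
from .solver import ResponseMatrix

__all__ = ["GroupComparison", "rank_unmeasured", "ranksum_compare"]

logger = logging.getLogger(__name__)

# exact enumeration of the rank-sum null up to this pooled size
EXACT_MAX_N = 20


def rank_unmeasured(
    rm: ResponseMatrix,
    R_hat: pd.DataFrame | np.ndarray,
    drug_id: str,
    top_n: int = 20,
    orientation: Literal["lower", "higher"] = "lower",
) -> list[str]:
    """Unmeasured cell lines for one drug, most-sensitive-first.

    Only cell lines with no observed response for ``drug_id`` are ranked,
    by predicted response under the declared orientation (``"lower"``:
    smaller predictions are more sensitive, IC50 semantics).  At most
    ``top_n`` identifiers are returned; a fully observed drug yields an
    empty list with a logged notice.
    """
    if drug_id not in rm.drug_ids:
        raise ValidationError(f"unknown drug {drug_id!r}")
    i = rm.drug_ids.index(drug_id)
    grid = R_hat.to_numpy() if isinstance(R_hat, pd.DataFrame) else np.asarray(R_hat)
    if grid.shape != rm.shape:
        raise ValidationError(
            f"predicted grid {grid.shape} does not match responses {rm.shape}"
        )
    unobserved = np.nonzero(rm.W[i] == 0)[0]
    if unobserved.size == 0:
        logger.info("drug %s is fully observed; nothing to rank", drug_id)
        return []
    preds = grid[i, unobserved]
    sign = 1.0 if orientation == "lower" else -1.0
    order = sorted(range(len(unobserved)), key=lambda t: (sign * preds[t], t))
    ranked = [rm.cell_ids[unobserved[t]] for t in order]
    return ranked[:top_n]


@dataclass
class GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two response groups."""

    group_a_values: np.ndarray
    group_b_values: np.ndarray
    statistic: float  # sum of pooled midranks over group A
    p_value: float
    method: str = "exact"


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """P(|W − μ| ≥ |w_obs − μ|) by dynamic programming over subset rank sums.

    Works on doubled midranks so all sums are integers; enumerates the
    distribution of the rank sum of a uniformly random n_a-subset of the
    pooled ranks (the permutation null, valid with ties).
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    # dp[j][s] = number of j-subsets with doubled-rank sum s
    dp = np.zeros((n_a + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        for j in range(min(n_a, len(r2)), 0, -1):
            dp[j, r:] += dp[j - 1, : total + 1 - r]
    counts = dp[n_a]
    n_total = counts.sum()
    mu2 = 2 * n_a * (len(ranks) + 1) / 2.0
    dev = abs(2 * w_obs - mu2) - 1e-9
    sums = np.arange(total + 1)
    extreme = counts[np.abs(sums - mu2) >= dev].sum()
    return float(min(1.0, extreme / n_total))


def _approx_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = len(ranks)
    n_b = n - n_a
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def ranksum_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test with midrank ties.

    For pooled sample sizes up to 20 the p-value is exact (full enumeration
    of the permutation null); above that a normal approximation with tie
    and continuity corrections is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if a.size + b.size < 3:
        raise ValidationError("combined sample size must be at least 3")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[: a.size].sum())
    if pooled.size <= EXACT_MAX_N:
        p = _exact_ranksum_p(ranks, a.size, w)
        method = "exact"
    else:
        p = _approx_ranksum_p(ranks, a.size, w)
        method = "normal-approx"
    p = max(p, np.nextafter(0, 1))
    return GroupComparison(a, b, statistic=w, p_value=p, method=method)
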