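"""Statistical layer: rank-sum test, paired t, and 95% CI summaries.

Small-cohort embryo comparisons (typically 5-14 embryos per group) call
for an exact Mann-Whitney test: with n1+n2 <= 12 all C(n1+n2, n1) group
assignments are enumerated, which is an exact permutation test whether
or not the data contain ties. Larger samples use the normal
approximation with tie-corrected variance and continuity correction.
Two-sided exact p-values follow the doubling convention
p = min(1, 2 * min(lower tail, upper tail)) — conventions differ across
software, so this one is stated explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInput, ParameterError

EXACT_LIMIT = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    two_sided: bool


def mann_whitney(
    sample_a, sample_b, two_sided: bool = True, exact_limit: int = EXACT_LIMIT
) -> TestResult:
    """Mann-Whitney-Wilcoxon rank-sum test.

    The statistic is U for ``sample_a`` computed with midranks. The
    one-sided alternative is "a tends larger than b" (upper tail of U).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must contain at least one observation")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    if n1 + n2 <= exact_limit:
        p = _exact_p(ranks, n1, u_obs, two_sided)
        method = "mann_whitney_exact"
    else:
        p = _normal_p(pooled, ranks, n1, n2, u_obs, two_sided)
        method = "mann_whitney_normal"
    return TestResult(
        statistic=u_obs, p_value=p, method=method, n1=n1, n2=n2, two_sided=two_sided
    )


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float, two_sided: bool) -> float:
    n = ranks.size
    offset = n1 * (n1 + 1) / 2
    total = comb(n, n1)
    lo = hi = 0
    eps = 1e-9
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + eps:
            lo += 1
        if u >= u_obs - eps:
            hi += 1
    p_lo, p_hi = lo / total, hi / total
    if two_sided:
        return min(1.0, 2.0 * min(p_lo, p_hi))
    return p_hi


def _normal_p(
    pooled: np.ndarray,
    ranks: np.ndarray,
    n1: int,
    n2: int,
    u_obs: float,
    two_sided: bool,
) -> float:
    n = n1 + n2
    mean = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise DegenerateInput("all pooled observations identical")
    # continuity correction toward the mean
    z = (u_obs - mean - 0.5 * np.sign(u_obs - mean)) / np.sqrt(var)
    if two_sided:
        return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return float(sps.norm.sf(z))


def paired_t(sample_a, sample_b=None, two_sided: bool = True) -> TestResult:
    """Paired t-test; pass two paired samples or one array of differences."""
    a = np.asarray(sample_a, dtype=float)
    d = a if sample_b is None else a - np.asarray(sample_b, dtype=float)
    n = d.size
    if n < 2:
        raise ParameterError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInput("all paired differences identical; t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    if two_sided:
        p = float(2.0 * sps.t.sf(abs(t), n - 1))
    else:
        p = float(sps.t.sf(t, n - 1))
    return TestResult(
        statistic=t, p_value=min(1.0, p), method="paired_t",
        n1=n, n2=n, two_sided=two_sided,
    )


def summarize_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a Student-t confidence interval: mean +/- t * sd / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("need at least 2 values for a CI")
    mean = float(v.mean())
    half = float(
        sps.t.ppf(0.5 + level / 2, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    )
    return mean, mean - half, mean + half
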