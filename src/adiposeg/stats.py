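"""Cohort-level statistical support: power/sample-size and rank correlation.

The sample-size routine answers the planning question "how many subjects per
group are needed for a two-sided, two-sample t test to detect a given
relative difference in mean fat volume": the effect size is
d = relative_difference * ref_mean / ref_sd, and power is computed from the
noncentral t distribution (noncentrality d * sqrt(n/2), 2n - 2 degrees of
freedom), iterating n upward to the smallest sufficient integer.  The normal
approximation can come out one subject lower, so the exact noncentral-t
route is used.

Spearman's rho is the Pearson correlation of mid-ranks; its two-sided p
comes from exact permutation enumeration for n <= 9 and from the usual
t approximation above that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sp_stats

from .core_io import AdiposegError, InsufficientDataError

EXACT_PERMUTATION_MAX_N = 9


class UndefinedCorrelationError(AdiposegError):
    """Correlation is undefined for a constant input vector."""


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the two-sample sample-size calculation (volumes in mL)."""

    ref_mean: float
    ref_sd: float
    relative_difference: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.ref_sd <= 0:
            raise ValueError(f"ref_sd must be > 0, got {self.ref_sd}")
        if self.relative_difference <= 0:
            raise ValueError("relative_difference must be > 0")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0, 1), got {self.power}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def effect_size(self) -> float:
        return self.relative_difference * self.ref_mean / self.ref_sd


def power_two_sample(n: int, effect_size: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t test with n per group (equal SDs)."""
    df = 2 * n - 2
    nc = effect_size * math.sqrt(n / 2.0)
    tcrit = sp_stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - sp_stats.nct.cdf(tcrit, df, nc)
                 + sp_stats.nct.cdf(-tcrit, df, nc))


def sample_size_two_sample(spec: PowerSpec, n_max: int = 10 ** 6) -> int:
    """Smallest per-group n reaching the requested power.

    Raises :class:`OverflowError` if the effect is so small that more than
    ``n_max`` subjects per group would be needed.
    """
    d = spec.effect_size
    if power_two_sample(2, d, spec.alpha) >= spec.power:
        return 2
    # power is monotone in n: bracket by doubling, then bisect
    lo, hi = 2, 4
    while power_two_sample(hi, d, spec.alpha) < spec.power:
        lo, hi = hi, hi * 2
        if lo > n_max:
            raise OverflowError(
                f"required sample size exceeds {n_max} per group for "
                f"effect size {d:.4g}"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_two_sample(mid, d, spec.alpha) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


def _rank_rho(xr: np.ndarray, yr: np.ndarray) -> float:
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    den = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc) / den


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with a tie-aware mid-rank rho.

    Two-sided p-value: exact enumeration over all n! orderings for n <= 9
    (counting |rho_perm| >= |rho_obs|), t approximation with n - 2 degrees
    of freedom otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be equal-length 1-D series")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for constant input")

    xr = sp_stats.rankdata(x)
    yr = sp_stats.rankdata(y)
    rho = _rank_rho(xr, yr)

    if n <= EXACT_PERMUTATION_MAX_N:
        perms = np.array(list(permutations(yr)))
        xc = xr - xr.mean()
        yc = perms - yr.mean()
        den = math.sqrt(float(xc @ xc) * float((yr - yr.mean()) @ (yr - yr.mean())))
        rhos = (yc @ xc) / den
        p = float(np.count_nonzero(np.abs(rhos) >= abs(rho) - 1e-12) / len(rhos))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sp_stats.t.sf(abs(t), n - 2))
    return SpearmanResult(rho=rho, p_value=min(p, 1.0), n=n)
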