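"""Ground-truth and baseline mid-p computations.

Three references against which the saddlepoint approximation is judged:

* :func:`exact_midp` — full enumeration of all 2^n equally likely sign
  assignments (integer counting, order-independent);
* :func:`montecarlo_midp` — seeded Monte-Carlo permutation sampling with
  a binomial standard error;
* :func:`normal_midp` — the asymptotic bivariate-normal approximation
  with null covariance (1/4) sum_i U_i U_i^T.

All three share the tail semantics of the saddlepoint module: the
default ``cdf`` convention measures the lower-orthant event {b1 < tau,
b2 < upsilon} plus half the joint-tie mass, and ``quadrant`` the
upper-orthant analogue (by default after reflecting coordinates so both
observed components are non-negative).  Under the antipodal symmetry of
the permutation law the two describe the same family of events with the
data sign flipped.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr
from scipy.stats import multivariate_normal

from .saddlepoint import MidPResult, resolve_orient
from .scores import ObservedStatistic, ScoreSystem, evaluate_statistic, orient_scores

__all__ = [
    "GaussianNull",
    "bvn_cdf",
    "normal_midp",
    "exact_midp",
    "montecarlo_midp",
    "EXACT_ENUMERATION_GUARD",
    "TIE_RULES",
]

#: Largest n for which exact 2^n enumeration is attempted (~3.4e7 evaluations).
EXACT_ENUMERATION_GUARD = 25

_TIE_RTOL = 1e-9


class GaussianNull:
    """The limiting normal law of B under the symmetry null: mean 0, cov (1/4) sum U U^T."""

    def __init__(self, system: ScoreSystem):
        self.mean = system.permutation_mean()
        self.cov = system.permutation_cov()

    def correlation(self, convention: str = "standardized") -> float:
        """Correlation of the two components.

        ``standardized`` (default) divides the covariance by the product
        of standard deviations.  ``unnormalized`` divides by the product
        of the variances instead; this is not a correlation in the usual
        sense but reproduces baselines from analyses that standardized
        the covariance without taking the square root.
        """
        if convention == "standardized":
            return float(self.cov[0, 1] / np.sqrt(self.cov[0, 0] * self.cov[1, 1]))
        if convention == "unnormalized":
            return float(self.cov[0, 1] / (self.cov[0, 0] * self.cov[1, 1]))
        raise ValueError(f"unknown correlation convention {convention!r}")


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """Standard bivariate normal lower-tail probability P(Z1 <= h, Z2 <= k).

    Uses the Genz algorithm (absolute accuracy well below 1e-7); the
    degenerate cases |rho| = 1 are evaluated by their closed forms.
    """
    if abs(rho) > 1.0:
        raise ValueError(f"correlation must satisfy |rho| <= 1, got {rho}")
    if np.isnan(h) or np.isnan(k):
        raise ValueError("bvn_cdf arguments must not be NaN")
    if rho == 1.0:
        return float(ndtr(min(h, k)))
    if rho == -1.0:
        return float(max(0.0, ndtr(h) + ndtr(k) - 1.0))
    # clip infinities for the quadrature routine
    h = float(np.clip(h, -38.0, 38.0))
    k = float(np.clip(k, -38.0, 38.0))
    val = multivariate_normal.cdf(
        np.array([h, k]), mean=np.zeros(2), cov=np.array([[1.0, rho], [rho, 1.0]])
    )
    return float(np.clip(val, 0.0, 1.0))


def normal_midp(
    system: ScoreSystem,
    observed: ObservedStatistic,
    tail_convention: str = "cdf",
    orient: bool | None = None,
    correlation: str = "standardized",
) -> MidPResult:
    """Asymptotic bivariate-normal approximation of the mid-p value.

    ``cdf`` returns P(N1 <= tau, N2 <= upsilon); ``quadrant`` returns
    P(N1 > tau, N2 > upsilon) by inclusion–exclusion; ``complement_cdf``
    the union tail 1 - P(N1 <= tau, N2 <= upsilon).  The continuous law
    carries no atom, so no tie term arises.  ``correlation`` selects how
    the covariance is standardized (see :meth:`GaussianNull.correlation`).
    """
    if resolve_orient(orient, tail_convention):
        system, observed = orient_scores(system, observed)
    null = GaussianNull(system)
    s1, s2 = np.sqrt(null.cov[0, 0]), np.sqrt(null.cov[1, 1])
    det = float(np.linalg.det(null.cov))
    if not (s1 > 0 and s2 > 0) or det <= 0:
        direction = "first" if null.cov[0, 0] <= null.cov[1, 1] else "second"
        raise ValueError(
            f"singular null covariance (det={det:g}); the {direction} coordinate "
            "of the score system is degenerate"
        )
    rho = null.correlation(correlation)
    h = (observed.tau - null.mean[0]) / s1
    k = (observed.upsilon - null.mean[1]) / s2
    if tail_convention == "cdf":
        value = bvn_cdf(h, k, rho)
    elif tail_convention == "quadrant":
        value = 1.0 - ndtr(h) - ndtr(k) + bvn_cdf(h, k, rho)
    elif tail_convention == "complement_cdf":
        value = 1.0 - bvn_cdf(h, k, rho)
    else:
        raise ValueError(f"unknown tail_convention {tail_convention!r}")
    return MidPResult(
        value=float(np.clip(value, 0.0, 1.0)),
        method="normal",
        tail_convention=tail_convention,
    )


#: Tie-weighting rules for the discrete orthant mid-p.
TIE_RULES = ("boundary", "joint")


def _count_tail(
    B: np.ndarray, tau: float, upsilon: float, tol: float, lower: bool
) -> tuple[int, int, int]:
    """Count strict orthant interior, single-coordinate boundary, and joint ties."""
    e1 = np.abs(B[:, 0] - tau) <= tol
    e2 = np.abs(B[:, 1] - upsilon) <= tol
    if lower:
        s1 = B[:, 0] < tau - tol
        s2 = B[:, 1] < upsilon - tol
    else:
        s1 = B[:, 0] > tau + tol
        s2 = B[:, 1] > upsilon + tol
    strict = s1 & s2
    tie = e1 & e2
    mixed = (e1 & s2) | (s1 & e2)
    return int(strict.sum()), int(mixed.sum()), int(tie.sum())


def _combine_counts(strict: int, mixed: int, tie: int, tie_rule: str) -> float:
    if tie_rule == "boundary":
        # half weight on the whole attainment boundary of the closed orthant
        return strict + 0.5 * (mixed + tie)
    if tie_rule == "joint":
        # strict joint exceedance plus half the joint-tie mass only
        return strict + 0.5 * tie
    raise ValueError(f"unknown tie_rule {tie_rule!r}; use one of {TIE_RULES}")


def _check_counting_convention(tail_convention: str) -> bool:
    if tail_convention not in ("cdf", "quadrant"):
        raise ValueError(
            f"counting methods support tail conventions 'cdf' and 'quadrant', "
            f"got {tail_convention!r}"
        )
    return tail_convention == "cdf"


def exact_midp(
    system: ScoreSystem,
    observed: ObservedStatistic,
    tail_convention: str = "cdf",
    tie_rule: str = "boundary",
    orient: bool | None = None,
    guard: int = EXACT_ENUMERATION_GUARD,
) -> MidPResult:
    """Exact permutation mid-p by enumeration of all 2^n sign assignments.

    Under ``cdf`` the event is the lower orthant {b1 < tau, b2 <
    upsilon}; under ``quadrant`` the upper orthant.  Equality per
    coordinate is judged at absolute tolerance 1e-9*(1+|tau|+|upsilon|).
    ``tie_rule`` sets the weight of lattice outcomes on the orthant
    boundary: ``boundary`` (default) gives half weight to every
    assignment on the attainment boundary of the closed orthant — the
    two-dimensional analogue of the univariate mid-p rule, which centres
    the discrete value on the continuum CDF the approximations target;
    ``joint`` counts only the joint tie {b1 = tau, b2 = upsilon} at half
    weight and drops single-coordinate boundary mass entirely.  Counts
    are accumulated in exact integers; the observed assignment always
    ties itself, so the result is positive.
    """
    n = system.n
    if n > guard:
        raise ValueError(
            f"exact enumeration over 2^{n} assignments exceeds the guard "
            f"(n <= {guard}); use montecarlo_midp instead"
        )
    lower = _check_counting_convention(tail_convention)
    if resolve_orient(orient, tail_convention):
        system, observed = orient_scores(system, observed)
    tau, upsilon = observed.tau, observed.upsilon
    tol = _TIE_RTOL * (1.0 + abs(tau) + abs(upsilon))
    total = 1 << n
    n_strict = n_mixed = n_tie = 0
    chunk = 1 << min(n, 18)
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.uint64)
        bits = (codes[:, None] >> np.arange(n, dtype=np.uint64)) & np.uint64(1)
        B = evaluate_statistic(system, bits.astype(np.float64))
        s, m, t = _count_tail(B, tau, upsilon, tol, lower)
        n_strict += s
        n_mixed += m
        n_tie += t
    value = _combine_counts(n_strict, n_mixed, n_tie, tie_rule) / total
    return MidPResult(value=float(value), method="exact", tail_convention=tail_convention)


def montecarlo_midp(
    system: ScoreSystem,
    observed: ObservedStatistic,
    n_perms: int = 1_000_000,
    seed: int | None = None,
    tail_convention: str = "cdf",
    tie_rule: str = "boundary",
    orient: bool | None = None,
) -> MidPResult:
    """Monte-Carlo permutation mid-p from seeded iid Bernoulli(1/2) indicators.

    Uses the same counting rule as :func:`exact_midp` and reports the
    binomial standard error sqrt(p(1-p)/n_perms).  Deterministic for a
    fixed seed.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    lower = _check_counting_convention(tail_convention)
    if resolve_orient(orient, tail_convention):
        system, observed = orient_scores(system, observed)
    tau, upsilon = observed.tau, observed.upsilon
    tol = _TIE_RTOL * (1.0 + abs(tau) + abs(upsilon))
    rng = np.random.default_rng(seed)
    n_strict = n_mixed = n_tie = 0
    chunk = 1 << 16
    remaining = n_perms
    while remaining > 0:
        m = min(chunk, remaining)
        bits = rng.integers(0, 2, size=(m, system.n))
        B = evaluate_statistic(system, bits.astype(np.float64))
        s, mx, t = _count_tail(B, tau, upsilon, tol, lower)
        n_strict += s
        n_mixed += mx
        n_tie += t
        remaining -= m
    value = _combine_counts(n_strict, n_mixed, n_tie, tie_rule) / n_perms
    se = float(np.sqrt(max(value * (1.0 - value), 0.0) / n_perms))
    return MidPResult(
        value=float(value),
        method="montecarlo",
        tail_convention=tail_convention,
        std_error=se,
    )
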