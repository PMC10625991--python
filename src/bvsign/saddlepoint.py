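"""Saddlepoint approximation of the permutation mid-p value.

The permutation distribution of the linear sign statistic
``B = sum_i beta_i U_i + C`` (iid Bernoulli(1/2) indicators) has the
everywhere-finite joint cumulant generating function

    K(t, u) = sum_i log{1/2 + 1/2 exp(t U_1i + u U_2i)} + t c1 + u c2,

with marginal CGFs K1(t) = K(t, 0) and K2(u) = K(0, u).  Tail
probabilities of B are approximated by a four-term bivariate expansion
(Wang's generalization of the univariate Lugannani–Rice formula)
anchored at the joint saddlepoint (t0, u0) solving grad K = (tau,
upsilon) and the marginal saddlepoint t_hat0 solving K1'(t) = tau.

The four-term sum ``Fhat(tau, upsilon) = I11 + I12 + I21 + I22``
approximates the joint CDF ``Pr(b1 <= tau, b2 <= upsilon)``.  Three tail
conventions are built on it:

* ``cdf`` (default) — ``Fhat(tau, upsilon)`` itself, the lower-orthant
  probability at the observed statistic.  Because the permutation law of
  B is exactly antipodally symmetric, this equals the upper-quadrant
  mid-p of the sign-flipped data, so the lower/upper reading is purely a
  data-sign convention.  This is the form calibrated against exact
  enumeration on the bundled refraction data.
* ``quadrant`` — the upper-orthant probability ``Pr(b1 > tau, b2 >
  upsilon)`` by inclusion–exclusion: ``1 - LR1(tau) - LR2(upsilon) +
  Fhat``, with LR_j the univariate Lugannani–Rice lower-tail value built
  from K_j.  By default it is evaluated after reflecting coordinates so
  both observed components are >= 0.
* ``complement_cdf`` — ``1 - Fhat``, the probability that at least one
  coordinate exceeds its observed value (a union event, not an orthant).

When the two coordinate supports are disjoint (K_tu = 0) the orthant
forms factorize exactly into products of univariate Lugannani–Rice
tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr
from scipy.stats import norm

from .scores import ObservedStatistic, ScoreSystem, orient_scores

__all__ = [
    "SaddlepointSolution",
    "WangComponents",
    "MidPResult",
    "SaddlepointRootError",
    "NumericInconsistencyError",
    "DEFAULT_TAIL_CONVENTION",
    "TAIL_CONVENTIONS",
    "cgf",
    "cgf_gradient",
    "cgf_hessian",
    "marginal_cgf",
    "solve_joint_saddlepoint",
    "solve_marginal_saddlepoint",
    "wang_components",
    "lugannani_rice_cdf",
    "saddlepoint_midp",
]

#: Tail conventions understood by the mid-p evaluators.
TAIL_CONVENTIONS = ("cdf", "quadrant", "complement_cdf")

#: Default tail convention: the direct lower-orthant (CDF) evaluation.
DEFAULT_TAIL_CONVENTION = "cdf"

_RESIDUAL_RTOL = 1e-10
_MAX_NEWTON_ITER = 200
#: |saddlepoint| below this is treated as degenerate (removable singularity
#: in the I-terms); the observed value is perturbed and results averaged.
_DEGENERACY_EPS = 1e-6
_PERTURB_REL = 1e-4
#: Shrink factors tried when the observed value sits on the support boundary
#: (a vertex of the convex hull of attainable statistics has no finite root).
_BOUNDARY_SHRINK = (1e-6, 1e-3)


class SaddlepointRootError(RuntimeError):
    """No finite saddlepoint root: the target sits on or outside the support."""


class NumericInconsistencyError(RuntimeError):
    """A square-root argument went significantly negative, signalling solver failure."""


def resolve_orient(orient: bool | None, tail_convention: str) -> bool:
    """Default orientation policy: reflect to the upper quadrant only for ``quadrant``."""
    if orient is None:
        return tail_convention == "quadrant"
    return bool(orient)


@dataclass(frozen=True)
class SaddlepointSolution:
    """Joint saddlepoint (t0, u0) and marginal saddlepoint t_hat0 for a target (tau, upsilon)."""

    t0: float
    u0: float
    t_hat0: float
    gradient_residual: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class WangComponents:
    """Intermediate quantities of the four-term bivariate tail approximation."""

    tau1: float
    w_u0: float
    upsilon0: float
    b: float
    G: float
    rho1: float
    upsilon1: float
    I11: float
    I12: float
    I21: float
    I22: float
    K_at_saddle: float
    Ktt: float
    Ktu: float
    Kuu: float

    @property
    def four_term_sum(self) -> float:
        return self.I11 + self.I12 + self.I21 + self.I22

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class MidPResult:
    """A mid-p value with its method label, tail convention and diagnostics."""

    value: float
    method: str
    tail_convention: str | None = None
    diagnostics: tuple[str, ...] = ()
    std_error: float | None = None

    def to_dict(self) -> dict:
        d = {
            "mid_p": self.value,
            "method": self.method,
            "tail_convention": self.tail_convention,
            "diagnostics": list(self.diagnostics),
        }
        if self.std_error is not None:
            d["se"] = self.std_error
        return d


# ---------------------------------------------------------------------------
# Cumulant generating function and derivatives
# ---------------------------------------------------------------------------

_LOG2 = np.log(2.0)


def cgf(system: ScoreSystem, t: float, u: float) -> float:
    """Joint CGF K(t, u) of (b1, b2), overflow-safe for large exponents."""
    x = system.U @ np.array([t, u])
    # log(1/2 + 1/2 e^x) = logaddexp(0, x) - log 2
    return float(np.logaddexp(0.0, x).sum() - system.n * _LOG2 + t * system.C[0] + u * system.C[1])


def cgf_gradient(system: ScoreSystem, t: float, u: float) -> np.ndarray:
    """Analytic gradient of K: sum_i U_i * logistic(t U_1i + u U_2i) + C."""
    x = system.U @ np.array([t, u])
    return system.U.T @ expit(x) + system.C


def cgf_hessian(system: ScoreSystem, t: float, u: float) -> tuple[float, float, float]:
    """Second derivatives (K_tt, K_tu, K_uu) of the joint CGF.

    Each term contributes ``p_i (1 - p_i) U_i U_i^T`` with
    ``p_i = logistic(t U_1i + u U_2i)``; the Hessian is PSD by convexity.
    """
    x = system.U @ np.array([t, u])
    p = expit(x)
    w = p * (1.0 - p)
    U1, U2 = system.U[:, 0], system.U[:, 1]
    Ktt = float(np.sum(w * U1 * U1))
    Ktu = float(np.sum(w * U1 * U2))
    Kuu = float(np.sum(w * U2 * U2))
    return Ktt, Ktu, Kuu


def marginal_cgf(system: ScoreSystem, axis: int, s: float) -> tuple[float, float, float]:
    """Marginal CGF K_axis(s) with its first two derivatives (axis 1 or 2)."""
    if axis not in (1, 2):
        raise ValueError(f"axis must be 1 or 2, got {axis}")
    Ua = system.U[:, axis - 1]
    ca = system.C[axis - 1]
    x = s * Ua
    value = float(np.logaddexp(0.0, x).sum() - system.n * _LOG2 + s * ca)
    p = expit(x)
    d1 = float(np.sum(Ua * p) + ca)
    d2 = float(np.sum(Ua * Ua * p * (1.0 - p)))
    return value, d1, d2


# ---------------------------------------------------------------------------
# Saddlepoint equations
# ---------------------------------------------------------------------------


def _marginal_support(system: ScoreSystem, axis: int) -> tuple[float, float]:
    Ua = system.U[:, axis - 1]
    ca = system.C[axis - 1]
    return float(Ua[Ua < 0].sum() + ca), float(Ua[Ua > 0].sum() + ca)


def solve_marginal_saddlepoint(system: ScoreSystem, axis: int, target: float) -> float:
    """Solve K_axis'(s) = target by safeguarded Newton (bisection fallback).

    K_axis' is strictly increasing from the support minimum to the support
    maximum; a target at or outside those extremes has no finite root.
    """
    lo_sup, hi_sup = _marginal_support(system, axis)
    if not (lo_sup < target < hi_sup):
        raise SaddlepointRootError(
            f"marginal target {target!r} is not strictly inside the attainable "
            f"range ({lo_sup!r}, {hi_sup!r}) of coordinate {axis}; the observed "
            "value sits on or outside the support boundary"
        )
    tol = _RESIDUAL_RTOL * (1.0 + abs(target))
    # bracket the root
    lo, hi = -1.0, 1.0
    for _ in range(600):
        if marginal_cgf(system, axis, lo)[1] < target:
            break
        lo *= 2.0
    else:
        raise SaddlepointRootError(
            f"could not bracket the marginal saddlepoint from below; the target "
            f"{target!r} is numerically at the support edge of coordinate {axis}"
        )
    for _ in range(600):
        if marginal_cgf(system, axis, hi)[1] > target:
            break
        hi *= 2.0
    else:
        raise SaddlepointRootError(
            f"could not bracket the marginal saddlepoint from above; the target "
            f"{target!r} is numerically at the support edge of coordinate {axis}"
        )
    s = 0.0 if lo < 0.0 < hi else 0.5 * (lo + hi)
    f = marginal_cgf(system, axis, s)[1] - target
    for _ in range(_MAX_NEWTON_ITER):
        _, d1, d2 = marginal_cgf(system, axis, s)
        f = d1 - target
        if abs(f) <= tol:
            return s
        if f > 0:
            hi = s
        else:
            lo = s
        s_new = s - f / d2 if d2 > 0 and np.isfinite(d2) else 0.5 * (lo + hi)
        if not (lo < s_new < hi):
            s_new = 0.5 * (lo + hi)
        s = s_new
    raise SaddlepointRootError(
        f"marginal saddlepoint iteration did not reach tolerance {tol:g} "
        f"(last residual {f:g}); the target may be numerically at the support edge"
    )


def solve_joint_saddlepoint(
    system: ScoreSystem, tau: float, upsilon: float
) -> SaddlepointSolution:
    """Solve grad K(t, u) = (tau, upsilon) by damped Newton with the analytic Hessian.

    Newton descent on the convex dual objective g(t, u) = K(t, u) - t*tau
    - u*upsilon, starting at (0, 0) (the permutation mean) with Armijo
    step-halving.  K is strictly convex on the span of the scores, so the
    root exists and is unique exactly when the target lies strictly
    inside the convex hull of the attainable statistics; for a target on
    or outside that hull g is unbounded below and a no-root error is
    raised.
    """
    target = np.array([tau, upsilon], dtype=float)
    tol = _RESIDUAL_RTOL * (1.0 + abs(tau) + abs(upsilon))
    tu = np.zeros(2)
    grad = cgf_gradient(system, *tu) - target
    resid = float(np.linalg.norm(grad, np.inf))
    iters = 0
    for iters in range(1, _MAX_NEWTON_ITER + 1):
        if resid <= tol:
            break
        Ktt, Ktu, Kuu = cgf_hessian(system, *tu)
        H = np.array([[Ktt, Ktu], [Ktu, Kuu]])
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -grad, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            raise SaddlepointRootError(
                "Newton step is not finite; the observed value likely sits on or "
                "outside the support boundary of the permutation distribution"
            )
        # step-halving on the residual norm: the Newton direction is a
        # descent direction for ||grad K - target|| by convexity of K
        lam = 1.0
        for _ in range(60):
            cand = tu + lam * step
            grad_c = cgf_gradient(system, *cand) - target
            resid_c = float(np.linalg.norm(grad_c, np.inf))
            if resid_c < resid:
                tu, grad, resid = cand, grad_c, resid_c
                break
            lam *= 0.5
        else:
            # no reducing step exists within round-off of the minimizer
            break
        if np.linalg.norm(tu, np.inf) > 1e8:
            raise SaddlepointRootError(
                "joint saddlepoint diverged; the observed value sits on or "
                "outside the support boundary of the permutation distribution"
            )
    if resid > tol:
        raise SaddlepointRootError(
            f"joint saddlepoint Newton did not converge (residual {resid:g}, "
            f"tolerance {tol:g}); the observed value may sit on or outside the "
            "support boundary of the permutation distribution"
        )
    t_hat0 = solve_marginal_saddlepoint(system, 1, tau)
    return SaddlepointSolution(
        t0=float(tu[0]),
        u0=float(tu[1]),
        t_hat0=t_hat0,
        gradient_residual=resid,
        iterations=iters,
        converged=True,
    )


# ---------------------------------------------------------------------------
# Wang four-term components
# ---------------------------------------------------------------------------


def _safe_sqrt(arg: float, what: str) -> float:
    if arg < -1e-12:
        raise NumericInconsistencyError(
            f"negative square-root argument {arg:g} while computing {what}; "
            "this signals saddlepoint solver failure or an out-of-tail evaluation"
        )
    return float(np.sqrt(max(arg, 0.0)))


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    # local import keeps reference -> saddlepoint imports acyclic
    from .reference import bvn_cdf

    return bvn_cdf(h, k, rho)


def wang_components(
    system: ScoreSystem, tau: float, upsilon: float, solution: SaddlepointSolution
) -> WangComponents:
    """Compute the I-terms of the four-term bivariate tail approximation.

    ``I11 + I12 + I21 + I22`` approximates the joint lower-orthant
    probability ``Pr(b1 <= tau, b2 <= upsilon)``.  Requires a converged
    solution with saddlepoints away from zero (the caller handles
    degeneracies by perturbation).  All square-root arguments are
    non-negative in exact arithmetic (convexity of K); values within
    round-off of zero are clipped, anything worse raises.
    """
    if not solution.converged:
        raise ValueError("saddlepoint solution did not converge")
    t0, u0, t_hat0 = solution.t0, solution.u0, solution.t_hat0
    K00 = cgf(system, t0, u0)
    K1_hat = marginal_cgf(system, 1, t_hat0)[0]
    K2_u0 = marginal_cgf(system, 2, u0)[0]
    Ktt, Ktu, Kuu = cgf_hessian(system, t0, u0)

    tau1 = np.sign(t_hat0) * _safe_sqrt(-2.0 * (K1_hat - t_hat0 * tau), "tau1")
    w_u0 = np.sign(t0) * _safe_sqrt(-2.0 * (K00 - K2_u0 - t0 * tau), "w_u0")
    upsilon0 = np.sign(u0) * _safe_sqrt(
        -2.0 * (K00 - K1_hat - (t0 - t_hat0) * tau - u0 * upsilon), "upsilon0"
    )
    b = (w_u0 - tau1) / upsilon0
    G = _safe_sqrt(Kuu - Ktu * Ktu / Ktt, "G")
    rho1 = -b / np.sqrt(1.0 + b * b)
    upsilon1 = (upsilon0 - b * tau1) / np.sqrt(1.0 + b * b)

    I11 = _bvn_cdf(tau1, upsilon1, rho1)
    I12 = ndtr(w_u0) * norm.pdf(upsilon0) * (1.0 / upsilon0 - 1.0 / (u0 * G))
    I21 = ndtr(upsilon0) * norm.pdf(tau1) * (1.0 / w_u0 - 1.0 / (t0 * np.sqrt(Ktt)))
    I22 = (
        np.exp(K00 - t0 * tau - u0 * upsilon)
        * (1.0 / w_u0 - 1.0 / (t0 * np.sqrt(Ktt)))
        * (1.0 / upsilon0 - 1.0 / (u0 * G))
        / (2.0 * np.pi)
    )
    return WangComponents(
        tau1=float(tau1),
        w_u0=float(w_u0),
        upsilon0=float(upsilon0),
        b=float(b),
        G=float(G),
        rho1=float(rho1),
        upsilon1=float(upsilon1),
        I11=float(I11),
        I12=float(I12),
        I21=float(I21),
        I22=float(I22),
        K_at_saddle=float(K00),
        Ktt=float(Ktt),
        Ktu=float(Ktu),
        Kuu=float(Kuu),
    )


def lugannani_rice_cdf(system: ScoreSystem, axis: int, x: float) -> float:
    """Univariate Lugannani–Rice lower-tail value Phi(w) + phi(w)(1/w - 1/v) for K_axis.

    The caller is responsible for keeping the marginal saddlepoint away
    from zero (removable singularity at the mean).
    """
    s = solve_marginal_saddlepoint(system, axis, x)
    K, _, d2 = marginal_cgf(system, axis, s)
    w = np.sign(s) * _safe_sqrt(2.0 * (s * x - K), "Lugannani-Rice w")
    v = s * np.sqrt(d2)
    return float(ndtr(w) + norm.pdf(w) * (1.0 / w - 1.0 / v))


# ---------------------------------------------------------------------------
# Mid-p evaluation
# ---------------------------------------------------------------------------


def _statistic_scale(system: ScoreSystem) -> np.ndarray:
    sd = np.sqrt(np.diag(system.permutation_cov()))
    return np.where(sd > 0, sd, 1.0)


def _four_term_sum(system: ScoreSystem, tau: float, upsilon: float) -> float:
    solution = solve_joint_saddlepoint(system, tau, upsilon)
    return wang_components(system, tau, upsilon, solution).four_term_sum


def _midp_at(system: ScoreSystem, tau: float, upsilon: float, tail_convention: str) -> float:
    if tail_convention == "cdf":
        return _four_term_sum(system, tau, upsilon)
    if tail_convention == "complement_cdf":
        return 1.0 - _four_term_sum(system, tau, upsilon)
    # quadrant: inclusion-exclusion completion of the upper-orthant event
    lr1 = lugannani_rice_cdf(system, 1, tau)
    lr2 = lugannani_rice_cdf(system, 2, upsilon)
    return 1.0 - lr1 - lr2 + _four_term_sum(system, tau, upsilon)


def _is_degenerate(system: ScoreSystem, tau: float, upsilon: float, quadrant: bool) -> bool:
    sol = solve_joint_saddlepoint(system, tau, upsilon)
    small = min(abs(sol.t0), abs(sol.u0), abs(sol.t_hat0)) < _DEGENERACY_EPS
    if quadrant and not small:
        u_hat0 = solve_marginal_saddlepoint(system, 2, upsilon)
        small = abs(u_hat0) < _DEGENERACY_EPS
    return small


def saddlepoint_midp(
    system: ScoreSystem,
    observed: ObservedStatistic,
    tail_convention: str = DEFAULT_TAIL_CONVENTION,
    orient: bool | None = None,
) -> MidPResult:
    """Saddlepoint approximation of the permutation mid-p value at ``observed``.

    Parameters
    ----------
    system, observed
        The score system and the realized statistic B0 = (tau, upsilon).
    tail_convention : {"cdf", "quadrant", "complement_cdf"}
        ``cdf`` (default): the four-term lower-orthant value F(tau,
        upsilon); ``quadrant``: the upper-orthant probability by
        inclusion–exclusion; ``complement_cdf``: 1 - F (union tail).
    orient : bool, optional
        Reflect coordinates so both observed components are >= 0 before
        evaluating.  Default: only for the ``quadrant`` convention.

    Notes
    -----
    If any saddlepoint falls within 1e-6 of zero the observed value is
    perturbed by +-1e-4 of the statistic's null standard deviation and
    the two evaluations averaged (the I-terms have removable
    singularities at zero).  If the observed value sits exactly on the
    boundary of the support hull (no finite saddlepoint) it is shrunk
    minutely toward the permutation mean.  Both fallbacks set diagnostic
    flags; the result is clipped to [0, 1].
    """
    if tail_convention not in TAIL_CONVENTIONS:
        raise ValueError(
            f"unknown tail_convention {tail_convention!r}; use one of {TAIL_CONVENTIONS}"
        )
    if resolve_orient(orient, tail_convention):
        system, observed = orient_scores(system, observed)
    tau, upsilon = observed.tau, observed.upsilon
    diagnostics: list[str] = []
    quadrant = tail_convention == "quadrant"
    try:
        solve_joint_saddlepoint(system, tau, upsilon)
        if quadrant:
            solve_marginal_saddlepoint(system, 2, upsilon)
    except SaddlepointRootError:
        # observed value on the boundary of the support hull (e.g. every
        # sign identical): no finite saddlepoint exists there
        return _counting_fallback(
            system,
            observed,
            tail_convention,
            diagnostics
            + ["observed value on the support boundary: exact counting used"],
        )
    if _is_degenerate(system, tau, upsilon, quadrant):
        eps = _PERTURB_REL * _statistic_scale(system)
        value = 0.5 * (
            _midp_at(system, tau + eps[0], upsilon + eps[1], tail_convention)
            + _midp_at(system, tau - eps[0], upsilon - eps[1], tail_convention)
        )
        diagnostics.append("near-zero saddlepoint: symmetric perturbation applied")
    else:
        value = _midp_at(system, tau, upsilon, tail_convention)
    if not (-1e-9 <= value <= 1.0 + 1e-9):
        # saturated saddlepoint (observed adjacent to the support boundary):
        # the expansion terms are unreliable, fall back to counting
        return _counting_fallback(
            system,
            observed,
            tail_convention,
            diagnostics + ["saddlepoint expansion out of [0, 1]: exact counting used"],
        )
    return MidPResult(
        value=float(np.clip(value, 0.0, 1.0)),
        method="saddlepoint",
        tail_convention=tail_convention,
        diagnostics=tuple(diagnostics),
    )


def _counting_fallback(
    system: ScoreSystem,
    observed: ObservedStatistic,
    tail_convention: str,
    diagnostics: list[str],
) -> MidPResult:
    """Exact (or, for large n, seeded Monte-Carlo) counting used where the
    saddlepoint expansion is undefined or numerically unreliable."""
    from .reference import EXACT_ENUMERATION_GUARD, exact_midp, montecarlo_midp

    counting_tail = "quadrant" if tail_convention == "quadrant" else "cdf"
    if system.n <= EXACT_ENUMERATION_GUARD:
        ref = exact_midp(system, observed, tail_convention=counting_tail, orient=False)
    else:  # pragma: no cover - n > 25 boundary observations are vanishingly rare
        ref = montecarlo_midp(
            system, observed, n_perms=100_000, seed=0, tail_convention=counting_tail, orient=False
        )
    value = 1.0 - ref.value if tail_convention == "complement_cdf" else ref.value
    return MidPResult(
        value=float(value),
        method="saddlepoint",
        tail_convention=tail_convention,
        diagnostics=tuple(diagnostics),
        std_error=ref.std_error,
    )
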