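"""Linear sign-statistic score systems for bivariate symmetry tests.

A bivariate sample ``z_1, ..., z_n`` is reduced to the linear sign
statistic ``B = sum_i beta_i * U_i + C``, where the ``beta_i`` are
Bernoulli(1/2) sign indicators under the symmetry null and the score
vectors ``U_i`` (with offset ``C``) encode the particular test:

* **Blumen's test** replaces data-point angles by equally spaced angular
  ranks ``pi*i/n`` on the upper half-circle, which makes the statistic
  distribution-free.
* **Brown–Hettmansperger-type test** ("brown") uses the gradient vector
  of the spatial objective at the origin, built from cyclic averages of
  the 90-degree-rotated, angle-ordered observations; radii are retained.

Both constructions are centred: ``(1/2) sum_i U_i + C = 0``, so the
permutation distribution of ``B`` has mean zero and is antipodally
symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BivariateSample",
    "PolarDecomposition",
    "ScoreSystem",
    "ObservedStatistic",
    "ZeroVectorError",
    "polar_decompose",
    "blumen_system",
    "brown_system",
    "evaluate_statistic",
    "orient_scores",
]


class ZeroVectorError(ValueError):
    """A sample point coincides with the origin, so its sign is undefined."""


@dataclass(frozen=True)
class BivariateSample:
    """An ordered sample of n paired real observations (x_i, y_i).

    Parameters
    ----------
    points : array-like of shape (n, 2)
        The paired observations. Must contain at least two rows and no
        row may be the zero vector ``(0, 0)``.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"expected an (n, 2) array of pairs, got shape {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError(f"need at least 2 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("sample contains non-finite values")
        zero = np.flatnonzero((pts[:, 0] == 0.0) & (pts[:, 1] == 0.0))
        if zero.size:
            raise ZeroVectorError(
                f"point(s) at index {zero.tolist()} are the zero vector; "
                "the sign of a point at the origin is undefined"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class PolarDecomposition:
    """Upper-half-plane polar representation z_i = gamma_i * r_i * (cos, sin)(theta_i).

    ``gamma_i = +1`` if the point lies strictly above the horizontal axis,
    ``-1`` if strictly below; on the axis (y = 0) the convention
    ``gamma = sign(x), theta = 0`` applies.  ``order`` ranks the points by
    ascending angle, ties broken by original index (stable).
    """

    gamma: np.ndarray
    alpha: np.ndarray
    radius: np.ndarray
    angle: np.ndarray
    order: np.ndarray


@dataclass(frozen=True)
class ScoreSystem:
    """The (U, C) pair defining the permutation family B = sum beta_i U_i + C.

    Attributes
    ----------
    U : (n, 2) array
        Score vectors, one row per observation (in angle-rank order for
        the built-in constructions).
    C : (2,) array
        Offset vector.
    label : str
        ``"blumen"``, ``"brown"`` or ``"custom"``.
    orientation : (2,) array of +-1
        Coordinate reflections applied by :func:`orient_scores`
        (identity ``(+1, +1)`` on construction).
    """

    U: np.ndarray
    C: np.ndarray
    label: str = "custom"
    orientation: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        C = np.asarray(self.C, dtype=float).reshape(2)
        if U.ndim != 2 or U.shape[1] != 2:
            raise ValueError(f"U must have shape (n, 2), got {U.shape}")
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "C", C)

    @property
    def n(self) -> int:
        return self.U.shape[0]

    def permutation_mean(self) -> np.ndarray:
        """Mean of B under iid Bernoulli(1/2) indicators: (1/2) sum U_i + C."""
        return 0.5 * self.U.sum(axis=0) + self.C

    def permutation_cov(self) -> np.ndarray:
        """Covariance of B under the null: (1/4) sum U_i U_i^T."""
        return 0.25 * (self.U.T @ self.U)

    def is_centered(self, rtol: float = 1e-10) -> bool:
        scale = max(np.abs(self.U).max(), 1.0)
        return bool(np.all(np.abs(self.permutation_mean()) <= rtol * scale))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "U": self.U.tolist(),
            "C": self.C.tolist(),
            "orientation": list(self.orientation),
        }


@dataclass(frozen=True)
class ObservedStatistic:
    """The realized value B_0 = (tau, upsilon) at which tails are evaluated."""

    tau: float
    upsilon: float

    def as_array(self) -> np.ndarray:
        return np.array([self.tau, self.upsilon], dtype=float)


def polar_decompose(sample: BivariateSample) -> PolarDecomposition:
    """Reflect each point into the closed upper half-plane and rank by angle.

    Returns gamma (signs), alpha = (gamma+1)/2, radii, angles in [0, pi),
    and the stable ascending-angle ordering.
    """
    pts = sample.points
    x, y = pts[:, 0], pts[:, 1]
    gamma = np.where(y > 0, 1, np.where(y < 0, -1, np.sign(x))).astype(int)
    upper = gamma[:, None] * pts  # representative in the closed upper half-plane
    radius = np.hypot(upper[:, 0], upper[:, 1])
    angle = np.arctan2(upper[:, 1], upper[:, 0])
    # upper rep has y >= 0, and y == 0 forces x > 0 via the gamma convention,
    # so arctan2 lands in [0, pi) with no angle-pi edge case.
    order = np.argsort(angle, kind="stable")
    alpha = (gamma + 1) // 2
    return PolarDecomposition(gamma=gamma, alpha=alpha, radius=radius, angle=angle, order=order)


def blumen_system(sample: BivariateSample) -> tuple[ScoreSystem, ObservedStatistic]:
    """Build Blumen's angular-rank score system and its observed statistic.

    The point with the i-th smallest angle (i = 0..n-1) receives score
    ``U = 2*(cos(pi*i/n), sin(pi*i/n))``; the offset is
    ``C = -sum_i (cos(pi*i/n), sin(pi*i/n))``.  The observed statistic is
    ``(l1, l2) = sum_i gamma_(i) * (cos(pi*i/n), sin(pi*i/n))`` with the
    sample's signs taken in angle order.
    """
    pol = polar_decompose(sample)
    n = sample.n
    i = np.arange(n)
    trig = np.column_stack([np.cos(np.pi * i / n), np.sin(np.pi * i / n)])
    U = 2.0 * trig
    C = -trig.sum(axis=0)
    gamma_sorted = pol.gamma[pol.order]
    observed = trig.T @ gamma_sorted
    system = ScoreSystem(U=U, C=C, label="blumen")
    return system, ObservedStatistic(tau=float(observed[0]), upsilon=float(observed[1]))


def brown_system(sample: BivariateSample) -> tuple[ScoreSystem, ObservedStatistic]:
    """Build the gradient-vector score system of the Brown et al. test.

    With the upper-half-plane representatives x_1..x_n sorted by ascending
    angle and extended cyclically by x_{n+i} = -x_i, the scores are the
    cyclic averages ``w_i = (1/n) sum_{l=1..n-1} rot90(x_{i+l})`` where
    ``rot90(a, b) = (-b, a)``.  Radii are retained (no normalization to
    the unit circle).  The observed statistic is the gradient vector
    ``q = (1/2) sum_i gamma_i w_i``.
    """
    pol = polar_decompose(sample)
    n = sample.n
    xs = (pol.gamma[:, None] * sample.points)[pol.order]  # angle-ordered upper reps
    ext = np.concatenate([xs, -xs], axis=0)  # x_{n+i} = -x_i
    rot = np.column_stack([-ext[:, 1], ext[:, 0]])  # 90-degree rotation
    # w_i = (1/n) * sum_{l=1}^{n-1} rot(x_{i+l}) ; 1-based i maps to row i-1
    csum = np.cumsum(rot, axis=0)
    W = np.empty((n, 2))
    for i in range(n):
        # rows i+1 .. i+n-1 of ext (0-based)
        W[i] = (csum[i + n - 1] - csum[i]) / n
    C = -0.5 * W.sum(axis=0)
    gamma_sorted = pol.gamma[pol.order]
    q = 0.5 * (W.T @ gamma_sorted)
    system = ScoreSystem(U=W, C=C, label="brown")
    return system, ObservedStatistic(tau=float(q[0]), upsilon=float(q[1]))


def evaluate_statistic(system: ScoreSystem, indicators: np.ndarray) -> np.ndarray:
    """Evaluate B = sum_i alpha_i U_i + C for a 0/1 indicator vector.

    ``indicators`` may also be a matrix of shape (m, n) in which case an
    (m, 2) array of statistics is returned.
    """
    a = np.asarray(indicators, dtype=float)
    if a.shape[-1] != system.n:
        raise ValueError(f"expected {system.n} indicators, got {a.shape[-1]}")
    return a @ system.U + system.C


def orient_scores(
    system: ScoreSystem, observed: ObservedStatistic
) -> tuple[ScoreSystem, ObservedStatistic]:
    """Reflect coordinates so that both observed components are >= 0.

    For each coordinate with a negative observed value, that coordinate of
    every score vector and of C is negated, and the observed coordinate is
    negated; the flips are recorded in ``orientation``.  This places the
    observed statistic in the upper-right tail before quadrant
    probabilities are formed.  Applying the operation twice equals
    applying it once (idempotent).
    """
    flips = np.where(observed.as_array() < 0, -1, 1)
    if np.all(flips == 1):
        return system, observed
    new_orient = (int(system.orientation[0] * flips[0]), int(system.orientation[1] * flips[1]))
    oriented = ScoreSystem(
        U=system.U * flips, C=system.C * flips, label=system.label, orientation=new_orient
    )
    b = observed.as_array() * flips
    return oriented, ObservedStatistic(tau=float(b[0]), upsilon=float(b[1]))
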