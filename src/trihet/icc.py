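"""Nested exchangeable correlation structures and their eigen-algebra.

A three-level trial (participants nested in subclusters nested in clusters)
induces a *nested exchangeable* correlation matrix for the ``n_s * m``
observations of one cluster: a common correlation ``a0`` between any two
observations sharing a subcluster and a common correlation ``a1`` between
observations in different subclusters of the same cluster,

    R = (1 - a0) I  +  (a0 - a1) I_{n_s} (x) J_m  +  a1 J_{n_s m},

where ``J_d`` is the d x d all-ones matrix.  The same structure describes the
outcome (conditional on covariates; ICCs ``alpha0, alpha1``) and the effect
modifier (ICCs ``rho0, rho1``).  R has exactly three distinct eigenvalues,

    lam1 = 1 - a0                            multiplicity n_s (m - 1)
    lam2 = 1 + (m-1) a0 - m a1               multiplicity n_s - 1
    lam3 = 1 + (m-1) a0 + (n_s-1) m a1       multiplicity 1

and a closed-form inverse in the same three-term basis.  All design formulas
downstream are O(1) functions of these eigenvalues; dense matrices are only
materialized for validation and small problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class InvalidCorrelationError(ValueError):
    """Raised when a correlation pair does not yield a positive definite matrix."""


class DimensionOverflowError(ValueError):
    """Raised when a dense matrix would exceed the configured side cap."""


@dataclass(frozen=True)
class EigenTriple:
    """The three distinct eigenvalues of a nested exchangeable matrix.

    Multiplicities are ``n_mid * (size_low - 1)``, ``n_mid - 1`` and ``1``
    for ``lam1``, ``lam2``, ``lam3`` respectively.
    """

    lam1: float
    lam2: float
    lam3: float
    n_mid: int
    size_low: int

    @property
    def multiplicities(self) -> tuple[int, int, int]:
        return (self.n_mid * (self.size_low - 1), self.n_mid - 1, 1)

    def spectrum(self) -> np.ndarray:
        """Full eigenvalue spectrum (with multiplicities), unsorted."""
        m1, m2, m3 = self.multiplicities
        return np.concatenate(
            [np.full(m1, self.lam1), np.full(m2, self.lam2), np.full(m3, self.lam3)]
        )

    def log_det(self) -> float:
        m1, m2, m3 = self.multiplicities
        return m1 * np.log(self.lam1) + m2 * np.log(self.lam2) + m3 * np.log(self.lam3)


@dataclass(frozen=True)
class NestedExchangeableSpec:
    """Parameters of a nested exchangeable correlation structure.

    Parameters
    ----------
    n_mid : int
        Number of mid-level units per top-level unit (subclusters per
        cluster, ``n_s``).
    size_low : int
        Number of low-level units per mid-level unit (participants per
        subcluster, ``m``).
    within_corr : float
        Correlation between two low-level units in the same mid-level unit
        (``alpha0`` for outcomes, ``rho0`` for covariates).
    between_corr : float
        Correlation between two low-level units in different mid-level units
        of the same top-level unit (``alpha1`` / ``rho1``).

    Validity is enforced through positivity of the three eigenvalues, not
    through ``0 <= between_corr <= within_corr``: the algebra only requires
    the former.  A warning is emitted when ``between_corr > within_corr``
    since in practice the within-subcluster correlation dominates.

    ``allow_singular`` relaxes positivity to nonnegativity; appropriate for
    covariate structures that are only multiplied, never inverted (e.g. a
    subcluster-level modifier has within_corr = 1 and a zero eigenvalue).
    """

    n_mid: int
    size_low: int
    within_corr: float
    between_corr: float
    allow_singular: bool = False

    def __post_init__(self) -> None:
        if self.n_mid < 1 or self.size_low < 1:
            raise ValueError("n_mid and size_low must both be >= 1")
        if self.between_corr > self.within_corr:
            warnings.warn(
                "between_corr exceeds within_corr; the structure is valid but "
                "unusual for nested data",
                stacklevel=2,
            )
        # eigenvalue positivity <=> positive definiteness
        tri = eigen_triple(self)
        del tri  # raises on violation

    @property
    def side(self) -> int:
        return self.n_mid * self.size_low


def eigen_triple(spec: NestedExchangeableSpec) -> EigenTriple:
    """Three distinct eigenvalues of the nested exchangeable structure.

    Raises
    ------
    InvalidCorrelationError
        If any eigenvalue is non-positive, naming the violated one.
    """
    m, n_s = spec.size_low, spec.n_mid
    a0, a1 = spec.within_corr, spec.between_corr
    lam1 = 1.0 - a0
    lam2 = 1.0 + (m - 1) * a0 - m * a1
    lam3 = 1.0 + (m - 1) * a0 + (n_s - 1) * m * a1
    floor = -1e-12 if spec.allow_singular else 0.0
    for name, val in (("lam1", lam1), ("lam2", lam2), ("lam3", lam3)):
        if val <= floor:
            raise InvalidCorrelationError(
                f"eigenvalue {name} = {val:.6g} is not positive for "
                f"(within={a0}, between={a1}, n_mid={n_s}, size_low={m}); "
                "the correlation matrix is not positive definite"
            )
    return EigenTriple(lam1, lam2, lam3, n_mid=n_s, size_low=m)


def build_matrix(spec: NestedExchangeableSpec, max_side: int = 4000) -> np.ndarray:
    """Dense nested exchangeable correlation matrix of side ``n_mid * size_low``.

    Intended for validation and small designs; production formulas use
    :func:`eigen_triple` instead.
    """
    side = spec.side
    if side > max_side:
        raise DimensionOverflowError(
            f"dense matrix of side {side} exceeds cap {max_side}"
        )
    m, n_s = spec.size_low, spec.n_mid
    a0, a1 = spec.within_corr, spec.between_corr
    eye = np.eye(side)
    within = np.kron(np.eye(n_s), np.ones((m, m)))
    return (1.0 - a0) * eye + (a0 - a1) * within + a1 * np.ones((side, side))


def explicit_inverse(spec: NestedExchangeableSpec, max_side: int = 4000) -> np.ndarray:
    """Closed-form inverse of :func:`build_matrix` in the same three-term basis.

    R^{-1} = (1/lam1) I - (lam2-lam1)/(m lam1 lam2) I_{n_s} (x) J_m
             - (lam3-lam2)/(n_s m lam2 lam3) J_{n_s m}.
    """
    side = spec.side
    if side > max_side:
        raise DimensionOverflowError(
            f"dense matrix of side {side} exceeds cap {max_side}"
        )
    m, n_s = spec.size_low, spec.n_mid
    tri = eigen_triple(spec)
    l1, l2, l3 = tri.lam1, tri.lam2, tri.lam3
    eye = np.eye(side)
    within = np.kron(np.eye(n_s), np.ones((m, m)))
    return (
        eye / l1
        - (l2 - l1) / (m * l1 * l2) * within
        - (l3 - l2) / (n_s * m * l2 * l3) * np.ones((side, side))
    )


def inverse_coefficients(spec: NestedExchangeableSpec) -> tuple[float, float, float]:
    """Distinct entries of R^{-1}: (diagonal, within-subcluster off-diagonal,
    between-subcluster) values.  O(1); used by the expected-information
    computations."""
    m, n_s = spec.size_low, spec.n_mid
    tri = eigen_triple(spec)
    l1, l2, l3 = tri.lam1, tri.lam2, tri.lam3
    c_within = -(l2 - l1) / (m * l1 * l2)
    c_between = -(l3 - l2) / (n_s * m * l2 * l3)
    diag = 1.0 / l1 + c_within + c_between
    same = c_within + c_between
    cross = c_between
    return diag, same, cross


@dataclass(frozen=True)
class BlockNestedExchangeable:
    """Nested *block* exchangeable covariance for p effect modifiers per
    participant.

    The stacked ``n_mid * size_low`` p-vectors of one cluster have covariance

        V = I_{n_s m} (x) (Sigma - B0) + (I_{n_s} (x) J_m) (x) (B0 - B1)
            + J_{n_s m} (x) B1,

    where ``sigma_total`` (p x p) is the per-participant covariance,
    ``within_block`` (B0) the cross-covariance between two participants in
    the same subcluster, and ``between_block`` (B1) across subclusters.
    The block analogues of the scalar eigenvalues are the "eigen-matrices"

        Z1 = Sigma - B0
        Z2 = Sigma + (m-1) B0 - m B1
        Z3 = Sigma + (m-1) B0 + (n_s-1) m B1

    with multiplicities n_s(m-1), n_s-1, 1; V is positive definite iff all
    three are.  With p = 1 this reduces exactly to ``sigma_x^2 L`` for the
    univariate structure L.
    """

    n_mid: int
    size_low: int
    sigma_total: np.ndarray
    within_block: np.ndarray
    between_block: np.ndarray
    _eigen_blocks: tuple[np.ndarray, np.ndarray, np.ndarray] = field(
        init=False, repr=False, compare=False, default=None
    )

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma_total, dtype=float)
        b0 = np.asarray(self.within_block, dtype=float)
        b1 = np.asarray(self.between_block, dtype=float)
        p = s.shape[0]
        for name, mat in (("sigma_total", s), ("within_block", b0), ("between_block", b1)):
            if mat.shape != (p, p):
                raise ValueError(f"{name} must be {p}x{p}, got {mat.shape}")
            if not np.allclose(mat, mat.T):
                raise ValueError(f"{name} must be symmetric")
        object.__setattr__(self, "sigma_total", s)
        object.__setattr__(self, "within_block", b0)
        object.__setattr__(self, "between_block", b1)
        m, n_s = self.size_low, self.n_mid
        z1 = s - b0
        z2 = s + (m - 1) * b0 - m * b1
        z3 = s + (m - 1) * b0 + (n_s - 1) * m * b1
        for name, z in (("Z1", z1), ("Z2", z2), ("Z3", z3)):
            if np.linalg.eigvalsh(z).min() <= 0:
                raise InvalidCorrelationError(
                    f"block eigen-matrix {name} is not positive definite; the "
                    "assembled covariance is invalid"
                )
        object.__setattr__(self, "_eigen_blocks", (z1, z2, z3))

    @property
    def p(self) -> int:
        return self.sigma_total.shape[0]

    @property
    def eigen_blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(Z1, Z2, Z3), the block analogues of the scalar eigenvalues."""
        return self._eigen_blocks

    def dense(self, max_side: int = 4000) -> np.ndarray:
        """Dense covariance of the stacked p-vectors (side n_mid*size_low*p)."""
        side = self.n_mid * self.size_low * self.p
        if side > max_side:
            raise DimensionOverflowError(
                f"dense matrix of side {side} exceeds cap {max_side}"
            )
        m, n_s = self.size_low, self.n_mid
        s, b0, b1 = self.sigma_total, self.within_block, self.between_block
        eye_nm = np.eye(n_s * m)
        within = np.kron(np.eye(n_s), np.ones((m, m)))
        ones = np.ones((n_s * m, n_s * m))
        return (
            np.kron(eye_nm, s - b0)
            + np.kron(within, b0 - b1)
            + np.kron(ones, b1)
        )


def block_nested_exchangeable(
    n_mid: int,
    size_low: int,
    sigma_total: np.ndarray,
    within_block: np.ndarray,
    between_block: np.ndarray,
) -> BlockNestedExchangeable:
    """Assemble and validate a nested block exchangeable covariance structure."""
    return BlockNestedExchangeable(
        n_mid=n_mid,
        size_low=size_low,
        sigma_total=np.asarray(sigma_total, dtype=float),
        within_block=np.asarray(within_block, dtype=float),
        between_block=np.asarray(between_block, dtype=float),
    )
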