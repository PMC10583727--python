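"""Power and sample-size solvers for three-level trial design.

A two-sided Wald test of a scalar effect Delta with unit variance sigma^2
(the scaled lim n_c n_s m var form) has approximate power

    Phi(|Delta|/SE - z_{1-a/2}) + Phi(-|Delta|/SE - z_{1-a/2}),
    SE = sqrt(sigma^2 / (n_c n_s m)),

under the normal reference.  Inverting the dominant term yields the
sample-size inequality n_c n_s m >= sigma^2 (z_{1-a/2} + z_{power})^2 /
Delta^2.  For the ATE under cluster randomization a t reference with the
between-within degrees of freedom (n_c - 2) is used instead, in which case
the required n_c is found by upward integer search (the t criterion has no
closed-form inverse).  Joint tests of p interaction coefficients use the
noncentral chi-square power equation with noncentrality
n_c Delta' Omega4^{-1} Delta.

Feasibility rounding: under cluster randomization the solved n_c is rounded
up to the smallest integer making n_c * alloc integral (the smallest even
integer for equal allocation); for the other levels a plain ceiling is
taken because the randomized dimension (n_s or m) is fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .icc import inverse_coefficients
from .variance import (
    DesignSpec,
    ModifierModel,
    OutcomeModel,
    ate_unit_variance,
    hte_unit_variance,
    with_dimensions,
)

REFERENCES = ("normal", "t_betweenwithin", "noncentral_chisq")


class UnattainablePowerError(RuntimeError):
    """Raised when the target power cannot be reached below the search cap."""


@dataclass(frozen=True)
class TestSpec:
    """Hypothesis-test settings: size, target power, effect, reference."""

    effect: Union[float, Sequence[float]]
    type1: float = 0.05
    target_power: float = 0.8
    reference: str = "normal"

    def __post_init__(self) -> None:
        if not 0 < self.type1 < 1:
            raise ValueError("type1 must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0, 1)")
        if self.reference not in REFERENCES:
            raise ValueError(f"reference must be one of {REFERENCES}")
        eff = np.atleast_1d(np.asarray(self.effect, dtype=float))
        if np.all(eff == 0):
            raise ValueError("effect must be nonzero")

    @property
    def effect_scalar(self) -> float:
        eff = np.atleast_1d(np.asarray(self.effect, dtype=float))
        if eff.size != 1:
            raise ValueError("a scalar effect is required here")
        return float(eff[0])


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a sample-size solve for one design dimension."""

    solved_dimension: str
    raw_solution: float
    rounded: int
    achieved_power: float
    target_power: float
    reference: str

    def to_dict(self) -> dict:
        return {
            "solved_dimension": self.solved_dimension,
            "raw_solution": self.raw_solution,
            "rounded": self.rounded,
            "achieved_power": self.achieved_power,
            "target_power": self.target_power,
            "reference": self.reference,
        }


def _normal_power(delta: float, se: float, type1: float) -> float:
    z = stats.norm.ppf(1.0 - type1 / 2.0)
    shift = abs(delta) / se
    return float(stats.norm.cdf(shift - z) + stats.norm.cdf(-shift - z))


def _t_power(delta: float, se: float, type1: float, df: int) -> float:
    if df < 1:
        raise ValueError("t reference requires n_c > 2")
    tcrit = stats.t.ppf(1.0 - type1 / 2.0, df)
    ncp = abs(delta) / se
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def wald_power(
    unit_variance: float, design: DesignSpec, test: TestSpec
) -> float:
    """Two-sided Wald power at the given design for a scalar effect.

    ``unit_variance`` is the scaled sigma^2; the standard error is
    sqrt(sigma^2 / (n_c n_s m)).  The minor tail is included (it is
    negligible at practical effect sizes but analytically part of the
    two-sided rejection probability).
    """
    if unit_variance <= 0:
        raise ValueError("unit_variance must be positive")
    se = math.sqrt(unit_variance / design.n_total)
    delta = test.effect_scalar
    if test.reference == "t_betweenwithin":
        if design.n_c <= 2:
            raise ValueError("t reference requires n_c > 2")
        return _t_power(delta, se, test.type1, design.n_c - 2)
    return _normal_power(delta, se, test.type1)


def _round_up_clusters(raw: float, design: DesignSpec) -> int:
    """Smallest feasible integer n_c >= raw.

    Cluster randomization requires n_c * alloc integral (even n_c for equal
    allocation); other levels only need a ceiling since their randomized
    dimension is fixed.
    """
    n = max(1, math.ceil(raw - 1e-9))
    if design.rand_level != "cluster":
        return n
    while True:
        k = n * design.alloc
        if abs(k - round(k)) < 1e-9:
            return n
        n += 1


def required_clusters(
    unit_variance: float, design: DesignSpec, test: TestSpec
) -> SampleSizeResult:
    """Required number of clusters for a scalar two-sided Wald test.

    Normal reference: closed-form inversion of the power formula followed by
    feasibility rounding.  t reference (between-within df): upward search
    over feasible integers, since the critical value changes with n_c.
    """
    if unit_variance <= 0:
        raise ValueError("unit_variance must be positive")
    delta = test.effect_scalar
    z_a = stats.norm.ppf(1.0 - test.type1 / 2.0)
    z_p = stats.norm.ppf(test.target_power)
    raw = unit_variance * (z_a + z_p) ** 2 / (delta**2 * design.n_s * design.m)
    n_c = _round_up_clusters(raw, design)
    if test.reference == "t_betweenwithin":
        step = _round_up_clusters(n_c + 1, design) - n_c if design.rand_level == "cluster" else 1
        step = max(step, 1)
        n_c = max(n_c, _round_up_clusters(3, design))
        cap = 10**6
        while n_c <= cap:
            pw = wald_power(unit_variance, with_dimensions(design, n_c=n_c), test)
            if pw >= test.target_power:
                break
            n_c += step
        else:
            raise UnattainablePowerError("target power unreachable below cap")
        achieved = pw
    else:
        achieved = wald_power(unit_variance, with_dimensions(design, n_c=n_c), test)
    return SampleSizeResult(
        solved_dimension="n_c",
        raw_solution=raw,
        rounded=n_c,
        achieved_power=achieved,
        target_power=test.target_power,
        reference=test.reference,
    )


def required_clusters_hte(
    design: DesignSpec,
    outcome: OutcomeModel,
    modifier: ModifierModel,
    test: TestSpec,
) -> SampleSizeResult:
    """Convenience wrapper: sigma_4^2 then :func:`required_clusters`."""
    sigma4 = hte_unit_variance(design, outcome, modifier).unit_variance
    return required_clusters(sigma4, design, test)


def required_clusters_ate(
    design: DesignSpec, outcome: OutcomeModel, test: TestSpec
) -> SampleSizeResult:
    """Convenience wrapper: sigma_2^2 then :func:`required_clusters`."""
    sigma2 = ate_unit_variance(design, outcome).unit_variance
    return required_clusters(sigma2, design, test)


def solve_dimension(
    free: str,
    design: DesignSpec,
    outcome: OutcomeModel,
    test: TestSpec,
    modifier: Optional[ModifierModel] = None,
    estimand: str = "hte",
    cap: int = 10**6,
) -> SampleSizeResult:
    """Smallest value of one design dimension achieving the target power.

    The unit variance is re-evaluated at every candidate because sigma_4^2
    depends on n_s and m.  Power is monotone in each dimension, so a
    doubling bracket plus bisection finds the smallest feasible integer; if
    the power at ``cap`` is still below target (e.g. growing m under cluster
    randomization, where the design effect plateaus) an
    :class:`UnattainablePowerError` is raised.
    """
    if free not in ("n_c", "n_s", "m"):
        raise ValueError("free must be one of n_c, n_s, m")

    def feasible(value: int) -> int:
        if free == "n_c" and design.rand_level == "cluster":
            d = with_dimensions(design, n_c=value)
            while not d.is_feasible():
                value += 1
                d = with_dimensions(design, n_c=value)
        elif free == "n_s" and design.rand_level == "subcluster":
            d = with_dimensions(design, n_s=value)
            while not d.is_feasible():
                value += 1
                d = with_dimensions(design, n_s=value)
        elif free == "m" and design.rand_level == "participant":
            d = with_dimensions(design, m=value)
            while not d.is_feasible():
                value += 1
                d = with_dimensions(design, m=value)
        return value

    def power_at(value: int) -> float:
        d = with_dimensions(design, **{free: value})
        if estimand == "hte":
            sigma = hte_unit_variance(d, outcome, modifier).unit_variance
        else:
            sigma = ate_unit_variance(d, outcome).unit_variance
        if test.reference == "t_betweenwithin" and d.n_c <= 2:
            return 0.0
        return wald_power(sigma, d, test)

    lo = feasible(2 if free != "n_c" or test.reference != "t_betweenwithin" else 4)
    if power_at(lo) >= test.target_power:
        raw = float(lo)
        return SampleSizeResult(free, raw, lo, power_at(lo), test.target_power, test.reference)
    hi = lo
    while power_at(feasible(hi)) < test.target_power:
        if hi >= cap:
            raise UnattainablePowerError(
                f"target power {test.target_power} unreachable in {free} below {cap}"
            )
        hi = min(cap, hi * 2)
    # bisect on raw integers; feasibility rounding is applied when probing so
    # the result is the smallest feasible value whose power reaches target
    lo_b, hi_b = lo, hi
    while hi_b - lo_b > 1:
        mid = (lo_b + hi_b) // 2
        if power_at(feasible(mid)) >= test.target_power:
            hi_b = mid
        else:
            lo_b = mid
    result = feasible(hi_b)
    return SampleSizeResult(
        solved_dimension=free,
        raw_solution=float(result),
        rounded=result,
        achieved_power=power_at(result),
        target_power=test.target_power,
        reference=test.reference,
    )


# ---------------------------------------------------------------------------
# Multivariate effect modifiers


def _w_pair_moments(design: DesignSpec) -> tuple[float, float, float]:
    """Second moments of the centered treatment indicator for participant
    pairs (same participant, same subcluster, different subclusters) under
    exactly balanced randomization at the configured level."""
    phi = design.alloc * (1.0 - design.alloc)
    if design.rand_level == "cluster":
        return phi, phi, phi
    if not design.is_feasible():
        raise ValueError(
            f"allocation {design.alloc} is infeasible at the "
            f"{design.rand_level} level (non-integral treated count)"
        )
    if design.rand_level == "subcluster":
        off = -phi / (design.n_s - 1) if design.n_s > 1 else 0.0
        return phi, phi, off
    same = -phi / (design.m - 1) if design.m > 1 else 0.0
    return phi, same, 0.0


def mv_omega4(
    design: DesignSpec,
    outcome: OutcomeModel,
    mu_x: np.ndarray,
    sigma_total: np.ndarray,
    within_block: np.ndarray,
    between_block: np.ndarray,
) -> np.ndarray:
    """Asymptotic covariance Omega_4 of sqrt(n_c) (b4-hat - b4) for p
    modifiers with a nested block exchangeable covariance.

    The expected per-cluster information for the interaction block is

        G = sum_{a,b} A_ab E[w_a w_b] C_ab,

    where A_ab are the (three distinct) entries of R^{-1}, E[w_a w_b] the
    pairwise treatment moments of the randomization scheme, and C_ab the
    modifier covariance block for the pair (Sigma, B0 or B1).  The modifier
    mean drops out of the interaction block exactly, so Omega_4 =
    sigma_{y|x}^2 G^{-1}.  With p = 1 this reduces to sigma_4^2 / (n_s m).
    """
    from .icc import block_nested_exchangeable

    structure = block_nested_exchangeable(
        design.n_s, design.m, sigma_total, within_block, between_block
    )
    p = structure.p
    mu_x = np.atleast_1d(np.asarray(mu_x, dtype=float))
    if mu_x.shape != (p,):
        raise ValueError(f"mu_x must have length {p}")
    a_diag, a_same, a_cross = inverse_coefficients(
        outcome.correlation_spec(design.n_s, design.m)
    )
    w_diag, w_same, w_cross = _w_pair_moments(design)
    n_s, m = design.n_s, design.m
    n_pairs_same = n_s * m * (m - 1)
    n_pairs_cross = n_s * (n_s - 1) * m * m
    g = (
        n_s * m * a_diag * w_diag * structure.sigma_total
        + n_pairs_same * a_same * w_same * structure.within_block
        + n_pairs_cross * a_cross * w_cross * structure.between_block
    )
    eigvals = np.linalg.eigvalsh(g)
    if eigvals.min() <= 1e-12 * max(1.0, eigvals.max()):
        direction = np.linalg.eigh(g)[1][:, 0]
        raise np.linalg.LinAlgError(
            "expected information for the interaction block is singular "
            f"along direction {np.round(direction, 4)}"
        )
    return outcome.sigma2_y_given_x * np.linalg.inv(g)


def mv_power(
    omega4: np.ndarray, n_c: int, effect: np.ndarray, type1: float = 0.05
) -> float:
    """Noncentral chi-square power of the joint p-dof interaction Wald test.

    The statistic n_c b4-hat' Omega4^{-1} b4-hat is chi-square(p) under the
    null; under the alternative its noncentrality is
    n_c Delta' Omega4^{-1} Delta.
    """
    omega4 = np.atleast_2d(np.asarray(omega4, dtype=float))
    effect = np.atleast_1d(np.asarray(effect, dtype=float))
    p = omega4.shape[0]
    ncp = float(n_c * effect @ np.linalg.solve(omega4, effect))
    crit = stats.chi2.ppf(1.0 - type1, p)
    if ncp == 0.0:
        return float(type1)
    return float(stats.ncx2.sf(crit, p, ncp))


def mv_required_clusters(
    omega4_fn: Callable[[int], np.ndarray],
    effect: np.ndarray,
    test: TestSpec,
    design: DesignSpec,
    free: str = "n_c",
    cap: int = 10**6,
) -> SampleSizeResult:
    """Smallest feasible free dimension achieving the joint-test power.

    ``omega4_fn`` maps a candidate value of the free dimension to the
    corresponding Omega_4 (re-evaluated because the covariance depends on
    n_s and m; for free n_c it is constant but the noncentrality scales).
    """
    effect = np.atleast_1d(np.asarray(effect, dtype=float))

    def feasible(value: int) -> int:
        dims = {free: value}
        d = with_dimensions(design, **dims)
        level_dim = {"cluster": "n_c", "subcluster": "n_s", "participant": "m"}[
            design.rand_level
        ]
        if free == level_dim:
            while not d.is_feasible():
                value += 1
                d = with_dimensions(design, **{free: value})
        return value

    def power_at(value: int) -> float:
        d = with_dimensions(design, **{free: value})
        return mv_power(omega4_fn(value), d.n_c, effect, test.type1)

    lo = feasible(2)
    if power_at(lo) >= test.target_power:
        return SampleSizeResult(free, float(lo), lo, power_at(lo), test.target_power, "noncentral_chisq")
    hi = lo
    while power_at(feasible(hi)) < test.target_power:
        if hi >= cap:
            raise UnattainablePowerError(
                f"target power unreachable in {free} below {cap}"
            )
        hi = min(cap, hi * 2)
    lo_b, hi_b = lo, hi
    while hi_b - lo_b > 1:
        mid = (lo_b + hi_b) // 2
        if power_at(feasible(mid)) >= test.target_power:
            hi_b = mid
        else:
            lo_b = mid
    result = feasible(hi_b)
    return SampleSizeResult(
        solved_dimension=free,
        raw_solution=float(result),
        rounded=result,
        achieved_power=power_at(result),
        target_power=test.target_power,
        reference="noncentral_chisq",
    )


def power_contour(
    design: DesignSpec,
    outcome: OutcomeModel,
    modifier: ModifierModel,
    test: TestSpec,
    primary_values: Sequence[float],
    ratio_values: Sequence[float],
    vary: str = "covariate",
) -> pd.DataFrame:
    """Grid of HTE powers over ICC values, long format.

    ``vary='covariate'`` sweeps rho0 over ``primary_values`` and
    rho1 = ratio * rho0 over ``ratio_values`` with the outcome ICCs fixed;
    ``vary='outcome'`` sweeps (alpha0, alpha1 = ratio * alpha0) with the
    covariate ICCs fixed.  Grid points violating eigenvalue positivity are
    flagged infeasible (power NaN), never dropped.
    """
    if vary not in ("covariate", "outcome"):
        raise ValueError("vary must be 'covariate' or 'outcome'")
    rows = []
    for primary in primary_values:
        for ratio in ratio_values:
            if vary == "covariate":
                a0, a1 = outcome.alpha0, outcome.alpha1
                r0, r1 = primary, ratio * primary
            else:
                a0, a1 = primary, ratio * primary
                r0, r1 = modifier.rho0, modifier.rho1
            row = {
                "alpha0": a0,
                "alpha1": a1,
                "rho0": r0,
                "rho1": r1,
                "n_c": design.n_c,
                "n_s": design.n_s,
                "m": design.m,
                "rand_level": design.rand_level,
                "effect": test.effect_scalar,
                "type1": test.type1,
            }
            try:
                out = OutcomeModel(
                    alpha0=a0, alpha1=a1, sigma2_y_given_x=outcome.sigma2_y_given_x
                )
                mod = ModifierModel(
                    rho0=r0,
                    rho1=r1,
                    level=modifier.level,
                    mu_x=modifier.mu_x,
                    sigma2_x=modifier.sigma2_x,
                )
                sigma4 = hte_unit_variance(design, out, mod).unit_variance
                row["power"] = wald_power(sigma4, design, test)
                row["feasible"] = True
            except (ValueError, ArithmeticError):
                row["power"] = np.nan
                row["feasible"] = False
            rows.append(row)
    return pd.DataFrame(rows)
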