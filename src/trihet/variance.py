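"""Closed-form variances and design effects for HTE and ATE estimators.

In the linear mixed ANCOVA model

    Y_ijk = b1 + b2 (W_ijk - Wbar) + b3 X_ijk + b4 (W_ijk - Wbar) X_ijk
            + gamma_i + u_ij + eps_ijk,

the large-sample variance of the interaction (HTE) estimator b4-hat and of
the covariate-adjusted treatment-effect (ATE) estimator b2-hat depend on the
level of randomization (cluster / subcluster / participant), the outcome
ICCs (alpha0, alpha1) conditional on the modifier, and — for the HTE — the
covariate ICCs (rho0, rho1) of the modifier itself.  Writing lam1..lam3 and
zeta1..zeta3 for the eigenvalues of the two nested exchangeable correlation
matrices, the scaled unit variance sigma_4^2 = lim n_c n_s m var(b4-hat) is

    cluster:      base * n_s m / (zeta3/lam3 + (n_s-1) zeta2/lam2
                                  + n_s (m-1) zeta1/lam1)
    subcluster:   base * m / (m/lam1 - (1 + (m-1) rho0) (1/lam1 - 1/lam2))
    participant:  base * lam1

with base = sigma_{y|x}^2 / (Wbar (1 - Wbar) sigma_x^2).  Modifiers measured
at the subcluster or cluster level are the degenerate cases rho0 = 1 and
rho0 = rho1 = 1 of the same formulas.  The ATE unit variance is
sigma_{y|x}^2 / (Wbar (1 - Wbar)) times lam3, lam2 or lam1 respectively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .icc import EigenTriple, NestedExchangeableSpec, eigen_triple

RAND_LEVELS = ("cluster", "subcluster", "participant")
MODIFIER_LEVELS = ("participant", "subcluster", "cluster")


@dataclass(frozen=True)
class DesignSpec:
    """Dimensions and randomization scheme of a balanced three-level trial.

    ``n_c`` clusters, each with ``n_s`` subclusters of ``m`` participants;
    randomization at ``rand_level`` with treated fraction ``alloc``.
    """

    n_c: int
    n_s: int
    m: int
    rand_level: str = "cluster"
    alloc: float = 0.5

    def __post_init__(self) -> None:
        if self.rand_level not in RAND_LEVELS:
            raise ValueError(f"rand_level must be one of {RAND_LEVELS}")
        if not 0 < self.alloc < 1:
            raise ValueError("alloc must lie strictly between 0 and 1")
        for name in ("n_c", "n_s", "m"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n_c * self.n_s * self.m

    def randomized_count(self) -> int:
        """Number of units at the randomized level within one randomization
        stratum (n_c, n_s or m)."""
        return {"cluster": self.n_c, "subcluster": self.n_s, "participant": self.m}[
            self.rand_level
        ]

    def is_feasible(self) -> bool:
        """Whether the allocation yields an integral number of treated units."""
        k = self.randomized_count() * self.alloc
        return abs(k - round(k)) < 1e-9


@dataclass(frozen=True)
class OutcomeModel:
    """Conditional outcome variance and ICCs given modifiers and treatment."""

    alpha0: float
    alpha1: float
    sigma2_y_given_x: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_y_given_x <= 0:
            raise ValueError("sigma2_y_given_x must be positive")

    def correlation_spec(self, n_s: int, m: int) -> NestedExchangeableSpec:
        return NestedExchangeableSpec(
            n_mid=n_s, size_low=m, within_corr=self.alpha0, between_corr=self.alpha1
        )

    @property
    def sigma2_gamma(self) -> float:
        return self.sigma2_y_given_x * self.alpha1

    @property
    def sigma2_u(self) -> float:
        return self.sigma2_y_given_x * (self.alpha0 - self.alpha1)

    @property
    def sigma2_eps(self) -> float:
        return self.sigma2_y_given_x * (1.0 - self.alpha0)


def binary_modifier_variance(prevalence: float) -> float:
    """Marginal variance p(1-p) of a binary effect modifier; maximal at 0.5."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    return prevalence * (1.0 - prevalence)


@dataclass(frozen=True)
class ModifierModel:
    """Moments and ICCs of an effect modifier.

    ``level`` is the measurement level.  A subcluster-level modifier is
    constant within subclusters (rho0 = 1 forced); a cluster-level modifier
    is constant within clusters (rho0 = rho1 = 1 forced).  A binary modifier
    must state its prevalence, which determines ``sigma2_x = p(1-p)``.
    """

    rho0: float
    rho1: float
    level: str = "participant"
    kind: str = "continuous"
    mu_x: float = 0.0
    sigma2_x: float = 1.0
    prevalence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.level not in MODIFIER_LEVELS:
            raise ValueError(f"level must be one of {MODIFIER_LEVELS}")
        if self.kind not in ("continuous", "binary"):
            raise ValueError("kind must be 'continuous' or 'binary'")
        if self.kind == "binary":
            if self.prevalence is None:
                raise ValueError("binary modifier requires a prevalence")
            object.__setattr__(
                self, "sigma2_x", binary_modifier_variance(self.prevalence)
            )
            object.__setattr__(self, "mu_x", float(self.prevalence))
        if self.sigma2_x <= 0:
            raise ValueError("sigma2_x must be positive")
        if self.level == "subcluster":
            object.__setattr__(self, "rho0", 1.0)
        elif self.level == "cluster":
            object.__setattr__(self, "rho0", 1.0)
            object.__setattr__(self, "rho1", 1.0)

    def correlation_spec(self, n_s: int, m: int) -> NestedExchangeableSpec:
        # singular structures allowed: the covariate matrix is never inverted,
        # and degenerate measurement levels (rho0 = 1) are legitimate
        return NestedExchangeableSpec(
            n_mid=n_s,
            size_low=m,
            within_corr=self.rho0,
            between_corr=self.rho1,
            allow_singular=True,
        )


@dataclass(frozen=True)
class VarianceResult:
    """A scaled unit variance together with its design-effect decomposition.

    ``unit_variance`` is sigma_4^2 (HTE) or sigma_2^2 (ATE), i.e.
    lim n_c n_s m var(estimator); it always factors as
    ``design_effect`` times the unclustered base variance.
    """

    unit_variance: float
    design_effect: float
    base_variance: float
    eigen_outcome: EigenTriple
    eigen_covariate: Optional[EigenTriple]
    inputs: dict

    def to_json(self, **kwargs) -> str:
        payload = {
            "unit_variance": self.unit_variance,
            "design_effect": self.design_effect,
            "base_variance": self.base_variance,
            "eigen_outcome": [
                self.eigen_outcome.lam1,
                self.eigen_outcome.lam2,
                self.eigen_outcome.lam3,
            ],
            "eigen_covariate": None
            if self.eigen_covariate is None
            else [
                self.eigen_covariate.lam1,
                self.eigen_covariate.lam2,
                self.eigen_covariate.lam3,
            ],
            "inputs": self.inputs,
        }
        return json.dumps(payload, **kwargs)


def _allocation_factor(design: DesignSpec) -> float:
    return design.alloc * (1.0 - design.alloc)


def hte_design_effect(
    design: DesignSpec, outcome: OutcomeModel, modifier: ModifierModel
) -> float:
    """Design effect theta for the interaction (HTE) estimator.

    theta_(3) (cluster randomization) depends on all four ICCs; theta_(2)
    (subcluster) is free of rho1; theta_(1) (participant) equals lam1 and is
    free of the covariate ICCs entirely.  The subcluster- and cluster-level
    modifier special cases follow automatically from rho0 = 1 (and rho1 = 1).
    """
    n_s, m = design.n_s, design.m
    lam = eigen_triple(outcome.correlation_spec(n_s, m))
    if design.rand_level == "participant":
        return lam.lam1
    if design.rand_level == "subcluster":
        denom = m / lam.lam1 - (1.0 + (m - 1) * modifier.rho0) * (
            1.0 / lam.lam1 - 1.0 / lam.lam2
        )
        return m / denom
    zeta = eigen_triple(modifier.correlation_spec(n_s, m))
    denom = (
        zeta.lam3 / lam.lam3
        + (n_s - 1) * zeta.lam2 / lam.lam2
        + n_s * (m - 1) * zeta.lam1 / lam.lam1
    )
    return n_s * m / denom


def hte_unit_variance(
    design: DesignSpec, outcome: OutcomeModel, modifier: ModifierModel
) -> VarianceResult:
    """Scaled unit variance sigma_4^2 = lim n_c n_s m var(b4-hat)."""
    theta = hte_design_effect(design, outcome, modifier)
    base = outcome.sigma2_y_given_x / (_allocation_factor(design) * modifier.sigma2_x)
    lam = eigen_triple(outcome.correlation_spec(design.n_s, design.m))
    zeta = eigen_triple(modifier.correlation_spec(design.n_s, design.m))
    return VarianceResult(
        unit_variance=base * theta,
        design_effect=theta,
        base_variance=base,
        eigen_outcome=lam,
        eigen_covariate=zeta,
        inputs={
            "estimand": "hte",
            "rand_level": design.rand_level,
            "n_s": design.n_s,
            "m": design.m,
            "alloc": design.alloc,
            "alpha0": outcome.alpha0,
            "alpha1": outcome.alpha1,
            "sigma2_y_given_x": outcome.sigma2_y_given_x,
            "rho0": modifier.rho0,
            "rho1": modifier.rho1,
            "sigma2_x": modifier.sigma2_x,
            "modifier_level": modifier.level,
        },
    )


def ate_unit_variance(design: DesignSpec, outcome: OutcomeModel) -> VarianceResult:
    """Scaled unit variance sigma_2^2 of the covariate-adjusted ATE estimator.

    The design effect is a single outcome eigenvalue: lam3, lam2 or lam1 for
    cluster, subcluster or participant randomization respectively.
    """
    lam = eigen_triple(outcome.correlation_spec(design.n_s, design.m))
    theta = {
        "cluster": lam.lam3,
        "subcluster": lam.lam2,
        "participant": lam.lam1,
    }[design.rand_level]
    base = outcome.sigma2_y_given_x / _allocation_factor(design)
    return VarianceResult(
        unit_variance=base * theta,
        design_effect=theta,
        base_variance=base,
        eigen_outcome=lam,
        eigen_covariate=None,
        inputs={
            "estimand": "ate",
            "rand_level": design.rand_level,
            "n_s": design.n_s,
            "m": design.m,
            "alloc": design.alloc,
            "alpha0": outcome.alpha0,
            "alpha1": outcome.alpha1,
            "sigma2_y_given_x": outcome.sigma2_y_given_x,
        },
    )


def contextual_decompose(x: np.ndarray, design: DesignSpec) -> pd.DataFrame:
    """Split a participant-level modifier into contextual components.

    Returns a DataFrame with columns ``within_dev`` (X - subcluster mean),
    ``subcluster_dev`` (subcluster mean - cluster mean) and ``cluster_mean``,
    which sum to the original values and are mutually orthogonal within each
    cluster under balance.  Input must be ordered by (cluster, subcluster,
    participant) and exactly balanced.
    """
    x = np.asarray(x, dtype=float)
    n_c, n_s, m = design.n_c, design.n_s, design.m
    if x.shape != (n_c * n_s * m,):
        raise ValueError(
            f"expected a balanced vector of length {n_c * n_s * m}, got {x.shape}"
        )
    cube = x.reshape(n_c, n_s, m)
    sub_mean = cube.mean(axis=2, keepdims=True)
    clus_mean = cube.mean(axis=(1, 2), keepdims=True)
    within = cube - sub_mean
    between = np.broadcast_to(sub_mean - clus_mean, cube.shape)
    top = np.broadcast_to(clus_mean, cube.shape)
    return pd.DataFrame(
        {
            "within_dev": within.ravel(),
            "subcluster_dev": between.ravel(),
            "cluster_mean": top.ravel(),
        }
    )


def with_dimensions(design: DesignSpec, **dims) -> DesignSpec:
    """Return a copy of ``design`` with some of n_c/n_s/m replaced."""
    return replace(design, **dims)
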