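"""Monte Carlo generator for balanced three-level trial data.

The generative model mirrors the linear mixed ANCOVA used for analysis.
The effect modifier follows a nested random-effects model,

    X_ijk = mu_x + a_i + b_ij + c_ijk,
    a_i ~ N(0, sigma_x^2 rho1),  b_ij ~ N(0, sigma_x^2 (rho0 - rho1)),
    c_ijk ~ N(0, sigma_x^2 (1 - rho0)),

which induces the nested exchangeable covariate correlation (rho0, rho1).
The outcome is

    Y_ijk = beta1 + beta2 W_ijk + beta3' X_ijk + beta4' W_ijk X_ijk
            + gamma_i + u_ij + eps_ijk,

with gamma_i ~ N(0, sigma_{y|x}^2 alpha1), u_ij ~ N(0, sigma_{y|x}^2
(alpha0 - alpha1)), eps_ijk ~ N(0, sigma_{y|x}^2 (1 - alpha0)).  Treatment
is assigned by permutation with exact balance at the randomized level.

Binary modifiers are generated by a beta-binomial-type shared-probability
scheme: cluster-level success probabilities drawn from a beta distribution
with variance rho1 p(1-p), subcluster probabilities from a beta around the
cluster draw, and Bernoulli outcomes at the participant level.  This matches
the prevalence and both covariate ICCs exactly in second moments, which is
all the design formulas use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .variance import DesignSpec


@dataclass(frozen=True)
class GenerativeConfig:
    """Full specification of one synthetic trial.

    Fixed effects are on the outcome scale; ICC/variance parameters define
    the nested random effects of both the modifier and the outcome.  The
    implied variance components must be nonnegative, i.e. rho1 >= 0,
    rho0 >= rho1, rho0 <= 1 (and likewise for alpha0, alpha1).
    """

    design: DesignSpec
    beta1: float = 1.0
    beta2: float = 0.2
    beta3: float = 0.3
    beta4: float = 0.1
    mu_x: float = 1.0
    sigma2_x: float = 1.0
    rho0: float = 0.1
    rho1: float = 0.05
    sigma2_y_given_x: float = 1.0
    alpha0: float = 0.05
    alpha1: float = 0.01
    seed: int = 0
    binary_modifier: bool = False
    prevalence: Optional[float] = None

    def __post_init__(self) -> None:
        for label, lo, hi in (
            ("rho", self.rho1, self.rho0),
            ("alpha", self.alpha1, self.alpha0),
        ):
            if lo < 0 or hi < lo or hi > 1:
                raise ValueError(
                    f"{label} parameters must satisfy 0 <= {label}1 <= {label}0 <= 1 "
                    "for a nonnegative variance-component decomposition"
                )
        if self.sigma2_x <= 0 or self.sigma2_y_given_x <= 0:
            raise ValueError("variances must be positive")
        if self.binary_modifier:
            if self.prevalence is None or not 0 < self.prevalence < 1:
                raise ValueError("binary modifier requires prevalence in (0, 1)")
            object.__setattr__(
                self, "sigma2_x", self.prevalence * (1 - self.prevalence)
            )
            object.__setattr__(self, "mu_x", float(self.prevalence))


def generate_modifier(config: GenerativeConfig, rng: np.random.Generator) -> np.ndarray:
    """Effect modifier values, ordered by (cluster, subcluster, participant)."""
    d = config.design
    n_c, n_s, m = d.n_c, d.n_s, d.m
    if config.binary_modifier:
        return _generate_binary_modifier(config, rng)
    sx = math.sqrt(config.sigma2_x)
    a = rng.normal(0.0, sx * math.sqrt(config.rho1), size=(n_c, 1, 1))
    b = rng.normal(0.0, sx * math.sqrt(config.rho0 - config.rho1), size=(n_c, n_s, 1))
    c = rng.normal(0.0, sx * math.sqrt(1.0 - config.rho0), size=(n_c, n_s, m))
    return (config.mu_x + a + b + c).ravel()


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, var_frac: float) -> np.ndarray:
    """Beta draws with the given means and variance var_frac * mean(1-mean).

    var_frac in [0, 1); var_frac = 0 returns the means unchanged.
    """
    mean = np.asarray(mean, dtype=float)
    if var_frac <= 0:
        return mean.copy()
    nu = 1.0 / var_frac - 1.0  # a + b of the beta; var = m(1-m)/(nu+1)
    return rng.beta(mean * nu, (1.0 - mean) * nu)


def _generate_binary_modifier(
    config: GenerativeConfig, rng: np.random.Generator
) -> np.ndarray:
    d = config.design
    n_c, n_s, m = d.n_c, d.n_s, d.m
    p, r0, r1 = config.prevalence, config.rho0, config.rho1
    p_clus = _beta_draw(rng, np.full(n_c, p), r1)
    # conditional variance fraction chosen so the marginal subcluster-level
    # probability variance equals rho0 p(1-p)
    if r0 > r1:
        frac = (r0 - r1) / (1.0 - r1)
        p_sub = _beta_draw(rng, np.repeat(p_clus, n_s), frac)
    else:
        p_sub = np.repeat(p_clus, n_s)
    probs = np.repeat(p_sub, m)
    return rng.binomial(1, probs).astype(float)


def assign_treatment(
    design: DesignSpec, rng: np.random.Generator
) -> np.ndarray:
    """Treatment indicators with exact balance at the randomized level."""
    n_c, n_s, m = design.n_c, design.n_s, design.m
    if not design.is_feasible():
        raise ValueError(
            f"allocation {design.alloc} infeasible at the {design.rand_level} "
            "level: treated count is not an integer"
        )

    def balanced(n_units: int) -> np.ndarray:
        k = round(n_units * design.alloc)
        w = np.zeros(n_units, dtype=float)
        w[:k] = 1.0
        return rng.permutation(w)

    if design.rand_level == "cluster":
        return np.repeat(balanced(n_c), n_s * m)
    if design.rand_level == "subcluster":
        per_cluster = [np.repeat(balanced(n_s), m) for _ in range(n_c)]
        return np.concatenate(per_cluster)
    per_sub = [balanced(m) for _ in range(n_c * n_s)]
    return np.concatenate(per_sub)


def generate_outcome(
    config: GenerativeConfig,
    x: np.ndarray,
    w: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Outcome values under the linear mixed ANCOVA generative model."""
    d = config.design
    n_c, n_s, m = d.n_c, d.n_s, d.m
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != (d.n_total,) or w.shape != (d.n_total,):
        raise ValueError("x and w must be balanced vectors of length n_c*n_s*m")
    sy = math.sqrt(config.sigma2_y_given_x)
    gamma = rng.normal(0.0, sy * math.sqrt(config.alpha1), size=(n_c, 1, 1))
    u = rng.normal(
        0.0, sy * math.sqrt(config.alpha0 - config.alpha1), size=(n_c, n_s, 1)
    )
    eps = rng.normal(0.0, sy * math.sqrt(1.0 - config.alpha0), size=(n_c, n_s, m))
    random_part = (gamma + u + eps).ravel()
    return (
        config.beta1
        + config.beta2 * w
        + config.beta3 * x
        + config.beta4 * w * x
        + random_part
    )


def simulate_trial(config: GenerativeConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """One complete trial dataset in tidy long format.

    Columns: cluster, subcluster, participant (1-based ids), W, X, Y; rows
    ordered by (cluster, subcluster, participant).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    d = config.design
    x = generate_modifier(config, rng)
    w = assign_treatment(d, rng)
    y = generate_outcome(config, x, w, rng)
    idx = pd.MultiIndex.from_product(
        [range(1, d.n_c + 1), range(1, d.n_s + 1), range(1, d.m + 1)],
        names=["cluster", "subcluster", "participant"],
    )
    return pd.DataFrame({"W": w, "X": x, "Y": y}, index=idx).reset_index()


@dataclass(frozen=True)
class MarginalICCResult:
    """Marginal (covariate-unadjusted) outcome moments implied by the model."""

    omega: float
    alpha0_marginal: float
    alpha1_marginal: float
    sigma2_y_marginal: float


def marginal_icc(config: GenerativeConfig) -> MarginalICCResult:
    """Marginal outcome variance and ICCs after integrating out the modifier.

    Conditioning on treatment arm (the standard convention for outcome ICCs
    in trials), the modifier contributes c^2 = (b3^2 + b4^2 Wbar(1-Wbar))
    sigma_x^2 to the outcome variance, where b3 = beta3 + beta4 Wbar is the
    centered-parameterization covariate slope.  With weight
    omega = sigma_{y|x}^2 / (sigma_{y|x}^2 + c^2), the marginal ICCs are the
    omega-weighted averages of the conditional outcome ICCs and the
    covariate ICCs.  These feed the covariate-unadjusted (marginal) design
    formulas for comparison with the adjusted ones.
    """
    wbar = config.design.alloc
    b3 = config.beta3 + config.beta4 * wbar
    b4 = config.beta4
    c2 = (b3**2 + b4**2 * wbar * (1.0 - wbar)) * config.sigma2_x
    sigma2_y = config.sigma2_y_given_x + c2
    omega = config.sigma2_y_given_x / sigma2_y
    return MarginalICCResult(
        omega=omega,
        alpha0_marginal=omega * config.alpha0 + (1.0 - omega) * config.rho0,
        alpha1_marginal=omega * config.alpha1 + (1.0 - omega) * config.rho1,
        sigma2_y_marginal=sigma2_y,
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Empirical rejection rate of a test over simulated replicates."""

    rejection_rate: float
    mc_se: float
    n_reps: int
    n_converged: int
    n_failed: int
    rejections: np.ndarray = field(repr=False, compare=False, default=None)
    estimates: np.ndarray = field(repr=False, compare=False, default=None)


def replicate_seeds(master_seed: int, reps: int) -> list[np.random.SeedSequence]:
    """Counter-based per-replicate seed derivation from a master seed.

    Each replicate's stream depends only on (master_seed, replicate index),
    so individual replicates are reproducible out of order.
    """
    return [np.random.SeedSequence(entropy=master_seed, spawn_key=(r,)) for r in range(reps)]


def operating_characteristics(
    config: GenerativeConfig,
    test: str = "hte",
    reference: str = "normal",
    reps: int = 1000,
    seed: Optional[int] = None,
    type1: float = 0.05,
    center_x: Optional[bool] = None,
) -> OperatingCharacteristics:
    """Empirical size or power of the REML Wald test over simulated trials.

    ``test`` selects the coefficient under test: 'hte' (interaction beta4,
    normal reference) or 'ate' (treatment effect beta2, globally mean
    centered modifier, normal or between-within t reference).  Replicates
    that fail to converge are refit once from null starting values, then
    counted as failures; the rejection rate is over converged replicates.
    """
    from .lmm import fit_lm_ancova, wald_ate, wald_hte

    if test not in ("hte", "ate"):
        raise ValueError("test must be 'hte' or 'ate'")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if center_x is None:
        center_x = test == "ate"
    master = config.seed if seed is None else seed
    rejections = np.zeros(reps, dtype=bool)
    converged = np.zeros(reps, dtype=bool)
    estimates = np.full(reps, np.nan)
    for r, ss in enumerate(replicate_seeds(master, reps)):
        rng = np.random.default_rng(ss)
        x = generate_modifier(config, rng)
        w = assign_treatment(config.design, rng)
        y = generate_outcome(config, x, w, rng)
        fit = fit_lm_ancova(
            y=y, x=x, w=w, design=config.design, center_x=center_x
        )
        if not fit.converged:
            fit = fit_lm_ancova(
                y=y, x=x, w=w, design=config.design, center_x=center_x,
                start=(0.0, 0.0),
            )
        converged[r] = fit.converged
        if not fit.converged:
            continue
        if test == "hte":
            res = wald_hte(fit)
        else:
            res = wald_ate(fit, reference=reference)
        rejections[r] = res.p_value < type1
        estimates[r] = res.estimate[0]
    n_conv = int(converged.sum())
    n_fail = reps - n_conv
    rate = float(rejections[converged].mean()) if n_conv else float("nan")
    mc_se = math.sqrt(rate * (1.0 - rate) / n_conv) if n_conv else float("nan")
    return OperatingCharacteristics(
        rejection_rate=rate,
        mc_se=mc_se,
        n_reps=reps,
        n_converged=n_conv,
        n_failed=n_fail,
        rejections=rejections,
        estimates=estimates,
    )
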