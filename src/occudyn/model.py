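"""Model core: parameters, link functions, log-likelihood and log-prior.

The model is a two-season, multi-species dynamic occupancy model with perfect
detection.  For species i in quadrat j:

    y1_ij ~ Bernoulli(psi1_ij)          logit(psi1_ij) = beta_o + eps_o_i + r_j
    y2_ij ~ Bernoulli(psi2_ij)          psi2_ij = y1_ij * phi_ij + (1 - y1_ij) * gamma_ij
    logit(phi_ij)   = beta_s + eps_s_i + (beta_sg + eps_sg_i) * g_j
    logit(gamma_ij) = beta_c + eps_c_i + (beta_cg + eps_cg_i) * g_j

phi is the survival (persistence) probability of an occupied quadrat, gamma
the colonization probability of an empty one, and g_j the binary canopy-gap
covariate.  Species random effects eps_* are exchangeable truncated normals
Normal(0, sigma_*^2) T(-10, 10); fixed effects get effectively-flat
Normal(0, 10^4) T(-10, 10) priors; the spatial effect r follows an intrinsic
CAR (ICAR) prior on the quadrat lattice, identified by a sum-to-zero
constraint with beta_o absorbing the level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, log_expit
from scipy.special import erf

from .data import PresenceAbsenceSurvey, QuadratLattice

__all__ = [
    "TRUNCATION_BOUND",
    "FIXED_EFFECT_SD",
    "EFFECT_FAMILIES",
    "FIXED_EFFECTS",
    "HYPER_SDS",
    "ModelParameters",
    "ProbabilityField",
    "inv_logit",
    "logit",
    "truncated_normal_logpdf",
    "compute_fields",
    "log_likelihood",
    "log_prior",
    "icar_log_density",
]

#: Truncation bound of every logit-scale effect: priors are cut to [-10, 10]
#: to keep the logit scale numerically stable.
TRUNCATION_BOUND = 10.0

#: SD of the fixed-effect prior Normal(0, 10^4): essentially flat over the box.
FIXED_EFFECT_SD = 100.0

#: Upper bound of the Uniform(0, 10) hyperprior on every scale parameter.
HYPER_SD_BOUND = 10.0

EFFECT_FAMILIES = ("o", "s", "sg", "c", "cg")
FIXED_EFFECTS = tuple(f"beta_{f}" for f in EFFECT_FAMILIES)
HYPER_SDS = tuple(f"sigma_{f}" for f in EFFECT_FAMILIES) + ("sigma_r",)

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)


def inv_logit(x):
    """Inverse logit 1 / (1 + exp(-x)); saturates gracefully at extreme x."""
    return expit(x)


def logit(p):
    """Log-odds log(p / (1 - p))."""
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def truncated_normal_logpdf(x, sd, bound: float = TRUNCATION_BOUND):
    """Log density of Normal(0, sd^2) truncated to [-bound, bound].

    Includes the normalizing constant log(2*Phi(bound/sd) - 1), which depends
    on ``sd`` and therefore matters when the scale itself is sampled.
    Returns -inf outside the truncation box.  Cross-checked against
    scipy.stats.truncnorm in the test suite; hand-rolled here so the sampler
    can evaluate vectorized density ratios cheaply.
    """
    x = np.asarray(x, dtype=float)
    if sd <= 0:
        return np.full(x.shape, -np.inf) if x.ndim else -np.inf
    # 2*Phi(b/sd) - 1 = erf(b / (sd*sqrt(2)))
    log_mass = math.log(erf(bound / (sd * _SQRT2)))
    out = -math.log(sd) - _LOG_SQRT_2PI - 0.5 * (x / sd) ** 2 - log_mass
    return np.where(np.abs(x) <= bound, out, -np.inf)


@dataclass
class ModelParameters:
    """One full state of the model's parameters (logit / SD scale)."""

    beta_o: float
    beta_s: float
    beta_sg: float
    beta_c: float
    beta_cg: float
    sigma_o: float
    sigma_s: float
    sigma_sg: float
    sigma_c: float
    sigma_cg: float
    sigma_r: float
    eps_o: np.ndarray
    eps_s: np.ndarray
    eps_sg: np.ndarray
    eps_c: np.ndarray
    eps_cg: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        for fam in EFFECT_FAMILIES:
            setattr(self, f"eps_{fam}", np.asarray(getattr(self, f"eps_{fam}"), float))
        self.r = np.asarray(self.r, dtype=float)
        S = self.eps_o.shape
        for fam in EFFECT_FAMILIES:
            if getattr(self, f"eps_{fam}").shape != S:
                raise ValueError("eps vectors must share one length (n_species)")

    @classmethod
    def zeros(cls, n_species: int, n_quadrats: int, **overrides) -> "ModelParameters":
        """All-zero effects with unit hyper-SDs; handy neutral starting state."""
        kw = dict(
            beta_o=0.0, beta_s=0.0, beta_sg=0.0, beta_c=0.0, beta_cg=0.0,
            sigma_o=1.0, sigma_s=1.0, sigma_sg=1.0, sigma_c=1.0, sigma_cg=1.0,
            sigma_r=1.0,
        )
        kw.update({f"eps_{f}": np.zeros(n_species) for f in EFFECT_FAMILIES})
        kw["r"] = np.zeros(n_quadrats)
        kw.update(overrides)
        return cls(**kw)

    @property
    def n_species(self) -> int:
        return self.eps_o.size

    @property
    def n_quadrats(self) -> int:
        return self.r.size

    def copy(self) -> "ModelParameters":
        return replace(
            self,
            **{f"eps_{f}": getattr(self, f"eps_{f}").copy() for f in EFFECT_FAMILIES},
            r=self.r.copy(),
        )

    def within_bounds(self, bound: float = TRUNCATION_BOUND) -> bool:
        """True iff every logit-scale effect lies inside the truncation box."""
        vals = [getattr(self, b) for b in FIXED_EFFECTS]
        if max(abs(v) for v in vals) > bound:
            return False
        for fam in EFFECT_FAMILIES:
            if np.abs(getattr(self, f"eps_{fam}")).max(initial=0.0) > bound:
                return False
        return np.abs(self.r).max(initial=0.0) <= bound


@dataclass
class ProbabilityField:
    """Per-cell probabilities implied by one parameter state."""

    psi1: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    psi2: np.ndarray


def _check_dims(params: ModelParameters, lattice: QuadratLattice, y1: np.ndarray):
    y1 = np.asarray(y1)
    if params.n_quadrats != lattice.n_quadrats:
        raise ValueError("params.r length does not match lattice")
    if y1.shape != (params.n_species, params.n_quadrats):
        raise ValueError(
            f"y1 shape {y1.shape} does not match (n_species={params.n_species}, "
            f"n_quadrats={params.n_quadrats})"
        )
    return y1


def linear_predictors(params: ModelParameters, lattice: QuadratLattice):
    """Logit-scale linear predictors (eta_psi1, eta_phi, eta_gamma), each (S, J)."""
    g = lattice.gap.astype(float)[None, :]
    eta1 = params.beta_o + params.eps_o[:, None] + params.r[None, :]
    eta_phi = params.beta_s + params.eps_s[:, None] + (params.beta_sg + params.eps_sg[:, None]) * g
    eta_gam = params.beta_c + params.eps_c[:, None] + (params.beta_cg + params.eps_cg[:, None]) * g
    return eta1, eta_phi, eta_gam


def compute_fields(
    params: ModelParameters, lattice: QuadratLattice, y1: np.ndarray
) -> ProbabilityField:
    """Evaluate psi1, phi, gamma and the mixture psi2 for every (species, quadrat)."""
    y1 = _check_dims(params, lattice, y1)
    eta1, eta_phi, eta_gam = linear_predictors(params, lattice)
    psi1, phi, gamma = expit(eta1), expit(eta_phi), expit(eta_gam)
    psi2 = np.where(y1 == 1, phi, gamma)
    return ProbabilityField(psi1=psi1, phi=phi, gamma=gamma, psi2=psi2)


def log_likelihood(
    params: ModelParameters, survey: PresenceAbsenceSurvey, lattice: QuadratLattice
) -> float:
    """Bernoulli log-likelihood of both census years.

    Computed on the logit scale via log_expit(s * eta) with s = 2y - 1, which
    stays finite for |eta| up to the truncation bound and far beyond.
    """
    y1 = _check_dims(params, lattice, survey.y1)
    y2 = np.asarray(survey.y2)
    eta1, eta_phi, eta_gam = linear_predictors(params, lattice)
    s1 = 2.0 * y1 - 1.0
    s2 = 2.0 * y2 - 1.0
    ll = log_expit(s1 * eta1).sum()
    eta2 = np.where(y1 == 1, eta_phi, eta_gam)
    ll += log_expit(s2 * eta2).sum()
    return float(ll)


def icar_log_density(
    r: np.ndarray, sigma_r: float, lattice: QuadratLattice
) -> float:
    """Joint ICAR log density of the spatial effect, up to an additive constant.

    The intrinsic model's joint kernel is the pairwise-difference form

        -(1 / (2 sigma_r^2)) * sum_{j<k} w_jk (r_j - r_k)^2
            - (J - 1) * log(sigma_r),

    whose full conditionals are Normal(sum_k w_jk r_k / w_j+, sigma_r^2 / w_j+)
    — the standard CAR conditional mean (neighbour average) and variance.  The
    quadratic form is r' L r with L the graph Laplacian; its rank J-1 on a
    connected lattice gives the scale exponent.
    """
    if sigma_r <= 0:
        return -np.inf
    if not lattice.is_connected():
        raise ValueError(
            "ICAR density requires a connected lattice (rank deficiency beyond "
            "the single sum-to-zero constraint is unsupported)"
        )
    r = np.asarray(r, dtype=float)
    if r.size != lattice.n_quadrats:
        raise ValueError("r length does not match lattice")
    quad = float(r @ (lattice.laplacian() @ r))
    J = lattice.n_quadrats
    return -(J - 1) * math.log(sigma_r) - quad / (2.0 * sigma_r**2)


def log_prior(params: ModelParameters, lattice: QuadratLattice) -> float:
    """Joint log prior of one parameter state.

    Fixed effects: Normal(0, 10^4) truncated to [-10, 10] (variance reading of
    the BUGS notation; effectively flat either way).  Species effects:
    Normal(0, sigma_*^2) T(-10, 10) with the sd-dependent truncation mass
    included.  Scales: Uniform(0, 10).  Spatial effect: ICAR.  Returns -inf
    for any effect outside the truncation box or any nonpositive/out-of-range
    scale (rejection semantics, not an exception).
    """
    for name in HYPER_SDS:
        s = getattr(params, name)
        if not (0.0 < s < HYPER_SD_BOUND):
            return -np.inf
    lp = 0.0
    for name in FIXED_EFFECTS:
        v = truncated_normal_logpdf(getattr(params, name), FIXED_EFFECT_SD)
        if not np.isfinite(v):
            return -np.inf
        lp += float(v)
    for fam in EFFECT_FAMILIES:
        vals = truncated_normal_logpdf(
            getattr(params, f"eps_{fam}"), getattr(params, f"sigma_{fam}")
        )
        if not np.all(np.isfinite(vals)):
            return -np.inf
        lp += float(np.sum(vals))
    if np.abs(params.r).max(initial=0.0) > TRUNCATION_BOUND:
        return -np.inf
    lp += icar_log_density(params.r, params.sigma_r, lattice)
    # Uniform(0, 10) hyperpriors contribute a constant -log(10) each
    lp += -len(HYPER_SDS) * math.log(HYPER_SD_BOUND)
    return lp
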