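"""Metropolis-within-Gibbs sampler for the dynamic occupancy model.

Each iteration sweeps, in a fixed order, through

1. the five fixed effects (scalar random-walk Metropolis),
2. the five species random-effect vectors (element-wise Metropolis; the
   elements are conditionally independent given the fixed effects, so the
   whole vector is proposed and accepted element-wise in one vectorized pass),
3. the spatial field r (element-wise Metropolis from the ICAR full
   conditional plus likelihood, swept over graph-colouring classes so that no
   two simultaneously updated quadrats are neighbours, then re-centred to
   sum to zero with beta_o absorbing the mean),
4. the six scale parameters (random-walk Metropolis on log sigma with the
   Jacobian correction).

Proposal scales adapt during burn-in by Robbins-Monro scaling toward a 0.44
acceptance rate and are frozen afterwards, so retained draws come from a
fixed kernel.  Runs are bit-reproducible: per-chain RNG streams are spawned
from the master seed with numpy's SeedSequence.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf, log_expit

from .data import PresenceAbsenceSurvey, QuadratLattice
from .model import (
    EFFECT_FAMILIES,
    FIXED_EFFECT_SD,
    FIXED_EFFECTS,
    HYPER_SD_BOUND,
    HYPER_SDS,
    TRUNCATION_BOUND,
    ModelParameters,
    log_likelihood,
    log_prior,
)

__all__ = [
    "SamplerConfig",
    "PosteriorSample",
    "run_chains",
    "adapt_step_size",
    "ALL_BLOCKS",
]

_EPS_BLOCKS = tuple(f"eps_{f}" for f in EFFECT_FAMILIES)
ALL_BLOCKS = FIXED_EFFECTS + _EPS_BLOCKS + ("r",) + HYPER_SDS

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration.

    Defaults follow the four-chain protocol of 13,000 iterations per chain
    with a 3,000-iteration burn-in and thinning interval 10, which retains
    1,000 draws per chain (4,000 in total).
    """

    n_chains: int = 4
    n_iter: int = 13_000
    burn_in: int = 3_000
    thin: int = 10
    seed: int = 0
    adapt: bool = True
    init_spread: float = 2.5

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.init_spread <= 0:
            raise ValueError("init_spread must be positive")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain: floor((n_iter - burn_in) / thin)."""
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSample:
    """Retained MCMC draws, (chain x draw x parameter), on the logit/SD scale."""

    draws: np.ndarray
    parameter_names: list[str]
    config: SamplerConfig

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chain, draw, parameter)")
        if self.draws.shape[2] != len(self.parameter_names):
            raise ValueError("parameter_names length must match draws")
        self._index = {n: i for i, n in enumerate(self.parameter_names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    @property
    def total_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter as a (chain, draw) array."""
        return self.draws[:, :, self._index[name]]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled over chains."""
        return self.get(name).ravel()

    def block(self, prefix: str) -> list[str]:
        """Parameter names belonging to one block, e.g. ``eps_o`` or ``r``."""
        return [n for n in self.parameter_names if n == prefix or n.startswith(prefix + "[")]

    def to_frame(self) -> pd.DataFrame:
        C, D, P = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(C * D, P), columns=self.parameter_names)
        df.insert(0, "draw", np.tile(np.arange(D), C))
        df.insert(0, "chain", np.repeat(np.arange(C), D))
        return df

    def to_csv(self, path) -> None:
        """Columnar, lossless serialization (config kept in a header comment)."""
        with open(path, "w") as fh:
            fh.write("# config: " + json.dumps(asdict(self.config)) + "\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "PosteriorSample":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# config:"):
                raise ValueError("missing config header line")
            config = SamplerConfig(**json.loads(header.split(":", 1)[1]))
            df = pd.read_csv(io.StringIO(fh.read()), float_precision="round_trip")
        names = [c for c in df.columns if c not in ("chain", "draw")]
        C = df["chain"].nunique()
        D = df["draw"].nunique()
        draws = df[names].to_numpy().reshape(C, D, len(names))
        return cls(draws=draws, parameter_names=names, config=config)


def adapt_step_size(
    scale: float, acceptance_rate: float, t: int, target: float = 0.44
) -> float:
    """Robbins-Monro update of a proposal scale toward a target acceptance rate.

    The log scale moves by ``t**-0.6 * (acceptance - target)``: acceptance
    above target widens the proposal, below target narrows it, and the
    adaptation gain decays so the scale settles.
    """
    gamma = min(1.0, t ** -0.6)
    return float(scale * math.exp(gamma * (acceptance_rate - target)))


def parameter_names(species_ids, quadrat_ids) -> list[str]:
    """Flat parameter layout shared by the sampler and the summaries."""
    names = list(FIXED_EFFECTS) + list(HYPER_SDS)
    for fam in EFFECT_FAMILIES:
        names += [f"eps_{fam}[{s}]" for s in species_ids]
    names += [f"r[{q}]" for q in quadrat_ids]
    return names


def _greedy_coloring(adjacency) -> list[np.ndarray]:
    """Partition quadrats into classes with no within-class neighbours."""
    lil = adjacency.tolil()
    J = adjacency.shape[0]
    color = np.full(J, -1, dtype=int)
    for j in range(J):
        used = {color[k] for k in lil.rows[j] if color[k] >= 0}
        c = 0
        while c in used:
            c += 1
        color[j] = c
    return [np.where(color == c)[0] for c in range(color.max() + 1)]


def _truncnorm_sum_logpdf(e: np.ndarray, sd: float) -> float:
    """Sum of truncated-normal log densities for a vector of in-bounds effects."""
    n = e.size
    log_mass = math.log(erf(TRUNCATION_BOUND / (sd * _SQRT2)))
    return -n * (math.log(sd) + _LOG_SQRT_2PI + log_mass) - float(e @ e) / (2.0 * sd**2)


class _ChainRunner:
    """State and update machinery for one chain."""

    def __init__(
        self,
        survey: PresenceAbsenceSurvey,
        lattice: QuadratLattice,
        config: SamplerConfig,
        rng: np.random.Generator,
        sample_blocks: frozenset,
        use_likelihood: bool,
        initial: ModelParameters | None,
    ):
        self.rng = rng
        self.cfg = config
        self.blocks = sample_blocks
        self.use_lik = use_likelihood
        self.S, self.J = survey.n_species, survey.n_quadrats
        self.g = lattice.gap.astype(float)
        self.W = lattice.adjacency.tocsr().astype(float)
        self.deg = lattice.neighbor_count.astype(float)
        self.L = lattice.laplacian()
        self.colors = _greedy_coloring(lattice.adjacency)
        self.survey, self.lattice = survey, lattice

        y1 = survey.y1.astype(float)
        y2 = survey.y2.astype(float)
        self.s1 = 2.0 * y1 - 1.0
        self.i1, self.j1 = np.nonzero(survey.y1 == 1)
        self.i0, self.j0 = np.nonzero(survey.y1 == 0)
        self.t2_1 = 2.0 * y2[self.i1, self.j1] - 1.0
        self.t2_0 = 2.0 * y2[self.i0, self.j0] - 1.0
        self.g1 = self.g[self.j1]
        self.g0 = self.g[self.j0]
        self.sel1g = np.where(self.g1 == 1.0)[0]
        self.sel0g = np.where(self.g0 == 1.0)[0]

        self._init_state(initial)
        self._refresh_caches()
        # translation (recentring) moves between an intercept/slope and its
        # random-effect family are run whenever both blocks are sampled: they
        # leave the likelihood invariant and decorrelate the slow
        # "intercept vs mean(eps)" direction of the hierarchy.
        self.shifts = tuple(
            f for f in EFFECT_FAMILIES
            if f"beta_{f}" in self.blocks and f"eps_{f}" in self.blocks
        )
        active = [b for b in ALL_BLOCKS if b in self.blocks]
        active += [f"shift_{f}" for f in self.shifts]
        self.active = active
        self.scales = {
            b: (0.3 if b.startswith(("beta", "sigma", "shift")) else 0.5)
            for b in active
        }
        self.acc_count = {b: 0.0 for b in active}

    # -- state ----------------------------------------------------------

    def _init_state(self, initial: ModelParameters | None) -> None:
        base = initial.copy() if initial is not None else ModelParameters.zeros(self.S, self.J)
        for attempt in range(100):
            p = base.copy()
            spread = self.cfg.init_spread
            for b in FIXED_EFFECTS:
                if b in self.blocks:
                    setattr(p, b, float(np.clip(
                        self.rng.uniform(-spread, spread),
                        -TRUNCATION_BOUND, TRUNCATION_BOUND,
                    )))
            for b in HYPER_SDS:
                if b in self.blocks:
                    setattr(p, b, float(self.rng.uniform(0.1, min(spread, HYPER_SD_BOUND))))
            lp = log_prior(p, self.lattice)
            if self.use_lik and np.isfinite(lp):
                lp += log_likelihood(p, self.survey, self.lattice)
            if np.isfinite(lp):
                self.p = p
                return
        raise RuntimeError("could not find a finite-target initial state in 100 attempts")

    def _refresh_caches(self) -> None:
        self.quad = float(self.p.r @ (self.L @ self.p.r))
        if not self.use_lik:
            return
        p = self.p
        self.L1 = p.beta_o + p.eps_o[:, None] + p.r[None, :]
        self.M1 = log_expit(self.s1 * self.L1)
        self.ls = p.beta_s + p.eps_s[self.i1] + (p.beta_sg + p.eps_sg[self.i1]) * self.g1
        self.ms = log_expit(self.t2_1 * self.ls)
        self.lc = p.beta_c + p.eps_c[self.i0] + (p.beta_cg + p.eps_cg[self.i0]) * self.g0
        self.mc = log_expit(self.t2_0 * self.lc)

    # -- scalar fixed effects -------------------------------------------

    def _update_beta(self, name: str) -> None:
        x = getattr(self.p, name)
        prop = x + self.scales[name] * self.rng.standard_normal()
        acc = 0.0
        if abs(prop) <= TRUNCATION_BOUND:
            delta = prop - x
            dl = (x * x - prop * prop) / (2.0 * FIXED_EFFECT_SD**2)
            if self.use_lik:
                if name == "beta_o":
                    Mp = log_expit(self.s1 * (self.L1 + delta))
                    dl += float(Mp.sum() - self.M1.sum())
                elif name == "beta_s":
                    mp = log_expit(self.t2_1 * (self.ls + delta))
                    dl += float(mp.sum() - self.ms.sum())
                elif name == "beta_sg":
                    sel = self.sel1g
                    mp = log_expit(self.t2_1[sel] * (self.ls[sel] + delta))
                    dl += float(mp.sum() - self.ms[sel].sum())
                elif name == "beta_c":
                    mp = log_expit(self.t2_0 * (self.lc + delta))
                    dl += float(mp.sum() - self.mc.sum())
                else:  # beta_cg
                    sel = self.sel0g
                    mp = log_expit(self.t2_0[sel] * (self.lc[sel] + delta))
                    dl += float(mp.sum() - self.mc[sel].sum())
            if math.log(self.rng.random()) < dl:
                acc = 1.0
                setattr(self.p, name, prop)
                if self.use_lik:
                    if name == "beta_o":
                        self.L1 += delta
                        self.M1 = Mp
                    elif name == "beta_s":
                        self.ls += delta
                        self.ms = mp
                    elif name == "beta_sg":
                        self.ls[self.sel1g] += delta
                        self.ms[self.sel1g] = mp
                    elif name == "beta_c":
                        self.lc += delta
                        self.mc = mp
                    else:
                        self.lc[self.sel0g] += delta
                        self.mc[self.sel0g] = mp
        self.acc_count[name] = acc

    # -- species random-effect vectors ----------------------------------

    def _update_eps(self, fam: str) -> None:
        name = f"eps_{fam}"
        e = getattr(self.p, name)
        sd = getattr(self.p, f"sigma_{fam}")
        prop = e + self.scales[name] * self.rng.standard_normal(self.S)
        inb = np.abs(prop) <= TRUNCATION_BOUND
        dl = (e * e - prop * prop) / (2.0 * sd * sd)
        if self.use_lik:
            d = prop - e
            if fam == "o":
                Lp = self.L1 + d[:, None]
                Mp = log_expit(self.s1 * Lp)
                dl = dl + (Mp.sum(axis=1) - self.M1.sum(axis=1))
            elif fam in ("s", "sg"):
                dc = d[self.i1] if fam == "s" else d[self.i1] * self.g1
                lp_ = self.ls + dc
                mp = log_expit(self.t2_1 * lp_)
                dl = dl + np.bincount(self.i1, weights=mp - self.ms, minlength=self.S)
            else:  # "c", "cg"
                dc = d[self.i0] if fam == "c" else d[self.i0] * self.g0
                lp_ = self.lc + dc
                mp = log_expit(self.t2_0 * lp_)
                dl = dl + np.bincount(self.i0, weights=mp - self.mc, minlength=self.S)
        acc = inb & (np.log(self.rng.random(self.S)) < dl)
        if acc.any():
            e[acc] = prop[acc]
            if self.use_lik:
                if fam == "o":
                    self.L1[acc] = Lp[acc]
                    self.M1[acc] = Mp[acc]
                elif fam in ("s", "sg"):
                    cells = acc[self.i1]
                    self.ls[cells] = lp_[cells]
                    self.ms[cells] = mp[cells]
                else:
                    cells = acc[self.i0]
                    self.lc[cells] = lp_[cells]
                    self.mc[cells] = mp[cells]
        self.acc_count[name] = float(acc.mean())

    def _update_shift(self, fam: str) -> None:
        """Joint translation beta_f + d, eps_f - d (likelihood-invariant)."""
        key = f"shift_{fam}"
        b = getattr(self.p, f"beta_{fam}")
        e = getattr(self.p, f"eps_{fam}")
        sd = getattr(self.p, f"sigma_{fam}")
        d = self.scales[key] * self.rng.standard_normal()
        bp, ep = b + d, e - d
        acc = 0.0
        if abs(bp) <= TRUNCATION_BOUND and np.abs(ep).max(initial=0.0) <= TRUNCATION_BOUND:
            dl = (b * b - bp * bp) / (2.0 * FIXED_EFFECT_SD**2)
            dl += (float(e @ e) - float(ep @ ep)) / (2.0 * sd * sd)
            if math.log(self.rng.random()) < dl:
                acc = 1.0
                setattr(self.p, f"beta_{fam}", bp)
                setattr(self.p, f"eps_{fam}", ep)
        self.acc_count[key] = acc

    # -- spatial field ---------------------------------------------------

    def _update_r(self) -> None:
        p = self.p
        sr2 = p.sigma_r * p.sigma_r
        n_acc, n_tot = 0.0, 0
        for C in self.colors:
            rC = p.r[C]
            delta = self.scales["r"] * self.rng.standard_normal(C.size)
            prop = rC + delta
            inb = np.abs(prop) <= TRUNCATION_BOUND
            nbr = self.W[C].dot(p.r)
            dl = -(self.deg[C] * (prop * prop - rC * rC) - 2.0 * delta * nbr) / (2.0 * sr2)
            if self.use_lik:
                LpC = self.L1[:, C] + delta[None, :]
                MpC = log_expit(self.s1[:, C] * LpC)
                dl = dl + (MpC.sum(axis=0) - self.M1[:, C].sum(axis=0))
            acc = inb & (np.log(self.rng.random(C.size)) < dl)
            if acc.any():
                idx = C[acc]
                p.r[idx] = prop[acc]
                if self.use_lik:
                    self.L1[:, idx] = LpC[:, acc]
                    self.M1[:, idx] = MpC[:, acc]
            n_acc += float(acc.sum())
            n_tot += C.size
        # re-centre: translate (r, beta_o) along the likelihood-invariant
        # direction; exact for the ICAR kernel, negligible for the flat
        # beta_o prior.  Skipped if it would leave the truncation box.
        m = float(p.r.mean())
        if (
            abs(p.beta_o + m) <= TRUNCATION_BOUND
            and np.abs(p.r - m).max(initial=0.0) <= TRUNCATION_BOUND
        ):
            p.r -= m
            p.beta_o += m
        self.quad = float(p.r @ (self.L @ p.r))
        self.acc_count["r"] = n_acc / max(n_tot, 1)

    # -- scale parameters ------------------------------------------------

    def _update_sigma(self, name: str) -> None:
        s = getattr(self.p, name)
        prop = s * math.exp(self.scales[name] * self.rng.standard_normal())
        acc = 0.0
        if 0.0 < prop < HYPER_SD_BOUND:
            if name == "sigma_r":
                J = self.J
                dl = (
                    -(J - 1) * math.log(prop) - self.quad / (2.0 * prop * prop)
                    + (J - 1) * math.log(s) + self.quad / (2.0 * s * s)
                )
            else:
                e = getattr(self.p, "eps_" + name.split("_", 1)[1])
                dl = _truncnorm_sum_logpdf(e, prop) - _truncnorm_sum_logpdf(e, s)
            dl += math.log(prop) - math.log(s)  # Jacobian of the log-scale walk
            if math.log(self.rng.random()) < dl:
                acc = 1.0
                setattr(self.p, name, prop)
        self.acc_count[name] = acc

    # -- sweep -----------------------------------------------------------

    def sweep(self, t: int, adapting: bool) -> None:
        for b in FIXED_EFFECTS:
            if b in self.blocks:
                self._update_beta(b)
        for fam in EFFECT_FAMILIES:
            if f"eps_{fam}" in self.blocks:
                self._update_eps(fam)
        for fam in self.shifts:
            self._update_shift(fam)
        if "r" in self.blocks:
            self._update_r()
        for b in HYPER_SDS:
            if b in self.blocks:
                self._update_sigma(b)
        if adapting:
            for b in self.active:
                self.scales[b] = adapt_step_size(self.scales[b], self.acc_count[b], t)

    def pack(self) -> np.ndarray:
        p = self.p
        return np.concatenate(
            [
                [getattr(p, b) for b in FIXED_EFFECTS],
                [getattr(p, b) for b in HYPER_SDS],
                *[getattr(p, f"eps_{f}") for f in EFFECT_FAMILIES],
                p.r,
            ]
        )


def run_chains(
    survey: PresenceAbsenceSurvey,
    lattice: QuadratLattice,
    config: SamplerConfig,
    *,
    initial: ModelParameters | None = None,
    sample_blocks=None,
    use_likelihood: bool = True,
) -> PosteriorSample:
    """Run the Metropolis-within-Gibbs sampler and return the retained draws.

    Parameters
    ----------
    survey, lattice
        The (already species-filtered) data; the lattice must be connected.
    config
        Chain count, iteration budget, burn-in, thinning, seed, adaptation.
    initial
        Starting state for blocks that are *not* sampled (defaults to the
        neutral all-zero state with unit scales).  Sampled fixed effects and
        scales are over-dispersed uniformly per chain; eps and r start at
        their ``initial`` values (zero by default).
    sample_blocks
        Subset of :data:`ALL_BLOCKS` to update; ``None`` updates everything.
        Blocks left out stay fixed — used for reductions such as prior-only
        sampling or single-parameter oracle checks.
    use_likelihood
        If False the sampler targets the prior alone (prior-recovery checks).
    """
    if sample_blocks is None:
        blocks = frozenset(ALL_BLOCKS)
    else:
        blocks = frozenset(sample_blocks)
        unknown = blocks - set(ALL_BLOCKS)
        if unknown:
            raise ValueError(f"unknown sampler blocks: {sorted(unknown)}")
    if use_likelihood and "r" in blocks and not lattice.is_connected():
        raise ValueError("lattice must be connected")

    names = parameter_names(survey.species_ids, survey.quadrat_ids)
    n_ret = config.n_retained
    draws = np.empty((config.n_chains, n_ret, len(names)))
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        runner = _ChainRunner(
            survey, lattice, config, rng, blocks, use_likelihood, initial
        )
        d = 0
        for t in range(1, config.n_iter + 1):
            runner.sweep(t, adapting=config.adapt and t <= config.burn_in)
            if t > config.burn_in and (t - config.burn_in) % config.thin == 0:
                if d < n_ret:
                    draws[c, d] = runner.pack()
                    d += 1
    return PosteriorSample(draws=draws, parameter_names=names, config=config)
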